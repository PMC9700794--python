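import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from socialdrift.cohort import CohortConfig, generate_cohort
from socialdrift.data import PIPD_MATRIX, RoundRecord, TreatmentSpec


@pytest.fixture(scope="session")
def pipd_spec():
    return TreatmentSpec("PIPD_f", "pairwise", "fixed", PIPD_MATRIX, n_rounds=21)


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed pairwise cohort with ground truth, shared across tests."""
    spec = TreatmentSpec("PIPD_t", "pairwise", "shuffled", PIPD_MATRIX, n_rounds=25)
    config = CohortConfig(
        treatment=spec,
        mixture={"ALL_C": 0.3, "ALL_D": 0.3, "CONDITIONAL": 0.4},
        n_participants=20,
        n_rounds=25,
        seed=9,
    )
    return generate_cohort(config)


def make_records(actions_contexts, pid="p1", tid="T", n_coplayers=1, rt=0.8):
    """RoundRecords from (action, context) pairs; context None for round 1."""
    return [
        RoundRecord(pid, tid, i + 1, act, rt, n_coplayers, ctx)
        for i, (act, ctx) in enumerate(actions_contexts)
    ]
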