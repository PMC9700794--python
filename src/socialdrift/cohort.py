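"""Synthetic cohorts: agents on game topologies deciding via diffusion.

Every choice and response time in a generated cohort comes from a single
drift-diffusion trial, so RT and action are jointly coherent by
construction.  Agents belong to behavioural archetypes:

* ``ALL_C`` — unconditional cooperators: positive base drift.
* ``ALL_D`` — unconditional defectors: negative base drift and (by default)
  a wider decision boundary, i.e. they perceive the task as harder.
* ``CONDITIONAL`` — reciprocators: drift g·(2 f_C − 1) where f_C is the
  fraction of co-players that cooperated last round, so their drift
  averages near zero over balanced contexts.

The generator is a test harness with the statistical structure the
analysis assumes (archetype mixtures are not a claim about real cohorts):
it lets the whole pipeline — context derivation, RA°, fitting,
correlations — run end-to-end with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import (
    MNIPD_MATRIX,
    N_COPLAYERS,
    PIPD_MATRIX,
    VNNIPD_MATRIX,
    RoundRecord,
    TreatmentSpec,
)
from .ddm import PARAM_BOUNDS, simulate_first_passage

__all__ = [
    "Archetype",
    "CohortConfig",
    "CohortData",
    "DEFAULT_ARCHETYPES",
    "build_topology",
    "generate_cohort",
    "default_experiment_configs",
]

#: clip ranges for sampled agent parameters (the fitting prior box)
_A_RANGE = PARAM_BOUNDS["a"]
_Z_RANGE = PARAM_BOUNDS["z"]
_T0_RANGE = (0.05, 0.8)
_V_RANGE = PARAM_BOUNDS["v"]

_SIM_DT = 1e-3
_SIM_MAX_T = 30.0
_RETRY_CAP = 5


@dataclass(frozen=True)
class Archetype:
    """Distribution of diffusion parameters for one behavioural type.

    ``v_mean`` is the context-independent drift component and
    ``gain_mean`` the context sensitivity g: an agent's drift in a round
    with cooperating fraction f is v + g·(2f − 1).
    """

    name: str
    p_coop_first_round: float
    v_mean: float
    v_sd: float
    a_mean: float
    a_sd: float
    z_mean: float = 0.5
    z_sd: float = 0.05
    t0_mean: float = 0.3
    t0_sd: float = 0.05
    gain_mean: float = 0.0
    gain_sd: float = 0.0


#: study-condition defaults: unconditional types drift fast toward their
#: preference; defectors carry the widest boundary (highest perceived
#: difficulty); conditional agents have zero base drift and unit context gain.
DEFAULT_ARCHETYPES: dict[str, Archetype] = {
    "ALL_C": Archetype(
        name="ALL_C", p_coop_first_round=0.9,
        v_mean=1.5, v_sd=0.3, a_mean=1.2, a_sd=0.2, z_mean=0.55,
    ),
    "ALL_D": Archetype(
        name="ALL_D", p_coop_first_round=0.1,
        v_mean=-1.5, v_sd=0.3, a_mean=2.0, a_sd=0.3, z_mean=0.45,
    ),
    "CONDITIONAL": Archetype(
        name="CONDITIONAL", p_coop_first_round=0.5,
        v_mean=0.0, v_sd=0.1, a_mean=1.6, a_sd=0.25, z_mean=0.5,
        gain_mean=1.0, gain_sd=0.2,
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic treatment."""

    treatment: TreatmentSpec
    mixture: Mapping[str, float]
    n_participants: int
    n_rounds: int = 21  # 1 context-seeding round + 20 scoreable
    seed: int = 0
    archetypes: Mapping[str, Archetype] = field(default_factory=lambda: DEFAULT_ARCHETYPES)
    notes: str = ""

    def __post_init__(self):
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions must sum to 1, got {total}")
        if self.n_rounds < 21:
            raise ValueError("need n_rounds >= 21 (20 scoreable + 1 context-seeding)")
        unknown = set(self.mixture) - set(self.archetypes)
        if unknown:
            raise ValueError(f"mixture names not in archetypes: {sorted(unknown)}")


@dataclass(frozen=True)
class CohortData:
    """Generated records plus the ground truth behind them."""

    records: list[RoundRecord]
    ground_truth: pd.DataFrame  # participant_id, archetype, true_a, true_v_base, ...
    flagged: list[tuple[str, int]]  # (participant_id, round) of truncated walks
    config: CohortConfig


def build_topology(
    kind: str, n_participants: int, rng: np.random.Generator | None = None
) -> dict[int, list[int]]:
    """Adjacency for one round: disjoint pairs or a periodic square lattice.

    Pairwise needs even n (a perfect matching, random when ``rng`` given);
    lattices need n a perfect square and give every node exactly 8 (Moore)
    or 4 (von Neumann) neighbours thanks to periodic boundaries.
    """
    n = n_participants
    if kind == "pairwise":
        if n % 2:
            raise ValueError(f"pairwise topology needs even n, got {n}")
        order = rng.permutation(n) if rng is not None else np.arange(n)
        adj: dict[int, list[int]] = {}
        for i in range(0, n, 2):
            a, b = int(order[i]), int(order[i + 1])
            adj[a] = [b]
            adj[b] = [a]
        return adj
    if kind in ("moore", "von_neumann"):
        side = math.isqrt(n)
        if side * side != n:
            raise ValueError(f"{kind} lattice needs a perfect-square n, got {n}")
        if kind == "moore":
            offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
        else:
            offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        # optional random placement of participants on lattice nodes
        place = rng.permutation(n) if rng is not None else np.arange(n)
        node_of = {int(place[i]): i for i in range(n)}
        adj = {}
        for pid in range(n):
            node = node_of[pid]
            r, c = divmod(node, side)
            adj[pid] = [
                int(place[((r + dr) % side) * side + (c + dc) % side]) for dr, dc in offsets
            ]
        return adj
    raise ValueError(f"unknown topology kind {kind!r}")


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_agents(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    names = sorted(config.mixture)
    counts = {k: int(round(config.mixture[k] * n)) for k in names}
    # fix rounding drift on the largest group
    drift = n - sum(counts.values())
    counts[max(names, key=lambda k: config.mixture[k])] += drift
    labels = np.repeat([k for k in names], [counts[k] for k in names])
    rng.shuffle(labels)
    rows = []
    for name in names:
        arch = config.archetypes[name]
        idx = np.flatnonzero(labels == name)
        k = idx.size
        a = _truncnorm(rng, arch.a_mean, arch.a_sd, *_A_RANGE, size=k)
        v = _truncnorm(rng, arch.v_mean, arch.v_sd, *_V_RANGE, size=k)
        z = _truncnorm(rng, arch.z_mean, arch.z_sd, *_Z_RANGE, size=k)
        t0 = _truncnorm(rng, arch.t0_mean, arch.t0_sd, *_T0_RANGE, size=k)
        g = np.maximum(_truncnorm(rng, arch.gain_mean, arch.gain_sd, 0.0, 5.0, size=k), 0.0)
        for j, i in enumerate(idx):
            rows.append(
                {
                    "participant_id": f"p{i:04d}",
                    "archetype": name,
                    "true_a": a[j],
                    "true_v_base": v[j],
                    "true_z": z[j],
                    "true_t0": t0[j],
                    "true_gain": g[j],
                    "p_coop_first_round": arch.p_coop_first_round,
                }
            )
    gt = pd.DataFrame(rows).sort_values("participant_id").reset_index(drop=True)
    return gt


def _simulate_round(a, v, z, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One decision per agent; truncated walks are re-drawn up to a cap."""
    up, t_dec, trunc = simulate_first_passage(a, v, z, rng, _SIM_DT, _SIM_MAX_T)
    tries = 0
    while trunc.any() and tries < _RETRY_CAP:
        idx = np.flatnonzero(trunc)
        u2, t2, tr2 = simulate_first_passage(a[idx], v[idx], z[idx], rng, _SIM_DT, _SIM_MAX_T)
        up[idx], t_dec[idx], trunc[idx] = u2, t2, tr2
        tries += 1
    return up, t_dec, trunc


def generate_cohort(config: CohortConfig) -> CohortData:
    """Simulate one full treatment; fully reproducible from ``config.seed``.

    Round 1 actions are drawn from each archetype's cooperation
    probability (their RTs come from diffusion trials rejection-matched to
    the drawn action); each later decision is one diffusion trial under the
    agent's context-adjusted drift.  Shuffled schemes re-wire the topology
    every round.
    """
    rng = np.random.default_rng(config.seed)
    spec = config.treatment
    gt = _sample_agents(config, rng)
    n = config.n_participants
    pids = gt["participant_id"].to_numpy()
    a = gt["true_a"].to_numpy()
    v_base = gt["true_v_base"].to_numpy()
    z = gt["true_z"].to_numpy()
    t0 = gt["true_t0"].to_numpy()
    gain = gt["true_gain"].to_numpy()
    n_co = spec.n_coplayers

    fixed_adj = build_topology(spec.topology, n, rng)
    records: list[RoundRecord] = []
    flagged: list[tuple[str, int]] = []

    # round 1: archetype-driven actions; RTs from neutral-context diffusion
    # trials, resampled until the boundary matches the drawn action
    target_up = rng.random(n) < gt["p_coop_first_round"].to_numpy()
    up, t_dec, trunc = _simulate_round(a, v_base, z, rng)
    pending = np.flatnonzero((up != target_up) | trunc)
    for _ in range(20):
        if pending.size == 0:
            break
        u2, t2, tr2 = _simulate_round(a[pending], v_base[pending], z[pending], rng)
        up[pending], t_dec[pending], trunc2 = u2, t2, tr2
        pending = pending[(u2 != target_up[pending]) | tr2]
    up[pending] = target_up[pending]  # force stragglers to the drawn action
    actions = np.where(target_up, "C", "D")
    for i in range(n):
        records.append(
            RoundRecord(pids[i], spec.treatment_id, 1, actions[i], float(t_dec[i] + t0[i]), n_co, None)
        )

    prev_actions = actions
    for rnd in range(2, config.n_rounds + 1):
        adj = (
            build_topology(spec.topology, n, rng)
            if spec.partner_scheme == "shuffled"
            else fixed_adj
        )
        context = np.array(
            [sum(prev_actions[nb] == "C" for nb in adj[i]) for i in range(n)], dtype=int
        )
        f_c = context / n_co
        v_round = np.clip(v_base + gain * (2.0 * f_c - 1.0), *_V_RANGE)
        up, t_dec, trunc = _simulate_round(a, v_round, z, rng)
        actions = np.where(up, "C", "D")
        for i in range(n):
            records.append(
                RoundRecord(
                    pids[i], spec.treatment_id, rnd, actions[i],
                    float(t_dec[i] + t0[i]), n_co, int(context[i]),
                )
            )
            if trunc[i]:
                flagged.append((pids[i], rnd))
        prev_actions = actions

    records.sort(key=lambda r: (r.participant_id, r.round))
    return CohortData(records=records, ground_truth=gt, flagged=flagged, config=config)


def default_experiment_configs(seed: int = 0) -> dict[str, CohortConfig]:
    """Six treatment configs mirroring the three experiments.

    Treatment sizes follow the source cohorts (PIPD fixed n=58 / shuffled
    n=96; Moore-lattice fixed and shuffled n=169; von Neumann informed
    n=50 and uninformed n=59, rounded to the nearest perfect squares 49
    and 64 for the periodic lattice — noted in the config).  Archetype
    mixtures are chosen to reproduce the qualitative RA° shapes: pairwise
    fixed concentrates near 45°, the weak-matrix Moore experiments pile up
    defectors near 0°, the von Neumann experiments centre near 45°.
    """
    pipd = lambda tid, scheme, nr: TreatmentSpec(tid, "pairwise", scheme, PIPD_MATRIX, n_rounds=nr)
    out = {
        "PIPD_f": CohortConfig(
            treatment=pipd("PIPD_f", "fixed", 21),
            mixture={"CONDITIONAL": 0.55, "ALL_C": 0.25, "ALL_D": 0.20},
            n_participants=58, seed=seed,
        ),
        "PIPD_s": CohortConfig(
            treatment=pipd("PIPD_s", "shuffled", 21),
            mixture={"CONDITIONAL": 0.40, "ALL_C": 0.25, "ALL_D": 0.35},
            n_participants=96, seed=seed + 1,
        ),
        "mNIPD_f": CohortConfig(
            treatment=TreatmentSpec("mNIPD_f", "moore", "fixed", MNIPD_MATRIX, n_rounds=21),
            mixture={"CONDITIONAL": 0.35, "ALL_C": 0.20, "ALL_D": 0.45},
            n_participants=169, seed=seed + 2,
        ),
        "mNIPD_s": CohortConfig(
            treatment=TreatmentSpec("mNIPD_s", "moore", "shuffled", MNIPD_MATRIX, n_rounds=21),
            mixture={"CONDITIONAL": 0.30, "ALL_C": 0.20, "ALL_D": 0.50},
            n_participants=169, seed=seed + 3,
        ),
        "vnNIPD_i": CohortConfig(
            treatment=TreatmentSpec(
                "vnNIPD_i", "von_neumann", "fixed", VNNIPD_MATRIX,
                info_condition="payoffs_shown", n_rounds=21,
            ),
            mixture={"CONDITIONAL": 0.50, "ALL_C": 0.30, "ALL_D": 0.20},
            n_participants=49, seed=seed + 4,
            notes="source cohort n=50 rounded to 49 (7x7 periodic lattice)",
        ),
        "vnNIPD_o": CohortConfig(
            treatment=TreatmentSpec(
                "vnNIPD_o", "von_neumann", "fixed", VNNIPD_MATRIX,
                info_condition="payoffs_hidden", n_rounds=21,
            ),
            mixture={"CONDITIONAL": 0.50, "ALL_C": 0.30, "ALL_D": 0.20},
            n_participants=64, seed=seed + 5,
            notes="source cohort n=59 rounded to 64 (8x8 periodic lattice)",
        ),
    }
    return out
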