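"""Relative Allocation angle (RA°): a proxy for social value orientation.

Each decision implies a *planned allocation* of payoff to self and to the
co-players, assuming the co-players repeat their previous-round actions
(the context ``c``).  Averaging the normalized allocations over the first
scoreable rounds places every participant at a point (ā_self, ā_other) in
the unit square; the angle from the origin,

    RA° = arctan(ā_other / ā_self),

summarises their social preference: near 0° — unconditional defection
against cooperators (individualistic), near 45° — conditional play with
equal allocation, near 90° — unconditional cooperation against defectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .data import PayoffMatrix, RoundRecord, TreatmentSpec

__all__ = [
    "RAResult",
    "InsufficientDataError",
    "planned_allocation",
    "ra_angle",
    "cohort_ra",
]

#: default number of scoreable rounds entering the angle
DEFAULT_N_ROUNDS = 20
#: minimum scoreable rounds before an insufficient-data error
DEFAULT_MIN_ROUNDS = 10


class InsufficientDataError(ValueError):
    """Fewer scoreable rounds than the configured minimum."""


@dataclass(frozen=True)
class RAResult:
    """Mean planned allocations and the resulting angle for one participant.

    ``angle_deg`` is ``None`` (``defined=False``) when both mean allocations
    are exactly zero, where no principled angle exists.
    """

    participant_id: str
    a_self_mean: float
    a_other_mean: float
    angle_deg: float | None
    n_rounds_used: int

    @property
    def defined(self) -> bool:
        return self.angle_deg is not None


def planned_allocation(
    action: str, context: int, n_coplayers: int, matrix: PayoffMatrix
) -> tuple[float, float]:
    """Normalized payoff planned for self and (on average) for each co-player.

    Co-players are assumed to repeat their previous-round action: ``context``
    of them play C, the rest play D.  Both returns lie in [0, 1].
    """
    if not matrix.normalized:
        raise ValueError("matrix must be normalized; see normalize_payoffs")
    if not 0 <= context <= n_coplayers:
        raise ValueError(f"context {context} outside [0, {n_coplayers}]")
    n_c, n_d = context, n_coplayers - context
    a_self = (
        n_c * matrix.payoff(action, "C") + n_d * matrix.payoff(action, "D")
    ) / n_coplayers
    a_other = (
        n_c * matrix.payoff("C", action) + n_d * matrix.payoff("D", action)
    ) / n_coplayers
    return a_self, a_other


def ra_angle(
    records: Sequence[RoundRecord],
    matrix: PayoffMatrix,
    n_rounds: int = DEFAULT_N_ROUNDS,
    min_rounds: int = DEFAULT_MIN_ROUNDS,
) -> RAResult:
    """RA° of one participant from their first ``n_rounds`` scoreable records.

    Scoreable records are those with a defined context (round 1 has none).
    The angle is taken via atan2 so that ā_self = 0 maps to 90°; the (0, 0)
    corner is reported undefined rather than imputed.
    """
    recs = sorted((r for r in records if r.context is not None), key=lambda r: r.round)
    recs = recs[:n_rounds]
    if len(recs) < min_rounds:
        pid = records[0].participant_id if records else "?"
        raise InsufficientDataError(
            f"participant {pid}: {len(recs)} scoreable rounds < minimum {min_rounds}"
        )
    pairs = [
        planned_allocation(r.action, r.context, r.n_coplayers, matrix) for r in recs
    ]
    a_self = sum(p[0] for p in pairs) / len(pairs)
    a_other = sum(p[1] for p in pairs) / len(pairs)
    if a_self == 0.0 and a_other == 0.0:
        angle = None
    else:
        angle = math.degrees(math.atan2(a_other, a_self))
    return RAResult(
        participant_id=recs[0].participant_id,
        a_self_mean=a_self,
        a_other_mean=a_other,
        angle_deg=angle,
        n_rounds_used=len(recs),
    )


def cohort_ra(
    records: Iterable[RoundRecord],
    spec: TreatmentSpec,
    n_rounds: int = DEFAULT_N_ROUNDS,
    min_rounds: int = DEFAULT_MIN_ROUNDS,
) -> pd.DataFrame:
    """RA° for every participant in a cohort.

    Returns one row per participant with columns participant_id,
    treatment_id, a_self_mean, a_other_mean, ra_angle_deg, n_rounds_used,
    defined.  Undefined angles are flagged, never dropped.
    """
    by_pid: dict[str, list[RoundRecord]] = {}
    for r in records:
        by_pid.setdefault(r.participant_id, []).append(r)
    rows = []
    for pid in sorted(by_pid):
        res = ra_angle(by_pid[pid], spec.payoff_matrix, n_rounds, min_rounds)
        rows.append(
            {
                "participant_id": pid,
                "treatment_id": spec.treatment_id,
                "a_self_mean": res.a_self_mean,
                "a_other_mean": res.a_other_mean,
                "ra_angle_deg": res.angle_deg,
                "n_rounds_used": res.n_rounds_used,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)
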