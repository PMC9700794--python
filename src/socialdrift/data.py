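"""Domain types and I/O for iterated Prisoner's Dilemma experiment records.

The experiments modelled here are repeated two-action (cooperate/defect)
dilemma games played either pairwise or on a square lattice (Moore
neighbourhood, 8 neighbours, or von Neumann neighbourhood, 4 neighbours).
Each decision is stored as one :class:`RoundRecord` carrying the action, the
response time, and the decision *context* ``c`` — the number of co-players
that cooperated in the previous round, which is the information a
participant holds when deciding.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PayoffMatrix",
    "TreatmentSpec",
    "RoundRecord",
    "ValidationError",
    "DegenerateMatrixError",
    "PIPD_MATRIX",
    "VNNIPD_MATRIX",
    "MNIPD_MATRIX",
    "N_COPLAYERS",
    "RECORD_COLUMNS",
    "normalize_payoffs",
    "is_strong_dilemma",
    "load_records",
    "write_records",
    "records_to_frame",
    "derive_context",
]

#: co-player count implied by each topology
N_COPLAYERS = {"pairwise": 1, "moore": 8, "von_neumann": 4}

#: canonical record CSV column order
RECORD_COLUMNS = [
    "participant_id",
    "treatment_id",
    "round",
    "action",
    "rt",
    "n_coplayers",
    "context",
]


class ValidationError(ValueError):
    """Raised when experiment records violate the schema; lists offending rows."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("invalid records:\n" + "\n".join(self.messages))


class DegenerateMatrixError(ValueError):
    """All four payoffs equal — min–max normalization is undefined."""


@dataclass(frozen=True)
class PayoffMatrix:
    """Payoffs of one treatment: temptation T, reward R, punishment P, sucker S.

    ``*_n`` fields hold the min–max normalized images in [0, 1]; they are
    ``None`` until :func:`normalize_payoffs` populates them.  A *strong*
    dilemma satisfies T > R > P > S and 2R > T + S.
    """

    T: float
    R: float
    P: float
    S: float
    T_n: float | None = None
    R_n: float | None = None
    P_n: float | None = None
    S_n: float | None = None

    @property
    def normalized(self) -> bool:
        return self.T_n is not None

    def payoff(self, own: str, other: str, normalized: bool = True) -> float:
        """Payoff to the focal player for action pair (own, other)."""
        if normalized and not self.normalized:
            raise ValueError("matrix has no normalized payoffs; call normalize_payoffs")
        key = {
            ("C", "C"): "R",
            ("C", "D"): "S",
            ("D", "C"): "T",
            ("D", "D"): "P",
        }[(own, other)]
        return getattr(self, key + "_n" if normalized else key)


def normalize_payoffs(matrix: PayoffMatrix) -> PayoffMatrix:
    """Min–max normalize {T, R, P, S} to [0, 1], preserving their proportions.

    Raises :class:`DegenerateMatrixError` when all four payoffs coincide.
    """
    vals = (matrix.T, matrix.R, matrix.P, matrix.S)
    lo, hi = min(vals), max(vals)
    if hi == lo:
        raise DegenerateMatrixError(f"all payoffs equal ({lo}); cannot normalize")
    t_n, r_n, p_n, s_n = ((x - lo) / (hi - lo) for x in vals)
    return replace(matrix, T_n=t_n, R_n=r_n, P_n=p_n, S_n=s_n)


def is_strong_dilemma(matrix: PayoffMatrix) -> bool:
    """True iff T > R > P > S and 2R > T + S hold on the raw payoffs."""
    m = matrix
    return (m.T > m.R > m.P > m.S) and (2 * m.R > m.T + m.S)


# Payoff matrices of the three experiments (raw points), pre-normalized.
PIPD_MATRIX = normalize_payoffs(PayoffMatrix(T=4, R=3, P=1, S=0))
VNNIPD_MATRIX = normalize_payoffs(PayoffMatrix(T=6, R=5, P=1, S=0))
MNIPD_MATRIX = normalize_payoffs(PayoffMatrix(T=10, R=7, P=0, S=0))


@dataclass(frozen=True)
class TreatmentSpec:
    """One experimental treatment: topology, partner scheme, info, payoffs."""

    treatment_id: str
    topology: str  # pairwise | moore | von_neumann
    partner_scheme: str  # fixed | shuffled
    payoff_matrix: PayoffMatrix
    info_condition: str = "payoffs_shown"  # payoffs_shown | payoffs_hidden
    n_rounds: int = 21

    def __post_init__(self):
        if self.topology not in N_COPLAYERS:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.partner_scheme not in ("fixed", "shuffled"):
            raise ValueError(f"unknown partner scheme {self.partner_scheme!r}")
        if self.info_condition not in ("payoffs_shown", "payoffs_hidden"):
            raise ValueError(f"unknown info condition {self.info_condition!r}")

    @property
    def n_coplayers(self) -> int:
        return N_COPLAYERS[self.topology]


@dataclass(frozen=True)
class RoundRecord:
    """One decision: action, response time, and the context it was taken in.

    ``context`` is the number of co-players that cooperated in the previous
    round; it is ``None`` for round 1, which has no previous round and is
    excluded from relative-allocation scoring.
    """

    participant_id: str
    treatment_id: str
    round: int
    action: str  # C | D
    rt: float  # seconds
    n_coplayers: int
    context: int | None

    def __post_init__(self):
        if self.action not in ("C", "D"):
            raise ValueError(f"action must be C or D, got {self.action!r}")


def _validate_frame(df: pd.DataFrame, n_coplayers: int | None) -> list[str]:
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        if row.action not in ("C", "D"):
            problems.append(f"row {i}: action must be C or D, got {row.action!r}")
        if not (isinstance(row.rt, (int, float)) and math.isfinite(row.rt) and row.rt > 0):
            problems.append(f"row {i}: rt must be finite and > 0, got {row.rt!r}")
        n_co = n_coplayers if n_coplayers is not None else int(row.n_coplayers)
        if int(row.n_coplayers) != n_co:
            problems.append(f"row {i}: n_coplayers {row.n_coplayers} != treatment value {n_co}")
        ctx = row.context
        if ctx is not None and not (isinstance(ctx, float) and math.isnan(ctx)):
            if not (0 <= int(ctx) <= n_co):
                problems.append(f"row {i}: context {int(ctx)} outside [0, {n_co}]")
        if int(row.round) < 1:
            problems.append(f"row {i}: round must be >= 1, got {row.round}")
    return problems


def load_records(path, spec: TreatmentSpec | None = None) -> list[RoundRecord]:
    """Read and validate a canonical record CSV.

    Records are returned sorted by (participant_id, round).  Schema
    violations raise :class:`ValidationError` naming the offending rows.
    When ``spec`` is given, the context bound is enforced by its topology.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "treatment_id": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing columns: {', '.join(missing)}"])
    problems = _validate_frame(df, spec.n_coplayers if spec else None)
    if problems:
        raise ValidationError(problems)
    df = df.sort_values(["participant_id", "round"], kind="mergesort")
    out = []
    for row in df.itertuples(index=False):
        ctx = row.context
        ctx = None if (ctx is None or (isinstance(ctx, float) and math.isnan(ctx))) else int(ctx)
        out.append(
            RoundRecord(
                participant_id=str(row.participant_id),
                treatment_id=str(row.treatment_id),
                round=int(row.round),
                action=row.action,
                rt=float(row.rt),
                n_coplayers=int(row.n_coplayers),
                context=ctx,
            )
        )
    return out


def _format_rt(x: float) -> str:
    # shortest representation that round-trips, for byte-identical rewrite
    return repr(float(x))


def write_records(records: Iterable[RoundRecord], path) -> None:
    """Write records in the canonical CSV dialect (UTF-8, comma, '.' decimal).

    The dialect is deterministic: ``load_records`` → ``write_records`` is a
    byte-identical round trip.
    """
    recs = sorted(records, key=lambda r: (r.participant_id, r.round))
    buf = io.StringIO()
    buf.write(",".join(RECORD_COLUMNS) + "\n")
    for r in recs:
        ctx = "" if r.context is None else str(r.context)
        buf.write(
            f"{r.participant_id},{r.treatment_id},{r.round},{r.action},"
            f"{_format_rt(r.rt)},{r.n_coplayers},{ctx}\n"
        )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def records_to_frame(records: Iterable[RoundRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of a record sequence."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "treatment_id": r.treatment_id,
                "round": r.round,
                "action": r.action,
                "rt": r.rt,
                "n_coplayers": r.n_coplayers,
                "context": r.context,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def derive_context(
    actions: pd.DataFrame,
    adjacency: Mapping[str, Sequence[str]] | Mapping[int, Mapping[str, Sequence[str]]],
) -> pd.DataFrame:
    """Fill the context column from co-players' previous-round actions.

    ``actions`` needs columns participant_id, round, action.  ``adjacency``
    maps each participant to its co-players; a per-round mapping
    ``{round: {pid: [neighbours]}}`` supports shuffled schemes.  The context
    of round r counts neighbours whose round r−1 action was C; round 1 is
    flagged undefined (``None``).  A missing neighbour action raises
    ``KeyError`` identifying participant and round.
    """
    per_round = adjacency and all(isinstance(k, int) for k in adjacency)
    act = {(str(r.participant_id), int(r.round)): r.action for r in actions.itertuples(index=False)}
    out = actions.copy()
    contexts: list[int | None] = []
    for row in actions.itertuples(index=False):
        pid, rnd = str(row.participant_id), int(row.round)
        if rnd == 1:
            contexts.append(None)
            continue
        adj = adjacency[rnd][pid] if per_round else adjacency[pid]
        c = 0
        for nb in adj:
            try:
                prev = act[(str(nb), rnd - 1)]
            except KeyError:
                raise KeyError(
                    f"no action for co-player {nb!r} of {pid!r} in round {rnd - 1}"
                ) from None
            c += prev == "C"
        contexts.append(c)
    out["context"] = pd.Series(contexts, index=out.index, dtype=object)  # keep None as None
    return out
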