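"""End-to-end analysis: simulate/load → fit → RA° → statistics → report.

The unit of analysis is the *cohort table*: one row per participant joining
the relative-allocation angle, the fitted diffusion parameters (a, v, z,
t0), the rationality index R, and convergence/definedness flags.  Every
exclusion (undefined angle, unconverged fit, insufficient trials) is
itemized, never silent; correlations use only rows that pass both gates.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    PayoffMatrix,
    RoundRecord,
    TreatmentSpec,
    normalize_payoffs,
    records_to_frame,
    load_records,
    write_records,
)
from .ddm import FitError, Trial, compute_rationality, fit_mle, sample_posterior
from .cohort import CohortConfig, CohortData, DEFAULT_ARCHETYPES, Archetype, generate_cohort
from .ra import cohort_ra
from .stats import ConstantInputError, ks_two_sample, ols_adjusted_r2, spearman

__all__ = [
    "build_cohort_table",
    "fit_participants",
    "analyze_cohort",
    "compare_treatments",
    "run_pipeline",
    "load_config",
    "load_external_records",
]

log = logging.getLogger("socialdrift")

#: diffusion parameters correlated against RA°, plus the rationality index
ANALYSIS_PARAMS = ("a", "v", "z", "R")
COMPARE_VARS = ("ra_angle_deg", "a", "v", "z", "R")


def fit_participants(
    records: Sequence[RoundRecord],
    mode: str = "mle",
    seed: int = 0,
    min_trials: int = 10,
    sampler_kwargs: Mapping | None = None,
) -> pd.DataFrame:
    """Fit one diffusion model per participant from their scoreable rounds.

    Round-1 decisions (undefined context) are excluded: they are not
    produced by the context-conditioned process being modelled.  Returns a
    fit table with NaN rows (converged=False) for participants whose data
    are degenerate, so nobody is dropped silently.
    """
    if mode not in ("mle", "sampler"):
        raise ValueError(f"fit mode must be 'mle' or 'sampler', got {mode!r}")
    by_pid: dict[str, list[Trial]] = {}
    for r in records:
        if r.context is None:
            continue
        by_pid.setdefault(r.participant_id, []).append(Trial(choice=r.action, rt=r.rt))
    rows = []
    for i, pid in enumerate(sorted(by_pid)):
        trials = by_pid[pid]
        base = {"participant_id": pid, "n_trials": len(trials)}
        try:
            if mode == "mle":
                res = fit_mle(trials, pid, min_trials=min_trials, seed=seed + i)
            else:
                res = sample_posterior(
                    trials, pid, min_trials=min_trials, seed=seed + i, **(sampler_kwargs or {})
                )
        except FitError as exc:
            log.warning("fit failed for %s: %s", pid, exc)
            rows.append(
                base | {"a": np.nan, "v": np.nan, "z": np.nan, "t0": np.nan,
                        "loglik": np.nan, "converged": False, "fit_error": str(exc)}
            )
            continue
        p = res.params
        row = base | {
            "a": p.a, "v": p.v, "z": p.z, "t0": p.t0,
            "loglik": res.loglik, "converged": res.converged, "fit_error": "",
        }
        if res.rhat:
            row |= {f"rhat_{k}": val for k, val in res.rhat.items()}
        rows.append(row)
    return pd.DataFrame(rows)


def build_cohort_table(
    records: Sequence[RoundRecord],
    spec: TreatmentSpec,
    ra_rounds: int = 20,
    fit_mode: str = "mle",
    seed: int = 0,
    sampler_kwargs: Mapping | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join RA° and fitted diffusion parameters per participant.

    Returns (table, exclusions).  The table has one row per participant;
    ``included`` marks rows usable for correlations (defined angle and
    converged fit).  ``exclusions`` itemizes every excluded participant
    with the reason.
    """
    ra = cohort_ra(records, spec, n_rounds=ra_rounds)
    fits = fit_participants(records, mode=fit_mode, seed=seed, sampler_kwargs=sampler_kwargs)
    table = ra.merge(fits, on="participant_id", how="left", validate="1:1")
    table["R"] = [
        compute_rationality_row(r) for r in table.itertuples(index=False)
    ]
    table["included"] = table["defined"] & table["converged"].fillna(False).astype(bool)
    excl = []
    for r in table.itertuples(index=False):
        if not r.defined:
            excl.append({"participant_id": r.participant_id, "reason": "undefined RA angle"})
        if not bool(r.converged) or (isinstance(r.a, float) and np.isnan(r.a)):
            reason = getattr(r, "fit_error", "") or "fit did not converge"
            excl.append({"participant_id": r.participant_id, "reason": reason})
    exclusions = pd.DataFrame(excl, columns=["participant_id", "reason"])
    n_in = int(table["included"].sum())
    log.info(
        "cohort %s: %d participants, %d included, %d excluded",
        spec.treatment_id, len(table), n_in, len(table) - n_in,
    )
    return table, exclusions


def compute_rationality_row(row) -> float:
    """Rationality R from one fitted cohort-table row (NaN if fit failed)."""
    from .ddm import DDMParams

    if any(np.isnan([row.a, row.v, row.z, row.t0])):
        return np.nan
    return compute_rationality(DDMParams(a=row.a, v=row.v, z=row.z, t0=row.t0))


def analyze_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations and OLS regressions of RA° on each parameter.

    Only ``included`` rows enter; each output row records the n used.
    Returns (correlations, regressions).
    """
    sub = table[table["included"]]
    tid = table["treatment_id"].iloc[0] if len(table) else ""
    corr_rows, reg_rows = [], []
    for par in ANALYSIS_PARAMS:
        x = sub[par].to_numpy(dtype=float)
        y = sub["ra_angle_deg"].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        try:
            c = spearman(y, x)
            corr_rows.append(
                {"treatment_id": tid, "parameter": par, "rho": c.rho, "p_value": c.p_value, "n": c.n}
            )
        except (ConstantInputError, ValueError) as exc:
            corr_rows.append(
                {"treatment_id": tid, "parameter": par, "rho": np.nan, "p_value": np.nan, "n": len(x)}
            )
            log.warning("correlation %s vs RA skipped: %s", par, exc)
        try:
            reg = ols_adjusted_r2(y, x)
            reg_rows.append(
                {
                    "treatment_id": tid, "parameter": par,
                    "slope": reg.slope, "slope_se": reg.slope_se, "slope_p": reg.slope_p,
                    "intercept": reg.intercept, "adjusted_r2": reg.adjusted_r2, "n": reg.n,
                }
            )
        except (ConstantInputError, ValueError) as exc:
            log.warning("regression RA ~ %s skipped: %s", par, exc)
    return pd.DataFrame(corr_rows), pd.DataFrame(reg_rows)


def compare_treatments(
    table1: pd.DataFrame, table2: pd.DataFrame, variables: Sequence[str] = COMPARE_VARS
) -> pd.DataFrame:
    """Two-sample KS comparison of RA° and fitted parameters across cohorts."""
    if len(table1) == 0 or len(table2) == 0:
        raise ValueError("cannot compare an empty cohort")
    t1 = table1[table1["included"]]
    t2 = table2[table2["included"]]
    rows = []
    for var in variables:
        x = t1[var].dropna().to_numpy(dtype=float)
        y = t2[var].dropna().to_numpy(dtype=float)
        res = ks_two_sample(x, y)
        rows.append(
            {
                "treatment_1": table1["treatment_id"].iloc[0],
                "treatment_2": table2["treatment_id"].iloc[0],
                "variable": var,
                "D": res.D,
                "p_value": res.p_value,
                "n1": res.n1,
                "n2": res.n2,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Config handling
# ----------------------------------------------------------------------

def _treatment_from_dict(d: Mapping) -> TreatmentSpec:
    pm = d["payoffs"]
    matrix = normalize_payoffs(PayoffMatrix(T=pm["T"], R=pm["R"], P=pm["P"], S=pm["S"]))
    return TreatmentSpec(
        treatment_id=d["treatment_id"],
        topology=d["topology"],
        partner_scheme=d["partner_scheme"],
        payoff_matrix=matrix,
        info_condition=d.get("info_condition", "payoffs_shown"),
        n_rounds=int(d.get("rounds", 21)),
    )


def _archetypes_from_dict(d: Mapping | None) -> Mapping[str, Archetype]:
    if not d:
        return DEFAULT_ARCHETYPES
    out = dict(DEFAULT_ARCHETYPES)
    for name, kv in d.items():
        base = out.get(name, DEFAULT_ARCHETYPES["CONDITIONAL"])
        out[name] = Archetype(**({**base.__dict__, **kv, "name": name}))
    return out


def load_config(path) -> dict:
    """Parse a YAML pipeline config (see README for the schema)."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def _cohort_config_from_dict(d: Mapping, seed: int) -> CohortConfig:
    spec = _treatment_from_dict(d["treatment"])
    sim = d["simulate"]
    return CohortConfig(
        treatment=spec,
        mixture=sim["mixture"],
        n_participants=int(sim["n_participants"]),
        n_rounds=int(sim.get("n_rounds", spec.n_rounds)),
        seed=int(sim.get("seed", seed)),
        archetypes=_archetypes_from_dict(sim.get("archetypes")),
    )


# ----------------------------------------------------------------------
# Report figures
# ----------------------------------------------------------------------

def _write_figures(table: pd.DataFrame, reg: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tid = table["treatment_id"].iloc[0]
    sub = table[table["included"]]

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].scatter(sub["a_self_mean"], sub["a_other_mean"], s=14, alpha=0.7)
    lim = max(1.0, sub[["a_self_mean", "a_other_mean"]].to_numpy().max() * 1.05)
    axes[0].plot([0, lim], [0, lim], ls="--", c="grey", lw=1)
    axes[0].set_xlabel(r"$\bar{a}_{self}$")
    axes[0].set_ylabel(r"$\bar{a}_{other}$")
    axes[0].set_title(f"{tid}: mean planned allocations")
    axes[1].hist(sub["ra_angle_deg"].dropna(), bins=np.arange(0, 95, 5), edgecolor="k")
    axes[1].axvline(45, ls=":", c="k")
    axes[1].set_xlabel("RA (degrees)")
    axes[1].set_ylabel("participants")
    axes[1].set_title("RA distribution")
    fig.tight_layout()
    fig.savefig(out_dir / f"{tid}_ra.png", dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    for ax, par in zip(axes, ("z", "a", "v")):
        ax.scatter(sub["ra_angle_deg"], sub[par], s=12, alpha=0.7)
        row = reg[reg["parameter"] == par]
        if len(row):
            xx = np.linspace(0, 90, 50)
            ax.plot(xx, row["intercept"].iloc[0] + row["slope"].iloc[0] * xx, c="C1")
        ax.axvline(45, ls=":", c="k", lw=0.8)
        ax.set_xlabel("RA (degrees)")
        ax.set_ylabel(par)
    fig.tight_layout()
    fig.savefig(out_dir / f"{tid}_params_vs_ra.png", dpi=110)
    plt.close(fig)


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------

def run_pipeline(config: Mapping | str | Path, out_dir, seed: int = 0) -> dict:
    """Execute the full workflow and write the report bundle to ``out_dir``.

    ``config`` is a mapping (or path to YAML) with a ``cohorts`` list; each
    entry either simulates a synthetic treatment (``treatment`` +
    ``simulate`` keys) or loads records (``records`` path + ``treatment``).
    Outputs per treatment: records, ground truth (if simulated), cohort
    table, correlation/regression CSVs and figures; across treatments:
    pairwise KS comparisons.  Deterministic given config + seed.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.get("log_level", "INFO"))
    fit_mode = config.get("fit", {}).get("mode", "mle")
    sampler_kwargs = {
        k: config["fit"][k]
        for k in ("n_samples", "burn_in", "n_chains")
        if "fit" in config and k in config["fit"]
    }
    ra_rounds = int(config.get("ra", {}).get("n_rounds", 20))
    log.info("socialdrift %s | seed=%d fit_mode=%s ra_rounds=%d", __version__, seed, fit_mode, ra_rounds)

    tables: dict[str, pd.DataFrame] = {}
    all_corr, all_reg, all_excl = [], [], []
    try:
        for i, entry in enumerate(config["cohorts"]):
            spec = _treatment_from_dict(entry["treatment"])
            tid = spec.treatment_id
            stage = f"cohort {tid}"
            try:
                if "simulate" in entry:
                    cc = _cohort_config_from_dict(entry, seed + 1000 * i)
                    data = generate_cohort(cc)
                    records = data.records
                    data.ground_truth.to_csv(out / f"{tid}_ground_truth.csv", index=False)
                    log.info("%s: simulated %d participants, %d flagged walks",
                             stage, cc.n_participants, len(data.flagged))
                else:
                    records = load_records(entry["records"], spec)
                    log.info("%s: loaded %d records from %s", stage, len(records), entry["records"])
                write_records(records, out / f"{tid}_records.csv")
                stage = f"fit+RA {tid}"
                table, excl = build_cohort_table(
                    records, spec, ra_rounds=ra_rounds, fit_mode=fit_mode,
                    seed=seed + 1000 * i, sampler_kwargs=sampler_kwargs or None,
                )
                stage = f"analysis {tid}"
                corr, reg = analyze_cohort(table)
                table.to_csv(out / f"{tid}_cohort.csv", index=False)
                excl.to_csv(out / f"{tid}_exclusions.csv", index=False)
                tables[tid] = table
                all_corr.append(corr)
                all_reg.append(reg)
                all_excl.append(excl)
                _write_figures(table, reg, out)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

        pd.concat(all_corr, ignore_index=True).to_csv(out / "correlations.csv", index=False)
        pd.concat(all_reg, ignore_index=True).to_csv(out / "regressions.csv", index=False)
        comps = []
        for t1, t2 in itertools.combinations(sorted(tables), 2):
            comps.append(compare_treatments(tables[t1], tables[t2]))
        if comps:
            pd.concat(comps, ignore_index=True).to_csv(out / "comparisons.csv", index=False)
        log.info("pipeline complete: %d treatment(s)", len(tables))
    finally:
        log.removeHandler(handler)
        handler.close()
    return {
        "out_dir": str(out),
        "treatments": sorted(tables),
        "tables": tables,
        "correlations": pd.concat(all_corr, ignore_index=True) if all_corr else pd.DataFrame(),
    }


def load_external_records(
    path, column_map: Mapping[str, str], spec: TreatmentSpec, rt_scale: float = 1.0
):
    """Adapter for third-party deposits of per-round records.

    ``column_map`` maps canonical column names to the deposit's names;
    ``rt_scale`` converts the deposit's RT unit to seconds (e.g. 1e-3 for
    milliseconds).  The mapped frame is validated through the canonical
    loader path.  No network access: ``path`` must be a local file.
    """
    import io as _io

    from .data import RECORD_COLUMNS

    df = pd.read_csv(path)
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns and c != "context"]
    if missing:
        raise ValueError(f"column map leaves canonical columns missing: {missing}")
    if "context" not in df.columns:
        df["context"] = np.nan
    df["rt"] = df["rt"].astype(float) * rt_scale
    buf = _io.StringIO()
    df[RECORD_COLUMNS].to_csv(buf, index=False)
    buf.seek(0)
    return load_records(buf, spec)
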