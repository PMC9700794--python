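"""Drift-diffusion model of binary choice and response time.

Evidence accumulates as a Wiener process with drift ``v`` (positive toward
cooperation) between absorbing boundaries at 0 (defection) and ``a``
(cooperation), starting at ``z*a``; a non-decision time ``t0`` is added to
the decision time.  The diffusion coefficient is fixed at 1 for
identifiability, so ``a`` is the boundary separation in noise units.

The likelihood is the Wiener first-passage-time (WFPT) density, evaluated
by two complementary series expansions — a small-time expansion in image
terms and a large-time Fourier sine expansion — with the conventional
switching rule that picks whichever needs fewer terms for the requested
truncation error.

Fitting is per-participant maximum likelihood (bounded, multi-start) with
an optional random-walk Metropolis sampler under uniform priors, gated by
the Gelman–Rubin potential-scale-reduction diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DDMParams",
    "Trial",
    "FitResult",
    "FitError",
    "PARAM_BOUNDS",
    "wfpt_density",
    "wfpt_logdensity",
    "choice_prob_upper",
    "mean_decision_time",
    "simulate_trials",
    "simulate_first_passage",
    "trials_to_arrays",
    "fit_mle",
    "sample_posterior",
    "gelman_rubin",
    "compute_rationality",
]

#: uniform prior box / optimizer bounds (t0 upper bound is data-dependent)
PARAM_BOUNDS = {"a": (0.3, 5.0), "v": (-5.0, 5.0), "z": (0.05, 0.95), "t0": (0.05, np.inf)}


class FitError(RuntimeError):
    """Degenerate data or optimizer failure during DDM fitting."""


@dataclass(frozen=True)
class DDMParams:
    """Parameters of one participant's diffusion process.

    a: boundary separation (> 0) — perceived difficulty / carefulness.
    v: drift rate — speed of evidence accumulation, signed toward cooperation.
    z: relative starting point in (0, 1) — a-priori decision bias (0.5 = none).
    t0: non-decision time in seconds (>= 0).
    """

    a: float
    v: float
    z: float = 0.5
    t0: float = 0.0
    sigma: float = 1.0  # fixed; kept explicit for the rescaling identity

    def __post_init__(self):
        if not (self.a > 0):
            raise ValueError(f"a must be > 0, got {self.a}")
        if not (0 < self.z < 1):
            raise ValueError(f"z must be in (0,1), got {self.z}")
        if not (self.t0 >= 0):
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class Trial:
    """One decision: boundary reached (C = upper, D = lower) and RT in seconds."""

    choice: str  # C | D
    rt: float
    truncated: bool = False

    def __post_init__(self):
        if self.choice not in ("C", "D"):
            raise ValueError(f"choice must be C or D, got {self.choice!r}")
        if not self.rt > 0:
            raise ValueError(f"rt must be > 0, got {self.rt}")


@dataclass(frozen=True)
class FitResult:
    participant_id: str
    params: DDMParams
    loglik: float
    n_trials: int
    converged: bool
    rhat: dict[str, float] | None = None  # sampler mode only


# ----------------------------------------------------------------------
# WFPT density
# ----------------------------------------------------------------------

def _f0(tau: np.ndarray, w: float, err: float = 1e-9) -> np.ndarray:
    """Zero-drift, unit-boundary FPT density at the lower boundary.

    ``tau`` is decision time scaled by a^2, ``w`` the relative start.  Uses
    the small-time image expansion or the large-time sine series, whichever
    needs fewer terms for truncation error ``err``.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not pos.any():
        return out
    t = tau[pos]

    with np.errstate(divide="ignore", invalid="ignore"):
        # terms needed by each expansion
        ks = 2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(2.0 * np.sqrt(2.0 * np.pi * t) * err), 0.0))
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        ks = np.where(2.0 * np.sqrt(2.0 * np.pi * t) * err < 1.0, ks, 2.0)
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.pi * t * err), 0.0) / (np.pi**2 * t))
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))
        kl = np.where(np.pi * t * err < 1.0, kl, 1.0 / (np.pi * np.sqrt(t)))

    f = np.zeros_like(t)
    small = ks < kl

    if small.any():
        ts = t[small]
        K = int(np.ceil(ks[small].max() / 2.0)) + 1  # generous symmetric image range
        acc = np.zeros_like(ts)
        for k in range(-K, K + 1):
            wk = w + 2.0 * k
            acc += wk * np.exp(-(wk * wk) / (2.0 * ts))
        f[small] = acc / np.sqrt(2.0 * np.pi * ts**3)

    large = ~small
    if large.any():
        tl = t[large]
        K = int(np.ceil(kl[large].max()))
        acc = np.zeros_like(tl)
        for k in range(1, K + 1):
            acc += k * np.exp(-(k * k) * (np.pi**2) * tl / 2.0) * math.sin(k * np.pi * w)
        f[large] = np.pi * acc

    out[pos] = np.maximum(f, 0.0)
    return out


def wfpt_logdensity(t, params: DDMParams, boundary: str = "lower") -> np.ndarray:
    """Log WFPT density of absorption at ``boundary`` at time(s) ``t``.

    Computed in log space so that large |v| or long times do not overflow.
    Times at or before ``t0`` get -inf.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    t = np.asarray(t, dtype=float)
    a, v, z, t0 = params.a, params.v, params.z, params.t0
    if boundary == "upper":
        v, w = -v, 1.0 - z
    else:
        w = z
    td = t - t0
    out = np.full(t.shape, -np.inf)
    pos = td > 0
    if pos.any():
        tp = td[pos]
        f0 = _f0(tp / a**2, w)
        with np.errstate(divide="ignore"):
            out[pos] = (-v * a * w - (v * v) * tp / 2.0 - 2.0 * math.log(a)) + np.log(f0)
    return out


def wfpt_density(t, params: DDMParams, boundary: str = "lower") -> np.ndarray:
    """WFPT density (per second) of absorption at ``boundary`` at time(s) ``t``."""
    scalar = np.isscalar(t)
    dens = np.exp(wfpt_logdensity(np.atleast_1d(t), params, boundary))
    return float(dens[0]) if scalar else dens


# ----------------------------------------------------------------------
# Closed-form oracles
# ----------------------------------------------------------------------

def choice_prob_upper(params: DDMParams) -> float:
    """Exact probability of absorption at the upper (cooperation) boundary.

    (1 - exp(-2 v z a)) / (1 - exp(-2 v a)) for v != 0, and z for v = 0.
    """
    a, v, z = params.a / params.sigma, params.v / params.sigma, params.z
    if v == 0.0:
        return z
    x = 2.0 * v * a  # exponent scale; overflow-safe limits for |x| large
    if x < -700.0:  # v very negative: mass escapes upward only with prob e^{-|x|(1-z)}
        return math.exp(x * (1.0 - z))
    if x > 700.0:  # v very positive: upper absorption almost sure
        return 1.0
    return float(np.expm1(-x * z) / np.expm1(-x))


def mean_decision_time(params: DDMParams) -> float:
    """Exact expected decision time (excluding t0).

    General unconditional mean exit time of drifted Brownian motion from
    (0, a) starting at z*a: a*(P_upper - z)/v for v != 0 and a^2 z (1-z)
    for v = 0.  For z = 0.5 this reduces to (a/2v) tanh(a v / 2).
    """
    a, v, z = params.a / params.sigma, params.v / params.sigma, params.z
    if v == 0.0:
        return a * a * z * (1.0 - z)
    return a * (choice_prob_upper(params) - z) / v


# ----------------------------------------------------------------------
# Simulation
# ----------------------------------------------------------------------

def simulate_first_passage(
    a,
    v,
    z,
    rng: np.random.Generator,
    dt: float = 1e-3,
    max_t: float = 30.0,
    bridge: bool = True,
    block: int = 256,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Euler–Maruyama first-passage simulation.

    ``a``, ``v``, ``z`` broadcast to a common shape; one walk per element.
    With ``bridge=True`` a Brownian-bridge crossing check is applied within
    each step, removing the O(sqrt(dt)) boundary-overshoot bias of the bare
    Euler scheme.  Returns (upper_hit, decision_time, truncated); truncated
    walks carry decision_time = max_t.
    """
    a, v, z = np.broadcast_arrays(np.asarray(a, float), np.asarray(v, float), np.asarray(z, float))
    a = a.ravel().copy()
    v = v.ravel().copy()
    x = (z.ravel() * a).copy()
    m = x.size
    upper = np.zeros(m, dtype=bool)
    steps = np.full(m, -1, dtype=np.int64)
    active = np.arange(m)
    max_steps = int(round(max_t / dt))
    done_steps = 0
    sdt = math.sqrt(dt)

    while active.size and done_steps < max_steps:
        b = min(block, max_steps - done_steps)
        na = active.size
        inc = rng.normal(0.0, 1.0, size=(na, b)) * sdt + v[active, None] * dt
        path = x[active, None] + np.cumsum(inc, axis=1)
        prev = np.concatenate([x[active, None], path[:, :-1]], axis=1)
        aa = a[active, None]
        up_d = path >= aa
        dn_d = path <= 0.0
        crossed = up_d | dn_d
        if bridge:
            du_prev = np.maximum(aa - prev, 0.0)
            du_new = np.maximum(aa - path, 0.0)
            dl_prev = np.maximum(prev, 0.0)
            dl_new = np.maximum(path, 0.0)
            p_up = np.exp(-2.0 * du_prev * du_new / dt)
            p_dn = np.exp(-2.0 * dl_prev * dl_new / dt)
            b_up = (~crossed) & (rng.random((na, b)) < p_up)
            b_dn = (~crossed) & (rng.random((na, b)) < p_dn)
            crossed = crossed | b_up | b_dn
        hit = crossed.any(axis=1)
        if hit.any():
            rows = np.flatnonzero(hit)
            j = crossed[rows].argmax(axis=1)
            idx = active[rows]
            d_up = up_d[rows, j]
            d_dn = dn_d[rows, j]
            if bridge:
                bu = b_up[rows, j]
                bd = b_dn[rows, j]
                tie = bu & bd
                is_up = np.where(
                    d_up, True, np.where(d_dn, False, np.where(tie, p_up[rows, j] >= p_dn[rows, j], bu))
                )
            else:
                is_up = d_up
            upper[idx] = is_up
            steps[idx] = done_steps + j + 1
        rem = ~hit
        x[active[rem]] = path[rem, -1]
        active = active[rem]
        done_steps += b

    truncated = steps < 0
    if truncated.any():
        # flag, classify by nearer boundary, clamp time
        upper[truncated] = x[truncated] >= a[truncated] / 2.0
        steps[truncated] = max_steps
    return upper, steps * dt, truncated


def simulate_trials(
    params: DDMParams,
    n: int,
    seed: int | np.random.Generator = 0,
    dt: float = 1e-3,
    max_t: float = 30.0,
    bridge: bool = True,
) -> list[Trial]:
    """Simulate ``n`` decisions from one parameter set; reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    up, t_dec, trunc = simulate_first_passage(
        np.full(n, params.a), np.full(n, params.v), np.full(n, params.z), rng, dt, max_t, bridge
    )
    return [
        Trial(choice="C" if u else "D", rt=float(t + params.t0), truncated=bool(tr))
        for u, t, tr in zip(up, t_dec, trunc)
    ]


def trials_to_arrays(trials: Sequence[Trial]) -> tuple[np.ndarray, np.ndarray]:
    """(rt, upper_mask) arrays from a trial sequence."""
    rt = np.array([t.rt for t in trials], dtype=float)
    upper = np.array([t.choice == "C" for t in trials], dtype=bool)
    return rt, upper


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

def _loglik(theta: np.ndarray, rt: np.ndarray, upper: np.ndarray) -> float:
    a, v, z, t0 = theta
    try:
        p = DDMParams(a=a, v=v, z=z, t0=t0)
    except ValueError:
        return -np.inf
    ll = np.empty_like(rt)
    ll[upper] = wfpt_logdensity(rt[upper], p, "upper")
    ll[~upper] = wfpt_logdensity(rt[~upper], p, "lower")
    ll = np.maximum(ll, -690.0)  # floor instead of -inf so the optimizer can recover
    return float(ll.sum())


def _check_trials(rt: np.ndarray, min_trials: int) -> None:
    if rt.size < min_trials:
        raise FitError(f"{rt.size} trials < minimum {min_trials}")
    if np.ptp(rt) == 0.0:
        raise FitError("degenerate data: all response times identical")
    if rt.min() <= PARAM_BOUNDS["t0"][0]:
        raise FitError(
            f"degenerate data: min rt {rt.min():.4f}s at or below the "
            f"plausible non-decision floor {PARAM_BOUNDS['t0'][0]}s"
        )


def fit_mle(
    trials: Sequence[Trial],
    participant_id: str = "",
    min_trials: int = 20,
    n_starts: int = 4,
    seed: int = 0,
) -> FitResult:
    """Per-participant maximum-likelihood fit of (a, v, z, t0).

    Bounded L-BFGS-B from multiple starting points (moment-based heuristics
    plus seeded jitter); the best optimum is returned with the optimizer's
    success flag.  Both boundaries need not be observed.
    """
    rt, upper = trials_to_arrays(trials)
    _check_trials(rt, min_trials)
    t0_hi = float(rt.min()) - 1e-4
    bounds = [
        PARAM_BOUNDS["a"],
        PARAM_BOUNDS["v"],
        PARAM_BOUNDS["z"],
        (PARAM_BOUNDS["t0"][0], t0_hi),
    ]
    p_hat = float(np.clip(upper.mean(), 0.1, 0.9))
    t0_0 = float(np.clip(0.9 * rt.min(), *bounds[3]))
    rng = np.random.default_rng(seed)
    starts = [
        np.array([1.2, 2.0 * (p_hat - 0.5), p_hat, t0_0]),
        np.array([2.0, 0.0, 0.5, t0_0]),
    ]
    while len(starts) < n_starts:
        starts.append(
            np.array(
                [
                    rng.uniform(0.6, 3.0),
                    rng.uniform(-2.0, 2.0),
                    rng.uniform(0.25, 0.75),
                    rng.uniform(bounds[3][0], max(bounds[3][0] + 1e-3, t0_hi)),
                ]
            )
        )
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [min(b[1], 1e9) for b in bounds])
        res = optimize.minimize(
            lambda th: -_loglik(th, rt, upper),
            x0,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    params = DDMParams(a=best.x[0], v=best.x[1], z=best.x[2], t0=best.x[3])
    return FitResult(
        participant_id=participant_id,
        params=params,
        loglik=-float(best.fun),
        n_trials=int(rt.size),
        converged=bool(best.success),
    )


# ----------------------------------------------------------------------
# Posterior sampling + diagnostics
# ----------------------------------------------------------------------

def gelman_rubin(chains) -> float | np.ndarray:
    """Gelman–Rubin potential-scale-reduction factor R-hat.

    ``chains`` is (m, n) for one parameter or (m, n, p) for p parameters;
    requires at least two chains of equal length >= 10.  Values near 1
    indicate convergence; identical chains give sqrt((n-1)/n) ~ 1.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim == 2:
        c = c[:, :, None]
        squeeze = True
    elif c.ndim == 3:
        squeeze = False
    else:
        raise ValueError("chains must be (m, n) or (m, n, p)")
    m, n, _ = c.shape
    if m < 2:
        raise ValueError("need at least two chains")
    if n < 10:
        raise ValueError("chains must have length >= 10")
    w = c.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = c.mean(axis=1).var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    rhat = np.where(w == 0, 1.0 if np.all(b_over_n == 0) else np.inf, rhat)
    return float(rhat[0]) if squeeze else rhat


def sample_posterior(
    trials: Sequence[Trial],
    participant_id: str = "",
    n_samples: int = 10_000,
    burn_in: int = 200,
    n_chains: int = 4,
    seed: int = 0,
    rhat_threshold: float = 1.1,
    min_trials: int = 20,
    return_chains: bool = False,
):
    """Random-walk Metropolis posterior for (a, v, z, t0), uniform priors.

    Each chain draws ``n_samples`` and discards the first ``burn_in``.  The
    point estimate is the posterior mean across chains; convergence is
    flagged via per-parameter Gelman–Rubin R-hat against ``rhat_threshold``
    (a failed gate still returns the result, marked unconverged).
    """
    rt, upper = trials_to_arrays(trials)
    _check_trials(rt, min_trials)
    t0_hi = float(rt.min()) - 1e-4
    lo = np.array([PARAM_BOUNDS["a"][0], PARAM_BOUNDS["v"][0], PARAM_BOUNDS["z"][0], PARAM_BOUNDS["t0"][0]])
    hi = np.array([PARAM_BOUNDS["a"][1], PARAM_BOUNDS["v"][1], PARAM_BOUNDS["z"][1], t0_hi])
    rng = np.random.default_rng(seed)
    start = fit_mle(trials, participant_id, min_trials=min_trials, n_starts=2, seed=seed)
    x_map = np.array([start.params.a, start.params.v, start.params.z, start.params.t0])
    scale = np.array([0.08, 0.12, 0.02, 0.01])

    chains = np.empty((n_chains, n_samples, 4))
    for ci in range(n_chains):
        x = np.clip(x_map + rng.normal(0, 2 * scale), lo + 1e-6, hi - 1e-6)
        lp = _loglik(x, rt, upper)
        for si in range(n_samples):
            prop = x + rng.normal(0, 1, 4) * scale
            if np.all(prop > lo) and np.all(prop < hi):
                lp_prop = _loglik(prop, rt, upper)
                if math.log(rng.random()) < lp_prop - lp:
                    x, lp = prop, lp_prop
            chains[ci, si] = x

    kept = chains[:, burn_in:, :]
    rhat_vals = gelman_rubin(kept)
    names = ("a", "v", "z", "t0")
    rhat = {k: float(r) for k, r in zip(names, rhat_vals)}
    mean = kept.reshape(-1, 4).mean(axis=0)
    params = DDMParams(a=mean[0], v=mean[1], z=mean[2], t0=min(mean[3], t0_hi))
    result = FitResult(
        participant_id=participant_id,
        params=params,
        loglik=_loglik(mean, rt, upper),
        n_trials=int(rt.size),
        converged=bool(all(r < rhat_threshold for r in rhat.values())),
        rhat=rhat,
    )
    return (result, kept) if return_chains else result


# ----------------------------------------------------------------------
# Rationality
# ----------------------------------------------------------------------

def compute_rationality(params: DDMParams) -> float:
    """Deliberation-vs-intuition index R in [0, 1].

    0 — the choice probability is fully explained by the starting bias z
    (no deliberation, v = 0); 1 — the bias is neutral (z = 0.5) and the
    choice is driven entirely by drift.  Operationalised as
    |p - z| / (|p - z| + |z - 0.5|) with p the upper-boundary absorption
    probability, and 0.5 by convention when both terms vanish.
    """
    p = choice_prob_upper(params)
    drift_part = abs(p - params.z)
    bias_part = abs(params.z - 0.5)
    if drift_part == 0.0 and bias_part == 0.0:
        return 0.5
    return drift_part / (drift_part + bias_part)
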