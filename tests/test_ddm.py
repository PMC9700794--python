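"""Wiener first-passage density, closed-form oracles, simulator, MLE."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from socialdrift.ddm import (
    DDMParams,
    FitError,
    Trial,
    choice_prob_upper,
    fit_mle,
    mean_decision_time,
    simulate_trials,
    trials_to_arrays,
    wfpt_density,
)

# parameter grid shared by the density/simulator consistency checks
GRID = [
    DDMParams(a=a, v=v, z=z)
    for a in (0.8, 1.5, 2.5)
    for v in (-1.0, 0.0, 1.0)
    for z in (0.3, 0.5, 0.7)
]


def _upper_mass(p: DDMParams, upper=60.0) -> float:
    return integrate.quad(lambda t: wfpt_density(t, p, "upper"), 0, upper, limit=200)[0]


def _lower_mass(p: DDMParams, upper=60.0) -> float:
    return integrate.quad(lambda t: wfpt_density(t, p, "lower"), 0, upper, limit=200)[0]


class TestClosedForms:
    def test_choice_prob_driftless_equals_start(self):
        assert choice_prob_upper(DDMParams(a=1.0, v=0.0, z=0.3)) == pytest.approx(0.3)

    def test_choice_prob_example(self):
        # independent closed form: (1 - e^{-2vza}) / (1 - e^{-2va})
        p = DDMParams(a=2.0, v=1.0, z=0.5)
        expected = (1 - math.exp(-2 * 1.0 * 0.5 * 2.0)) / (1 - math.exp(-2 * 1.0 * 2.0))
        assert choice_prob_upper(p) == pytest.approx(expected)
        assert choice_prob_upper(p) == pytest.approx(0.8808, abs=1e-4)

    def test_choice_prob_strong_drift_limit(self):
        assert choice_prob_upper(DDMParams(a=2.0, v=50.0, z=0.5)) == pytest.approx(1.0)
        assert choice_prob_upper(DDMParams(a=2.0, v=-50.0, z=0.5)) == pytest.approx(0.0, abs=1e-12)

    def test_mean_decision_time_driftless(self):
        assert mean_decision_time(DDMParams(a=2.0, v=0.0, z=0.5)) == pytest.approx(1.0)

    def test_mean_decision_time_tanh_form(self):
        p = DDMParams(a=2.0, v=1.0, z=0.5)
        assert mean_decision_time(p) == pytest.approx(math.tanh(1.0))
        # matches the first moment of the density itself
        num = integrate.quad(
            lambda t: t * (wfpt_density(t, p, "upper") + wfpt_density(t, p, "lower")),
            0, 60, limit=200,
        )[0]
        assert num == pytest.approx(math.tanh(1.0), rel=1e-6)

    def test_sigma_rescaling_identity(self):
        # doubling the noise is the same as halving boundary and drift
        base = DDMParams(a=2.0, v=1.0, z=0.5, sigma=2.0)
        rescaled = DDMParams(a=1.0, v=0.5, z=0.5, sigma=1.0)
        assert mean_decision_time(base) == pytest.approx(mean_decision_time(rescaled))
        assert choice_prob_upper(base) == pytest.approx(choice_prob_upper(rescaled))


class TestDensity:
    @pytest.mark.parametrize("p", GRID, ids=lambda p: f"a{p.a}_v{p.v}_z{p.z}")
    def test_total_mass_is_one(self, p):
        assert _upper_mass(p) + _lower_mass(p) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("p", GRID, ids=lambda p: f"a{p.a}_v{p.v}_z{p.z}")
    def test_upper_mass_matches_choice_prob(self, p):
        assert _upper_mass(p) == pytest.approx(choice_prob_upper(p), abs=1e-3)

    def test_symmetry_at_neutral_parameters(self):
        p = DDMParams(a=2.0, v=0.0, z=0.5)
        t = np.linspace(0.01, 8.0, 200)
        np.testing.assert_allclose(
            wfpt_density(t, p, "upper"), wfpt_density(t, p, "lower"), rtol=1e-10
        )

    def test_density_zero_before_nondecision_time(self):
        p = DDMParams(a=1.5, v=0.5, z=0.5, t0=0.4)
        assert wfpt_density(0.39, p, "upper") == 0.0
        assert wfpt_density(0.41, p, "upper") > 0.0

    def test_density_nonnegative(self):
        t = np.linspace(1e-4, 20, 500)
        for p in GRID[:6]:
            assert (wfpt_density(t, p, "upper") >= 0).all()


class TestSimulator:
    def test_same_seed_identical_trials(self):
        p = DDMParams(a=1.5, v=0.5, z=0.5, t0=0.2)
        assert simulate_trials(p, 50, seed=7) == simulate_trials(p, 50, seed=7)

    def test_driftless_choice_frequency(self):
        p = DDMParams(a=2.0, v=0.0, z=0.5)
        _, upper = trials_to_arrays(simulate_trials(p, 10_000, seed=1))
        se = math.sqrt(0.25 / 10_000)
        assert abs(upper.mean() - 0.5) <= 3 * se

    def test_choice_frequency_matches_closed_form(self):
        p = DDMParams(a=2.0, v=1.0, z=0.5)
        _, upper = trials_to_arrays(simulate_trials(p, 10_000, seed=2))
        prob = choice_prob_upper(p)
        se = math.sqrt(prob * (1 - prob) / 10_000)
        assert abs(upper.mean() - prob) <= 3 * se

    def test_simulated_times_match_density(self):
        """Two-sample KS between simulated decision times and inverse-CDF
        samples from the density is non-significant at alpha=0.01."""
        p = DDMParams(a=1.5, v=0.8, z=0.4)
        rt, upper = trials_to_arrays(simulate_trials(p, 5000, seed=3))
        # inverse-CDF sampling of the unconditional decision-time density
        tg = np.linspace(1e-4, 30, 20_000)
        pdf = wfpt_density(tg, p, "upper") + wfpt_density(tg, p, "lower")
        cdf = np.cumsum(pdf) * (tg[1] - tg[0])
        cdf /= cdf[-1]
        u = np.random.default_rng(4).random(5000)
        sampled = np.interp(u, cdf, tg)
        res = stats.ks_2samp(rt, sampled)
        assert res.pvalue > 0.01

    def test_bias_and_drift_both_raise_cooperation(self):
        """Monotone choice shares: in z at v=0, and in v at z=0.5."""
        fracs_z = []
        for z in (0.3, 0.5, 0.7):
            _, up = trials_to_arrays(simulate_trials(DDMParams(a=1.5, v=0.0, z=z), 4000, seed=5))
            fracs_z.append(up.mean())
        assert fracs_z[0] < fracs_z[1] < fracs_z[2]
        fracs_v = []
        for v in (-0.8, 0.0, 0.8):
            _, up = trials_to_arrays(simulate_trials(DDMParams(a=1.5, v=v, z=0.5), 4000, seed=6))
            fracs_v.append(up.mean())
        assert fracs_v[0] < fracs_v[1] < fracs_v[2]


class TestMLE:
    def test_recovers_generating_parameters(self):
        true = DDMParams(a=1.5, v=0.3, z=0.55, t0=0.3)
        trials = simulate_trials(true, 2000, seed=11)
        fit = fit_mle(trials, seed=1)
        assert abs(fit.params.a - true.a) <= 0.15
        assert abs(fit.params.v - true.v) <= 0.10
        assert abs(fit.params.z - true.z) <= 0.05
        assert abs(fit.params.t0 - true.t0) <= 0.05
        assert fit.converged

    def test_recovers_drift_sign(self):
        trials = simulate_trials(DDMParams(a=1.5, v=-0.4, z=0.5, t0=0.3), 500, seed=5)
        assert fit_mle(trials).params.v < 0

    def test_fitted_loglik_beats_truth(self):
        from socialdrift.ddm import _loglik

        true = DDMParams(a=1.5, v=0.3, z=0.55, t0=0.3)
        trials = simulate_trials(true, 500, seed=13)
        fit = fit_mle(trials, seed=2)
        rt, upper = trials_to_arrays(trials)
        assert fit.loglik >= _loglik(np.array([1.5, 0.3, 0.55, 0.3]), rt, upper)

    def test_too_few_trials_rejected(self):
        trials = simulate_trials(DDMParams(a=1.5, v=0.3), 5, seed=1, max_t=30)
        with pytest.raises(FitError):
            fit_mle(trials, min_trials=20)

    def test_degenerate_identical_rts_rejected(self):
        trials = [Trial("C", 0.7)] * 50
        with pytest.raises(FitError, match="identical"):
            fit_mle(trials)
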