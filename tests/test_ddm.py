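"""Wiener engine: density identities, simulator agreement, ML and EZ fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import kstest

from diffscore import (
    DDMParams,
    absorption_probability,
    ddm_loglik,
    ez_fit_trials,
    fit_ddm_ml,
    fit_ez,
    simulate_ddm_trials,
    wiener_fpt_density,
)
from diffscore.ddm import _fpt_grid


def _total_density(t, p):
    return wiener_fpt_density(t, p, "upper") + wiener_fpt_density(t, p, "lower")


class TestDensity:
    def test_no_mass_at_nonpositive_times(self):
        p = DDMParams(v=1.0, a=1.0, t0=0.3)
        assert wiener_fpt_density(0.0, p, "upper") == 0.0
        assert wiener_fpt_density(-0.5, p, "lower") == 0.0

    @pytest.mark.parametrize(
        "v,a,zr",
        [(1.0, 1.0, 0.5), (0.0, 1.0, 0.5), (3.0, 0.6, 0.5), (-1.5, 2.0, 0.3),
         (0.5, 1.5, 0.7), (4.0, 2.0, 0.5)],
    )
    def test_defective_densities_normalize(self, v, a, zr):
        # the two boundary densities jointly carry all the probability mass
        p = DDMParams(v=v, a=a, t0=0.0, zr=zr)
        total = quad(_total_density, 0, 60, args=(p,), limit=300)[0]
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("v,a,zr", [(1.0, 1.0, 0.5), (-0.5, 1.4, 0.35), (2.0, 0.8, 0.6)])
    def test_choice_probability_matches_closed_form(self, v, a, zr):
        p = DDMParams(v=v, a=a, t0=0.0, zr=zr)
        mass_up = quad(wiener_fpt_density, 0, 60, args=(p, "upper"), limit=300)[0]
        assert mass_up == pytest.approx(absorption_probability(p, "upper"), abs=1e-6)

    def test_zero_drift_closed_forms(self):
        # unbiased walk: 50/50 absorption, mean decision time z(a-z) = 0.25 s
        p = DDMParams(v=0.0, a=1.0, t0=0.0)
        assert absorption_probability(p, "upper") == pytest.approx(0.5, abs=1e-12)
        mean_t = quad(lambda t: t * _total_density(t, p), 0, 120, limit=400)[0]
        assert mean_t == pytest.approx(0.25, abs=1e-6)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        v=st.floats(-4.0, 4.0),
        a=st.floats(0.4, 2.5),
        zr=st.floats(0.25, 0.75),
    )
    def test_density_nonnegative_everywhere(self, v, a, zr):
        p = DDMParams(v=v, a=a, t0=0.0, zr=zr)
        t = np.linspace(-0.1, 10.0, 500)
        assert (wiener_fpt_density(t, p, "upper") >= 0.0).all()
        assert (wiener_fpt_density(t, p, "lower") >= 0.0).all()


class TestSimulator:
    def test_simulated_times_match_density_cdf(self):
        # KS distance between simulated decision times and the density-implied
        # conditional CDF, per boundary
        p = DDMParams(v=1.2, a=1.1, t0=0.0)
        trials = simulate_ddm_trials(p, 50_000, seed=123)
        tgrid, cum_up, cum_lo = _fpt_grid(p)
        for resp, cum in ((1, cum_up), (0, cum_lo)):
            rts = trials.loc[trials.response == resp, "rt"].to_numpy()
            cdf = lambda x: np.interp(x, tgrid, cum / cum[-1])
            d = kstest(rts, cdf).statistic
            assert d < 0.01

    def test_accuracy_matches_absorption_probability(self):
        p = DDMParams(v=0.8, a=1.4, t0=0.2)
        trials = simulate_ddm_trials(p, 50_000, seed=7)
        p_up = absorption_probability(p, "upper")
        assert trials.response.mean() == pytest.approx(p_up, abs=4 * np.sqrt(p_up * (1 - p_up) / 50_000))

    def test_overwhelming_drift_all_correct(self):
        trials = simulate_ddm_trials(DDMParams(v=50.0, a=1.0, t0=0.3), 1000, seed=1)
        assert trials.response.mean() == 1.0

    def test_zero_drift_mean_rt(self):
        # t0 + closed-form mean first-passage time 0.25 s
        trials = simulate_ddm_trials(DDMParams(v=0.0, a=1.0, t0=0.3), 100_000, seed=2)
        assert trials.rt.mean() == pytest.approx(0.55, abs=0.005)

    def test_euler_agrees_with_inverse_cdf(self):
        p = DDMParams(v=1.5, a=1.0, t0=0.25)
        a = simulate_ddm_trials(p, 4000, seed=3, method="euler", dt=2e-4)
        b = simulate_ddm_trials(p, 4000, seed=3, method="inverse_cdf")
        assert a.response.mean() == pytest.approx(b.response.mean(), abs=0.03)
        assert a.rt.mean() == pytest.approx(b.rt.mean(), abs=0.02)

    def test_empty_and_reproducible(self):
        p = DDMParams(v=1.0, a=1.0, t0=0.3)
        assert len(simulate_ddm_trials(p, 0, seed=1)) == 0
        pd.testing.assert_frame_equal(
            simulate_ddm_trials(p, 100, seed=5), simulate_ddm_trials(p, 100, seed=5)
        )


class TestLoglik:
    def test_empty_table_gives_zero(self):
        p = DDMParams(v=1.0, a=1.0, t0=0.3)
        assert ddm_loglik(p, pd.DataFrame({"rt": [], "response": []})) == 0.0

    def test_matches_per_trial_brute_force(self):
        # term-by-term summation oracle over a handful of fixed trials
        p = DDMParams(v=1.3, a=0.9, t0=0.25)
        trials = pd.DataFrame(
            {"rt": [0.4, 0.55, 0.31, 0.8, 1.2], "response": [1, 1, 0, 1, 0]}
        )
        expected = 0.0
        for _, row in trials.iterrows():
            bound = "upper" if row.response == 1 else "lower"
            expected += np.log(wiener_fpt_density(row.rt - p.t0, p, bound))
        assert ddm_loglik(p, trials) == pytest.approx(expected, rel=1e-10)

    def test_premature_rts_use_floor_not_exception(self):
        p = DDMParams(v=1.0, a=1.0, t0=0.5)
        trials = pd.DataFrame({"rt": [0.4], "response": [1]})  # rt < t0
        ll = ddm_loglik(p, trials)
        assert np.isfinite(ll) and ll == pytest.approx(np.log(1e-10))

    def test_true_parameters_beat_perturbed(self):
        p = DDMParams(v=2.0, a=1.0, t0=0.3)
        trials = simulate_ddm_trials(p, 10_000, seed=4)
        worse = DDMParams(v=2.0, a=1.2, t0=0.3)
        assert ddm_loglik(p, trials) >= ddm_loglik(worse, trials)


class TestMLFit:
    def test_single_sample_recovery_within_5pct(self):
        p = DDMParams(v=2.0, a=1.0, t0=0.3)
        trials = simulate_ddm_trials(p, 10_000, seed=6)
        fit = fit_ddm_ml(trials)
        est = fit.params["all"]
        assert est.v == pytest.approx(2.0, rel=0.05)
        assert est.a == pytest.approx(1.0, rel=0.05)
        assert est.t0 == pytest.approx(0.3, rel=0.05)
        assert fit.converged

    def test_recovery_over_random_parameter_sets(self):
        # median absolute relative error below 3% per parameter
        rng = np.random.default_rng(8)
        errs = {"v": [], "a": [], "t0": []}
        for _ in range(25):
            true = DDMParams(
                v=rng.uniform(0.5, 3.5), a=rng.uniform(0.6, 1.8), t0=rng.uniform(0.2, 0.5)
            )
            trials = simulate_ddm_trials(true, 5000, seed=rng)
            est = fit_ddm_ml(trials, seed=rng).params["all"]
            for name in errs:
                errs[name].append(abs(getattr(est, name) - getattr(true, name)) / getattr(true, name))
        for name, e in errs.items():
            assert np.median(e) < 0.03, f"median relative error too high for {name}"

    def test_likelihood_separability(self):
        # unconstrained two-condition fit == independent per-condition fits
        p1, p2 = DDMParams(v=1.5, a=1.0, t0=0.3), DDMParams(v=2.5, a=1.3, t0=0.35)
        t1 = simulate_ddm_trials(p1, 800, seed=9).assign(condition="easy")
        t2 = simulate_ddm_trials(p2, 800, seed=10).assign(condition="hard")
        both = pd.concat([t1, t2], ignore_index=True)
        joint = fit_ddm_ml(both, seed=1)
        f1 = fit_ddm_ml(t1.drop(columns="condition"), seed=1)
        f2 = fit_ddm_ml(t2.drop(columns="condition"), seed=1)
        assert joint.loglik == pytest.approx(f1.loglik + f2.loglik, abs=0.1)
        assert joint.n_free_params == 6

    def test_shared_drift_constraint_returns_five_parameters(self):
        p = DDMParams(v=2.0, a=1.0, t0=0.3)
        t1 = simulate_ddm_trials(p, 400, seed=11).assign(condition="easy")
        t2 = simulate_ddm_trials(p, 400, seed=12).assign(condition="hard")
        both = pd.concat([t1, t2], ignore_index=True)
        fit = fit_ddm_ml(both, constraint=(False, True, True), seed=2)
        assert fit.n_free_params == 5
        assert fit.params["easy"].v == fit.params["hard"].v
        # nested likelihood: shared-v model can never beat the free model
        free = fit_ddm_ml(both, seed=2)
        assert fit.loglik <= free.loglik + 1e-6

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="trials"):
            fit_ddm_ml(pd.DataFrame({"rt": [0.5], "response": [1]}))


class TestEZ:
    def test_round_trip_recovery_within_5pct(self):
        p = DDMParams(v=2.0, a=1.0, t0=0.3)
        trials = simulate_ddm_trials(p, 100_000, seed=13)
        est = ez_fit_trials(trials)
        assert est.v == pytest.approx(2.0, rel=0.05)
        assert est.a == pytest.approx(1.0, rel=0.05)
        assert est.t0 == pytest.approx(0.3, rel=0.05)

    def test_perfect_accuracy_edge_corrected(self):
        # pc = 1 at n = 500 is treated as 1 - 1/(2*500) before inversion
        est = fit_ez(1.0, 0.05, 0.5, n_trials=500)
        corrected = fit_ez(1.0 - 1.0 / 1000.0, 0.05, 0.5, n_trials=500)
        assert np.isfinite(est.v) and est.v == corrected.v

    def test_chance_accuracy_edge_corrected(self):
        est = fit_ez(0.5, 0.08, 0.6, n_trials=200)
        assert np.isfinite(est.v) and est.v > 0

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_ez(0.8, 0.0, 0.5)

    def test_ez_and_ml_agree_on_large_clean_sample(self):
        p = DDMParams(v=1.8, a=1.1, t0=0.35)
        trials = simulate_ddm_trials(p, 20_000, seed=14)
        ez = ez_fit_trials(trials)
        ml = fit_ddm_ml(trials, seed=3).params["all"]
        for name in ("v", "a", "t0"):
            assert getattr(ez, name) == pytest.approx(getattr(ml, name), rel=0.10)


class TestParamValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DDMParams(v=1.0, a=-1.0, t0=0.3)
        with pytest.raises(ValueError):
            DDMParams(v=1.0, a=1.0, t0=-0.1)
        with pytest.raises(ValueError):
            DDMParams(v=1.0, a=1.0, t0=0.3, zr=1.2)
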