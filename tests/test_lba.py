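"""LBA engine: simulator, defective likelihood, fitting, caution."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import ndtr

from diffscore import LBAParams, compute_caution, fit_lba_ml, lba_loglik, simulate_lba_trials
from diffscore.lba import lba_finishing_cdf, lba_finishing_pdf, lba_start_heuristics


class TestSimulator:
    def test_strong_drift_gives_high_accuracy(self):
        p = LBAParams(v=4.0, A=0.5, b=1.5, t0=0.3)
        trials = simulate_lba_trials(p, 10_000, seed=1)
        assert trials.response.mean() > 0.95

    def test_zero_startpoint_limit(self):
        # A -> 0: every start is 0, so decision time is exactly b/drift and
        # can never undercut b divided by the largest plausible drift
        p = LBAParams(v=2.0, A=1e-9, b=1.2, t0=0.3)
        trials = simulate_lba_trials(p, 5000, seed=2)
        dec = trials.rt - p.t0
        assert (dec > 0).all()
        max_drift = max(p.v, 1 - p.v) + 6 * p.s
        assert dec.min() >= p.b / max_drift

    def test_accuracy_monotone_in_drift(self):
        accs = []
        for v in (1.0, 2.0, 3.0, 4.0):
            p = LBAParams(v=v, A=0.8, b=1.4, t0=0.3)
            accs.append(simulate_lba_trials(p, 10_000, seed=3).response.mean())
        assert all(b >= a for a, b in zip(accs, accs[1:]))

    def test_empty_and_reproducible(self):
        p = LBAParams(v=2.0, A=0.5, b=1.0, t0=0.2)
        assert len(simulate_lba_trials(p, 0, seed=1)) == 0
        pd.testing.assert_frame_equal(
            simulate_lba_trials(p, 200, seed=5), simulate_lba_trials(p, 200, seed=5)
        )


class TestLikelihood:
    def test_single_accumulator_normalizes(self):
        # finishing-time pdf mass plus the never-finishing mass equals 1
        v, A, b, s = 1.5, 0.8, 1.4, 0.3
        mass = quad(lba_finishing_pdf, 0, 200, args=(v, A, b, s), limit=300)[0]
        assert mass + ndtr(-v / s) == pytest.approx(1.0, abs=1e-6)

    def test_pdf_is_derivative_of_cdf(self):
        v, A, b, s = 2.0, 0.6, 1.2, 0.3
        t = np.linspace(0.05, 3.0, 50)
        h = 1e-6
        num = (lba_finishing_cdf(t + h, v, A, b, s) - lba_finishing_cdf(t - h, v, A, b, s)) / (2 * h)
        np.testing.assert_allclose(lba_finishing_pdf(t, v, A, b, s), num, atol=1e-5)

    def test_joint_defective_densities_normalize(self):
        # correct + error defective densities integrate to 1 after
        # renormalizing for redrawn all-negative-drift trials
        p = LBAParams(v=1.3, A=0.7, b=1.3, t0=0.0)
        z = 1.0 - float(ndtr(-p.v / p.s) * ndtr(-(1 - p.v) / p.s))

        def dens(t, win, lose):
            f = lba_finishing_pdf(np.array([t]), win, p.A, p.b, p.s)[0]
            surv = 1.0 - lba_finishing_cdf(np.array([t]), lose, p.A, p.b, p.s)[0]
            return f * surv / z

        total = (
            quad(dens, 0, 300, args=(p.v, 1 - p.v), limit=400)[0]
            + quad(dens, 0, 300, args=(1 - p.v, p.v), limit=400)[0]
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_density_matches_simulation_histogram(self):
        # chi-square agreement between simulated RTs and the defective density
        p = LBAParams(v=2.2, A=0.8, b=1.5, t0=0.25)
        trials = simulate_lba_trials(p, 100_000, seed=4)
        rt = trials.loc[trials.response == 1, "rt"].to_numpy()
        edges = np.quantile(rt, np.linspace(0, 1, 21))
        edges[0] -= 1e-9
        obs, _ = np.histogram(rt, edges)
        z = 1.0 - float(ndtr(-p.v / p.s) * ndtr(-(1 - p.v) / p.s))

        def dens(t):
            f = lba_finishing_pdf(np.array([t - p.t0]), p.v, p.A, p.b, p.s)[0]
            surv = 1.0 - lba_finishing_cdf(np.array([t - p.t0]), 1 - p.v, p.A, p.b, p.s)[0]
            return f * surv / z

        exp = np.array(
            [quad(dens, lo, hi, limit=200)[0] for lo, hi in zip(edges[:-1], edges[1:])]
        ) * len(trials)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        # 20 bins: generous bound ~ 3x the dof scale catches real mismatch
        assert chi2 < 60.0

    def test_empty_trials_and_floor(self):
        p = LBAParams(v=2.0, A=0.5, b=1.0, t0=0.4)
        assert lba_loglik(p, pd.DataFrame({"rt": [], "response": []})) == 0.0
        ll = lba_loglik(p, pd.DataFrame({"rt": [0.2], "response": [1]}))  # rt < t0
        assert ll == pytest.approx(np.log(1e-10))


class TestFit:
    def test_start_heuristics_match_stated_rules(self):
        rt = np.array([0.50, 0.60, 0.70, 0.80, 0.90])
        correct = np.array([True, True, True, False, True])
        v0, A0, b0, t00 = lba_start_heuristics(rt, correct)
        assert t00 == pytest.approx(0.45)  # 90% of the fastest response
        assert A0 == pytest.approx(2 * 0.2)  # twice the RT inter-quartile range
        assert b0 == pytest.approx(1.25 * A0)
        assert v0 == pytest.approx(0.5 + 0.3 * 0.8416, abs=1e-3)  # Phi^-1(0.8), sd 0.3

    def test_caution_recovery_within_10pct(self):
        p = LBAParams(v=2.5, A=1.0, b=1.5, t0=0.3)
        trials = simulate_lba_trials(p, 10_000, seed=6)
        fit = fit_lba_ml(trials, seed=6)
        est = fit.params["all"]
        assert est.caution == pytest.approx(p.caution, rel=0.10)
        assert est.b > est.A  # guaranteed by the b = A + delta parameterization

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="trials"):
            fit_lba_ml(pd.DataFrame({"rt": [0.5], "response": [1]}))


class TestDriftSDSensitivity:
    def test_artefact_not_specific_to_drift_sd_convention(self):
        # the caution-diff/t0-diff artefact must survive a different drift
        # SD scaling: generate and fit at s = 1 instead of the default 0.3
        import numpy as np
        from diffscore import sample_lba_population

        s = 1.0
        pop = sample_lba_population(100, seed=31)
        frames = []
        for _, row in pop.iterrows():
            p = LBAParams(v=row.v, A=row.A, b=row.b, t0=row.t0, s=s)
            ci = 0 if row.condition == "easy" else 1
            tr = simulate_lba_trials(p, 300, seed=np.random.default_rng([31, int(row.participant), ci]))
            tr.insert(0, "participant", row.participant)
            tr.insert(1, "condition", row.condition)
            frames.append(tr)
        trials = pd.concat(frames, ignore_index=True)
        rows = []
        for pid, sub in trials.groupby("participant"):
            fit = fit_lba_ml(sub, seed=np.random.default_rng([32, int(pid)]), s=s)
            for cond, q in fit.params.items():
                rows.append({"participant": pid, "condition": cond,
                             "caution": q.caution, "t0": q.t0})
        wide = pd.DataFrame(rows).pivot_table(
            index="participant", columns="condition", values=["caution", "t0"]
        )
        cd = wide[("caution", "hard")] - wide[("caution", "easy")]
        td = wide[("t0", "hard")] - wide[("t0", "easy")]
        assert np.corrcoef(cd, td)[0, 1] <= -0.5


class TestCaution:
    def test_direct_arithmetic(self):
        assert compute_caution(A=1.0, b=1.5) == pytest.approx(1.0)

    def test_zero_startpoint_limit(self):
        assert compute_caution(A=1e-12, b=1.3) == pytest.approx(1.3)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            compute_caution(A=1.5, b=1.0)
        with pytest.raises(ValueError):
            LBAParams(v=2.0, A=1.5, b=1.0, t0=0.3)

    def test_fitted_table_caution_recomputed(self, lba_study):
        # stored caution equals an independent recomputation from A and b
        fitted = lba_study["fitted"]
        recomputed = fitted.apply(lambda r: compute_caution(r.A, r.b), axis=1)
        np.testing.assert_allclose(fitted["caution"], recomputed, rtol=0, atol=1e-12)
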