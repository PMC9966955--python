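"""Cox prognostic index, KM estimator, log-rank test and hazard ratio."""

import numpy as np
import pandas as pd
import pytest

from fluidmark.prognosis import (
    evaluate_prognosis,
    fit_cox,
    hazard_ratio,
    km_curve,
    logrank_test,
    prognostic_index,
    stratify,
)
from fluidmark.simulate import CohortSimConfig, SurvivalCohort, simulate_survival_cohort


def cohort_from(expr: dict, time, event) -> SurvivalCohort:
    df = pd.DataFrame(expr)
    df.index = [f"S{i}" for i in range(len(df))]
    return SurvivalCohort(expression=df,
                          time=pd.Series(time, index=df.index, dtype=float),
                          event=pd.Series(event, index=df.index, dtype=bool))


class TestFitCox:
    def test_constant_covariate_gives_zero_beta(self):
        c = cohort_from({"G0": [1.0] * 6}, [1, 2, 3, 4, 5, 6], [True] * 6)
        fit = fit_cox(c, ["G0"])
        assert fit.betas["G0"] == 0.0 and fit.converged

    def test_parameter_recovery(self):
        c = simulate_survival_cohort(CohortSimConfig(
            n_subjects=2000, n_genes=1, true_beta=[0.8], censor_rate=0.2, seed=101))
        fit = fit_cox(c, ["G0"])
        assert fit.converged
        assert abs(fit.betas["G0"] - 0.8) < 0.1

    def test_collinear_design_flagged(self):
        x = [0.0, 1.0]
        c = cohort_from({"G0": x, "G1": x}, [1.0, 2.0], [True, True])
        fit = fit_cox(c, ["G0", "G1"])
        assert not fit.converged

    def test_zero_events_rejected(self):
        c = cohort_from({"G0": [0.1, 0.2, 0.3]}, [1, 2, 3], [False] * 3)
        with pytest.raises(ValueError):
            fit_cox(c, ["G0"])

    def test_missing_gene_rejected(self):
        c = cohort_from({"G0": [0.1, 0.2]}, [1, 2], [True, True])
        with pytest.raises(ValueError):
            fit_cox(c, ["NOPE"])


class TestPrognosticIndex:
    def test_zero_betas(self):
        c = cohort_from({"G0": [1.0, -1.0]}, [1, 2], [True, True])
        assert (prognostic_index(c, {"G0": 0.0}) == 0).all()

    def test_linearity_and_homogeneity(self):
        c = cohort_from({"G0": [1.0, -1.0]}, [1, 2], [True, True])
        pi = prognostic_index(c, {"G0": 2.0})
        assert list(pi) == [2.0, -2.0]
        assert (prognostic_index(c, {"G0": 4.0}) == 2 * pi).all()

    def test_affine_rescaling_preserves_order(self, rng):
        x = rng.normal(0, 1, 20)
        c = cohort_from({"G0": x}, np.arange(1, 21), [True] * 20)
        pi1 = prognostic_index(c, {"G0": 1.3})
        c2 = cohort_from({"G0": 5 * x + 2}, np.arange(1, 21), [True] * 20)
        pi2 = prognostic_index(c2, {"G0": 1.3 / 5})
        assert (pi1.rank() == pi2.rank()).all()

    def test_nonfinite_beta_rejected(self):
        c = cohort_from({"G0": [1.0, 2.0]}, [1, 2], [True, True])
        with pytest.raises(ValueError):
            prognostic_index(c, {"G0": float("nan")})


class TestStratify:
    def test_even_n_midpoint_threshold(self):
        pi = pd.Series([1.0, 2.0, 3.0, 4.0])
        groups, thr = stratify(pi)
        assert thr == 2.5
        assert list(groups) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_high(self):
        groups, _ = stratify(pd.Series([0.0, 0.0, 1.0]))
        assert list(groups) == ["high", "high", "high"] or list(groups) == ["high", "high", "high"]
        # median is 0; rule is pi >= median -> all three are high
        assert (groups == "high").all()

    def test_odd_n_split_sizes(self, rng):
        pi = pd.Series(rng.normal(size=101))
        groups, _ = stratify(pi)
        assert (groups == "high").sum() == 51 and (groups == "low").sum() == 50

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            stratify(pd.Series([1.0, 1.0, 1.0]))


class TestKmCurve:
    def test_no_censoring_empirical_survival(self):
        curve = km_curve([1.0, 2.0, 3.0], [True, True, True])
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        curve = km_curve([1.0, 2.0], [False, False])
        assert (curve["survival"] == 1.0).all()

    def test_hand_computed_product_limit_with_censoring(self):
        # events at 1,3,4,6; censored at 2,5
        times = [1, 2, 3, 4, 5, 6]
        events = [True, False, True, True, False, True]
        curve = km_curve(times, events)
        lookup = dict(zip(curve["time"], curve["survival"]))
        assert lookup[1.0] == pytest.approx(5 / 6)
        assert lookup[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert lookup[4.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert lookup[6.0] == pytest.approx(0.0)

    def test_monotone_from_one(self, rng):
        t = rng.exponential(1, 50)
        e = rng.random(50) < 0.7
        curve = km_curve(t, e)
        s = curve["survival"].to_numpy()
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, True, True]
        chi2, p = logrank_test((t, e), (t, e))
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_label_swap_invariance(self, rng):
        ta, tb = rng.exponential(1, 30), rng.exponential(2, 30)
        ea = eb = np.ones(30, bool)
        r1 = logrank_test((ta, ea), (tb, eb))
        r2 = logrank_test((tb, eb), (ta, ea))
        assert r1[0] == pytest.approx(r2[0], rel=1e-10)
        assert r1[1] == pytest.approx(r2[1], rel=1e-10)

    def test_strong_separation(self, rng):
        ta = rng.exponential(1.0, 100)
        tb = rng.exponential(5.0, 100)
        _, p = logrank_test((ta, np.ones(100, bool)), (tb, np.ones(100, bool)))
        assert p < 1e-6

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(([1.0], [False]), ([2.0], [False]))


class TestHazardRatio:
    def test_identical_groups_hr_near_one(self, rng):
        t = rng.exponential(1, 400)
        labels = np.array(["high", "low"] * 200)
        hr, ci = hazard_ratio(labels, t, np.ones(400, bool))
        assert ci[0] < 1 < ci[1]

    def test_recovery_of_planted_group_effect(self, rng):
        n = 2000
        labels = np.array(["high"] * (n // 2) + ["low"] * (n // 2))
        haz = 0.1 * np.exp(np.where(labels == "high", 0.7, 0.0))
        t = rng.exponential(1 / haz)
        hr, _ = hazard_ratio(labels, t, np.ones(n, bool))
        assert abs(hr - np.exp(0.7)) / np.exp(0.7) < 0.15

    def test_swapping_labels_inverts_hr(self, rng):
        n = 100
        labels = np.array(["high"] * 50 + ["low"] * 50)
        t = rng.exponential(np.where(labels == "high", 0.5, 1.0))
        hr, _ = hazard_ratio(labels, t, np.ones(n, bool))
        swapped = np.where(labels == "high", "low", "high")
        hr_swapped, _ = hazard_ratio(swapped, t, np.ones(n, bool))
        assert hr == pytest.approx(1 / hr_swapped, rel=1e-6)

    def test_group_without_events_rejected(self):
        labels = ["high", "high", "low", "low"]
        with pytest.raises(ValueError):
            hazard_ratio(labels, [1, 2, 3, 4], [True, True, False, False])


class TestEndToEnd:
    def test_planted_signal_detected(self):
        c = simulate_survival_cohort(CohortSimConfig(
            n_subjects=500, n_genes=1, true_beta=[0.5], censor_rate=0.2, seed=55))
        strat = evaluate_prognosis(c, ["G0"])
        assert strat.logrank_p < 0.05
        assert strat.hazard_ratio > 1.0

    def test_group_sizes_balanced(self):
        c = simulate_survival_cohort(CohortSimConfig(n_subjects=200, seed=3))
        strat = evaluate_prognosis(c, c.genes)
        n_high = (strat.groups == "high").sum()
        assert abs(n_high - 100) <= 1


class TestKmPlot:
    def test_plot_written(self, tmp_path):
        c = simulate_survival_cohort(CohortSimConfig(n_subjects=80, seed=12))
        from fluidmark.prognosis import evaluate_prognosis, km_plot

        strat = evaluate_prognosis(c, c.genes)
        out = tmp_path / "km.png"
        km_plot(strat, c, path=str(out))
        assert out.exists() and out.stat().st_size > 0
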