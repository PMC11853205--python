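"""Cox regression, stepwise selection, ROC cutoffs, KM / log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from _oracles import (cox_loglik_enumerated, km_survival_product,
                      logrank_chi2_enumerated, youden_exhaustive)
from petdmax import (GeneratorConfig, SeparationError, cox_fit, cox_stepwise,
                     km_logrank, roc_best_cutoff, sample_feature_table,
                     stratify_dmax_mtv)


def make_cohort(time, event, **covariates):
    df = pd.DataFrame({"os_months": time, "os_event": event})
    for name, vals in covariates.items():
        df[name] = vals
    return df


class TestCoxFit:
    def test_four_subject_enumeration_oracle(self):
        # times {1,2,3,4}, all events: explicit risk-set enumeration.  The
        # covariate must not perfectly order the deaths (that is monotone
        # likelihood, tested separately), so x alternates.
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        res = minimize_scalar(
            lambda b: -cox_loglik_enumerated(b, x, time, event),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10})
        fit = cox_fit(make_cohort(time, event, x=x), "OS", ["x"])
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-6)
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-6)

    @pytest.mark.parametrize("n,seed", [(6, 0), (6, 1), (5, 2)])
    def test_small_datasets_match_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        time = rng.permutation(np.arange(1.0, n + 1))
        event = np.ones(n, dtype=int)
        x = rng.normal(size=n)
        fit = cox_fit(make_cohort(time, event, x=x), "OS", ["x"])
        ll_oracle = cox_loglik_enumerated(fit.coef[0], x, time, event)
        assert fit.log_likelihood == pytest.approx(ll_oracle, abs=1e-6)
        # oracle optimum
        res = minimize_scalar(
            lambda b: -cox_loglik_enumerated(b, x, time, event),
            bounds=(-15, 15), method="bounded", options={"xatol": 1e-10})
        assert fit.coef[0] == pytest.approx(res.x, abs=1e-5)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter
        n = 120
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, size=n)
        time = np.ceil(rng.exponential(10 * np.exp(-0.5 * x1), size=n))  # ties
        event = rng.binomial(1, 0.8, size=n)
        df = make_cohort(time, event, x1=x1, x2=x2.astype(float))
        fit = cox_fit(df, "OS", ["x1", "x2"], ties="efron")
        cph = CoxPHFitter()
        cph.fit(df, "os_months", "os_event")
        np.testing.assert_allclose(fit.coef,
                                   cph.params_[["x1", "x2"]].values, atol=1e-5)
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-5)
        np.testing.assert_allclose(
            fit.se, cph.standard_errors_[["x1", "x2"]].values, atol=1e-5)

    def test_breslow_differs_from_efron_under_ties(self, rng):
        n = 60
        x = rng.normal(size=n)
        time = np.ceil(rng.exponential(5, size=n))
        event = np.ones(n, dtype=int)
        df = make_cohort(time, event, x=x)
        fe = cox_fit(df, "OS", ["x"], ties="efron")
        fb = cox_fit(df, "OS", ["x"], ties="breslow")
        assert fe.coef[0] != pytest.approx(fb.coef[0], abs=1e-12)

    def test_null_covariate_small_beta(self, rng):
        n = 200
        x = rng.normal(size=n)
        time = rng.exponential(10, size=n)
        event = np.ones(n, dtype=int)
        fit = cox_fit(make_cohort(time, event, x=x), "OS", ["x"])
        assert abs(fit.coef[0]) < 3 * fit.se[0] + 0.2

    def test_parameter_recovery_beta_07(self):
        rng = np.random.default_rng(42)
        n = 500
        x = rng.normal(size=n)
        time = rng.exponential(np.exp(-0.7 * x) / 0.05)
        event = np.ones(n, dtype=int)
        fit = cox_fit(make_cohort(time, event, x=x), "OS", ["x"])
        assert fit.coef[0] == pytest.approx(0.7, abs=3 * fit.se[0])
        assert fit.hazard_ratio[0] == pytest.approx(np.exp(fit.coef[0]))

    def test_no_events_errors(self):
        df = make_cohort([1.0, 2.0], [0, 0], x=[0.0, 1.0])
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, "OS", ["x"])

    def test_perfect_separation_names_variable(self):
        # covariate order identical to death order: monotone likelihood
        time = np.arange(1.0, 21.0)
        event = np.ones(20, dtype=int)
        sep = -np.arange(20.0)
        df = make_cohort(time, event, sep=sep)
        with pytest.raises(SeparationError, match="sep"):
            cox_fit(df, "OS", ["sep"])

    def test_missing_rows_excluded(self, rng):
        n = 50
        df = make_cohort(rng.exponential(5, n), np.ones(n, dtype=int),
                         x=rng.normal(size=n))
        df.loc[:4, "x"] = np.nan
        fit = cox_fit(df, "OS", ["x"])
        assert fit.n == n - 5

    def test_wald_type_one_error_calibrated(self):
        # null simulation: rejection rate at 5% within binomial 99% bounds
        rng = np.random.default_rng(12345)
        n, reps = 200, 1000
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            time = rng.exponential(10, size=n)
            event = rng.binomial(1, 0.8, size=n)
            fit = cox_fit(make_cohort(time, event, x=x), "OS", ["x"])
            rejections += fit.wald_p[0] < 0.05
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < half_width + 1e-9


class TestStepwise:
    def simulate(self, rng, n=500, beta=1.0):
        strong = rng.normal(size=n)
        noise = {f"n{i}": rng.normal(size=n) for i in range(4)}
        time = rng.exponential(np.exp(-beta * strong) / 0.05)
        event = np.ones(n, dtype=int)
        return make_cohort(time, event, strong=strong, **noise)

    def test_strong_predictor_retained(self, rng):
        df = self.simulate(rng)
        fit = cox_stepwise(df, "OS", ["strong", "n0", "n1", "n2", "n3"])
        assert "strong" in fit.variables
        assert fit.inclusion_log[0].startswith("add strong")

    def test_all_noise_usually_empty_never_errors(self):
        rng = np.random.default_rng(7)
        empties = 0
        for _ in range(20):
            df = self.simulate(rng, n=150, beta=0.0)
            fit = cox_stepwise(df, "OS",
                               ["strong", "n0", "n1", "n2", "n3"])
            empties += len(fit.variables) == 0
        # P(any of 5 null candidates entering) ~ 1-(1-.05)^5 ~ 0.23
        assert empties >= 10

    def test_single_significant_candidate_equals_plain_fit(self, rng):
        df = self.simulate(rng, n=300)
        step = cox_stepwise(df, "OS", ["strong"])
        plain = cox_fit(df, "OS", ["strong"])
        assert step.variables == plain.variables
        assert step.coef[0] == pytest.approx(plain.coef[0], rel=1e-10)


class TestRocCutoff:
    def test_perfect_separation_midpoint(self):
        df = make_cohort([1.0] * 4, [0, 0, 1, 1], marker=[1.0, 2.0, 9.0, 10.0])
        cut = roc_best_cutoff(df, "marker", "OS")
        assert cut.cutoff == pytest.approx(5.5)
        assert cut.youden_j == pytest.approx(1.0)
        assert cut.sensitivity == 1.0 and cut.specificity == 1.0

    def test_uninformative_marker_j_zero(self):
        df = make_cohort([1.0] * 6, [0, 1, 0, 1, 0, 1],
                         marker=[3.0, 3.0, 5.0, 5.0, 7.0, 7.0])
        cut = roc_best_cutoff(df, "marker", "OS")
        assert cut.youden_j == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            n = 200
            values = np.round(rng.normal(size=n), 2)
            labels = rng.binomial(1, 0.4, size=n)
            if labels.min() == labels.max():
                continue
            df = make_cohort(np.ones(n), labels, marker=values)
            cut = roc_best_cutoff(df, "marker", "OS")
            j_oracle, _ = youden_exhaustive(values, labels)
            assert cut.youden_j == pytest.approx(j_oracle, abs=1e-12)

    def test_tie_broken_toward_lower_cutoff(self):
        # two cutoffs achieve J=1; the lower midpoint must be returned
        df = make_cohort([1.0] * 4, [0, 0, 1, 1], marker=[1.0, 2.0, 8.0, 9.0])
        cut = roc_best_cutoff(df, "marker", "OS")
        assert cut.cutoff == pytest.approx(5.0)

    def test_single_class_errors(self):
        df = make_cohort([1.0, 2.0], [1, 1], marker=[1.0, 2.0])
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_best_cutoff(df, "marker", "OS")


class TestKmLogrank:
    def test_identical_groups_chi2_zero(self):
        time = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        event = [1, 1, 0, 1, 1, 0]
        df = make_cohort(time, event)
        res = km_logrank(df, "OS", ["a", "a", "a", "b", "b", "b"])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_four_subject_hand_enumeration(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        group = np.array(["A", "A", "B", "B"])
        df = make_cohort(time, event)
        res = km_logrank(df, "OS", group)
        expected = logrank_chi2_enumerated(time, event, group)
        assert res.chi_square == pytest.approx(expected, abs=1e-9)

    def test_three_groups_df_two(self, rng):
        n = 60
        df = make_cohort(rng.exponential(5, n), np.ones(n, dtype=int))
        res = km_logrank(df, "OS", rng.choice(["a", "b", "c"], size=n))
        assert res.df == 2
        assert len(res.curves) == 3

    def test_km_curves_start_at_one_nonincreasing(self, rng):
        n = 40
        df = make_cohort(rng.exponential(5, n), rng.binomial(1, 0.7, n))
        res = km_logrank(df, "OS", rng.choice(["x", "y"], size=n))
        for times, surv in res.curves.values():
            assert surv[0] == pytest.approx(1.0)
            assert np.all(np.diff(surv) <= 1e-12)

    def test_km_terminal_value_closed_form(self, rng):
        n = 30
        time = np.ceil(rng.exponential(5, n))
        event = rng.binomial(1, 0.7, n)
        if event.sum() == 0:
            event[0] = 1
        df = make_cohort(np.concatenate([time, time + 0.5]),
                         np.concatenate([event, event]))
        group = ["g1"] * n + ["g2"] * n
        res = km_logrank(df, "OS", group)
        times, surv = res.curves["g1"]
        expected = km_survival_product(time, event)
        assert surv[-1] == pytest.approx(expected, abs=1e-9)

    def test_invariance_relabel_and_monotone_time_transform(self, rng):
        n = 50
        time = rng.exponential(5, n)
        event = rng.binomial(1, 0.8, n)
        group = rng.choice(["a", "b"], size=n)
        df = make_cohort(time, event)
        base = km_logrank(df, "OS", group).chi_square
        relabel = km_logrank(df, "OS",
                             np.where(group == "a", "z", "q")).chi_square
        transformed = km_logrank(make_cohort(np.exp(time / 10), event), "OS",
                                 group).chi_square
        assert relabel == pytest.approx(base, abs=1e-9)
        assert transformed == pytest.approx(base, abs=1e-9)

    def test_fewer_than_two_groups_errors(self):
        df = make_cohort([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="2"):
            km_logrank(df, "OS", ["a", "a"])

    def test_all_censored_errors(self):
        df = make_cohort([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="censored"):
            km_logrank(df, "OS", ["a", "a", "b", "b"])


class TestStratify:
    def test_boundary_counts_as_below(self):
        df = pd.DataFrame({"dmax_cm": [8.8], "mtv_tot_ml": [83.9]})
        assert stratify_dmax_mtv(df, 8.8, 83.9).iloc[0] == "both_low"

    def test_one_above(self):
        df = pd.DataFrame({"dmax_cm": [10.0], "mtv_tot_ml": [50.0]})
        assert stratify_dmax_mtv(df, 8.8, 83.9).iloc[0] == "one_high"

    def test_both_above(self):
        df = pd.DataFrame({"dmax_cm": [10.0], "mtv_tot_ml": [100.0]})
        assert stratify_dmax_mtv(df, 8.8, 83.9).iloc[0] == "both_high"

    def test_missing_column_errors(self):
        with pytest.raises(KeyError):
            stratify_dmax_mtv(pd.DataFrame({"dmax_cm": [1.0]}), 1, 1)
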