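"""Outcome models: fits, metrics, CV selection, consensus, stratification."""

import numpy as np
import pandas as pd
import pytest

import dcetrack as dt
from dcetrack.outcome_models import _stratified_folds


def brute_force_auc(labels, scores):
    num = den = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] == 1 and labels[j] == 0:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def brute_force_c(times, events, scores):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestMetrics:
    def test_perfect_separation_auc(self):
        assert dt.auc_score(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1])) == 1.0

    def test_worked_auc_example(self):
        auc = dt.auc_score(np.array([1, 0, 1, 0]), np.array([0.9, 0.2, 0.15, 0.1]))
        assert auc == pytest.approx(0.75)

    def test_all_concordant_c(self):
        c = dt.harrell_c(np.array([1.0, 2, 3]), np.array([1, 1, 1]), np.array([3.0, 2, 1]))
        assert c == 1.0

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            dt.auc_score(np.ones(4), np.random.default_rng(0).random(4))

    def test_no_usable_pairs_c_undefined(self):
        with pytest.raises(ValueError, match="usable"):
            dt.harrell_c(np.array([1.0, 2.0]), np.array([0, 0]), np.array([1.0, 2.0]))

    @pytest.mark.parametrize("seed", range(10))
    def test_rank_formulations_match_brute_force(self, seed):
        """AUC and Harrell's C equal brute-force pair enumeration on small
        tables with ties."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert dt.auc_score(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores))
        times = np.round(rng.exponential(2, n), 1) + 0.1
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        assert dt.harrell_c(times, events, scores) == pytest.approx(
            brute_force_c(times, events, scores))

    def test_c_agrees_with_lifelines_on_tie_free_data(self):
        # lifelines orients scores the other way (higher = longer survival)
        # and treats time ties differently, so compare on tie-free data
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(5)
        times = rng.permutation(np.arange(1.0, 41.0))
        events = rng.integers(0, 2, 40)
        events[0] = 1
        scores = rng.standard_normal(40)
        assert dt.harrell_c(times, events, scores) == pytest.approx(
            concordance_index(times, -scores, events))

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        assert dt.auc_score(labels, scores) == pytest.approx(roc_auc_score(labels, scores))


class TestFits:
    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(0)
        n = 400
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=n, seed=0))
        fit = dt.fit_outcome_model(table, ["frac_jacobian"], "logistic")
        assert abs(fit.coef["frac_jacobian"]) < 2 * fit.se["frac_jacobian"]

    def test_aic_definitional_identity(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=150, seed=1))
        for family in ("logistic", "cox"):
            fit = dt.fit_outcome_model(table, list(dt.BASELINE_COVARIATES), family)
            assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)

    def test_cox_matches_lifelines_directly(self):
        """Cross-check the wrapped Cox fit against a direct lifelines fit on
        pre-standardized data."""
        from lifelines import CoxPHFitter

        table = dt.simulate_cohort(
            dt.CohortSpec(n_patients=300, log_hazard={"frac_jacobian": 0.7}, seed=2))
        fit = dt.fit_outcome_model(table, ["frac_jacobian"], "cox")
        z = (table["frac_jacobian"] - table["frac_jacobian"].mean()) / table[
            "frac_jacobian"].std(ddof=0)
        df = pd.DataFrame({"z": z, "rfs_time": table["rfs_time"],
                           "rfs_event": table["rfs_event"]})
        cph = CoxPHFitter().fit(df, "rfs_time", "rfs_event")
        assert fit.coef["frac_jacobian"] == pytest.approx(cph.params_["z"], rel=1e-6)

    def test_perfect_separation_flagged_not_raised(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=60, seed=3))
        table["sep"] = np.where(table["pcr"] == 1, 10.0, -10.0)
        fit = dt.fit_outcome_model(table, ["sep"], "logistic")
        assert not fit.converged
        assert fit.aic == np.inf

    def test_pcr_missing_rows_excluded_from_logistic_only(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=200, pcr_missing_rate=0.1, seed=4))
        fit_l = dt.fit_outcome_model(table, ["age"], "logistic")
        fit_c = dt.fit_outcome_model(table, ["age"], "cox")
        assert fit_l.n == table["pcr"].notna().sum()
        assert fit_c.n == len(table)

    def test_hormone_categorical_mode(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=300, seed=5))
        fit = dt.fit_outcome_model(table, ["hormone_status"], "logistic",
                                   hormone_coding="categorical")
        assert "hormone_2" in fit.coef.index and "hormone_3" in fit.coef.index


class TestCVSelect:
    def test_folds_partition_rows(self):
        rng = np.random.default_rng(0)
        strata = rng.integers(0, 2, 103)
        assign = _stratified_folds(strata, 5, rng)
        assert len(assign) == 103
        assert set(assign) == set(range(5))
        # stratification balances classes across folds
        for f in range(5):
            frac = strata[assign == f].mean()
            assert abs(frac - strata.mean()) < 0.15

    def test_nested_sequence_covers_all_candidates(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=150, seed=6))
        report = dt.cv_select(table, dt.BASELINE_COVARIATES,
                              list(dt.VOXELWISE_FEATURES), "logistic", seed=0)
        for fold in report.folds:
            assert len(fold.ranked) == 7  # one nested model per candidate

    def test_informative_feature_selected_in_most_folds(self):
        table = dt.simulate_cohort(
            dt.CohortSpec(n_patients=400, log_odds={"frac_jacobian": np.log(3)}, seed=7))
        report = dt.cv_select(table, dt.BASELINE_COVARIATES,
                              list(dt.VOXELWISE_FEATURES), "logistic", seed=8)
        assert report.selection_counts["frac_jacobian"] >= 4

    def test_deterministic_given_seed(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=150, seed=9))
        r1 = dt.cv_select(table, dt.BASELINE_COVARIATES,
                          list(dt.AGGREGATE_FEATURES), "cox", seed=10)
        r2 = dt.cv_select(table, dt.BASELINE_COVARIATES,
                          list(dt.AGGREGATE_FEATURES), "cox", seed=10)
        assert r1.selection_counts == r2.selection_counts
        assert r1.mean_metric == r2.mean_metric
        assert [f.selected for f in r1.folds] == [f.selected for f in r2.folds]

    def test_candidate_order_invariance(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=200, seed=11))
        cands = list(dt.VOXELWISE_FEATURES)
        r1 = dt.cv_select(table, dt.BASELINE_COVARIATES, cands, "logistic", seed=12)
        r2 = dt.cv_select(table, dt.BASELINE_COVARIATES, cands[::-1], "logistic", seed=12)
        assert r1.selection_counts == r2.selection_counts
        assert r1.mean_metric == pytest.approx(r2.mean_metric)


class TestConsensusRefit:
    def test_four_of_five_included(self):
        table = dt.simulate_cohort(
            dt.CohortSpec(n_patients=400, log_odds={"frac_jacobian": np.log(3)}, seed=13))
        report = dt.cv_select(table, dt.BASELINE_COVARIATES,
                              list(dt.VOXELWISE_FEATURES), "logistic", seed=14)
        assert report.selection_counts["frac_jacobian"] >= 4
        assert "frac_jacobian" in report.consensus()

    def test_empty_consensus_returns_baseline_with_p_one(self):
        report = dt.CVReport("logistic", [], 0.5, 0.0,
                             {"frac_jacobian": 1, "frac_PRM_PE": 0}, 5, 0)
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=150, seed=15))
        full, base, p = dt.consensus_refit(report, table, dt.BASELINE_COVARIATES, "logistic")
        assert p == 1.0
        assert full is base

    def test_lrt_statistic_nonnegative_and_identity_case(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=150, seed=16))
        base = dt.fit_outcome_model(table, list(dt.BASELINE_COVARIATES), "logistic")
        assert dt.likelihood_ratio_p(base, base, df=1) == pytest.approx(1.0)


class TestRiskStratify:
    def test_even_cohort_splits_into_equal_groups(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=200, seed=17))
        fit = dt.fit_outcome_model(table, ["frac_jacobian", "age"], "cox")
        strat = dt.risk_stratify(fit, table)
        assert abs(int((strat.groups == 1).sum()) - 100) <= 1

    def test_constant_signature_flagged_single_group(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=100, seed=18))
        fit = dt.fit_outcome_model(table, ["frac_jacobian"], "cox")
        fit.coef["frac_jacobian"] = 0.0
        strat = dt.risk_stratify(fit, table)
        assert "constant_risk_signature" in strat.flags
        assert (strat.groups == 0).all()

    def test_strong_effect_separates_groups(self):
        table = dt.simulate_cohort(
            dt.CohortSpec(n_patients=200, log_hazard={"frac_jacobian": 1.5},
                          censor_rate=0.5, seed=19))
        fit = dt.fit_outcome_model(table, ["frac_jacobian"], "cox")
        strat = dt.risk_stratify(fit, table)
        assert strat.logrank_p < 0.01
        assert strat.survival_ratio_at_median_time > 1.0

    def test_logistic_fit_rejected(self):
        table = dt.simulate_cohort(dt.CohortSpec(n_patients=100, seed=20))
        fit = dt.fit_outcome_model(table, ["age"], "logistic")
        with pytest.raises(ValueError, match="cox"):
            dt.risk_stratify(fit, table)
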