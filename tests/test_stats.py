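"""Evaluation statistics: exact binomial CIs, Cohen's kappa, Cox hazard
ratios, the OR-combination rule, longitudinal aggregation and the paired
accuracy bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neomer_mrd.errors import NeomerMRDError
from neomer_mrd.stats import (
    ConfusionMatrix,
    aggregate_longitudinal,
    bootstrap_accuracy_compare,
    clopper_pearson,
    cohens_kappa,
    combine_status,
    confusion_from_calls,
    kappa_from_table,
    km_cox_hr,
    metrics,
)

from oracle_utils import cox_hr_grid


class TestConfusion:
    def test_all_positive_agreement(self):
        cm = confusion_from_calls([True] * 4, [True] * 4)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (4, 0, 0, 0)

    def test_polarity_swap_symmetry(self):
        rng = np.random.default_rng(0)
        calls = rng.random(30) < 0.5
        labels = rng.random(30) < 0.5
        cm = confusion_from_calls(calls, labels)
        sw = confusion_from_calls(~calls, labels)
        assert (sw.tp, sw.fp, sw.fn, sw.tn) == (cm.fn, cm.tn, cm.tp, cm.fp)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestMetrics:
    def test_exact_binomial_operating_point(self):
        # 10/1/15/13 cohort: sensitivity 40% (21.1-61.3), specificity
        # 92.9% (66.1-99.8) at the printed precision
        m = metrics(ConfusionMatrix(10, 1, 15, 13))
        assert m["sensitivity"].estimate == pytest.approx(0.400, abs=5e-4)
        assert m["sensitivity"].ci_low == pytest.approx(0.211, abs=5e-4)
        assert m["sensitivity"].ci_high == pytest.approx(0.613, abs=5e-4)
        assert m["specificity"].estimate == pytest.approx(0.929, abs=5e-4)
        assert m["specificity"].ci_low == pytest.approx(0.661, abs=5e-4)
        assert m["specificity"].ci_high == pytest.approx(0.998, abs=5e-4)

    def test_accuracy_and_npv_small_cohort(self):
        m = metrics(ConfusionMatrix(5, 1, 6, 13))
        assert m["accuracy"].estimate == pytest.approx(0.720, abs=5e-4)
        assert m["npv"].estimate == pytest.approx(0.684, abs=5e-4)

    def test_saturated_specificity_ci_upper_is_one(self):
        m = metrics(ConfusionMatrix(9, 0, 11, 13))
        assert m["specificity"].estimate == 1.0
        assert m["specificity"].ci_high == 1.0
        assert m["specificity"].ci_low == pytest.approx(0.753, abs=5e-4)

    def test_zero_denominator_reported_as_none_not_zero(self):
        m = metrics(ConfusionMatrix(0, 0, 0, 5))  # nobody progressed
        assert m["sensitivity"] is None
        assert m["ppv"] is None
        assert m["specificity"].estimate == 1.0

    def test_clopper_pearson_coverage(self):
        """95% CIs on Binomial(25, 0.4) draws cover p in >= 94% of 2000
        simulations (exact intervals are conservative)."""
        rng = np.random.default_rng(123)
        draws = rng.binomial(25, 0.4, size=2000)
        covered = 0
        for x in draws:
            ci = clopper_pearson(int(x), 25)
            covered += ci.ci_low <= 0.4 <= ci.ci_high
        assert covered / 2000 >= 0.94


class TestKappa:
    def test_perfect_agreement(self):
        assert kappa_from_table(5, 0, 0, 5) == 1.0

    def test_independence_gives_zero(self):
        # cells proportional to marginal products: 20/20/30/30 split
        assert kappa_from_table(8, 12, 8, 12) == pytest.approx(0.0, abs=1e-12)

    def test_published_landmark_agreement_value(self):
        # 6 model-high, 4 assay-positive, 2 overlap among 25 samples
        assert kappa_from_table(2, 4, 2, 17) == pytest.approx(0.2574, abs=1e-4)

    def test_label_swap_invariance(self):
        assert kappa_from_table(3, 4, 5, 8) == pytest.approx(
            kappa_from_table(8, 5, 4, 3)
        )

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        r1 = cohens_kappa(2, 4, 2, 17, n_boot=500, seed=7)
        r2 = cohens_kappa(2, 4, 2, 17, n_boot=500, seed=7)
        assert r1 == r2
        assert r1["ci_low"] <= r1["kappa"] <= r1["ci_high"]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_kappa_bounded(self, table):
        a, b, c, d = table
        if a + b + c + d < 2:
            return
        k = kappa_from_table(a, b, c, d)
        if not np.isnan(k):
            assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12


class TestCox:
    def test_identical_groups_hr_one(self):
        time = [3.0, 5.0, 7.0, 11.0] * 2
        event = [True, True, False, True] * 2
        group = [True] * 4 + [False] * 4
        res, km = km_cox_hr(time, event, group)
        assert res.hr == pytest.approx(1.0, abs=1e-6)
        assert set(km["group"]) == {"high", "low"}

    def test_matches_partial_likelihood_grid_oracle(self):
        # interleaved event times so the partial likelihood has a finite
        # maximizer (fully separated groups would diverge)
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        event = [True] * 6
        group = [True, False, True, False, True, False]
        res, _ = km_cox_hr(time, event, group)
        oracle = cox_hr_grid(time, event, group)
        assert res.hr == pytest.approx(oracle, rel=2e-3)

    def test_random_data_matches_grid_oracle(self):
        rng = np.random.default_rng(42)
        group = rng.random(30) < 0.5
        time = rng.exponential(np.where(group, 0.5, 1.0))
        event = rng.random(30) < 0.8
        res, _ = km_cox_hr(time, event, group)
        oracle = cox_hr_grid(time, event, group)
        assert res.hr == pytest.approx(oracle, rel=2e-3)

    def test_monotone_likelihood_flagged_not_raised(self):
        # all events in the high group: beta diverges
        time = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        event = [True, True, True, False, False, False]
        group = [True, True, True, False, False, False]
        res, _ = km_cox_hr(time, event, group)
        assert not res.converged
        assert res.ci_low == 0.0 and np.isinf(res.ci_high)

    def test_single_group_is_an_error(self):
        with pytest.raises(NeomerMRDError):
            km_cox_hr([1.0, 2.0], [True, True], [True, True])

    def test_km_curves_start_at_one_and_decrease(self):
        rng = np.random.default_rng(1)
        time = rng.exponential(1.0, 20)
        event = rng.random(20) < 0.7
        group = rng.random(20) < 0.5
        _, km = km_cox_hr(time, event, group)
        for _, grp in km.groupby("group"):
            surv = grp.sort_values("time")["survival"].to_numpy()
            assert surv[0] == 1.0
            assert (np.diff(surv) <= 1e-12).all()


class TestCombineAndAggregate:
    def test_or_rule_truth_table(self):
        out = combine_status([True, False, False, True], [False, False, True, True])
        assert out.tolist() == [True, False, True, True]

    def test_or_rule_monotone_in_sensitivity_and_specificity(self):
        rng = np.random.default_rng(3)
        labels = rng.random(50) < 0.5
        a = rng.random(50) < 0.4
        b = rng.random(50) < 0.3
        combined = combine_status(a, b)
        for component in (a, b):
            cm_c = confusion_from_calls(combined, labels)
            cm_a = confusion_from_calls(component, labels)
            sens = lambda cm: cm.tp / (cm.tp + cm.fn)
            spec = lambda cm: cm.tn / (cm.tn + cm.fp)
            assert sens(cm_c) >= sens(cm_a)
            assert spec(cm_c) <= spec(cm_a)

    def test_any_positive_aggregation(self):
        calls = pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p1", "p2", "p2", "p3"],
                "timepoint": ["TP1", "TP2", "TP3", "TP1", "TP2", "TP1"],
                "high_risk": [False, True, False, False, False, False],
            }
        )
        agg = aggregate_longitudinal(calls).set_index("patient_id")
        assert agg.loc["p1", "high_risk"]
        assert not agg.loc["p2", "high_risk"]
        complete = aggregate_longitudinal(calls, complete_cases_only=True)
        assert complete["patient_id"].tolist() == ["p1"]

    def test_aggregated_sensitivity_dominates_single_timepoints(self):
        rng = np.random.default_rng(5)
        patients = [f"p{i}" for i in range(30)]
        labels = {p: bool(rng.random() < 0.5) for p in patients}
        rows = []
        for tp in ("TP1", "TP2", "TP3"):
            for p in patients:
                # perfect specificity, imperfect sensitivity per time point
                call = labels[p] and bool(rng.random() < 0.5)
                rows.append({"patient_id": p, "timepoint": tp, "high_risk": call})
        calls = pd.DataFrame(rows)
        agg = aggregate_longitudinal(calls).set_index("patient_id")
        y = np.array([labels[p] for p in patients])
        agg_calls = agg.loc[patients, "high_risk"].to_numpy()
        agg_sens = (agg_calls & y).sum() / y.sum()
        for tp in ("TP1", "TP2", "TP3"):
            tp_calls = (
                calls[calls["timepoint"] == tp].set_index("patient_id")
                .loc[patients, "high_risk"].to_numpy()
            )
            assert agg_sens >= (tp_calls & y).sum() / y.sum()


class TestBootstrapCompare:
    def test_identical_call_sets_give_zero_differences(self):
        rng = np.random.default_rng(0)
        calls = rng.random(20) < 0.5
        labels = rng.random(20) < 0.5
        res = bootstrap_accuracy_compare(calls, calls, labels, n_boot=200, seed=1)
        assert res["mean_difference"] == 0.0
        assert res["wilcoxon_p"] == 1.0

    def test_dominating_call_set_is_significant(self):
        labels = np.array([True, False] * 25)
        perfect = labels.copy()
        noisy = labels.copy()
        noisy[::3] = ~noisy[::3]
        res = bootstrap_accuracy_compare(perfect, noisy, labels, n_boot=1000, seed=2)
        assert res["mean_difference"] > 0
        assert res["wilcoxon_p"] < 0.001

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        a = rng.random(30) < 0.5
        b = rng.random(30) < 0.5
        y = rng.random(30) < 0.5
        r1 = bootstrap_accuracy_compare(a, b, y, n_boot=300, seed=9)
        r2 = bootstrap_accuracy_compare(a, b, y, n_boot=300, seed=9)
        assert r1 == r2
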