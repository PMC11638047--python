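"""Cohort statistics: percent change, rank tests, logistic ROC with DeLong CI."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dcequant import (paired_t_test, percent_change, predict_response,
                      roc_auc, wilcoxon_rank_sum)
from dcequant.stats import add_percent_changes


class TestPercentChange:
    def test_published_iqr_worked_example(self):
        # iqr sequences of two tumors across three visits: the non-responder
        # rises then falls, the responder collapses by the midpoint visit
        non_pcr = [0.33, 0.44, 0.21]
        pcr = [0.42, 0.21, 0.0072]
        assert round(percent_change(non_pcr[1], non_pcr[0])) == 33
        assert round(percent_change(non_pcr[2], non_pcr[0])) == -36
        assert round(percent_change(pcr[1], pcr[0])) == -50
        assert round(percent_change(pcr[2], pcr[0])) == -98

    def test_equal_values_zero(self):
        assert percent_change(0.4, 0.4) == 0.0

    def test_zero_baseline_undefined(self):
        assert np.isnan(percent_change(1.0, 0.0))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(scale=st.floats(1e-3, 1e3),
           v1=st.floats(0.01, 10.0), v2=st.floats(0.01, 10.0))
    def test_scale_free(self, scale, v1, v2):
        assert percent_change(scale * v2, scale * v1) == \
            pytest.approx(percent_change(v2, v1), rel=1e-9)


def exact_rank_sum_p(a, b):
    """Enumeration oracle: two-sided p over all rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n_a)]
    mu = np.mean(sums)
    p = np.mean([abs(s - mu) >= abs(obs - mu) - 1e-12 for s in sums])
    return p


class TestWilcoxon:
    def test_small_fixture_matches_enumeration(self):
        a, b = [1.0, 2.0], [3.0, 4.0]
        assert wilcoxon_rank_sum(a, b) == pytest.approx(1 / 3)
        assert exact_rank_sum_p(a, b) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (4, 4), (5, 6), (6, 6)])
    def test_exact_matches_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.normal(0, 1, na)
        b = rng.normal(0.8, 1, nb)
        assert wilcoxon_rank_sum(a, b) == \
            pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_exact_and_approximate_agree_at_moderate_n(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1.0, 1, 6)
        exact = wilcoxon_rank_sum(a, b)
        approx = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue)
        assert abs(exact - approx) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestPairedT:
    def test_closed_form_oracle(self):
        # differences {1,2,3}: t = dbar / (s/sqrt(3)) = 2*sqrt(3), df = 2
        b = np.array([10.0, 20.0, 30.0])
        a = b + np.array([1.0, 2.0, 3.0])
        t_oracle = 2.0 * np.sqrt(3.0)
        p_oracle = 2.0 * (1.0 - sps.t.cdf(t_oracle, df=2))
        assert paired_t_test(a, b) == pytest.approx(p_oracle, rel=1e-9)
        assert p_oracle == pytest.approx(0.0742, abs=5e-4)

    def test_reduces_to_one_sample_test_of_noise(self):
        rng = np.random.default_rng(3)
        a = rng.normal(5, 1, 12)
        noise = rng.normal(0.3, 0.5, 12)
        b = a + noise
        assert paired_t_test(a, b) == \
            pytest.approx(float(sps.ttest_1samp(-noise, 0).pvalue), rel=1e-9)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        assert paired_t_test(a, b) == pytest.approx(paired_t_test(b, a))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


def pairwise_auc(labels, scores):
    """Brute-force concordant-pair AUC with half credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = c = 0.0
    for p in pos:
        for n in neg:
            total += 1
            c += 1.0 if p > n else (0.5 if p == n else 0.0)
    return c / total


class TestROC:
    def test_four_point_fixture(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        assert pairwise_auc(labels, scores) == pytest.approx(0.75)
        res = roc_auc(labels, scores)
        assert res.auc == pytest.approx(0.75)
        assert res.auc_logistic == pytest.approx(res.auc_rank, abs=1e-9)

    def test_perfect_separation(self):
        res = roc_auc(np.array([0, 0, 0, 1, 1]),
                      np.array([1.0, 2.0, 3.0, 10.0, 11.0]))
        assert res.auc == 1.0
        assert res.ci95 == (1.0, 1.0)

    def test_negation_symmetry_of_rank_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        labels = np.array([0] * 8 + [1] * 7)
        scores = rng.normal(labels, 1.0)
        a = roc_auc_score(labels, scores)
        assert roc_auc_score(labels, -scores) == pytest.approx(1 - a)
        # the reported AUC uses the discriminative orientation either way
        assert roc_auc(labels, -scores).auc == \
            pytest.approx(roc_auc(labels, scores).auc)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_logistic_roc_equals_rank_auc(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.array([0] * 6 + [1] * 6)
        scores = rng.normal(0.7 * labels, 1.0)
        res = roc_auc(labels, scores)
        assert res.auc_logistic == pytest.approx(res.auc_rank, abs=1e-9)
        assert res.auc == pytest.approx(pairwise_auc(
            labels, -scores if res.flipped else scores), abs=1e-12)

    def test_ties_get_half_credit(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([1.0, 2.0, 2.0, 3.0])
        assert roc_auc(labels, scores).auc == \
            pytest.approx(pairwise_auc(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1, 1, 1]), np.array([1.0, 2.0, 3.0]))


def make_cohort(values_by_patient, visits=("V1", "V2", "V3"), metric="m"):
    rows = []
    for pid, (group, vals) in values_by_patient.items():
        for visit, v in zip(visits, vals):
            if v is not None:
                rows.append({"patient": pid, "group": group, "visit": visit,
                             "metric": metric, "value": v})
    return pd.DataFrame(rows)


class TestPredictResponse:
    def test_disjoint_groups_perfect_auc_and_significant_p(self):
        cohort = make_cohort({
            **{f"n{i}": ("non-pCR", [1.0, 1.0, 1.0 - 0.02 * i])
               for i in range(9)},
            **{f"p{i}": ("pCR", [1.0, 0.5, 0.1 - 0.01 * i])
               for i in range(6)},
        })
        row = predict_response(cohort, "m", "V31%")
        assert row["n_pos"] == 6 and row["n_neg"] == 9
        assert row["roc"].auc == 1.0
        assert row["wilcoxon_p"] < 0.05

    def test_permuted_labels_center_auc_at_half(self):
        # unoriented rank-AUC permutation distribution centers at 0.5
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1, 15)
        labels = np.array([1] * 6 + [0] * 9)
        aucs = [roc_auc_score(rng.permutation(labels), vals)
                for _ in range(200)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_patient_missing_visit_dropped_and_counted(self):
        cohort = make_cohort({
            **{f"n{i}": ("non-pCR", [1.0, 0.9, 0.8 + 0.01 * i])
               for i in range(4)},
            "p0": ("pCR", [1.0, 0.4, 0.2]),
            "p1": ("pCR", [1.0, 0.5, 0.25]),
            "p2": ("pCR", [1.0, 0.45, None]),  # missed the midpoint scan
        })
        full = predict_response(cohort, "m", "V21%")
        row = predict_response(cohort, "m", "V31%")
        assert full["n_pos"] == 3 and full["n_dropped"] == 0
        assert row["n_pos"] == 2 and row["n_dropped"] == 1

    def test_percent_change_columns(self):
        cohort = make_cohort({"a": ("pCR", [2.0, 1.0, 0.5]),
                              "b": ("non-pCR", [2.0, 2.2, None])})
        wide = add_percent_changes(cohort)
        a = wide[wide.patient == "a"].iloc[0]
        assert a["V21%"] == pytest.approx(-50.0)
        assert a["V31%"] == pytest.approx(-75.0)
        b = wide[wide.patient == "b"].iloc[0]
        assert np.isnan(b["V31%"])
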