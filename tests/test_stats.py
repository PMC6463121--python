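import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from lpstopo.stats import (
    auc_separation,
    aupr_separation,
    bh_correct,
    clinical_correlation,
    mann_whitney,
    nodal_contrast,
    whole_brain_comparison,
)
from lpstopo.topology import NodalMetrics, TopologySummary


class TestMannWhitney:
    def test_exact_p_by_exhaustive_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        u, p = mann_whitney(x, y)
        assert u == 0.0
        # oracle: enumerate all C(6,3)=20 labelings of the pooled sample
        pooled = x + y
        observed_u = 0
        more_extreme = 0
        for combo in itertools.combinations(range(6), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            u_stat = sum(1 for a in xs for b in ys if a > b)
            if min(u_stat, 9 - u_stat) <= min(observed_u, 9 - observed_u):
                more_extreme += 1
        assert p == pytest.approx(more_extreme / 20) == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        assert mann_whitney([2.0, 2.0], [2.0, 2.0])[1] == 1.0

    def test_invariant_to_monotone_transformation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        u1, p1 = mann_whitney(x, y)
        u2, p2 = mann_whitney(np.exp(x), np.exp(y))
        assert (u1, p1) == (u2, p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestAuc:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11]
        groups = ["MCS"] * 3 + ["UWS"] * 2
        assert auc_separation(scores, groups, "UWS") == 1.0

    def test_label_swap_complements(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=12)
        groups = ["UWS"] * 5 + ["MCS"] * 7
        auc = auc_separation(scores, groups, "UWS")
        assert auc_separation(scores, groups, "MCS") == pytest.approx(1 - auc)

    def test_equals_u_over_n1n2(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(0.5, 1, 6)
            y = rng.normal(0, 1, 8)
            u, _ = mann_whitney(x, y)
            scores = np.concatenate([x, y])
            groups = ["UWS"] * 6 + ["MCS"] * 8
            assert auc_separation(scores, groups, "UWS") == pytest.approx(
                u / (6 * 8), abs=1e-12)

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=2000)
        groups = ["UWS"] * 1000 + ["MCS"] * 1000
        assert auc_separation(scores, groups, "UWS") == pytest.approx(0.5, abs=0.05)


class TestAupr:
    def test_perfect_separation_and_single_positive(self):
        assert aupr_separation([1, 2, 9], ["MCS", "MCS", "UWS"], "UWS") == 1.0
        assert aupr_separation([9, 1, 2, 3], ["UWS", "MCS", "MCS", "MCS"], "UWS") == 1.0

    def test_random_scores_approach_prevalence(self):
        # chance level of AUPR is the positive prevalence (12/25 at the
        # emulated group sizes); checked at large n where the small-sample
        # upward bias of average precision is negligible
        rng = np.random.default_rng(4)
        values = []
        for _ in range(20):
            scores = rng.normal(size=500)
            groups = ["UWS"] * 240 + ["MCS"] * 260
            values.append(aupr_separation(scores, groups, "UWS"))
        assert np.mean(values) == pytest.approx(12 / 25, abs=0.03)


class TestClinicalCorrelation:
    def test_exact_linear_relation(self):
        result = clinical_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert result.pearson_rho == pytest.approx(1.0)
        assert result.spearman_rho == pytest.approx(1.0)

    def test_monotone_nonlinear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        result = clinical_correlation(x**3, x)
        assert result.spearman_rho == pytest.approx(1.0)
        assert result.pearson_rho < 1.0

    def test_hand_computed_pearson_on_five_pairs(self):
        v = [2.0, 4.0, 5.0, 4.0, 7.0]
        c = [10.0, 12.0, 13.0, 15.0, 19.0]
        result = clinical_correlation(v, c)
        assert result.pearson_rho == pytest.approx(oracles.pearson(v, c), abs=1e-12)

    def test_nan_pairs_excluded_and_counted(self):
        result = clinical_correlation([1.0, np.nan, 3.0, 4.0], [1, 2, 3, 4])
        assert result.n_used == 3
        assert result.n_excluded == 1

    def test_zero_variance_flagged_undefined(self):
        result = clinical_correlation([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(result.pearson_rho) and np.isnan(result.spearman_rho)


class TestBhCorrect:
    def test_hand_step_up_all_significant(self):
        adjusted, significant = bh_correct([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert significant.all()  # largest k with p_(k) <= k q / m is k = 4
        assert adjusted[-1] == pytest.approx(0.04)

    def test_all_ones_none_significant(self):
        _, significant = bh_correct([1.0, 1.0, 1.0])
        assert not significant.any()

    def test_single_p_is_identity(self):
        adjusted, _ = bh_correct([0.03])
        assert adjusted[0] == pytest.approx(0.03)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.001, 1.0, size=int(rng.integers(2, 20)))
        adjusted, significant = bh_correct(p, q=0.05)
        np.testing.assert_allclose(adjusted, oracles.bh_adjusted(p), atol=1e-12)
        # significance by direct search over all k
        order = np.argsort(p)
        m = len(p)
        k_star = max((k + 1 for k in range(m) if p[order[k]] <= (k + 1) * 0.05 / m),
                     default=0)
        expected = np.zeros(m, dtype=bool)
        expected[order[:k_star]] = True
        np.testing.assert_array_equal(significant, expected)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_correct([0.0, 0.5])

    @given(st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=1, max_size=25))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_adjusted_p_bounded_and_rank_monotone(self, p):
        adjusted, _ = bh_correct(p)
        assert np.all((adjusted > 0) & (adjusted <= 1))
        assert np.all(adjusted >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)


def _nodal(degrees, n=4):
    return NodalMetrics(roi_indices=list(range(n)),
                        degree=np.asarray(degrees, dtype=float),
                        clustering=np.zeros(n), betweenness=np.zeros(n))


class TestNodalContrast:
    def test_equal_group_means_give_zero_percent_change(self):
        a = [_nodal([2, 2, 2, 2]), _nodal([4, 4, 4, 4])]
        b = [_nodal([3, 3, 3, 3]), _nodal([3, 3, 3, 3])]
        table = nodal_contrast(a, b, n_rois=4)
        np.testing.assert_allclose(table["pct_change"], 0.0)

    def test_hand_percent_change(self):
        a = [_nodal([6, 0, 0, 0]), _nodal([6, 0, 0, 0])]
        b = [_nodal([4, 0, 0, 0]), _nodal([4, 0, 0, 0])]
        table = nodal_contrast(a, b, n_rois=4)
        assert table.loc[0, "pct_change"] == pytest.approx(50.0)
        assert np.isnan(table.loc[1, "pct_change"])  # zero reference mean

    def test_null_cohort_rarely_bh_significant(self):
        rng = np.random.default_rng(5)
        flagged = 0
        for _ in range(30):
            a = [_nodal(rng.normal(5, 1, 20), n=20) for _ in range(8)]
            b = [_nodal(rng.normal(5, 1, 20), n=20) for _ in range(8)]
            flagged += nodal_contrast(a, b, n_rois=20)["significant"].any()
        assert flagged <= 3


def _summary(sid, **kw):
    return TopologySummary(subject_id=sid, band="beta1", pt=20.0, **kw)


class TestWholeBrainComparison:
    def _cohort_and_summaries(self, rng, uws_shift=0.0):
        rows = []
        summaries = []
        for k in range(12):
            sid = f"uws{k}"
            rows.append({"subject_id": sid, "group": "UWS", "crs_r": rng.normal(5, 1)})
            summaries.append(_summary(sid, ACC=rng.normal(0.33 + uws_shift, 0.02),
                                      E_loc=rng.normal(0.5, 0.05)))
        for k in range(13):
            sid = f"mcs{k}"
            rows.append({"subject_id": sid, "group": "MCS", "crs_r": rng.normal(13, 4)})
            summaries.append(_summary(sid, ACC=rng.normal(0.33, 0.02),
                                      E_loc=rng.normal(0.5, 0.05)))
        return summaries, pd.DataFrame(rows)

    def test_one_row_per_requested_measure(self):
        rng = np.random.default_rng(6)
        summaries, cohort = self._cohort_and_summaries(rng)
        table = whole_brain_comparison(summaries, cohort, measures=("ACC", "E_loc"))
        assert list(table["measure"]) == ["ACC", "E_loc"]
        assert (table["n_a"] == 12).all() and (table["n_b"] == 13).all()

    def test_positive_class_is_higher_mean_group(self):
        rng = np.random.default_rng(7)
        summaries, cohort = self._cohort_and_summaries(rng, uws_shift=0.1)
        table = whole_brain_comparison(summaries, cohort, measures=("ACC",))
        row = table.iloc[0]
        assert row["positive_group"] == "UWS"
        assert row["auc"] >= 0.5
        assert row["mw_p"] < 0.05

    def test_missing_subject_summary_reported(self):
        rng = np.random.default_rng(8)
        summaries, cohort = self._cohort_and_summaries(rng)
        with pytest.raises(ValueError, match="missing topology summaries"):
            whole_brain_comparison(summaries[:-1], cohort, measures=("ACC",))

    def test_undefined_values_excluded_pairwise(self):
        rng = np.random.default_rng(9)
        summaries, cohort = self._cohort_and_summaries(rng)
        summaries[0].ACC = float("nan")
        table = whole_brain_comparison(summaries, cohort, measures=("ACC",))
        assert table.iloc[0]["n_a"] == 11
        assert table.iloc[0]["n_excluded"] == 1
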