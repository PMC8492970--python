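"""Covariate-adjusted ANOVA, BH-FDR, post-hoc t-tests, cluster extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from hemifc import group_stats as gs


def _brute_force_bh(p, q):
    """Enumerate every i and apply the step-up rule literally."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


class TestFdrBh:
    def test_worked_example_all_rejected(self):
        # thresholds i*q/m = 0.0125/0.025/0.0375/0.05
        assert gs.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), 0.05).all()

    def test_all_ones_none_rejected(self):
        assert not gs.fdr_bh(np.ones(10), 0.05).any()

    def test_single_p_reduces_to_plain_threshold(self):
        assert gs.fdr_bh(np.array([0.04]), 0.05)[0]
        assert not gs.fdr_bh(np.array([0.06]), 0.05)[0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gs.fdr_bh(np.array([]))

    @given(st.integers(1, 12), st.integers(0, 2**31 - 1))
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_enumeration(self, m, seed):
        p = np.random.default_rng(seed).random(m)
        assert np.array_equal(gs.fdr_bh(p, 0.05), _brute_force_bh(p, 0.05))

    def test_matches_statsmodels(self, rng):
        p = rng.random(500)
        ours = gs.fdr_bh(p, 0.05)
        theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert np.array_equal(ours, theirs)

    def test_shape_preserved(self, rng):
        p = rng.random((5, 7))
        assert gs.fdr_bh(p).shape == (5, 7)


class TestGlmGroupF:
    def test_hand_computed_oneway_anova(self):
        # groups [1,2,3], [2,3,4], [3,4,5]: SSB = 6, SSW = 6, F = (6/2)/(6/6) = 3
        y = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], float)[:, None]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = gs.glm_group_f(y, groups)
        assert res.df == (2.0, 6.0)
        assert res.stat[0] == pytest.approx(3.0, abs=1e-10)
        assert res.p[0] == pytest.approx(sps.f.sf(3.0, 2, 6), abs=1e-12)

    def test_matches_scipy_f_oneway_many_voxels(self, rng):
        y = rng.normal(size=(15, 40))
        groups = np.repeat(["a", "b", "c"], 5)
        res = gs.glm_group_f(y, groups)
        for v in range(40):
            f_ref, p_ref = sps.f_oneway(y[:5, v], y[5:10, v], y[10:, v])
            assert res.stat[v] == pytest.approx(f_ref, rel=1e-8)
            assert res.p[v] == pytest.approx(p_ref, rel=1e-8)

    def test_identical_groups_f_zero(self, rng):
        block = rng.normal(size=(4, 6))
        y = np.vstack([block, block])
        res = gs.glm_group_f(y, ["a"] * 4 + ["b"] * 4)
        assert np.allclose(res.stat, 0.0, atol=1e-10)
        assert np.allclose(res.p, 1.0, atol=1e-10)

    def test_covariate_adjustment_removes_confound(self, rng):
        # group difference entirely explained by age: adjusted F must be small
        n = 30
        age = np.concatenate([rng.normal(60, 2, 15), rng.normal(80, 2, 15)])
        y = (2.0 * age + rng.normal(0, 0.1, n))[:, None]
        groups = ["a"] * 15 + ["b"] * 15
        raw = gs.glm_group_f(y, groups)
        adj = gs.glm_group_f(y, groups, age[:, None])
        assert raw.stat[0] > 100
        assert adj.p[0] > 0.01

    def test_degrees_of_freedom_with_covariates(self, rng):
        y = rng.normal(size=(20, 3))
        groups = np.repeat(["a", "b", "c", "d"], 5)
        cov = rng.normal(size=(20, 2))
        res = gs.glm_group_f(y, groups, cov)
        assert res.df == (3.0, 20 - 4 - 2)

    def test_too_small_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            gs.glm_group_f(rng.normal(size=(3, 2)), ["a", "a", "b"])


class TestPosthocT:
    def test_matches_scipy_without_covariates(self, rng):
        y = rng.normal(size=(12, 20))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = gs.posthoc_t(y, groups, "a", "b", m_comparisons=6)
        for v in range(20):
            t_ref, p_ref = sps.ttest_ind(y[:6, v], y[6:, v])
            assert res.stat[v] == pytest.approx(t_ref, rel=1e-8)
            assert res.p[v] == pytest.approx(p_ref, rel=1e-8)

    @pytest.mark.parametrize("m, alpha_each", [(6, 0.05 / 6), (9, 0.05 / 9)])
    def test_bonferroni_thresholds(self, rng, m, alpha_each):
        y = rng.normal(size=(10, 50))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res = gs.posthoc_t(y, groups, "a", "b", m_comparisons=m)
        assert np.array_equal(res.reject, res.p < alpha_each)

    def test_identical_groups_not_significant(self, rng):
        block = rng.normal(size=(5, 8))
        y = np.vstack([block, block])
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res = gs.posthoc_t(y, groups, "a", "b")
        assert np.allclose(res.stat, 0.0, atol=1e-8)
        assert not res.reject.any()

    def test_nonpositive_m_rejected(self, rng):
        with pytest.raises(ValueError):
            gs.posthoc_t(rng.normal(size=(6, 2)), ["a"] * 3 + ["b"] * 3, "a", "b", m_comparisons=0)


class TestExtractClusters:
    def test_size_is_voxel_count_times_voxel_volume(self):
        reject = np.zeros((10, 10, 10), bool)
        reject[1:4, 1:4, 1:4] = True  # 27 voxels, one-sided
        stat = np.ones((10, 10, 10))
        table, labels = gs.extract_clusters(reject, stat, voxel_size_mm=3.0)
        assert len(table) == 1
        assert table.loc[0, "n_voxels"] == 27
        assert table.loc[0, "size_mm3"] == 27 * 27.0
        assert table.loc[0, "size_mm3"] % 27.0 == 0.0

    def test_reported_sizes_always_divisible_by_voxel_volume(self, rng):
        reject = rng.random((12, 10, 10)) < 0.2
        table, _ = gs.extract_clusters(reject, rng.normal(size=(12, 10, 10)), 3.0)
        assert (table["size_mm3"] % 27.0 == 0.0).all()

    def test_empty_rejection_map_gives_empty_table(self):
        table, labels = gs.extract_clusters(np.zeros((5, 5, 5), bool), np.zeros((5, 5, 5)))
        assert len(table) == 0 and not labels.any()

    def test_mirrored_components_merged_to_bilateral_record(self):
        reject = np.zeros((10, 6, 6), bool)
        reject[1:3, 2:4, 2:4] = True
        reject[7:9, 2:4, 2:4] = True  # exact mirror of the first block
        stat = np.zeros((10, 6, 6))
        stat[2, 2, 2] = 5.0
        stat[7, 2, 2] = 5.0
        table, labels = gs.extract_clusters(reject, stat, voxel_size_mm=3.0)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["bilateral"]
        assert row["n_voxels"] == 16  # both hemispheres pooled
        assert row["peak_stat"] == 5.0
        assert row["peak_x_mm"] > 0  # reported as +/-|x|
        assert len(np.unique(labels[labels > 0])) == 1

    def test_unilateral_component_not_merged(self):
        reject = np.zeros((10, 6, 6), bool)
        reject[1:3, 2:4, 2:4] = True
        table, _ = gs.extract_clusters(reject, np.ones((10, 6, 6)))
        assert len(table) == 1 and not table.iloc[0]["bilateral"]

    def test_peak_is_max_abs_statistic(self):
        reject = np.zeros((6, 6, 6), bool)
        reject[1:3, 1:3, 1:3] = True
        stat = np.zeros((6, 6, 6))
        stat[1, 1, 1] = -7.0
        stat[2, 2, 2] = 4.0
        table, _ = gs.extract_clusters(reject, stat, merge_mirrored=False)
        assert table.iloc[0]["peak_stat"] == -7.0

    def test_connectivity_changes_component_count(self):
        reject = np.zeros((6, 6, 6), bool)
        reject[1, 1, 1] = reject[2, 2, 2] = True  # diagonal touch
        t26, _ = gs.extract_clusters(reject, np.ones((6, 6, 6)), connectivity=26,
                                     merge_mirrored=False)
        t6, _ = gs.extract_clusters(reject, np.ones((6, 6, 6)), connectivity=6,
                                    merge_mirrored=False)
        assert len(t26) == 1 and len(t6) == 2

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            gs.extract_clusters(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4)), connectivity=10)


class TestEncodeCovariates:
    def test_sex_mapped_to_binary(self):
        df = pd.DataFrame({"age": [70.0, 80.0], "sex": ["M", "F"], "education": [12.0, 16.0]})
        out = gs.encode_covariates(df)
        assert np.array_equal(out, [[70, 1, 12], [80, 0, 16]])
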