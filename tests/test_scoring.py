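import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfa_pvst.scoring import (
    RFAPVSTSelector,
    abs_pearson,
    correlation_matrix,
    detect_cut,
    discernibility,
    discernibility_all,
    independence,
    rank_features,
    risk_degree,
    scatter_coordinates,
)
from .conftest import random_small_cohort


def brute_force_S(x, y, tie_weight=1.0):
    """Independent double-loop pair count: non-PVST value <= PVST value."""
    pos = [v for v, lab in zip(x, y) if lab == 1]
    neg = [v for v, lab in zip(x, y) if lab == -1]
    S = 0.0
    for xk in pos:
        for xi in neg:
            if xi < xk:
                S += 1.0
            elif xi == xk:
                S += tie_weight
    return S


class TestDiscernibility:
    def test_hand_counted_pairs(self):
        S, dis = discernibility([3, 1, 2, 0], [1, 1, -1, -1])
        assert (S, dis) == (3, 3)

    def test_perfect_separation_saturates(self):
        S, dis = discernibility([5, 6, 1, 2], [1, 1, -1, -1])
        assert (S, dis) == (4, 4)

    def test_constant_column_pathology_and_midrank_fix(self):
        x, y = [5] * 5, [1, 1, -1, -1, -1]
        assert discernibility(x, y) == (6, 6)
        assert discernibility(x, y, tie_mode="midrank") == (3, 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            discernibility([1, 2], [1, 1])

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000), tie_mode=st.sampled_from(["paper", "midrank"]))
    def test_matches_brute_force_oracle(self, seed, tie_mode):
        rng = np.random.default_rng(seed)
        X, y = random_small_cohort(rng)
        S, dis = discernibility_all(X, y, tie_mode)
        w = 1.0 if tie_mode == "paper" else 0.5
        n_pairs = (y == 1).sum() * (y == -1).sum()
        for j in range(X.shape[1]):
            expected = brute_force_S(X[:, j], y, w)
            assert S[j] == expected
            assert dis[j] == max(n_pairs - expected, expected)

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_label_swap_symmetry_and_bounds(self, seed):
        """dis is label-symmetric (tie-free data in the literal mode; any
        data under mid-rank tie weighting) and stays in its bounds."""
        rng = np.random.default_rng(seed)
        X, y = random_small_cohort(rng)
        X_cont = rng.standard_normal(X.shape)  # ties almost surely absent
        _, dis_c = discernibility_all(X_cont, y)
        _, dis_c_swapped = discernibility_all(X_cont, -y)
        np.testing.assert_array_equal(dis_c, dis_c_swapped)
        _, dis_m = discernibility_all(X, y, tie_mode="midrank")
        _, dis_m_swapped = discernibility_all(X, -y, tie_mode="midrank")
        np.testing.assert_array_equal(dis_m, dis_m_swapped)
        n_pairs = (y == 1).sum() * (y == -1).sum()
        for dis in (dis_c, dis_m, discernibility_all(X, y)[1]):
            assert np.all(dis >= n_pairs / 2)
            assert np.all(dis <= n_pairs)

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        """dis is a rank statistic: strictly increasing maps leave it fixed."""
        rng = np.random.default_rng(seed)
        X, y = random_small_cohort(rng)
        _, dis = discernibility_all(X, y)
        _, dis_t = discernibility_all(np.exp(X) + X**3, y)
        np.testing.assert_array_equal(dis, dis_t)


class TestAbsPearson:
    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0])
        assert abs_pearson(x, -x) == pytest.approx(1.0)

    def test_orthogonal_centered_vectors(self):
        assert abs_pearson([1, -1, 1, -1], [1, 1, -1, -1]) == pytest.approx(0.0)

    def test_worked_value(self):
        assert abs_pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_defined_as_zero(self):
        with pytest.warns(UserWarning):
            assert abs_pearson([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            abs_pearson([1, 2], [1, 2, 3])

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((12, 4))
        C = correlation_matrix(X)
        assert C.shape == (4, 4)
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        for i in range(4):
            for j in range(i):
                assert C[i, j] == pytest.approx(abs_pearson(X[:, i], X[:, j]))


class TestIndependence:
    def test_two_features_forced_values(self):
        ind, anchor = independence([4.0, 2.0], [[1.0, 1.0], [1.0, 1.0]])
        assert ind[0] == pytest.approx(np.exp(-1))
        assert ind[1] == pytest.approx(np.exp(-1))
        assert list(anchor) == [1, 0]

    def test_three_feature_branch_example(self):
        corr = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        ind, anchor = independence([3.0, 2.0, 1.0], corr)
        assert ind[0] == pytest.approx(np.exp(-0.1), abs=1e-12)
        assert ind[1] == pytest.approx(np.exp(-0.9), abs=1e-12)
        assert ind[2] == pytest.approx(np.exp(-0.2), abs=1e-12)
        assert list(anchor) == [2, 0, 1]

    def test_uncorrelated_features_all_get_one(self):
        corr = np.eye(3)
        ind, _ = independence([3.0, 2.0, 1.0], corr)
        np.testing.assert_allclose(ind, 1.0)

    def test_lone_feature(self):
        ind, anchor = independence([5.0], [[1.0]])
        assert ind[0] == 1.0 and anchor[0] == -1

    def test_tied_global_max_uses_max_branch(self):
        corr = np.array([[1.0, 0.8, 0.3], [0.8, 1.0, 0.5], [0.3, 0.5, 1.0]])
        ind, anchor = independence([3.0, 3.0, 1.0], corr)
        # both maxima pair with their least-correlated partner
        assert ind[0] == pytest.approx(np.exp(-0.3))
        assert ind[1] == pytest.approx(np.exp(-0.5))
        assert list(anchor[:2]) == [2, 2]

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_and_top_feature_guarantee(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_small_cohort(rng, max_m=20, max_n=6)
        if X.shape[1] < 2:
            return
        _, dis = discernibility_all(X, y)
        corr = correlation_matrix(X)
        ind, _ = independence(dis, corr)
        assert np.all(ind >= np.exp(-1) - 1e-12)
        assert np.all(ind <= 1 + 1e-12)
        # the max-dis feature does at least as well as under the other branch
        j = int(np.argmax(dis))
        others = np.delete(np.arange(X.shape[1]), j)
        assert ind[j] >= np.exp(-corr[j, others].max()) - 1e-12


class TestRankingAndDetection:
    def test_risk_degree_is_elementwise_product(self):
        np.testing.assert_allclose(risk_degree([4, 3], [0.5, np.exp(-0.2)]),
                                   [2.0, 3 * np.exp(-0.2)])

    def test_tie_break_by_dis_then_id(self):
        order = rank_features([2.0, 5.0, 5.0], dis=[2.0, 6.0, 5.0],
                              feature_ids=[1, 2, 3])
        assert list(order) == [1, 2, 0]  # ids [2, 3, 1]

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_ranking_matches_naive_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rd = rng.choice([1.0, 2.0, 3.0], size=8)
        dis = rng.choice([1.0, 2.0], size=8)
        order = rank_features(rd, dis)
        naive = sorted(range(8), key=lambda j: (-rd[j], -dis[j], j))
        assert list(order) == naive

    def test_unambiguous_gap(self):
        cut, gap = detect_cut([10.0, 9.0, 2.0, 1.0])
        assert (cut, gap) == (2, 7.0)

    def test_gap_right_after_top(self):
        cut, _ = detect_cut([10.0, 4.0, 3.5, 3.0])
        assert cut == 1

    def test_all_equal_falls_back_to_top_one(self):
        with pytest.warns(UserWarning):
            cut, gap = detect_cut([5.0, 5.0, 5.0])
        assert (cut, gap) == (1, 0.0)

    def test_max_cut_limits_search(self):
        cut, _ = detect_cut([10.0, 9.5, 9.0, 1.0], max_cut=2)
        assert cut == 1  # the big rank-3 drop is out of reach


class TestSelector:
    def test_full_scoring_matches_from_scratch_recomputation(self, tiny_cohort):
        X, y = tiny_cohort
        sel = RFAPVSTSelector().fit(X, y)
        S, dis = discernibility_all(X, y)
        corr = correlation_matrix(X)
        ind, _ = independence(dis, corr)
        rd = risk_degree(dis, ind)
        np.testing.assert_allclose(sel.rd_, rd)
        np.testing.assert_array_equal(sel.ranking_, rank_features(rd, dis))

    def test_separating_feature_ranks_first(self, tiny_cohort):
        X, y = tiny_cohort
        sel = RFAPVSTSelector().fit(X, y)
        assert sel.ranking_[0] == 0
        assert sel.get_support()[0]

    def test_transform_keeps_selected_prefix(self, tiny_cohort):
        X, y = tiny_cohort
        sel = RFAPVSTSelector(n_select=2).fit(X, y)
        assert sel.transform(X).shape == (8, 2)
        assert sel.cut_index_ == 2

    def test_scatter_table_is_consistent(self, tiny_cohort):
        X, y = tiny_cohort
        sel = RFAPVSTSelector().fit(X, y)
        ids = [11, 22, 33]
        table = scatter_coordinates(sel, ids, ["a", "b", "c"])
        assert len(table) == 3
        assert table["is_selected"].sum() == sel.cut_index_
        assert list(table["RD"]) == sorted(table["RD"], reverse=True)
        assert set(table["feature_id"]) == set(ids)

    def test_scatter_table_round_trips_tsv(self, tiny_cohort, tmp_path):
        import pandas as pd

        X, y = tiny_cohort
        table = scatter_coordinates(RFAPVSTSelector().fit(X, y))
        path = tmp_path / "scores.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(back["RD"], table["RD"])
        assert list(back["feature_id"]) == list(table["feature_id"])
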