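"""DAve/DCI indices, F-ratio screen and Ward clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import secretomics as sx
from secretomics.maproma_differential import (compute_dave, compute_dci,
                                              f_ratio_screen, pairwise_compare,
                                              ward_cluster)
from secretomics.psm_matrix import build_apsm_matrix
from secretomics.synthetic_data import PsmRunTable

finite = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


def matrix_from_values(values):
    """AbundanceMatrix with one protein per row of ``values`` laid out as
    {condition: [replicate values]}."""
    runs = []
    for cond, reps in values.items():
        for i, vals in enumerate(reps):
            runs.append(PsmRunTable(
                run_id=f"{cond}_r{i}", condition=cond, bio_replicate=i + 1,
                tech_replicate=1,
                counts={f"P{j}": v for j, v in enumerate(vals)}))
    return build_apsm_matrix(runs, normalize=False)


class TestIndices:
    @pytest.mark.parametrize("x, y, expected", [
        (1.5, 1.0, 0.4),        # the 1.5-fold change sits exactly at the cut
        (5.0, 5.0, 0.0),
        (10.0, 0.0, 2.0),
        (0.0, 0.0, 0.0),
    ])
    def test_dave_values(self, x, y, expected):
        assert compute_dave(x, y) == expected

    @pytest.mark.parametrize("x, y, expected", [
        (10.0, 5.0, 37.5),
        (5.0, 5.0, 0.0),
        (0.0, 8.0, -32.0),
    ])
    def test_dci_values(self, x, y, expected):
        assert compute_dci(x, y) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_dave(-1.0, 2.0)
        with pytest.raises(ValueError):
            compute_dci(1.0, -2.0)

    @given(finite, finite)
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_and_bound(self, x, y):
        assert compute_dave(x, y) == -compute_dave(y, x)
        assert compute_dci(x, y) == -compute_dci(y, x)
        assert abs(compute_dave(x, y)) <= 2.0

    @given(st.floats(0.01, 1e3), st.floats(0.01, 1e3), st.floats(0.01, 1e3))
    @settings(max_examples=200, deadline=None)
    def test_scaling_behaviour(self, x, y, k):
        # DAve is ratio-scale invariant; DCI scales with the square
        assert compute_dave(k * x, k * y) == pytest.approx(compute_dave(x, y))
        assert compute_dci(k * x, k * y) == pytest.approx(k ** 2 * compute_dci(x, y))

    def test_threshold_equivalent_to_fold_change_1p5(self):
        # |DAve| >= 0.4 <=> max/min >= 1.5, on a dense positive grid
        grid = np.linspace(0.1, 50.0, 120)
        for x in grid:
            for y in grid:
                assert (abs(compute_dave(x, y)) >= 0.4 - 1e-12) == \
                    (max(x, y) / min(x, y) >= 1.5 - 1e-12)


class TestPairwiseCompare:
    @pytest.fixture
    def two_cond_matrix(self):
        return matrix_from_values({
            "A": [[12.0, 1.2, 3.0]], "B": [[6.0, 1.0, 1.5]]})

    def test_joint_threshold_logic(self, two_cond_matrix):
        rec = pairwise_compare(two_cond_matrix, "A", "B")
        # P0: dave 0.667, dci 54 -> selected
        assert rec.loc["P0", "selected"] and rec.loc["P0", "dave"] == pytest.approx(2 / 3)
        # P1: dave ~0.18 -> below the DAve cut
        assert not rec.loc["P1", "selected"]
        # P2: dave 2/3 passes the DAve cut but dci 3.375 < 5 fails DCI
        assert rec.loc["P2", "dave"] == pytest.approx(2 / 3)
        assert rec.loc["P2", "dci"] == pytest.approx(3.375)
        assert not rec.loc["P2", "selected"]

    def test_swap_flips_signs_same_selection(self, two_cond_matrix):
        ab = pairwise_compare(two_cond_matrix, "A", "B")
        ba = pairwise_compare(two_cond_matrix, "B", "A")
        np.testing.assert_allclose(ab["dave"], -ba["dave"])
        np.testing.assert_allclose(ab["dci"], -ba["dci"])
        assert (ab["selected"] == ba["selected"]).all()

    def test_unknown_condition_rejected(self, two_cond_matrix):
        with pytest.raises(KeyError):
            pairwise_compare(two_cond_matrix, "A", "nope")


class TestFRatioScreen:
    def test_identical_groups_give_zero_f(self):
        m = matrix_from_values({"A": [[5.0], [5.0]], "B": [[5.0], [5.0]]})
        res = f_ratio_screen(m)
        assert res.loc["P0", "f_ratio"] == 0.0
        assert not res.loc["P0", "retained"]

    def test_two_groups_equal_squared_t(self):
        m = matrix_from_values({"A": [[3.0], [5.0], [4.0]],
                                "B": [[8.0], [7.0], [9.5]]})
        res = f_ratio_screen(m)
        t = stats.ttest_ind([3, 5, 4], [8, 7, 9.5], equal_var=True)
        assert res.loc["P0", "f_ratio"] == pytest.approx(t.statistic ** 2)
        assert res.loc["P0", "p_value"] == pytest.approx(t.pvalue)

    def test_matches_brute_force_mean_squares(self):
        groups = {"A": [1.0, 2.0, 3.0], "B": [7.0, 8.0, 9.0]}
        m = matrix_from_values({c: [[v] for v in vs] for c, vs in groups.items()})
        res = f_ratio_screen(m)
        # oracle: explicit model/error mean squares
        allv = [v for vs in groups.values() for v in vs]
        grand = np.mean(allv)
        msb = sum(len(v) * (np.mean(v) - grand) ** 2
                  for v in groups.values()) / (len(groups) - 1)
        msw = sum(sum((x - np.mean(v)) ** 2 for x in v)
                  for v in groups.values()) / (len(allv) - len(groups))
        assert res.loc["P0", "f_ratio"] == pytest.approx(msb / msw)

    def test_single_replicate_condition_rejected(self):
        m = matrix_from_values({"A": [[1.0], [2.0]], "B": [[3.0]]})
        with pytest.raises(ValueError, match="< 2 replicate"):
            f_ratio_screen(m)


def naive_ward(X):
    """Independent greedy Ward: at each step merge the pair of clusters whose
    union minimally increases the total within-cluster sum of squares,
    computed from scratch (no Lance-Williams update)."""
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    nxt = len(X)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pts = X[clusters[a] + clusters[b]]
            ess_ab = ((pts - pts.mean(axis=0)) ** 2).sum()
            ess_a = ((X[clusters[a]] - X[clusters[a]].mean(axis=0)) ** 2).sum()
            ess_b = ((X[clusters[b]] - X[clusters[b]].mean(axis=0)) ** 2).sum()
            d = ess_ab - ess_a - ess_b
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, np.sqrt(2.0 * d)))   # Ward height convention
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        nxt += 1
    return merges


class TestWardCluster:
    def test_two_items_merge_at_euclidean_distance(self):
        df = pd.DataFrame({"a": [0.0, 0.0], "b": [3.0, 4.0]})
        tree = ward_cluster(df, axis="columns")
        assert tree.heights[0] == pytest.approx(5.0)

    def test_duplicated_item_merges_at_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]})
        tree = ward_cluster(df)
        assert tree.heights[0] == pytest.approx(0.0)

    def test_two_tight_groups_recovered_at_top_split(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(0, 0.1, size=(3, 4))
        g2 = rng.normal(8, 0.1, size=(2, 4))
        df = pd.DataFrame(np.vstack([g1, g2]).T,
                          columns=["a1", "a2", "a3", "b1", "b2"])
        left, right = ward_cluster(df).top_split()
        assert {frozenset(left), frozenset(right)} == \
            {frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2"})}

    @pytest.mark.parametrize("seed", range(4))
    def test_merge_heights_match_naive_ward(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 3))
        df = pd.DataFrame(X.T, columns=[f"i{i}" for i in range(5)])
        tree = ward_cluster(df)
        expected = sorted(h for _, _, h in naive_ward(X))
        np.testing.assert_allclose(sorted(tree.heights), expected, rtol=1e-8)

    def test_heights_monotone_on_real_profiles(self, default_proteome):
        _, _, matrix = default_proteome
        tree = ward_cluster(matrix.apsm)
        assert (np.diff(tree.heights) >= -1e-9).all()

    def test_newick_export_has_all_leaves(self):
        df = pd.DataFrame(np.eye(3), columns=["x", "y", "z"])
        nwk = ward_cluster(df).to_newick()
        assert nwk.endswith(";") and all(l in nwk for l in "xyz")
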