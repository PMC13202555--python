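import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mobindex.diversity import (
    PermanovaResult,
    alpha_table,
    bray_curtis,
    group_compare,
    horn,
    n_distinct_assignments,
    pcoa,
    permanova,
    pielou,
    richness,
    shannon,
    shared_unique_fractions,
)


def random_abundance(rng, n, m):
    x = rng.gamma(0.7, 10.0, size=(n, m))
    x[x < 0.5] = 0.0
    x[:, 0] += 1.0  # keep rows non-degenerate
    return pd.DataFrame(x, index=[f"S{i}" for i in range(n)])


class TestAlpha:
    def test_single_feature_has_zero_entropy(self):
        assert shannon([5, 0, 0]) == 0.0

    def test_two_equal_features_give_ln2(self):
        assert shannon([3, 3]) == pytest.approx(math.log(2), abs=1e-12)

    def test_shannon_matches_term_sum_oracle(self):
        rng = np.random.default_rng(1)
        row = rng.gamma(1, 5, 10)
        p = row / row.sum()
        expected = -sum(pi * math.log(pi) for pi in p if pi > 0)
        assert shannon(row) == pytest.approx(expected, rel=1e-12)

    def test_richness_counts_positives(self):
        assert richness([0, 1, 0, 2, 0, 0, 3, 0, 0, 0.5]) == 4

    def test_uniform_row_is_perfectly_even(self):
        assert pielou([2, 2, 2, 2, 2]) == pytest.approx(1.0, abs=1e-12)

    def test_single_species_evenness_undefined(self):
        assert math.isnan(pielou([7, 0, 0]))

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=15).filter(
        lambda xs: sum(1 for x in xs if x > 0) >= 2))
    def test_evenness_bounded(self, row):
        assert 0.0 <= pielou(row) <= 1.0 + 1e-12

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    def test_alpha_table_shape(self):
        m = random_abundance(np.random.default_rng(0), 4, 6)
        t = alpha_table(m)
        assert list(t.columns) == ["shannon", "richness", "pielou"]
        assert len(t) == 4


class TestGroupCompare:
    def test_identical_groups_exact_wilcoxon_p_is_one(self):
        _, p = group_compare({"a": [1, 2, 3], "b": [1, 2, 3]}, method="wilcoxon")
        assert p == 1.0

    def test_zero_variance_t_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            group_compare({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}, method="t")

    def test_t_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        from scipy import stats

        stat, p = group_compare({"a": a, "b": b}, method="t")
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_exact_wilcoxon_matches_enumeration_oracle(self):
        # no-ties fixture: the exact rank-sum p equals a full C(8,4)=70
        # enumeration, independently recomputed here
        a, b = [1.0, 5.0, 7.0, 11.0], [2.0, 3.0, 4.0, 6.0]
        from scipy import stats

        pooled = np.array(a + b)
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:4].sum()
        mu = ranks.sum() * 4 / 8
        count = total = 0
        for idx in combinations(range(8), 4):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= abs(w_obs - mu) - 1e-12:
                count += 1
        _, p = group_compare({"a": a, "b": b}, method="wilcoxon")
        assert total == 70
        assert p == pytest.approx(count / total)
        # and agrees with the standard exact Mann-Whitney (no ties)
        ref = stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert p == pytest.approx(ref.pvalue)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 15), rng.normal(1.0, 1, 15)
        _, p = group_compare({"a": a, "b": b}, method="wilcoxon")
        from scipy import stats

        ref = stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestDissimilarities:
    def test_identical_rows_have_zero_distance(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == 0.0
        assert horn(m).loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_have_distance_one(self):
        m = pd.DataFrame([[1, 1, 0, 0], [0, 0, 2, 5]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == 1.0
        assert horn(m).loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_match_direct_formula_oracle(self):
        m = random_abundance(np.random.default_rng(4), 5, 8)
        bc, ho = bray_curtis(m), horn(m)
        for i in range(5):
            for j in range(5):
                x, y = m.iloc[i].to_numpy(), m.iloc[j].to_numpy()
                bc_ref = np.abs(x - y).sum() / (x + y).sum()
                X, Y = x.sum(), y.sum()
                mh = 2 * (x * y).sum() / (((x**2).sum() / X**2 + (y**2).sum() / Y**2) * X * Y)
                assert bc.iloc[i, j] == pytest.approx(bc_ref, abs=1e-12)
                assert ho.iloc[i, j] == pytest.approx(1 - mh, abs=1e-12)

    def test_feature_order_invariance(self):
        m = random_abundance(np.random.default_rng(5), 4, 7)
        perm = m[np.random.default_rng(0).permutation(m.columns)]
        assert np.allclose(bray_curtis(m), bray_curtis(perm))
        assert np.allclose(horn(m), horn(perm))

    def test_horn_is_scale_invariant_bray_is_not(self):
        m = random_abundance(np.random.default_rng(6), 3, 6)
        scaled = m.copy()
        scaled.iloc[0] *= 7.0
        assert np.allclose(horn(m), horn(scaled), atol=1e-12)
        assert not np.allclose(bray_curtis(m), bray_curtis(scaled))

    def test_all_zero_row_rejected(self):
        m = pd.DataFrame([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            bray_curtis(m)


class TestPCoA:
    def test_two_samples_sit_at_plus_minus_half_distance(self):
        d = 0.6
        dm = pd.DataFrame([[0, d], [d, 0]], index=["a", "b"], columns=["a", "b"])
        res = pcoa(dm)
        coords = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        assert coords == pytest.approx([-d / 2, d / 2])

    def test_three_equidistant_samples_have_two_equal_eigenvalues(self):
        dm = pd.DataFrame(1 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-10)

    def test_reconstructed_distances_match_for_euclidean_input(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform

        dm = pd.DataFrame(squareform(pdist(pts)), index=range(6), columns=range(6))
        res = pcoa(dm)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, dm.to_numpy(), atol=1e-8)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        m = random_abundance(np.random.default_rng(8), 6, 10)
        dm = bray_curtis(m)
        res = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.to_numpy(), ids=list(map(str, dm.index)))
        )
        n_axes = res.coordinates.shape[1]
        ref_eig = np.asarray(ref.eigvals)[:n_axes]
        assert np.allclose(res.eigenvalues[:n_axes], ref_eig, atol=1e-8)
        assert np.allclose(
            np.abs(res.coordinates.to_numpy()),
            np.abs(np.asarray(ref.samples)[:, :n_axes]),
            atol=1e-6,
        )

    def test_asymmetric_input_rejected(self):
        dm = pd.DataFrame([[0, 0.5], [0.4, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(dm)


class TestPermanova:
    @staticmethod
    def _oracle_f(d2, labels):
        n = len(labels)
        groups = {}
        for i, g in enumerate(labels):
            groups.setdefault(g, []).append(i)
        ss_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_w = sum(
            sum(d2[i, j] for i, j in combinations(idx, 2)) / len(idx)
            for idx in groups.values()
        )
        k = len(groups)
        return ((ss_t - ss_w) / (k - 1)) / (ss_w / (n - k))

    def test_exhaustive_p_equals_full_enumeration(self):
        rng = np.random.default_rng(9)
        m = random_abundance(rng, 6, 8)
        m.iloc[:3] += 15.0  # separate the first group
        dm = bray_curtis(m)
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        res = permanova(dm, labels, seed=0)
        assert res.exhaustive and res.n_permutations == 20
        # independent oracle: every distinct relabeling via multiset perms
        from itertools import permutations as iperm

        d2 = dm.to_numpy() ** 2
        f_obs = self._oracle_f(d2, labels)
        assert res.pseudo_F == pytest.approx(f_obs, rel=1e-10)
        seen = {p for p in iperm(labels)}
        fs = [self._oracle_f(d2, np.array(p)) for p in seen]
        p_oracle = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        assert res.p_value == pytest.approx(p_oracle)

    def test_coincident_points_degenerate_with_p_one(self):
        dm = pd.DataFrame(np.zeros((4, 4)))
        res = permanova(dm, ["a", "a", "b", "b"], seed=1)
        assert res.degenerate and res.p_value == 1.0

    def test_separated_clusters_reach_minimum_p(self):
        rng = np.random.default_rng(10)
        m = random_abundance(rng, 6, 8)
        m.iloc[:4] += 100.0
        dm = bray_curtis(m)
        res = permanova(dm, ["a"] * 4 + ["b"] * 2, seed=2)
        # C(6,2)=15 distinct labelings; the observed split is the best one
        assert res.n_permutations == 15
        assert res.p_value == pytest.approx(1 / 15)

    def test_r2_complements_residual_fraction(self):
        rng = np.random.default_rng(11)
        m = random_abundance(rng, 8, 10)
        dm = bray_curtis(m)
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(dm, labels, seed=3)
        from mobindex.diversity import _permanova_ss

        ss_t, ss_w = _permanova_ss(dm.to_numpy() ** 2, np.array(labels))
        assert res.R2 + ss_w / ss_t == pytest.approx(1.0, abs=1e-12)

    def test_seed_irrelevant_when_exhaustive(self):
        rng = np.random.default_rng(12)
        m = random_abundance(rng, 6, 6)
        dm = bray_curtis(m)
        labels = ["a", "a", "a", "b", "b", "b"]
        p1 = permanova(dm, labels, seed=1).p_value
        p2 = permanova(dm, labels, seed=999).p_value
        assert p1 == p2

    def test_sample_reordering_does_not_change_p(self):
        rng = np.random.default_rng(13)
        m = random_abundance(rng, 6, 6)
        dm = bray_curtis(m)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        perm = np.random.default_rng(0).permutation(6)
        dm2 = dm.iloc[perm, perm]
        res1 = permanova(dm, labels, seed=5)
        res2 = permanova(dm2, labels[perm], seed=5)
        assert res1.p_value == res2.p_value
        assert res1.pseudo_F == pytest.approx(res2.pseudo_F)

    def test_pseudo_f_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(14)
        m = random_abundance(rng, 8, 10)
        dm = bray_curtis(m)
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(dm, labels, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.to_numpy(), ids=list(map(str, range(8)))),
            grouping=labels,
            permutations=99,
        )
        assert res.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_single_group_rejected(self):
        dm = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="two groups"):
            permanova(dm, ["a", "a", "a"])

    def test_distinct_assignment_count(self):
        assert n_distinct_assignments(["a"] * 3 + ["b"] * 3) == 20
        assert n_distinct_assignments(["a"] * 8 + ["b"] * 4) == 495


class TestVennFractions:
    def test_percentages_sum_to_100(self):
        out = shared_unique_fractions(50, 30, 20)
        assert out["shared_pct"] + out["unique_a_pct"] + out["unique_b_pct"] == 100.0
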