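import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial import distance as sdist
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac
from skbio.stats.distance import anosim as skbio_anosim

from concord16s.alpha import rarefy, sample_seeds
from concord16s.beta import (
    anosim,
    average_rarefied_table,
    bray_curtis,
    distance_matrix,
    jaccard_binary,
    pcoa,
    unifrac,
)
from concord16s.io import read_newick
from concord16s.types import PhyloTree

from conftest import make_table


class TestAverageRarefiedTable:
    def test_single_draw_equals_one_rarefaction(self):
        t = make_table([[40, 10], [60, 30]])
        m, _, _ = average_rarefied_table(t, depth=40, n_draws=1, seed=5)
        expected = np.column_stack(
            [rarefy(t.counts[:, j], 40, rng) for j, rng in enumerate(sample_seeds(5, 2))]
        )
        assert np.array_equal(m, expected)

    def test_columns_sum_to_depth(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(0, 100, size=(12, 5)))
        m, _, _ = average_rarefied_table(t, depth=int(t.sample_totals().min()), n_draws=25, seed=1)
        assert np.allclose(m.sum(axis=0), t.sample_totals().min())

    def test_symmetric_counts_converge_to_half(self):
        t = make_table([[50], [50]])
        m, _, _ = average_rarefied_table(t, depth=10, n_draws=4000, seed=2)
        assert np.allclose(m[:, 0], [5, 5], atol=0.15)

    def test_mean_matches_hypergeometric_expectation(self):
        # exact E[count_i] = depth * K_i / N
        t = make_table([[6], [3], [1]])
        m, _, _ = average_rarefied_table(t, depth=2, n_draws=20000, seed=3)
        expect = 2 * np.array([6, 3, 1]) / 10
        assert np.allclose(m[:, 0], expect, atol=0.03)


class TestVectorMetrics:
    def test_identical_vectors_are_zero(self):
        v = np.array([3.0, 1.0, 0.0])
        assert bray_curtis(v, v) == 0.0
        assert jaccard_binary(v, v) == 0.0

    def test_disjoint_supports_are_one(self):
        x, y = np.array([5.0, 0.0]), np.array([0.0, 2.0])
        assert bray_curtis(x, y) == 1.0
        assert jaccard_binary(x, y) == 1.0

    def test_hand_example(self):
        x, y = np.array([6, 2, 0]), np.array([2, 2, 0])
        assert bray_curtis(x, y) == pytest.approx(1 / 3)
        assert jaccard_binary(x, y) == 0.0

    def test_both_zero_rejected(self):
        z = np.zeros(3)
        with pytest.raises(ValueError):
            bray_curtis(z, z)
        with pytest.raises(ValueError):
            jaccard_binary(z, z)

    def test_oracle_equivalence_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.integers(0, 20, size=10).astype(float)
            y = rng.integers(0, 20, size=10).astype(float)
            if (x + y).sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(sdist.braycurtis(x, y), abs=1e-12)
            assert jaccard_binary(x, y) == pytest.approx(sdist.jaccard(x > 0, y > 0), abs=1e-12)


def random_tree(rng, n):
    pts = rng.random((n, 2))
    z = sch.linkage(pts, method="average")
    names = [f"L{i}" for i in range(n)]
    t = TreeNode.from_linkage_matrix(z, names)
    for node in t.traverse(include_self=False):
        if node.length is None or node.length < 0:
            node.length = 0.0
    t.length = None
    return PhyloTree(t.copy()), t, names


class TestUnifrac:
    TREE = "((A:1,B:1):1,(C:1,D:1):1);"

    def test_equal_compositions_zero_in_all_modes(self):
        t = read_newick(self.TREE)
        x = np.array([3, 1, 0, 2])
        for mode in ("unweighted", "weighted_raw", "weighted_normalized"):
            assert unifrac(t, x, x.copy(), list("ABCD"), mode) == pytest.approx(0.0)

    def test_star_tree_disjoint_communities(self):
        t = read_newick("(A:1,B:1,C:1,D:1);")
        x, y = np.array([5, 5, 0, 0]), np.array([0, 0, 3, 3])
        assert unifrac(t, x, y, list("ABCD"), "unweighted") == 1.0

    def test_hand_traced_two_clade_tree(self):
        t = read_newick(self.TREE)
        x, y = np.array([5, 0, 0, 0]), np.array([0, 0, 3, 0])
        assert unifrac(t, x, y, list("ABCD"), "unweighted") == pytest.approx(1.0)
        # branches A, AB, C, CD each carry |p_x - p_y| = 1
        assert unifrac(t, x, y, list("ABCD"), "weighted_raw") == pytest.approx(4.0)
        assert unifrac(t, x, y, list("ABCD"), "weighted_normalized") == pytest.approx(1.0)

    def test_missing_feature_listed(self):
        t = read_newick(self.TREE)
        with pytest.raises(KeyError, match="E"):
            unifrac(t, np.array([1, 1]), np.array([1, 0]), ["A", "E"], "unweighted")

    def test_oracle_equivalence_vs_skbio(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            n = int(rng.integers(3, 7))
            mine, sk, names = random_tree(rng, n)
            x, y = rng.integers(0, 10, n), rng.integers(0, 10, n)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert unifrac(mine, x, y, names, "unweighted") == pytest.approx(
                unweighted_unifrac(x, y, taxa=names, tree=sk), abs=1e-9
            )
            assert unifrac(mine, x, y, names, "weighted_raw") == pytest.approx(
                weighted_unifrac(x, y, taxa=names, tree=sk), abs=1e-9
            )
            assert unifrac(mine, x, y, names, "weighted_normalized") == pytest.approx(
                weighted_unifrac(x, y, taxa=names, tree=sk, normalized=True), abs=1e-9
            )


class TestDistanceMatrixProperties:
    def test_symmetry_zero_diagonal_and_bounds(self):
        rng = np.random.default_rng(7)
        m = rng.integers(0, 30, size=(15, 6)).astype(float) + 0.5
        for metric in ("jaccard", "braycurtis"):
            dm = distance_matrix(m, [f"s{j}" for j in range(6)], metric)
            assert np.allclose(dm.data, dm.data.T)
            assert np.allclose(np.diag(dm.data), 0)
            assert (dm.data >= 0).all() and (dm.data <= 1).all()


class TestPcoa:
    def test_collinear_points_recovered_on_one_axis(self):
        dm = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float), ids=list("abc"))
        ord_ = pcoa(dm)
        d01 = abs(ord_.coordinates[0, 0] - ord_.coordinates[1, 0])
        d02 = abs(ord_.coordinates[0, 0] - ord_.coordinates[2, 0])
        assert d01 == pytest.approx(1.0, abs=1e-9)
        assert d02 == pytest.approx(2.0, abs=1e-9)
        assert ord_.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_square_has_two_equal_leading_eigenvalues(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        dm = DistanceMatrix(sdist.squareform(sdist.pdist(pts)), ids=list("abcd"))
        ord_ = pcoa(dm)
        assert ord_.eigenvalues[0] == pytest.approx(ord_.eigenvalues[1], abs=1e-9)

    def test_euclidean_input_reconstructs_distances(self):
        rng = np.random.default_rng(8)
        pts = rng.random((8, 3))
        d = sdist.squareform(sdist.pdist(pts))
        ord_ = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(8)]))
        assert ord_.n_negative == 0
        recon = sdist.squareform(sdist.pdist(ord_.coordinates))
        assert np.allclose(recon, d, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=list("ab")))


def exhaustive_anosim_oracle(dm: np.ndarray, labels: list[str]):
    """Full enumeration of distinct label assignments (independent oracle)."""
    from scipy.stats import rankdata

    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm[iu])

    def r_stat(labs):
        labs = np.asarray(labs)
        same = labs[:, None] == labs[None, :]
        w = ranks[same[iu]]
        b = ranks[~same[iu]]
        return (b.mean() - w.mean()) / (n * (n - 1) / 4)

    obs = r_stat(labels)
    seen = sorted(set(itertools.permutations(labels)))
    count = sum(1 for perm in seen if r_stat(perm) >= obs - 1e-12)
    return obs, count / len(seen)


class TestAnosim:
    def six_sample_dm(self, scale=1.0):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.random((3, 2)), rng.random((3, 2)) + scale])
        return DistanceMatrix(sdist.squareform(sdist.pdist(pts)), ids=[f"s{i}" for i in range(6)])

    def test_perfect_separation_r_is_one(self):
        dm = self.six_sample_dm(scale=10.0)
        res = anosim(dm, ["g1"] * 3 + ["g2"] * 3)
        assert res.r == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        dm = self.six_sample_dm(scale=1.2)
        labels = ["g1"] * 3 + ["g2"] * 3
        res = anosim(dm, labels)
        obs, p = exhaustive_anosim_oracle(dm.data, labels)
        assert res.exhaustive
        assert res.r == pytest.approx(obs, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_r_matches_skbio(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            pts = rng.random((9, 2))
            dm = DistanceMatrix(sdist.squareform(sdist.pdist(pts)), ids=[f"s{i}" for i in range(9)])
            labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
            mine = anosim(dm, labels, posthoc=False)
            theirs = skbio_anosim(dm, grouping=labels, permutations=0)
            assert mine.r == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        dm = self.six_sample_dm(scale=1.5)
        labels = ["g1"] * 3 + ["g2"] * 3
        squared = DistanceMatrix(dm.data**2, ids=dm.ids)
        assert anosim(dm, labels).r == pytest.approx(anosim(squared, labels).r)

    def test_fixed_seed_reproducible_in_permutation_mode(self):
        rng = np.random.default_rng(11)
        pts = rng.random((12, 2))
        dm = DistanceMatrix(sdist.squareform(sdist.pdist(pts)), ids=[f"s{i}" for i in range(12)])
        labels = ["a"] * 6 + ["b"] * 6
        r1 = anosim(dm, labels, n_permutations=99, seed=7, exhaustive=False)
        r2 = anosim(dm, labels, n_permutations=99, seed=7, exhaustive=False)
        assert not r1.exhaustive
        assert r1.p_value == r2.p_value

    def test_singleton_group_named_in_error(self):
        dm = self.six_sample_dm()
        with pytest.raises(ValueError, match="lonely"):
            anosim(dm, ["a", "a", "a", "a", "a", "lonely"])

    def test_posthoc_adjusted_pairs(self):
        rng = np.random.default_rng(12)
        pts = np.vstack([rng.random((3, 2)) + k * 3 for k in range(3)])
        dm = DistanceMatrix(sdist.squareform(sdist.pdist(pts)), ids=[f"s{i}" for i in range(9)])
        res = anosim(dm, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert len(res.pairwise) == 3
        for entry in res.pairwise:
            assert entry["p_adjusted"] >= entry["p_value"] - 1e-12
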