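import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from tfclust import lineage as lin
from tfclust.genomic_io import GenomicInterval, merge_intervals
from tfclust.synthetic import gen_lineage_dataset


def random_tree(rng, n=8):
    """A dendrogram from random binary data (for property tests)."""
    mat = (rng.random((n, 40)) < 0.5).astype(np.uint8)
    return lin.cluster_nearest_neighbour(lin.distance_matrix(mat))


class TestPresenceMatrix:
    def test_full_containment_required(self):
        ref = [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)]
        pm = lin.presence_matrix(
            {"A": [GenomicInterval("c", 10, 20)],
             "B": [GenomicInterval("c", 90, 110)]},
            ref,
        )
        assert pm.row("A").tolist() == [1, 0]
        assert pm.row("B").tolist() == [0, 0]

    def test_union_reference_maps_each_region_once(self, rng):
        sets = {}
        for cell in "ABC":
            starts = rng.choice(5000, 30, replace=False) * 10
            sets[cell] = [GenomicInterval("c", int(s), int(s) + int(rng.integers(20, 200)))
                          for s in starts]
        ref = merge_intervals([iv for ivs in sets.values() for iv in ivs])
        starts = np.array([iv.start for iv in ref])
        ends = np.array([iv.end for iv in ref])
        for ivs in sets.values():
            for w in ivs:
                inside = np.sum((starts <= w.start) & (ends >= w.end))
                assert inside == 1

    def test_empty_reference_error(self):
        with pytest.raises(ValueError):
            lin.presence_matrix({"A": []}, [])


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        d = lin.distance_matrix(np.array([[1, 0, 1], [1, 0, 1]]))
        assert d[0, 1] == 0.0

    def test_hand_example(self):
        d = lin.distance_matrix(np.array([[1, 0, 1], [1, 1, 0]]))
        assert d[0, 1] == pytest.approx(np.sqrt(2))

    def test_complementary_rows(self):
        m = 9
        d = lin.distance_matrix(np.array([[1] * m, [0] * m]))
        assert d[0, 1] == pytest.approx(np.sqrt(m))


class TestClusterNearestNeighbour:
    def test_three_point_trace(self):
        d = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], float)
        t = lin.cluster_nearest_neighbour(d, ["A", "B", "C"])
        assert [(sorted(a), sorted(b), h) for a, b, h in t.merges] == [
            ([0], [1], 1.0), ([0, 1], [2], 5.0)
        ]

    def test_equal_distances_caterpillar(self):
        d = np.ones((4, 4)) - np.eye(4)
        t = lin.cluster_nearest_neighbour(d)
        assert [sorted(a | b) for a, b, _ in t.merges] == [
            [0, 1], [0, 1, 2], [0, 1, 2, 3]
        ]

    def test_heights_non_decreasing(self, rng):
        for _ in range(10):
            pts = rng.random((10, 3))
            d = lin.distance_matrix(pts)
            t = lin.cluster_nearest_neighbour(d)
            hs = [h for _, _, h in t.merges]
            assert all(a <= b + 1e-12 for a, b in zip(hs, hs[1:]))

    def test_recovers_separated_lineage(self):
        per_leaf, truth = gen_lineage_dataset(
            "((((A,B),(C,D)),((E,F),(G,H))));", 50, seed=3
        )
        ref = merge_intervals([iv for ivs in per_leaf.values() for iv in ivs])
        pm = lin.presence_matrix(per_leaf, ref)
        tree = lin.cluster_nearest_neighbour(lin.distance_matrix(pm.matrix), pm.cells)
        assert tree.bipartitions() == truth.bipartitions


class TestPlacePrecursors:
    def _tree(self):
        d = np.array([[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]], float)
        return lin.cluster_nearest_neighbour(d, list("ABCD"))

    def test_single_precursor_argmin(self):
        tree = self._tree()
        mat = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 1, 1], [0, 0, 1, 0]], float)
        res = lin.place_precursors(tree, {"p": np.array([1, 1, 0, 0])}, mat)
        clades = [frozenset(tree.leaves[i] for i in c) for c in tree.clades()]
        cents = [mat[sorted(c)].mean(axis=0) for c in tree.clades()]
        costs = [np.linalg.norm(np.array([1, 1, 0, 0]) - c) for c in cents]
        assert res.assignment["p"] == clades[int(np.argmin(costs))]

    def test_matches_brute_force(self, rng):
        tree = self._tree()
        mat = rng.random((4, 6))
        pvecs = {f"p{i}": rng.random(6) for i in range(3)}
        res = lin.place_precursors(tree, pvecs, mat)
        cents = np.stack([mat[sorted(c)].mean(axis=0) for c in tree.clades()])
        names = sorted(pvecs)
        cost = np.stack([
            [np.linalg.norm(pvecs[p] - c) for c in cents] for p in names
        ])
        best = min(
            sum(cost[i, pi] for i, pi in enumerate(perm))
            for perm in itertools.permutations(range(cost.shape[1]), len(names))
        )
        assert res.total_cost == pytest.approx(best)

    def test_too_many_precursors_error(self):
        tree = self._tree()
        mat = np.zeros((4, 3))
        with pytest.raises(ValueError):
            lin.place_precursors(
                tree, {f"p{i}": np.zeros(3) for i in range(5)}, mat
            )


class TestPcoa:
    def test_equilateral(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = lin.pcoa(d, dims=2)
        assert np.allclose(pdist(coords), 1.0)

    def test_collinear_points_one_dim(self):
        x = np.array([[0.0], [1.0], [2.0], [3.5]])
        d = lin.distance_matrix(x)
        with pytest.warns(UserWarning):
            coords = lin.pcoa(d, dims=3)
        assert coords.shape[1] <= 3
        assert np.allclose(pdist(coords[:, :1]), pdist(x))

    def test_duplicate_points_coincide(self):
        x = np.array([[0.0, 0], [0, 0], [3, 4]])
        d = lin.distance_matrix(x)
        with pytest.warns(UserWarning):
            coords = lin.pcoa(d, dims=2)
        assert np.allclose(coords[0], coords[1])

    def test_full_dimension_reconstruction(self, rng):
        pts = rng.random((7, 4))
        d = lin.distance_matrix(pts)
        coords = lin.pcoa(d, dims=7)
        assert np.allclose(pdist(coords), pdist(pts), atol=1e-8)


class TestBootstrapSupport:
    def test_separated_clades_full_support(self):
        per_leaf, _ = gen_lineage_dataset(
            "((A,B),(C,D));",
            {frozenset("AB"): 40, frozenset("CD"): 40},
            seed=2,
        )
        ref = merge_intervals([iv for ivs in per_leaf.values() for iv in ivs])
        pm = lin.presence_matrix(per_leaf, ref)
        support = lin.bootstrap_branch_support(pm.matrix, pm.cells, n_iter=100, seed=0)
        assert support and all(v == 100.0 for v in support.values())

    def test_support_bounded_and_deterministic(self, rng):
        mat = (rng.random((6, 25)) < 0.4).astype(np.uint8)
        s1 = lin.bootstrap_branch_support(mat, list("ABCDEF"), n_iter=50, seed=7)
        s2 = lin.bootstrap_branch_support(mat, list("ABCDEF"), n_iter=50, seed=7)
        assert s1 == s2
        assert all(0.0 <= v <= 100.0 for v in s1.values())


class TestLeaveCategoryOut:
    def test_ten_categories_gives_1022(self):
        subsets = lin.leave_category_out_ensemble([f"TC{i}" for i in range(10)])
        assert len(subsets) == 1022

    def test_three_categories(self):
        subsets = lin.leave_category_out_ensemble(list("abc"))
        assert len(subsets) == 6
        assert subsets[0] == ("a",)

    def test_two_categories(self):
        assert len(lin.leave_category_out_ensemble(list("ab"))) == 2

    def test_single_category_error(self):
        with pytest.raises(ValueError):
            lin.leave_category_out_ensemble(["only"])


class TestBakersGamma:
    def test_identical_trees(self, rng):
        t = random_tree(rng)
        assert lin.bakers_gamma(t, t).gamma == pytest.approx(1.0)

    def test_leaf_order_invariance(self, rng):
        mat = (rng.random((7, 30)) < 0.5).astype(np.uint8)
        names = list("ABCDEFG")
        t1 = lin.cluster_nearest_neighbour(lin.distance_matrix(mat), names)
        perm = rng.permutation(7)
        t2 = lin.cluster_nearest_neighbour(
            lin.distance_matrix(mat[perm]), [names[i] for i in perm]
        )
        assert lin.bakers_gamma(t1, t2).gamma == pytest.approx(1.0)

    def test_random_trees_near_zero(self):
        rng = np.random.default_rng(0)
        gs = [
            lin.bakers_gamma(random_tree(rng), random_tree(rng)).gamma
            for _ in range(100)
        ]
        assert abs(np.mean(gs)) < 0.1

    def test_leaf_set_mismatch_error(self, rng):
        t1 = random_tree(rng, 5)
        t2 = random_tree(rng, 6)
        with pytest.raises(ValueError):
            lin.bakers_gamma(t1, t2)

    def test_gamma_bk_identity_property(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = random_tree(rng, n=int(rng.integers(4, 10)))
            assert lin.bakers_gamma(t, t).gamma == pytest.approx(1.0)
            curve = lin.fowlkes_mallows_bk(t, t)
            assert np.allclose(curve.bk[curve.defined], 1.0)


class TestFowlkesMallows:
    def test_hand_example(self):
        # n=6, contingency [[2,1],[1,2]]
        l1 = np.array([0, 0, 0, 1, 1, 1])
        l2 = np.array([0, 0, 1, 0, 1, 1])
        bk, e, v = lin.bk_statistics(l1, l2)
        assert bk == pytest.approx(1 / 3)
        assert e == pytest.approx(0.4)

    def test_moments_exact_under_full_permutation(self):
        # closed forms are the exact permutation-null moments (n=6: 720 perms)
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([0, 1, 1, 2, 2, 0])
        bk, e, v = lin.bk_statistics(a, b)
        sims = [
            lin.bk_statistics(a, b[list(p)])[0]
            for p in itertools.permutations(range(6))
        ]
        assert e == pytest.approx(np.mean(sims), abs=1e-12)
        assert v == pytest.approx(np.var(sims), abs=1e-12)

    def test_undefined_for_all_singletons(self):
        bk, e, v = lin.bk_statistics(np.arange(5), np.arange(5))
        assert np.isnan(bk)

    def test_curve_limits(self, rng):
        t1, t2 = random_tree(rng), random_tree(rng)
        curve = lin.fowlkes_mallows_bk(t1, t2)
        d = curve.defined
        assert np.all(curve.bk[d] >= -1e-12) and np.all(curve.bk[d] <= 1 + 1e-12)
        assert np.all(curve.upper[d] >= curve.lower[d])


class TestLineageRestricted:
    def _setup(self):
        per_leaf, truth = gen_lineage_dataset(
            "((A,B),(C,D));",
            {frozenset("ABCD"): 10, frozenset("AB"): 10, frozenset("CD"): 10},
            seed=9,
        )
        ref = merge_intervals([iv for ivs in per_leaf.values() for iv in ivs])
        pm = lin.presence_matrix(per_leaf, ref)
        tree = lin.cluster_nearest_neighbour(lin.distance_matrix(pm.matrix), pm.cells)
        return pm, tree, truth

    def test_groups_recover_planted_branches(self):
        pm, tree, truth = self._setup()
        groups = lin.lineage_restricted_regions(pm, tree)
        by_clade = {c: {pm.elements[i] for i in idx} for c, idx in groups.items()}
        for clade, elems in truth.branch_elements.items():
            got = by_clade.get(frozenset(clade), set())
            # planted element positions match (reference is the union merge)
            assert {(e.start, e.end) for e in elems} == {(e.start, e.end) for e in got}

    def test_ubiquitous_element_goes_to_root(self):
        pm, tree, _ = self._setup()
        groups = lin.lineage_restricted_regions(pm, tree)
        root = frozenset(tree.leaves)
        everywhere = np.nonzero(pm.matrix.all(axis=0))[0]
        assert set(everywhere) <= set(groups[root])

    def test_alpha_beta_validation(self):
        pm, tree, _ = self._setup()
        with pytest.raises(ValueError):
            lin.lineage_restricted_regions(pm, tree, alpha=0.2, beta=0.5)
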