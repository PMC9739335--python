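"""Tests for patristic distances and the permutation Mantel test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ricascade.assoc import (
    DistanceMatrix,
    mantel_test,
    parse_newick,
    patristic_distances,
    ri_distance_report,
    symmetrize_ri,
    write_newick,
)
from ricascade.barriers import SchemaError
from ricascade.synth import simulate_tree


class TestParseNewick:
    def test_minimal_two_leaf_tree(self):
        tree = parse_newick("(A:1,B:2);")
        leaves = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert leaves == {"A": 1.0, "B": 2.0}

    def test_nested_tree_internal_edge(self):
        tree = parse_newick("((A:1,B:1):0.5,C:2);")
        assert len(tree.leaf_nodes()) == 3
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.length is not None and not e.head_node.is_leaf()]
        assert 0.5 in internal

    def test_round_trip_preserves_distances(self):
        nwk = simulate_tree(6, rng_seed=3)
        once = patristic_distances(parse_newick(nwk))
        again = patristic_distances(parse_newick(write_newick(parse_newick(nwk))))
        np.testing.assert_allclose(once.values, again.values, rtol=1e-6)

    @pytest.mark.parametrize("bad", ["((A:1,B:2;", "(A:1,A:2);", "(A:1,B);"])
    def test_malformed_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_newick(bad)


class TestPatristicDistances:
    def test_two_leaf_path_sum(self):
        m = patristic_distances(parse_newick("(A:1,B:2);"))
        assert m.values[m.labels.index("A"), m.labels.index("B")] == pytest.approx(3.0)

    def test_hand_path_sums(self):
        m = patristic_distances(parse_newick("((A:1,B:1):0.5,C:2);"))
        d = m.to_frame()
        assert d.loc["A", "C"] == pytest.approx(3.5)
        assert d.loc["A", "B"] == pytest.approx(2.0)

    def test_ultrametric_tree_equal_root_depths(self):
        # coalescent-style simulated trees are ultrametric by construction
        tree = parse_newick(simulate_tree(6, rng_seed=1))
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        np.testing.assert_allclose(depths, depths[0], rtol=1e-5)

    def test_four_point_condition_on_random_trees(self):
        for seed in range(5):
            m = patristic_distances(parse_newick(simulate_tree(6, rng_seed=seed))).values
            n = m.shape[0]
            for (i, j, k, l) in itertools.combinations(range(n), 4):
                sums = sorted([m[i, j] + m[k, l], m[i, k] + m[j, l], m[i, l] + m[j, k]])
                assert sums[1] == pytest.approx(sums[2], abs=1e-9)

    def test_matrix_is_symmetric_nonnegative_zero_diagonal(self):
        m = patristic_distances(parse_newick(simulate_tree(8, rng_seed=7))).values
        np.testing.assert_allclose(m, m.T)
        assert (np.diag(m) == 0).all()
        assert (m >= 0).all()


def _random_distance_matrix(labels, rng):
    n = len(labels)
    m = rng.uniform(0, 1, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(list(labels), m)


class TestMantel:
    def test_identity_gives_perfect_correlation(self):
        rng = np.random.default_rng(0)
        m = _random_distance_matrix("abcdef", rng)
        r, p = mantel_test(m, m, n_permutations=199, rng_seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_affine_transform_preserves_correlation(self):
        rng = np.random.default_rng(1)
        m1 = _random_distance_matrix("abcdef", rng)
        m2 = DistanceMatrix(m1.labels, 3.0 * m1.values + 0.7)
        m2.values[np.diag_indices(6)] = 0.0
        r, _ = mantel_test(m1, m2, n_permutations=99, rng_seed=0)
        assert r == pytest.approx(1.0)

    def test_agrees_with_exact_enumeration_on_four_taxa(self):
        """The sampled permutation null converges to the exhaustive one."""
        rng = np.random.default_rng(5)
        m1 = _random_distance_matrix("abcd", rng)
        m2 = _random_distance_matrix("abcd", rng)
        tri = np.tril_indices(4, k=-1)

        def r_of(perm):
            pm = m2.values[np.ix_(perm, perm)]
            return np.corrcoef(m1.values[tri], pm[tri])[0, 1]

        r_obs = r_of(list(range(4)))
        exact = [r_of(list(p)) for p in itertools.permutations(range(4))]
        p_exact = np.mean([rp >= r_obs - 1e-12 for rp in exact])
        r, p_mc = mantel_test(m1, m2, n_permutations=9999, rng_seed=3)
        assert r == pytest.approx(r_obs)
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_statistic_matches_independent_implementation(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(9)
        m1 = _random_distance_matrix("abcdefgh", rng)
        m2 = _random_distance_matrix("abcdefgh", rng)
        r_ours, _ = mantel_test(m1, m2, n_permutations=99, rng_seed=0)
        r_ref, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(m1.values, m1.labels),
            skbio_distance.DistanceMatrix(m2.values, m2.labels),
            method="pearson", permutations=0,
        )
        assert r_ours == pytest.approx(r_ref)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        m1 = _random_distance_matrix("abcdef", rng)
        m2 = _random_distance_matrix("abcdef", rng)
        r1, p1 = mantel_test(m1, m2, n_permutations=999, rng_seed=0)
        order = list("fedcba")
        r2, p2 = mantel_test(m1.reorder(order), m2.reorder(order),
                             n_permutations=999, rng_seed=0)
        assert r1 == pytest.approx(r2)
        assert abs(p1 - p2) < 0.05  # same null, different permutation stream

    def test_constant_triangle_rejected(self):
        m1 = DistanceMatrix(list("abcd"), np.ones((4, 4)) - np.eye(4))
        rng = np.random.default_rng(0)
        m2 = _random_distance_matrix("abcd", rng)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(m1, m2, n_permutations=9, rng_seed=0)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        m1 = _random_distance_matrix("abcd", rng)
        m2 = _random_distance_matrix("wxyz", rng)
        with pytest.raises(SchemaError):
            mantel_test(m1, m2, n_permutations=9, rng_seed=0)


class TestRiDistanceReport:
    def _directed_ri(self, labels, rng):
        n = len(labels)
        m = rng.uniform(0, 1, size=(n, n))
        np.fill_diagonal(m, np.nan)
        return pd.DataFrame(m, index=labels, columns=labels).fillna(0.0)

    def test_ri_equal_to_distances_gives_r_one(self):
        nwk = simulate_tree(6, rng_seed=0)
        tree = parse_newick(nwk)
        pat = patristic_distances(tree)
        ri = pat.to_frame()
        rep = ri_distance_report(ri, ri, tree, n_permutations=99, rng_seed=0)
        assert rep["tests"]["garden"]["r"] == pytest.approx(1.0)

    def test_constant_ri_surfaces_error(self):
        nwk = simulate_tree(5, rng_seed=0)
        tree = parse_newick(nwk)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        const = pd.DataFrame(0.5, index=labels, columns=labels)
        with pytest.raises(ValueError, match="constant"):
            ri_distance_report(const, const, tree, n_permutations=9, rng_seed=0)

    def test_species_absent_from_tree_rejected(self):
        tree = parse_newick(simulate_tree(4, rng_seed=0))
        rng = np.random.default_rng(0)
        ri = self._directed_ri(["species_1", "species_2", "species_3", "ghost"], rng)
        with pytest.raises(SchemaError):
            ri_distance_report(ri, ri, tree, n_permutations=9, rng_seed=0)

    def test_symmetrization_modes(self):
        labels = list("abc")
        m = pd.DataFrame([[0.0, 0.2, 0.4], [0.6, 0.0, 0.8], [0.2, 0.4, 0.0]],
                         index=labels, columns=labels)
        mean = symmetrize_ri(m, "mean").values
        assert mean[0, 1] == pytest.approx(0.4)
        assert symmetrize_ri(m, "max").values[0, 1] == pytest.approx(0.6)
        assert symmetrize_ri(m, "min").values[0, 1] == pytest.approx(0.2)
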