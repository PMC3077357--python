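import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from spdprog.cluster import GeneModule, ModuleSet
from spdprog.concordance import (
    concordance_statistic,
    module_msts,
    permutation_pvalue,
    progression_similarity,
)
from spdprog.config import RunConfig
from spdprog.tree import boruvka_mst, module_distance_matrix, path_tree


def _distance_frame(d, ids):
    return pd.DataFrame(d, index=ids, columns=ids)


def all_spanning_trees_k4(ids):
    """All 16 labeled trees on 4 nodes via exhaustive Prüfer sequences."""
    from spdprog.tree import _decode_prufer

    for seq in itertools.product(range(4), repeat=2):
        t = nx.Graph()
        t.add_nodes_from(ids)
        for u, v in _decode_prufer(np.array(seq), 4):
            t.add_edge(ids[u], ids[v])
        yield t


class TestConcordanceStatistic:
    def test_zero_distances_give_zero(self):
        ids = list("abcd")
        D = _distance_frame(np.zeros((4, 4)), ids)
        assert concordance_statistic(D, path_tree(ids)) == 0.0

    def test_collinear_path_sums_unit_edges(self):
        ids = list("abcd")
        coords = np.arange(4.0)
        D = _distance_frame(np.abs(coords[:, None] - coords[None, :]), ids)
        assert concordance_statistic(D, path_tree(ids)) == pytest.approx(3.0)

    def test_star_matches_direct_summation(self, rng):
        ids = list("abcd")
        pts = rng.normal(size=(4, 2))
        D = _distance_frame(
            np.linalg.norm(pts[:, None] - pts[None, :], axis=2), ids
        )
        star = nx.Graph()
        star.add_edges_from([("a", "b"), ("a", "c"), ("a", "d")])
        expected = D.loc["a", "b"] + D.loc["a", "c"] + D.loc["a", "d"]
        assert concordance_statistic(D, star) == pytest.approx(expected)

    def test_sample_mismatch_rejected(self):
        D = _distance_frame(np.zeros((3, 3)), list("abc"))
        with pytest.raises(ValueError, match="different sample sets"):
            concordance_statistic(D, path_tree(["a", "b", "x"]))


class TestPermutationPvalue:
    def test_two_samples_statistic_invariant(self):
        expr = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["g1", "g2"], columns=["a", "b"])
        t = path_tree(["a", "b"])
        assert permutation_pvalue(expr, t, n_perm=100, seed=0) == 1.0

    def test_monotone_gradient_vs_own_mst_attains_minimum_p(self):
        """A strict 1-D gradient's own MST is the sorted path; no permutation
        can produce a strictly smaller statistic, so p = 1/1001."""
        ids = [f"s{i}" for i in range(6)]
        expr = pd.DataFrame(
            [np.array([0.0, 1.0, 2.5, 4.0, 6.0, 9.0])] * 3 * np.array([[1.0], [0.8], [1.3]]),
            index=["g1", "g2", "g3"], columns=ids,
        )
        D = module_distance_matrix(expr, list(expr.index), standardized=True)
        tree = boruvka_mst(D, seed=0)
        p = permutation_pvalue(expr, tree, n_perm=1000, seed=3, standardized=True)
        assert p == pytest.approx(1.0 / 1001.0)

    def test_exhaustive_enumeration_confirms_no_smaller_statistic(self):
        """Independent oracle: enumerate all 720 column permutations at n=6."""
        ids = [f"s{i}" for i in range(6)]
        coords = np.array([0.0, 1.0, 2.5, 4.0, 6.0, 9.0])
        D = _distance_frame(np.abs(coords[:, None] - coords[None, :]), ids)
        tree = boruvka_mst(D, seed=0)
        pos = {s: k for k, s in enumerate(ids)}
        edges = [(pos[u], pos[v]) for u, v in tree.edges]
        d = D.to_numpy()
        observed = sum(d[i, j] for i, j in edges)
        smaller = 0
        for perm in itertools.permutations(range(6)):
            stat = sum(d[perm[i], perm[j]] for i, j in edges)
            smaller += stat < observed - 1e-12
        assert smaller == 0

    def test_degenerate_distances_return_one(self):
        # samples at the vertices of an equilateral triangle: every pairwise
        # distance is 1, so the statistic is permutation-invariant
        expr = pd.DataFrame(
            [[0.0, 1.0, 0.5], [0.0, 0.0, np.sqrt(3) / 2]],
            index=["g1", "g2"], columns=list("abc"),
        )
        t = path_tree(list("abc"))
        p = permutation_pvalue(expr, t, n_perm=50, seed=0, standardized=True)
        assert p == 1.0

    def test_bit_identical_across_runs_with_same_seed(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(6, 8)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(8)],
        )
        t = path_tree(list(expr.columns))
        a = permutation_pvalue(expr, t, n_perm=300, seed=11)
        b = permutation_pvalue(expr, t, n_perm=300, seed=11)
        assert a == b


class TestMstOptimalityTransfer:
    @pytest.mark.parametrize("seed", range(10))
    def test_own_mst_minimizes_statistic_over_all_k4_trees(self, seed):
        rng = np.random.default_rng(seed)
        ids = list("abcd")
        expr = pd.DataFrame(
            rng.normal(size=(5, 4)), index=[f"g{i}" for i in range(5)], columns=ids
        )
        D = module_distance_matrix(expr, list(expr.index))
        mst = boruvka_mst(D, seed=seed)
        best = concordance_statistic(D, mst)
        for t in all_spanning_trees_k4(ids):
            assert best <= concordance_statistic(D, t) + 1e-12


class TestProgressionSimilarity:
    def _module_set(self, expr, groups):
        return ModuleSet(
            [GeneModule(f"M{i+1}", list(g), 1.0) for i, g in enumerate(groups)]
        )

    def test_single_module_concordant_by_construction(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(6)],
        )
        modules = self._module_set(expr, [list(expr.index)])
        trees = module_msts(modules, expr, seed=0)
        S, table = progression_similarity(modules, trees, expr, RunConfig(seed=0))
        assert S.S.tolist() == [[1]]
        assert table.own_tree.all()

    def test_identical_modules_fully_concordant(self, rng):
        block = rng.normal(size=(4, 8)) + np.linspace(0, 4, 8)
        expr = pd.DataFrame(
            np.vstack([block, block]),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(8)],
        )
        groups = [list(expr.index[:4]), list(expr.index[4:])]
        modules = self._module_set(expr, groups)
        trees = module_msts(modules, expr, seed=1)
        S, _ = progression_similarity(modules, trees, expr, RunConfig(seed=1))
        assert S.S.tolist() == [[2, 2], [2, 2]]

    def test_planted_concordant_pair_vs_noise_module(self):
        """Two modules sharing the planted ordering support each other's trees;
        a pure-noise module supports neither."""
        from spdprog.synth import simulate_progression

        expr, truth = simulate_progression(
            n_samples=14, n_prog_modules=2, genes_per_module=10,
            n_noise_genes=8, pattern="sinusoid", phases=[0.0, np.pi / 2],
            noise_sd=0.05, seed=0,
        )
        groups = truth.progression_module_gene_ids + [truth.noise_gene_ids]
        modules = self._module_set(expr, groups)
        from spdprog.cluster import standardize_genes

        std = standardize_genes(expr)
        trees = module_msts(modules, std, seed=2, standardized=True)
        S, _ = progression_similarity(
            modules, trees, std, RunConfig(seed=2), standardized=True
        )
        assert S.S[0, 1] == 2
        assert S.S[0, 2] == 0
        assert S.S[1, 2] == 0

    def test_similarity_invariant_to_module_order(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(12, 8)) + np.linspace(0, 3, 8),
            index=[f"g{i}" for i in range(12)],
            columns=[f"s{j}" for j in range(8)],
        )
        groups = [list(expr.index[:4]), list(expr.index[4:8]), list(expr.index[8:])]
        modules = self._module_set(expr, groups)
        trees = module_msts(modules, expr, seed=3)
        S1, _ = progression_similarity(modules, trees, expr, RunConfig(seed=3))
        rev = ModuleSet(modules.modules[::-1])
        S2, _ = progression_similarity(rev, trees[::-1], expr, RunConfig(seed=3))
        # module M_k keeps its identity; S2 is S1 with rows/cols reversed, up to
        # permutation-stream differences -- the diagonal and symmetry must agree
        np.testing.assert_array_equal(S1.S, S1.S.T)
        np.testing.assert_array_equal(S2.S, S2.S.T)
        assert np.diag(S1.S).tolist() == np.diag(S2.S)[::-1].tolist()
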