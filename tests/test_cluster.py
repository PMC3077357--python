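import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from spdprog.cluster import (
    ConsensusModuleClustering,
    DegenerateModuleError,
    GeneModule,
    ModuleSet,
    SplitFailedError,
    consensus_split,
    iterative_consensus_cluster,
    merge_modules,
    module_coherence,
    standardize_genes,
)
from spdprog.config import RunConfig


def _frame(rows, genes=None, samples=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


def _planted_sinusoids(n_modules=3, genes_per=20, n_samples=20, noise_sd=0.05, seed=0):
    """Distinct planted patterns (sinusoid phases 120 deg apart, pairwise corr -1/2)."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    rows, labels = [], []
    for m in range(n_modules):
        pattern = np.sin(t + 2 * np.pi * m / n_modules)
        for _ in range(genes_per):
            rows.append(rng.uniform(0.5, 1.5) * pattern + rng.normal(0, noise_sd, n_samples))
            labels.append(m)
    genes = [f"m{l}_{i}" for i, l in enumerate(labels)]
    return _frame(rows, genes=genes), np.array(labels)


class TestModuleCoherence:
    def test_identical_rows_give_one(self):
        expr = _frame([[1, 2, 3]] * 4)
        assert module_coherence(expr) == pytest.approx(1.0)

    def test_single_gene_is_one(self):
        assert module_coherence(_frame([[5, 1, 9]])) == 1.0

    def test_anticorrelated_pair_is_degenerate(self):
        expr = _frame([[1, 2, 3], [-1, -2, -3]])
        with pytest.raises(DegenerateModuleError):
            module_coherence(expr)

    def test_matches_direct_formula_evaluation(self):
        rows = np.array([[1, 2, 3], [2, 4, 6], [3, 2, 1]], dtype=float)
        center = rows.mean(axis=0)
        expected = np.mean(
            [np.corrcoef(r, center)[0, 1] for r in rows]
        )
        assert module_coherence(_frame(rows)) == pytest.approx(expected, rel=1e-12)


class TestConsensusSplit:
    def test_planted_partition_recovered_exactly(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 15)
        p, q = t, np.sin(2 * np.pi * t)  # corr(p, q) ~ 0
        rows = [p + rng.normal(0, 1e-3, 15) for _ in range(10)]
        rows += [q + rng.normal(0, 1e-3, 15) for _ in range(10)]
        expr = standardize_genes(_frame(rows))
        a, b = consensus_split(expr, runs=50, seed=1)
        sides = {frozenset(a), frozenset(b)}
        genes = list(expr.index)
        assert sides == {frozenset(genes[:10]), frozenset(genes[10:])}

    def test_single_run_consensus_equals_that_run(self):
        expr, _ = _planted_sinusoids(n_modules=2, genes_per=5, seed=3)
        a, b = consensus_split(standardize_genes(expr), runs=1, seed=5)
        assert set(a) | set(b) == set(expr.index)
        assert set(a) & set(b) == set()

    def test_two_distinct_genes_forced_bipartition(self):
        a, b = consensus_split(_frame([[0, 1, 2], [5, 1, 0]]), runs=10, seed=0)
        assert len(a) == len(b) == 1

    def test_identical_rows_cannot_split(self):
        with pytest.raises(SplitFailedError):
            consensus_split(_frame([[1, 2, 3]] * 5), runs=10, seed=0)

    def test_deterministic_given_seed(self):
        expr, _ = _planted_sinusoids(seed=4)
        one = consensus_split(expr, runs=20, seed=9)
        two = consensus_split(expr, runs=20, seed=9)
        assert one == two


class TestIterativeConsensusCluster:
    @pytest.mark.parametrize("seed", range(10))
    def test_planted_patterns_recovered_exactly(self, seed):
        """Three distinct planted patterns are recovered with Rand index 1.0."""
        expr, labels = _planted_sinusoids(noise_sd=0.05, seed=seed)
        cfg = RunConfig(coherence_threshold=0.7, min_module_size=2, seed=seed)
        out = iterative_consensus_cluster(expr, cfg)
        assert len(out.modules) == 3
        found = np.empty(len(labels), dtype=int)
        pos = {g: i for i, g in enumerate(expr.index)}
        for k, mod in enumerate(out.modules):
            for g in mod.gene_ids:
                found[pos[g]] = k
        assert adjusted_rand_score(labels, found) == 1.0

    def test_single_coherent_pattern_yields_one_module(self):
        rng = np.random.default_rng(1)
        pattern = np.sin(np.linspace(0, 3, 12))
        rows = [rng.uniform(0.5, 1.5) * pattern + rng.normal(0, 0.01, 12) for _ in range(20)]
        out = iterative_consensus_cluster(_frame(rows), RunConfig(seed=1))
        assert len(out.modules) == 1
        assert len(out.modules[0].gene_ids) == 20

    def test_small_modules_moved_to_unassigned(self):
        """Module-size filter: sizes {3, 7} with minimum 5 keeps only the 7."""
        rng = np.random.default_rng(2)
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        rows = [np.sin(t) * rng.uniform(0.5, 1.5) + rng.normal(0, 0.01, 16) for _ in range(7)]
        rows += [np.cos(2 * t) * rng.uniform(0.5, 1.5) + rng.normal(0, 0.01, 16) for _ in range(3)]
        out = iterative_consensus_cluster(_frame(rows), RunConfig(min_module_size=5, seed=2))
        assert [len(m.gene_ids) for m in out.modules] == [7]
        assert len(out.unassigned_gene_ids) == 3

    def test_partition_property_and_invariants(self, linear_data):
        expr, _ = linear_data
        cfg = RunConfig(seed=11)
        out = iterative_consensus_cluster(expr, cfg)
        covered = [g for m in out.modules for g in m.gene_ids] + list(
            out.unassigned_gene_ids
        )
        assert sorted(covered) == sorted(expr.index)
        for m in out.modules:
            assert m.coherence >= cfg.coherence_threshold
        std = standardize_genes(expr)
        centers = np.vstack(
            [std.loc[m.gene_ids].mean(axis=0).to_numpy() for m in out.modules]
        )
        corr = np.corrcoef(centers)
        np.fill_diagonal(corr, -1)
        assert corr.max() <= cfg.merge_threshold + 1e-12

    def test_deterministic_given_seed(self, linear_data):
        expr, _ = linear_data
        a = iterative_consensus_cluster(expr, RunConfig(seed=5))
        b = iterative_consensus_cluster(expr, RunConfig(seed=5))
        assert [m.gene_ids for m in a.modules] == [m.gene_ids for m in b.modules]
        assert a.unassigned_gene_ids == b.unassigned_gene_ids


class TestMergeModules:
    def _mods(self, expr, groups):
        return ModuleSet(
            [GeneModule(f"M{i+1}", list(g), 1.0) for i, g in enumerate(groups)]
        )

    def test_identical_centers_merge(self):
        rows = [[0, 1, 2, 3]] * 4
        expr = _frame(rows)
        out = merge_modules(
            self._mods(expr, [["g0", "g1"], ["g2", "g3"]]), expr, 0.9
        )
        assert len(out.modules) == 1

    def test_anticorrelated_centers_unchanged(self):
        expr = _frame([[0, 1, 2, 3], [0, 1, 2, 3], [3, 2, 1, 0], [3, 2, 1, 0]])
        out = merge_modules(
            self._mods(expr, [["g0", "g1"], ["g2", "g3"]]), expr, 0.9
        )
        assert len(out.modules) == 2

    def test_greedy_fixpoint_merges_chain(self):
        """Three highly correlated centers collapse to one module at 0.9."""
        rng = np.random.default_rng(0)
        base = np.linspace(0, 1, 30)
        bumps = [np.zeros(30), rng.normal(0, 0.03, 30), rng.normal(0, 0.05, 30)]
        rows, groups = [], []
        for k, bump in enumerate(bumps):
            groups.append([f"g{2*k}", f"g{2*k+1}"])
            rows += [base + bump, base + bump]
        expr = _frame(rows)
        centers = np.vstack([expr.loc[g].mean(axis=0) for g in groups])
        corr = np.corrcoef(standardize_genes(_frame(centers)).values)
        assert (corr[np.triu_indices(3, 1)] > 0.9).all()  # premise of the trace
        out = merge_modules(self._mods(expr, groups), expr, 0.9)
        assert len(out.modules) == 1
        assert sorted(out.modules[0].gene_ids) == sorted(g for gr in groups for g in gr)


class TestConsensusModuleClusteringEstimator:
    def test_labels_cover_all_features(self, linear_data):
        expr, truth = linear_data
        est = ConsensusModuleClustering(random_state=0).fit(expr.T)
        assert est.labels_.shape == (expr.shape[0],)
        assert est.n_features_in_ == expr.shape[0]
        assert set(est.labels_) >= {0}

    def test_sklearn_clone_and_params(self):
        est = ConsensusModuleClustering(min_module_size=3, random_state=1)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
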