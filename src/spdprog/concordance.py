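"""Concordance between gene modules and sample trees.

The concordance statistic between a module's sample distance matrix D and a
tree with adjacency A is the total edge weight the tree accrues under that
module's geometry, sum over tree edges (i, j) of D_ij.  Small values mean the
tree connects samples the module places close together, i.e. the module's
gradual change supports the tree's progression.  Only closeness of connected
samples is scored (one-sided), so progressions that drift away from a state
and return — the cell cycle being the motivating case — are not penalized.

Significance comes from a permutation null: sample columns are randomly
permuted (equivalently, rows/columns of D reshuffled) and the statistic
recomputed against the fixed tree.  The progression similarity matrix counts,
for each module pair, the trees concordant with both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .cluster import ModuleSet
from .config import RunConfig, derive_seed
from .tree import boruvka_mst, module_distance_matrix

logger = logging.getLogger("spdprog")

__all__ = [
    "ConcordanceRecord",
    "ProgressionSimilarityMatrix",
    "concordance_statistic",
    "permutation_pvalue",
    "module_msts",
    "progression_similarity",
]


@dataclass
class ConcordanceRecord:
    module_id: str
    tree_id: str
    statistic: float
    p_value: float
    concordant: bool
    own_tree: bool = False


@dataclass
class ProgressionSimilarityMatrix:
    module_ids: List[str]
    S: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.module_ids, columns=self.module_ids)


def _edge_indices(D: pd.DataFrame, tree: nx.Graph) -> Tuple[np.ndarray, np.ndarray]:
    if set(tree.nodes) != set(D.index):
        raise ValueError("tree and distance matrix have different sample sets")
    pos = {s: k for k, s in enumerate(D.index)}
    a = np.fromiter((pos[u] for u, v in tree.edges), dtype=np.intp)
    b = np.fromiter((pos[v] for u, v in tree.edges), dtype=np.intp)
    return a, b


def concordance_statistic(D: pd.DataFrame, tree: nx.Graph) -> float:
    """Sum of D over the tree's edges (equivalently sum_{i<j} A_ij D_ij)."""
    a, b = _edge_indices(D, tree)
    return float(D.to_numpy()[a, b].sum())


def _permutation_pvalues(
    d: np.ndarray,
    edge_sets: Sequence[Tuple[np.ndarray, np.ndarray]],
    observed: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shared-permutation p-values of one D against several trees at once."""
    n = d.shape[0]
    perms = rng.permuted(
        np.tile(np.arange(n), (n_perm, 1)), axis=1
    )  # (n_perm, n)
    smaller = np.zeros(len(edge_sets), dtype=np.int64)
    for t, (a, b) in enumerate(edge_sets):
        stats = d[perms[:, a], perms[:, b]].sum(axis=1)
        smaller[t] = int((stats < observed[t]).sum())
    return (1.0 + smaller) / (1.0 + n_perm)


def permutation_pvalue(
    module_expr: pd.DataFrame,
    tree: nx.Graph,
    n_perm: int = 1000,
    seed: int = 0,
    standardized: bool = False,
) -> float:
    """Permutation p-value of a module/tree concordance statistic.

    p = (1 + #{permutations with statistic < observed}) / (1 + n_perm), with
    strict "smaller than" and add-one smoothing so p is never zero while the
    canonical 0.002 threshold at 1000 permutations stays attainable.
    Degenerate distance matrices (all off-diagonal entries equal) return
    p = 1 with a warning.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    D = module_distance_matrix(module_expr, list(module_expr.index), standardized)
    d = D.to_numpy()
    off = d[~np.eye(d.shape[0], dtype=bool)]
    if np.allclose(off, off[0]):
        logger.warning("degenerate distance matrix (all distances equal); p = 1")
        return 1.0
    a, b = _edge_indices(D, tree)
    obs = float(d[a, b].sum())
    rng = np.random.default_rng(seed)
    return float(
        _permutation_pvalues(d, [(a, b)], np.array([obs]), n_perm, rng)[0]
    )


def module_msts(
    modules: ModuleSet, expr: pd.DataFrame, seed: int = 0, standardized: bool = False
) -> List[nx.Graph]:
    """One MST per module, seeded per module from the root seed."""
    trees = []
    for m in modules.modules:
        D = module_distance_matrix(expr, m, standardized)
        t = boruvka_mst(D, derive_seed(seed, f"mst:{m.module_id}"))
        t.graph["tree_id"] = m.module_id
        trees.append(t)
    return trees


def progression_similarity(
    modules: ModuleSet,
    trees: Sequence[nx.Graph],
    expr: pd.DataFrame,
    cfg: RunConfig,
    standardized: bool = False,
    share_permutations: bool = False,
) -> Tuple[ProgressionSimilarityMatrix, pd.DataFrame]:
    """Full module x tree concordance table and the similarity matrix S.

    S[i, j] counts the trees concordant with both modules i and j, where
    concordance is a permutation p-value below ``cfg.p_threshold``; each
    module is concordant with its own MST by construction (the test result is
    still recorded in the returned table).  By default each module/tree pair
    draws its own permutations; ``share_permutations`` reuses a single
    permutation set per module across all trees to cut cost.
    """
    m = len(modules.modules)
    if m != len(trees):
        raise ValueError("need exactly one tree per module")
    records = []
    conc = np.zeros((m, m), dtype=bool)
    for i, mod in enumerate(modules.modules):
        D = module_distance_matrix(expr, mod, standardized)
        d = D.to_numpy()
        off = d[~np.eye(d.shape[0], dtype=bool)]
        degenerate = np.allclose(off, off[0])
        edge_sets = [_edge_indices(D, t) for t in trees]
        observed = np.array([d[a, b].sum() for a, b in edge_sets])
        if degenerate:
            pvals = np.ones(m)
        elif share_permutations:
            rng = np.random.default_rng(
                derive_seed(cfg.seed, f"perm:{mod.module_id}")
            )
            pvals = _permutation_pvalues(
                d, edge_sets, observed, cfg.n_permutations, rng
            )
        else:
            pvals = np.empty(m)
            for j in range(m):
                rng = np.random.default_rng(
                    derive_seed(cfg.seed, f"perm:{mod.module_id}:{j}")
                )
                pvals[j] = _permutation_pvalues(
                    d, edge_sets[j : j + 1], observed[j : j + 1],
                    cfg.n_permutations, rng,
                )[0]
        for j in range(m):
            own = i == j
            flag = bool(pvals[j] < cfg.p_threshold) or own
            conc[i, j] = flag
            records.append(
                ConcordanceRecord(
                    module_id=mod.module_id,
                    tree_id=trees[j].graph.get("tree_id", str(j)),
                    statistic=float(observed[j]),
                    p_value=float(pvals[j]),
                    concordant=flag,
                    own_tree=own,
                )
            )
    S = (conc.astype(np.int64) @ conc.astype(np.int64).T) if m else np.zeros((0, 0))
    # S[i,j] = sum_t conc[i,t] & conc[j,t]
    table = pd.DataFrame([r.__dict__ for r in records])
    return ProgressionSimilarityMatrix(modules.module_ids, S), table
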