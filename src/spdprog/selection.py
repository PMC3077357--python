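"""Module selection and the overall progression tree.

The progression similarity matrix is reordered by hierarchical clustering of
its columns so mutually concordant modules form visible diagonal blocks.
Selection of a block is manual by design (automated block finding proved
unreliable across datasets and is offered only as an advisory heuristic); the
union of the selected modules' genes defines the distance matrix whose MST is
the overall progression hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.cluster.hierarchy as sch

from .cluster import ModuleSet
from .concordance import ProgressionSimilarityMatrix
from .tree import boruvka_mst, module_distance_matrix

__all__ = [
    "SelectionResult",
    "reorder_similarity",
    "select_modules",
    "auto_select_block",
    "overall_mst",
]


@dataclass
class SelectionResult:
    selected_module_ids: List[str]
    selected_gene_ids: List[str]
    display_order: List[str]
    overall_tree: Optional[nx.Graph] = None
    auto_selected: bool = False


def reorder_similarity(S: ProgressionSimilarityMatrix) -> List[str]:
    """Leaf order of average-linkage (Euclidean) clustering of S's columns."""
    m = len(S.module_ids)
    if m == 1:
        return list(S.module_ids)
    if m < 1:
        raise ValueError("empty similarity matrix")
    cols = S.S.T.astype(float)
    linkage = sch.linkage(cols, method="average", metric="euclidean")
    leaves = sch.leaves_list(linkage)
    return [S.module_ids[k] for k in leaves]


def select_modules(
    S: ProgressionSimilarityMatrix, module_ids: Sequence[str]
) -> SelectionResult:
    """Validate and record a manual block selection."""
    ids = list(module_ids)
    if not ids:
        raise ValueError("selection is empty")
    unknown = [i for i in ids if i not in S.module_ids]
    if unknown:
        raise KeyError(
            f"unknown module id(s) {unknown}; valid ids: {S.module_ids}"
        )
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate module ids in selection")
    return SelectionResult(
        selected_module_ids=ids,
        selected_gene_ids=[],
        display_order=reorder_similarity(S),
    )


def auto_select_block(
    S: ProgressionSimilarityMatrix, min_block: int = 2
) -> List[str]:
    """Advisory heuristic: best contiguous diagonal block after reordering.

    Scores each contiguous block of the reordered matrix by
    size x (mean off-diagonal entry) — the "mass" of a uniformly high
    diagonal block — and returns the maximizer (ties favour the larger, then
    the leftmost, block).  Diagonal entries are excluded because every module
    is concordant with its own tree by construction, which would inflate
    small blocks; a singleton block is scored by its diagonal.  The mean is
    used rather than the minimum so one marginal module pair does not veto an
    otherwise uniformly high block.  This is a convenience only — canonical use is visual
    inspection of the reordered matrix and manual selection.
    """
    m = len(S.module_ids)
    if m < min_block:
        raise ValueError(f"need at least min_block={min_block} modules, got {m}")
    order = reorder_similarity(S)
    pos = {mid: k for k, mid in enumerate(S.module_ids)}
    perm = [pos[mid] for mid in order]
    R = S.S[np.ix_(perm, perm)].astype(float)
    best = (-np.inf, 0, 0, 0)  # (score, size, -start) maximized
    for start in range(m):
        for stop in range(start + max(min_block, 1), m + 1):
            block = R[start:stop, start:stop]
            size = stop - start
            if size == 1:
                score = float(block[0, 0])
            else:
                score = size * float(block[~np.eye(size, dtype=bool)].mean())
            key = (score, size, -start)
            if key > best[:3]:
                best = (score, size, -start, stop)
    start = -best[2]
    stop = best[3]
    return order[start:stop]


def overall_mst(
    expr,
    modules: ModuleSet,
    selected_ids: Sequence[str],
    seed: int = 0,
    standardized: bool = False,
) -> nx.Graph:
    """MST over the union of the selected modules' genes.

    Gene order follows the expression matrix row order; duplicates across
    modules (impossible for disjoint module sets) are collapsed.
    """
    ids = list(selected_ids)
    if not ids:
        raise ValueError("no modules selected")
    union = set()
    for mid in ids:
        union.update(modules[mid].gene_ids)
    genes = [g for g in expr.index if g in union]
    if not genes:
        raise ValueError("selected modules contain no genes")
    D = module_distance_matrix(expr, genes, standardized)
    tree = boruvka_mst(D, seed)
    tree.graph["tree_id"] = "overall"
    tree.graph["selected_module_ids"] = ",".join(ids)
    return tree
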