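"""Agreement between recovered and reference progressions.

Tree topologies are compared through the topological overlap measure (TOM):
for an unweighted tree adjacency A with degrees k and shared-neighbor counts
l_ij, TOM_ij = (l_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij), TOM_ii = 1.  The
distance between two trees on the same samples is the L1 sum of TOM
differences over unordered pairs — a declared aggregation choice (the measure
is a pseudometric; other aggregations exist and give different scales).
Null distributions come from uniform random labeled trees, and robustness
from gene-subsampling bootstrap of the whole pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import RunConfig, derive_seed
from .tree import (
    path_tree,
    random_spanning_tree,
    tree_adjacency,
    tree_diameter,
    validate_sample_tree,
)

logger = logging.getLogger("spdprog")

__all__ = [
    "TomReport",
    "BootstrapReport",
    "RandomTreeNull",
    "tom_matrix",
    "tom_distance",
    "random_tree_null",
    "bootstrap_spd",
]


@dataclass
class TomReport:
    distance: float
    tree_a_id: str
    tree_b_id: str


@dataclass
class RandomTreeNull:
    n_trees: int
    tom_mean: float
    tom_sd: float
    diameter_mean: float
    diameter_sd: float
    diameter_query: Optional[int] = None
    p_diameter_ge_query: Optional[float] = None


@dataclass
class BootstrapReport:
    n_iterations: int
    gene_fraction: float
    tom_distances: List[float]
    n_failed: int
    mean: float
    sd: float


def tom_matrix(tree: nx.Graph, sample_ids: Optional[Sequence[str]] = None) -> np.ndarray:
    """Topological overlap matrix of an unweighted tree adjacency."""
    validate_sample_tree(tree)
    ids = list(sample_ids) if sample_ids is not None else sorted(tree.nodes, key=str)
    A = tree_adjacency(tree, ids)
    shared = A @ A
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_distance(tree_a: nx.Graph, tree_b: nx.Graph) -> TomReport:
    """L1 distance between TOM matrices over unordered sample pairs."""
    if set(tree_a.nodes) != set(tree_b.nodes):
        raise ValueError("trees are over different sample sets")
    ids = sorted(tree_a.nodes, key=str)
    ta = tom_matrix(tree_a, ids)
    tb = tom_matrix(tree_b, ids)
    iu = np.triu_indices(len(ids), k=1)
    dist = float(np.abs(ta - tb)[iu].sum())
    return TomReport(
        distance=dist,
        tree_a_id=tree_a.graph.get("tree_id", "a"),
        tree_b_id=tree_b.graph.get("tree_id", "b"),
    )


def random_tree_null(
    n: int,
    n_trees: int,
    reference: nx.Graph,
    seed: int = 0,
    diameter_query: Optional[int] = None,
) -> RandomTreeNull:
    """Null distributions of TOM distance to a reference tree and of diameter.

    Draws ``n_trees`` uniform labeled trees on the reference's samples and
    summarizes the TOM-distance and diameter distributions, plus the
    empirical probability of a diameter at least ``diameter_query``.
    """
    if reference.number_of_nodes() != n:
        raise ValueError("n does not match the reference tree")
    ids = sorted(reference.nodes, key=str)
    rng = np.random.default_rng(seed)
    toms = np.empty(n_trees)
    diams = np.empty(n_trees, dtype=int)
    for t in range(n_trees):
        tree = random_spanning_tree(n, rng, sample_ids=ids)
        toms[t] = tom_distance(tree, reference).distance
        diams[t] = tree_diameter(tree)
    p_ge = (
        float((diams >= diameter_query).mean()) if diameter_query is not None else None
    )
    return RandomTreeNull(
        n_trees=n_trees,
        tom_mean=float(toms.mean()),
        tom_sd=float(toms.std(ddof=1)),
        diameter_mean=float(diams.mean()),
        diameter_sd=float(diams.std(ddof=1)),
        diameter_query=diameter_query,
        p_diameter_ge_query=p_ge,
    )


def bootstrap_spd(
    expr: pd.DataFrame,
    cfg: RunConfig,
    reference_order: Sequence[str],
    gene_fraction: float = 0.9,
    n_iterations: int = 100,
    selected_ids_policy: str = "rerun-auto",
    selected_ids: Optional[Sequence[str]] = None,
    min_block: int = 2,
    seed: int = 0,
) -> BootstrapReport:
    """Gene-subsampling bootstrap of the full pipeline.

    Each iteration draws ``gene_fraction`` of the genes without replacement,
    reruns clustering, per-module MSTs, concordance and selection, and scores
    the overall MST against the reference ordering by TOM distance.  The
    pipeline seed is held fixed across iterations (only the subsampling
    stream varies) so a fraction of 1.0 reproduces one deterministic result.
    ``selected_ids_policy`` is "rerun-auto" (advisory block heuristic per
    iteration — manual selection is impossible inside a loop) or "fixed"
    (apply ``selected_ids`` to each iteration's modules).  Failed iterations
    are recorded, not fatal.
    """
    from .pipeline import fit_progression  # local import to avoid cycle

    if not 0.0 < gene_fraction <= 1.0:
        raise ValueError("gene_fraction must be in (0, 1]")
    if selected_ids_policy not in {"rerun-auto", "fixed"}:
        raise ValueError("selected_ids_policy must be 'rerun-auto' or 'fixed'")
    if selected_ids_policy == "fixed" and not selected_ids:
        raise ValueError("fixed policy requires selected_ids")
    reference = path_tree(reference_order)
    rng = np.random.default_rng(derive_seed(seed, "bootstrap"))
    n_genes = expr.shape[0]
    n_keep = max(2, int(round(gene_fraction * n_genes)))
    distances: List[float] = []
    n_failed = 0
    for it in range(n_iterations):
        keep = np.sort(rng.choice(n_genes, size=n_keep, replace=False))
        sub = expr.iloc[keep]
        try:
            result = fit_progression(
                sub,
                cfg,
                select=list(selected_ids) if selected_ids_policy == "fixed" else None,
                auto_select=selected_ids_policy == "rerun-auto",
                min_block=min_block,
            )
            distances.append(
                tom_distance(result.overall_tree, reference).distance
            )
        except Exception as exc:  # noqa: BLE001 - per-iteration failures recorded
            logger.warning("bootstrap iteration %d failed: %s", it, exc)
            n_failed += 1
            distances.append(math.nan)
    arr = np.asarray(distances, dtype=float)
    ok = arr[~np.isnan(arr)]
    return BootstrapReport(
        n_iterations=n_iterations,
        gene_fraction=gene_fraction,
        tom_distances=distances,
        n_failed=n_failed,
        mean=float(ok.mean()) if ok.size else math.nan,
        sd=float(ok.std(ddof=1)) if ok.size > 1 else math.nan,
    )
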