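"""Sample distance matrices and minimum spanning trees.

Each gene module induces a Euclidean distance matrix between samples
(computed on the gene-standardized expression restricted to the module); the
MST of that matrix is the module's hypothesized sample progression.  The MST
is grown from the smallest component by single-linkage merging — a
Prim-flavoured variant of Boruvka's scheme that yields the minimum total
weight.  Utilities cover path trees (known orderings), uniform random labeled
trees (Prüfer decoding) for null distributions, and the unweighted diameter.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cluster import GeneModule, standardize_genes

__all__ = [
    "module_distance_matrix",
    "distance_matrix_from_columns",
    "boruvka_mst",
    "tree_diameter",
    "path_tree",
    "random_spanning_tree",
    "validate_sample_tree",
    "tree_adjacency",
]


def validate_sample_tree(tree: nx.Graph) -> nx.Graph:
    """Assert the tree invariants: n-1 edges, connected, acyclic."""
    n = tree.number_of_nodes()
    if n == 0:
        raise ValueError("empty tree")
    if tree.number_of_edges() != n - 1:
        raise ValueError(
            f"tree on {n} nodes must have {n - 1} edges, "
            f"got {tree.number_of_edges()}"
        )
    if n > 1 and not nx.is_connected(tree):
        raise ValueError("tree is disconnected")
    return tree


def distance_matrix_from_columns(expr: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between sample columns of a (sub)matrix."""
    d = squareform(pdist(expr.to_numpy(dtype=float).T, metric="euclidean"))
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


def module_distance_matrix(
    expr: pd.DataFrame,
    module: Union[GeneModule, Sequence[str]],
    standardized: bool = False,
) -> pd.DataFrame:
    """Sample x sample Euclidean distances restricted to a module's genes.

    ``expr`` is the full genes x samples matrix; genes are z-scored first
    unless ``standardized`` says the caller already did so.
    """
    gene_ids = module.gene_ids if isinstance(module, GeneModule) else list(module)
    if len(gene_ids) == 0:
        raise ValueError("empty module")
    missing = [g for g in gene_ids if g not in expr.index]
    if missing:
        raise KeyError(f"module genes absent from expression matrix: {missing[:5]}")
    if standardized:
        sub = expr.loc[gene_ids]
    else:
        # z-scoring is per gene, so standardizing the subset equals
        # standardizing the full matrix first and then subsetting
        sub = standardize_genes(expr.loc[gene_ids])
    return distance_matrix_from_columns(sub)


def boruvka_mst(D: pd.DataFrame, seed: int = 0) -> nx.Graph:
    """Minimum spanning tree grown from the smallest component.

    Starting from the edgeless graph, repeatedly pick one of the smallest
    components at random, compute its single-linkage distance to every other
    component and add the minimizing edge.  Ties in component choice are
    broken uniformly by the seeded generator; ties in distance by the smallest
    (i, j) index pair.  Edge weights are copied from ``D``.
    """
    samples = list(D.index)
    n = len(samples)
    d = D.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    tree = nx.Graph()
    tree.add_nodes_from(samples)
    if n == 1:
        return tree
    rng = np.random.default_rng(seed)
    comp_id = np.arange(n)
    while True:
        ids, counts = np.unique(comp_id, return_counts=True)
        if len(ids) == 1:
            break
        smallest = ids[counts == counts.min()]
        chosen = smallest[rng.integers(len(smallest))]
        inside = np.nonzero(comp_id == chosen)[0]
        outside = np.nonzero(comp_id != chosen)[0]
        block = d[np.ix_(inside, outside)]
        flat = block.argmin()
        bi, bj = np.unravel_index(flat, block.shape)
        best = block[bi, bj]
        # deterministic tie-break: smallest (i, j) among minimizing pairs
        ties = np.argwhere(block == best)
        pairs = sorted((inside[a], outside[b]) for a, b in ties)
        i, j = pairs[0]
        tree.add_edge(samples[i], samples[j], weight=float(d[i, j]))
        comp_id[comp_id == comp_id[j]] = comp_id[i]
    return validate_sample_tree(tree)


def tree_diameter(tree: nx.Graph) -> int:
    """Number of edges on the longest shortest path (unweighted)."""
    validate_sample_tree(tree)
    if tree.number_of_nodes() == 1:
        return 0
    return int(nx.diameter(tree))


def path_tree(sample_order: Sequence[str]) -> nx.Graph:
    """Unit-weight path connecting samples in the given order."""
    order = list(sample_order)
    if len(order) < 2:
        raise ValueError("need at least 2 samples")
    if len(set(order)) != len(order):
        raise ValueError("duplicate sample ids in order")
    tree = nx.Graph()
    tree.add_nodes_from(order)
    for a, b in zip(order, order[1:]):
        tree.add_edge(a, b, weight=1.0)
    return tree


def _decode_prufer(seq: np.ndarray, n: int) -> List[tuple]:
    """Standard Prüfer-sequence decoding into a labeled tree edge list."""
    degree = np.ones(n, dtype=np.intp)
    for x in seq:
        degree[x] += 1
    edges = []
    import heapq

    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, int(x)))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, int(x))
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((u, v))
    return edges


def random_spanning_tree(
    n: int,
    seed: Union[int, np.random.Generator] = 0,
    sample_ids: Optional[Sequence[str]] = None,
) -> nx.Graph:
    """Uniformly random labeled tree on n nodes via Prüfer decoding.

    Unit edge weights; deterministic given seed.  ``sample_ids`` relabels the
    nodes (default integer labels 0..n-1).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(sample_ids) if sample_ids is not None else list(range(n))
    if len(labels) != n:
        raise ValueError("sample_ids length must equal n")
    tree = nx.Graph()
    tree.add_nodes_from(labels)
    if n == 2:
        tree.add_edge(labels[0], labels[1], weight=1.0)
        return tree
    seq = rng.integers(0, n, size=n - 2)
    for u, v in _decode_prufer(seq, n):
        tree.add_edge(labels[u], labels[v], weight=1.0)
    return validate_sample_tree(tree)


def tree_adjacency(tree: nx.Graph, sample_ids: Sequence[str]) -> np.ndarray:
    """0/1 adjacency matrix in the given sample order."""
    idx = {s: k for k, s in enumerate(sample_ids)}
    if set(tree.nodes) != set(sample_ids):
        raise ValueError("tree sample set does not match requested sample ids")
    A = np.zeros((len(sample_ids), len(sample_ids)), dtype=float)
    for a, b in tree.edges:
        A[idx[a], idx[b]] = 1.0
        A[idx[b], idx[a]] = 1.0
    return A
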