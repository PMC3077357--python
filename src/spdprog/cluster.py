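"""Iterative consensus k-means discovery of coherent gene modules.

Genes are partitioned by a divisive procedure: each cluster is repeatedly
bipartitioned by a consensus over many random-restart k=2 k-means runs until
its coherence (mean Pearson correlation of each gene with the cluster's mean
profile) reaches a threshold.  Coherent clusters whose center profiles are
highly correlated are then merged, and clusters below a minimum size are moved
to an unassigned pool.  All k-means restarts for one split run as a single
vectorised batch so the recursion stays fast on the many small clusters it
visits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import RunConfig, derive_seed

logger = logging.getLogger("spdprog")

__all__ = [
    "GeneModule",
    "ModuleSet",
    "DegenerateModuleError",
    "SplitFailedError",
    "standardize_genes",
    "module_coherence",
    "consensus_split",
    "merge_modules",
    "iterative_consensus_cluster",
    "ConsensusModuleClustering",
]


class DegenerateModuleError(ValueError):
    """Cluster mean is constant across samples; coherence is undefined."""


class SplitFailedError(RuntimeError):
    """Cluster cannot be bipartitioned (e.g. all gene rows identical)."""


@dataclass
class GeneModule:
    module_id: str
    gene_ids: List[str]
    coherence: float


@dataclass
class ModuleSet:
    modules: List[GeneModule]
    unassigned_gene_ids: List[str] = field(default_factory=list)

    @property
    def module_ids(self) -> List[str]:
        return [m.module_id for m in self.modules]

    def __getitem__(self, module_id: str) -> GeneModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)


def standardize_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene row across samples (constant rows become zero)."""
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=expr.index, columns=expr.columns)


def _row_corr_with(values: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row with a center vector (0 if a row is flat)."""
    vc = values - values.mean(axis=1, keepdims=True)
    cc = center - center.mean()
    denom = np.sqrt((vc**2).sum(axis=1) * (cc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = vc @ cc / denom
    return np.where(denom > 0, corr, 0.0)


def module_coherence(expr: pd.DataFrame) -> float:
    """Mean Pearson correlation between each gene and the cluster mean profile.

    A single-gene module has coherence 1.0 by convention.  Raises
    :class:`DegenerateModuleError` when the cluster mean is constant across
    samples (e.g. two perfectly anti-correlated genes).
    """
    values = expr.to_numpy(dtype=float)
    if values.shape[0] == 0:
        raise ValueError("empty module")
    if values.shape[0] == 1:
        return 1.0
    center = values.mean(axis=0)
    if np.allclose(center, center[0]):
        raise DegenerateModuleError("cluster mean constant across samples")
    return float(_row_corr_with(values, center).mean())


def _batched_two_means(
    X: np.ndarray, n_runs: int, rng: np.random.Generator, max_iter: int = 100
) -> Tuple[np.ndarray, np.ndarray]:
    """Run ``n_runs`` random-initialization k=2 Lloyd clusterings at once.

    Returns (labels, inertia) with labels of shape (n_runs, n_points) in {0,1}.
    Empty clusters are re-seeded at the point farthest from the surviving
    centroid, guaranteeing a bipartition whenever two distinct rows exist.
    """
    g = X.shape[0]
    init = np.empty((n_runs, 2), dtype=np.intp)
    for r in range(n_runs):
        init[r] = rng.choice(g, size=2, replace=False)
    centers = X[init]  # (runs, 2, d)
    labels = np.zeros((n_runs, g), dtype=np.intp)
    sq = (X**2).sum(axis=1)
    for _ in range(max_iter):
        # squared distance to each of the two centers, all runs at once
        d = (
            sq[None, :, None]
            - 2.0 * np.einsum("gd,rkd->rgk", X, centers)
            + (centers**2).sum(axis=2)[:, None, :]
        )
        new_labels = d.argmin(axis=2)
        counts1 = new_labels.sum(axis=1)
        # re-seed empty clusters at the farthest point from the other center
        for r in np.nonzero((counts1 == 0) | (counts1 == g))[0]:
            k_empty = 0 if counts1[r] == g else 1
            far = d[r, :, 1 - k_empty].argmax()
            new_labels[r, far] = k_empty
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        w1 = labels.astype(float)
        n1 = w1.sum(axis=1, keepdims=True)
        n0 = g - n1
        s1 = w1 @ X
        centers = np.stack([(X.sum(axis=0) - s1) / n0, s1 / n1], axis=1)
    d = (
        sq[None, :, None]
        - 2.0 * np.einsum("gd,rkd->rgk", X, centers)
        + (centers**2).sum(axis=2)[:, None, :]
    )
    inertia = np.take_along_axis(d, labels[:, :, None], axis=2)[:, :, 0].sum(axis=1)
    return labels, inertia


def consensus_split(
    expr: pd.DataFrame, runs: int, seed: int
) -> Tuple[List[str], List[str]]:
    """Bipartition genes by the consensus of ``runs`` k=2 k-means runs.

    The per-run 0/1 labels form a genes x runs matrix; a final k=2 k-means on
    the rows of that matrix gives the consensus bipartition.  A global 0/1
    flip of one run's column is a rigid transformation of the label vectors,
    so no label alignment across runs is needed.  Deterministic given seed.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    genes = list(expr.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to split")
    X = expr.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise SplitFailedError("all gene rows identical")
    rng = np.random.default_rng(seed)
    if len(genes) == 2:
        return [genes[0]], [genes[1]]
    label_matrix, _ = _batched_two_means(X, runs, rng)
    if runs == 1:
        consensus = label_matrix[0]
    else:
        L = label_matrix.T.astype(float)  # genes x runs
        if np.allclose(L, L[0]):
            raise SplitFailedError("all runs assigned every gene identically")
        cons_labels, inertia = _batched_two_means(L, 10, rng)
        consensus = cons_labels[inertia.argmin()]
    side0 = [g for g, c in zip(genes, consensus) if c == consensus[0]]
    side1 = [g for g, c in zip(genes, consensus) if c != consensus[0]]
    if not side1:
        raise SplitFailedError("consensus produced a single cluster")
    return side0, side1


def _centers(std: pd.DataFrame, gene_lists: Sequence[List[str]]) -> np.ndarray:
    return np.vstack([std.loc[g].to_numpy().mean(axis=0) for g in gene_lists])


def _center_corr(centers: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of center profiles; flat centers give 0."""
    c = centers - centers.mean(axis=1, keepdims=True)
    norms = np.sqrt((c**2).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    corr = (c / safe[:, None]) @ (c / safe[:, None]).T
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    return corr


def merge_modules(
    modules: ModuleSet, expr: pd.DataFrame, merge_threshold: float
) -> ModuleSet:
    """Greedily merge the most-correlated module-center pair above threshold.

    Centers and coherences are recomputed after every merge; iterates until no
    pair of centers correlates above ``merge_threshold``.
    """
    std = standardize_genes(expr)
    gene_lists = [list(m.gene_ids) for m in modules.modules]
    while len(gene_lists) > 1:
        corr = _center_corr(_centers(std, gene_lists))
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(corr.argmax(), corr.shape)
        if corr[i, j] <= merge_threshold:
            break
        a, b = min(i, j), max(i, j)
        gene_lists[a] = gene_lists[a] + gene_lists[b]
        del gene_lists[b]
    out = []
    for k, genes in enumerate(gene_lists):
        try:
            coh = module_coherence(std.loc[genes])
        except DegenerateModuleError:
            coh = float("nan")
        out.append(GeneModule(f"M{k + 1}", genes, coh))
    return ModuleSet(out, list(modules.unassigned_gene_ids))


def iterative_consensus_cluster(expr: pd.DataFrame, cfg: RunConfig) -> ModuleSet:
    """Divisive consensus clustering of genes into coherent modules.

    Recursion stops for a cluster when its coherence reaches
    ``cfg.coherence_threshold``, when it has one gene, or when a split fails;
    accepted clusters are then pairwise-merged to a fixpoint and clusters
    smaller than ``cfg.min_module_size`` are moved to the unassigned pool.
    Deterministic given ``cfg.seed``.
    """
    std = standardize_genes(expr)
    rng = np.random.default_rng(derive_seed(cfg.seed, "cluster"))
    accepted: List[List[str]] = []
    unassigned: List[str] = []
    stack: List[List[str]] = [list(std.index)]
    while stack:
        genes = stack.pop()
        sub = std.loc[genes]
        try:
            coh = module_coherence(sub)
            degenerate = False
        except DegenerateModuleError:
            coh = -np.inf
            degenerate = True
        if len(genes) == 1 or coh >= cfg.coherence_threshold:
            accepted.append(genes)
            continue
        try:
            side0, side1 = consensus_split(
                sub, cfg.kmeans_runs, int(rng.integers(2**31 - 1))
            )
        except SplitFailedError:
            if degenerate:
                # constant, unsplittable genes carry no profile information
                unassigned.extend(genes)
            else:
                accepted.append(genes)
            continue
        stack.append(side1)
        stack.append(side0)
    modules = ModuleSet(
        [GeneModule(f"M{k + 1}", g, 0.0) for k, g in enumerate(accepted)], unassigned
    )
    modules = merge_modules(modules, expr, cfg.merge_threshold)
    kept, dropped = [], list(modules.unassigned_gene_ids)
    for m in modules.modules:
        if len(m.gene_ids) >= cfg.min_module_size:
            kept.append(m)
        else:
            dropped.extend(m.gene_ids)
    for k, m in enumerate(kept):
        m.module_id = f"M{k + 1}"
    logger.info(
        "clustering: %d modules, %d unassigned genes", len(kept), len(dropped)
    )
    return ModuleSet(kept, dropped)


class ConsensusModuleClustering(BaseEstimator):
    """Cluster features (genes) into coherent modules, sklearn style.

    Follows the FeatureAgglomeration convention: ``fit`` takes an array of
    shape (n_samples, n_features) and ``labels_`` assigns each feature to a
    module (-1 for unassigned genes).

    Parameters mirror :class:`~spdprog.config.RunConfig`; ``random_state``
    seeds the consensus splits.

    Attributes
    ----------
    module_set_ : ModuleSet
        Full module structure with ids, gene lists and coherences.
    labels_ : ndarray of shape (n_features,)
        Module index per feature, -1 for unassigned.
    """

    def __init__(
        self,
        kmeans_runs: int = 50,
        coherence_threshold: float = 0.9,
        merge_threshold: float = 0.9,
        min_module_size: int = 5,
        random_state: int = 0,
    ):
        self.kmeans_runs = kmeans_runs
        self.coherence_threshold = coherence_threshold
        self.merge_threshold = merge_threshold
        self.min_module_size = min_module_size
        self.random_state = random_state

    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.T.copy()
        X = np.asarray(X, dtype=float)
        genes = [f"g{i}" for i in range(X.shape[1])]
        samples = [f"s{j}" for j in range(X.shape[0])]
        return pd.DataFrame(X.T, index=genes, columns=samples)

    def fit(self, X, y=None) -> "ConsensusModuleClustering":
        expr = self._to_frame(X)
        cfg = RunConfig(
            kmeans_runs=self.kmeans_runs,
            coherence_threshold=self.coherence_threshold,
            merge_threshold=self.merge_threshold,
            min_module_size=self.min_module_size,
            seed=self.random_state if self.random_state is not None else 0,
        )
        self.module_set_ = iterative_consensus_cluster(expr, cfg)
        index = {g: k for k, m in enumerate(self.module_set_.modules) for g in m.gene_ids}
        self.labels_ = np.array([index.get(g, -1) for g in expr.index])
        self.n_features_in_ = expr.shape[0]
        self.feature_names_in_ = np.asarray(list(expr.index), dtype=object)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
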