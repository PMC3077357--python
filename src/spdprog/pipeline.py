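"""End-to-end progression discovery: estimator, functional core, manifest.

:class:`SampleProgressionDiscovery` is the scikit-learn-style entry point:
``fit(X)`` with X of shape (n_samples, n_genes) runs (1) gene-module
clustering, (2) per-module sample MSTs, (3) permutation concordance and the
progression similarity matrix, (4) module selection and the overall MST.
:func:`fit_progression` is the same computation on a genes x samples
DataFrame; :func:`run_pipeline` adds on-disk artifacts, logging and the
two-phase pause for manual module selection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import io as spd_io
from .cluster import ModuleSet, iterative_consensus_cluster, standardize_genes
from .concordance import (
    ProgressionSimilarityMatrix,
    module_msts,
    progression_similarity,
)
from .config import RunConfig, derive_seed
from .selection import (
    SelectionResult,
    auto_select_block,
    overall_mst,
    reorder_similarity,
    select_modules,
)

logger = logging.getLogger("spdprog")

__all__ = [
    "ProgressionResult",
    "RunManifest",
    "fit_progression",
    "run_pipeline",
    "SampleProgressionDiscovery",
]

__version__ = "0.1.0"


@dataclass
class ProgressionResult:
    modules: ModuleSet
    trees: List[nx.Graph]
    similarity: ProgressionSimilarityMatrix
    concordance_table: pd.DataFrame
    display_order: List[str]
    selection: Optional[SelectionResult] = None

    @property
    def overall_tree(self) -> nx.Graph:
        if self.selection is None or self.selection.overall_tree is None:
            raise RuntimeError("no modules selected yet; stage 4 not run")
        return self.selection.overall_tree


def fit_progression(
    expr: pd.DataFrame,
    cfg: RunConfig,
    select: Optional[Sequence[str]] = None,
    auto_select: bool = False,
    min_block: int = 2,
) -> ProgressionResult:
    """Run the four pipeline stages on a genes x samples matrix.

    With neither ``select`` nor ``auto_select`` the result stops after the
    similarity matrix (stage 3), leaving selection for manual inspection.
    """
    spd_io.validate_expression_matrix(expr)
    expr = spd_io.variance_filter(expr, cfg.top_n_variance_genes)
    std = standardize_genes(expr)
    modules = iterative_consensus_cluster(expr, cfg)
    if not modules.modules:
        raise RuntimeError("clustering produced no modules of sufficient size")
    trees = module_msts(modules, std, seed=cfg.seed, standardized=True)
    similarity, table = progression_similarity(
        modules, trees, std, cfg, standardized=True
    )
    display_order = reorder_similarity(similarity)
    result = ProgressionResult(modules, trees, similarity, table, display_order)
    if select is None and auto_select:
        select = auto_select_block(similarity, min_block=min(min_block, len(modules.modules)))
    if select is not None:
        sel = select_modules(similarity, select)
        sel.auto_selected = auto_select and select is not None
        union: List[str] = []
        seen = set()
        for mid in sel.selected_module_ids:
            for g in modules[mid].gene_ids:
                if g not in seen:
                    seen.add(g)
                    union.append(g)
        sel.selected_gene_ids = union
        sel.overall_tree = overall_mst(
            std, modules, sel.selected_module_ids,
            seed=derive_seed(cfg.seed, "overall"), standardized=True,
        )
        sel_idx = [similarity.module_ids.index(m) for m in sel.selected_module_ids]
        block = similarity.S[np.ix_(sel_idx, sel_idx)]
        off_diag = block[~np.eye(len(sel_idx), dtype=bool)]
        if off_diag.size and off_diag.max() == 0:
            logger.warning(
                "selected modules share no concordant trees; "
                "overall tree is low-confidence"
            )
        result.selection = sel
    return result


class SampleProgressionDiscovery(BaseEstimator):
    """Discover a progression (possibly branched) among unordered samples.

    Clusters genes into coherent modules, builds a minimum spanning tree over
    the samples for each module, keeps modules whose gradual expression
    changes support a common progression (permutation-tested concordance
    between module distance matrices and trees), and reconstructs an overall
    MST over the union of the selected modules' genes.

    Parameters
    ----------
    kmeans_runs, coherence_threshold, merge_threshold, min_module_size,
    n_permutations, p_threshold, top_n_variance_genes :
        See :class:`~spdprog.config.RunConfig`.
    selection : "auto", None, or list of module ids
        "auto" applies the advisory block heuristic; an explicit list selects
        those modules; None stops after the similarity matrix.
    min_block : int
        Minimum block size for the auto heuristic.
    random_state : int
        Root seed for every stochastic stage.

    Attributes
    ----------
    modules_ : ModuleSet
    module_trees_ : list of networkx.Graph
    similarity_ : DataFrame, module x module concordant-tree counts
    concordance_ : DataFrame, per module/tree statistic, p-value and flag
    display_order_ : list of module ids (heatmap seriation order)
    selected_module_ids_ : list of str (when selection ran)
    overall_tree_ : networkx.Graph (when selection ran)

    Examples
    --------
    >>> from spdprog.synth import simulate_progression
    >>> expr, truth = simulate_progression(seed=1)
    >>> est = SampleProgressionDiscovery(selection="auto", random_state=1)
    >>> est.fit(expr.T)                                   # doctest: +ELLIPSIS
    SampleProgressionDiscovery(...)
    >>> sorted(est.overall_tree_.nodes) == sorted(truth.sample_order)
    True
    """

    def __init__(
        self,
        kmeans_runs: int = 50,
        coherence_threshold: float = 0.9,
        merge_threshold: float = 0.9,
        min_module_size: int = 5,
        n_permutations: int = 1000,
        p_threshold: float = 0.002,
        top_n_variance_genes: Union[int, str] = "all",
        selection: Union[str, Sequence[str], None] = "auto",
        min_block: int = 2,
        random_state: int = 0,
    ):
        self.kmeans_runs = kmeans_runs
        self.coherence_threshold = coherence_threshold
        self.merge_threshold = merge_threshold
        self.min_module_size = min_module_size
        self.n_permutations = n_permutations
        self.p_threshold = p_threshold
        self.top_n_variance_genes = top_n_variance_genes
        self.selection = selection
        self.min_block = min_block
        self.random_state = random_state

    def _config(self) -> RunConfig:
        return RunConfig(
            kmeans_runs=self.kmeans_runs,
            coherence_threshold=self.coherence_threshold,
            merge_threshold=self.merge_threshold,
            min_module_size=self.min_module_size,
            n_permutations=self.n_permutations,
            p_threshold=self.p_threshold,
            top_n_variance_genes=self.top_n_variance_genes,
            seed=self.random_state if self.random_state is not None else 0,
        )

    def fit(self, X, y=None) -> "SampleProgressionDiscovery":
        """Fit on X of shape (n_samples, n_genes); y is ignored."""
        if isinstance(X, pd.DataFrame):
            expr = X.T.copy()
            expr.index = expr.index.astype(str)
            expr.columns = expr.columns.astype(str)
        else:
            X = np.asarray(X, dtype=float)
            expr = pd.DataFrame(
                X.T,
                index=[f"g{i}" for i in range(X.shape[1])],
                columns=[f"s{j}" for j in range(X.shape[0])],
            )
        select = None
        auto = False
        if isinstance(self.selection, str):
            if self.selection != "auto":
                raise ValueError("selection must be 'auto', None or a list of ids")
            auto = True
        elif self.selection is not None:
            select = list(self.selection)
        result = fit_progression(
            expr, self._config(), select=select, auto_select=auto,
            min_block=self.min_block,
        )
        self.result_ = result
        self.modules_ = result.modules
        self.module_trees_ = result.trees
        self.similarity_ = result.similarity.to_frame()
        self.concordance_ = result.concordance_table
        self.display_order_ = result.display_order
        if result.selection is not None:
            self.selected_module_ids_ = result.selection.selected_module_ids
            self.overall_tree_ = result.selection.overall_tree
        self.n_features_in_ = expr.shape[0]
        self.feature_names_in_ = np.asarray(list(expr.index), dtype=object)
        return self


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    version: str = __version__
    seed: int = 0
    selection_mode: Optional[str] = None

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def run_pipeline(
    cfg: RunConfig,
    input_path: Union[str, Path],
    out_dir: Union[str, Path],
    select: Optional[Sequence[str]] = None,
    auto_select: bool = False,
    min_block: int = 2,
    delimiter: str = "\t",
) -> RunManifest:
    """Run the pipeline against a matrix on disk, writing all artifacts.

    Without ``select``/``auto_select`` the run completes stages 1-3 and
    writes the reordered similarity matrix for manual inspection; re-running
    with ``select`` resumes at stage 4 (stages 1-3 are recomputed only if
    their artifacts are absent — they are deterministic given the config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        manifest = RunManifest(config=cfg.to_dict(), seed=cfg.seed)
        cfg.write(out / "config.yaml")
        manifest.artifacts["config"] = str(out / "config.yaml")
        expr = spd_io.read_expression_matrix(input_path, delimiter)
        result = fit_progression(
            expr, cfg, select=select, auto_select=auto_select, min_block=min_block
        )
        spd_io.write_module_tables(
            result.modules, out / "modules.tsv", out / "module_summary.tsv"
        )
        manifest.artifacts["modules"] = str(out / "modules.tsv")
        manifest.artifacts["module_summary"] = str(out / "module_summary.tsv")
        manifest.stages["cluster"] = "complete"
        tree_dir = out / "trees"
        tree_dir.mkdir(exist_ok=True)
        for t in result.trees:
            spd_io.write_tree(t, tree_dir / f"{t.graph['tree_id']}.tsv", "edgelist")
        manifest.artifacts["module_trees"] = str(tree_dir)
        manifest.stages["module_msts"] = "complete"
        result.concordance_table.to_csv(
            out / "concordance.tsv", sep="\t", index=False, float_format="%.6g"
        )
        spd_io.write_similarity_matrix(
            result.similarity.S, result.similarity.module_ids, out / "similarity.tsv"
        )
        order_idx = [result.similarity.module_ids.index(m) for m in result.display_order]
        spd_io.write_similarity_matrix(
            result.similarity.S[np.ix_(order_idx, order_idx)],
            result.display_order,
            out / "similarity_reordered.tsv",
        )
        manifest.artifacts["concordance"] = str(out / "concordance.tsv")
        manifest.artifacts["similarity"] = str(out / "similarity.tsv")
        manifest.artifacts["similarity_reordered"] = str(out / "similarity_reordered.tsv")
        manifest.stages["concordance"] = "complete"
        if result.selection is not None:
            sel = result.selection
            (out / "selection.json").write_text(
                json.dumps(
                    {
                        "selected_module_ids": sel.selected_module_ids,
                        "selected_gene_ids": sel.selected_gene_ids,
                        "display_order": sel.display_order,
                        "auto_selected": sel.auto_selected,
                    },
                    indent=2,
                )
            )
            spd_io.write_tree(sel.overall_tree, out / "overall_tree.tsv", "edgelist")
            manifest.artifacts["selection"] = str(out / "selection.json")
            manifest.artifacts["overall_tree"] = str(out / "overall_tree.tsv")
            manifest.stages["selection"] = "complete"
            manifest.selection_mode = "auto" if sel.auto_selected else "manual"
        else:
            manifest.stages["selection"] = "pending"
            logger.info(
                "stages 1-3 complete; inspect %s and re-run with --select",
                out / "similarity_reordered.tsv",
            )
        manifest.write(out / "manifest.json")
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
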