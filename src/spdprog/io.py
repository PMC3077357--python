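"""Reading and writing of on-disk artifacts.

Expression matrices are plain delimited text with genes in rows (first column
gene ids) and a header row of sample ids; in memory they are pandas DataFrames
indexed by gene id with sample-id columns, values assumed already
log-transformed/normalized upstream.  Trees are networkx graphs serialized as
edge-list TSV (primary), GraphML or DOT.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Union

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("spdprog")

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "validate_expression_matrix",
    "variance_filter",
    "write_tree",
    "read_tree",
    "write_module_tables",
    "read_module_table",
    "write_similarity_matrix",
    "read_similarity_matrix",
]


def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants, returning the frame unchanged.

    Requires unique gene and sample ids, at least 2 genes and 2 samples, and
    no missing values.
    """
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValueError(
            f"expression matrix needs at least 2 genes and 2 samples, "
            f"got {expr.shape[0]} x {expr.shape[1]}"
        )
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return expr


def read_expression_matrix(
    path: Union[str, Path], delimiter: str = "\t"
) -> pd.DataFrame:
    """Read a genes x samples expression matrix from delimited text.

    First row holds sample ids, first column gene ids.  Gene rows containing
    any missing value are dropped (the count is logged).  Malformed numeric
    cells raise a parse error naming the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    raw = pd.read_csv(path, sep=delimiter, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    # locate non-numeric cells explicitly for a useful error message
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        gi, sj = np.argwhere(bad.values)[0]
        raise ValueError(
            f"malformed numeric cell at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[sj]!r}: {raw.iloc[gi, sj]!r}"
        )
    n_missing = int(numeric.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d gene rows with missing values", n_missing)
        numeric = numeric.dropna(axis=0)
    return validate_expression_matrix(numeric.astype(float))


def write_expression_matrix(
    expr: pd.DataFrame, path: Union[str, Path], delimiter: str = "\t"
) -> None:
    """Write the matrix with 12 significant digits so read/write round-trips."""
    expr.to_csv(path, sep=delimiter, float_format="%.12g")


def variance_filter(expr: pd.DataFrame, top_n: Union[int, str]) -> pd.DataFrame:
    """Keep the top_n genes by per-gene sample variance.

    Original gene order is preserved among the survivors; ties broken by input
    order.  ``top_n="all"`` or top_n >= gene count returns all genes (the
    latter with a warning).
    """
    if top_n == "all":
        return expr
    top_n = int(top_n)
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if top_n >= expr.shape[0]:
        if top_n > expr.shape[0]:
            logger.warning(
                "top_n=%d exceeds gene count %d; keeping all genes",
                top_n,
                expr.shape[0],
            )
        return expr
    variances = expr.var(axis=1, ddof=1).to_numpy()
    # stable sort on negated variance keeps input order among ties
    keep = np.sort(np.argsort(-variances, kind="stable")[:top_n])
    return expr.iloc[keep]


def _check_tree(tree: nx.Graph) -> None:
    n = tree.number_of_nodes()
    if n >= 2 and (tree.number_of_edges() != n - 1 or not nx.is_connected(tree)):
        raise ValueError("not a tree: wrong edge count or disconnected")


def write_tree(
    tree: nx.Graph, path: Union[str, Path], format: str = "edgelist"
) -> None:
    """Serialize a sample tree.

    ``edgelist`` writes three tab-separated columns (sample_id_a, sample_id_b,
    weight), one row per edge, weights with 10 significant digits.
    """
    _check_tree(tree)
    path = Path(path)
    if format == "edgelist":
        with open(path, "w") as fh:
            for a, b, data in tree.edges(data=True):
                w = data.get("weight", 1.0)
                fh.write(f"{a}\t{b}\t{w:.10g}\n")
    elif format == "graphml":
        nx.write_graphml(tree, path)
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("graph tree {\n")
            for node in tree.nodes:
                fh.write(f'  "{node}";\n')
            for a, b, data in tree.edges(data=True):
                w = data.get("weight", 1.0)
                fh.write(f'  "{a}" -- "{b}" [weight={w:.10g}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown tree format {format!r}; use edgelist/graphml/dot")


def read_tree(path: Union[str, Path], format: str = "edgelist") -> nx.Graph:
    """Read a tree written by :func:`write_tree` (edgelist or graphml)."""
    path = Path(path)
    if format == "edgelist":
        tree = nx.Graph()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                a, b, w = line.split("\t")
                tree.add_edge(a, b, weight=float(w))
    elif format == "graphml":
        tree = nx.read_graphml(path)
    else:
        raise ValueError(f"unknown tree format {format!r}")
    _check_tree(tree)
    return tree


def write_module_tables(
    module_set, path_assignments: Union[str, Path], path_summary: Union[str, Path]
) -> None:
    """Write gene->module assignments and a per-module summary as TSV."""
    rows = []
    for mod in module_set.modules:
        for g in mod.gene_ids:
            rows.append((g, mod.module_id))
    for g in module_set.unassigned_gene_ids:
        rows.append((g, "unassigned"))
    pd.DataFrame(rows, columns=["gene_id", "module_id"]).to_csv(
        path_assignments, sep="\t", index=False
    )
    summary = pd.DataFrame(
        [
            (m.module_id, len(m.gene_ids), m.coherence)
            for m in module_set.modules
        ],
        columns=["module_id", "size", "coherence"],
    )
    summary.to_csv(path_summary, sep="\t", index=False, float_format="%.6g")


def read_module_table(path: Union[str, Path]) -> dict:
    """Read a gene->module TSV back into ``{module_id: [gene ids]}``.

    Genes tagged ``unassigned`` are returned under that key.  Also the entry
    point for user-supplied curated gene sets used in place of clustering.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict = {}
    for g, m in zip(df["gene_id"], df["module_id"]):
        out.setdefault(m, []).append(g)
    return out


def write_similarity_matrix(
    S: np.ndarray, module_ids: Iterable[str], path: Union[str, Path]
) -> None:
    pd.DataFrame(S, index=list(module_ids), columns=list(module_ids)).to_csv(
        path, sep="\t"
    )


def read_similarity_matrix(path: Union[str, Path]):
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
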