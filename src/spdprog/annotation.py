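"""Gene-set over-representation for modules (hypergeometric test).

Minimal annotation machinery: gene sets come from GMT-style text (set name,
description, then tab-separated gene ids); each module is scored against each
set by the upper-tail hypergeometric probability of its overlap given the
analysis universe.  No gene-set content ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Union

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["GeneSet", "read_gmt", "hypergeometric_enrichment", "enrich_modules"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: frozenset

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path: Union[str, Path]) -> List[GeneSet]:
    """Read GMT text: one set per line, name <tab> description <tab> genes..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(GeneSet(parts[0], frozenset(g for g in parts[2:] if g)))
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def hypergeometric_enrichment(
    module_genes: Set[str], gene_set: GeneSet, universe: Set[str]
) -> float:
    """Upper-tail hypergeometric p-value of the module/set overlap.

    P[X >= k] for overlap k, module size n, set size K (after intersecting
    the set with the universe) and universe size M; the observed overlap is
    included in the tail.  Module genes outside the universe are an error —
    silently inflating the universe would bias every p-value.
    """
    module_genes = set(module_genes)
    universe = set(universe)
    outside = module_genes - universe
    if outside:
        raise ValueError(
            f"module genes outside the universe: {sorted(outside)[:5]}"
        )
    in_set = gene_set.gene_ids & universe
    k = len(module_genes & in_set)
    return float(hypergeom.sf(k - 1, len(universe), len(in_set), len(module_genes)))


def enrich_modules(
    module_gene_ids: Dict[str, Sequence[str]],
    gene_sets: Iterable[GeneSet],
    universe: Set[str],
    adjust: str = "none",
) -> pd.DataFrame:
    """Score every module against every gene set.

    Returns columns (module_id, set_name, overlap, p, adjusted_p);
    ``adjust="bh"`` applies Benjamini-Hochberg across sets within each module
    (off by default — the canonical analysis reported uncorrected p-values).
    """
    gene_sets = list(gene_sets)
    rows = []
    for mid, genes in module_gene_ids.items():
        genes = set(genes)
        ps = []
        for gs in gene_sets:
            p = hypergeometric_enrichment(genes, gs, universe)
            overlap = len(genes & gs.gene_ids & set(universe))
            ps.append((gs.name, overlap, p))
        if adjust == "bh":
            from statsmodels.stats.multitest import multipletests

            adj = multipletests([p for _, _, p in ps], method="fdr_bh")[1]
        elif adjust == "none":
            adj = [float("nan")] * len(ps)
        else:
            raise ValueError("adjust must be 'none' or 'bh'")
        for (name, overlap, p), ap in zip(ps, adj):
            rows.append((mid, name, overlap, p, ap))
    return pd.DataFrame(
        rows, columns=["module_id", "set_name", "overlap", "p", "adjusted_p"]
    )
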