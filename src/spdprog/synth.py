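"""Synthetic expression data with planted progression structure.

The generator emits a genes x samples matrix in which a known arrangement of
the samples (a path, or a star of arms radiating from a root) drives the mean
expression of several gene modules, plus unstructured noise genes.  Member
genes are the module's latent curve scaled by a gene-specific positive
loading (Uniform(0.5, 1.5)) plus i.i.d. Gaussian noise, so modules are
co-expressed but not identical.  Sample columns are emitted in a seeded
random order by default — the pipeline must never see ordering information
in column position — and the planted truth is returned alongside.

Path curves: monotone ramp, unimodal bump (module-specific center), or
sinusoid with module-specific phase covering three quarters of a period, so
the endpoint samples stay well separated (a full period would make first and
last samples coincide in module space).

Star (branched) curves emulate lineage data: every module changes along
every arm, with an arm-specific signed rate.  Sign patterns cycle through
the six non-constant +/- patterns over three arms, so each arm pair is
sign-contrasted in two thirds of the modules; this guarantees same-depth
samples on different arms are farther apart than consecutive samples within
an arm, making the planted star the true minimum spanning tree.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .tree import path_tree, validate_sample_tree

__all__ = ["SyntheticTruth", "simulate_progression", "simulate_null"]


@dataclass
class SyntheticTruth:
    topology: str
    sample_order: List[str]
    arms: Optional[Dict[str, List[str]]]
    root: Optional[str]
    progression_module_gene_ids: List[List[str]]
    noise_gene_ids: List[str]
    noise_sd: float
    seed: int

    def planted_tree(self) -> nx.Graph:
        """The planted progression as a unit-weight tree."""
        if self.topology == "path":
            tree = path_tree(self.sample_order)
        else:
            tree = nx.Graph()
            tree.add_node(self.root)
            for arm_samples in self.arms.values():
                prev = self.root
                for s in arm_samples:
                    tree.add_edge(prev, s, weight=1.0)
                    prev = s
        tree.graph["tree_id"] = "planted"
        return validate_sample_tree(tree)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _path_gene_rows(
    n_samples: int,
    n_modules: int,
    genes_per_module: int,
    pattern: str,
    rng: np.random.Generator,
    phases: Optional[Sequence[float]],
) -> np.ndarray:
    """Per-gene curves along a path arrangement.

    Member genes get a positive loading and a small per-gene shift of the
    module curve (phase for sinusoids, center for bumps, steepness for
    ramps): co-expressed genes track the same process but peak at slightly
    different points.  The shift matters beyond realism — were every gene an
    exact multiple of one curve, the module submatrix would be rank one and
    its own MST would fold the progression back on itself wherever the curve
    takes equal values at different times.
    """
    t = np.linspace(0.0, 1.0, n_samples)
    rows = np.empty((n_modules * genes_per_module, n_samples))
    if pattern not in {"monotone", "unimodal", "sinusoid"}:
        raise ValueError(f"unknown pattern {pattern!r}")
    if pattern == "sinusoid" and phases is None:
        phases = 2.0 * np.pi * np.arange(n_modules) / max(n_modules, 1)
    centers = np.linspace(0.2, 0.8, n_modules)
    for m in range(n_modules):
        for g in range(genes_per_module):
            loading = rng.uniform(0.5, 1.5)
            row = rows[m * genes_per_module + g]
            if pattern == "monotone":
                direction = 1.0 if m % 2 == 0 else -1.0
                steep = 1.0 + 0.5 * (m // 2 % 3) + rng.normal(0.0, 0.1)
                row[:] = direction * loading * t ** max(0.3, steep)
            elif pattern == "unimodal":
                c = centers[m] + rng.normal(0.0, 0.03)
                row[:] = loading * np.exp(-((t - c) ** 2) / (2 * 0.15**2))
            else:
                # 3/4 of a period keeps the two endpoint samples far apart
                phi = phases[m] + rng.normal(0.0, 0.3)
                row[:] = loading * np.sin(2.0 * np.pi * 0.75 * t + phi)
    return rows


def _star_layout(topology: dict) -> tuple:
    n_arms = int(topology.get("arms", 3))
    arm_length = int(topology.get("arm_length", 6))
    if n_arms < 2 or arm_length < 1:
        raise ValueError("star topology needs >= 2 arms of length >= 1")
    root = "s_root"
    arms = {
        f"arm{a + 1}": [f"a{a + 1}_{d + 1:02d}" for d in range(arm_length)]
        for a in range(n_arms)
    }
    sample_ids = [root] + [s for arm in arms.values() for s in arm]
    return root, arms, sample_ids, n_arms, arm_length


def _star_gene_rows(
    n_modules: int,
    genes_per_module: int,
    n_arms: int,
    arm_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-gene lineage trajectories: signed arm rates times a linear depth ramp.

    Each module carries a sign pattern over arms (cycling the non-constant
    +/- patterns, so every arm pair is sign-contrasted in two thirds of the
    modules) and per-arm rate magnitudes; each member gene perturbs those
    magnitudes with its own loading and per-arm jitter.  The jitter matters:
    were every gene an exact multiple of one module curve, the module
    submatrix would be rank one, its MST a 1-D chain interleaving same-sign
    arms — lineage modules in real data respond with gene-specific per-branch
    strengths.  The concave depth ramp (early commitment) keeps near-root margins wide, and the sign
    contrasts keep same-depth samples on different arms farther apart than
    consecutive samples within an arm, so the planted star is the true MST.
    """
    sign_patterns = [
        p for p in itertools.product((1.0, -1.0), repeat=n_arms)
        if len(set(p)) > 1
    ]
    # concave in depth (early commitment): arms diverge quickly after the
    # root and keep drifting, so the near-root cross-arm margins — the
    # tightest comparisons in the star geometry — stay robust to noise
    depth = (np.arange(1, arm_length + 1) / arm_length) ** 0.85
    amplitude = 2.0  # keeps worst-case gene signal well above noise_sd ~ 0.1
    rows = np.empty((n_modules * genes_per_module, 1 + n_arms * arm_length))
    for m in range(n_modules):
        signs = sign_patterns[m % len(sign_patterns)]
        mags = rng.uniform(0.8, 1.3, size=n_arms)
        for g in range(genes_per_module):
            loading = rng.uniform(0.5, 1.5)
            jitter = rng.normal(0.0, 0.3, size=n_arms)
            row = rows[m * genes_per_module + g]
            row[0] = 0.0
            for a in range(n_arms):
                rate = signs[a] * max(0.25, mags[a] * loading + jitter[a])
                lo = 1 + a * arm_length
                row[lo : lo + arm_length] = amplitude * rate * depth
    return rows


def simulate_progression(
    n_samples: int = 17,
    topology: Union[str, dict] = "path",
    n_prog_modules: int = 9,
    genes_per_module: int = 12,
    n_noise_genes: Optional[int] = None,
    pattern: str = "sinusoid",
    noise_sd: float = 0.1,
    seed: int = 0,
    phases: Optional[Sequence[float]] = None,
    shuffle_columns: bool = True,
):
    """Generate a planted-progression expression matrix and its truth.

    Returns ``(expr, truth)`` with ``expr`` a genes x samples DataFrame whose
    columns are (by default) randomly ordered, and ``truth`` the
    :class:`SyntheticTruth`.  ``n_noise_genes`` defaults to 1.5x the number
    of progression genes (60% of genes are noise), mirroring expression data
    where most genes do not track the process.
    """
    rng = np.random.default_rng(seed)
    if n_prog_modules < 1 or genes_per_module < 1:
        raise ValueError("module counts must be positive")
    if isinstance(topology, str) and topology == "path":
        if n_samples < 3:
            raise ValueError("need at least 3 samples")
        sample_ids = [f"s{k + 1:02d}" for k in range(n_samples)]
        signal_rows = _path_gene_rows(
            n_samples, n_prog_modules, genes_per_module, pattern, rng, phases
        )
        root, arms = None, None
        topo_name = "path"
    else:
        if isinstance(topology, str):
            raise ValueError(f"unknown topology {topology!r}")
        root, arms, sample_ids, n_arms, arm_length = _star_layout(topology)
        signal_rows = _star_gene_rows(
            n_prog_modules, genes_per_module, n_arms, arm_length, rng
        )
        topo_name = "star"
    n = len(sample_ids)
    if n_noise_genes is None:
        n_noise_genes = int(round(1.5 * n_prog_modules * genes_per_module))

    rows, gene_ids, module_gene_ids = [], [], []
    for m in range(n_prog_modules):
        ids = [f"m{m + 1}_g{k + 1:02d}" for k in range(genes_per_module)]
        module_gene_ids.append(ids)
        gene_ids.extend(ids)
        noise = rng.normal(0.0, noise_sd, size=(genes_per_module, n))
        signal = signal_rows[m * genes_per_module : (m + 1) * genes_per_module]
        rows.append(signal + noise)
    noise_ids = [f"noise_g{k + 1:03d}" for k in range(n_noise_genes)]
    gene_ids.extend(noise_ids)
    if n_noise_genes:
        rows.append(rng.normal(0.0, 1.0, size=(n_noise_genes, n)))
    values = np.vstack(rows)

    column_order = list(sample_ids)
    if shuffle_columns:
        column_order = [sample_ids[k] for k in rng.permutation(n)]
    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)[column_order]
    truth = SyntheticTruth(
        topology=topo_name,
        sample_order=list(sample_ids),
        arms=arms,
        root=root,
        progression_module_gene_ids=module_gene_ids,
        noise_gene_ids=noise_ids,
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    return expr, truth


def simulate_null(n_samples: int, n_genes: int, seed: int = 0) -> pd.DataFrame:
    """Pure i.i.d. standard-Gaussian matrix for calibration tests."""
    if n_samples < 2 or n_genes < 1:
        raise ValueError("need at least 2 samples and 1 gene")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{k + 1}" for k in range(n_genes)],
        columns=[f"s{k + 1:02d}" for k in range(n_samples)],
    )
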