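"""Run configuration for the progression-discovery pipeline.

All tunable parameters of the pipeline live in :class:`RunConfig` so a run can
be reproduced from a single serialized file.  Defaults follow the published
procedure where values are printed (minimum module size 5, 1000 permutations,
p-value threshold 0.002) and sensible conventions elsewhere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(seed: int, label: str) -> int:
    """Derive a per-stage child seed from a root seed and a stage label.

    Uses numpy's SeedSequence-style splitting via zlib.crc32 of the label so
    every source of randomness in a run flows from one root seed, and the
    result stays below 2**31.
    """
    import zlib

    return (int(seed) * 1_000_003 + zlib.crc32(label.encode("utf-8"))) % (2**31 - 1)


@dataclass
class RunConfig:
    """Parameters controlling the full pipeline.

    Attributes
    ----------
    kmeans_runs : int
        Number of random-initialization k=2 k-means runs pooled into each
        consensus split.
    coherence_threshold : float in (0, 1]
        A cluster whose mean gene-to-center Pearson correlation reaches this
        value is accepted as a coherent module and not split further.
    merge_threshold : float in (0, 1]
        Module pairs whose center profiles correlate above this value are
        merged after the divisive phase.
    min_module_size : int
        Modules with fewer genes are moved to the unassigned pool.
    n_permutations : int
        Column permutations per module-vs-tree concordance test.
    p_threshold : float in (0, 1)
        Permutation p-value below which a module and a tree are called
        concordant.
    top_n_variance_genes : int or "all"
        Keep only the top-n genes by sample variance before clustering.
    seed : int
        Root seed; every stage derives its own stream from it.
    """

    kmeans_runs: int = 50
    coherence_threshold: float = 0.9
    merge_threshold: float = 0.9
    min_module_size: int = 5
    n_permutations: int = 1000
    p_threshold: float = 0.002
    top_n_variance_genes: Union[int, str] = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kmeans_runs < 1:
            raise ValueError("kmeans_runs must be a positive integer")
        if not 0.0 < self.coherence_threshold <= 1.0:
            raise ValueError("coherence_threshold must be in (0, 1]")
        if not 0.0 < self.merge_threshold <= 1.0:
            raise ValueError("merge_threshold must be in (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be a positive integer")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be a positive integer")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.top_n_variance_genes != "all":
            if int(self.top_n_variance_genes) < 1:
                raise ValueError("top_n_variance_genes must be positive or 'all'")
            self.top_n_variance_genes = int(self.top_n_variance_genes)
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**d)

    def write(self, path: Union[str, Path]) -> None:
        """Serialize to YAML or JSON depending on the file suffix."""
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yml", ".yaml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
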