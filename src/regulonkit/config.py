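"""Pipeline configuration: every threshold the workflow uses, in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the regulon-prediction workflow.

    Attributes
    ----------
    upstream_length : promoter length U extracted upstream of each operon's
        translation start (bp).
    motif_width : fixed motif width w (bp).
    top_k : motifs kept per co-expression module.
    t1, t2 : motif-similarity thresholds for highly reliable (T1) and
        relatively reliable (T2) motif clusters; 0 < T2 <= T1 <= 1.
    cut_fraction : dendrogram cut height as a fraction of the maximum
        pairwise expression distance (h = cut_fraction * max distance).
    max_cem_size : co-expression modules larger than this (in operons) are
        discarded as likely spurious agglomerates.
    deg_alpha : significance threshold on the raw signed-rank p-value.
    motif_alpha : threshold on the seed-adjusted motif p-value.
    tfbs_evalue : E-value gate for matches against the TFBS library.
    tf_map_evalue : E-value gate for mapping a template TF protein onto the
        target proteome.
    literature_evalue : stricter E-value gate for literature gene mapping.
    linkage : agglomeration rule for expression clustering.
    paired : paired signed-rank test (True) or unpaired rank-sum fallback.
    seed_cap : maximum number of over-represented seed words refined per
        module (smallest Poisson tails kept).
    dedup_similarity : motifs more similar than this within one module are
        collapsed to the higher-scoring one.
    em_max_iter, em_tol : motif refinement iteration cap and log-likelihood
        convergence tolerance.
    shuffle_n : column-shuffled nulls per (query, library) pair.
    rng_seed : governs every stochastic stage.
    """

    upstream_length: int = 300
    motif_width: int = 12
    top_k: int = 5
    t1: float = 0.8
    t2: float = 0.6
    cut_fraction: float = 0.05
    max_cem_size: int = 200
    deg_alpha: float = 0.05
    motif_alpha: float = 0.001
    tfbs_evalue: float = 0.05
    tf_map_evalue: float = 1e-5
    literature_evalue: float = 1e-10
    linkage: str = "complete"
    paired: bool = True
    seed_cap: int = 40
    dedup_similarity: float = 0.95
    em_max_iter: int = 20
    em_tol: float = 1e-4
    min_overlap: int = 6
    shuffle_n: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0 < self.cut_fraction < 1:
            raise ConfigError(f"cut_fraction must be in (0,1), got {self.cut_fraction}")
        if not 0 < self.t2 <= self.t1 <= 1:
            raise ConfigError(f"require 0 < T2 <= T1 <= 1, got T1={self.t1}, T2={self.t2}")
        for name in ("deg_alpha", "motif_alpha", "tfbs_evalue"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0,1], got {v}")
        if self.upstream_length < 1 or self.motif_width < 1 or self.top_k < 1:
            raise ConfigError("lengths and counts must be positive")
        if self.motif_width < self.min_overlap:
            raise ConfigError(
                f"motif_width {self.motif_width} smaller than the minimum "
                f"similarity overlap {self.min_overlap}"
            )
        if self.linkage not in ("complete", "average", "single"):
            raise ConfigError(f"unsupported linkage {self.linkage!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def snapshot(self) -> dict:
        return asdict(self)
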