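"""Pipeline configuration and library metadata.

All thresholds used across the tile-curation, ChIP-enrichment and small-RNA
stages live in :class:`PipelineConfig`. The defaults reproduce the analysis
settings of the heterochromatin/piRNA study this package models: 1-kb tiles,
a 25% mappability floor, a threefold input-deviation cutoff, pseudocount 1,
per-million depth scaling, a >23 nt read-length filter for transposon
consensus mapping, 23–29 nt piRNA length bounds, normalization to one million
miRNA reads, a twofold dependence cutoff, and 70% minimum alignment-column
coverage. Every value is overridable, either in code or via a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import Tuple

import yaml

__all__ = ["PipelineConfig", "LibraryMeta"]


@dataclass
class PipelineConfig:
    tile_size: int = 1000
    mappability_min: float = 0.25
    input_deviation_fold: float = 3.0
    ko_residual_log2_max: float = 1.0
    pseudocount: float = 1.0
    depth_scale: float = 1_000_000.0
    te_min_read_length: int = 24  # "longer than 23 nucleotides"
    pirna_length_range: Tuple[int, int] = (23, 29)
    mirna_norm_target: float = 1_000_000.0
    dependence_fold: float = 2.0
    msa_min_column_coverage: float = 0.70
    clash_tolerance: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_size < 1:
            raise ValueError(f"tile_size must be >= 1, got {self.tile_size}")
        if not 0.0 <= self.mappability_min <= 1.0:
            raise ValueError(
                f"mappability_min must be in [0, 1], got {self.mappability_min}"
            )
        for name in ("input_deviation_fold", "dependence_fold"):
            value = getattr(self, name)
            if value <= 1.0:
                raise ValueError(f"{name} must be > 1, got {value}")
        if self.pseudocount < 0:
            raise ValueError(f"pseudocount must be >= 0, got {self.pseudocount}")
        lo, hi = self.pirna_length_range
        if lo > hi:
            raise ValueError(f"pirna_length_range min > max: {self.pirna_length_range}")
        if not 0.0 < self.msa_min_column_coverage <= 1.0:
            raise ValueError(
                "msa_min_column_coverage must be in (0, 1], got "
                f"{self.msa_min_column_coverage}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML key/value file; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pirna_length_range" in data:
            data["pirna_length_range"] = tuple(data["pirna_length_range"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["pirna_length_range"] = list(data["pirna_length_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class LibraryMeta:
    """Identity of one sequencing library used for normalization bookkeeping."""

    name: str
    role: str  # chip | input | small_rna
    genotype: str = "control"
    tissue: str = "ovary"
    total_mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.role not in {"chip", "input", "small_rna"}:
            raise ValueError(f"unknown library role {self.role!r}")
        if self.tissue not in {"ovary", "testis"}:
            raise ValueError(f"unknown tissue {self.tissue!r}")
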