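"""Fixed-width genomic tiles and the three curation filters.

The genome is partitioned into non-overlapping tiles (1 kb by default); a
short terminal tile per chromosome is retained with its true length. Tiles
are then curated by three independent filters before any enrichment
analysis:

* ``mappability`` — mappable fraction below a floor (default 0.25),
* ``input_deviation`` — read count in a representative input library more
  than threefold (default) away from the tile median, in either direction,
* ``ko_residual`` — strong residual ChIP signal in a knockout library
  (log2 enrichment above a configurable ceiling), which flags tiles whose
  apparent signal does not depend on the immunoprecipitated protein.

A tile may carry several exclusion labels; it is curated iff it carries none.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import IntervalIndex, covered_in_range, merge_intervals

__all__ = [
    "GenomeTile",
    "TileSet",
    "make_tiles",
    "compute_mappability",
    "annotate_clusters",
    "curate_tiles",
]

FILTER_NAMES = ("mappability", "input_deviation", "ko_residual")


@dataclass
class GenomeTile:
    chrom: str
    start: int
    end: int
    mappable_fraction: float = 1.0
    excluded_by: Set[str] = field(default_factory=set)
    cluster_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty tile {self.chrom}:{self.start}-{self.end}")

    @property
    def tile_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def curated(self) -> bool:
        return not self.excluded_by


@dataclass
class TileSet:
    tiles: List[GenomeTile]
    genome_id: str = "genome"
    tile_size: int = 1000

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    @property
    def tile_ids(self) -> List[str]:
        return [t.tile_id for t in self.tiles]

    def chromosomes(self) -> List[str]:
        seen = dict.fromkeys(t.chrom for t in self.tiles)
        return list(seen)

    def curated_mask(self) -> np.ndarray:
        return np.array([t.curated for t in self.tiles], dtype=bool)

    def index_of(self, chrom: str, pos: int) -> Optional[int]:
        """Tile index containing genomic position pos, or None if off-tile."""
        base = self._chrom_offsets().get(chrom)
        if base is None:
            return None
        first, n_tiles, length = base
        if not 0 <= pos < length:
            return None
        return first + pos // self.tile_size

    def _chrom_offsets(self) -> Dict[str, tuple]:
        if not hasattr(self, "_offsets"):
            offsets: Dict[str, tuple] = {}
            i = 0
            while i < len(self.tiles):
                chrom = self.tiles[i].chrom
                j = i
                while j < len(self.tiles) and self.tiles[j].chrom == chrom:
                    j += 1
                offsets[chrom] = (i, j - i, self.tiles[j - 1].end)
                i = j
            self._offsets = offsets
        return self._offsets

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [t.chrom for t in self.tiles],
                "start": [t.start for t in self.tiles],
                "end": [t.end for t in self.tiles],
                "tile_id": self.tile_ids,
                "mappable_fraction": [t.mappable_fraction for t in self.tiles],
                "curated": [t.curated for t in self.tiles],
                "excluded_by": [",".join(sorted(t.excluded_by)) for t in self.tiles],
                "cluster_label": [t.cluster_label or "." for t in self.tiles],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, genome_id: str = "genome",
                 tile_size: int = 1000) -> "TileSet":
        df = pd.read_csv(path, sep="\t")
        tiles = [
            GenomeTile(
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                mappable_fraction=float(r.mappable_fraction),
                excluded_by=set(str(r.excluded_by).split(","))
                if isinstance(r.excluded_by, str) and r.excluded_by
                else set(),
                cluster_label=None if r.cluster_label == "." else str(r.cluster_label),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(tiles=tiles, genome_id=genome_id, tile_size=tile_size)


def make_tiles(chrom_sizes: Mapping[str, int], tile_size: int = 1000,
               genome_id: str = "genome") -> TileSet:
    """Partition each chromosome into non-overlapping tiles of tile_size.

    The terminal tile is shortened to the chromosome end; a zero-length
    chromosome yields no tiles.
    """
    if tile_size < 1:
        raise ValueError(f"tile_size must be >= 1, got {tile_size}")
    tiles: List[GenomeTile] = []
    for chrom, length in chrom_sizes.items():
        if length < 0:
            raise ValueError(f"negative length for chromosome {chrom}: {length}")
        for start in range(0, length, tile_size):
            tiles.append(GenomeTile(chrom, start, min(start + tile_size, length)))
    return TileSet(tiles=tiles, genome_id=genome_id, tile_size=tile_size)


def compute_mappability(tiles: TileSet, mappable_blocks) -> TileSet:
    """Set each tile's mappable_fraction from blocks of continuous mappability.

    Blocks may overlap (merged on ingest); blocks on chromosomes absent from
    the tile set are ignored with a warning.
    """
    import warnings

    merged = mappable_blocks if isinstance(mappable_blocks, dict) else merge_intervals(
        mappable_blocks
    )
    known = set(tiles.chromosomes())
    unknown = set(merged) - known
    if unknown:
        warnings.warn(f"mappability blocks on unknown chromosomes ignored: {sorted(unknown)}")
    for tile in tiles:
        arr = merged.get(tile.chrom)
        covered = covered_in_range(arr, tile.start, tile.end) if arr is not None else 0
        tile.mappable_fraction = covered / tile.length
    return tiles


def annotate_clusters(tiles: TileSet, clusters: pd.DataFrame) -> TileSet:
    """Label tiles overlapping piRNA-cluster intervals (BED with name column)."""
    by_name = {
        str(name): IntervalIndex(merge_intervals(sub))
        for name, sub in clusters.groupby("name")
    }
    for tile in tiles:
        for name, index in by_name.items():
            if index.overlaps(tile.chrom, tile.start, tile.end):
                tile.cluster_label = name
                break
    return tiles


def curate_tiles(
    tiles: TileSet,
    representative_input_counts: Mapping[str, float] | Sequence[float],
    ko_chip_log2: Optional[Mapping[str, float]] = None,
    config: Optional[PipelineConfig] = None,
) -> TileSet:
    """Apply the three curation filters; excluded_by records every trigger.

    Filters are independent: the input-deviation filter is evaluated on all
    tiles regardless of mappability, and a tile may carry several labels.
    The deviation filter is two-sided and strict: a tile is excluded when its
    input count is more than ``input_deviation_fold`` times the median, or
    less than the median divided by that fold.
    """
    config = config or PipelineConfig()
    counts = _as_tile_array(representative_input_counts, tiles, "input counts")
    if counts.size == 0:
        raise ValueError("empty input count table")
    median = float(np.median(counts))
    for i, tile in enumerate(tiles):
        tile.excluded_by.discard("mappability")
        tile.excluded_by.discard("input_deviation")
        tile.excluded_by.discard("ko_residual")
        if tile.mappable_fraction < config.mappability_min:
            tile.excluded_by.add("mappability")
        count = counts[i]
        if count > config.input_deviation_fold * median or (
            median > 0 and count < median / config.input_deviation_fold
        ):
            tile.excluded_by.add("input_deviation")
        if ko_chip_log2 is not None:
            residual = _lookup(ko_chip_log2, tile.tile_id, i)
            if residual is not None and residual > config.ko_residual_log2_max:
                tile.excluded_by.add("ko_residual")
    return tiles


def _as_tile_array(values, tiles: TileSet, what: str) -> np.ndarray:
    if isinstance(values, Mapping):
        missing = [t for t in tiles.tile_ids if t not in values]
        if missing:
            raise ValueError(f"{what} missing for tiles, e.g. {missing[0]}")
        return np.asarray([values[t] for t in tiles.tile_ids], dtype=float)
    arr = np.asarray(values, dtype=float)
    if arr.shape[0] != len(tiles):
        raise ValueError(f"{what}: expected {len(tiles)} values, got {arr.shape[0]}")
    return arr


def _lookup(mapping, tile_id: str, index: int):
    if isinstance(mapping, Mapping):
        return mapping.get(tile_id)
    return mapping[index]
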