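"""ChIP-seq enrichment over genomic tiles and transposon consensus sequences.

The enrichment model: per-unit read counts are scaled to a common depth
(reads per million by default), a pseudocount of 1 is added to both ChIP and
input, and the ratio is taken. Because ChIP efficiency differs between
samples, every sample is then rescaled by a correction factor chosen so that
the median enrichment over a background unit set (all curated tiles by
default) equals exactly 1.

Reads mapping to several transposon consensus positions are resolved before
counting: the unique best-stratum (minimal-mismatch) hit wins, and exact
ties are broken uniformly at random with a seeded generator, so the whole
stage is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import LibraryMeta, PipelineConfig
from .tiles import TileSet

__all__ = [
    "AlignmentRecord",
    "EnrichmentTable",
    "read_alignments",
    "group_hits_by_read",
    "count_unique_reads_per_tile",
    "tile_enrichment",
    "background_correction",
    "assign_multimappers",
    "te_consensus_enrichment",
    "average_replicates",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapping of one read; the common currency of all counting stages."""

    read_id: str
    target: str  # chromosome or TE consensus name
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"
    mismatches: int = 0
    n_best_hits: int = 1
    read_length: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty alignment {self.read_id}@{self.target}")
        if self.n_best_hits < 1:
            raise ValueError("n_best_hits must be >= 1")

    @property
    def genome_unique(self) -> bool:
        return self.n_best_hits == 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' end: leftmost base on +, rightmost base on -."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class EnrichmentTable:
    """Per-unit corrected enrichments plus the applied correction factor."""

    unit: str  # "tile" | "te_element"
    table: pd.DataFrame  # indexed by unit id
    correction_factor: float
    background_units: List[str]
    chip_meta: Optional[LibraryMeta] = None
    input_meta: Optional[LibraryMeta] = None

    @property
    def values(self) -> pd.Series:
        return self.table["corrected_enrichment"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "unit", out.index)
        out.to_csv(path, sep="\t", index=False)


def read_alignments(path: str | Path) -> List[AlignmentRecord]:
    """Read SAM/BAM into alignment records.

    Hit multiplicity is taken from the NH tag when present; otherwise it is
    computed by grouping records by read name (the aligner's best-stratum
    report emits one record per hit). Mismatch counts come from the NM tag.
    """
    import pysam

    records: List[AlignmentRecord] = []
    per_read: Dict[str, int] = {}
    have_nh = True
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            nh = aln.get_tag("NH") if aln.has_tag("NH") else None
            if nh is None:
                have_nh = False
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            rec = AlignmentRecord(
                read_id=aln.query_name,
                target=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                mismatches=int(nm),
                n_best_hits=int(nh) if nh is not None else 1,
                read_length=aln.query_length or (aln.reference_end - aln.reference_start),
            )
            records.append(rec)
            per_read[rec.read_id] = per_read.get(rec.read_id, 0) + 1
    if not have_nh:
        records = [
            AlignmentRecord(
                r.read_id, r.target, r.start, r.end, r.strand, r.mismatches,
                per_read[r.read_id], r.read_length,
            )
            for r in records
        ]
    return records


def group_hits_by_read(
    alignments: Iterable[AlignmentRecord],
) -> Dict[str, List[AlignmentRecord]]:
    hits: Dict[str, List[AlignmentRecord]] = {}
    for rec in alignments:
        hits.setdefault(rec.read_id, []).append(rec)
    return hits


def count_unique_reads_per_tile(
    alignments: Iterable[AlignmentRecord],
    tiles: TileSet,
    assignment: str = "midpoint",
) -> Tuple[np.ndarray, int]:
    """Count genome-unique reads per tile.

    Each unique read is assigned to exactly one tile by its midpoint
    (alternative: its leftmost-coordinate 5' end); multimappers contribute to
    no tile. Returns (per-tile counts aligned with the tile order, number of
    unique reads seen), the latter including reads falling on no tile so the
    caller can use it as library depth.
    """
    if assignment not in {"midpoint", "five_prime"}:
        raise ValueError(f"unknown assignment rule {assignment!r}")
    counts = np.zeros(len(tiles), dtype=np.int64)
    known_chroms = set(tiles.chromosomes())
    n_unique = 0
    for rec in alignments:
        if not rec.genome_unique:
            continue
        if rec.target not in known_chroms:
            raise ValueError(
                f"alignment chromosome {rec.target!r} absent from tile set "
                f"(tile chromosomes: {sorted(known_chroms)})"
            )
        n_unique += 1
        pos = rec.midpoint if assignment == "midpoint" else rec.five_prime
        idx = tiles.index_of(rec.target, pos)
        if idx is not None:
            counts[idx] += 1
    return counts, n_unique


def tile_enrichment(
    chip_counts: Sequence[float],
    input_counts: Sequence[float],
    chip_depth: float,
    input_depth: float,
    config: Optional[PipelineConfig] = None,
) -> np.ndarray:
    """Raw per-unit enrichment: depth-scaled counts plus pseudocount, ratioed.

    enrichment = (chip * scale/chip_depth + pc) / (input * scale/input_depth + pc)
    """
    config = config or PipelineConfig()
    if chip_depth <= 0 or input_depth <= 0:
        raise ValueError("library depth must be > 0")
    chip = np.asarray(chip_counts, dtype=float) * config.depth_scale / chip_depth
    inp = np.asarray(input_counts, dtype=float) * config.depth_scale / input_depth
    return (chip + config.pseudocount) / (inp + config.pseudocount)


def background_correction(
    raw: Sequence[float],
    background_mask: Sequence[bool],
    unit_ids: Optional[Sequence[str]] = None,
    unit: str = "tile",
) -> EnrichmentTable:
    """Rescale enrichments so the background median becomes exactly 1.

    correction_factor = 1 / median(raw over background units).
    """
    raw = np.asarray(raw, dtype=float)
    mask = np.asarray(background_mask, dtype=bool)
    if raw.shape != mask.shape:
        raise ValueError("raw and background mask lengths differ")
    if not mask.any():
        raise ValueError("background unit set is empty")
    med = float(np.median(raw[mask]))
    if med == 0:
        raise ValueError("background median enrichment is 0; cannot correct")
    factor = 1.0 / med
    ids = list(unit_ids) if unit_ids is not None else [str(i) for i in range(raw.size)]
    table = pd.DataFrame(
        {
            "raw_enrichment": raw,
            "corrected_enrichment": raw * factor,
            "log2_corrected": np.log2(raw * factor, where=raw * factor > 0,
                                      out=np.full(raw.size, -np.inf)),
            "background": mask,
        },
        index=pd.Index(ids, name="unit"),
    )
    return EnrichmentTable(
        unit=unit,
        table=table,
        correction_factor=factor,
        background_units=[i for i, m in zip(ids, mask) if m],
    )


def assign_multimappers(
    hits_by_read: Mapping[str, Sequence[AlignmentRecord]],
    seed: int,
) -> Dict[str, AlignmentRecord]:
    """Resolve each read's hit list to a single alignment.

    The unique minimal-mismatch hit wins; exact mismatch ties are broken
    uniformly at random. Reads are processed in lexicographic read_id order
    with one seeded generator, so the assignment is independent of input
    ordering and bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    assigned: Dict[str, AlignmentRecord] = {}
    for read_id in sorted(hits_by_read):
        hits = hits_by_read[read_id]
        if not hits:
            raise ValueError(f"empty hit list for read {read_id}")
        best = min(h.mismatches for h in hits)
        candidates = [h for h in hits if h.mismatches == best]
        if len(candidates) == 1:
            assigned[read_id] = candidates[0]
        else:
            assigned[read_id] = candidates[int(rng.integers(len(candidates)))]
    return assigned


def _mean_coverage(
    assigned: Mapping[str, AlignmentRecord],
    te_lengths: Mapping[str, int],
) -> Dict[str, float]:
    """Per element, covered bases summed over reads divided by element length."""
    covered = {name: 0 for name in te_lengths}
    for rec in assigned.values():
        length = te_lengths.get(rec.target)
        if length is None:
            continue
        lo = max(rec.start, 0)
        hi = min(rec.end, length)
        covered[rec.target] += max(hi - lo, 0)
    return {name: covered[name] / te_lengths[name] for name in te_lengths}


def te_consensus_enrichment(
    chip_hits: Mapping[str, Sequence[AlignmentRecord]],
    input_hits: Mapping[str, Sequence[AlignmentRecord]],
    te_lengths: Mapping[str, int],
    chip_depth: float,
    input_depth: float,
    correction_factor: float,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> EnrichmentTable:
    """Per-element enrichment from multimapper-resolved consensus coverage.

    Reads shorter than ``te_min_read_length`` (default 24 nt, i.e. longer
    than 23) are discarded. Per element, depth-normalized coverage is
    averaged over all consensus positions for ChIP and input; the pseudocount
    ratio is then scaled by the sample-specific correction factor determined
    from tile-level background.
    """
    config = config or PipelineConfig()
    for name, length in te_lengths.items():
        if length <= 0:
            raise ValueError(f"TE element {name!r} has length {length}")
    if chip_depth <= 0 or input_depth <= 0:
        raise ValueError("library depth must be > 0")
    seed = config.rng_seed if seed is None else seed

    def prepare(hits_by_read, sub_seed):
        kept = {
            rid: hits
            for rid, hits in hits_by_read.items()
            if hits and max(h.read_length or (h.end - h.start) for h in hits)
            >= config.te_min_read_length
        }
        return assign_multimappers(kept, sub_seed)

    chip_mean = _mean_coverage(prepare(chip_hits, seed), te_lengths)
    input_mean = _mean_coverage(prepare(input_hits, seed + 1), te_lengths)
    names = sorted(te_lengths)
    chip_arr = np.array([chip_mean[n] for n in names]) * config.depth_scale / chip_depth
    input_arr = np.array([input_mean[n] for n in names]) * config.depth_scale / input_depth
    raw = (chip_arr + config.pseudocount) / (input_arr + config.pseudocount)
    corrected = raw * correction_factor
    table = pd.DataFrame(
        {
            "chip_mean": chip_arr,
            "input_mean": input_arr,
            "raw_enrichment": raw,
            "corrected_enrichment": corrected,
            "log2_corrected": np.log2(corrected),
        },
        index=pd.Index(names, name="unit"),
    )
    return EnrichmentTable(
        unit="te_element",
        table=table,
        correction_factor=correction_factor,
        background_units=[],
    )


def average_replicates(tables: Sequence[EnrichmentTable]) -> pd.Series:
    """Average replicate experiments per unit as the mean of log2 enrichments.

    Returns the geometric-mean corrected enrichment (linear scale) per unit.
    """
    if len(tables) < 1:
        raise ValueError("need at least one table")
    frames = [t.values for t in tables]
    idx = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(idx):
            raise ValueError("replicate tables cover different unit sets")
    logs = np.mean([np.log2(f.to_numpy(dtype=float)) for f in frames], axis=0)
    return pd.Series(2.0 ** logs, index=idx, name="mean_corrected_enrichment")
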