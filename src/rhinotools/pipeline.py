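"""End-to-end ChIP-tile and small-RNA pipelines.

``run_chip_pipeline`` goes from two alignment sources (ChIP and input) and a
curated tile set to background-corrected per-tile enrichments.
``run_smallrna_pipeline`` goes from raw adapter-carrying FASTQ reads to the
three normalized count tables (per transposon, per piRNA cluster, per
cluster tile), all scaled by the same miRNA normalization factor, plus a
run report that accounts for every read exactly once.

Both pipelines are deterministic for fixed inputs and seed; re-running with
the same configuration yields identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .chip import (
    AlignmentRecord,
    EnrichmentTable,
    assign_multimappers,
    background_correction,
    count_unique_reads_per_tile,
    group_hits_by_read,
    read_alignments,
    tile_enrichment,
)
from .config import LibraryMeta, PipelineConfig
from .intervals import IntervalIndex, merge_intervals
from .pirna import ClusterDef, cluster_unique_count, te_antisense_count
from .simulate import exact_match_hits
from .smallrna import (
    AdapterScheme,
    SmallRNALibrary,
    filter_ncrna,
    mirna_norm_factor,
    read_fastq,
    trim_library,
)
from .tiles import TileSet

__all__ = ["SmallRNAResult", "run_chip_pipeline", "run_smallrna_pipeline"]

AlignmentSource = Union[str, Path, Iterable[AlignmentRecord]]


def _as_records(source: AlignmentSource) -> List[AlignmentRecord]:
    if isinstance(source, (str, Path)):
        return read_alignments(source)
    return list(source)


def run_chip_pipeline(
    config: PipelineConfig,
    chip: AlignmentSource,
    input_: AlignmentSource,
    tiles: TileSet,
    background_mask: Optional[Sequence[bool]] = None,
    chip_meta: Optional[LibraryMeta] = None,
    input_meta: Optional[LibraryMeta] = None,
    assignment: str = "midpoint",
) -> EnrichmentTable:
    """Corrected per-tile ChIP enrichment from genome-unique reads.

    Library depth is the number of genome-unique mapped reads of each
    library (reads off any tile still count toward depth). The background
    set for the correction factor defaults to all curated tiles.
    """
    chip_records = _as_records(chip)
    input_records = _as_records(input_)
    if not chip_records or not input_records:
        raise ValueError("no mapped reads in ChIP or input alignment source")
    chip_counts, chip_depth = count_unique_reads_per_tile(chip_records, tiles, assignment)
    input_counts, input_depth = count_unique_reads_per_tile(input_records, tiles, assignment)
    if chip_depth == 0 or input_depth == 0:
        raise ValueError("no mapped reads after uniqueness filtering")
    raw = tile_enrichment(chip_counts, input_counts, chip_depth, input_depth, config)
    mask = (
        np.asarray(background_mask, dtype=bool)
        if background_mask is not None
        else tiles.curated_mask()
    )
    table = background_correction(raw, mask, unit_ids=tiles.tile_ids, unit="tile")
    table.table.insert(0, "input_count", input_counts)
    table.table.insert(0, "chip_count", chip_counts)
    table.chip_meta = chip_meta or LibraryMeta("chip", "chip", total_mapped_reads=chip_depth)
    table.input_meta = input_meta or LibraryMeta(
        "input", "input", total_mapped_reads=input_depth
    )
    return table


@dataclass
class SmallRNAResult:
    library: SmallRNALibrary
    norm_factor: float
    per_te: pd.DataFrame  # element, antisense_reads, normalized_count (per kb)
    per_cluster: pd.DataFrame  # cluster, unique_reads, normalized_count
    per_tile: pd.DataFrame  # tile_id, unique_reads, normalized_count
    report: Dict[str, int] = field(default_factory=dict)


def run_smallrna_pipeline(
    config: PipelineConfig,
    raw_reads: Union[str, Path, Iterable[Tuple[str, str]]],
    genome: Mapping[str, str],
    annotations: pd.DataFrame,
    te_seqs: Mapping[str, str],
    clusters: Sequence[ClusterDef],
    mito_chrom: str = "chrM",
    scheme: Optional[AdapterScheme] = None,
    tiles: Optional[TileSet] = None,
    meta: Optional[LibraryMeta] = None,
    genome_hits: Optional[Mapping[str, List[AlignmentRecord]]] = None,
) -> SmallRNAResult:
    """Trim, categorize, normalize and count one small-RNA library.

    ``annotations`` is a BED-like frame whose name column labels each locus
    (rRNA/tRNA/snRNA/snoRNA/miRNA). Genome and transposon mapping use exact
    matching on both strands (the 0-mismatch rule); precomputed genome hits
    can be supplied instead via ``genome_hits``. All three count tables are
    scaled by the same miRNA normalization factor.
    """
    scheme = scheme or AdapterScheme()
    if isinstance(raw_reads, (str, Path)):
        raw_reads = read_fastq(raw_reads)
    raw_list = list(raw_reads)
    kept, rejected = trim_library(raw_list, scheme)
    inserts = {read_id: insert for read_id, insert, _ in kept}

    if genome_hits is None:
        genome_hits = exact_match_hits(inserts, genome)
    ann_index = {
        str(name): IntervalIndex(merge_intervals(sub))
        for name, sub in annotations.groupby("name")
    }
    read_lengths = {rid: len(ins) for rid, ins in inserts.items()}
    categories = filter_ncrna(
        {rid: genome_hits.get(rid, []) for rid in inserts if rid in genome_hits},
        ann_index,
        mito_chrom,
        read_lengths,
        config,
    )
    for rid in inserts:
        categories.setdefault(rid, "other")  # unmapped reads

    reads_df = pd.DataFrame(
        {
            "read_id": [rid for rid, _, _ in kept],
            "insert": [ins for _, ins, _ in kept],
            "barcode": [bc for _, _, bc in kept],
            "length": [len(ins) for _, ins, _ in kept],
            "category": [categories[rid] for rid, _, _ in kept],
        }
    )
    library = SmallRNALibrary(
        meta=meta or LibraryMeta("srna", "small_rna"),
        reads=reads_df,
        rejected=rejected,
        config=config,
    )
    nf = mirna_norm_factor(library.mirna_reads, config.mirna_norm_target)

    pirna_ids = [rid for rid, cat in categories.items() if cat == "pirna_candidate"]

    # transposon antisense counts: exact-match to consensi, multimapper-resolved
    te_hits = exact_match_hits({rid: inserts[rid] for rid in pirna_ids}, te_seqs)
    assigned = assign_multimappers(te_hits, seed=config.rng_seed)
    te_lengths = {name: len(seq) for name, seq in te_seqs.items()}
    normalized = te_antisense_count(assigned, te_lengths, nf, config)
    antisense_raw = {name: 0 for name in te_lengths}
    for rec in assigned.values():
        if rec.strand == "-" and rec.target in antisense_raw:
            antisense_raw[rec.target] += 1
    per_te = pd.DataFrame(
        {
            "element": sorted(te_lengths),
            "length": [te_lengths[n] for n in sorted(te_lengths)],
            "antisense_reads": [antisense_raw[n] for n in sorted(te_lengths)],
            "normalized_count": [normalized[n] for n in sorted(te_lengths)],
        }
    )

    # locus-unique cluster counts from complete genome hit lists
    pirna_genome_hits = {
        rid: genome_hits[rid] for rid in pirna_ids if rid in genome_hits
    }
    cluster_counts = cluster_unique_count(pirna_genome_hits, clusters)
    per_cluster = pd.DataFrame(
        {
            "cluster": sorted(cluster_counts),
            "unique_reads": [cluster_counts[c] for c in sorted(cluster_counts)],
            "normalized_count": [cluster_counts[c] * nf for c in sorted(cluster_counts)],
        }
    )

    # per-tile counts over cluster tiles, mirroring the locus-unique rule at
    # tile granularity (every hit's 5' end inside the same single tile)
    per_tile = pd.DataFrame(columns=["tile_id", "unique_reads", "normalized_count"])
    if tiles is not None:
        cluster_index = [cd.index() for cd in clusters]
        tile_clusters = [
            ClusterDef.from_intervals(t.tile_id, [(t.chrom, t.start, t.end)])
            for t in tiles
            if any(ix.overlaps(t.chrom, t.start, t.end) for ix in cluster_index)
        ]
        tile_counts = cluster_unique_count(pirna_genome_hits, tile_clusters)
        per_tile = pd.DataFrame(
            {
                "tile_id": sorted(tile_counts),
                "unique_reads": [tile_counts[t] for t in sorted(tile_counts)],
                "normalized_count": [tile_counts[t] * nf for t in sorted(tile_counts)],
            }
        )

    counts = library.category_counts()
    report = {
        "raw_reads": len(raw_list),
        "rejected_no_adapter": rejected.get("no_adapter", 0),
        "rejected_too_short": rejected.get("too_short", 0),
        **{f"category_{c}": n for c, n in counts.items()},
    }
    assert report["raw_reads"] == sum(
        v for k, v in report.items() if k != "raw_reads"
    ), "read accounting failed"
    return SmallRNAResult(
        library=library,
        norm_factor=nf,
        per_te=per_te,
        per_cluster=per_cluster,
        per_tile=per_tile,
        report=report,
    )
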