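"""Synthetic genomes, ChIP/input libraries, and small-RNA libraries with truth.

The generator emulates the statistical structure of the real datasets the
analysis was designed for, at desk scale:

* a toy genome (two 100-kb chromosomes plus a small mitochondrial
  chromosome) carrying two piRNA clusters, embedded transposon copies
  (exact copies of consensus sequences, so reads drawn from them are
  genuine multimappers), structural-ncRNA and miRNA loci, and planted
  low-mappability blocks;
* ChIP/input alignment sets: input reads uniform over the genome, ChIP
  reads sampled proportionally to per-tile enrichment multipliers
  (background 1, planted domains 2/4/8 by default);
* raw small-RNA FASTQ libraries with the full adapter architecture
  (4 random 5' nt; insert; 6 random nt; 5 nt barcode; constant 3' linker)
  mixing miRNA reads, sense/antisense transposon piRNAs with planted
  fold changes across genotypes, cluster-unique piRNAs, structural-ncRNA
  and mitochondrial contaminants.

Every generator is a pure function of (config, seed); the recorded truth
suffices to recompute each expected pipeline output analytically. A k-mer
exact-match aligner over the toy references stands in for the external
aligner, matching the 0-mismatch small-RNA mapping rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chip import AlignmentRecord
from .pirna import ClusterDef

__all__ = [
    "SimGenomeConfig",
    "SyntheticGenome",
    "SmallRNAComposition",
    "sim_genome",
    "sim_chip",
    "sim_srna",
    "exact_match_hits",
    "revcomp",
    "write_fasta",
    "write_fastq",
    "write_sam",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimGenomeConfig:
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr2L": 100_000, "chr3R": 100_000}
    )
    mito_chrom: str = "chrM"
    mito_length: int = 5_000
    te_lengths: Dict[str, int] = field(
        default_factory=lambda: {"TE1": 2_000, "TE2": 1_500, "TE3": 1_000}
    )
    # TE copy layout: (te, chrom, start). TE1 twice inside cluster 42AB
    # (locus-unique multimappers); TE2 split across the two clusters
    # (shared multimappers); TE3 single-copy outside any cluster.
    te_copies: List[Tuple[str, str, int]] = field(
        default_factory=lambda: [
            ("TE1", "chr2L", 61_000),
            ("TE1", "chr2L", 66_000),
            ("TE2", "chr2L", 71_000),
            ("TE2", "chr3R", 61_000),
            ("TE3", "chr3R", 80_000),
        ]
    )
    clusters: Dict[str, Tuple[str, int, int]] = field(
        default_factory=lambda: {
            "42AB": ("chr2L", 60_000, 75_000),
            "38C": ("chr3R", 60_000, 70_000),
        }
    )
    low_mappability: List[Tuple[str, int, int]] = field(
        default_factory=lambda: [("chr2L", 20_000, 23_000), ("chr3R", 40_000, 42_000)]
    )
    ncrna_loci: List[Tuple[str, str, int, int]] = field(
        default_factory=lambda: [
            ("rRNA", "chr2L", 5_000, 5_500),
            ("tRNA", "chr2L", 10_000, 10_100),
            ("snRNA", "chr3R", 5_000, 5_200),
            ("snoRNA", "chr3R", 10_000, 10_150),
        ]
    )
    mirna_loci: List[Tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("chr2L", 30_000, 30_500),
            ("chr2L", 40_000, 40_500),
            ("chr3R", 20_000, 20_500),
            ("chr3R", 30_000, 30_500),
        ]
    )
    # annotation-free stretch per chromosome used for "other"-category reads
    neutral_regions: List[Tuple[str, int, int]] = field(
        default_factory=lambda: [("chr2L", 80_000, 95_000)]
    )

    def validate(self) -> None:
        for te, chrom, start in self.te_copies:
            end = start + self.te_lengths[te]
            if chrom not in self.chrom_lengths or end > self.chrom_lengths[chrom]:
                raise ValueError(f"TE copy {te}@{chrom}:{start} exceeds chromosome")
        for name, (chrom, start, end) in self.clusters.items():
            if end > self.chrom_lengths.get(chrom, -1):
                raise ValueError(f"cluster {name} exceeds chromosome {chrom}")


@dataclass
class SyntheticGenome:
    config: SimGenomeConfig
    seed: int
    sequences: Dict[str, str]  # chrom -> sequence (includes the mito chromosome)
    te_consensus: Dict[str, str]
    clusters: List[ClusterDef]

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def nuclear_chroms(self) -> List[str]:
        return [c for c in self.sequences if c != self.config.mito_chrom]

    def mappable_blocks(self) -> List[Tuple[str, int, int]]:
        """Mappability track: each nuclear chromosome minus planted blocks."""
        blocks = []
        for chrom in self.nuclear_chroms:
            length = len(self.sequences[chrom])
            cursor = 0
            for bc, bs, be in sorted(
                b for b in self.config.low_mappability if b[0] == chrom
            ):
                if bs > cursor:
                    blocks.append((chrom, cursor, bs))
                cursor = max(cursor, be)
            if cursor < length:
                blocks.append((chrom, cursor, length))
        return blocks

    def annotation_bed(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "start": s, "end": e, "name": cls}
            for cls, c, s, e in self.config.ncrna_loci
        ]
        rows += [
            {"chrom": c, "start": s, "end": e, "name": "miRNA"}
            for c, s, e in self.config.mirna_loci
        ]
        return pd.DataFrame(rows)

    def cluster_bed(self) -> pd.DataFrame:
        rows = []
        for cd in self.clusters:
            for chrom, arr in cd.intervals.items():
                for s, e in arr:
                    rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                                 "name": cd.name})
        return pd.DataFrame(rows)

    def te_copy_intervals(self) -> List[Tuple[str, str, int, int]]:
        return [
            (te, chrom, start, start + len(self.te_consensus[te]))
            for te, chrom, start in self.config.te_copies
        ]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def sim_genome(config: Optional[SimGenomeConfig] = None, seed: int = 0) -> SyntheticGenome:
    """Build the toy genome; deterministic for a fixed (config, seed)."""
    config = config or SimGenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    te_consensus = {
        name: _random_seq(rng, length) for name, length in sorted(config.te_lengths.items())
    }
    sequences: Dict[str, str] = {}
    for chrom in config.chrom_lengths:
        seq = list(_random_seq(rng, config.chrom_lengths[chrom]))
        for te, te_chrom, start in config.te_copies:
            if te_chrom == chrom:
                seq[start : start + len(te_consensus[te])] = te_consensus[te]
        sequences[chrom] = "".join(seq)
    sequences[config.mito_chrom] = _random_seq(rng, config.mito_length)
    clusters = [
        ClusterDef.from_intervals(name, [(chrom, start, end)])
        for name, (chrom, start, end) in sorted(config.clusters.items())
    ]
    return SyntheticGenome(config, seed, sequences, te_consensus, clusters)


# ---------------------------------------------------------------------------
# exact-match alignment


def exact_match_hits(
    reads: Mapping[str, str],
    references: Mapping[str, str],
    k: int = 16,
) -> Dict[str, List[AlignmentRecord]]:
    """All exact occurrences of each read on either strand of the references.

    Equivalent to best-stratum alignment with 0 mismatches reported for all
    hits; reads shorter than the seed size k are matched by brute force.
    """
    index: Dict[str, List[Tuple[str, int]]] = {}
    for name, seq in references.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((name, i))

    def occurrences(query: str) -> List[Tuple[str, int]]:
        if len(query) >= k:
            out = []
            for name, pos in index.get(query[:k], ()):  # verify full extension
                ref = references[name]
                if ref[pos : pos + len(query)] == query:
                    out.append((name, pos))
            return out
        hits = []
        for name, seq in references.items():
            start = seq.find(query)
            while start != -1:
                hits.append((name, start))
                start = seq.find(query, start + 1)
        return hits

    result: Dict[str, List[AlignmentRecord]] = {}
    for read_id, seq in reads.items():
        fw = [(n, p, "+") for n, p in occurrences(seq)]
        rv = [(n, p, "-") for n, p in occurrences(revcomp(seq))]
        hits = fw + rv
        records = [
            AlignmentRecord(read_id, name, pos, pos + len(seq), strand, 0,
                            max(len(hits), 1), len(seq))
            for name, pos, strand in sorted(hits)
        ]
        if records:
            result[read_id] = records
    return result


# ---------------------------------------------------------------------------
# ChIP simulation


DEFAULT_DOMAINS = (
    # (chrom, first tile index on that chromosome, n tiles, multiplier)
    ("chr2L", 5, 5, 2.0),
    ("chr2L", 45, 5, 4.0),
    ("chr3R", 5, 5, 8.0),
)


@dataclass
class ChipTruth:
    tile_multipliers: Dict[str, float]  # tile_id -> planted enrichment
    n_reads: int
    read_length: int
    seed: int


def sim_chip(
    genome: SyntheticGenome,
    n_reads: int = 100_000,
    seed: int = 0,
    domains: Sequence[Tuple[str, int, int, float]] = DEFAULT_DOMAINS,
    tile_size: int = 1000,
    read_length: int = 50,
) -> Tuple[List[AlignmentRecord], List[AlignmentRecord], ChipTruth]:
    """Sample ChIP and input alignment sets with planted per-tile enrichment.

    Input reads are uniform over the nuclear genome; ChIP reads are sampled
    per tile proportionally to (tile length x multiplier), uniformly within
    the tile. Reads falling entirely inside an embedded TE copy receive one
    alignment record per copy of that TE (a genuine best-stratum multimapper).
    Returns (chip records, input records, truth).
    """
    import warnings

    rng = np.random.default_rng(seed)
    chroms = genome.nuclear_chroms
    sizes = [len(genome.sequences[c]) for c in chroms]
    tile_rows: List[Tuple[str, int, int]] = []  # (chrom, start, end)
    for chrom, size in zip(chroms, sizes):
        for start in range(0, size, tile_size):
            tile_rows.append((chrom, start, min(start + tile_size, size)))
    multipliers = np.ones(len(tile_rows))
    tile_index = {(c, s // tile_size): i for i, (c, s, _) in enumerate(tile_rows)}
    truth_mult: Dict[str, float] = {}
    for chrom, first, n_tiles, mult in domains:
        for j in range(first, first + n_tiles):
            i = tile_index[(chrom, j)]
            multipliers[i] = mult
    for i, (c, s, e) in enumerate(tile_rows):
        truth_mult[f"{c}:{s}-{e}"] = float(multipliers[i])
    if n_reads < len(tile_rows):
        warnings.warn("fewer reads than tiles: sparse regime")

    copies_by_te: Dict[str, List[Tuple[str, int]]] = {}
    for te, chrom, start in genome.config.te_copies:
        copies_by_te.setdefault(te, []).append((chrom, start))
    copy_lookup = [
        (chrom, start, start + len(genome.te_consensus[te]), te)
        for te, chrom, start in genome.config.te_copies
    ]

    def hits_for(chrom: str, start: int, read_id: str, strand: str) -> List[AlignmentRecord]:
        end = start + read_length
        for c, cs, ce, te in copy_lookup:
            if c == chrom and cs <= start and end <= ce:
                copies = copies_by_te[te]
                offset = start - cs
                return [
                    AlignmentRecord(read_id, cc, cstart + offset,
                                    cstart + offset + read_length, strand, 0,
                                    len(copies), read_length)
                    for cc, cstart in copies
                ]
        return [AlignmentRecord(read_id, chrom, start, end, strand, 0, 1, read_length)]

    def sample(weights: np.ndarray, prefix: str) -> List[AlignmentRecord]:
        probs = weights / weights.sum()
        tile_draws = rng.choice(len(tile_rows), size=n_reads, p=probs)
        records: List[AlignmentRecord] = []
        for i, t in enumerate(tile_draws):
            chrom, ts, te_ = tile_rows[t]
            chrom_len = len(genome.sequences[chrom])
            hi = min(te_, chrom_len - read_length)
            lo = min(ts, hi)
            start = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            strand = "+" if rng.integers(2) == 0 else "-"
            records.extend(hits_for(chrom, start, f"{prefix}{i:07d}", strand))
        return records

    lengths = np.array([e - s for _, s, e in tile_rows], dtype=float)
    chip = sample(lengths * multipliers, "chip")
    inp = sample(lengths, "input")
    return chip, inp, ChipTruth(truth_mult, n_reads, read_length, seed)


# ---------------------------------------------------------------------------
# small-RNA simulation


@dataclass
class SmallRNAComposition:
    """Per-genotype read composition of the simulated small-RNA libraries.

    The default plants miRNA-normalized antisense fold changes of 8x (TE1),
    4x (TE2) and 1x (TE3) between control and rhino knockdown — the dynamic
    range the twofold dependence classifier must resolve. The knockdown
    library has half the miRNA reads of the control, so its raw counts are
    additionally halved to realize those normalized folds.
    """

    libraries: Dict[str, Dict] = field(
        default_factory=lambda: {
            "control": {
                "mirna": 20_000,
                "te_antisense": {"TE1": 4_000, "TE2": 2_000, "TE3": 1_000},
                "te_sense": {"TE1": 400, "TE2": 200, "TE3": 100},
                "cluster_unique": {"42AB": 3_000, "38C": 2_000},
                "ncrna": 1_000,
                "mito": 300,
                "other": 500,
            },
            "rhino_kd": {
                "mirna": 10_000,
                "te_antisense": {"TE1": 250, "TE2": 250, "TE3": 500},
                "te_sense": {"TE1": 25, "TE2": 25, "TE3": 50},
                "cluster_unique": {"42AB": 188, "38C": 250},
                "ncrna": 1_000,
                "mito": 300,
                "other": 500,
            },
        }
    )
    barcodes: Dict[str, str] = field(
        default_factory=lambda: {"control": "ACGTC", "rhino_kd": "TGCAT"}
    )
    pirna_lengths: Tuple[int, int] = (23, 29)
    mirna_length: int = 22
    other_length: int = 31  # outside the piRNA range on purpose


@dataclass
class SmallRNATruth:
    composition: SmallRNAComposition
    seed: int
    inserts: Dict[str, Dict[str, str]]  # genotype -> read_id -> insert
    categories: Dict[str, Dict[str, str]]  # genotype -> read_id -> planted category

    def expected_category_counts(self, genotype: str) -> Dict[str, int]:
        lib = self.composition.libraries[genotype]
        return {
            "mirna": lib["mirna"],
            "filtered_ncrna": lib["ncrna"] + lib["mito"],
            "pirna_candidate": (
                sum(lib["te_antisense"].values())
                + sum(lib["te_sense"].values())
                + sum(lib["cluster_unique"].values())
            ),
            "other": lib["other"],
        }

    def expected_norm_factor(self, genotype: str, target: float = 1e6) -> float:
        return target / self.composition.libraries[genotype]["mirna"]

    def expected_te_antisense(
        self, genotype: str, te_lengths: Mapping[str, int], target: float = 1e6
    ) -> Dict[str, float]:
        lib = self.composition.libraries[genotype]
        nf = self.expected_norm_factor(genotype, target)
        return {
            te: lib["te_antisense"][te] * nf * 1000.0 / te_lengths[te]
            for te in lib["te_antisense"]
        }

    def expected_dependence_ratio(self, control: str, test: str, te: str) -> float:
        """Planted test/control ratio of normalized antisense counts."""
        c = self.composition.libraries[control]
        t = self.composition.libraries[test]
        return (t["te_antisense"][te] * self.expected_norm_factor(test)) / (
            c["te_antisense"][te] * self.expected_norm_factor(control)
        )

    def expected_cluster_counts(self, genome: SyntheticGenome, genotype: str) -> Dict[str, int]:
        """Locus-unique cluster counts implied by the planted layout.

        TE reads join the count of a cluster iff every genomic copy of that
        TE lies inside that one cluster (TE1 -> 42AB under the default
        layout); TEs split across clusters or outside clusters contribute
        nothing.
        """
        lib = self.composition.libraries[genotype]
        counts = dict(lib["cluster_unique"])
        copies_by_te: Dict[str, List[Tuple[str, int, int]]] = {}
        for te, chrom, start in genome.config.te_copies:
            end = start + len(genome.te_consensus[te])
            copies_by_te.setdefault(te, []).append((chrom, start, end))
        for te, copies in copies_by_te.items():
            homes = set()
            for chrom, start, end in copies:
                hit = [
                    cd.name
                    for cd in genome.clusters
                    if cd.index().overlaps(chrom, start, end)
                ]
                homes.add(hit[0] if hit else None)
            if len(homes) == 1 and None not in homes:
                home = homes.pop()
                counts[home] += lib["te_antisense"].get(te, 0) + lib["te_sense"].get(te, 0)
        return counts


def _window(rng, seq: str, length: int) -> str:
    start = int(rng.integers(0, len(seq) - length + 1))
    return seq[start : start + length]


def sim_srna(
    genome: SyntheticGenome,
    composition: Optional[SmallRNAComposition] = None,
    seed: int = 0,
    linker3: str = "AGATCGGAAGAGCACACGTCT",
) -> Tuple[Dict[str, List[Tuple[str, str]]], SmallRNATruth]:
    """Emit raw small-RNA reads with the full adapter architecture, plus truth.

    Returns ({genotype: [(read_id, raw sequence), ...]}, truth). Raw reads
    are ``4 random nt + insert + 6 random nt + barcode + linker``.
    """
    composition = composition or SmallRNAComposition()
    rng = np.random.default_rng(seed)
    lo, hi = composition.pirna_lengths
    cluster_space: Dict[str, List[Tuple[str, int, int]]] = {}
    te_spans = [(c, s, s + len(genome.te_consensus[t])) for t, c, s in genome.config.te_copies]
    for cd in genome.clusters:
        spans = []
        for chrom, arr in cd.intervals.items():
            for cs, ce in arr:
                cursor = int(cs)
                for tc, ts, te_ in sorted(te_spans):
                    if tc == chrom and ts < ce and te_ > cs:
                        if ts > cursor:
                            spans.append((chrom, cursor, ts))
                        cursor = max(cursor, te_)
                if cursor < ce:
                    spans.append((chrom, cursor, int(ce)))
        cluster_space[cd.name] = [s for s in spans if s[2] - s[1] >= hi]

    ncrna_seqs = [
        genome.sequences[c][s:e] for _, c, s, e in genome.config.ncrna_loci
    ]
    mirna_seqs = [genome.sequences[c][s:e] for c, s, e in genome.config.mirna_loci]
    neutral_seqs = [
        genome.sequences[c][s:e] for c, s, e in genome.config.neutral_regions
    ]
    mito_seq = genome.sequences[genome.config.mito_chrom]

    fastq: Dict[str, List[Tuple[str, str]]] = {}
    truth_inserts: Dict[str, Dict[str, str]] = {}
    truth_categories: Dict[str, Dict[str, str]] = {}

    for genotype in sorted(composition.libraries):
        lib = composition.libraries[genotype]
        barcode = composition.barcodes[genotype]
        reads: List[Tuple[str, str]] = []
        inserts: Dict[str, str] = {}
        categories: Dict[str, str] = {}
        counter = 0

        def emit(insert: str, category: str) -> None:
            nonlocal counter
            read_id = f"{genotype}_{category}_{counter:06d}"
            counter += 1
            raw = (
                _random_seq(rng, 4)
                + insert
                + _random_seq(rng, 6)
                + barcode
                + linker3
            )
            reads.append((read_id, raw))
            inserts[read_id] = insert
            categories[read_id] = category

        for _ in range(lib["mirna"]):
            emit(_window(rng, mirna_seqs[int(rng.integers(len(mirna_seqs)))],
                         composition.mirna_length), "mirna")
        for te in sorted(lib["te_antisense"]):
            for _ in range(lib["te_antisense"][te]):
                length = int(rng.integers(lo, hi + 1))
                emit(revcomp(_window(rng, genome.te_consensus[te], length)),
                     f"te_antisense:{te}")
        for te in sorted(lib.get("te_sense", {})):
            for _ in range(lib["te_sense"][te]):
                length = int(rng.integers(lo, hi + 1))
                emit(_window(rng, genome.te_consensus[te], length), f"te_sense:{te}")
        for cname in sorted(lib.get("cluster_unique", {})):
            spans = cluster_space[cname]
            weights = np.array([e - s for _, s, e in spans], dtype=float)
            probs = weights / weights.sum()
            for _ in range(lib["cluster_unique"][cname]):
                chrom, s, e = spans[int(rng.choice(len(spans), p=probs))]
                length = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(s, e - length + 1))
                insert = genome.sequences[chrom][start : start + length]
                if rng.integers(2):
                    insert = revcomp(insert)
                emit(insert, f"cluster:{cname}")
        for _ in range(lib.get("ncrna", 0)):
            emit(_window(rng, ncrna_seqs[int(rng.integers(len(ncrna_seqs)))], 22),
                 "ncrna")
        for _ in range(lib.get("mito", 0)):
            length = int(rng.integers(lo, hi + 1))
            emit(_window(rng, mito_seq, length), "mito")
        for _ in range(lib.get("other", 0)):
            emit(_window(rng, neutral_seqs[int(rng.integers(len(neutral_seqs)))],
                         composition.other_length), "other")

        fastq[genotype] = reads
        truth_inserts[genotype] = inserts
        truth_categories[genotype] = categories

    return fastq, SmallRNATruth(composition, seed, truth_inserts, truth_categories)


# ---------------------------------------------------------------------------
# writers (plain-text standard formats)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[Tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_sam(
    records: Iterable[AlignmentRecord],
    reference_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write alignment records as headered SAM with NH/NM tags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in reference_lengths.items()],
    }
    ref_ids = {name: i for i, name in enumerate(reference_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_id = ref_ids[rec.target]
            a.reference_start = rec.start
            a.flag = 16 if rec.strand == "-" else 0
            a.cigarstring = f"{rec.end - rec.start}M"
            a.query_sequence = "N" * (rec.end - rec.start)
            a.mapping_quality = 255
            a.set_tag("NH", rec.n_best_hits)
            a.set_tag("NM", rec.mismatches)
            out.write(a)
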