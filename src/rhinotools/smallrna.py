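"""Small-RNA read trimming, structural-ncRNA filtering, and miRNA normalization.

Library architecture (configurable, defaults match the cloning chemistry this
package models): each raw read is

    [4 random nt] insert [6 random nt] [5 nt barcode] [constant 3' linker]

Trimming locates the constant linker (leftmost match with a small mismatch
allowance), strips it together with the preceding random nucleotides and
barcode, and strips the 4 random 5' nucleotides; the barcode is recorded but
reads are not collapsed by it. After genome mapping (consumed from SAM/BAM
or any exact-match aligner; 0 mismatches), reads touching rRNA/tRNA/snRNA/
snoRNA loci or the mitochondrial genome are removed, miRNA reads are
identified by locus overlap, and everything downstream is normalized to one
million sequenced miRNA reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .chip import AlignmentRecord
from .config import LibraryMeta, PipelineConfig
from .intervals import IntervalIndex

__all__ = [
    "AdapterScheme",
    "TrimResult",
    "SmallRNALibrary",
    "read_fastq",
    "trim_read",
    "trim_library",
    "filter_ncrna",
    "mirna_norm_factor",
]

DEFAULT_LINKER3 = "AGATCGGAAGAGCACACGTCT"

CATEGORIES = ("mirna", "filtered_ncrna", "pirna_candidate", "other")
REJECT_REASONS = ("no_adapter", "too_short")
NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")


@dataclass
class AdapterScheme:
    linker3: str = DEFAULT_LINKER3
    random3: int = 6
    barcode_len: int = 5
    random5: int = 4
    max_linker_mismatches: int = 1
    min_insert: int = 18
    min_linker_overlap: int = 6  # shortest linker prefix accepted at the read end

    def __post_init__(self) -> None:
        if not self.linker3:
            raise ValueError("linker3 must be non-empty")
        for name in ("random3", "barcode_len", "random5", "min_insert"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TrimResult:
    insert: Optional[str]
    barcode: Optional[str]
    status: str  # "ok" | "no_adapter" | "too_short"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def read_fastq(path: str | Path) -> Iterator[Tuple[str, str]]:
    """Yield (read id, sequence) from a FASTQ file (gzip allowed).

    Malformed records raise with the 1-based record number.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            record += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record {record} in {path}")
            if len(qual) != len(seq):
                raise ValueError(
                    f"malformed FASTQ record {record} in {path}: "
                    "sequence/quality length mismatch"
                )
            yield header[1:].split()[0], seq.upper()


def _find_linker(seq: str, scheme: AdapterScheme) -> Optional[int]:
    """Leftmost start of the 3' linker, allowing mismatches and a truncated
    linker at the read end; None if absent."""
    linker = scheme.linker3
    n, L = len(seq), len(linker)
    for i in range(0, n - scheme.min_linker_overlap + 1):
        span = min(L, n - i)
        mism = 0
        for a, b in zip(seq[i : i + span], linker[:span]):
            if a != b:
                mism += 1
                if mism > scheme.max_linker_mismatches:
                    break
        else:
            return i
    return None


def trim_read(seq: str, scheme: Optional[AdapterScheme] = None) -> TrimResult:
    """Strip adapters from one raw read, recording the 5 nt barcode.

    Rejections are categorized (``no_adapter``, ``too_short``), never raised.
    """
    scheme = scheme or AdapterScheme()
    seq = seq.upper()
    pos = _find_linker(seq, scheme)
    if pos is None:
        return TrimResult(None, None, "no_adapter")
    tail = scheme.random3 + scheme.barcode_len
    insert_end = pos - tail
    if insert_end - scheme.random5 < scheme.min_insert:
        return TrimResult(None, None, "too_short")
    barcode = seq[pos - scheme.barcode_len : pos]
    insert = seq[scheme.random5 : insert_end]
    return TrimResult(insert, barcode, "ok")


@dataclass
class SmallRNALibrary:
    """Trimmed, categorized reads plus the miRNA normalization factor."""

    meta: LibraryMeta
    reads: pd.DataFrame  # read_id, insert, barcode, length, category
    rejected: Dict[str, int] = field(default_factory=dict)
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @property
    def mirna_reads(self) -> int:
        return int((self.reads["category"] == "mirna").sum())

    @property
    def norm_factor(self) -> float:
        return mirna_norm_factor(self.mirna_reads, self.config.mirna_norm_target)

    def category_counts(self) -> Dict[str, int]:
        counts = self.reads["category"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CATEGORIES}

    def summary(self) -> pd.DataFrame:
        rows = [{"category": c, "reads": n} for c, n in self.category_counts().items()]
        rows += [{"category": f"rejected_{r}", "reads": n} for r, n in self.rejected.items()]
        return pd.DataFrame(rows)


def trim_library(
    raw_reads: Iterable[Tuple[str, str]],
    scheme: Optional[AdapterScheme] = None,
) -> Tuple[List[Tuple[str, str, str]], Dict[str, int]]:
    """Trim an iterable of (read_id, sequence).

    Returns (list of (read_id, insert, barcode), rejection counts by reason).
    """
    scheme = scheme or AdapterScheme()
    kept: List[Tuple[str, str, str]] = []
    rejected = {r: 0 for r in REJECT_REASONS}
    for read_id, seq in raw_reads:
        res = trim_read(seq, scheme)
        if res.ok:
            kept.append((read_id, res.insert, res.barcode))
        else:
            rejected[res.status] += 1
    return kept, rejected


def filter_ncrna(
    hits_by_read: Mapping[str, Sequence[AlignmentRecord]],
    annotations: Mapping[str, IntervalIndex],
    mito_chrom: str,
    read_lengths: Mapping[str, int],
    config: Optional[PipelineConfig] = None,
    mirna_index: Optional[IntervalIndex] = None,
) -> Dict[str, str]:
    """Partition genome-mapped reads into the four library categories.

    A read is ``filtered_ncrna`` if ANY of its genome hits overlaps an
    annotated rRNA/tRNA/snRNA/snoRNA locus or lies on the mitochondrial
    chromosome. Of the remainder, a read is ``mirna`` if any hit overlaps a
    miRNA locus, ``pirna_candidate`` if its length falls in the configured
    piRNA range, else ``other``. Reads without genome hits are ``other``.
    """
    import warnings

    config = config or PipelineConfig()
    if mirna_index is None:
        mirna_index = annotations.get("miRNA")
    structural = []
    for cls in NCRNA_CLASSES:
        if cls in annotations:
            structural.append(annotations[cls])
        else:
            warnings.warn(f"annotation category {cls} missing; skipped")
    lo, hi = config.pirna_length_range
    categories: Dict[str, str] = {}
    for read_id, hits in hits_by_read.items():
        if any(
            h.target == mito_chrom
            or any(ix.overlaps(h.target, h.start, h.end) for ix in structural)
            for h in hits
        ):
            categories[read_id] = "filtered_ncrna"
        elif mirna_index is not None and any(
            mirna_index.overlaps(h.target, h.start, h.end) for h in hits
        ):
            categories[read_id] = "mirna"
        elif lo <= read_lengths[read_id] <= hi:
            categories[read_id] = "pirna_candidate"
        else:
            categories[read_id] = "other"
    return categories


def mirna_norm_factor(mirna_reads: int, target: float = 1_000_000.0) -> float:
    """Scaling factor that maps the library's miRNA total onto ``target`` reads."""
    if mirna_reads <= 0:
        raise ValueError("library has no miRNA reads; normalization undefined")
    return target / mirna_reads
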