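"""Genomic interval plumbing: BED/TSV ingest and merged-interval arithmetic.

Coordinates are 0-based, half-open throughout the package; BED files are
read and written natively in that convention, GFF is converted on ingest
(1-based inclusive -> 0-based half-open).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "read_gff",
    "merge_intervals",
    "covered_in_range",
    "IntervalIndex",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path: str | Path) -> Dict[str, int]:
    """Read a two-column TSV of (chromosome name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    sizes = dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
    for chrom, length in sizes.items():
        if length < 0:
            raise ValueError(f"negative length for chromosome {chrom}: {length}")
    return sizes


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ into a DataFrame with 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_gff(path: str | Path) -> pd.DataFrame:
    """Read GFF3/GTF features, converting to 0-based half-open intervals.

    Returns columns chrom, start, end, name (feature type), strand.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError(f"malformed GFF line: {line!r}")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "name": parts[2],
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def merge_intervals(
    intervals: pd.DataFrame | Iterable[Tuple[str, int, int]],
) -> Dict[str, np.ndarray]:
    """Merge possibly-overlapping intervals into per-chromosome (N, 2) arrays.

    Bookended intervals ([0,10) + [10,20)) are merged as well.
    """
    if isinstance(intervals, pd.DataFrame):
        triples = intervals[["chrom", "start", "end"]].itertuples(index=False)
    else:
        triples = intervals
    by_chrom: Dict[str, list] = {}
    for chrom, start, end in triples:
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    merged: Dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = []
        for start, end in ivs:
            if out and start <= out[-1][1]:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def covered_in_range(merged: np.ndarray, start: int, end: int) -> int:
    """Bases of [start, end) covered by merged, sorted, disjoint intervals."""
    if merged.size == 0 or end <= start:
        return 0
    lo = np.clip(merged[:, 0], start, end)
    hi = np.clip(merged[:, 1], start, end)
    return int(np.maximum(hi - lo, 0).sum())


class IntervalIndex:
    """Overlap queries against a merged interval set, one array per chromosome."""

    def __init__(self, merged: Mapping[str, np.ndarray]):
        self._merged = {c: np.asarray(a, dtype=np.int64) for c, a in merged.items()}

    @classmethod
    def from_bed(cls, df: pd.DataFrame) -> "IntervalIndex":
        return cls(merge_intervals(df))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any interval on chrom."""
        arr = self._merged.get(chrom)
        if arr is None or arr.size == 0 or end <= start:
            return False
        i = int(np.searchsorted(arr[:, 0], end, side="left"))
        return i > 0 and arr[i - 1, 1] > start

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.overlaps(chrom, pos, pos + 1)

    def chromosomes(self) -> list:
        return sorted(self._merged)
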