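"""Subfamily-discriminative residue and indel scanning of protein MSAs.

Given an HP1-family alignment partitioned into a focal subfamily (e.g. the
Rhino orthologs) and everything else, three operations reproduce the
family-analysis workflow:

* ``condense_alignment`` removes columns covered by fewer than 70% (default)
  of the sequences;
* ``column_discrimination`` scores each column by how specifically its focal
  consensus residue marks the focal subfamily. The score is a deterministic
  frequency contrast — focal frequency minus non-focal frequency of the
  focal consensus residue, in [-1, 1] — standing in for sampling-based
  relief-style weighting: it is reproducible, and on clear-cut columns
  (score 1: residue fixed in the subfamily, absent elsewhere) the two agree
  by construction;
* ``find_subfamily_indels`` reports columns occupied almost exclusively in
  the focal subfamily (insertions) or almost exclusively outside it
  (deletions).

Gaps never count as consensus residues but do count in denominators, so
poorly covered columns are penalized rather than scored spuriously high.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "SubfamilyMSA",
    "ColumnScore",
    "read_labels",
    "condense_alignment",
    "column_discrimination",
    "find_subfamily_indels",
    "column_to_residue_number",
]

GAP_CHARS = {"-", "."}


@dataclass
class SubfamilyMSA:
    names: List[str]
    sequences: List[str]  # aligned rows, equal length
    labels: Dict[str, str]  # sequence name -> subfamily
    focal: str

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        width = len(self.sequences[0])
        if any(len(s) != width for s in self.sequences):
            raise ValueError("alignment rows differ in length")
        missing = [n for n in self.names if n not in self.labels]
        if missing:
            raise ValueError(f"sequences without subfamily label, e.g. {missing[0]}")
        focal_rows = self.focal_rows()
        if not focal_rows:
            raise ValueError(f"focal subfamily {self.focal!r} has no sequences")
        if len(focal_rows) == len(self.sequences):
            raise ValueError("focal subfamily must be a proper subset of the alignment")

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    def focal_rows(self) -> List[int]:
        return [i for i, n in enumerate(self.names) if self.labels[n] == self.focal]

    def other_rows(self) -> List[int]:
        return [i for i, n in enumerate(self.names) if self.labels[n] != self.focal]

    @classmethod
    def from_fasta(cls, path: str | Path, labels: Mapping[str, str],
                   focal: str) -> "SubfamilyMSA":
        """Load an aligned FASTA (or Stockholm via Biopython) with labels."""
        from Bio import SeqIO

        fmt = "stockholm" if str(path).endswith((".sto", ".stk")) else "fasta"
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), fmt):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(names, seqs, dict(labels), focal)


def read_labels(path: str | Path) -> Dict[str, str]:
    """Two-column TSV: sequence id, subfamily."""
    df = pd.read_csv(path, sep="\t", header=None, names=["seq", "subfamily"])
    return dict(zip(df["seq"].astype(str), df["subfamily"].astype(str)))


@dataclass(frozen=True)
class ColumnScore:
    column: int  # 0-based alignment index
    focal_consensus: Optional[str]
    score: float  # focal_freq - other_freq, in [-1, 1]; nan when undefined
    focal_freq: float
    other_freq: float


def condense_alignment(
    msa: SubfamilyMSA, min_coverage: float = 0.70
) -> Tuple[SubfamilyMSA, List[int]]:
    """Drop columns covered by fewer than ``min_coverage`` of the sequences.

    Coverage is the fraction of non-gap rows; the threshold is inclusive
    (a column at exactly min_coverage is kept). Returns the condensed
    alignment and the list of retained original column indices (the old->new
    map: kept[new_index] == old_index).
    """
    if not 0.0 < min_coverage <= 1.0:
        raise ValueError(f"min_coverage must be in (0, 1], got {min_coverage}")
    n = len(msa.sequences)
    kept = [
        c
        for c in range(msa.width)
        if sum(s[c] not in GAP_CHARS for s in msa.sequences) / n >= min_coverage
    ]
    new_seqs = ["".join(s[c] for c in kept) for s in msa.sequences]
    condensed = SubfamilyMSA(list(msa.names), new_seqs, dict(msa.labels), msa.focal)
    return condensed, kept


def column_discrimination(msa: SubfamilyMSA) -> List[ColumnScore]:
    """Score every column for focal-subfamily specificity.

    focal_consensus is the modal non-gap residue among focal rows (ties
    resolved alphabetically); frequencies are taken over all rows of the
    respective partition, gaps included in the denominator. Columns where
    every focal row is a gap have no defined consensus and score nan.
    """
    focal = [msa.sequences[i] for i in msa.focal_rows()]
    other = [msa.sequences[i] for i in msa.other_rows()]
    scores: List[ColumnScore] = []
    for c in range(msa.width):
        residues = Counter(s[c] for s in focal if s[c] not in GAP_CHARS)
        if not residues:
            scores.append(ColumnScore(c, None, float("nan"), 0.0, 0.0))
            continue
        top = max(residues.values())
        consensus = min(r for r, n in residues.items() if n == top)
        focal_freq = residues[consensus] / len(focal)
        other_freq = sum(s[c] == consensus for s in other) / len(other)
        scores.append(
            ColumnScore(c, consensus, focal_freq - other_freq, focal_freq, other_freq)
        )
    return scores


def find_subfamily_indels(
    msa: SubfamilyMSA,
    min_focal_occupancy: float = 0.9,
    max_other_occupancy: float = 0.1,
) -> Dict[str, List[int]]:
    """Columns occupied (non-gap) almost only inside or outside the focal set.

    Returns {"insertions": focal-specific columns, "deletions": columns with
    the opposite polarity (occupied outside, gapped in the focal subfamily)}.
    """
    for v in (min_focal_occupancy, max_other_occupancy):
        if not 0.0 <= v <= 1.0:
            raise ValueError("occupancy thresholds must be in [0, 1]")
    focal = [msa.sequences[i] for i in msa.focal_rows()]
    other = [msa.sequences[i] for i in msa.other_rows()]
    insertions, deletions = [], []
    for c in range(msa.width):
        focal_occ = sum(s[c] not in GAP_CHARS for s in focal) / len(focal)
        other_occ = sum(s[c] not in GAP_CHARS for s in other) / len(other)
        if focal_occ >= min_focal_occupancy and other_occ <= max_other_occupancy:
            insertions.append(c)
        elif other_occ >= min_focal_occupancy and focal_occ <= max_other_occupancy:
            deletions.append(c)
    return {"insertions": insertions, "deletions": deletions}


def column_to_residue_number(
    msa: SubfamilyMSA, seq_name: str, column: int, first_residue: int = 1
) -> Optional[int]:
    """Residue number in an ungapped reference sequence for an alignment column.

    Returns None when the reference carries a gap at that column.
    """
    row = msa.sequences[msa.names.index(seq_name)]
    if row[column] in GAP_CHARS:
        return None
    return first_residue + sum(ch not in GAP_CHARS for ch in row[: column + 1]) - 1
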