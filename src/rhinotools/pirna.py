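"""piRNA quantification and the twofold Rhino-dependence classifier.

Four quantities are computed from categorized piRNA reads:

* per-transposon antisense counts, normalized by the miRNA factor and by
  consensus length (per-kilobase scale);
* locus-unique piRNA-cluster counts: a read counts once for a cluster iff
  the 5' end of every one of its genome hits lies inside that single
  cluster and nowhere else in the genome;
* per-tile log2 fold changes across genotypes over cluster tiles, excluding
  any tile with a zero count in any genotype;
* the binary dependence call — an element is called dependent when its
  antisense piRNA level in the test condition drops to at most half
  (configurable fold) of the control level, boundary inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chip import AlignmentRecord
from .config import PipelineConfig
from .intervals import IntervalIndex, merge_intervals

__all__ = [
    "ClusterDef",
    "DependenceCall",
    "clusters_from_bed",
    "te_antisense_count",
    "cluster_unique_count",
    "tile_pirna_log2fc",
    "classify_dependence",
]


@dataclass
class ClusterDef:
    """A named piRNA cluster: one or more genomic intervals, merged on ingest."""

    name: str
    intervals: Mapping[str, np.ndarray]  # chrom -> merged (N, 2)
    relevant_tissue: str = "both"  # ovary | testis | both

    @classmethod
    def from_intervals(cls, name, triples, relevant_tissue="both") -> "ClusterDef":
        return cls(name, merge_intervals(triples), relevant_tissue)

    def index(self) -> IntervalIndex:
        return IntervalIndex(self.intervals)


def clusters_from_bed(df: pd.DataFrame) -> List[ClusterDef]:
    """Build cluster definitions from a BED DataFrame with a name column."""
    return [
        ClusterDef(str(name), merge_intervals(sub))
        for name, sub in df.groupby("name", sort=True)
    ]


@dataclass(frozen=True)
class DependenceCall:
    element: str
    control_value: float
    test_value: float
    ratio: float  # test / control; nan when control == 0
    call: str  # dependent | independent | unclassifiable


def te_antisense_count(
    assigned_hits: Mapping[str, AlignmentRecord],
    te_lengths: Mapping[str, int],
    norm_factor: float,
    config: Optional[PipelineConfig] = None,
) -> Dict[str, float]:
    """Normalized antisense piRNA count per transposon consensus.

    Only reads assigned antisense to the consensus are counted; the count is
    scaled by the miRNA normalization factor and by 1000/length so elements
    of different size are comparable (reads per kb).
    """
    for name, length in te_lengths.items():
        if length <= 0:
            raise ValueError(f"TE element {name!r} has length {length}")
    raw = {name: 0 for name in te_lengths}
    for rec in assigned_hits.values():
        if rec.strand == "-" and rec.target in raw:
            raw[rec.target] += 1
    return {
        name: raw[name] * norm_factor * 1000.0 / te_lengths[name]
        for name in te_lengths
    }


def cluster_unique_count(
    hits_by_read: Mapping[str, Sequence[AlignmentRecord]],
    clusters: Sequence[ClusterDef],
) -> Dict[str, int]:
    """Count locus-unique cluster piRNAs by 5'-end intersection.

    A read contributes exactly 1 to cluster C iff the strand-aware 5' end of
    every one of its genome hits falls within C's intervals; a read with any
    hit outside all clusters, or with hits in two different clusters,
    contributes nothing.
    """
    indexes = [(c.name, c.index()) for c in clusters]
    counts = {c.name: 0 for c in clusters}
    for read_id, hits in hits_by_read.items():
        homes = set()
        orphan = False
        for h in hits:
            pos = h.five_prime
            hit_homes = {name for name, ix in indexes if ix.contains_point(h.target, pos)}
            if not hit_homes:
                orphan = True
                break
            homes |= hit_homes
        if orphan or len(homes) != 1:
            continue
        counts[homes.pop()] += 1
    return counts


def tile_pirna_log2fc(
    counts_by_genotype: pd.DataFrame,
    control: str,
    cluster_tile_ids: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tile log2 fold change of piRNA counts relative to a control genotype.

    ``counts_by_genotype`` is tiles x genotypes. Analysis is restricted to
    ``cluster_tile_ids`` when given. Tiles with a zero count in ANY genotype
    are excluded and reported with the offending genotype. Returns
    (log2fc table for retained tiles, exclusion report).
    """
    if control not in counts_by_genotype.columns:
        raise ValueError(f"control genotype {control!r} absent from count table")
    table = counts_by_genotype
    if cluster_tile_ids is not None:
        table = table.loc[table.index.intersection(cluster_tile_ids)]
    zero_any = (table == 0).any(axis=1)
    excluded = pd.DataFrame(
        {
            "tile_id": table.index[zero_any],
            "reason": [
                "zero_count_in:" + ",".join(table.columns[(table.loc[t] == 0)])
                for t in table.index[zero_any]
            ],
        }
    )
    kept = table.loc[~zero_any]
    log2fc = np.log2(kept.div(kept[control], axis=0)).drop(columns=[control])
    return log2fc, excluded


def classify_dependence(
    control_counts: Mapping[str, float],
    test_counts: Mapping[str, float],
    config: Optional[PipelineConfig] = None,
) -> List[DependenceCall]:
    """Binary dependence call per element at a twofold-reduction cutoff.

    dependent iff test <= control / dependence_fold (the boundary — exactly
    a twofold reduction — counts as dependent). Elements with a zero control
    value are reported as unclassifiable.
    """
    config = config or PipelineConfig()
    calls: List[DependenceCall] = []
    for element in sorted(control_counts):
        if element not in test_counts:
            raise ValueError(f"element {element!r} missing from test counts")
        c = float(control_counts[element])
        t = float(test_counts[element])
        if c == 0:
            calls.append(DependenceCall(element, c, t, float("nan"), "unclassifiable"))
            continue
        call = "dependent" if t <= c / config.dependence_fold else "independent"
        calls.append(DependenceCall(element, c, t, t / c, call))
    return calls
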