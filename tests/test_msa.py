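"""Subfamily-discriminative column scoring and indel detection."""

import math

import numpy as np
import pytest

from rhinotools.msa import (
    SubfamilyMSA,
    column_discrimination,
    column_to_residue_number,
    condense_alignment,
    find_subfamily_indels,
)


def build_msa(focal_rows, other_rows, focal="Rhino"):
    names = [f"f{i}" for i in range(len(focal_rows))] + [
        f"o{i}" for i in range(len(other_rows))
    ]
    labels = {n: (focal if n.startswith("f") else "HP1") for n in names}
    return SubfamilyMSA(names, list(focal_rows) + list(other_rows), labels, focal)


class TestCondense:
    def test_sixty_percent_column_removed_at_default(self):
        rows = ["A-"] * 6 + ["--"] * 4  # col0: 60% covered, col1: 0%
        msa = build_msa(rows[:2], rows[2:])
        condensed, kept = condense_alignment(msa)
        assert kept == [] and condensed.width == 0

    def test_seventy_percent_boundary_kept(self):
        rows = ["A"] * 7 + ["-"] * 3
        msa = build_msa(rows[:2], rows[2:])
        _, kept = condense_alignment(msa)
        assert kept == [0]

    def test_gapless_alignment_is_identity(self):
        msa = build_msa(["ACD", "ACD"], ["ACE", "GCE"])
        condensed, kept = condense_alignment(msa)
        assert kept == [0, 1, 2] and condensed.sequences == msa.sequences

    def test_column_index_map_points_to_original_columns(self):
        msa = build_msa(["A-C", "A-C"], ["A-C", "--C"])
        _, kept = condense_alignment(msa)
        assert kept == [0, 2]


class TestColumnDiscrimination:
    def test_fully_discriminative_column_scores_one(self):
        msa = build_msa(["G", "G", "G"], ["D", "D", "D"])
        (score,) = column_discrimination(msa)
        assert score.focal_consensus == "G" and score.score == 1.0

    def test_conserved_column_scores_zero(self):
        msa = build_msa(["K", "K"], ["K", "K", "K"])
        (score,) = column_discrimination(msa)
        assert score.score == 0.0

    def test_hand_counted_partial_column(self):
        msa = build_msa(["G", "G", "G", "A"], ["D", "D", "G", "D"])
        (score,) = column_discrimination(msa)
        assert score.focal_consensus == "G"
        assert score.score == pytest.approx(0.75 - 0.25)

    def test_all_gap_focal_column_reported_missing(self):
        msa = build_msa(["-", "-"], ["A", "A"])
        (score,) = column_discrimination(msa)
        assert score.focal_consensus is None and math.isnan(score.score)

    def test_consensus_tie_resolved_alphabetically(self):
        msa = build_msa(["G", "A"], ["D", "D"])
        (score,) = column_discrimination(msa)
        assert score.focal_consensus == "A"

    def test_gaps_count_in_denominator(self):
        msa = build_msa(["G", "G", "-", "-"], ["D", "D"])
        (score,) = column_discrimination(msa)
        assert score.focal_freq == 0.5

    def test_invariant_to_row_order_within_subfamilies(self):
        rng = np.random.default_rng(4)
        focal = ["GAV", "GAC", "GCV"]
        other = ["DAV", "DKV", "GAV", "DAC"]
        base = [(s.focal_consensus, s.score) for s in column_discrimination(build_msa(focal, other))]
        for _ in range(5):
            f = list(rng.permutation(focal))
            o = list(rng.permutation(other))
            assert [(s.focal_consensus, s.score) for s in column_discrimination(build_msa(f, o))] == base

    def test_score_one_iff_fixed_in_focal_and_absent_outside(self):
        fixed = build_msa(["GA", "GA"], ["DA", "DG"])
        scores = column_discrimination(fixed)
        assert scores[0].score == 1.0  # G fixed in focal, absent outside
        assert scores[1].score < 1.0  # A occurs outside the focal subfamily


class TestIndels:
    def test_focal_only_insertion_reported(self):
        msa = build_msa(["AGA", "AGA"], ["A-A", "A-A"])
        found = find_subfamily_indels(msa)
        assert found["insertions"] == [1] and found["deletions"] == []

    def test_uniformly_occupied_column_not_reported(self):
        msa = build_msa(["AGA", "AGA"], ["AGA", "AGA"])
        found = find_subfamily_indels(msa)
        assert found["insertions"] == [] and found["deletions"] == []

    def test_thresholds(self):
        # 19/20 focal occupied (95%), 1/20 other occupied (5%)
        focal = ["A"] * 19 + ["-"]
        other = ["A"] + ["-"] * 19
        msa = build_msa(focal, other)
        assert find_subfamily_indels(msa)["insertions"] == [0]
        assert find_subfamily_indels(msa, 0.99, 0.01)["insertions"] == []

    def test_deletion_polarity(self):
        msa = build_msa(["A-A", "A-A"], ["AGA", "AGA"])
        assert find_subfamily_indels(msa)["deletions"] == [1]


class TestPlantedRecovery:
    def build_family(self, seed=0, n_focal=6, n_other=18, width=60,
                     planted_col=23, planted_insert=41):
        """One planted discriminative column and one focal-only insertion in an
        otherwise-shared alignment with 20% random divergence."""
        rng = np.random.default_rng(seed)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        consensus = alphabet[rng.integers(0, 20, width)]
        rows = []
        for _ in range(n_focal + n_other):
            row = consensus.copy()
            mutate = rng.random(width) < 0.2
            row[mutate] = alphabet[rng.integers(0, 20, mutate.sum())]
            rows.append(row)
        focal_res, other_res = "G", "D"
        if focal_res == consensus[planted_col]:
            other_res = "E"
        for i, row in enumerate(rows):
            row[planted_col] = focal_res if i < n_focal else other_res
            if i >= n_focal:
                row[planted_insert] = "-"
        return build_msa(
            ["".join(r) for r in rows[:n_focal]], ["".join(r) for r in rows[n_focal:]]
        ), planted_col, planted_insert

    def test_planted_column_scores_one_and_is_top_ranked(self):
        msa, planted_col, planted_insert = self.build_family()
        scores = column_discrimination(msa)
        assert scores[planted_col].score == 1.0
        ranked = sorted(
            (s for s in scores if not math.isnan(s.score)),
            key=lambda s: s.score,
            reverse=True,
        )
        assert ranked[0].column == planted_col

    def test_planted_insertion_recovered_exactly(self):
        msa, _, planted_insert = self.build_family()
        assert find_subfamily_indels(msa)["insertions"] == [planted_insert]

    def test_low_coverage_columns_removed_before_scoring(self):
        msa, planted_col, planted_insert = self.build_family()
        condensed, kept = condense_alignment(msa, 0.70)
        # the focal-only insertion covers 6/24 rows (25%) and must be gone
        assert planted_insert not in kept
        assert planted_col in kept


def test_column_to_residue_number_skips_gaps():
    msa = build_msa(["A-CD", "A-CD"], ["AGCD", "AGCD"])
    assert column_to_residue_number(msa, "f0", 0) == 1
    assert column_to_residue_number(msa, "f0", 1) is None
    assert column_to_residue_number(msa, "f0", 2) == 2
    assert column_to_residue_number(msa, "f0", 3, first_residue=20) == 22
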