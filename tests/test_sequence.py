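"""Hydrophobic masks, cluster delineation, segment merging, HCA scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hcafold.sequence import (
    FoldableSegment,
    ProteinSequence,
    delineate_clusters,
    delineate_foldable_segments,
    eligible_clusters,
    filter_soluble_long,
    hca_score,
    hydrophobic_mask,
)

from oracle import brute_force_clusters


def seq(residues: str) -> ProteinSequence:
    return ProteinSequence("t", residues)


class TestHydrophobicMask:
    @pytest.mark.parametrize(
        "residues, mode, expected",
        [
            ("VAP", "plot", [1, 0, 0]),
            ("CACA", "segmentation", [1, 0, 1, 0]),  # cysteine joins the alphabet
            ("CACA", "plot", [0, 0, 0, 0]),
            ("VILMFYW", "plot", [1] * 7),
            ("BZUOX", "plot", [0] * 5),  # non-standard residues never hydrophobic
        ],
    )
    def test_alphabet_membership(self, residues, mode, expected):
        assert hydrophobic_mask(seq(residues), mode) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ProteinSequence("t", "")

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            hydrophobic_mask(seq("VA"), "sideways")


class TestClusterDelineation:
    def test_gap_of_three_joins(self):
        (c,) = delineate_clusters(seq("MAAAV"), "plot")
        assert (c.start, c.end, c.pattern) == (1, 5, "10001")

    def test_gap_of_four_splits(self):
        c1, c2 = delineate_clusters(seq("MAAAAV"), "plot")
        assert (c1.start, c1.end) == (1, 1)
        assert (c2.start, c2.end) == (6, 6)

    def test_proline_splits_regardless_of_gap(self):
        c1, c2 = delineate_clusters(seq("MAPV"), "plot")
        assert (c1.start, c1.end) == (1, 1)
        assert (c2.start, c2.end) == (4, 4)

    def test_no_hydrophobics_empty(self):
        assert delineate_clusters(seq("AAAA"), "plot") == []

    @pytest.mark.parametrize("mode", ["plot", "segmentation"])
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(7)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWYX"))
        for _ in range(2000):
            length = int(rng.integers(1, 201))
            residues = "".join(rng.choice(letters, size=length))
            got = [
                (c.start, c.end, c.pattern)
                for c in delineate_clusters(seq(residues), mode)
            ]
            assert got == brute_force_clusters(residues, mode)

    @given(
        left=st.text(alphabet="AVLPGS", min_size=1, max_size=30),
        right=st.text(alphabet="AVLPGS", min_size=1, max_size=30),
        spacer_len=st.integers(min_value=4, max_value=9),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_concatenation_locality(self, left, right, spacer_len):
        """A >=4-residue non-hydrophobic, non-proline spacer separates the
        cluster lists of the two halves (with shifted coordinates)."""
        spacer = "G" * spacer_len
        combined = left + spacer + right
        try:
            cl_left = delineate_clusters(seq(left), "plot")
        except ValueError:
            return
        cl_right = delineate_clusters(seq(right), "plot")
        shift = len(left) + spacer_len
        cl_all = delineate_clusters(seq(combined), "plot")
        expected = [(c.start, c.end, c.pattern) for c in cl_left] + [
            (c.start + shift, c.end + shift, c.pattern) for c in cl_right
        ]
        assert [(c.start, c.end, c.pattern) for c in cl_all] == expected


class TestEligibility:
    def test_single_and_double_consecutive_removed(self):
        clusters = delineate_clusters(seq("VAAAAAVVAAAAAVAV"), "plot")
        patterns = [c.pattern for c in clusters]
        assert "1" in patterns and "11" in patterns
        kept = eligible_clusters(clusters)
        assert all(c.pattern not in ("1", "11") for c in kept)

    def test_multipart_pattern_kept(self):
        (c,) = delineate_clusters(seq("VAAV"), "plot")
        assert c.pattern == "1001"
        assert eligible_clusters([c]) == [c]

    def test_empty_input(self):
        assert eligible_clusters([]) == []


class TestSegmentDelineation:
    def test_short_linker_merges(self):
        # two eligible clusters separated by 5 residues -> one segment
        s = seq("VVV" + "A" * 5 + "VVV")
        segments = delineate_foldable_segments(s, linker_max=10)
        assert len(segments) == 1
        assert (segments[0].start, segments[0].end) == (1, 11)

    def test_long_linker_splits(self):
        s = seq("VVV" + "AAAAP" * 6 + "VVV")  # 30-residue proline-laced linker
        segments = delineate_foldable_segments(s, linker_max=10)
        assert [(x.start, x.end) for x in segments] == [(1, 3), (34, 36)]

    def test_no_eligible_clusters(self):
        assert delineate_foldable_segments(seq("AAAA")) == []

    def test_linker_max_validated(self):
        with pytest.raises(ValueError):
            delineate_foldable_segments(seq("VVV"), linker_max=0)

    def test_planted_block_recovery_jaccard(self):
        """[disordered flank | dense cluster block | disordered flank]:
        the recovered span overlaps the planted block with Jaccard >= 0.8."""
        rng = np.random.default_rng(11)
        flank_letters = list("AGSTNQDEKR")
        for _ in range(50):
            f1 = int(rng.integers(15, 40))
            block = int(rng.integers(35, 90))
            f2 = int(rng.integers(15, 40))
            flank = lambda n: "".join(
                "P" if rng.random() < 0.15 else str(rng.choice(flank_letters))
                for _ in range(n)
            )
            core = "".join(
                "V" if i % 7 in (0, 3, 4) else "A" for i in range(block)
            )
            s = seq(flank(f1) + core + flank(f2))
            segments = delineate_foldable_segments(s)
            planted = set(range(f1 + 1, f1 + block + 1))
            best = 0.0
            for x in segments:
                span = set(range(x.start, x.end + 1))
                best = max(best, len(span & planted) / len(span | planted))
            assert best >= 0.8


class TestHcaScore:
    def test_deterministic(self):
        s = seq("A" * 10 + "VVVAVVV" + "A" * 10)
        (segment,) = delineate_foldable_segments(s)
        assert hca_score(segment, s) == hca_score(segment, s)

    def test_dense_clusters_score_higher_than_none(self):
        dense = "".join("V" if i % 3 == 0 else "A" for i in range(40))
        s = seq(dense)
        (segment,) = delineate_foldable_segments(s)
        bare = FoldableSegment("t", 1, 40, clusters=())
        assert hca_score(segment, s) > hca_score(bare, s)

    def test_invariant_to_residues_outside_segment(self):
        core = "VVVAVVV"
        s1 = seq("A" * 5 + core + "A" * 5)
        s2 = seq("K" * 5 + core + "R" * 5)
        (g1,) = delineate_foldable_segments(s1)
        (g2,) = delineate_foldable_segments(s2)
        assert hca_score(g1, s1) == hca_score(g2, s2)

    def test_degenerate_spans_rejected(self):
        with pytest.raises(ValueError):
            FoldableSegment("t", 5, 4)  # inverted (zero-length) span
        s = seq("VVVA")
        with pytest.raises(ValueError):
            hca_score(FoldableSegment("t", 1, 10), s)  # beyond the sequence


class TestSolubleLongFilter:
    def _seg(self, length: int, score: float) -> FoldableSegment:
        return FoldableSegment("t", 1, length, clusters=(), hca_score=score)

    @pytest.mark.parametrize(
        "length, score, kept",
        [
            (30, 1.0, False),  # length bound is strict
            (31, 1.0, True),
            (45, -1.0, True),  # window bounds inclusive
            (45, 3.5, True),
            (45, 3.6, False),
            (45, -1.01, False),
        ],
    )
    def test_boundaries(self, length, score, kept):
        out = filter_soluble_long([self._seg(length, score)])
        assert (len(out) == 1) is kept

    def test_unscored_segment_rejected(self):
        with pytest.raises(ValueError):
            filter_soluble_long([FoldableSegment("t", 1, 40)])
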