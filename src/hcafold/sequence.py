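"""Sequence-only layer: hydrophobic clusters, foldable segments, HCA score.

Hydrophobic Cluster Analysis (HCA) reads a protein sequence as a pattern of
strong hydrophobic residues (V, I, L, M, F, Y, W).  Groups of such residues
separated by fewer than four other residues — and not interrupted by a
proline — form *hydrophobic clusters*, which statistically coincide with
regular secondary structure elements of folded domains.  Regions dense in
clusters are *foldable segments* (FS): candidate structured units.  A
per-segment HCA score summarises the density of in-cluster hydrophobic
residues as a log-odds between a globular and a disordered composition
model; segments scoring inside a soluble-domain window (−1..3.5 by default)
and longer than 30 residues are the pipeline's objects of study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "STRONG_HYDROPHOBIC",
    "ProteinSequence",
    "HydrophobicCluster",
    "FoldableSegment",
    "hydrophobic_mask",
    "delineate_clusters",
    "eligible_clusters",
    "delineate_foldable_segments",
    "hca_score",
    "filter_soluble_long",
]

#: Strong hydrophobic amino acids of the HCA "plot" alphabet.
STRONG_HYDROPHOBIC = frozenset("VILMFYW")

#: Segmentation mode integrates cysteine into the hydrophobic alphabet.
SEGMENTATION_ALPHABET = STRONG_HYDROPHOBIC | frozenset("C")

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Two-state composition model behind the HCA score: expected frequency of
# in-cluster strong-hydrophobic residues in globular domains (~1/3) versus
# disordered sequence.  The scale maps the per-residue log-odds (nats) onto
# the conventional score axis where soluble domains fall in [-1, 3.5].
_P_GLOBULAR = 0.335
_P_DISORDER = 0.15
_SCORE_SCALE = 10.0
_LLR_HYDRO = math.log(_P_GLOBULAR / _P_DISORDER)
_LLR_OTHER = math.log((1.0 - _P_GLOBULAR) / (1.0 - _P_DISORDER))


def _check_mode(mode: str) -> frozenset:
    if mode == "plot":
        return STRONG_HYDROPHOBIC
    if mode == "segmentation":
        return SEGMENTATION_ALPHABET
    raise ValueError(f"mode must be 'plot' or 'segmentation', got {mode!r}")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with 1-based residue indexing.

    Letters outside the 20 standard amino acids are normalised to ``X``;
    ``X`` is never hydrophobic and never a proline.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError("empty sequence")
        cleaned = "".join(
            c if c in _STANDARD_AA else "X" for c in self.residues.upper()
        )
        object.__setattr__(self, "residues", cleaned)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]


@dataclass(frozen=True)
class HydrophobicCluster:
    """A maximal group of hydrophobic residues under the HCA separation rule.

    ``pattern`` is the binary string over the span ``[start, end]`` (1-based
    inclusive), with ``1`` marking residues hydrophobic in the active
    alphabet; it starts and ends with ``1`` by construction.
    """

    start: int
    end: int
    pattern: str
    mode: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.pattern):
            raise ValueError("pattern length does not match span")
        if not (self.pattern.startswith("1") and self.pattern.endswith("1")):
            raise ValueError("pattern must start and end with a hydrophobic residue")
        if "0000" in self.pattern:
            raise ValueError("pattern contains a gap of >= 4 non-hydrophobic residues")

    @property
    def n_hydrophobic(self) -> int:
        return self.pattern.count("1")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FoldableSegment:
    """A segment dense in hydrophobic clusters, span 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    clusters: tuple[HydrophobicCluster, ...] = ()
    hca_score: float | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end precedes start")
        prev_end = self.start - 1
        for c in self.clusters:
            if c.start <= prev_end or c.end > self.end:
                raise ValueError("clusters must be sorted, disjoint and inside the span")
            prev_end = c.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def hydrophobic_mask(seq: ProteinSequence, mode: str = "plot") -> list[int]:
    """Binary vector, 1 where the residue is hydrophobic in the active alphabet."""
    alphabet = _check_mode(mode)
    return [1 if c in alphabet else 0 for c in seq.residues]


def delineate_clusters(
    seq: ProteinSequence, mode: str = "plot"
) -> list[HydrophobicCluster]:
    """Partition hydrophobic positions into clusters.

    Two hydrophobic residues belong to the same cluster iff fewer than four
    non-hydrophobic residues separate them and no proline lies strictly
    between them.
    """
    alphabet = _check_mode(mode)
    res = seq.residues
    positions = [i + 1 for i, c in enumerate(res) if c in alphabet]
    clusters: list[HydrophobicCluster] = []
    if not positions:
        return clusters

    def flush(group: list[int]) -> None:
        start, end = group[0], group[-1]
        in_group = set(group)
        pattern = "".join(
            "1" if p in in_group else "0" for p in range(start, end + 1)
        )
        clusters.append(HydrophobicCluster(start, end, pattern, mode))

    group = [positions[0]]
    for pos in positions[1:]:
        prev = group[-1]
        gap = pos - prev - 1
        has_proline = "P" in res[prev : pos - 1]
        if gap >= 4 or has_proline:
            flush(group)
            group = [pos]
        else:
            group.append(pos)
    flush(group)
    return clusters


def eligible_clusters(
    clusters: Iterable[HydrophobicCluster],
) -> list[HydrophobicCluster]:
    """Drop clusters made of only one or two *consecutive* hydrophobic residues.

    Patterns ``1`` and ``11`` are associated with coils rather than regular
    secondary structures and do not count toward foldable segments;
    multi-part patterns such as ``1001`` are kept.
    """
    return [c for c in clusters if c.pattern not in ("1", "11")]


def delineate_foldable_segments(
    seq: ProteinSequence,
    linker_max: int = 10,
    mode: str = "segmentation",
) -> list[FoldableSegment]:
    """Merge eligible clusters separated by short linkers into foldable segments.

    Consecutive eligible clusters whose inter-cluster linker (number of
    residues strictly between them) is shorter than ``linker_max`` join the
    same segment; each segment spans from its first to its last member
    cluster.  Scores are filled in by :func:`hca_score`.
    """
    if linker_max < 1:
        raise ValueError("linker_max must be >= 1")
    eligible = eligible_clusters(delineate_clusters(seq, mode))
    segments: list[FoldableSegment] = []
    if not eligible:
        return segments

    run: list[HydrophobicCluster] = [eligible[0]]
    for c in eligible[1:]:
        linker = c.start - run[-1].end - 1
        if linker < linker_max:
            run.append(c)
        else:
            segments.append(_segment_from_run(seq, run))
            run = [c]
    segments.append(_segment_from_run(seq, run))
    return segments


def _segment_from_run(
    seq: ProteinSequence, run: Sequence[HydrophobicCluster]
) -> FoldableSegment:
    seg = FoldableSegment(
        protein_id=seq.id,
        start=run[0].start,
        end=run[-1].end,
        clusters=tuple(run),
    )
    return FoldableSegment(
        protein_id=seg.protein_id,
        start=seg.start,
        end=seg.end,
        clusters=seg.clusters,
        hca_score=hca_score(seg, seq),
    )


def hca_score(segment: FoldableSegment, seq: ProteinSequence) -> float:
    """Density score of in-cluster hydrophobic residues over the segment.

    The score is the per-residue log-odds of the segment's in-cluster
    hydrophobic frequency under a globular composition model (~33.5% strong
    hydrophobics organised in clusters) against a disordered one (~15%),
    Jeffreys-smoothed for short segments and scaled so that soluble globular
    domains fall in roughly [-1, 3.5]: disordered sequence scores below -1,
    and strongly hydrophobic (e.g. transmembrane) segments score above 3.5.
    Only residues inside the segment contribute.
    """
    length = segment.length
    if length < 1:
        raise ValueError("zero-length segment")
    if segment.end > len(seq):
        raise ValueError("segment extends beyond the sequence")
    n_in_cluster = sum(c.n_hydrophobic for c in segment.clusters)
    f = (n_in_cluster + 0.5) / (length + 1.0)
    return _SCORE_SCALE * (f * _LLR_HYDRO + (1.0 - f) * _LLR_OTHER)


def filter_soluble_long(
    segments: Iterable[FoldableSegment],
    min_len: int = 30,
    score_low: float = -1.0,
    score_high: float = 3.5,
) -> list[FoldableSegment]:
    """Keep long (> min_len, strict) soluble-like (score in window, inclusive) segments."""
    kept = []
    for s in segments:
        if s.hca_score is None:
            raise ValueError(f"segment {s.protein_id}:{s.start}-{s.end} is unscored")
        if s.length > min_len and score_low <= s.hca_score <= score_high:
            kept.append(s)
    return kept
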