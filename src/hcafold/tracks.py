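"""Per-residue evidence tracks: disorder scores and alignment-derived homolog depth.

The pipeline does not run IUPred2 or jackhmmer itself; their outputs are
the interface.  Disorder tracks are IUPred2-style tabular text (position,
residue, score in [0, 1]).  Homolog depth comes from a multiple sequence
alignment (Stockholm or aligned FASTA) containing the query: the depth at a
query position is the number of aligned sequences with a non-gap character
in that column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .sequence import FoldableSegment

__all__ = [
    "DisorderTrack",
    "DepthTrack",
    "read_disorder_track",
    "disorder_coverage",
    "read_alignment_depth",
    "mean_depth",
]

_GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class DisorderTrack:
    protein_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not 0.0 <= s <= 1.0 for s in self.scores):
            raise ValueError("disorder scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class DepthTrack:
    protein_id: str
    depth: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depth):
            raise ValueError("depth must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)


def read_disorder_track(
    path, protein_id: str | None = None, sequence: str | None = None
) -> DisorderTrack:
    """Read an IUPred2-style track: '#'-comments, then position/residue/score.

    Positions must be contiguous from 1; residue letters are cross-checked
    against ``sequence`` when given.
    """
    path = Path(path)
    scores: list[float] = []
    letters: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path.name}: malformed line {line!r}")
            pos, res, score = int(fields[0]), fields[1], float(fields[2])
            if pos != len(scores) + 1:
                raise ValueError(
                    f"{path.name}: positions not contiguous at {pos} "
                    f"(expected {len(scores) + 1})"
                )
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path.name}: score {score} outside [0, 1] at {pos}")
            scores.append(score)
            letters.append(res)
    if not scores:
        raise ValueError(f"{path.name}: empty disorder track")
    if sequence is not None:
        if len(sequence) != len(scores):
            raise ValueError(
                f"{path.name}: track length {len(scores)} != sequence length "
                f"{len(sequence)}"
            )
        for i, (a, b) in enumerate(zip(letters, sequence), start=1):
            if a != "X" and b != "X" and a != b:
                raise ValueError(f"{path.name}: residue mismatch at {i}: {a} vs {b}")
    if protein_id is None:
        protein_id = path.stem
    return DisorderTrack(protein_id, tuple(scores))


def disorder_coverage(
    segment: FoldableSegment, track: DisorderTrack, cutoff: float = 0.5
) -> float:
    """Percent of segment residues with disorder score strictly above cutoff."""
    if segment.end > len(track):
        raise ValueError("track does not cover the segment")
    window = track.scores[segment.start - 1 : segment.end]
    return 100.0 * sum(1 for s in window if s > cutoff) / segment.length


def _sniff_format(path: Path) -> str:
    with path.open() as fh:
        first = fh.readline()
    return "stockholm" if first.startswith("# STOCKHOLM") else "fasta"


def read_alignment_depth(
    alignment_file,
    query_id: str,
    fmt: str | None = None,
    include_query: bool = True,
) -> DepthTrack:
    """Per-position homolog depth of the query from a multiple alignment.

    Alignment columns where the query has a non-gap character map to query
    positions 1..L; the depth at a position is the number of sequences with
    a non-gap character in that column.  The query itself counts by default
    (so the minimum depth is 1); pass ``include_query=False`` to exclude it.
    Insert columns relative to the query ('-' or '.' in the query row) map
    to no position and are skipped.
    """
    path = Path(alignment_file)
    if fmt is None:
        fmt = _sniff_format(path)
    aln = AlignIO.read(str(path), fmt)
    query_rows = [rec for rec in aln if rec.id == query_id or rec.id.split("/")[0] == query_id]
    if not query_rows:
        raise ValueError(f"query {query_id!r} absent from alignment {path.name}")
    query = str(query_rows[0].seq)

    columns = np.array([list(str(rec.seq)) for rec in aln])
    non_gap = ~np.isin(columns, list(_GAP_CHARS))
    depth_per_col = non_gap.sum(axis=0)
    if not include_query:
        depth_per_col = depth_per_col - np.asarray(
            [q not in _GAP_CHARS for q in query], dtype=int
        )
    depth = [int(depth_per_col[j]) for j, q in enumerate(query) if q not in _GAP_CHARS]
    return DepthTrack(query_id, tuple(depth))


def mean_depth(segment: FoldableSegment, track: DepthTrack) -> float:
    """Arithmetic mean of homolog depth over the segment positions."""
    if segment.end > len(track):
        raise ValueError("track does not cover the segment")
    window = track.depth[segment.start - 1 : segment.end]
    return float(np.mean(window))
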