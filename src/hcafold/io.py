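"""FASTA and tabular I/O for the pipeline (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import FoldableSegment, ProteinSequence

__all__ = ["read_fasta", "write_fasta", "segments_to_frame", "write_segments_tsv"]


def read_fasta(path) -> list[ProteinSequence]:
    """Read a multi-record FASTA (line wrapping allowed)."""
    return [
        ProteinSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences: Iterable[ProteinSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def segments_to_frame(segments: Iterable[FoldableSegment]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": s.protein_id,
            "start": s.start,
            "end": s.end,
            "length": s.length,
            "hca_score": s.hca_score,
            "n_clusters": len(s.clusters),
        }
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=["protein_id", "start", "end", "length", "hca_score", "n_clusters"],
    )


def write_segments_tsv(segments: Iterable[FoldableSegment], path) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False, float_format="%.4f")
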