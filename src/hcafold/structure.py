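"""Structural layer: AF2-style PDB models, pLDDT, secondary structure, solvent access.

AlphaFold2 model files store the per-residue confidence (pLDDT, 0-100) in
the B-factor column of every atom of the residue.  This module parses such
single-chain models, exposes the pLDDT track, assigns Kabsch-Sander
secondary structure from the backbone, and computes relative solvent
accessibility (Shrake-Rupley ASA normalised by the Sander-Rost Gly-X-Gly
maxima).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence as _BiotiteProteinSequence

from . import dssp
from .sequence import FoldableSegment, ProteinSequence

__all__ = [
    "MAX_ASA_SANDER_ROST",
    "ResidueRecord",
    "ProteinEntry",
    "read_af2_model",
    "assign_secondary_structure",
    "rss_coverage",
    "compute_rel_asa",
    "accessibility_coverage",
]

#: Maximum accessible surface area (A^2) per residue, computed on extended
#: Gly-X-Gly tripeptides (Rost & Sander 1994), the normalisation scale used
#: by classic DSSP.  X gets the 20-residue mean.
MAX_ASA_SANDER_ROST: dict[str, float] = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}
MAX_ASA_SANDER_ROST["X"] = round(
    sum(v for k, v in MAX_ASA_SANDER_ROST.items() if k != "X") / 20.0, 1
)

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class ResidueRecord:
    """Per-residue state: confidence, backbone coordinates, derived labels."""

    index: int  # 1-based
    aa: str
    plddt: float
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None
    o: np.ndarray | None = None
    ss_label: str = "C"
    rel_asa: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(
                f"pLDDT {self.plddt} outside [0, 100]: not a pLDDT-bearing model"
            )

    @property
    def backbone_complete(self) -> bool:
        return all(x is not None for x in (self.n, self.ca, self.c, self.o))


@dataclass
class ProteinEntry:
    """One protein: sequence, residue records, and the underlying atom array."""

    id: str
    sequence: ProteinSequence
    residues: list[ResidueRecord]
    atoms: struc.AtomArray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.sequence):
            raise ValueError("residue records do not match sequence length")
        for i, r in enumerate(self.residues, start=1):
            if r.index != i:
                raise ValueError("residue indices must be contiguous from 1")

    def plddt_track(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues])


def _three_to_one(res_name: str) -> str:
    try:
        one = _BiotiteProteinSequence.convert_letter_3to1(res_name)
    except KeyError:
        return "X"
    return one if one in "ACDEFGHIKLMNPQRSTVWY" else "X"


def read_af2_model(pdb_file, entry_id: str | None = None) -> ProteinEntry:
    """Parse a single-model, single-chain AF2-style PDB file.

    The sequence is derived from the ATOM records; pLDDT is taken from the
    CA B-factor (a warning is emitted if a residue's atoms disagree).
    B-factors outside [0, 100] are rejected as non-pLDDT models.
    """
    pdbf = PDBFile.read(pdb_file)
    atoms = pdbf.get_structure(model=1, extra_fields=["b_factor"])
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError("no amino-acid ATOM records found")
    chains = np.unique(atoms.chain_id)
    if len(chains) > 1:
        raise ValueError(f"multi-chain model (chains {', '.join(chains)})")

    if entry_id is None:
        entry_id = getattr(pdb_file, "name", None) or "model"
        entry_id = str(entry_id).rsplit("/", 1)[-1].removesuffix(".pdb")

    records: list[ResidueRecord] = []
    letters: list[str] = []
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for idx, (lo, hi) in enumerate(zip(starts[:-1], starts[1:]), start=1):
        res = atoms[lo:hi]
        aa = _three_to_one(res.res_name[0])
        b = res.b_factor
        if np.any(b < 0.0) or np.any(b > 100.0):
            raise ValueError(
                f"B-factor outside [0, 100] at residue {idx}: not a pLDDT-bearing model"
            )
        ca_sel = res.atom_name == "CA"
        plddt = float(b[ca_sel][0]) if np.any(ca_sel) else float(b[0])
        if np.ptp(b) > 0.01:
            warnings.warn(
                f"{entry_id} residue {idx}: atoms disagree on B-factor "
                f"(spread {np.ptp(b):.2f}); using CA",
                stacklevel=2,
            )
        coords = {}
        for name in _BACKBONE_ATOMS:
            sel = res.atom_name == name
            coords[name] = res.coord[sel][0].astype(float) if np.any(sel) else None
        letters.append(aa)
        records.append(
            ResidueRecord(
                index=idx, aa=aa, plddt=plddt,
                n=coords["N"], ca=coords["CA"], c=coords["C"], o=coords["O"],
            )
        )
    sequence = ProteinSequence(entry_id, "".join(letters))
    return ProteinEntry(id=entry_id, sequence=sequence, residues=records, atoms=atoms)


def assign_secondary_structure(entry: ProteinEntry) -> str:
    """Kabsch-Sander labels for every residue; incomplete backbone -> C.

    Also stores the label on each :class:`ResidueRecord`.
    """
    L = len(entry.residues)
    arrs = {}
    for name in ("n", "ca", "c", "o"):
        a = np.full((L, 3), np.nan)
        for i, r in enumerate(entry.residues):
            v = getattr(r, name)
            if v is not None:
                a[i] = v
        arrs[name] = a
    labels = dssp.assign_labels(
        arrs["n"], arrs["ca"], arrs["c"], arrs["o"], entry.sequence.residues
    )
    for r, s in zip(entry.residues, labels):
        r.ss_label = s
    return labels


def rss_coverage(segment: FoldableSegment, ss_labels: str) -> float:
    """Percent of segment residues in regular secondary structure (H,G,I,E,B)."""
    return dssp.rss_coverage(ss_labels, segment.start, segment.end)


def compute_rel_asa(
    entry: ProteinEntry, probe_radius: float = 1.4, point_number: int = 1000
) -> list[float | None]:
    """Relative solvent accessibility per residue.

    Shrake-Rupley ASA over all atoms present (probe 1.4 A), normalised by
    the Sander-Rost Gly-X-Gly maximum of the residue type.  Values may
    exceed 1 and are not clipped.  Residues with no atoms get None and are
    treated as inaccessible downstream.  Results are stored on the records.
    """
    if entry.atoms is None:
        raise ValueError("entry has no atom coordinates")
    atom_sasa = struc.sasa(
        entry.atoms, probe_radius=probe_radius, point_number=point_number
    )
    res_ids = entry.atoms.res_id
    starts = struc.get_residue_starts(entry.atoms, add_exclusive_stop=True)
    per_res: list[float | None] = [None] * len(entry.residues)
    for idx, (lo, hi) in enumerate(zip(starts[:-1], starts[1:])):
        vals = atom_sasa[lo:hi]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        aa = entry.residues[idx].aa
        per_res[idx] = float(vals.sum()) / MAX_ASA_SANDER_ROST[aa]
    for r, v in zip(entry.residues, per_res):
        r.rel_asa = v
    return per_res


def accessibility_coverage(
    segment: FoldableSegment,
    rel_asa_track: list[float | None],
    cutoff: float = 0.36,
) -> float:
    """Percent of segment residues with relative ASA strictly above cutoff."""
    if segment.end > len(rel_asa_track):
        raise ValueError("track does not cover the segment")
    window = rel_asa_track[segment.start - 1 : segment.end]
    n_acc = sum(1 for v in window if v is not None and v > cutoff)
    return 100.0 * n_acc / segment.length
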