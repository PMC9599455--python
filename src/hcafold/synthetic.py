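"""Seeded synthetic fixture bundles with planted ground truth.

Generates everything the pipeline consumes — sequences with controlled
hydrophobic-cluster density, idealized backbone PDB models carrying planted
pLDDT tracks in the B-factor column, IUPred2-style disorder tracks, and
Stockholm alignments with chosen per-column depth — so every stage is
testable without downloads.  One integer seed drives all randomness and is
embedded in every generated file.

The generator emulates the study conditions, not real biophysics: helix
blocks use amphipathic i, i+3/i+4 hydrophobic periodicity, strand blocks
alternate hydrophobic/polar, disordered linkers draw from a hydrophobic-
poor, proline-rich composition, and backbone geometry is ideal (NeRF-built
from canonical bond lengths/angles and per-block dihedrals, with
self-avoiding random-walk coils).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .sequence import ProteinSequence

__all__ = [
    "BlockSpec",
    "FixturePlan",
    "PlantedTruth",
    "make_sequence",
    "make_structure",
    "make_tracks",
    "make_bundle",
    "default_study_plans",
    "make_antiparallel_sheet_coords",
]

BlockKind = Literal["helix", "strand", "coil", "disordered_linker"]

# canonical backbone geometry (Angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_OMEGA = 180.0

_DIHEDRALS: dict[str, tuple[float, float]] = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}

_HYDROPHOBIC_POOL = "VILMF"
_POLAR_POOL = "ADEGKNQRST"
_LINKER_POOL = "GSENDQKRTA"  # proline inserted explicitly

#: default hydrophobic densities per block kind (fraction of residues)
_DEFAULT_DENSITY = {"helix": 3.0 / 7.0, "strand": 0.5, "coil": 0.0, "disordered_linker": 0.0}

#: rigid transform pairing a second, antiparallel ideal 8-residue strand
#: with a first one so that the narrow-pair N-H...O=C energies fall below
#: the Kabsch-Sander bond cutoff; fitted once by minimising those energies
#: over the 6 rigid degrees of freedom (see make_antiparallel_sheet_coords).
_SHEET_ROT = np.array(
    [
        [-0.4611884301, -0.8744163651, 0.1506693480],
        [-0.8117144332, 0.3471920959, -0.4696566060],
        [0.3583642155, -0.3389006772, -0.8698973618],
    ]
)
_SHEET_SHIFT = np.array([24.5880185451, 10.6152837689, 0.6709888905])


@dataclass(frozen=True)
class BlockSpec:
    """One building block of a synthetic protein."""

    kind: BlockKind
    length: int
    hydrophobic_density: float | None = None  # None -> kind default
    plddt: float | tuple[float, float] = 90.0  # constant or (start, end) ramp
    disorder: float = 0.5
    depth: int = 1
    #: backbone geometry override; None follows ``kind``.  A helix-patterned
    #: sequence built with "coil" geometry emulates a foldable sequence whose
    #: model is unfolded (the full-VL situation).
    geometry: BlockKind | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("block length must be >= 1")
        d = self.density
        if not 0.0 <= d <= 1.0:
            raise ValueError("hydrophobic density must lie in [0, 1]")
        lo, hi = self.plddt_bounds
        if not (0.0 <= lo <= 100.0 and 0.0 <= hi <= 100.0):
            raise ValueError("pLDDT levels must lie in [0, 100]")
        if not 0.0 <= self.disorder <= 1.0:
            raise ValueError("disorder level must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("alignment depth must be >= 1")

    @property
    def density(self) -> float:
        if self.hydrophobic_density is not None:
            return self.hydrophobic_density
        return _DEFAULT_DENSITY[self.kind]

    @property
    def structured(self) -> bool:
        return self.kind in ("helix", "strand")

    @property
    def plddt_bounds(self) -> tuple[float, float]:
        if isinstance(self.plddt, tuple):
            return self.plddt
        return (self.plddt, self.plddt)

    def plddt_track(self) -> np.ndarray:
        lo, hi = self.plddt_bounds
        return np.linspace(lo, hi, self.length)


@dataclass(frozen=True)
class FixturePlan:
    """A seeded, ordered list of blocks defining one synthetic protein."""

    protein_id: str
    seed: int
    blocks: tuple[BlockSpec, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("plan needs at least one block")

    @property
    def length(self) -> int:
        return sum(b.length for b in self.blocks)

    def block_spans(self) -> list[tuple[int, int, BlockSpec]]:
        """1-based inclusive span of every block."""
        spans = []
        pos = 1
        for b in self.blocks:
            spans.append((pos, pos + b.length - 1, b))
            pos += b.length
        return spans


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded at generation time."""

    protein_id: str
    structured_spans: tuple[tuple[int, int], ...]  # maximal runs of structured blocks
    plddt: tuple[float, ...]
    disorder_level: tuple[float, ...]
    depth: tuple[int, ...]


def _rng(plan: FixturePlan, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([plan.seed & 0x7FFFFFFF, salt]))


def _block_letters(block: BlockSpec, rng: np.random.Generator) -> str:
    """Residues for one block at its hydrophobic density target.

    Structured blocks place hydrophobics on a periodic scaffold (i, i+3,
    i+4 of each helical heptad; alternating positions of strands) thinned
    or densified to the requested density; linkers place at most isolated
    hydrophobics and sprinkle prolines so no eligible cluster can form.
    """
    L = block.length
    target = block.density
    letters = []
    if block.kind == "helix":
        scaffold = [i for i in range(L) if i % 7 in (0, 3, 4)]
    elif block.kind == "strand":
        scaffold = [i for i in range(L) if i % 2 == 0]
    else:
        scaffold = []

    if block.structured:
        n_want = int(round(target * L))
        if n_want <= len(scaffold):
            chosen = set(
                scaffold
                if n_want == len(scaffold)
                else sorted(rng.choice(scaffold, size=n_want, replace=False))
            )
        else:
            extra = [i for i in range(L) if i not in scaffold]
            add = rng.choice(extra, size=n_want - len(scaffold), replace=False)
            chosen = set(scaffold) | set(int(i) for i in add)
        for i in range(L):
            if i in chosen:
                letters.append(str(rng.choice(list(_HYDROPHOBIC_POOL))))
            else:
                letters.append(str(rng.choice(list(_POLAR_POOL))))
    else:
        n_want = int(round(target * L))
        # isolated hydrophobics only: at least 4 residues apart
        positions: list[int] = []
        candidates = list(range(L))
        rng.shuffle(candidates)
        for i in candidates:
            if len(positions) >= n_want:
                break
            if all(abs(i - p) > 4 for p in positions):
                positions.append(i)
        chosen = set(positions)
        for i in range(L):
            if i in chosen:
                letters.append(str(rng.choice(list(_HYDROPHOBIC_POOL))))
            elif rng.random() < 0.12:
                letters.append("P")
            else:
                letters.append(str(rng.choice(list(_LINKER_POOL))))
    return "".join(letters)


def make_sequence(plan: FixturePlan) -> tuple[ProteinSequence, PlantedTruth]:
    """Deterministically generate the sequence and its planted truth."""
    rng = _rng(plan, salt=1)
    parts = [_block_letters(b, rng) for b in plan.blocks]
    seq = ProteinSequence(plan.protein_id, "".join(parts))

    structured: list[tuple[int, int]] = []
    for start, end, b in plan.block_spans():
        if b.structured:
            if structured and structured[-1][1] + 1 == start:
                structured[-1] = (structured[-1][0], end)
            else:
                structured.append((start, end))

    plddt = np.concatenate([b.plddt_track() for b in plan.blocks])
    dis = np.concatenate([np.full(b.length, b.disorder) for b in plan.blocks])
    dep = np.concatenate([np.full(b.length, b.depth, dtype=int) for b in plan.blocks])
    truth = PlantedTruth(
        protein_id=plan.protein_id,
        structured_spans=tuple(structured),
        plddt=tuple(float(x) for x in plddt),
        disorder_level=tuple(float(x) for x in dis),
        depth=tuple(int(x) for x in dep),
    )
    return seq, truth


# ---------------------------------------------------------------------------
# backbone geometry


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position of atom D from A-B-C with C-D bond, B-C-D angle (deg),
    A-B-C-D torsion (deg)."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi_psi: Sequence[tuple[float, float]], with_cb: bool = False
) -> dict[str, np.ndarray]:
    """Ideal-geometry backbone (N, CA, C, O arrays of shape (L, 3)) from
    per-residue (phi, psi) in degrees; phi of the first residue is unused.
    With ``with_cb`` an ideal beta carbon is added for every residue."""
    L = len(phi_psi)
    n = np.zeros((L, 3))
    ca = np.zeros((L, 3))
    c = np.zeros((L, 3))
    n[0] = [0.0, 0.0, 0.0]
    ca[0] = [_B_N_CA, 0.0, 0.0]
    ang = math.radians(_A_N_CA_C)
    c[0] = ca[0] + [_B_CA_C * math.cos(math.pi - ang), _B_CA_C * math.sin(math.pi - ang), 0.0]
    for i in range(1, L):
        psi_prev = phi_psi[i - 1][1]
        n[i] = _place_atom(n[i - 1], ca[i - 1], c[i - 1], _B_C_N, _A_CA_C_N, psi_prev)
        ca[i] = _place_atom(ca[i - 1], c[i - 1], n[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        c[i] = _place_atom(c[i - 1], n[i], ca[i], _B_CA_C, _A_N_CA_C, phi_psi[i][0])
    o = np.zeros((L, 3))
    for i in range(L):
        # carbonyl O opposite the next amide N: torsion psi + 180
        o[i] = _place_atom(n[i], ca[i], c[i], _B_C_O, _A_CA_C_O, phi_psi[i][1] + 180.0)
    out = {"N": n, "CA": ca, "C": c, "O": o}
    if with_cb:
        cb = np.zeros((L, 3))
        for i in range(L):
            # ideal tetrahedral CB, L-configuration
            cb[i] = _place_atom(c[i], n[i], ca[i], 1.526, 110.4, -122.6)
        out["CB"] = cb
    return out


def _coil_phi_psi(rng: np.random.Generator) -> tuple[float, float]:
    """Broad coil region of the Ramachandran map (extended / PPII-like)."""
    return (float(rng.uniform(-160.0, -60.0)), float(rng.uniform(60.0, 180.0)))


def _plan_phi_psi(
    plan: FixturePlan, rng: np.random.Generator
) -> list[tuple[float, float]]:
    phi_psi: list[tuple[float, float]] = []
    for b in plan.blocks:
        geometry = b.geometry or b.kind
        if geometry in _DIHEDRALS:
            phi_psi.extend([_DIHEDRALS[geometry]] * b.length)
        else:
            phi_psi.extend(_coil_phi_psi(rng) for _ in range(b.length))
    return phi_psi


def _has_clash(
    coords: dict[str, np.ndarray],
    coil_mask: np.ndarray,
    min_dist: float = 2.5,
    structured_min_dist: float = 2.0,
) -> bool:
    """Any non-bonded atom pair closer than the tolerance (residues >= 2 apart).

    The self-avoidance criterion (2.5 A) applies to pairs involving a
    random-walk coil residue; pairs between two ideal-geometry residues get
    a looser floor, since their near-contacts at block junctions are fixed
    by construction, not resampling.
    """
    pts = np.concatenate([coords[k] for k in ("N", "CA", "C", "O")])
    L = coords["N"].shape[0]
    res_idx = np.concatenate([np.arange(L)] * 4)
    coil = np.concatenate([coil_mask] * 4)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    far_in_seq = np.abs(res_idx[:, None] - res_idx[None, :]) >= 2
    involves_coil = coil[:, None] | coil[None, :]
    cutoff2 = np.where(involves_coil, min_dist**2, structured_min_dist**2)
    return bool(np.any((d2 < cutoff2) & far_in_seq))


def make_structure(plan: FixturePlan, sequence: ProteinSequence) -> str:
    """Idealized backbone PDB text with the planted pLDDT in the B-factor column.

    Helix and strand blocks get ideal dihedrals; coil blocks draw random
    extended dihedrals, resampled (up to 200 attempts) until no two
    non-bonded atoms come within 2.5 Angstrom.
    """
    if len(sequence) != plan.length:
        raise ValueError("sequence does not match the plan")
    rng = _rng(plan, salt=2)
    coil_mask = np.concatenate(
        [
            np.full(b.length, (b.geometry or b.kind) not in _DIHEDRALS)
            for b in plan.blocks
        ]
    )
    for _attempt in range(200):
        phi_psi = _plan_phi_psi(plan, rng)
        coords = build_backbone(phi_psi)
        if not _has_clash(coords, coil_mask):
            break
    else:
        raise RuntimeError(f"{plan.protein_id}: could not build a clash-free backbone")

    plddt = np.concatenate([b.plddt_track() for b in plan.blocks])
    return _coords_to_pdb(sequence, coords, plddt, header=f"seed {plan.seed}")


def _coords_to_pdb(
    sequence: ProteinSequence,
    coords: dict[str, np.ndarray],
    plddt: np.ndarray,
    header: str = "",
) -> str:
    from biotite.sequence import ProteinSequence as _BPS

    L = len(sequence)
    atom_names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
    if "CB" in coords:
        atom_names.append(("CB", "C"))
    per_res = len(atom_names)
    atoms = struc.AtomArray(L * per_res)
    b_factors = []
    k = 0
    keep = np.ones(L * per_res, dtype=bool)
    for i in range(L):
        res3 = _BPS.convert_letter_1to3(sequence[i + 1]).upper()
        for name, elem in atom_names:
            if name == "CB" and (res3 == "GLY" or np.any(~np.isfinite(coords[name][i]))):
                keep[k] = False
            atoms.coord[k] = coords[name][i]
            atoms.chain_id[k] = "A"
            atoms.res_id[k] = i + 1
            atoms.res_name[k] = res3
            atoms.atom_name[k] = name
            atoms.element[k] = elem
            atoms.hetero[k] = False
            b_factors.append(round(float(plddt[i]), 2))
            k += 1
    atoms.set_annotation("b_factor", np.array(b_factors))
    atoms = atoms[keep]
    pdbf = PDBFile()
    pdbf.set_structure(atoms)
    if header:
        pdbf.lines.insert(0, f"REMARK 250 {header}")
    return "\n".join(pdbf.lines) + "\n"


def make_antiparallel_sheet_coords(n_res: int = 8) -> dict[str, np.ndarray]:
    """Two ideal antiparallel strands of ``n_res`` residues each, H-bond paired.

    The second strand is a rigidly transformed copy of the first, placed so
    the antiparallel narrow-pair hydrogen bonds form (the transform was
    fitted for 8-residue strands, the default); the combined chain has a
    deliberate break between residues n_res and n_res + 1.  Returned arrays
    have shape (2 * n_res, 3).
    """
    single = build_backbone([_DIHEDRALS["strand"]] * n_res)
    out: dict[str, np.ndarray] = {}
    for key in ("N", "CA", "C", "O"):
        a = single[key]
        b = a @ _SHEET_ROT.T + _SHEET_SHIFT
        out[key] = np.concatenate([a, b])
    return out


# ---------------------------------------------------------------------------
# tracks


def make_tracks(
    plan: FixturePlan, sequence: ProteinSequence, noise_sd: float = 0.05
) -> tuple[str, str]:
    """IUPred2-style disorder TSV and Stockholm alignment for one protein.

    Disorder scores are sampled around each block's planted level (Gaussian,
    sd ``noise_sd``) and clipped to the side of the 0.5 decision cutoff the
    planted level sits on, so a block's disorder coverage is exact by
    construction (level > 0.5 gives 100%, level <= 0.5 gives 0%).  The
    alignment contains max-depth rows; a block planted at depth k leaves
    exactly k rows (query included) ungapped over its columns.
    """
    rng = _rng(plan, salt=3)
    scores: list[float] = []
    for b in plan.blocks:
        lo_clip, hi_clip = (0.55, 1.0) if b.disorder > 0.5 else (0.0, 0.5)
        raw = rng.normal(b.disorder, noise_sd, size=b.length)
        scores.extend(np.clip(raw, lo_clip, hi_clip))
    # IUPred2-style: position, residue, score
    lines = [f"# synthetic disorder track, seed {plan.seed}"]
    for i, s in enumerate(scores, start=1):
        lines.append(f"{i}\t{sequence[i]}\t{s:.4f}")
    disorder_text = "\n".join(lines) + "\n"

    max_depth = max(b.depth for b in plan.blocks)
    rows: list[str] = []
    query = sequence.residues
    rows.append(query)
    for r in range(2, max_depth + 1):
        chars = []
        for start, end, b in plan.block_spans():
            cover = r <= b.depth
            seg = query[start - 1 : end]
            chars.append(seg if cover else "-" * b.length)
        rows.append("".join(chars))
    names = [plan.protein_id] + [
        f"homolog{r:04d}" for r in range(2, max_depth + 1)
    ]
    width = max(len(n) for n in names) + 2
    sto = ["# STOCKHOLM 1.0", f"#=GF CC synthetic alignment, seed {plan.seed}"]
    sto += [f"{n:<{width}}{s}" for n, s in zip(names, rows)]
    sto.append("//")
    return disorder_text, "\n".join(sto) + "\n"


# ---------------------------------------------------------------------------
# bundles


def make_bundle(
    plans: Iterable[FixturePlan], outdir
) -> dict[str, PlantedTruth]:
    """Write FASTA + per-protein PDB/disorder/alignment files; return truths."""
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    (outdir / "alignments").mkdir(exist_ok=True)
    truths: dict[str, PlantedTruth] = {}
    sequences = []
    for plan in plans:
        seq, truth = make_sequence(plan)
        truths[plan.protein_id] = truth
        sequences.append(seq)
        (outdir / "models" / f"{plan.protein_id}.pdb").write_text(
            make_structure(plan, seq)
        )
        dis, sto = make_tracks(plan, seq)
        (outdir / "tracks" / f"{plan.protein_id}.tsv").write_text(dis)
        (outdir / "alignments" / f"{plan.protein_id}.sto").write_text(sto)
    from .io import write_fasta

    write_fasta(sequences, outdir / "sequences.fasta")
    return truths


def default_study_plans(
    n_proteins: int, seed: int, vl_fraction: float = 0.5
) -> list[FixturePlan]:
    """Plans emulating the study conditions at desk scale.

    Each protein is [disordered linker | foldable domain | disordered
    linker].  Domains are either confidently folded (full-VH-like: pLDDT
    92-98, helical geometry, low disorder, deep alignment) or low-confidence
    (full-VL-like: pLDDT 30-48, shallow alignment, variable disorder);
    most VL domains keep a foldable sequence but get random-coil model
    geometry — the foldable-but-unfolded situation the taxonomy exists to
    expose — while a minority keep folded geometry (hidden-order-like).
    VL domains are shorter on average than VH ones, mirroring the published
    mean segment lengths (about 61 vs 92 residues).
    """
    master = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 99]))
    plans = []
    for i in range(n_proteins):
        pid = f"SYN{i:04d}"
        is_vl = master.random() < vl_fraction
        if is_vl:
            dom_len = int(master.integers(45, 81))
            plddt = float(master.uniform(30.0, 48.0))
            disorder = float(master.choice([0.15, 0.8]))
            depth = int(master.choice([3, 12, 40]))
            geometry = "coil" if master.random() < 0.7 else "helix"
            dom = BlockSpec(
                "helix", dom_len, plddt=plddt, disorder=disorder, depth=depth,
                geometry=geometry,
            )
        else:
            dom_len = int(master.integers(68, 131))
            plddt = float(master.uniform(92.0, 98.0))
            dom = BlockSpec("helix", dom_len, plddt=plddt, disorder=0.12,
                            depth=int(master.choice([40, 120])))
        blocks = [
            BlockSpec(
                "disordered_linker",
                int(master.integers(22, 40)),
                plddt=float(master.uniform(25.0, 45.0)),
                disorder=0.85,
                depth=2,
            ),
            dom,
            BlockSpec(
                "disordered_linker",
                int(master.integers(22, 40)),
                plddt=float(master.uniform(25.0, 45.0)),
                disorder=0.85,
                depth=2,
            ),
        ]
        plans.append(
            FixturePlan(protein_id=pid, seed=int(master.integers(0, 2**31 - 1)), blocks=tuple(blocks))
        )
    return plans
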