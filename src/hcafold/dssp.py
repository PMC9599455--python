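"""Kabsch–Sander secondary-structure assignment from backbone coordinates.

Implements the classic electrostatic hydrogen-bond model: the amide
hydrogen is reconstructed from the preceding peptide plane, an H-bond is
called when the Coulomb interaction energy between the N-H dipole of the
donor and the C=O dipole of the acceptor falls below -0.5 kcal/mol, and
helices (G/H/I), beta bridges/ladders (B/E), turns (T) and bends (S) are
derived from the resulting bond pattern.  Residues not covered by any
pattern, or lacking a complete backbone, are coils (C).
"""

from __future__ import annotations

import numpy as np

__all__ = ["assign_labels", "RSS_CLASSES", "rss_coverage"]

#: DSSP classes counted as regular secondary structure.
RSS_CLASSES = frozenset("HGIEB")

_Q = 0.084 * 332.0  # kcal/mol * Angstrom; partial charges times Coulomb factor
_HBOND_E_CUTOFFF = -0.5  # kcal/mol
_CA_PREFILTER = 9.0  # Angstrom; pairs farther apart cannot H-bond
_PEPTIDE_BOND_MAX = 2.5  # Angstrom; C(i)-N(i+1) beyond this is a chain break
_NH_BOND = 1.01  # Angstrom, amide N-H bond length
_MIN_E = -9.9  # clamp for near-contact geometries, as in classic DSSP


def _hydrogen_positions(
    n: np.ndarray, c: np.ndarray, o: np.ndarray, connected: np.ndarray, is_pro: np.ndarray
) -> np.ndarray:
    """Amide H of residue i along the C(i-1)->O(i-1) opposite direction.

    The first residue of a chain (or any residue after a break) has no
    preceding carbonyl and gets no H; proline has no amide hydrogen.
    Positions without an H are NaN.
    """
    L = n.shape[0]
    h = np.full((L, 3), np.nan)
    for i in range(1, L):
        if not connected[i] or is_pro[i]:
            continue
        d = c[i - 1] - o[i - 1]
        norm = np.linalg.norm(d)
        if norm > 0 and np.all(np.isfinite(d)) and np.all(np.isfinite(n[i])):
            h[i] = n[i] + d / norm * _NH_BOND
    return h


def _hbond_matrix(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, o: np.ndarray, h: np.ndarray
) -> np.ndarray:
    """HB[d, a] = True iff N-H of residue d donates to C=O of residue a."""
    L = n.shape[0]
    hb = np.zeros((L, L), dtype=bool)
    donor_ok = np.all(np.isfinite(h), axis=1) & np.all(np.isfinite(n), axis=1)
    acceptor_ok = np.all(np.isfinite(c), axis=1) & np.all(np.isfinite(o), axis=1)
    ca_ok = np.all(np.isfinite(ca), axis=1)
    for d in range(L):
        if not donor_ok[d]:
            continue
        for a in range(L):
            if a == d or not acceptor_ok[a]:
                continue
            if ca_ok[d] and ca_ok[a] and np.linalg.norm(ca[d] - ca[a]) > _CA_PREFILTER:
                continue
            r_on = np.linalg.norm(o[a] - n[d])
            r_ch = np.linalg.norm(c[a] - h[d])
            r_oh = np.linalg.norm(o[a] - h[d])
            r_cn = np.linalg.norm(c[a] - n[d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                e = _MIN_E
            else:
                e = _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
                e = max(e, _MIN_E)
            if e < _HBOND_E_CUTOFFF:
                hb[d, a] = True
    return hb


def _bend_flags(ca: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """S-bend where the virtual CA chain kinks by more than 70 degrees."""
    L = ca.shape[0]
    bend = np.zeros(L, dtype=bool)
    for i in range(2, L - 2):
        if not (valid[i - 2] and valid[i] and valid[i + 2]):
            continue
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            continue
        cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        if np.degrees(np.arccos(cosang)) > 70.0:
            bend[i] = True
    return bend


def assign_labels(
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    o: np.ndarray,
    aa: str,
) -> str:
    """Assign one of H, G, I, E, B, T, S, C to every residue.

    Parameters are (L, 3) float arrays of backbone atom coordinates in
    Angstrom, NaN where an atom is absent, and the one-letter sequence
    (used only to deny proline an amide hydrogen).  Chains shorter than 3
    complete residues are all-coil.
    """
    L = len(aa)
    for arr in (n, ca, c, o):
        if arr.shape != (L, 3):
            raise ValueError("coordinate arrays must be (L, 3)")
    labels = np.full(L, "C", dtype="U1")
    complete = (
        np.all(np.isfinite(n), axis=1)
        & np.all(np.isfinite(ca), axis=1)
        & np.all(np.isfinite(c), axis=1)
        & np.all(np.isfinite(o), axis=1)
    )
    if int(complete.sum()) < 3:
        return "".join(labels)

    # peptide connectivity; a break also severs H placement and turn/bridge context
    connected = np.zeros(L, dtype=bool)
    for i in range(1, L):
        if complete[i - 1] and complete[i]:
            connected[i] = np.linalg.norm(c[i - 1] - n[i]) < _PEPTIDE_BOND_MAX

    is_pro = np.array([a == "P" for a in aa])
    h = _hydrogen_positions(n, c, o, connected, is_pro)
    hb = _hbond_matrix(n, ca, c, o, h)

    # n-turns: C=O of i accepts from N-H of i+n
    turns = {ln: np.zeros(L, dtype=bool) for ln in (3, 4, 5)}
    for ln in (3, 4, 5):
        for i in range(L - ln):
            if hb[i + ln, i] and all(connected[k] for k in range(i + 1, i + ln + 1)):
                turns[ln][i] = True

    # bridges, |i-j| >= 3
    par = np.zeros((L, L), dtype=bool)
    anti = np.zeros((L, L), dtype=bool)
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            p = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            a_ = (hb[j, i] and hb[i, j]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if p:
                par[i, j] = par[j, i] = True
            if a_:
                anti[i, j] = anti[j, i] = True

    # ladders: runs of consecutive bridges of one type
    strand = np.zeros(L, dtype=bool)
    bridge = np.zeros(L, dtype=bool)
    seen = set()
    for i in range(L):
        for j in range(i + 3, L):
            for mat, step in ((par, 1), (anti, -1)):
                if not mat[i, j] or (i, j, step) in seen:
                    continue
                ii, jj = i, j
                members_i, members_j = [ii], [jj]
                while (
                    ii + 1 < L
                    and 0 <= jj + step < L
                    and mat[ii + 1, jj + step]
                ):
                    ii += 1
                    jj += step
                    seen.add((ii, jj, step) if step == 1 else (ii, jj, step))
                    members_i.append(ii)
                    members_j.append(jj)
                seen.add((i, j, step))
                target = strand if len(members_i) > 1 else bridge
                for k in members_i + members_j:
                    target[k] = True

    # helices from two consecutive n-turns
    helix = {ln: np.zeros(L, dtype=bool) for ln in (3, 4, 5)}
    for ln in (3, 4, 5):
        t = turns[ln]
        for i in range(1, L - ln):
            if t[i] and t[i - 1]:
                helix[ln][i : i + ln] = True

    in_turn = np.zeros(L, dtype=bool)
    for ln in (3, 4, 5):
        t = turns[ln]
        for i in range(L - ln):
            if t[i]:
                in_turn[i + 1 : i + ln] = True

    bend = _bend_flags(ca, complete)

    # priority: H, E, B, G, I, T, S
    for i in range(L):
        if not complete[i]:
            labels[i] = "C"
        elif helix[4][i]:
            labels[i] = "H"
        elif strand[i]:
            labels[i] = "E"
        elif bridge[i]:
            labels[i] = "B"
        elif helix[3][i]:
            labels[i] = "G"
        elif helix[5][i]:
            labels[i] = "I"
        elif in_turn[i]:
            labels[i] = "T"
        elif bend[i]:
            labels[i] = "S"
    return "".join(labels)


def rss_coverage(labels: str, start: int, end: int) -> float:
    """Percent of residues in [start, end] (1-based inclusive) in RSS classes."""
    if not 1 <= start <= end <= len(labels):
        raise ValueError("segment outside the label track")
    window = labels[start - 1 : end]
    return 100.0 * sum(1 for s in window if s in RSS_CLASSES) / len(window)
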