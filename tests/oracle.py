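"""Independent brute-force oracle for hydrophobic-cluster delineation.

Enumerates all pairs of hydrophobic positions and applies the separation
rules directly (union-find), with no reuse of the scan implementation.
"""

from __future__ import annotations

PLOT = frozenset("VILMFYW")
SEGMENTATION = PLOT | {"C"}


def brute_force_clusters(residues: str, mode: str) -> list[tuple[int, int, str]]:
    """(start, end, pattern) triples, 1-based inclusive, in sequence order."""
    alphabet = PLOT if mode == "plot" else SEGMENTATION
    pos = [i + 1 for i, ch in enumerate(residues) if ch in alphabet]
    k = len(pos)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    # prefix counts for O(1) pair queries
    n = len(residues)
    hydro_prefix = [0] * (n + 1)
    pro_prefix = [0] * (n + 1)
    for i, ch in enumerate(residues):
        hydro_prefix[i + 1] = hydro_prefix[i] + (ch in alphabet)
        pro_prefix[i + 1] = pro_prefix[i] + (ch == "P")

    for a in range(k):
        for b in range(a + 1, k):
            i, j = pos[a], pos[b]
            total_between = j - i - 1
            hydro_between = hydro_prefix[j - 1] - hydro_prefix[i]
            non_hydro = total_between - hydro_between
            proline = (pro_prefix[j - 1] - pro_prefix[i]) > 0
            if non_hydro < 4 and not proline:
                union(a, b)

    groups: dict[int, list[int]] = {}
    for a in range(k):
        groups.setdefault(find(a), []).append(pos[a])
    out = []
    for members in groups.values():
        members.sort()
        start, end = members[0], members[-1]
        mset = set(members)
        pattern = "".join("1" if p in mset else "0" for p in range(start, end + 1))
        out.append((start, end, pattern))
    out.sort()
    return out
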