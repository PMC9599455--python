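"""Confidence classing, threshold calibration, the binary-tree taxonomy,
and proteome-level accounting.

A foldable segment whose residues all have pLDDT <= 50 is *full-VL* (very
low confidence along its entire length); one whose residues all have
pLDDT > 90 is *full-VH*; anything else is MIXED and enters neither tree.
Full-VH segments — confidently folded by construction — calibrate one-sided
feature thresholds covering at least 95% of them; those thresholds then
route both full-VH and full-VL segments through a fixed four-level binary
tree (RSS presence, accessibility, disorder, known homologs) that separates
well-folded domains from candidates for conditional or hidden order.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence import FoldableSegment

__all__ = [
    "ConfidenceClass",
    "SegmentFeatures",
    "FeatureThresholds",
    "TaxonomyTree",
    "confidence_class",
    "calibrate_thresholds",
    "paper_default_thresholds",
    "build_tree",
    "summarize_proteome",
]

logger = logging.getLogger(__name__)

#: pLDDT bounds of the confidence classes (VL: <= 50, VH: > 90).
PLDDT_VL_MAX = 50.0
PLDDT_VH_MIN = 90.0


class ConfidenceClass(enum.Enum):
    FULL_VL = "full-VL"
    FULL_VH = "full-VH"
    MIXED = "mixed"


@dataclass(frozen=True)
class SegmentFeatures:
    """The four per-segment descriptors driving the taxonomy."""

    rss_pct: float | None = None
    access_pct: float | None = None
    disorder_pct: float | None = None
    mean_depth: float | None = None

    def complete(self) -> bool:
        return all(
            v is not None
            for v in (self.rss_pct, self.access_pct, self.disorder_pct, self.mean_depth)
        )


@dataclass(frozen=True)
class FeatureThresholds:
    """Cutoffs on the tree edges.

    ``disorder_max`` and ``access_max`` are upper bounds on the folded side
    (segment passes with value <= threshold); ``depth_min`` is a lower
    bound (passes with value > threshold).  RSS is always split on
    presence/absence.  Defaults are the published values.
    """

    disorder_max: float = 33.4
    access_max: float = 82.9
    depth_min: float = 23.5
    provenance: str = "paper_defaults"


def paper_default_thresholds() -> FeatureThresholds:
    return FeatureThresholds()


def confidence_class(
    segment: FoldableSegment,
    plddt_track: Sequence[float],
    vl_max: float = PLDDT_VL_MAX,
    vh_min: float = PLDDT_VH_MIN,
) -> ConfidenceClass:
    """FULL_VL iff every residue pLDDT <= vl_max; FULL_VH iff all > vh_min."""
    if segment.end > len(plddt_track):
        raise ValueError("pLDDT track does not cover the segment")
    window = plddt_track[segment.start - 1 : segment.end]
    if all(p <= vl_max for p in window):
        return ConfidenceClass.FULL_VL
    if all(p > vh_min for p in window):
        return ConfidenceClass.FULL_VH
    return ConfidenceClass.MIXED


def _upper_coverage_bound(values: np.ndarray, coverage: float) -> float:
    """Smallest observed value v with at least `coverage` of values <= v."""
    srt = np.sort(values)
    k = math.ceil(coverage * srt.size)
    return float(srt[k - 1])


def _lower_coverage_bound(values: np.ndarray, coverage: float) -> float:
    """Largest observed value v with at least `coverage` of values >= v."""
    srt = np.sort(values)[::-1]
    k = math.ceil(coverage * srt.size)
    return float(srt[k - 1])


def calibrate_thresholds(
    full_vh_features: Sequence[SegmentFeatures],
    coverage: float = 0.95,
    decimals: int | None = None,
    min_segments: int = 20,
) -> FeatureThresholds:
    """Calibrate one-sided thresholds covering >= `coverage` of full-VH segments.

    disorder_max and access_max are upper bounds (>= coverage of full-VH at
    or below); depth_min is a lower bound (>= coverage at or above).  With
    ``decimals`` set, thresholds are rounded outward (up for upper bounds,
    down for lower) so the coverage guarantee survives rounding.
    """
    feats = [f for f in full_vh_features if f.complete()]
    if len(feats) < min_segments:
        raise ValueError(
            f"need at least {min_segments} fully-featured full-VH segments, "
            f"got {len(feats)}"
        )
    dis = np.array([f.disorder_pct for f in feats])
    acc = np.array([f.access_pct for f in feats])
    dep = np.array([f.mean_depth for f in feats])
    disorder_max = _upper_coverage_bound(dis, coverage)
    access_max = _upper_coverage_bound(acc, coverage)
    depth_min = _lower_coverage_bound(dep, coverage)
    if decimals is not None:
        scale = 10.0**decimals
        disorder_max = math.ceil(disorder_max * scale) / scale
        access_max = math.ceil(access_max * scale) / scale
        depth_min = math.floor(depth_min * scale) / scale
    return FeatureThresholds(
        disorder_max=disorder_max,
        access_max=access_max,
        depth_min=depth_min,
        provenance="calibrated",
    )


# Tree level order is fixed: RSS, Accessibility, Disorder, KnownHomologs.
_LEVELS = ("RSS", "Accessibility", "Disorder", "KnownHomologs")


def _route(features: SegmentFeatures, thr: FeatureThresholds) -> tuple[bool, bool, bool, bool]:
    """True on the folded-like side of each split, following the printed
    comparators strictly (no epsilon)."""
    return (
        features.rss_pct > 0.0,
        features.access_pct <= thr.access_max,
        features.disorder_pct <= thr.disorder_max,
        features.mean_depth > thr.depth_min,
    )


def _edge_label(level: str, side: bool, thr: FeatureThresholds) -> str:
    if level == "RSS":
        return "RSS > 0" if side else "RSS = 0"
    if level == "Accessibility":
        return (
            f"Accessibility <= {thr.access_max:g}"
            if side
            else f"Accessibility > {thr.access_max:g}"
        )
    if level == "Disorder":
        return (
            f"Disorder <= {thr.disorder_max:g}"
            if side
            else f"Disorder > {thr.disorder_max:g}"
        )
    return (
        f"Known homologs > {thr.depth_min:g}"
        if side
        else f"Known homologs <= {thr.depth_min:g}"
    )


@dataclass
class TaxonomyTree:
    """Four-level binary tree over segments; every segment lands in one leaf."""

    thresholds: FeatureThresholds
    leaves: dict[tuple[bool, bool, bool, bool], list[str]] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    @property
    def root_count(self) -> int:
        return sum(len(v) for v in self.leaves.values())

    def leaf_counts(self) -> dict[tuple[bool, bool, bool, bool], int]:
        return {k: len(v) for k, v in self.leaves.items()}

    def node_count(self, path: tuple[bool, ...]) -> int:
        """Count of segments under an internal node given a path prefix."""
        return sum(
            len(v) for k, v in self.leaves.items() if k[: len(path)] == path
        )

    def leaf_path_label(self, key: tuple[bool, bool, bool, bool]) -> str:
        return " / ".join(
            _edge_label(level, side, self.thresholds)
            for level, side in zip(_LEVELS, key)
        )

    def to_text(self) -> str:
        lines = [f"root n={self.root_count}"]

        def walk(path: tuple[bool, ...]) -> None:
            depth = len(path)
            if depth == len(_LEVELS):
                return
            for side in (True, False):
                sub = path + (side,)
                n = self.node_count(sub)
                label = _edge_label(_LEVELS[depth], side, self.thresholds)
                lines.append("  " * (depth + 1) + f"{label}: n={n}")
                walk(sub)

        walk(())
        if self.excluded:
            lines.append(f"excluded (missing features): n={len(self.excluded)}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        def walk(path: tuple[bool, ...]) -> dict:
            depth = len(path)
            node: dict = {"n": self.node_count(path)}
            if depth < len(_LEVELS):
                node["children"] = {}
                for side in (True, False):
                    label = _edge_label(_LEVELS[depth], side, self.thresholds)
                    node["children"][label] = walk(path + (side,))
            else:
                node["members"] = sorted(self.leaves.get(path, []))
            return node

        out = walk(())
        out["excluded"] = sorted(self.excluded)
        out["thresholds"] = {
            "disorder_max": self.thresholds.disorder_max,
            "access_max": self.thresholds.access_max,
            "depth_min": self.thresholds.depth_min,
            "provenance": self.thresholds.provenance,
        }
        return out


def build_tree(
    segments: Mapping[str, SegmentFeatures] | Iterable[tuple[str, SegmentFeatures]],
    thresholds: FeatureThresholds,
) -> TaxonomyTree:
    """Route each (segment_id, features) pair through the four fixed splits.

    Segments with a missing feature are excluded from the tree, logged, and
    counted separately.
    """
    items = segments.items() if isinstance(segments, Mapping) else segments
    tree = TaxonomyTree(thresholds=thresholds)
    for seg_id, feats in items:
        if not feats.complete():
            logger.warning("segment %s excluded from tree: missing feature(s)", seg_id)
            tree.excluded.append(seg_id)
            continue
        key = _route(feats, thresholds)
        tree.leaves.setdefault(key, []).append(seg_id)
    return tree


def summarize_proteome(
    entries: Mapping[str, int],
    segments: Sequence[FoldableSegment],
    classes: Mapping[str, ConfidenceClass],
    plddt_tracks: Mapping[str, Sequence[float]],
    proteome_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-proteome accounting of residues and segments.

    Parameters
    ----------
    entries
        protein id -> protein length, for every protein considered.
    segments
        long soluble-like foldable segments (already filtered).
    classes
        segment key ``"{protein_id}:{start}-{end}"`` -> confidence class.
    plddt_tracks
        protein id -> per-residue pLDDT.
    proteome_of
        protein id -> proteome label; defaults to one proteome "all".
    """
    if proteome_of is None:
        proteome_of = {pid: "all" for pid in entries}
    by_prot: dict[str, list[FoldableSegment]] = {}
    for s in segments:
        by_prot.setdefault(s.protein_id, []).append(s)

    rows = []
    for proteome in sorted(set(proteome_of.values())):
        pids = [p for p in entries if proteome_of.get(p) == proteome]
        total_res = sum(entries[p] for p in pids)
        in_fs = vh_in_fs = vl_in_fs = 0
        vl_in_full = vh_in_full = 0
        full_vl_lens: list[int] = []
        full_vh_lens: list[int] = []
        for pid in pids:
            track = plddt_tracks.get(pid)
            for s in by_prot.get(pid, []):
                in_fs += s.length
                key = f"{pid}:{s.start}-{s.end}"
                cls = classes.get(key)
                if track is not None:
                    window = track[s.start - 1 : s.end]
                    n_vh = sum(1 for p in window if p > PLDDT_VH_MIN)
                    n_vl = sum(1 for p in window if p <= PLDDT_VL_MAX)
                    vh_in_fs += n_vh
                    vl_in_fs += n_vl
                    if cls is ConfidenceClass.FULL_VL:
                        vl_in_full += n_vl
                    elif cls is ConfidenceClass.FULL_VH:
                        vh_in_full += n_vh
                if cls is ConfidenceClass.FULL_VL:
                    full_vl_lens.append(s.length)
                elif cls is ConfidenceClass.FULL_VH:
                    full_vh_lens.append(s.length)

        def pct(num: int, den: int) -> float:
            return 100.0 * num / den if den else 0.0

        rows.append(
            {
                "proteome": proteome,
                "n_proteins": len(pids),
                "total_residues": total_res,
                "pct_residues_in_fs": pct(in_fs, total_res),
                "pct_fs_residues_vh": pct(vh_in_fs, in_fs),
                "pct_fs_residues_vl": pct(vl_in_fs, in_fs),
                "pct_vl_residues_in_full_vl": pct(vl_in_full, vl_in_fs),
                "pct_vh_residues_in_full_vh": pct(vh_in_full, vh_in_fs),
                "n_full_vl": len(full_vl_lens),
                "n_full_vh": len(full_vh_lens),
                "mean_len_full_vl": float(np.mean(full_vl_lens)) if full_vl_lens else 0.0,
                "mean_len_full_vh": float(np.mean(full_vh_lens)) if full_vh_lens else 0.0,
            }
        )
    return pd.DataFrame(rows)
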