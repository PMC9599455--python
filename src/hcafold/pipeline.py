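"""End-to-end orchestration: sequences + models + tracks -> segment table,
confidence classes, calibrated thresholds, binary trees, proteome summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as hio
from .classify import (
    ConfidenceClass,
    FeatureThresholds,
    SegmentFeatures,
    TaxonomyTree,
    build_tree,
    calibrate_thresholds,
    confidence_class,
    paper_default_thresholds,
    summarize_proteome,
)
from .sequence import FoldableSegment, delineate_foldable_segments, filter_soluble_long
from .structure import (
    accessibility_coverage,
    assign_secondary_structure,
    compute_rel_asa,
    read_af2_model,
    rss_coverage,
)
from .tracks import disorder_coverage, mean_depth, read_alignment_depth, read_disorder_track

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the published cutoffs."""

    fasta: str | Path | None = None
    models_dir: str | Path | None = None
    tracks_dir: str | Path | None = None
    alignments_dir: str | Path | None = None
    out_dir: str | Path | None = None
    thresholds_mode: str = "paper_defaults"  # or "calibrate"
    linker_max: int = 10
    plddt_vl: float = 50.0
    plddt_vh: float = 90.0
    min_len: int = 30
    score_low: float = -1.0
    score_high: float = 3.5
    disorder_cutoff: float = 0.5
    asa_cutoff: float = 0.36
    coverage: float = 0.95
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides (e.g. CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunResult:
    segments: pd.DataFrame
    thresholds: FeatureThresholds
    tree_full_vl: TaxonomyTree
    tree_full_vh: TaxonomyTree
    summary: pd.DataFrame
    exclusions: list[str] = field(default_factory=list)


def _segment_key(s: FoldableSegment) -> str:
    return f"{s.protein_id}:{s.start}-{s.end}"


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage and (optionally) write the report files.

    Missing models leave a segment unclassified (excluded, logged); missing
    disorder/alignment tracks leave features absent — such segments keep
    their class but are excluded from the trees by :func:`build_tree`.
    """
    if config.fasta is None:
        raise ValueError("config.fasta is required")
    sequences = hio.read_fasta(config.fasta)
    if not sequences:
        logger.warning("no sequences found in %s", config.fasta)

    models_dir = Path(config.models_dir) if config.models_dir else None
    tracks_dir = Path(config.tracks_dir) if config.tracks_dir else None
    aln_dir = Path(config.alignments_dir) if config.alignments_dir else None

    exclusions: list[str] = []
    all_segments: list[FoldableSegment] = []
    classes: dict[str, ConfidenceClass] = {}
    features: dict[str, SegmentFeatures] = {}
    plddt_tracks: dict[str, list[float]] = {}
    entry_lengths: dict[str, int] = {}

    for seq in sequences:
        entry_lengths[seq.id] = len(seq)
        segments = filter_soluble_long(
            delineate_foldable_segments(seq, linker_max=config.linker_max),
            min_len=config.min_len,
            score_low=config.score_low,
            score_high=config.score_high,
        )
        all_segments.extend(segments)
        if not segments:
            continue

        ss_labels = None
        rel_asa = None
        plddt = None
        model_path = models_dir / f"{seq.id}.pdb" if models_dir else None
        if model_path and model_path.exists():
            entry = read_af2_model(model_path, entry_id=seq.id)
            if entry.sequence.residues != seq.residues:
                raise ValueError(f"{seq.id}: model sequence differs from FASTA")
            plddt = list(entry.plddt_track())
            plddt_tracks[seq.id] = plddt
            ss_labels = assign_secondary_structure(entry)
            rel_asa = compute_rel_asa(entry)
        else:
            exclusions.append(f"{seq.id}: no model; segments unclassified")

        dis_track = None
        if tracks_dir:
            p = tracks_dir / f"{seq.id}.tsv"
            if p.exists():
                dis_track = read_disorder_track(p, seq.id, sequence=seq.residues)
            else:
                exclusions.append(f"{seq.id}: no disorder track")
        depth_track = None
        if aln_dir:
            for suffix in (".sto", ".stk", ".fasta", ".afa"):
                p = aln_dir / f"{seq.id}{suffix}"
                if p.exists():
                    depth_track = read_alignment_depth(p, seq.id)
                    break
            else:
                exclusions.append(f"{seq.id}: no alignment")

        for s in segments:
            key = _segment_key(s)
            if plddt is not None:
                classes[key] = confidence_class(
                    s, plddt, vl_max=config.plddt_vl, vh_min=config.plddt_vh
                )
            features[key] = SegmentFeatures(
                rss_pct=rss_coverage(s, ss_labels) if ss_labels else None,
                access_pct=(
                    accessibility_coverage(s, rel_asa, cutoff=config.asa_cutoff)
                    if rel_asa is not None
                    else None
                ),
                disorder_pct=(
                    disorder_coverage(s, dis_track, cutoff=config.disorder_cutoff)
                    if dis_track is not None
                    else None
                ),
                mean_depth=mean_depth(s, depth_track) if depth_track else None,
            )

    vh_keys = [k for k, c in classes.items() if c is ConfidenceClass.FULL_VH]
    vl_keys = [k for k, c in classes.items() if c is ConfidenceClass.FULL_VL]

    if config.thresholds_mode == "calibrate":
        thresholds = calibrate_thresholds(
            [features[k] for k in vh_keys], coverage=config.coverage
        )
    elif config.thresholds_mode == "paper_defaults":
        thresholds = paper_default_thresholds()
    else:
        raise ValueError(f"unknown thresholds_mode {config.thresholds_mode!r}")

    tree_vl = build_tree({k: features[k] for k in vl_keys}, thresholds)
    tree_vh = build_tree({k: features[k] for k in vh_keys}, thresholds)

    summary = summarize_proteome(entry_lengths, all_segments, classes, plddt_tracks)

    seg_table = hio.segments_to_frame(all_segments)
    keys = [_segment_key(s) for s in all_segments]
    seg_table["confidence_class"] = [
        classes[k].value if k in classes else "unclassified" for k in keys
    ]
    for col, attr in (
        ("rss_pct", "rss_pct"),
        ("access_pct", "access_pct"),
        ("disorder_pct", "disorder_pct"),
        ("mean_depth", "mean_depth"),
    ):
        seg_table[col] = [getattr(features.get(k, SegmentFeatures()), attr) for k in keys]

    def leaf_of(key: str) -> str:
        cls = classes.get(key)
        tree = {ConfidenceClass.FULL_VL: tree_vl, ConfidenceClass.FULL_VH: tree_vh}.get(cls)
        if tree is None:
            return ""
        for leaf_key, members in tree.leaves.items():
            if key in members:
                return tree.leaf_path_label(leaf_key)
        return ""

    seg_table["tree_leaf"] = [leaf_of(k) for k in keys]

    result = RunResult(
        segments=seg_table,
        thresholds=thresholds,
        tree_full_vl=tree_vl,
        tree_full_vh=tree_vh,
        summary=summary,
        exclusions=exclusions,
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.segments.to_csv(out_dir / "segments.tsv", sep="\t", index=False, float_format="%.4f")
    result.summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False, float_format="%.4f")
    for name, tree in (("full_vl", result.tree_full_vl), ("full_vh", result.tree_full_vh)):
        (out_dir / f"tree_{name}.txt").write_text(tree.to_text() + "\n")
        with open(out_dir / f"tree_{name}.json", "w") as fh:
            json.dump(tree.to_json_dict(), fh, indent=2)
    (out_dir / "exclusions.log").write_text(
        "\n".join(result.exclusions) + ("\n" if result.exclusions else "")
    )
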