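"""Shared fixtures: a seeded synthetic proteome bundle and its pipeline run."""

from __future__ import annotations

import pytest

from hcafold.pipeline import RunConfig, run_pipeline
from hcafold.synthetic import default_study_plans, make_bundle

BUNDLE_SEED = 20260927


@pytest.fixture(scope="session")
def bundle50(tmp_path_factory):
    """50 synthetic proteins (FASTA + PDB + tracks + alignments) with truth."""
    outdir = tmp_path_factory.mktemp("bundle50")
    plans = default_study_plans(50, seed=BUNDLE_SEED)
    truths = make_bundle(plans, outdir)
    return outdir, plans, truths


@pytest.fixture(scope="session")
def run50(bundle50):
    outdir, _plans, _truths = bundle50
    config = RunConfig(
        fasta=outdir / "sequences.fasta",
        models_dir=outdir / "models",
        tracks_dir=outdir / "tracks",
        alignments_dir=outdir / "alignments",
        thresholds_mode="paper_defaults",
    )
    return run_pipeline(config)
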