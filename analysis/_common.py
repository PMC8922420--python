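"""Shared paths and deterministic reference rebuilding for the analysis
scripts.  Every script regenerates the mock references from SEED rather
than pickling state, so each stage stands alone and stays reproducible."""

from __future__ import annotations

from pathlib import Path

from rivervirome.pipeline import default_config

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

DATA = SCRATCH / "data"
CLEAN = SCRATCH / "clean"
ASM = SCRATCH / "assembly"
CLS = SCRATCH / "classify"
ANN = SCRATCH / "annotation"


def config():
    return default_config(SCRATCH / "run", seed=SEED)


def references():
    """Rebuild taxa, databases, background genomes and HMMs from SEED."""
    from rivervirome.synthetic import (
        build_background_genomes,
        build_hallmark_hmms,
        build_mock_community,
        reference_sets_from_taxa,
    )

    cfg = config()
    taxa = build_mock_community(cfg.n_viral_taxa, SEED)
    viral, nvnr, truth = reference_sets_from_taxa(
        taxa, cfg.n_nvnr_proteins, SEED, decoy_fraction=cfg.decoy_fraction)
    background = build_background_genomes(nvnr, truth, SEED)
    hmms = build_hallmark_hmms(taxa, SEED)
    return taxa, viral, nvnr, truth, background, hmms


def ensure_dirs(*paths: Path) -> None:
    for p in paths:
        p.mkdir(parents=True, exist_ok=True)
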