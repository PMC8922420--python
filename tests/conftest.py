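from __future__ import annotations

import numpy as np
import pytest

from rivervirome.pipeline import default_config, run_pipeline
from rivervirome.records import Read
from rivervirome.scoring import ScoringScheme
from rivervirome.synthetic import (
    build_background_genomes,
    build_hallmark_hmms,
    build_mock_community,
    reference_sets_from_taxa,
)


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def mock_refs():
    """A 17-family mock community with databases, background and HMMs."""
    taxa = build_mock_community(17, seed=11)
    viral, nvnr, truth = reference_sets_from_taxa(taxa, 50, seed=11,
                                                  decoy_fraction=0.2)
    background = build_background_genomes(nvnr, truth, seed=11)
    hmms = build_hallmark_hmms(taxa, seed=11)
    return {"taxa": taxa, "viral": viral, "nvnr": nvnr, "truth": truth,
            "background": background, "hmms": hmms}


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The full six-site + control synthetic run (shared across tests)."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = default_config(outdir, seed=1)
    return run_pipeline(cfg)


def make_read(seq: str, read_id: str = "r0", library: str = "lib",
              qual: int | list[int] = 30) -> Read:
    q = [qual] * len(seq) if isinstance(qual, int) else qual
    return Read(read_id, library, seq, q)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
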