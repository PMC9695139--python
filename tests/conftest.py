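"""Shared fixtures: simulated genomes and their annotation, reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from retrozyme.annotate import annotate_genome
from retrozyme.homology import scan_genome
from retrozyme.simulate import GenomeSimConfig, simulate_genome


@pytest.fixture(scope="session")
def default_sim():
    """Default simulated genome: 9 full (7 Group 1 + 2 Group 2), 5 partial, 20 fragments."""
    cfg = GenomeSimConfig(seed=11)
    scaffolds, truth = simulate_genome(cfg)
    return cfg, scaffolds, truth


@pytest.fixture(scope="session")
def annotated(default_sim):
    """Scan + annotate the default simulated genome once for the whole session."""
    _cfg, scaffolds, truth = default_sim
    ltr_hits = scan_genome(scaffolds, truth.templates["ltr_query"], query_id="LTR")
    cr_hits = []
    for key in sorted(truth.templates):
        if key.startswith("cr_query"):
            cr_hits.extend(
                scan_genome(scaffolds, truth.templates[key], query_id=key)
            )
    loci = annotate_genome(
        scaffolds, ltr_hits, cr_hits,
        trna_3prime=truth.templates["trna_3prime"],
        ltr_query=truth.templates["ltr_query"],
    )
    return scaffolds, truth, ltr_hits, cr_hits, loci


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
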