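"""Shared fixtures.

The default synthetic study (reference fixture, signatures, enrichment,
similarity matrices) is expensive to build, so it is session-scoped and
shared by the evaluation-level tests.
"""

from __future__ import annotations

import pytest

from diseasim.synthetic import FixtureConfig, generate_fixture
from diseasim.workflows import all_similarity_matrices, disease_enrichment, network_signatures


@pytest.fixture(scope="session")
def small_cfg() -> FixtureConfig:
    """A scaled-down configuration for fast structural tests."""
    return FixtureConfig(
        seed=11,
        n_proteins=80,
        n_offnet_genes=20,
        n_diseases=16,
        n_modules=8,
        overlap_fraction=0.25,
    )


@pytest.fixture(scope="session")
def small_fixture(small_cfg):
    return generate_fixture(small_cfg)


@pytest.fixture(scope="session")
def study():
    """The default synthetic study with all derived artefacts."""
    fx = generate_fixture(FixtureConfig())
    signatures = network_signatures(fx.graph)
    enriched = disease_enrichment(fx.dmap, fx.annotations, fx.ontology)
    sims = all_similarity_matrices(fx.dmap, signatures=signatures, enriched=enriched)
    return {"fixture": fx, "signatures": signatures, "enriched": enriched, "sims": sims}
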