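"""Shared fixtures: one default synthetic study analyzed once per session."""

from __future__ import annotations

import pytest

from tul import SimulationConfig, simulate_study
from tul.io_formats import GeneFeature, GenomeAnnotation, GenomeSequence
from tul.pipeline import analyze_study


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study(default_config):
    """(annotation, truth, libraries) for the default simulated study."""
    return simulate_study(default_config)


@pytest.fixture(scope="session")
def pipeline_result(study, default_config):
    annotation, truth, libraries = study
    return analyze_study(
        annotation,
        libraries,
        conditions=default_config.conditions,
        n_replicates=default_config.n_replicates,
    )


@pytest.fixture()
def toy_annotation() -> GenomeAnnotation:
    """A 5-kb contig with one + gene [1000, 2000) and one - gene [3000, 3600)."""
    seq = GenomeSequence("c1", "ACGT" * 1250)
    genes = [
        GeneFeature("geneA", "c1", 1000, 2000, "+", cog_category="M"),
        GeneFeature("geneB", "c1", 3000, 3600, "-", cog_category="D"),
    ]
    return GenomeAnnotation(sequences={"c1": seq}, genes=genes)
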