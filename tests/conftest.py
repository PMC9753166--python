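"""Shared fixtures: a canonical substrate pair, its complexes, and fast
deterministic mock-backend pipelines."""

from __future__ import annotations

import pytest
from hypothesis import settings

from heckregio import (
    PipelineConfig,
    enumerate_complexes,
    parse_substrates,
    rank_reactive_sites,
)
from heckregio.backends import MockBackend

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def styrene_pair():
    return parse_substrates("C=Cc1ccccc1", "Clc1ccccc1")


@pytest.fixture(scope="session")
def styrene_specs(styrene_pair):
    site = rank_reactive_sites(styrene_pair)[0]
    return enumerate_complexes(styrene_pair, site)


@pytest.fixture
def mock_config():
    return PipelineConfig()


def forced_backends(neutral_delta=None, cationic_delta=None, spread=1.0, **kwargs):
    """Mock backends with E(alpha)-E(beta) forced per pathway; the small
    conformer spread keeps the forced gap sharp."""
    from heckregio.fixtures import mock_bias_for_deltas

    bias = mock_bias_for_deltas(neutral_delta, cationic_delta)
    return {
        lvl: MockBackend(level=lvl, bias=bias, spread=spread, **kwargs)
        for lvl in ("forcefield", "semiempirical", "dft_singlepoint")
    }


@pytest.fixture
def mock_backends():
    return forced_backends()
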