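"""Shared fixtures: small simulations and constructed coding transcripts."""

from __future__ import annotations

import numpy as np
import pytest

from twintx.synthetic_data import PlantedCDS, SimulationConfig, \
    generate_twin_transcriptomes


@pytest.fixture(scope="session")
def small_twin():
    """20 ortholog pairs + 5 specifics per species at default divergence."""
    cfg = SimulationConfig(n_orthologs=20, n_specific_a=5, n_specific_b=5, seed=7)
    return generate_twin_transcriptomes(cfg)


class _CDSFactory:
    """Yields planted-CDS constructs plus named truncation records."""

    def __init__(self, seed: int):
        self._rng = np.random.default_rng(seed)

    def __call__(self) -> PlantedCDS:
        return PlantedCDS(self._rng)


@pytest.fixture(scope="session")
def planted_cds_factory():
    return _CDSFactory(20240917)
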