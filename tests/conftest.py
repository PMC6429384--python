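"""Shared session-scoped fixtures.

The simulation bundles and full pipeline reports are expensive; they are
built once per session and shared across test modules.
"""

from __future__ import annotations

import pytest

from satfam import pipeline, satsim

SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def cfic_bundle():
    return satsim.fixture("cfic_like")


@pytest.fixture(scope="session")
def hor_bundle():
    return satsim.fixture("hor_worked_example")


@pytest.fixture(scope="session")
def two_species_bundle():
    return satsim.fixture("two_species_ancestor")


@pytest.fixture(scope="session")
def vulvaria_bundle():
    return satsim.fixture("vulvaria_like")


@pytest.fixture(scope="session")
def seven_bundles():
    """seven_species fixture realised for seeds 1-5 (truth only)."""
    return {seed: satsim.fixture("seven_species", seed=seed) for seed in SEEDS}


@pytest.fixture(scope="session")
def seven_reports():
    """Full pipeline reports for seeds 1-5 (the heavy end-to-end runs)."""
    return {seed: pipeline.run_all("seven_species", seed=seed) for seed in SEEDS}
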