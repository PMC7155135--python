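"""Shared fixtures: one synthetic region, climate, farms and a fitted SDM
subset, generated once per session (everything is seeded)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import alpscape as alp
from alpscape.synthetic import pool_config_for_climate

SEED = 11


@pytest.fixture(scope="session")
def landscape():
    return alp.generate_landscape(alp.LandscapeConfig(rows=96, cols=96), seed=SEED)


@pytest.fixture(scope="session")
def climate(landscape):
    return alp.generate_climate(landscape, seed=SEED)


@pytest.fixture(scope="session")
def farm_state(landscape):
    return alp.generate_farms(landscape, n_farms=40, seed=SEED)


@pytest.fixture(scope="session")
def species_pool(climate):
    return alp.generate_species_pool(
        12,
        {
            "Forests": 0.25,
            "Alpine habitats": 0.25,
            "Grasslands": 0.25,
            "Agricultural lands": 0.25,
        },
        seed=SEED,
        climate_dominant_fraction=0.5,
        config=pool_config_for_climate(climate),
    )


@pytest.fixture(scope="session")
def plots(species_pool, landscape, climate):
    return alp.sample_plots(
        species_pool, landscape, climate, n_plots=1500, seed=SEED, min_occurrences=40
    )


@pytest.fixture(scope="session")
def sdm_fits(plots):
    """Ensemble fits for the first six species passing the occurrence filter."""
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sp in plots.usable_species()[:6]:
            fit = alp.fit_species_models(plots, sp, seed=SEED)
            if fit.usable:
                fits.append(fit)
    assert fits, "no usable ensemble fit in the session fixture"
    return fits


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
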