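"""Shared fixtures: one synthetic world per session, plus derived models."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cwrgap.geodata import GridSpec
from cwrgap.niche_model import build_distribution, draw_background
from cwrgap.occurrence_qc import modeling_points
from cwrgap.synthetic import (
    ErrorRates,
    SimConfig,
    VirtualSpecies,
    generate_environment,
    sample_occurrences,
)


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Default world geometry with error injection and sampling bias off."""
    return SimConfig(
        seed=1, error_rates=ErrorRates(0, 0, 0, 0), sampling_bias_strength=0.0
    )


@pytest.fixture(scope="session")
def world(clean_config):
    return generate_environment(clean_config)


@pytest.fixture(scope="session")
def background(world, clean_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # background_n capped at land-cell count
        return draw_background(world.land, clean_config.grid, 10_000, seed=3)


@pytest.fixture(scope="session")
def recovery_species(world) -> VirtualSpecies:
    """A species whose niche lies along the dominant temperature axes.

    Its drivers are informative in the PCA-loading sense, so the subset
    selector has a fair chance to recover them; used by the
    parameter-recovery checks.
    """

    def qv(name, q):
        return float(np.quantile(world.stack.layers[name].valid_values(), q))

    def sdv(name):
        return float(world.stack.layers[name].valid_values().std())

    return VirtualSpecies(
        "recovery",
        niche_center={"bio1": qv("bio1", 0.6), "bio4": qv("bio4", 0.4)},
        niche_width={"bio1": 0.5 * sdv("bio1"), "bio4": 0.6 * sdv("bio4")},
        native_countries={1, 2, 3, 4, 5},
        prevalence=0.2,
    )


@pytest.fixture(scope="session")
def recovery_sample(recovery_species, world, clean_config):
    return sample_occurrences(recovery_species, world, clean_config, n_records=200)


@pytest.fixture(scope="session")
def recovery_points(recovery_sample, clean_config):
    return modeling_points(recovery_sample.occurrences, clean_config.grid)


@pytest.fixture(scope="session")
def recovery_distribution(recovery_points, world, background, recovery_species):
    from cwrgap.synthetic import native_mask

    nat = native_mask(world, recovery_species)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_distribution(
            "recovery", recovery_points, world.stack, nat, background, seed=2
        )


@pytest.fixture()
def small_spec() -> GridSpec:
    """20x20 half-degree grid straddling the equator, for counting oracles."""
    return GridSpec(n_rows=20, n_cols=20, x_min=-5.0, y_max=5.0, resolution=0.5)
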