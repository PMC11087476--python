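"""Shared fixtures: synthetic datasets prepared once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from sizesel import SimulationConfig, generate_dataset
from sizesel.ppmr import stomach_summaries
from sizesel.preprocess import attach_station_covariates, drop_empty_stomachs


def prepare(dataset):
    """Attach SST covariates, drop empty stomachs, build stomach summaries."""
    stations = attach_station_covariates(dataset.stations, dataset.sst_daily)
    predators = drop_empty_stomachs(dataset.predators, dataset.stomachs)
    summaries = stomach_summaries(predators, dataset.stomachs).merge(
        stations[["station", "sst", "lat", "lon"]], on="station", how="left"
    )
    return stations, predators, summaries


@pytest.fixture(scope="session")
def default_dataset():
    """One survey under the default study conditions."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_prepared(default_dataset):
    stations, predators, summaries = prepare(default_dataset)
    return {
        "dataset": default_dataset,
        "stations": stations,
        "predators": predators,
        "summaries": summaries,
    }


@pytest.fixture(scope="session")
def hypothesis1_config():
    """Predators shrink with SST; environment and feeding kernel are static."""
    return SimulationConfig(
        seed=0,
        species_niche_sd=None,
        selectivity_slope=0.0,
        selectivity_intercept=-2.75,
        beta_predator=-0.03,
        beta_env_prey=0.0,
    )
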