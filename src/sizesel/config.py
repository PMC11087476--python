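"""Configuration objects for the simulation and the analysis pipeline.

Both configs are plain dataclasses with YAML round-trip helpers so that a
run is fully described by a single text file.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "SimulationConfig",
    "SelectivityParams",
    "PipelineConfig",
    "load_yaml",
    "dump_yaml",
]


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic stomach-content study.

    The generator emulates a latitudinal survey: stations sit on a
    sea-surface-temperature (SST) gradient, grouped into spatio-temporal
    clusters (sampling locations).  Fish body mass, the environmental
    zooplankton size pool and size-selective feeding all respond to SST
    through the slopes below, so every downstream estimate can be checked
    against a known truth.

    Parameters
    ----------
    n_stations
        Number of stations (one predator haul and one zooplankton haul each).
    n_clusters
        Number of spatio-temporal sampling locations the stations are grouped
        into; ``None`` means one station per cluster.
    sst_range
        (min, max) SST in deg C spanned by the cluster gradient.
    n_species
        Number of predator species.
    species_mass_medians
        Median log10 body mass (g) per species at SST = 0; length must equal
        ``n_species``.
    species_niche_sd
        Width (deg C) of each species' Gaussian abundance niche along the
        SST gradient; niche centres run from warm (smallest species) to
        cold (largest), emulating the community turnover that concentrates
        a few species at each station.  ``None`` samples species uniformly
        everywhere.
    beta_predator
        Slope of log10 predator body mass per deg C.
    beta_env_prey
        Slope of the environmental prey log10-mass mean per deg C.
    env_prey_mean
        Mean log10 prey mass (g) of the environmental pool at SST = 0.
    env_prey_sd
        SD of environmental log10 prey mass.
    selectivity_intercept, selectivity_slope
        The optimal log10 prey mass for a predator of log10 mass m is
        ``selectivity_intercept + selectivity_slope * m``.
    selectivity_sd
        Width (log10 g) of the lognormal feeding kernel; ``inf`` gives
        purely density-dependent (neutral) feeding.
    mean_prey_per_stomach
        Poisson mean of prey items per stomach (zero draws yield the empty
        stomachs that ingest later discards).
    n_fish_per_station, n_zoop_per_haul
        Sample sizes per station.
    mass_sd
        Within-species SD of log10 body mass.
    year_sd
        SD of the shared random year intercept on log10 predator mass.
    species_slope_sd
        SD of per-species deviations around ``beta_predator``.
    sst_daily_sd
        Day-to-day SD of the synthetic daily SST series.
    seed
        Seed for the single random generator; fully determines the output.
    """

    n_stations: int = 72
    n_clusters: int | None = 24
    sst_range: tuple[float, float] = (0.0, 5.0)
    n_species: int = 10
    species_mass_medians: tuple[float, ...] = (
        -0.4, -0.2, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4,
    )
    species_niche_sd: float | None = 1.2
    beta_predator: float = -0.03
    beta_env_prey: float = 0.0
    env_prey_mean: float = -3.0
    env_prey_sd: float = 0.5
    selectivity_intercept: float = -2.5
    selectivity_slope: float = 0.85
    selectivity_sd: float = 0.4
    mean_prey_per_stomach: float = 2.35
    n_fish_per_station: int = 25
    n_zoop_per_haul: int = 40
    mass_sd: float = 0.1
    year_sd: float = 0.05
    species_slope_sd: float = 0.005
    sst_daily_sd: float = 0.1
    seed: int = 0

    def selectivity_mu(self, log10_predator_mass: float) -> float:
        """Optimal log10 prey mass for a predator of the given log10 mass."""
        return self.selectivity_intercept + self.selectivity_slope * log10_predator_mass

    def validate(self) -> None:
        for name in ("n_stations", "n_species", "n_fish_per_station", "n_zoop_per_haul"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_clusters is not None and not (1 <= self.n_clusters <= self.n_stations):
            raise ValueError("n_clusters must be between 1 and n_stations")
        if self.species_niche_sd is not None and not self.species_niche_sd > 0:
            raise ValueError(f"species_niche_sd must be > 0 or None, got {self.species_niche_sd}")
        for name in ("env_prey_sd", "selectivity_sd", "mass_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        lo, hi = self.sst_range
        if not lo < hi:
            raise ValueError(f"sst_range min must be < max, got {self.sst_range}")
        if len(self.species_mass_medians) != self.n_species:
            raise ValueError(
                f"species_mass_medians has {len(self.species_mass_medians)} entries "
                f"for n_species={self.n_species}"
            )
        if self.mean_prey_per_stomach <= 0:
            raise ValueError("mean_prey_per_stomach must be > 0")
        # selectivity_sd = inf is the meaningful neutral-feeding limit; every
        # other parameter must be finite.
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("seed", "n_clusters") or not isinstance(v, (int, float)):
                continue
            if f.name == "selectivity_sd" and math.isinf(v) and v > 0:
                continue
            _check_finite(f.name, v)
        for i, m in enumerate(self.species_mass_medians):
            _check_finite(f"species_mass_medians[{i}]", m)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sst_range"] = list(self.sst_range)
        d["species_mass_medians"] = list(self.species_mass_medians)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "sst_range" in d:
            d["sst_range"] = tuple(d["sst_range"])
        if "species_mass_medians" in d:
            d["species_mass_medians"] = tuple(d["species_mass_medians"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SelectivityParams:
    """Tunables of the preference-distribution stage."""

    bandwidth_scale: float = 1.0
    min_prey: int = 10
    grid_size: int = 512
    max_km: float = 100.0
    max_days: int = 5
    floor_quantile: float = 0.01
    class_width: float = 0.05
    class_anchor: float = 0.025
    weight_by_count: bool = True


@dataclass
class PipelineConfig:
    """Paths, parameters and the seed for one end-to-end run."""

    predators: str = "predators.csv"
    stomachs: str = "stomachs.csv"
    zooplankton: str = "zooplankton.csv"
    stations: str = "stations.csv"
    sst_daily: str = "sst_daily.csv"
    out_dir: str = "results"
    selectivity: SelectivityParams = field(default_factory=SelectivityParams)
    covariate_window_days: int = 30
    sqrt_transform: bool = True
    seed: int = 0

    def input_paths(self) -> dict[str, Path]:
        return {
            name: Path(getattr(self, name))
            for name in ("predators", "stomachs", "zooplankton", "stations", "sst_daily")
        }

    def validate_paths(self) -> None:
        for name, p in self.input_paths().items():
            if not p.exists():
                raise FileNotFoundError(f"{name} table not found: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "selectivity" in d and isinstance(d["selectivity"], dict):
            d["selectivity"] = SelectivityParams(**d["selectivity"])
        return cls(**d)


def load_yaml(path: str | Path, cls):
    """Load a config dataclass (``SimulationConfig`` or ``PipelineConfig``) from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return cls.from_dict(data)


def dump_yaml(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
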