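"""Unit conversions and covariate preparation.

Raw field measurements arrive in survey units (standard length in mm, dry
mass in mg, raw counts per tow, daily covariate series); everything
downstream works in grams, individuals per 1000 m^3 and window-averaged
covariates.  Units are tracked by a naming convention — mass columns end in
``_g``, densities in ``_per_1000m3`` — and downstream stages refuse columns
that do not declare them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LengthWeightParams",
    "TowGeometry",
    "DEFAULT_LENGTH_WEIGHT",
    "length_to_mass",
    "drymass_to_wetmass",
    "standardize_density",
    "average_covariate",
    "require_mass_column",
    "attach_station_covariates",
    "drop_empty_stomachs",
]


@dataclass(frozen=True)
class LengthWeightParams:
    """Power-law length-weight coefficients: mass_g = a * SL_mm ** b."""

    species: str
    a: float  # g per mm^b
    b: float  # dimensionless

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError(f"length-weight a must be > 0 for {self.species}, got {self.a}")
        if not self.b > 0:
            raise ValueError(f"length-weight b must be > 0 for {self.species}, got {self.b}")


# Default allometries for the packaged synthetic species.  Values are typical
# of small mesopelagic fish (near-cubic growth, ~50 mm at 1 g); real analyses
# supply survey-specific coefficients via the `length_weight:` config block.
DEFAULT_LENGTH_WEIGHT: dict[str, LengthWeightParams] = {
    f"Myctophid_{i + 1:02d}": LengthWeightParams(f"Myctophid_{i + 1:02d}", a=3.0e-6, b=3.2)
    for i in range(10)
}


@dataclass(frozen=True)
class TowGeometry:
    """Swept-volume geometry of one net deployment."""

    distance_towed: float  # m
    net_mouth_area: float = 25.0  # m^2, nominal rectangular mid-water trawl mouth

    def __post_init__(self):
        if not self.distance_towed > 0:
            raise ValueError(f"distance_towed must be > 0, got {self.distance_towed}")
        if not self.net_mouth_area > 0:
            raise ValueError(f"net_mouth_area must be > 0, got {self.net_mouth_area}")

    @property
    def swept_volume_m3(self) -> float:
        return self.distance_towed * self.net_mouth_area


def length_to_mass(standard_length, params: LengthWeightParams):
    """Convert standard length (mm) to body mass (g) via W = a * SL^b.

    Accepts scalars or arrays; raises on non-positive lengths.
    """
    sl = np.asarray(standard_length, dtype=float)
    if np.any(sl <= 0):
        raise ValueError(f"standard length must be > 0 (species {params.species})")
    mass = params.a * sl**params.b
    return float(mass) if np.isscalar(standard_length) else mass


def lookup_length_weight(species: str, table: dict[str, LengthWeightParams] | None = None) -> LengthWeightParams:
    table = DEFAULT_LENGTH_WEIGHT if table is None else table
    try:
        return table[species]
    except KeyError:
        raise KeyError(f"no length-weight parameters for species {species!r}") from None


def drymass_to_wetmass(dry_mass_mg: float, factor: float) -> float:
    """Dry mass (mg) to wet mass (g) using a taxon DM-to-WM conversion factor."""
    if not dry_mass_mg > 0:
        raise ValueError(f"dry mass must be > 0, got {dry_mass_mg}")
    if not factor > 0:
        raise ValueError(f"conversion factor must be > 0, got {factor}")
    return dry_mass_mg * factor / 1000.0


def standardize_density(count: float, tow: TowGeometry) -> float:
    """Raw count per tow to individuals per 1000 m^3 of water filtered."""
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return count / tow.swept_volume_m3 * 1000.0


def average_covariate(
    daily_values: pd.Series,
    sampling_date: dt.date | str | pd.Timestamp,
    window_days: int = 30,
) -> float:
    """Mean of a daily series over the ``window_days`` days ending at (and
    including) the sampling date.

    The window must be fully covered — missing days raise with the dates
    listed rather than being silently interpolated.
    """
    if window_days < 1:
        raise ValueError(f"window_days must be >= 1, got {window_days}")
    end = pd.Timestamp(sampling_date).normalize()
    idx = pd.DatetimeIndex(pd.to_datetime(daily_values.index)).normalize()
    series = pd.Series(daily_values.to_numpy(dtype=float), index=idx)
    wanted = pd.date_range(end=end, periods=window_days, freq="D")
    missing = wanted.difference(series.index)
    if len(missing):
        days = ", ".join(d.date().isoformat() for d in missing)
        raise ValueError(f"covariate series is missing {len(missing)} day(s) in the window: {days}")
    window = series.loc[series.index.isin(wanted)]
    # a duplicated date would silently skew the mean
    if window.index.has_duplicates:
        dupes = window.index[window.index.duplicated()].unique()
        raise ValueError(f"duplicate covariate entries for: {', '.join(d.date().isoformat() for d in dupes)}")
    return float(window.mean())


def require_mass_column(df: pd.DataFrame, column: str) -> None:
    """Refuse columns that do not declare grams via the ``_g`` suffix."""
    if column not in df.columns:
        raise KeyError(f"column {column!r} not in table")
    if not column.endswith("_g"):
        raise ValueError(f"column {column!r} does not declare mass units (expected a '_g' suffix)")


def attach_station_covariates(
    stations: pd.DataFrame,
    sst_daily: pd.DataFrame,
    window_days: int = 30,
) -> pd.DataFrame:
    """Return the station table with a window-averaged ``sst`` column added."""
    sst = []
    for _, st in stations.iterrows():
        sub = sst_daily[sst_daily["station"] == st["station"]]
        series = pd.Series(sub["sst"].to_numpy(), index=pd.to_datetime(sub["date"]))
        sst.append(average_covariate(series, st["date"], window_days=window_days))
    out = stations.copy()
    out["sst"] = sst
    return out


def drop_empty_stomachs(predators: pd.DataFrame, stomachs: pd.DataFrame) -> pd.DataFrame:
    """Keep only predators with at least one stomach item (ingest-time rule)."""
    fed = set(stomachs["predator_id"].unique())
    return predators[predators["predator_id"].isin(fed)].reset_index(drop=True)
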