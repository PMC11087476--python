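"""Community-level descriptors: per-haul species densities and diversity.

Diversity is the Shannon-Wiener index on natural logs; a square-root
transform of the densities (applied before forming proportions) damps the
weighting of dominant species, as is conventional for strongly uneven
plankton and micronekton communities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import TowGeometry, standardize_density

__all__ = ["shannon_diversity", "haul_composition", "community_table"]


def shannon_diversity(densities, sqrt_transform: bool = True) -> float:
    """Shannon-Wiener H (nats) of a vector of per-species densities."""
    d = np.asarray(densities, dtype=float)
    if np.any(d < 0):
        raise ValueError("densities must be >= 0")
    if d.sum() <= 0:
        raise ValueError("all-zero density vector has no diversity")
    if sqrt_transform:
        d = np.sqrt(d)
    p = d / d.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def haul_composition(
    predators: pd.DataFrame,
    tow_by_station: dict[int, TowGeometry] | None = None,
    default_tow: TowGeometry | None = None,
) -> pd.DataFrame:
    """Per-haul species densities (individuals per 1000 m^3) from catch counts.

    One haul per station; tow geometry per station, or a shared default.
    """
    if default_tow is None:
        default_tow = TowGeometry(distance_towed=3000.0)
    counts = predators.groupby(["station", "species"]).size().rename("count").reset_index()
    dens = []
    for _, r in counts.iterrows():
        tow = (tow_by_station or {}).get(r["station"], default_tow)
        dens.append(standardize_density(r["count"], tow))
    counts["density_per_1000m3"] = dens
    return counts


def community_table(
    predators: pd.DataFrame,
    stations: pd.DataFrame,
    sqrt_transform: bool = True,
    tow_by_station: dict[int, TowGeometry] | None = None,
) -> pd.DataFrame:
    """One row per haul: Shannon H, species richness, total density, covariates."""
    comp = haul_composition(predators, tow_by_station=tow_by_station)
    rows = []
    for station, grp in comp.groupby("station"):
        d = grp["density_per_1000m3"].to_numpy()
        rows.append(
            {
                "station": station,
                "shannon_h": shannon_diversity(d, sqrt_transform=sqrt_transform),
                "richness": int((d > 0).sum()),
                "total_density_per_1000m3": float(d.sum()),
            }
        )
    out = pd.DataFrame(rows)
    keep = [c for c in ("station", "sst", "chla", "lat", "lon", "year") if c in stations.columns]
    return out.merge(stations[keep], on="station", how="left")
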