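"""Prey-size preference from realised vs environmental size distributions.

The selectivity of predators for prey of different sizes is estimated by
comparing two kernel density estimates on the log10 prey-mass axis:

* the *realised* distribution — prey masses found in stomachs, weighted by
  item counts, pooled over all predators of one species size class within
  one sampling location;
* the *environmental* distribution — zooplankton taxon masses in the same
  location, weighted by standardised abundance, over the comparable range.

Their normalised ratio is the *preference* distribution: flat under purely
density-dependent feeding, peaked where predators take prey
disproportionately to availability.  Its mean is the average preferred prey
size for that size class at that location's temperature.

Predators are pooled into body-mass classes of width 10^0.05 g before
density estimation so each aggregate holds enough prey items; bins are
anchored at an offset of +0.025 on the log10 axis, giving bounds at odd
multiples of 0.025 (e.g. the 0.30 g class spans 10^-0.525 to 10^-0.475 g).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .config import SelectivityParams
from .preprocess import TowGeometry, require_mass_column, standardize_density

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceGroup",
    "PreferenceDistribution",
    "NoPreyInRange",
    "great_circle_km",
    "group_cooccurrence",
    "size_class_index",
    "size_class_bounds",
    "assign_size_classes",
    "fit_kde",
    "silverman_bandwidth",
    "environmental_distribution",
    "preference_distribution",
    "comparable_range",
    "selectivity_table",
]

_EARTH_RADIUS_KM = 6371.0


class NoPreyInRange(ValueError):
    """No environmental taxa fall inside the comparable mass range."""


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine distance in km; accepts scalars or arrays (degrees)."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class CooccurrenceGroup:
    """Predator and zooplankton hauls taken in the same area within days."""

    group_id: int
    predator_stations: list = field(default_factory=list)
    zoop_stations: list = field(default_factory=list)
    mean_sst: float = float("nan")
    extent_km: float = 0.0
    date_min: pd.Timestamp | None = None
    date_max: pd.Timestamp | None = None

    @property
    def stations(self) -> list:
        return sorted(set(self.predator_stations) | set(self.zoop_stations))


def group_cooccurrence(
    predator_hauls: pd.DataFrame,
    zooplankton_hauls: pd.DataFrame,
    max_km: float = 100.0,
    max_days: int = 5,
) -> list[CooccurrenceGroup]:
    """Cluster hauls into sampling locations by single linkage.

    Two hauls are linked when they lie within ``max_km`` great-circle km AND
    within ``max_days`` days; groups are the connected components.  Haul
    tables need ``station``, ``lat``, ``lon``, ``date`` and (optionally)
    ``sst`` columns.  Group ids are assigned by ascending earliest date,
    then latitude, so they do not depend on input row order.  Components
    without a zooplankton haul cannot support a preference estimate and are
    dropped with a warning.
    """
    ph = predator_hauls.assign(_kind="predator")
    zh = zooplankton_hauls.assign(_kind="zoop")
    hauls = pd.concat([ph, zh], ignore_index=True)
    lat = hauls["lat"].to_numpy(dtype=float)
    lon = hauls["lon"].to_numpy(dtype=float)
    days = pd.to_datetime(hauls["date"]).to_numpy(dtype="datetime64[D]").astype(int)

    n = len(hauls)
    dist = great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    close = (dist <= max_km) & (np.abs(days[:, None] - days[None, :]) <= max_days)
    _, labels = connected_components(csr_matrix(close), directed=False)

    groups = []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        sub = hauls.iloc[idx]
        g = CooccurrenceGroup(
            group_id=-1,
            predator_stations=sorted(sub.loc[sub["_kind"] == "predator", "station"].tolist()),
            zoop_stations=sorted(sub.loc[sub["_kind"] == "zoop", "station"].tolist()),
            mean_sst=float(sub["sst"].mean()) if "sst" in sub.columns else float("nan"),
            extent_km=float(dist[np.ix_(idx, idx)].max()),
            date_min=pd.to_datetime(sub["date"]).min(),
            date_max=pd.to_datetime(sub["date"]).max(),
        )
        if not g.zoop_stations:
            logger.warning(
                "dropping co-occurrence group with %d predator haul(s) and no zooplankton haul",
                len(g.predator_stations),
            )
            continue
        if not g.predator_stations:
            logger.warning("dropping co-occurrence group with no predator haul")
            continue
        groups.append(g)

    # deterministic ids: earliest date, then southernmost member latitude
    min_lat = {
        id(g): float(hauls.loc[hauls["station"].isin(g.stations), "lat"].min()) for g in groups
    }
    groups.sort(key=lambda g: (g.date_min, min_lat[id(g)]))
    for i, g in enumerate(groups):
        g.group_id = i
    return groups


def size_class_index(mass_g, width: float = 0.05, anchor: float = 0.025):
    """Index k of the half-open log10-mass bin [width*k+anchor, width*(k+1)+anchor)."""
    m = np.asarray(mass_g, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mass must be > 0")
    k = np.floor((np.log10(m) - anchor) / width).astype(int)
    return int(k) if np.isscalar(mass_g) else k


def size_class_bounds(k: int, width: float = 0.05, anchor: float = 0.025) -> tuple[float, float]:
    """(lower, upper) bounds in grams of size class ``k``."""
    lo = width * k + anchor
    return 10.0**lo, 10.0 ** (lo + width)


def size_class_midpoint(k: int, width: float = 0.05, anchor: float = 0.025) -> float:
    """Class midpoint on the log10 g axis."""
    return width * k + anchor + width / 2.0


@dataclass
class SizeClassAggregate:
    """Stomachs of one species size class within one sampling location."""

    group_id: int
    species: str
    class_index: int
    class_mid_log10: float
    mean_sst: float
    year: int
    predator_ids: list
    prey_log10_mass: np.ndarray
    prey_counts: np.ndarray

    @property
    def n_predators(self) -> int:
        return len(self.predator_ids)

    @property
    def n_prey(self) -> int:
        return int(self.prey_counts.sum())


def assign_size_classes(
    summaries: pd.DataFrame,
    stomachs: pd.DataFrame,
    groups: list[CooccurrenceGroup],
    params: SelectivityParams | None = None,
) -> list[SizeClassAggregate]:
    """Pool stomachs into (location, species, size class) aggregates.

    ``summaries`` is the per-stomach table from :func:`sizesel.ppmr.stomach_summaries`.
    Aggregates whose pooled prey items fall below ``params.min_prey`` are
    discarded (too few items to estimate a density).
    """
    params = params or SelectivityParams()
    require_mass_column(stomachs, "prey_mass_g")
    station_to_group = {}
    for g in groups:
        for s in g.predator_stations:
            station_to_group[s] = g
    df = summaries.copy()
    df["_group"] = df["station"].map(lambda s: getattr(station_to_group.get(s), "group_id", None))
    df = df[df["_group"].notna()]
    df["_k"] = size_class_index(
        df["predator_mass_g"].to_numpy(), width=params.class_width, anchor=params.class_anchor
    )
    group_by_id = {g.group_id: g for g in groups}

    aggregates = []
    for (gid, species, k), sub in df.groupby(["_group", "species", "_k"], sort=True):
        items = stomachs[stomachs["predator_id"].isin(sub["predator_id"])]
        counts = items["count"].to_numpy(dtype=float)
        if not params.weight_by_count:
            counts = np.ones_like(counts)
        if counts.sum() < params.min_prey:
            continue
        g = group_by_id[int(gid)]
        year = int(sub["year"].mode().iloc[0])
        aggregates.append(
            SizeClassAggregate(
                group_id=int(gid),
                species=species,
                class_index=int(k),
                class_mid_log10=size_class_midpoint(int(k), params.class_width, params.class_anchor),
                mean_sst=g.mean_sst,
                year=year,
                predator_ids=sorted(sub["predator_id"].tolist()),
                prey_log10_mass=np.log10(items["prey_mass_g"].to_numpy(dtype=float)),
                prey_counts=counts,
            )
        )
    return aggregates


_DEGENERATE_BW = 0.05  # log10 g; fallback when the sample has no spread


def silverman_bandwidth(
    values, weights=None, scale: float = 1.0, weights_are_counts: bool = True
) -> float:
    """Silverman's-rule bandwidth of a weighted 1-d sample, times ``scale``.

    With ``weights_are_counts`` (prey-item counts) the effective sample size
    is the total count, so a weight of 2 behaves exactly like a duplicated
    observation; otherwise weights are relative (abundance on an arbitrary
    scale) and the Kish effective sample size is used.
    """
    x = np.asarray(values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    wn = w / w.sum()
    mean = (wn * x).sum()
    if weights_are_counts:
        neff = w.sum()
        denom = max(neff - 1.0, 1e-12)
        var = (w * (x - mean) ** 2).sum() / denom
    else:
        neff = 1.0 / (wn**2).sum()
        var = (wn * (x - mean) ** 2).sum()
    if var <= 0:
        return _DEGENERATE_BW * scale
    factor = (neff * 3.0 / 4.0) ** (-1.0 / 5.0)
    return float(factor * math.sqrt(var) * scale)


def fit_kde(
    log10_masses,
    weights,
    grid: np.ndarray,
    bandwidth_scale: float = 1.0,
    weights_are_counts: bool = True,
) -> np.ndarray:
    """Weighted Gaussian KDE evaluated on ``grid`` and renormalised to
    integrate to 1 over the grid (trapezoid rule).

    Bandwidth is Silverman's rule on the weighted sample, times
    ``bandwidth_scale`` (see :func:`silverman_bandwidth` for the two weight
    interpretations; count weights make ``(x, weight 2)`` identical to a
    duplicated point).  A sample with no spread degrades to a narrow
    Gaussian bump rather than failing.
    """
    x = np.asarray(log10_masses, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size == 0:
        raise ValueError("cannot fit a KDE to an empty sample")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    grid = np.asarray(grid, dtype=float)
    bw = silverman_bandwidth(x, w, scale=bandwidth_scale, weights_are_counts=weights_are_counts)
    wn = w / w.sum()
    # sum of Gaussian kernels; (n_grid, n_points) is small in practice
    dens = (wn[None, :] * stats.norm.pdf((grid[:, None] - x[None, :]) / bw)).sum(axis=1) / bw
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("density integrates to zero over the grid (grid misses the sample)")
    return dens / area


def environmental_distribution(
    zoop: pd.DataFrame,
    grid: np.ndarray,
    bandwidth_scale: float = 1.0,
) -> np.ndarray:
    """Abundance-weighted KDE of the zooplankton log10 masses on ``grid``.

    ``zoop`` needs ``mass_g`` and ``density_per_1000m3`` (or ``count``)
    columns.  Raises :class:`NoPreyInRange` when no taxon falls inside the
    grid's mass range.
    """
    require_mass_column(zoop, "mass_g")
    x = np.log10(zoop["mass_g"].to_numpy(dtype=float))
    wcol = "density_per_1000m3" if "density_per_1000m3" in zoop.columns else "count"
    w = zoop[wcol].to_numpy(dtype=float)
    grid = np.asarray(grid, dtype=float)
    if not np.any((x >= grid[0]) & (x <= grid[-1])):
        raise NoPreyInRange(
            f"no environmental taxa within [{grid[0]:.3f}, {grid[-1]:.3f}] log10 g"
        )
    return fit_kde(x, w, grid, bandwidth_scale=bandwidth_scale, weights_are_counts=False)


@dataclass
class PreferenceDistribution:
    """Realised, environmental and preference densities on a common grid."""

    grid: np.ndarray
    realised: np.ndarray
    environmental: np.ndarray
    preference: np.ndarray
    mean_preferred: float


def preference_distribution(
    realised: np.ndarray,
    environmental: np.ndarray,
    grid: np.ndarray,
    floor_quantile: float = 0.01,
) -> PreferenceDistribution:
    """Normalised ratio of realised to environmental density.

    The environmental density is floored at the ``floor_quantile`` quantile
    of its positive values so that vanishing availability at the range edges
    cannot blow the ratio up.  The ratio is renormalised to integrate to 1
    and summarised by its mean — the average preferred prey size (log10 g).
    """
    realised = np.asarray(realised, dtype=float)
    environmental = np.asarray(environmental, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if realised.shape != grid.shape or environmental.shape != grid.shape:
        raise ValueError("realised, environmental and grid must share one shape")
    positive = environmental[environmental > 0]
    if positive.size == 0:
        raise ValueError("environmental density is zero everywhere")
    floor = np.quantile(positive, floor_quantile)
    ratio = realised / np.maximum(environmental, floor)
    area = np.trapezoid(ratio, grid)
    if area <= 0:
        raise ValueError("preference ratio integrates to zero")
    pref = ratio / area
    mean_pref = float(np.trapezoid(grid * pref, grid))
    return PreferenceDistribution(
        grid=grid,
        realised=realised,
        environmental=environmental,
        preference=pref,
        mean_preferred=mean_pref,
    )


def comparable_range(
    realised_log10: np.ndarray,
    env_log10: np.ndarray,
    pad: float,
) -> tuple[float, float]:
    """Intersection of the realised and environmental log10-mass ranges,
    padded outward by ``pad`` (one bandwidth)."""
    lo = max(np.min(realised_log10), np.min(env_log10)) - pad
    hi = min(np.max(realised_log10), np.max(env_log10)) + pad
    if not lo < hi:
        raise ValueError("realised and environmental mass ranges do not overlap")
    return float(lo), float(hi)


def _zoop_with_density(zoop: pd.DataFrame) -> pd.DataFrame:
    if "density_per_1000m3" in zoop.columns:
        return zoop
    out = zoop.copy()
    out["density_per_1000m3"] = [
        standardize_density(r["count"], TowGeometry(r["distance_towed_m"], r["net_mouth_area_m2"]))
        for _, r in zoop.iterrows()
    ]
    return out


def selectivity_table(
    summaries: pd.DataFrame,
    stomachs: pd.DataFrame,
    zooplankton: pd.DataFrame,
    stations: pd.DataFrame,
    params: SelectivityParams | None = None,
    return_distributions: bool = False,
):
    """End-to-end preference estimation.

    Groups hauls into sampling locations, pools stomachs into species size
    classes, estimates realised/environmental/preference densities per
    aggregate and returns one row per aggregate with its mean preferred
    prey size.  ``stations`` must carry ``lat``, ``lon``, ``date`` and
    ``sst`` columns (see :func:`sizesel.preprocess.attach_station_covariates`).
    """
    params = params or SelectivityParams()
    zoop = _zoop_with_density(zooplankton)
    haul_cols = ["station", "lat", "lon", "date"] + (["sst"] if "sst" in stations.columns else [])
    pred_hauls = stations[stations["station"].isin(summaries["station"])][haul_cols]
    zoop_hauls = stations[stations["station"].isin(zoop["station"])][haul_cols]
    groups = group_cooccurrence(pred_hauls, zoop_hauls, max_km=params.max_km, max_days=params.max_days)
    aggregates = assign_size_classes(summaries, stomachs, groups, params=params)
    group_by_id = {g.group_id: g for g in groups}

    rows = []
    dists = {}
    for agg in aggregates:
        g = group_by_id[agg.group_id]
        zsub = zoop[zoop["station"].isin(g.zoop_stations)]
        zx = np.log10(zsub["mass_g"].to_numpy(dtype=float))
        zw = zsub["density_per_1000m3"].to_numpy(dtype=float)
        env_bw = silverman_bandwidth(zx, zw, scale=params.bandwidth_scale, weights_are_counts=False)
        try:
            lo, hi = comparable_range(agg.prey_log10_mass, zx, pad=env_bw)
        except ValueError:
            logger.warning(
                "group %d species %s class %d: no comparable mass range; skipped",
                agg.group_id, agg.species, agg.class_index,
            )
            continue
        grid = np.linspace(lo, hi, params.grid_size)
        try:
            env_dens = environmental_distribution(zsub, grid, bandwidth_scale=params.bandwidth_scale)
        except NoPreyInRange as e:
            logger.warning(
                "group %d species %s class %d: %s; skipped", agg.group_id, agg.species, agg.class_index, e
            )
            continue
        real_dens = fit_kde(agg.prey_log10_mass, agg.prey_counts, grid, bandwidth_scale=params.bandwidth_scale)
        pref = preference_distribution(real_dens, env_dens, grid, floor_quantile=params.floor_quantile)
        rows.append(
            {
                "group_id": agg.group_id,
                "species": agg.species,
                "class_index": agg.class_index,
                "class_mid_log10": agg.class_mid_log10,
                "mean_sst": agg.mean_sst,
                "year": agg.year,
                "n_predators": agg.n_predators,
                "n_prey": agg.n_prey,
                "mean_preferred_log10": pref.mean_preferred,
            }
        )
        if return_distributions:
            dists[(agg.group_id, agg.species, agg.class_index)] = pref
    table = pd.DataFrame(
        rows,
        columns=[
            "group_id", "species", "class_index", "class_mid_log10", "mean_sst",
            "year", "n_predators", "n_prey", "mean_preferred_log10",
        ],
    )
    return (table, dists) if return_distributions else table
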