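"""Synthetic survey generator with known ground truth.

Emulates a stomach-content study of mesopelagic fish along a temperature
gradient: stations grouped into spatio-temporal sampling locations, a
zooplankton haul and a predator haul per station, and size-biased feeding
from the local zooplankton pool.  Every response to temperature is
controlled by an explicit slope so downstream estimators can be tested by
parameter recovery.

Generating model, per station with (realised 30-day mean) SST ``T``:

* predator log10 mass  ~ Normal(median_s + (beta_predator + b_s) * T + u_y, mass_sd)
  with species deviation ``b_s`` and year intercept ``u_y``;
* environmental prey log10 mass ~ Normal(env_prey_mean + beta_env_prey * T,
  env_prey_sd), realised as a finite taxon list with abundances;
* stomach contents: prey count ~ Poisson(mean_prey_per_stomach); each item
  drawn with replacement from the local taxon list with probability
  proportional to density * exp(-(x - mu(m))^2 / (2 * selectivity_sd^2)),
  where ``mu(m)`` is the affine optimal prey size for predator log10 mass
  ``m``.  ``selectivity_sd = inf`` removes selection (neutral feeding).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .preprocess import DEFAULT_LENGTH_WEIGHT, LengthWeightParams

__all__ = ["SyntheticDataset", "generate_dataset", "feeding_probabilities"]

_YEARS = (2006, 2008, 2009)
_CRUISE_START = {2006: dt.date(2006, 10, 15), 2008: dt.date(2008, 1, 15), 2009: dt.date(2009, 3, 15)}
_SERIES_DAYS = 40  # daily SST record length per station; covers the 30-day window


@dataclass
class SyntheticDataset:
    """The four survey tables, the daily SST series and the generating truth."""

    predators: pd.DataFrame
    stomachs: pd.DataFrame
    zooplankton: pd.DataFrame
    stations: pd.DataFrame
    sst_daily: pd.DataFrame
    truth: dict

    _TABLES = ("predators", "stomachs", "zooplankton", "stations", "sst_daily")

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in self._TABLES:
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths

    @classmethod
    def from_csv(cls, in_dir: str | Path) -> "SyntheticDataset":
        d = Path(in_dir)
        tables = {name: pd.read_csv(d / f"{name}.csv") for name in cls._TABLES}
        return cls(truth={}, **tables)


def feeding_probabilities(
    log10_masses: np.ndarray,
    densities: np.ndarray,
    mu: float,
    sd: float,
) -> np.ndarray:
    """Selection probabilities over a finite prey pool.

    Probability of drawing taxon ``t`` is proportional to
    ``density_t * exp(-(x_t - mu)^2 / (2 sd^2))``; computed in log space so
    far-from-optimum pools do not underflow.  ``sd = inf`` gives pure
    density-dependence.
    """
    x = np.asarray(log10_masses, dtype=float)
    d = np.asarray(densities, dtype=float)
    if np.any(d < 0) or d.sum() <= 0:
        raise ValueError("densities must be non-negative with positive sum")
    with np.errstate(divide="ignore"):
        logw = np.log(d)
    if math.isfinite(sd):
        logw = logw - (x - mu) ** 2 / (2.0 * sd**2)
    logw = logw - logw[np.isfinite(logw)].max()
    w = np.exp(logw)
    w[~np.isfinite(logw)] = 0.0
    return w / w.sum()


def _station_frame(cfg: SimulationConfig, rng: np.random.Generator):
    lo, hi = cfg.sst_range
    n_clusters = cfg.n_clusters or cfg.n_stations
    cluster_sst = np.linspace(lo, hi, n_clusters) if n_clusters > 1 else np.array([(lo + hi) / 2])
    # latitude tracks the SST gradient (warm north, cold south, Scotia Sea-like)
    cluster_lat = -62.0 + (cluster_sst - lo) / max(hi - lo, 1e-9) * 12.0
    cluster_year = [_YEARS[c % len(_YEARS)] for c in range(n_clusters)]
    # visits within a cruise are a week apart so locations stay temporally distinct
    cluster_date = [_CRUISE_START[cluster_year[c]] + dt.timedelta(days=7 * (c // len(_YEARS))) for c in range(n_clusters)]

    rows = []
    daily = []
    for s in range(cfg.n_stations):
        c = s % n_clusters
        lat = cluster_lat[c] + rng.normal(0.0, 0.02)
        lon = -45.0 + rng.normal(0.0, 0.03)
        date = cluster_date[c] + dt.timedelta(days=int(rng.integers(0, 3)))
        series = cluster_sst[c] + rng.normal(0.0, cfg.sst_daily_sd, size=_SERIES_DAYS)
        days = [date - dt.timedelta(days=k) for k in range(_SERIES_DAYS - 1, -1, -1)]
        for d_, v in zip(days, series):
            daily.append({"station": s, "date": d_.isoformat(), "sst": v})
        sst_30d = float(series[-30:].mean())
        rows.append(
            {
                "station": s,
                "cluster": c,
                "year": cluster_year[c],
                "lat": lat,
                "lon": lon,
                "date": date.isoformat(),
                "chla": float(np.exp(rng.normal(np.log(0.5), 0.3))),
                "_sst": sst_30d,  # realised generating covariate; dropped before output
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(daily)


def _zooplankton_frame(cfg: SimulationConfig, stations: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for _, st in stations.iterrows():
        mu = cfg.env_prey_mean + cfg.beta_env_prey * st["_sst"]
        log10_m = rng.normal(mu, cfg.env_prey_sd, size=cfg.n_zoop_per_haul)
        # right-skewed abundances: a handful of taxa dominate each haul
        counts = np.maximum(1, np.round(np.exp(rng.normal(4.0, 1.0, size=cfg.n_zoop_per_haul)))).astype(int)
        dist = float(rng.uniform(2500.0, 3500.0))
        for i in range(cfg.n_zoop_per_haul):
            rows.append(
                {
                    "station": int(st["station"]),
                    "taxon": f"taxon_s{int(st['station'])}_{i:03d}",
                    "count": int(counts[i]),
                    "distance_towed_m": dist,
                    "net_mouth_area_m2": 25.0,
                    "mass_g": float(10.0 ** log10_m[i]),
                }
            )
    return pd.DataFrame(rows)


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic survey; the seed fully determines every table."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    stations, sst_daily = _station_frame(cfg, rng)
    zoop = _zooplankton_frame(cfg, stations, rng)

    u_year = {y: float(rng.normal(0.0, cfg.year_sd)) for y in _YEARS}
    slope_dev = rng.normal(0.0, cfg.species_slope_sd, size=cfg.n_species)
    species = [f"Myctophid_{i + 1:02d}" for i in range(cfg.n_species)]
    # Gaussian abundance niches along the gradient: largest-bodied species
    # centred on the cold end, smallest on the warm end (community turnover)
    lo_sst, hi_sst = cfg.sst_range
    niche_centre = np.linspace(hi_sst, lo_sst, cfg.n_species) if cfg.n_species > 1 else np.array([(lo_sst + hi_sst) / 2])

    pred_rows = []
    stomach_rows = []
    pid = 0
    for _, st in stations.iterrows():
        sst = st["_sst"]
        zh = zoop[zoop["station"] == st["station"]]
        zx = np.log10(zh["mass_g"].to_numpy())
        # within a haul all taxa share tow geometry, so counts are already
        # proportional to standardised density
        zdens = zh["count"].to_numpy(dtype=float)
        ztaxa = zh["taxon"].to_numpy()
        zmass = zh["mass_g"].to_numpy()

        if cfg.species_niche_sd is None:
            sp_idx = rng.integers(0, cfg.n_species, size=cfg.n_fish_per_station)
        else:
            sp_p = np.exp(-((sst - niche_centre) ** 2) / (2.0 * cfg.species_niche_sd**2))
            sp_p = sp_p / sp_p.sum()
            sp_idx = rng.choice(cfg.n_species, size=cfg.n_fish_per_station, p=sp_p)
        for i in range(cfg.n_fish_per_station):
            s = int(sp_idx[i])
            m_log10 = (
                cfg.species_mass_medians[s]
                + (cfg.beta_predator + slope_dev[s]) * sst
                + u_year[int(st["year"])]
                + rng.normal(0.0, cfg.mass_sd)
            )
            mass = 10.0**m_log10
            lw: LengthWeightParams = DEFAULT_LENGTH_WEIGHT[species[s]]
            sl_mm = (mass / lw.a) ** (1.0 / lw.b)
            pred_rows.append(
                {
                    "predator_id": pid,
                    "station": int(st["station"]),
                    "species": species[s],
                    "year": int(st["year"]),
                    "sl_mm": float(sl_mm),
                    "mass_g": float(mass),
                }
            )
            n_prey = int(rng.poisson(cfg.mean_prey_per_stomach))
            if n_prey > 0:
                p = feeding_probabilities(zx, zdens, cfg.selectivity_mu(m_log10), cfg.selectivity_sd)
                draws = rng.choice(len(ztaxa), size=n_prey, p=p)
                counts = np.bincount(draws, minlength=len(ztaxa))
                for t in np.nonzero(counts)[0]:
                    stomach_rows.append(
                        {
                            "predator_id": pid,
                            "prey_taxon": ztaxa[t],
                            "count": int(counts[t]),
                            "prey_mass_g": float(zmass[t]),
                        }
                    )
            pid += 1

    truth = dict(
        cfg.to_dict(),
        year_effects=u_year,
        species_slope_dev={sp: float(d) for sp, d in zip(species, slope_dev)},
        station_sst={int(r["station"]): float(r["_sst"]) for _, r in stations.iterrows()},
    )
    return SyntheticDataset(
        predators=pd.DataFrame(pred_rows),
        stomachs=pd.DataFrame(stomach_rows),
        zooplankton=zoop,
        stations=stations.drop(columns=["_sst"]),
        sst_daily=sst_daily,
        truth=truth,
    )
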