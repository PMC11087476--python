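"""Per-stomach predator-prey mass ratios.

PPMR is the predator body mass (g) divided by the abundance-weighted
average prey mass (g) in its stomach — prey are averaged on the linear gram
scale within each stomach first (prey-averaged PPMR, one row per fish), and
the ratio is analysed on log10 scale downstream.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .preprocess import require_mass_column

__all__ = ["weighted_mean_prey_mass", "compute_ppmr", "stomach_summaries"]


def weighted_mean_prey_mass(counts, masses_g) -> float:
    """Abundance-weighted mean prey mass: sum(c_i m_i) / sum(c_i), in grams."""
    c = np.asarray(counts, dtype=float)
    m = np.asarray(masses_g, dtype=float)
    if c.size == 0:
        raise ValueError("empty stomach: cannot average prey mass (excluded at ingest)")
    if c.shape != m.shape:
        raise ValueError("counts and masses differ in length")
    if np.any(c < 1):
        raise ValueError("prey counts must be >= 1")
    if np.any(m <= 0):
        raise ValueError("prey masses must be > 0")
    return float((c * m).sum() / c.sum())


def compute_ppmr(predator_mass_g: float, mean_prey_g: float) -> dict:
    """PPMR and its log10 decomposition for one stomach."""
    if not predator_mass_g > 0:
        raise ValueError(f"predator mass must be > 0, got {predator_mass_g}")
    if not mean_prey_g > 0:
        raise ValueError(f"mean prey mass must be > 0, got {mean_prey_g}")
    ppmr = predator_mass_g / mean_prey_g
    return {
        "predator_mass_g": predator_mass_g,
        "mean_prey_mass_g": mean_prey_g,
        "ppmr": ppmr,
        "log10_predator_mass": math.log10(predator_mass_g),
        "log10_mean_prey_mass": math.log10(mean_prey_g),
        "log10_ppmr": math.log10(ppmr),
    }


def stomach_summaries(predators: pd.DataFrame, stomachs: pd.DataFrame) -> pd.DataFrame:
    """One row per non-empty stomach with PPMR and log10 fields.

    ``predators`` needs predator_id, species, station, year and a ``mass_g``
    column; ``stomachs`` needs predator_id, count and ``prey_mass_g``.
    """
    require_mass_column(predators, "mass_g")
    require_mass_column(stomachs, "prey_mass_g")
    agg = stomachs.groupby("predator_id").apply(
        lambda g: weighted_mean_prey_mass(g["count"], g["prey_mass_g"]),
        include_groups=False,
    )
    merged = predators.merge(agg.rename("mean_prey_mass_g"), on="predator_id", how="inner")
    rows = []
    for _, r in merged.iterrows():
        d = compute_ppmr(r["mass_g"], r["mean_prey_mass_g"])
        d.update(
            predator_id=r["predator_id"],
            species=r["species"],
            station=r["station"],
            year=r["year"],
        )
        rows.append(d)
    cols = [
        "predator_id", "species", "station", "year",
        "predator_mass_g", "mean_prey_mass_g", "ppmr",
        "log10_predator_mass", "log10_mean_prey_mass", "log10_ppmr",
    ]
    return pd.DataFrame(rows, columns=cols)
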