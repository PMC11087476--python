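"""End-to-end orchestration: preprocess -> ppmr -> selectivity -> community -> inference.

Stages communicate through CSV files inside the output directory so each
is independently inspectable and re-runnable; a JSON manifest records the
config hash, seed, per-stage row counts and timings.  Re-running the same
config on the same inputs reproduces byte-identical outputs — nothing in
the analysis itself draws random numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import community_table
from .config import PipelineConfig
from .inference import (
    ModelSpec,
    fit_mixed,
    morans_i,
    percent_change_per_degree,
    select_model,
)
from .ppmr import stomach_summaries
from .preprocess import (
    DEFAULT_LENGTH_WEIGHT,
    TowGeometry,
    attach_station_covariates,
    drop_empty_stomachs,
    length_to_mass,
    lookup_length_weight,
    standardize_density,
)
from .selectivity import selectivity_table

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _result_payload(res, sst_term: str = "sst") -> dict:
    out = {
        "model": res.spec.label,
        "method": res.method,
        "converged": res.converged,
        "aic": res.aic,
        "r2_marginal": res.r2_marginal,
        "r2_conditional": res.r2_conditional,
        "n": res.n,
        "coefficients": res.params.to_dict(orient="records"),
    }
    if sst_term in set(res.params["term"]):
        c = res.coef(sst_term)
        out["sst_slope"] = float(c["estimate"])
        out["sst_slope_se"] = float(c["se"])
        out["percent_change_per_degC"] = percent_change_per_degree(float(c["estimate"]))
    if res.coords is not None:
        try:
            m = morans_i(res.residuals, res.coords.to_numpy())
            out["morans_i"] = {"i": m.i, "expected": m.expected, "p": m.p, "n": m.n}
        except ValueError as e:
            out["morans_i"] = {"error": str(e)}
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to out_dir)."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("sizesel")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    def _finish_stage(name: str, t0: float, **counts) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **counts}
        logger.info("stage %s complete: %s", name, counts)

    try:
        # ---- preprocess ----------------------------------------------------
        t0 = time.time()
        predators = pd.read_csv(cfg.predators)
        stomachs = pd.read_csv(cfg.stomachs)
        zoop = pd.read_csv(cfg.zooplankton)
        stations = pd.read_csv(cfg.stations)
        sst_daily = pd.read_csv(cfg.sst_daily)

        stations = attach_station_covariates(stations, sst_daily, window_days=cfg.covariate_window_days)
        if "mass_g" not in predators.columns:
            predators = predators.assign(
                mass_g=[
                    length_to_mass(r["sl_mm"], lookup_length_weight(r["species"], DEFAULT_LENGTH_WEIGHT))
                    for _, r in predators.iterrows()
                ]
            )
        if "density_per_1000m3" not in zoop.columns:
            zoop = zoop.assign(
                density_per_1000m3=[
                    standardize_density(
                        r["count"], TowGeometry(r["distance_towed_m"], r["net_mouth_area_m2"])
                    )
                    for _, r in zoop.iterrows()
                ]
            )
        predators = drop_empty_stomachs(predators, stomachs)
        stations.to_csv(out / "stations_preprocessed.csv", index=False)
        predators.to_csv(out / "predators_preprocessed.csv", index=False)
        zoop.to_csv(out / "zooplankton_preprocessed.csv", index=False)
        _finish_stage(
            "preprocess",
            t0,
            n_predators=len(predators),
            n_stomach_items=len(stomachs),
            n_zoop=len(zoop),
            n_stations=len(stations),
        )

        # ---- ppmr ----------------------------------------------------------
        t0 = time.time()
        summaries = stomach_summaries(predators, stomachs)
        covars = stations[["station", "sst", "lat", "lon"]]
        summaries = summaries.merge(covars, on="station", how="left")
        summaries.to_csv(out / "ppmr.csv", index=False)
        _finish_stage("ppmr", t0, n_stomachs=len(summaries))

        # ---- selectivity ---------------------------------------------------
        t0 = time.time()
        sel = selectivity_table(summaries, stomachs, zoop, stations, params=cfg.selectivity)
        sel = sel.merge(
            stations.groupby("station")[["lat", "lon"]].first().reset_index(),
            left_on="group_id",
            right_on="station",
            how="left",
        ).drop(columns=["station"], errors="ignore")
        sel.to_csv(out / "selectivity.csv", index=False)
        _finish_stage("selectivity", t0, n_aggregates=len(sel), n_groups=int(sel["group_id"].nunique()) if len(sel) else 0)

        # ---- community -----------------------------------------------------
        t0 = time.time()
        community = community_table(predators, stations, sqrt_transform=cfg.sqrt_transform)
        community.to_csv(out / "community.csv", index=False)
        _finish_stage("community", t0, n_hauls=len(community))

        # ---- inference -----------------------------------------------------
        t0 = time.time()
        inference: dict = {}
        selection_tables = []
        for response in ("log10_ppmr", "log10_predator_mass", "log10_mean_prey_mass"):
            candidates = [
                ModelSpec(response=response, fixed=("sst",), random_intercept="year",
                          random_slope=("sst", "species"), name=f"{response} ~ sst"),
                ModelSpec(response=response, fixed=(), random_intercept="year",
                          random_slope=("sst", "species"), name=f"{response} ~ 1"),
            ]
            best, sel_table = select_model(summaries, candidates)
            sel_table.insert(0, "response", response)
            selection_tables.append(sel_table)
            inference[response] = _result_payload(best)

        if len(sel) >= 8 and sel["mean_sst"].nunique() > 1:
            pref_spec = ModelSpec(
                response="mean_preferred_log10",
                fixed=("mean_sst", "class_mid_log10", "mean_sst:class_mid_log10"),
                random_intercept="species",
                name="mean_preferred ~ sst * size_class",
            )
            pref_table = sel.rename(columns={})
            pref_fit = fit_mixed(pref_table, pref_spec)
            inference["mean_preferred_log10"] = _result_payload(pref_fit, sst_term="mean_sst")
        else:
            inference["mean_preferred_log10"] = {"skipped": "too few size-class aggregates"}

        div_fit = fit_mixed(community, ModelSpec(response="shannon_h", fixed=("sst",), name="shannon_h ~ sst"))
        inference["shannon_diversity"] = _result_payload(div_fit)

        coef_rows = []
        for name, payload in inference.items():
            for c in payload.get("coefficients", []):
                coef_rows.append({"response": name, **c})
        pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
        pd.concat(selection_tables, ignore_index=True).to_csv(out / "model_selection.csv", index=False)
        with open(out / "inference.json", "w") as fh:
            json.dump(inference, fh, indent=2, default=float)
        _finish_stage("inference", t0, n_models=len(inference))

        manifest["status"] = "complete"
    except Exception as e:
        done = list(manifest["stages"])
        stage = ["preprocess", "ppmr", "selectivity", "community", "inference"][len(done)] if len(done) < 5 else "finalise"
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(e).__name__}: {e}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    root.removeHandler(handler)
    handler.close()
    return manifest
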