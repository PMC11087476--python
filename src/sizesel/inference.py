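"""Mixed-model inference: fits, AIC selection, spatial checks, effect sizes.

The analysis chain regresses log10-scale responses (PPMR, predator mass,
mean prey mass, preferred prey size, diversity) on temperature with a
random intercept for sampling year and a random SST slope by predator
species.  Fitting is delegated to statsmodels' ``MixedLM``; crossed random
effects are approximated by grouping on species and entering year as a
variance component within species.  Residual spatial independence is
checked with Moran's I (inverse-distance, row-standardised weights), and
slopes on the log10-per-degree scale are reported as percent change per
degree C.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .selectivity import great_circle_km

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelResult",
    "MoranResult",
    "fit_mixed",
    "select_model",
    "morans_i",
    "inverse_distance_weights",
    "percent_change_per_degree",
    "slope_from_percent_change",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative fixed/random structure of one candidate model.

    ``fixed`` are formula terms (patsy syntax, e.g. ``"sst"`` or
    ``"sst:class_mid_log10"``); ``random_intercept`` a grouping column;
    ``random_slope`` a ``(term, group)`` pair; ``variance_weights`` a list
    of grouping columns for two-stage inverse-variance reweighting.
    """

    response: str
    fixed: tuple[str, ...] = ()
    random_intercept: str | None = None
    random_slope: tuple[str, str] | None = None
    variance_weights: tuple[str, ...] = ()
    name: str = ""

    @property
    def label(self) -> str:
        return self.name or (self.response + " ~ " + (" + ".join(self.fixed) or "1"))

    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"

    def n_parameters(self, table: pd.DataFrame) -> int:
        """Count of estimated parameters (fixed + variance parameters)."""
        import patsy

        fixed_k = patsy.dmatrix(" + ".join(self.fixed) or "1", table).shape[1]
        k = fixed_k + 1  # residual variance
        if self.random_slope is not None:
            k += 3  # intercept var, slope var, covariance
        elif self.random_intercept is not None:
            k += 1
        if self.random_slope is not None and self.random_intercept is not None:
            k += 1  # year variance component
        return k

    def validate(self, table: pd.DataFrame) -> None:
        cols = set(table.columns)
        if self.response not in cols:
            raise KeyError(f"response column {self.response!r} not in table")
        import re

        for term in self.fixed:
            for name in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", term):
                if name not in cols and name not in {"C", "I", "np", "log", "log10"}:
                    raise KeyError(f"fixed-effect column {name!r} not in table (term {term!r})")
        if self.random_intercept is not None and self.random_intercept not in cols:
            raise KeyError(f"random-intercept column {self.random_intercept!r} not in table")
        if self.random_slope is not None:
            term, group = self.random_slope
            for c in (term, group):
                if c not in cols:
                    raise KeyError(f"random-slope column {c!r} not in table")


@dataclass
class ModelResult:
    """Coefficients, fit statistics and coordinate-keyed residuals."""

    spec: ModelSpec
    params: pd.DataFrame  # term, estimate, se, df, t, p
    aic: float
    r2_marginal: float
    r2_conditional: float
    residuals: np.ndarray
    coords: pd.DataFrame | None
    converged: bool
    n: int
    method: str  # "mixed", "ols", "ols-downgrade"
    notes: list = field(default_factory=list)

    def coef(self, term: str) -> pd.Series:
        row = self.params[self.params["term"] == term]
        if row.empty:
            raise KeyError(f"no coefficient for term {term!r}")
        return row.iloc[0]

    def ci95(self, term: str) -> tuple[float, float]:
        c = self.coef(term)
        return c["estimate"] - 1.96 * c["se"], c["estimate"] + 1.96 * c["se"]


def _coef_table(terms, estimates, ses, df_resid) -> pd.DataFrame:
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    return pd.DataFrame(
        {"term": list(terms), "estimate": est, "se": se, "df": df_resid, "t": t, "p": p}
    )


def _nakagawa_r2(var_fixed: float, var_random: float, var_resid: float) -> tuple[float, float]:
    total = var_fixed + var_random + var_resid
    if total <= 0:
        return float("nan"), float("nan")
    return var_fixed / total, (var_fixed + var_random) / total


def _stage_weights(table: pd.DataFrame, resid: np.ndarray, cols: tuple[str, ...]) -> np.ndarray:
    """Inverse of the per-group residual SD (combined over ``cols``)."""
    key = table[list(cols)].astype(str).agg("|".join, axis=1)
    sd = pd.Series(resid).groupby(key.values).transform("std")
    sd = sd.fillna(sd.mean()).clip(lower=1e-8).to_numpy()
    return 1.0 / sd


def fit_mixed(table: pd.DataFrame, spec: ModelSpec, reml: bool = True) -> ModelResult:
    """Fit one mixed (or fixed-effects) model.

    REML by default for final estimates; use ``reml=False`` when comparing
    AICs across fixed structures.  A random term whose grouping column has
    a single level is downgraded to a fixed-effects fit with a logged note.
    Degrees of freedom follow the containment approximation (n minus the
    number of fixed coefficients).
    """
    spec.validate(table)
    data = table.reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"response {spec.response!r} contains non-finite values")

    notes: list[str] = []
    has_random = spec.random_intercept is not None or spec.random_slope is not None
    group_col = spec.random_slope[1] if spec.random_slope else spec.random_intercept
    if has_random and data[group_col].nunique() < 2:
        notes.append(f"random grouping {group_col!r} has one level; downgraded to fixed-effects fit")
        logger.warning(notes[-1])
        has_random = False

    coords = None
    if {"lat", "lon"}.issubset(data.columns):
        coords = data[["lat", "lon"]].copy()

    def _ols_result() -> ModelResult:
        res = smf.ols(spec.formula(), data=data).fit()
        if spec.variance_weights:
            w = _stage_weights(data, res.resid.to_numpy(), spec.variance_weights) ** 2
            res = smf.wls(spec.formula(), data=data, weights=w).fit()
            notes.append("two-stage inverse-variance reweighting applied (WLS)")
        params = _coef_table(res.params.index, res.params.values, res.bse.values, res.df_resid)
        r2m, r2c = _nakagawa_r2(float(np.var(res.fittedvalues)), 0.0, float(res.scale))
        return ModelResult(
            spec=spec,
            params=params,
            aic=float(res.aic),
            r2_marginal=r2m,
            r2_conditional=r2c,
            residuals=np.asarray(res.resid, dtype=float),
            coords=coords,
            converged=True,
            n=len(data),
            method="ols-downgrade" if notes else "ols",
            notes=notes,
        )

    if not has_random:
        return _ols_result()

    re_formula = "1"
    vc_formula = None
    if spec.random_slope is not None:
        slope_term = spec.random_slope[0]
        re_formula = f"1 + {slope_term}"
        if spec.random_intercept is not None and spec.random_intercept != group_col:
            # crossed intercept approximated as a variance component within groups
            vc_formula = {spec.random_intercept: f"0 + C({spec.random_intercept})"}

    def _build(frame):
        return smf.mixedlm(
            spec.formula(),
            data=frame,
            groups=frame[group_col],
            re_formula=re_formula,
            vc_formula=vc_formula,
        )

    def _fit(model):
        # near-zero variance components sit on the boundary where gradient
        # methods stall or go singular; fall through to derivative-free ones
        last_res = None
        last_err: Exception | None = None
        for meth in ("lbfgs", "powell", "nm", "cg"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(reml=reml, method=meth, maxiter=1000)
            except np.linalg.LinAlgError as e:
                last_err = e
                continue
            if getattr(res, "converged", False) and np.isfinite(res.llf):
                return res
            last_res = last_res or res
        if last_res is not None:
            return last_res
        raise last_err if last_err is not None else RuntimeError("mixed fit failed")

    model = _build(data)
    try:
        res = _fit(model)
    except np.linalg.LinAlgError as e:
        notes.append(f"mixed fit numerically singular ({e}); downgraded to fixed-effects fit")
        logger.warning(notes[-1])
        return _ols_result()

    if spec.variance_weights:
        # two-stage feasible weighting: standardise rows by the estimated
        # per-group residual SD and refit (approximates heteroscedastic
        # residual structures the fitter lacks natively)
        sw = _stage_weights(data, np.asarray(res.resid, dtype=float), spec.variance_weights)
        exog2 = model.exog * sw[:, None]
        exog_re2 = model.exog_re * sw[:, None] if model.exog_re is not None else None
        model2 = sm.MixedLM(
            endog=y * sw,
            exog=exog2,
            groups=data[group_col].to_numpy(),
            exog_re=exog_re2,
        )
        model2.data.xnames = model.data.xnames
        res = _fit(model2)
        notes.append("two-stage inverse-variance reweighting applied (variance components dropped in refit)")

    converged = bool(getattr(res, "converged", True))
    if not converged:
        notes.append("optimizer reported non-convergence")
        logger.warning("mixed model %s did not converge", spec.label)

    try:
        resid = np.asarray(res.resid, dtype=float)
    except (ValueError, np.linalg.LinAlgError):
        # BLUPs unavailable when a random covariance is singular; fall back
        # to marginal residuals
        resid = np.asarray(res.model.endog, dtype=float) - res.model.exog @ res.fe_params
        notes.append("singular random-effect covariance; residuals are marginal")

    fe_names = list(res.model.data.xnames)
    k_fixed = len(fe_names)
    df_resid = max(len(data) - k_fixed, 1)
    params = _coef_table(fe_names, res.fe_params, res.bse_fe, df_resid)

    # Nakagawa variance decomposition
    var_fixed = float(np.var(res.model.exog @ res.fe_params))
    var_random = 0.0
    if res.model.exog_re is not None and res.cov_re.size:
        zre = np.asarray(res.model.exog_re, dtype=float)
        cov_re = np.asarray(res.cov_re, dtype=float)
        var_random += float(np.mean(np.einsum("ij,jk,ik->i", zre, cov_re, zre)))
    if getattr(res, "vcomp", None) is not None and len(res.vcomp):
        var_random += float(np.sum(res.vcomp))
    var_resid = float(res.scale)
    r2m, r2c = _nakagawa_r2(var_fixed, var_random, var_resid)

    aic = float(res.aic)
    if not np.isfinite(aic):
        # statsmodels leaves AIC undefined under REML; compute it from the
        # restricted log-likelihood (fixed + variance parameters + scale)
        aic = float(-2.0 * res.llf + 2.0 * (len(res.params) + 1))

    return ModelResult(
        spec=spec,
        params=params,
        aic=aic,
        r2_marginal=r2m,
        r2_conditional=r2c,
        residuals=resid,
        coords=coords,
        converged=converged,
        n=len(data),
        method="mixed",
        notes=notes,
    )


def select_model(table: pd.DataFrame, candidates: list[ModelSpec]) -> tuple[ModelResult, pd.DataFrame]:
    """Fit all candidates by maximum likelihood and pick the lowest AIC.

    Ties (within 1e-6) break to the candidate with fewer parameters, then
    to listing order.  Returns the winning fit and a selection table with
    AIC, delta AIC and parameter counts.
    """
    if not candidates:
        raise ValueError("need at least one candidate spec")
    fits: list[tuple[int, ModelSpec, ModelResult | None, str]] = []
    for i, spec in enumerate(candidates):
        try:
            fits.append((i, spec, fit_mixed(table, spec, reml=False), ""))
        except Exception as e:  # keep diagnostics per candidate
            fits.append((i, spec, None, f"{type(e).__name__}: {e}"))
    ok = [f for f in fits if f[2] is not None and f[2].converged and np.isfinite(f[2].aic)]
    if not ok:
        detail = "; ".join(f"{s.label}: {err or 'did not converge'}" for _, s, _, err in fits)
        raise RuntimeError(f"no candidate model converged ({detail})")

    rows = []
    for i, spec, res, err in fits:
        rows.append(
            {
                "model": spec.label,
                "aic": res.aic if res is not None else float("nan"),
                "k_params": spec.n_parameters(table),
                "converged": res is not None and res.converged,
                "error": err,
            }
        )
    sel = pd.DataFrame(rows)
    best_aic = min(f[2].aic for f in ok)
    sel["delta_aic"] = sel["aic"] - best_aic
    winners = sorted(
        (f for f in ok if f[2].aic <= best_aic + 1e-6),
        key=lambda f: (f[1].n_parameters(table), f[0]),
    )
    best_idx, best_spec = winners[0][0], winners[0][1]
    # refit the winner with REML for final estimates
    best = fit_mixed(table, best_spec, reml=True)
    sel = sel[["model", "aic", "delta_aic", "k_params", "converged", "error"]]
    return best, sel


def inverse_distance_weights(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Row-standardised inverse great-circle-distance weights, zero diagonal."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    d = great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, np.inf)
    if np.any(d == 0):
        raise ValueError("duplicate coordinates give infinite inverse-distance weights; collapse them first")
    w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1, keepdims=True)
    if np.any(rs == 0):
        raise ValueError("isolated point with zero total weight")
    return w / rs


@dataclass
class MoranResult:
    i: float
    expected: float
    variance: float
    z: float
    p: float
    n: int


def morans_i(
    residuals: np.ndarray,
    coords: pd.DataFrame | np.ndarray,
    weights: np.ndarray | None = None,
    collapse_duplicates: bool = True,
) -> MoranResult:
    """Global Moran's I of residuals at coordinates, with a two-sided
    normal-approximation p-value (randomisation variance).

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with centred residuals
    z; E[I] = -1/(n-1).  Weights default to inverse great-circle distance,
    row-standardised; duplicate coordinates (several fish at one station)
    are collapsed to their mean residual so the weight matrix stays finite.
    """
    z = np.asarray(residuals, dtype=float)
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError("coords must be (n, 2) lat/lon")
    if len(z) != len(c):
        raise ValueError("residuals and coords differ in length")

    if weights is None and collapse_duplicates:
        df = pd.DataFrame({"lat": c[:, 0], "lon": c[:, 1], "z": z})
        g = df.groupby(["lat", "lon"], sort=False)["z"].mean().reset_index()
        if len(g) < len(df):
            c = g[["lat", "lon"]].to_numpy()
            z = g["z"].to_numpy()

    n = len(z)
    if n < 4:
        raise ValueError(f"need >= 4 points for Moran's I, got {n}")
    if np.allclose(z, z[0]):
        raise ValueError("residuals are constant; Moran's I is undefined")
    if weights is None:
        w = inverse_distance_weights(c[:, 0], c[:, 1])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")

    zc = z - z.mean()
    s0 = w.sum()
    i_stat = (n / s0) * float(zc @ w @ zc) / float(zc @ zc)
    e_i = -1.0 / (n - 1)

    # randomisation-assumption variance (field-standard normal approximation)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (zc**4).sum() / (zc**2).sum() ** 2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    var_i = num / den - e_i**2
    if var_i <= 0:
        raise ValueError("non-positive Moran variance; weights are degenerate")
    zscore = (i_stat - e_i) / math.sqrt(var_i)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(i=i_stat, expected=e_i, variance=var_i, z=zscore, p=p, n=n)


def percent_change_per_degree(slope_log10: float) -> float:
    """Percent change per deg C implied by a log10-scale slope.

    Positive values are declines: a slope of -0.053 log10 units per deg C
    is a ~11% decrease per degree.
    """
    if not math.isfinite(slope_log10):
        raise ValueError(f"slope must be finite, got {slope_log10}")
    return 100.0 * (1.0 - 10.0**slope_log10)


def slope_from_percent_change(percent: float) -> float:
    """Inverse of :func:`percent_change_per_degree`."""
    return math.log10(1.0 - percent / 100.0)
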