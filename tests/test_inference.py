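"""Mixed models, AIC selection, Moran's I and effect-size transforms."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sizesel import SimulationConfig, generate_dataset
from sizesel.inference import (
    ModelSpec,
    fit_mixed,
    inverse_distance_weights,
    morans_i,
    percent_change_per_degree,
    select_model,
    slope_from_percent_change,
)

from conftest import prepare

PAPER_STRUCTURE = dict(random_intercept="year", random_slope=("sst", "species"))


def _toy_table(rng, n=120, slope=-0.03, noise=0.05, year_sd=0.0, n_years=8):
    sst = rng.uniform(0, 5, n)
    species = rng.choice(["a", "b", "c"], n)
    years = 2000 + np.arange(n_years)
    year = rng.choice(years, n)
    u = dict(zip(years, year_sd * rng.standard_normal(n_years)))
    y = 1.0 + slope * sst + np.array([u[v] for v in year]) + noise * rng.standard_normal(n)
    return pd.DataFrame({"y": y, "sst": sst, "species": species, "year": year})


class TestFitMixed:
    def test_noiseless_linear_response_recovered_exactly(self):
        rng = np.random.default_rng(0)
        df = _toy_table(rng, noise=0.0)
        res = fit_mixed(df, ModelSpec(response="y", fixed=("sst",), **PAPER_STRUCTURE))
        assert res.coef("sst")["estimate"] == pytest.approx(-0.03, abs=1e-6)
        assert res.coef("Intercept")["estimate"] == pytest.approx(1.0, abs=1e-6)

    def test_missing_column_named_in_error(self):
        df = _toy_table(np.random.default_rng(1))
        with pytest.raises(KeyError, match="chla"):
            fit_mixed(df, ModelSpec(response="y", fixed=("chla",)))
        with pytest.raises(KeyError, match="mass"):
            fit_mixed(df, ModelSpec(response="mass", fixed=("sst",)))

    def test_single_level_grouping_downgrades_to_ols(self, caplog):
        df = _toy_table(np.random.default_rng(2))
        df["species"] = "only_one"
        with caplog.at_level("WARNING"):
            res = fit_mixed(df, ModelSpec(response="y", fixed=("sst",), **PAPER_STRUCTURE))
        assert res.method == "ols-downgrade"
        assert res.converged
        assert "one level" in caplog.text

    def test_slope_recovery_on_synthetic_survey(self, hypothesis1_config):
        ds = generate_dataset(hypothesis1_config)
        _, _, summaries = prepare(ds)
        res = fit_mixed(
            summaries, ModelSpec(response="log10_predator_mass", fixed=("sst",), **PAPER_STRUCTURE)
        )
        c = res.coef("sst")
        assert res.converged
        assert abs(c["estimate"] - (-0.03)) < 2 * c["se"]
        assert np.isfinite(res.aic)
        # t = estimate / se consistency
        assert c["t"] == pytest.approx(c["estimate"] / c["se"])

    def test_variance_weights_leave_slope_close(self):
        rng = np.random.default_rng(3)
        df = _toy_table(rng, n=300, noise=0.05)
        spec = ModelSpec(response="y", fixed=("sst",), **PAPER_STRUCTURE, variance_weights=("year",))
        res = fit_mixed(df, spec)
        assert res.coef("sst")["estimate"] == pytest.approx(-0.03, abs=0.02)
        assert any("reweighting" in n for n in res.notes)


class TestSelectModel:
    def test_irrelevant_covariate_rejected_by_aic(self):
        """AIC prefers the true model over one with a pure-noise covariate
        in most replicates."""
        rng = np.random.default_rng(7)
        wins = 0
        n_rep = 50
        for _ in range(n_rep):
            df = _toy_table(rng, n=150, noise=0.1, year_sd=0.15)
            df["noise_cov"] = rng.standard_normal(len(df))
            small = ModelSpec(response="y", fixed=("sst",), random_intercept="year", name="sst")
            big = ModelSpec(
                response="y", fixed=("sst", "noise_cov"), random_intercept="year", name="sst+noise"
            )
            best, sel = select_model(df, [big, small])
            wins += best.spec.name == "sst"
        assert wins >= 0.8 * n_rep

    def test_identical_candidates_tie_to_first(self):
        df = _toy_table(np.random.default_rng(8))
        a = ModelSpec(response="y", fixed=("sst",), name="first")
        b = ModelSpec(response="y", fixed=("sst",), name="second")
        best, sel = select_model(df, [a, b])
        assert best.spec.name == "first"
        assert sel["delta_aic"].min() == pytest.approx(0.0, abs=1e-9)

    def test_single_candidate_returned(self):
        df = _toy_table(np.random.default_rng(9))
        only = ModelSpec(response="y", fixed=("sst",), name="only")
        best, sel = select_model(df, [only])
        assert best.spec.name == "only"
        assert len(sel) == 1


class TestMoransI:
    def _random_instance(self, rng, n):
        lat = rng.uniform(-62, -50, n)
        lon = rng.uniform(-50, -40, n)
        z = rng.standard_normal(n)
        return z, np.column_stack([lat, lon])

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(10)
        for n in (4, 7, 23, 50):
            z, coords = self._random_instance(rng, n)
            w = inverse_distance_weights(coords[:, 0], coords[:, 1])
            zc = z - z.mean()
            brute = (n / w.sum()) * sum(
                w[i, j] * zc[i] * zc[j] for i in range(n) for j in range(n)
            ) / (zc**2).sum()
            res = morans_i(z, coords)
            assert res.i == pytest.approx(brute, abs=1e-12)
            assert res.expected == pytest.approx(-1.0 / (n - 1))

    def test_gradient_residuals_strongly_autocorrelated(self):
        rng = np.random.default_rng(11)
        lat = rng.uniform(-62, -50, 40)
        lon = rng.uniform(-50, -40, 40)
        res = morans_i(lat.copy(), np.column_stack([lat, lon]))
        assert res.i > res.expected + 3 * math.sqrt(res.variance)
        assert res.p < 0.001

    def test_constant_residuals_rejected(self):
        rng = np.random.default_rng(12)
        _, coords = self._random_instance(rng, 10)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(10), coords)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.array([1.0, 2.0, 1.5]), np.array([[0, 0], [1, 1], [2, 2]]))

    def test_duplicate_coordinates_collapsed(self):
        rng = np.random.default_rng(13)
        z, coords = self._random_instance(rng, 12)
        dup_coords = np.vstack([coords, coords[:3]])
        dup_z = np.concatenate([z, z[:3] + 0.1])
        res = morans_i(dup_z, dup_coords)
        assert res.n == 12


class TestPercentChange:
    @pytest.mark.parametrize(
        "slope,expected_round",
        [(-0.053, 11), (-0.027, 6), (0.0, 0)],
    )
    def test_printed_effect_sizes(self, slope, expected_round):
        assert round(percent_change_per_degree(slope)) == expected_round

    def test_signs(self):
        assert percent_change_per_degree(-0.01) > 0  # decline
        assert percent_change_per_degree(0.01) < 0

    @given(slope=st.floats(min_value=-0.5, max_value=0.5))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, slope):
        assert slope_from_percent_change(percent_change_per_degree(slope)) == pytest.approx(
            slope, abs=1e-12
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            percent_change_per_degree(float("nan"))
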