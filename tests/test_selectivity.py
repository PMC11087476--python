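"""Size classes, co-occurrence grouping, KDEs and preference distributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sizesel import SimulationConfig, generate_dataset
from sizesel.config import SelectivityParams
from sizesel.selectivity import (
    NoPreyInRange,
    comparable_range,
    environmental_distribution,
    fit_kde,
    group_cooccurrence,
    preference_distribution,
    selectivity_table,
    size_class_bounds,
    size_class_index,
)

from conftest import prepare


class TestSizeClasses:
    def test_printed_extreme_bounds(self):
        """The smallest and largest observed classes have bounds
        10^-0.525 = 0.30 g and 10^1.575 = 37.58 g."""
        lo_small, _ = size_class_bounds(size_class_index(0.30))
        lo_big, _ = size_class_bounds(size_class_index(38.0))
        assert round(lo_small, 2) == 0.30
        assert round(lo_big, 2) == 37.58
        assert lo_small == pytest.approx(10.0**-0.525)
        assert lo_big == pytest.approx(10.0**1.575)

    def test_class_membership_half_open(self):
        k = size_class_index(0.30)
        assert k == -11
        lo, hi = size_class_bounds(k)
        assert size_class_index(lo) == k  # mass exactly on a bound -> upper class
        assert size_class_index(hi) == k + 1
        assert size_class_index(np.nextafter(hi, 0)) == k

    def test_width_is_005_log10(self):
        for k in (-11, 0, 17, 31):
            lo, hi = size_class_bounds(k)
            assert np.log10(hi) - np.log10(lo) == pytest.approx(0.05)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            size_class_index(0.0)


class TestGroupCooccurrence:
    def _hauls(self, rows):
        return pd.DataFrame(rows, columns=["station", "lat", "lon", "date", "sst"])

    def test_identical_place_and_day_single_group(self):
        p = self._hauls([(0, -60.0, -45.0, "2008-01-10", 2.0)])
        z = self._hauls([(1, -60.0, -45.0, "2008-01-10", 2.2)])
        groups = group_cooccurrence(p, z, max_km=100, max_days=5)
        assert len(groups) == 1
        assert groups[0].mean_sst == pytest.approx(2.1)

    def test_distant_hauls_split(self):
        p = self._hauls([(0, -60.0, -45.0, "2008-01-10", 2.0), (1, -55.5, -45.0, "2008-01-10", 3.0)])
        z = self._hauls([(2, -60.0, -45.0, "2008-01-10", 2.0), (3, -55.5, -45.0, "2008-01-10", 3.0)])
        assert len(group_cooccurrence(p, z, max_km=100, max_days=5)) == 2

    def test_same_place_far_apart_in_time_split(self):
        p = self._hauls([(0, -60.0, -45.0, "2008-01-10", 2.0), (1, -60.0, -45.0, "2008-02-10", 2.0)])
        z = self._hauls([(2, -60.0, -45.0, "2008-01-10", 2.0), (3, -60.0, -45.0, "2008-02-10", 2.0)])
        assert len(group_cooccurrence(p, z, max_km=100, max_days=5)) == 2

    def test_predator_only_cluster_dropped_with_warning(self, caplog):
        p = self._hauls([(0, -60.0, -45.0, "2008-01-10", 2.0), (1, -50.0, -45.0, "2008-01-10", 4.0)])
        z = self._hauls([(2, -60.0, -45.0, "2008-01-10", 2.0)])
        with caplog.at_level("WARNING"):
            groups = group_cooccurrence(p, z, max_km=100, max_days=5)
        assert len(groups) == 1
        assert "no zooplankton" in caplog.text

    def test_planted_cluster_structure_recovered(self, default_dataset, default_prepared):
        """The generator plants 24 spatio-temporal station clusters."""
        st_ = default_prepared["stations"]
        groups = group_cooccurrence(st_, st_, max_km=100, max_days=5)
        assert len(groups) == 24
        # group ids deterministic under row shuffling
        shuffled = st_.sample(frac=1.0, random_state=0)
        regroups = group_cooccurrence(shuffled, shuffled, max_km=100, max_days=5)
        assert [g.stations for g in groups] == [g.stations for g in regroups]


class TestFitKde:
    def test_identical_values_single_bump(self):
        grid = np.linspace(-4, -2, 512)
        dens = fit_kde([-3.0] * 20, np.ones(20), grid)
        assert grid[np.argmax(dens)] == pytest.approx(-3.0, abs=np.diff(grid)[0])
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_weights_equal_replication(self):
        grid = np.linspace(-5, -1, 512)
        weighted = fit_kde([-3.5, -2.0], [2.0, 1.0], grid)
        replicated = fit_kde([-3.5, -3.5, -2.0], [1.0, 1.0, 1.0], grid)
        np.testing.assert_allclose(weighted, replicated, atol=1e-12)

    def test_large_sample_close_to_true_pdf(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(20000)
        grid = np.linspace(-4, 4, 1024)
        dens = fit_kde(x, np.ones_like(x), grid)
        assert np.max(np.abs(dens - stats.norm.pdf(grid))) < 0.05

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            fit_kde([1.0, 2.0], [0.0, 0.0], np.linspace(0, 3, 64))


class TestEnvironmentalDistribution:
    def _zoop(self, masses, weights):
        return pd.DataFrame({"mass_g": masses, "density_per_1000m3": weights})

    def test_single_taxon_bump(self):
        grid = np.linspace(-4, -2, 512)
        dens = environmental_distribution(self._zoop([1e-3], [5.0]), grid)
        assert grid[np.argmax(dens)] == pytest.approx(-3.0, abs=np.diff(grid)[0])

    def test_mixture_mean_matches_weighted_mass_mean(self):
        # mean of a Gaussian mixture is the weighted mean of the components
        masses, weights = [1e-3, 1e-2], [70.0, 30.0]
        grid = np.linspace(-6, 1, 2048)  # wide grid: negligible truncation
        dens = environmental_distribution(self._zoop(masses, weights), grid)
        kde_mean = np.trapezoid(grid * dens, grid)
        expected = 0.7 * -3.0 + 0.3 * -2.0
        assert kde_mean == pytest.approx(expected, abs=0.02)

    def test_no_taxa_in_range_signals_skip(self):
        with pytest.raises(NoPreyInRange):
            environmental_distribution(self._zoop([10.0], [1.0]), np.linspace(-4, -2, 64))


class TestPreferenceDistribution:
    def test_neutral_feeding_uniform_preference(self):
        grid = np.linspace(-4, -1, 512)
        dens = stats.norm.pdf(grid, -2.5, 0.4)
        dens /= np.trapezoid(dens, grid)
        pref = preference_distribution(dens, dens, grid, floor_quantile=0.0)
        assert np.ptp(pref.preference) < 1e-10  # constant ratio
        assert pref.mean_preferred == pytest.approx(-2.5)  # grid midpoint
        # with the default tail floor the mean is still the midpoint (symmetry)
        pref_floored = preference_distribution(dens, dens, grid, floor_quantile=0.01)
        assert pref_floored.mean_preferred == pytest.approx(-2.5, abs=1e-6)

    def test_uniform_preference_mean_is_interval_midpoint(self):
        grid = np.linspace(-4, -1, 512)
        realised = np.full_like(grid, 1 / 3)
        env = np.full_like(grid, 1 / 3)
        assert preference_distribution(realised, env, grid).mean_preferred == pytest.approx(-2.5)

    def test_grid_mismatch_rejected(self):
        g1, g2 = np.linspace(0, 1, 64), np.linspace(0, 1, 65)
        with pytest.raises(ValueError):
            preference_distribution(np.ones(64), np.ones(65), g2)

    def test_floor_prevents_ratio_blowup(self):
        grid = np.linspace(-4, -1, 512)
        env = stats.norm.pdf(grid, -3.5, 0.2)
        env /= np.trapezoid(env, grid)
        realised = stats.norm.pdf(grid, -1.5, 0.2)
        realised /= np.trapezoid(realised, grid)
        pref = preference_distribution(realised, env, grid, floor_quantile=0.01)
        assert np.all(np.isfinite(pref.preference))
        assert np.trapezoid(pref.preference, grid) == pytest.approx(1.0, abs=1e-6)


class TestPipelineInvariants:
    def test_distribution_invariants_on_survey(self, default_prepared):
        ds = default_prepared["dataset"]
        table, dists = selectivity_table(
            default_prepared["summaries"],
            ds.stomachs,
            ds.zooplankton,
            default_prepared["stations"],
            return_distributions=True,
        )
        assert len(table) > 20
        for key, pref in dists.items():
            g = pref.grid
            assert np.trapezoid(pref.realised, g) == pytest.approx(1.0, abs=1e-6)
            assert np.trapezoid(pref.environmental, g) == pytest.approx(1.0, abs=1e-6)
            assert np.trapezoid(pref.preference, g) == pytest.approx(1.0, abs=1e-6)
            assert np.all(pref.preference >= 0)
            assert g[0] <= pref.mean_preferred <= g[-1]
        # table-level: every aggregate meets the pooled-prey threshold
        assert (table["n_prey"] >= 10).all()
        assert (table["n_predators"] >= 1).all()

    def test_monotone_recovery_of_kernel_slope(self):
        """A steeper optimal-prey-size vs predator-size kernel yields a
        steeper fitted slope of preferred size on size class."""
        fitted = []
        for slope in (0.0, 0.5, 1.0):
            cfg = SimulationConfig(seed=21, selectivity_slope=slope, selectivity_intercept=-2.9)
            ds = generate_dataset(cfg)
            stations, _, summaries = prepare(ds)
            table = selectivity_table(summaries, ds.stomachs, ds.zooplankton, stations)
            b = np.polyfit(table["class_mid_log10"], table["mean_preferred_log10"], 1)[0]
            fitted.append(b)
        assert fitted[0] < fitted[1] < fitted[2]


class TestComparableRange:
    def test_intersection_padded(self):
        lo, hi = comparable_range(np.array([-3.0, -2.0]), np.array([-4.0, -2.5]), pad=0.1)
        assert lo == pytest.approx(-3.1)
        assert hi == pytest.approx(-2.4)

    def test_disjoint_ranges_rejected(self):
        with pytest.raises(ValueError):
            comparable_range(np.array([1.0, 2.0]), np.array([-4.0, -3.0]), pad=0.0)
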