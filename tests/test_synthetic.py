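"""Generators: determinism, invariants, variogram recovery, serialisation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist

from airlur.qc import classify_schedule, reported_days
from airlur.synthetic import (generate_blocks, generate_landscape,
                              generate_truth_field, monitor_series_to_csv,
                              read_blocks_csv, read_landscape,
                              sample_monitor_series, site_coords_km,
                              write_blocks_csv, write_landscape)
from airlur.qc import read_monitor_csv


class TestGenerateLandscape:
    def test_deterministic_for_same_seed(self):
        a = generate_landscape(seed=1, n_roads=10, n_sources=5, domain_km=50.0)
        b = generate_landscape(seed=1, n_roads=10, n_sources=5, domain_km=50.0)
        np.testing.assert_array_equal(a.roads.segments, b.roads.segments)
        np.testing.assert_array_equal(a.sources.points, b.sources.points)
        np.testing.assert_array_equal(a.population.values, b.population.values)
        np.testing.assert_array_equal(a.satellite.values, b.satellite.values)

    def test_different_seeds_differ(self):
        a = generate_landscape(seed=1, n_roads=10, n_sources=5, domain_km=50.0)
        b = generate_landscape(seed=2, n_roads=10, n_sources=5, domain_km=50.0)
        assert not np.array_equal(a.population.values, b.population.values)

    def test_empty_feature_lists_allowed(self):
        land = generate_landscape(seed=1, n_roads=0, n_sources=0, domain_km=50.0)
        assert land.roads.segments.shape == (0, 4)
        assert land.sources.points.shape == (0, 2)
        assert land.population.values.size > 0

    def test_nonpositive_domain_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(seed=1, domain_km=0.0)

    def test_invariants(self, landscape):
        assert np.all(landscape.population.values >= 0)
        assert landscape.satellite.cellsize > landscape.population.cellsize
        pts = landscape.roads.segments.reshape(-1, 2)
        assert pts.min() >= 0 and pts.max() <= landscape.domain_km

    def test_io_round_trip(self, landscape, tmp_path):
        write_landscape(landscape, tmp_path / "land")
        back = read_landscape(tmp_path / "land")
        np.testing.assert_allclose(back.roads.segments, landscape.roads.segments,
                                   atol=1e-6)
        np.testing.assert_allclose(back.population.values, landscape.population.values,
                                   rtol=1e-5)
        assert back.domain_km == landscape.domain_km


class TestTruthField:
    def test_zero_variance_field_is_exact_linear_mean(self, landscape):
        truth = generate_truth_field(landscape, partial_sill=0.0, range_km=10.0,
                                     nugget=0.0, seed=1)
        pts = np.array([[5.0, 5.0], [30.0, 40.0]])
        np.testing.assert_array_equal(truth.truth_fn(pts), truth.mean(pts))

    def test_same_point_same_value(self, landscape):
        truth = generate_truth_field(landscape, partial_sill=0.3, seed=2)
        p = np.array([[12.0, 34.0]])
        first = truth.truth_fn(p)
        rng = np.random.default_rng(0)
        truth.truth_fn(rng.uniform(0, 60, (25, 2)))  # interleave other queries
        np.testing.assert_array_equal(truth.truth_fn(p), first)

    def test_back_transformed_concentration_nonnegative(self, landscape):
        truth = generate_truth_field(landscape, partial_sill=0.4, seed=3)
        rng = np.random.default_rng(1)
        vals = truth.truth_fn(rng.uniform(0, 60, (200, 2)))
        assert np.all(np.maximum(vals, 0.0) ** 2 >= 0)

    def test_negative_variance_rejected(self, landscape):
        with pytest.raises(ValueError):
            generate_truth_field(landscape, partial_sill=-1.0)
        with pytest.raises(ValueError):
            generate_truth_field(landscape, nugget=-0.1)

    def test_variogram_recovery(self):
        """With zero mean coefficients the empirical semivariogram of 600
        samples, binned to 10 lags, fits the exponential model within 25%
        on partial sill and range."""
        land = generate_landscape(seed=5, n_roads=5, n_sources=3, domain_km=100.0)
        sill_true, range_true = 1.0, 20.0
        truth = generate_truth_field(land, coeffs=np.zeros(4), offset=0.0,
                                     partial_sill=sill_true, range_km=range_true,
                                     nugget=0.0, seed=42)
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 100, (600, 2))
        z = truth.truth_fn(pts)
        d = pdist(pts)
        gamma = 0.5 * pdist(z[:, None], "sqeuclidean")
        bins = np.linspace(0, 60.0, 11)
        which = np.digitize(d, bins) - 1
        lag_mid, lag_gamma = [], []
        for b in range(10):
            mask = which == b
            if mask.sum() > 30:
                lag_mid.append(d[mask].mean())
                lag_gamma.append(gamma[mask].mean())

        def model(h, sill, rng_km):
            return sill * (1.0 - np.exp(-h / rng_km))

        (sill_hat, range_hat), _ = curve_fit(model, lag_mid, lag_gamma,
                                             p0=[1.0, 10.0], maxfev=10000)
        assert abs(sill_hat - sill_true) / sill_true < 0.25
        assert abs(range_hat - range_true) / range_true < 0.25


class TestSampleMonitorSeries:
    def test_no_missingness_everyday_has_366_days(self, truth):
        series = sample_monitor_series(truth, n_sites=3, year=2016,
                                       missingness=0.0, seed=1)
        for s in series:
            assert len(reported_days(s)) == 366  # leap year

    def test_one_in_three_modal_gap(self, truth):
        series = sample_monitor_series(truth, n_sites=4,
                                       schedule_mix={"one_in_three": 1.0}, seed=2)
        for s in series:
            assert classify_schedule(s) == "one_in_three"
            n_sched = len(reported_days(s))
            assert 110 <= n_sched <= 123

    def test_deterministic_and_seed_sensitive(self, truth):
        a = sample_monitor_series(truth, n_sites=3, seed=5)
        b = sample_monitor_series(truth, n_sites=3, seed=5)
        c = sample_monitor_series(truth, n_sites=3, seed=6)
        for sa, sb in zip(a, b):
            pd.testing.assert_series_equal(sa.records, sb.records)
            assert (sa.lon, sa.lat) == (sb.lon, sb.lat)
        assert not np.array_equal(a[0].records.to_numpy(), c[0].records.to_numpy())

    def test_fewer_than_two_sites_rejected(self, truth):
        with pytest.raises(ValueError):
            sample_monitor_series(truth, n_sites=1)

    def test_clustered_sites_concentrate_near_foci(self, truth):
        series = sample_monitor_series(truth, n_sites=40, clustered=True, seed=3)
        coords = site_coords_km(series)
        foci = truth.landscape.urban_foci(4)
        from scipy.spatial.distance import cdist
        nearest = cdist(coords, foci).min(axis=1)
        assert np.median(nearest) < 0.15 * truth.landscape.domain_km

    def test_hourly_gas_series_have_hourly_cadence(self, truth):
        series = sample_monitor_series(truth, n_sites=2, pollutant="NO2", seed=4,
                                       missingness=0.9)
        assert all(s.cadence == "hourly" for s in series)
        hours = pd.DatetimeIndex(series[0].records.index).hour
        assert hours.nunique() > 1

    def test_csv_round_trip(self, truth, tmp_path):
        series = sample_monitor_series(truth, n_sites=3, seed=9, missingness=0.3)
        monitor_series_to_csv(series, tmp_path / "monitors.csv")
        back = read_monitor_csv(tmp_path / "monitors.csv")
        assert len(back) == 3
        for orig, rt in zip(series, back):
            assert orig.site_id == rt.site_id
            np.testing.assert_allclose(rt.records.to_numpy(), orig.records.to_numpy())


class TestGenerateBlocks:
    def test_single_block(self, landscape):
        df = generate_blocks(1, landscape, seed=1)
        assert len(df) == 1
        assert df["population"].iloc[0] > 0

    def test_all_populations_positive(self, landscape):
        df = generate_blocks(500, landscape, seed=2)
        assert (df["population"] > 0).all()

    def test_fips_nesting_is_a_function(self, landscape):
        df = generate_blocks(400, landscape, seed=3)
        assert df["block_fips"].is_unique
        # each block group maps to exactly one tract, each tract to one county
        assert (df.groupby("bg_fips")["tract_fips"].nunique() == 1).all()
        assert (df.groupby("tract_fips")["county_fips"].nunique() == 1).all()
        # prefix consistency
        assert (df.apply(lambda r: r["bg_fips"].startswith(r["tract_fips"]), axis=1)).all()
        assert (df.apply(lambda r: r["tract_fips"].startswith(r["county_fips"]), axis=1)).all()

    def test_tract_then_county_grouping_partitions_blocks(self, landscape):
        df = generate_blocks(300, landscape, seed=4)
        by_tract = {b for g in df.groupby("tract_fips").groups.values() for b in g}
        by_county = {b for g in df.groupby("county_fips").groups.values() for b in g}
        assert by_tract == set(df.index)
        assert by_county == set(df.index)

    def test_csv_round_trip_preserves_fips_strings(self, landscape, tmp_path):
        df = generate_blocks(50, landscape, seed=5)
        write_blocks_csv(df, tmp_path / "blocks.csv")
        back = read_blocks_csv(tmp_path / "blocks.csv")
        assert (back["block_fips"] == df["block_fips"]).all()
        np.testing.assert_allclose(back["x_km"], df["x_km"], atol=1e-6)
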