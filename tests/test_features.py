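"""Feature-extraction oracles: closed-form index values, hand-computed
trapezoids, sort-based percentile checks, and assembly/imputation rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phenomass as pm
from phenomass.features import (FeatureCatalog, FeatureDef,
                                assemble_feature_tensor,
                                extract_hyperspectral_features,
                                extract_lidar_features,
                                extract_weather_features)
from phenomass.trialsim import PlotPointCloud


WL = np.linspace(400, 1000, 272)


class TestHyperspectral:
    def test_flat_spectrum_symmetries(self, catalog):
        vals = extract_hyperspectral_features(WL, np.full(272, 0.5), catalog)
        for f in catalog.by_source("hyperspectral"):
            if f.kind == "nd_index":
                assert vals[f.name] == pytest.approx(0.0, abs=1e-12)
            elif f.kind == "deriv" and f.params.get("order", 1) == 1:
                assert vals[f.name] == pytest.approx(0.0, abs=1e-12)
            elif f.kind == "ratio":
                assert vals[f.name] == pytest.approx(1.0)

    def test_ndvi_closed_form(self):
        cat = FeatureCatalog([FeatureDef("ndvi", "hyperspectral", "nd_index",
                                         {"band1": 800.0, "band2": 670.0})])
        refl = np.full(272, 0.1)
        refl[np.argmin(np.abs(WL - 800))] = 0.5
        vals = extract_hyperspectral_features(WL, refl, cat)
        assert vals["ndvi"] == pytest.approx((0.5 - 0.1) / (0.5 + 0.1), abs=1e-12)

    def test_integration_matches_hand_trapezoid(self):
        # triangular spectrum on a 7-point grid; area by hand
        wl = np.array([500., 520., 540., 560., 580., 600., 620.])
        refl = np.array([0.0, 0.25, 0.5, 0.75, 0.5, 0.25, 0.0])
        cat = FeatureCatalog([FeatureDef("aud", "hyperspectral", "aud",
                                         {"low": 500.0, "high": 600.0})])
        # trapezoid over [500, 600]: 20 * (sum of interior + half endpoints)
        hand = 20 * (0.0 / 2 + 0.25 + 0.5 + 0.75 + 0.5 + 0.25 / 2)
        vals = extract_hyperspectral_features(wl, refl, cat)
        assert vals["aud"] == pytest.approx(hand, abs=1e-12)

    def test_wavelength_outside_grid_rejected(self):
        cat = FeatureCatalog([FeatureDef("bad", "hyperspectral", "nd_index",
                                         {"band1": 1200.0, "band2": 670.0})])
        with pytest.raises(ValueError, match="bad"):
            extract_hyperspectral_features(WL, np.full(272, 0.5), cat)

    def test_nearest_band_stability(self):
        """With reference wavelengths on band centres, perturbing the grid
        by less than half the band spacing leaves index features unchanged."""
        wl = np.arange(400.0, 1001.0, 5.0)  # 670 and 800 are band centres
        cat = FeatureCatalog([FeatureDef("nd", "hyperspectral", "nd_index",
                                         {"band1": 800.0, "band2": 670.0})])
        refl = 0.2 + 0.3 * np.linspace(0, 1, len(wl)) ** 2
        a = extract_hyperspectral_features(wl, refl, cat)
        for shift in (-2.4, -1.0, 1.0, 2.4):  # |shift| < 2.5 = half spacing
            b = extract_hyperspectral_features(wl + shift, refl, cat)
            assert b["nd"] == pytest.approx(a["nd"], abs=1e-12)

    @given(c=st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        cat = FeatureCatalog([
            FeatureDef("nd", "hyperspectral", "nd_index",
                       {"band1": 800.0, "band2": 670.0}),
            FeatureDef("aud", "hyperspectral", "aud",
                       {"low": 500.0, "high": 600.0}),
        ])
        rng = np.random.default_rng(0)
        refl = 0.1 + 0.5 * rng.random(272)
        a = extract_hyperspectral_features(WL, refl, cat)
        b = extract_hyperspectral_features(WL, c * refl, cat)
        assert b["nd"] == pytest.approx(a["nd"], rel=1e-9)
        assert b["aud"] == pytest.approx(c * a["aud"], rel=1e-9)


def _cloud(z_canopy, z_ground=(0.0,), plot="p", date=0):
    n = len(z_canopy) + len(z_ground)
    pts = np.zeros((n, 3))
    pts[:, 0] = np.linspace(0, 1, n)
    pts[:, 1] = np.linspace(0, 3, n)
    pts[:len(z_ground), 2] = z_ground
    pts[len(z_ground):, 2] = z_canopy
    grd = np.zeros(n, dtype=bool)
    grd[:len(z_ground)] = True
    return PlotPointCloud(pts, grd, plot, date)


class TestLidar:
    def test_cover_counting(self):
        cat = FeatureCatalog([FeatureDef("cover", "lidar", "canopy_cover",
                                         {"threshold": 1.0})])
        # 10 points total, 4 above 1 m
        cloud = _cloud([1.5, 1.2, 2.0, 1.1, 0.5, 0.2], z_ground=[0.0] * 4)
        res = extract_lidar_features(cloud, cat)
        assert res.values["cover"] == pytest.approx(0.4)

    def test_degenerate_equal_heights(self):
        cat = FeatureCatalog([
            FeatureDef("p50", "lidar", "height_percentile", {"level": 50.0}),
            FeatureDef("p90", "lidar", "height_percentile", {"level": 90.0}),
            FeatureDef("sd", "lidar", "height_std"),
        ])
        cloud = _cloud([2.0] * 10)
        res = extract_lidar_features(cloud, cat)
        assert res.values["p50"] == pytest.approx(2.0)
        assert res.values["p90"] == pytest.approx(2.0)
        assert res.values["sd"] == pytest.approx(0.0)

    def test_percentiles_against_sort_oracle(self):
        rng = np.random.default_rng(42)
        z = rng.uniform(0, 3, 100)
        levels = [10, 25, 50, 75, 90, 99]
        cat = FeatureCatalog([FeatureDef(f"p{l}", "lidar", "height_percentile",
                                         {"level": float(l)}) for l in levels])
        res = extract_lidar_features(_cloud(z), cat)
        z_sorted = np.sort(z)
        for l in levels:
            # linear-interpolation percentile on the sorted sample
            pos = (l / 100) * (len(z) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            oracle = z_sorted[lo] + (pos - lo) * (z_sorted[hi] - z_sorted[lo])
            assert res.values[f"p{l}"] == pytest.approx(oracle, abs=1e-9)

    def test_percentiles_monotone_in_level(self, catalog, trial):
        cloud = next(iter(trial.clouds.values()))
        res = extract_lidar_features(cloud, catalog)
        levels = sorted(f.params["level"] for f in catalog.by_source("lidar")
                        if f.kind == "height_percentile")
        vals = [res.values[f"h_p{int(l)}"] for l in levels]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_height_normalised_to_median_ground(self):
        cat = FeatureCatalog([FeatureDef("p100", "lidar", "height_percentile",
                                         {"level": 100.0})])
        cloud = _cloud([3.0, 2.5], z_ground=[0.8, 1.0, 1.2])
        res = extract_lidar_features(cloud, cat)
        assert res.values["p100"] == pytest.approx(3.0 - 1.0)

    def test_empty_canopy_structured_outcome(self):
        cat = FeatureCatalog([
            FeatureDef("p50", "lidar", "height_percentile", {"level": 50.0}),
            FeatureDef("cover", "lidar", "canopy_cover", {"threshold": 0.5}),
        ])
        cloud = _cloud([], z_ground=[0.0, 0.01])
        res = extract_lidar_features(cloud, cat)
        assert res.empty_canopy
        assert res.values["cover"] == 0.0
        assert res.values["p50"] == 0.0

    def test_no_ground_points_rejected(self):
        cat = FeatureCatalog([FeatureDef("m", "lidar", "height_mean")])
        pts = np.ones((5, 3))
        cloud = PlotPointCloud(pts, np.zeros(5, dtype=bool), "p", 0)
        with pytest.raises(ValueError, match="ground"):
            extract_lidar_features(cloud, cat)

    def test_cover_bounded(self, catalog, trial):
        for key in list(trial.clouds)[:8]:
            res = extract_lidar_features(trial.clouds[key], catalog)
            for f in catalog.by_source("lidar"):
                if f.kind == "canopy_cover":
                    assert 0.0 <= res.values[f.name] <= 1.0


class TestWeatherFeatures:
    def _weather(self, tmeans, precip=None, rad=None):
        n = len(tmeans)
        return pd.DataFrame({
            "day": np.arange(n),
            "t_min": np.array(tmeans) - 5.0,
            "t_max": np.array(tmeans) + 5.0,
            "precipitation": precip if precip is not None else np.zeros(n),
            "radiation": rad if rad is not None else np.full(n, 20.0),
        })

    def test_gdd_hand_arithmetic(self, catalog):
        w = self._weather([15.0, 20.0, 25.0])
        vals = extract_weather_features(w, 0, 2, catalog)
        assert vals["gdd"] == pytest.approx(5 + 10 + 15)

    def test_single_day_below_base(self, catalog):
        w = self._weather([8.0])
        vals = extract_weather_features(w, 0, 0, catalog)
        assert vals["gdd"] == 0.0

    def test_cumulative_features_non_decreasing(self, weather, catalog):
        prev = None
        for day in range(0, len(weather), 10):
            vals = extract_weather_features(weather, 0, day, catalog)
            if prev is not None:
                for k in vals:
                    assert vals[k] >= prev[k] - 1e-9
            prev = vals

    def test_gap_in_series_rejected(self, catalog):
        w = self._weather([15.0, 20.0, 25.0])
        w = w[w["day"] != 1]
        with pytest.raises(ValueError, match="day 1"):
            extract_weather_features(w, 0, 2, catalog)

    def test_sowing_after_obs_rejected(self, catalog):
        w = self._weather([15.0, 20.0])
        with pytest.raises(ValueError, match="sowing"):
            extract_weather_features(w, 1, 0, catalog)


class TestAssembly:
    def _inputs(self, catalog, plots=("p1", "p2"), dates=(0, 1)):
        rng = np.random.default_rng(0)
        hyper, wfeat, lidar = {}, {}, {}
        h_names = [f.name for f in catalog.by_source("hyperspectral")]
        l_names = [f.name for f in catalog.by_source("lidar")]
        w_names = [f.name for f in catalog.by_source("weather")]
        for p in plots:
            for t in dates:
                hyper[(p, t)] = {n: rng.random() for n in h_names}
                wfeat[(p, t)] = {n: rng.random() for n in w_names}
                lidar[(p, t)] = {n: rng.random() for n in l_names}
        return hyper, wfeat, lidar

    def test_complete_inputs_no_imputation(self, catalog):
        hyper, wfeat, lidar = self._inputs(catalog)
        tens = assemble_feature_tensor(catalog, ["p1", "p2"], [0, 1],
                                       [100.0, 200.0], hyper, wfeat, lidar)
        assert not tens.imputed.any()
        assert tens.values.shape == (2, len(catalog.names), 2)

    def test_missing_lidar_date_flagged_exactly(self, catalog):
        hyper, wfeat, lidar = self._inputs(catalog)
        del lidar[("p1", 1)]
        tens = assemble_feature_tensor(catalog, ["p1", "p2"], [0, 1],
                                       [100.0, 200.0], hyper, wfeat, lidar)
        lidar_idx = [i for i, s in enumerate(tens.feature_sources)
                     if s == "lidar"]
        assert tens.imputed[0, lidar_idx, 1].all()
        assert not tens.imputed[0, lidar_idx, 0].any()
        assert not tens.imputed[1].any()
        # carried block equals the nearest date's block
        assert np.array_equal(tens.values[0, lidar_idx, 1],
                              tens.values[0, lidar_idx, 0])

    def test_order_independence(self, catalog):
        hyper, wfeat, lidar = self._inputs(catalog, plots=("a", "b", "c"))
        t1 = assemble_feature_tensor(catalog, ["a", "b", "c"], [0, 1],
                                     [1.0, 2.0], hyper, wfeat, lidar)
        shuffled = dict(reversed(list(hyper.items())))
        t2 = assemble_feature_tensor(catalog, ["a", "b", "c"], [0, 1],
                                     [1.0, 2.0], shuffled, wfeat, lidar)
        assert np.array_equal(t1.values, t2.values)

    def test_missing_plot_rejected(self, catalog):
        hyper, wfeat, lidar = self._inputs(catalog)
        with pytest.raises(ValueError, match="p3"):
            assemble_feature_tensor(catalog, ["p1", "p2", "p3"], [0, 1],
                                    [1.0, 2.0], hyper, wfeat, lidar)

    def test_long_csv_round_trip(self, tensor, tmp_path):
        path = tmp_path / "tensor.csv"
        tensor.to_long_csv(path)
        back = pm.FeatureTensor.from_long_csv(path)
        assert back.feature_names == tensor.feature_names
        assert np.allclose(back.values, tensor.values)
        assert np.array_equal(back.imputed, tensor.imputed)


class TestCatalog:
    def test_default_shape(self, catalog):
        by = {s: len(catalog.by_source(s))
              for s in ("hyperspectral", "lidar", "weather")}
        assert by == {"hyperspectral": 22, "lidar": 19, "weather": 3}

    def test_yaml_round_trip(self, catalog, tmp_path):
        p = tmp_path / "cat.yaml"
        catalog.to_yaml(p)
        back = FeatureCatalog.from_yaml(p)
        assert back.names == catalog.names
        assert [f.params for f in back.features] == \
            [f.params for f in catalog.features]

    def test_duplicate_names_rejected(self):
        f = FeatureDef("x", "lidar", "height_mean")
        with pytest.raises(ValueError, match="unique"):
            FeatureCatalog([f, f])

    def test_bad_percentile_level_rejected(self):
        with pytest.raises(ValueError, match="percentile"):
            FeatureCatalog([FeatureDef("p0", "lidar", "height_percentile",
                                       {"level": 0.0})])
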