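"""Plot-level feature extraction: hyperspectral indices, LiDAR canopy
metrics and cumulative weather features, assembled into the plots x
features x dates tensor consumed by the prediction model.

The feature catalog is data (YAML-serialisable), so the exact feature list
used in any given campaign can be swapped in without code changes.  The
default catalog ships 22 hyperspectral features (10 two-band vegetation
indices, 8 integration ranges, 4 spectral-derivative features), 19 LiDAR
canopy metrics and 3 cumulative weather features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .trialsim import PlotPointCloud, TrialData

__all__ = [
    "FeatureDef",
    "FeatureCatalog",
    "FeatureTensor",
    "default_catalog",
    "extract_hyperspectral_features",
    "extract_lidar_features",
    "extract_weather_features",
    "assemble_feature_tensor",
    "extract_trial_features",
]


@dataclass(frozen=True)
class FeatureDef:
    """One catalog entry: name, data source and extraction parameters."""

    name: str
    source: str  # "hyperspectral" | "lidar" | "weather"
    kind: str
    params: dict = field(default_factory=dict)


@dataclass
class FeatureCatalog:
    """Ordered feature definitions; order fixes the tensor feature axis."""

    features: list[FeatureDef]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("FeatureCatalog names must be unique")
        for f in self.features:
            lvl = f.params.get("level")
            if lvl is not None and not (0 < lvl <= 100):
                raise ValueError(f"percentile level of {f.name} must be in (0, 100]")

    def by_source(self, source: str) -> list[FeatureDef]:
        return [f for f in self.features if f.source == source]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def drop(self, names: Iterable[str]) -> "FeatureCatalog":
        names = set(names)
        unknown = names - set(self.names)
        if unknown:
            raise KeyError(f"unknown features: {sorted(unknown)}")
        return FeatureCatalog([f for f in self.features if f.name not in names])

    def to_yaml(self, path: str | Path) -> None:
        data = [{"name": f.name, "source": f.source, "kind": f.kind,
                 "params": dict(f.params)} for f in self.features]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureCatalog":
        data = yaml.safe_load(Path(path).read_text())
        return cls([FeatureDef(d["name"], d["source"], d["kind"],
                               d.get("params", {})) for d in data])


def default_catalog(gdd_base: float = 10.0, cover_thresholds=(0.5, 1.0, 2.0),
                    volume_cell: float = 0.1) -> FeatureCatalog:
    """Default 44-feature catalog (22 hyperspectral + 19 LiDAR + 3 weather).

    The hyperspectral indices are common two-band formulations (NDVI-style
    normalised differences and simple ratios), integration features are
    areas under the reflectance curve over visible / red-edge / NIR ranges,
    and the derivative features sample the red-edge slope and curvature.
    GDD uses base temperature ``gdd_base`` (C), the sorghum standard 10 C.
    """
    fs: list[FeatureDef] = []

    nd_pairs = [("ndvi", 800, 670), ("gndvi", 800, 550), ("ndre", 790, 720),
                ("nd_750_705", 750, 705), ("nd_858_645", 858, 645),
                ("nd_800_680", 800, 680), ("psnd", 800, 635),
                ("nd_860_720", 860, 720)]
    for name, b1, b2 in nd_pairs:
        fs.append(FeatureDef(name, "hyperspectral", "nd_index",
                             {"band1": float(b1), "band2": float(b2)}))
    fs.append(FeatureDef("sr_800_670", "hyperspectral", "ratio",
                         {"band1": 800.0, "band2": 670.0}))
    fs.append(FeatureDef("sr_750_550", "hyperspectral", "ratio",
                         {"band1": 750.0, "band2": 550.0}))

    aud_ranges = [(530, 590), (630, 690), (735, 785), (790, 900),
                  (905, 925), (930, 950), (955, 975), (980, 1000)]
    for lo, hi in aud_ranges:
        fs.append(FeatureDef(f"aud_{lo}_{hi}", "hyperspectral", "aud",
                             {"low": float(lo), "high": float(hi)}))

    # first-derivative samples spread over green edge, red well and red
    # edge; first-order only by default — second-order central differences
    # on a ~2 nm grid are noise-dominated for typical sensor SNR (order-2
    # remains available through the catalog)
    for wl in (712, 718, 724, 730):
        fs.append(FeatureDef(f"d1_{wl}", "hyperspectral", "deriv",
                             {"wavelength": float(wl), "order": 1}))

    for lvl in (10, 25, 30, 50, 60, 75, 80, 90, 95, 99, 100):
        fs.append(FeatureDef(f"h_p{lvl}", "lidar", "height_percentile",
                             {"level": float(lvl)}))
    fs.append(FeatureDef("h_mean", "lidar", "height_mean"))
    fs.append(FeatureDef("h_std", "lidar", "height_std"))
    fs.append(FeatureDef("h_skew", "lidar", "height_skew"))
    fs.append(FeatureDef("h_cv", "lidar", "height_cv"))
    fs.append(FeatureDef("canopy_volume", "lidar", "canopy_volume",
                         {"cell_size": float(volume_cell)}))
    for thr in cover_thresholds:
        fs.append(FeatureDef(f"cover_{thr}", "lidar", "canopy_cover",
                             {"threshold": float(thr)}))

    fs.append(FeatureDef("cum_precip", "weather", "cum_precip"))
    fs.append(FeatureDef("cum_radiation", "weather", "cum_radiation"))
    fs.append(FeatureDef("gdd", "weather", "gdd", {"t_base": float(gdd_base)}))
    return FeatureCatalog(fs)


# ---------------------------------------------------------------------------
# hyperspectral
# ---------------------------------------------------------------------------

def _nearest_band(wavelengths: np.ndarray, wl: float, name: str) -> int:
    if wl < wavelengths[0] or wl > wavelengths[-1]:
        raise ValueError(
            f"feature {name!r} references {wl} nm outside the sensor grid "
            f"[{wavelengths[0]}, {wavelengths[-1]}]")
    return int(np.argmin(np.abs(wavelengths - wl)))


def extract_hyperspectral_features(
    wavelengths: np.ndarray,
    reflectance: np.ndarray,
    catalog: FeatureCatalog,
) -> dict[str, float]:
    """Hyperspectral features for one plot-date spectrum.

    Band lookups use nearest-wavelength matching, integration the
    trapezoidal rule on the native grid, derivatives central finite
    differences on the native grid.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    reflectance = np.asarray(reflectance, dtype=float)
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    out: dict[str, float] = {}
    for f in catalog.by_source("hyperspectral"):
        if f.kind in ("nd_index", "ratio"):
            i1 = _nearest_band(wavelengths, f.params["band1"], f.name)
            i2 = _nearest_band(wavelengths, f.params["band2"], f.name)
            r1, r2 = reflectance[i1], reflectance[i2]
            if f.kind == "nd_index":
                denom = r1 + r2
                out[f.name] = 0.0 if denom == 0 else (r1 - r2) / denom
            else:
                out[f.name] = np.inf if r2 == 0 else r1 / r2
        elif f.kind == "aud":
            lo = _nearest_band(wavelengths, f.params["low"], f.name)
            hi = _nearest_band(wavelengths, f.params["high"], f.name)
            sl = slice(lo, hi + 1)
            out[f.name] = float(np.trapezoid(reflectance[sl], wavelengths[sl]))
        elif f.kind == "deriv":
            i = _nearest_band(wavelengths, f.params["wavelength"], f.name)
            i = min(max(i, 1), len(wavelengths) - 2)
            h1 = wavelengths[i] - wavelengths[i - 1]
            h2 = wavelengths[i + 1] - wavelengths[i]
            if f.params.get("order", 1) == 1:
                out[f.name] = float(
                    (reflectance[i + 1] - reflectance[i - 1]) / (h1 + h2))
            else:
                out[f.name] = float(
                    2 * (h1 * reflectance[i + 1] - (h1 + h2) * reflectance[i]
                         + h2 * reflectance[i - 1]) / (h1 * h2 * (h1 + h2)))
        else:
            raise ValueError(f"unknown hyperspectral kind {f.kind!r}")
    return out


# ---------------------------------------------------------------------------
# LiDAR
# ---------------------------------------------------------------------------

@dataclass
class LidarFeatures:
    """Values plus a flag for segments with no canopy returns."""

    values: dict[str, float]
    empty_canopy: bool = False


def extract_lidar_features(cloud: PlotPointCloud,
                           catalog: FeatureCatalog) -> LidarFeatures:
    """LiDAR canopy metrics for one plot-date point cloud.

    Heights are normalised to (z - median ground z).  Percentiles and
    statistics are computed on non-ground points; canopy cover counts points
    above the threshold over *all* points in the segment; canopy volume sums
    cell-max normalised height x cell area over a planimetric grid.

    An empty canopy (no non-ground returns) yields zero for every metric and
    ``empty_canopy=True``.
    """
    ground = cloud.points[cloud.is_ground]
    if len(ground) == 0:
        raise ValueError(f"plot {cloud.plot_id}: no ground points for "
                         "height normalisation")
    z0 = float(np.median(ground[:, 2]))
    canopy = cloud.points[~cloud.is_ground]
    hz = canopy[:, 2] - z0
    all_hz = cloud.points[:, 2] - z0
    empty = len(canopy) == 0

    out: dict[str, float] = {}
    for f in catalog.by_source("lidar"):
        if empty and f.kind != "canopy_cover":
            out[f.name] = 0.0
            continue
        if f.kind == "height_percentile":
            out[f.name] = float(np.percentile(hz, f.params["level"]))
        elif f.kind == "height_mean":
            out[f.name] = float(np.mean(hz))
        elif f.kind == "height_std":
            out[f.name] = float(np.std(hz))
        elif f.kind == "height_skew":
            s = float(stats.skew(hz)) if len(hz) > 2 and np.std(hz) > 0 else 0.0
            out[f.name] = s
        elif f.kind == "height_cv":
            m = float(np.mean(hz))
            out[f.name] = float(np.std(hz) / m) if m != 0 else 0.0
        elif f.kind == "canopy_volume":
            cell = f.params.get("cell_size", 0.1)
            ix = np.floor(canopy[:, 0] / cell).astype(np.int64)
            iy = np.floor(canopy[:, 1] / cell).astype(np.int64)
            _, inv = np.unique(np.stack([ix, iy]), axis=1, return_inverse=True)
            tops = np.zeros(inv.max() + 1)
            np.maximum.at(tops, inv, np.maximum(hz, 0.0))
            out[f.name] = float(tops.sum() * cell * cell)
        elif f.kind == "canopy_cover":
            thr = f.params["threshold"]
            out[f.name] = float(np.sum(all_hz > thr) / len(all_hz))
        else:
            raise ValueError(f"unknown lidar kind {f.kind!r}")
    return LidarFeatures(out, empty_canopy=empty)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def extract_weather_features(weather: pd.DataFrame, sowing_day: int,
                             obs_day: int,
                             catalog: FeatureCatalog) -> dict[str, float]:
    """Cumulative weather features over the closed interval
    [sowing_day, obs_day] (day-of-season integers)."""
    if sowing_day > obs_day:
        raise ValueError("sowing_day must be <= obs_day")
    days = weather["day"].to_numpy()
    wanted = np.arange(sowing_day, obs_day + 1)
    missing = np.setdiff1d(wanted, days)
    if len(missing):
        raise ValueError(f"weather series is missing day {int(missing[0])}")
    w = weather.set_index("day").loc[wanted]
    tmean = 0.5 * (w["t_min"].to_numpy() + w["t_max"].to_numpy())
    out: dict[str, float] = {}
    for f in catalog.by_source("weather"):
        if f.kind == "cum_precip":
            out[f.name] = float(w["precipitation"].sum())
        elif f.kind == "cum_radiation":
            out[f.name] = float(w["radiation"].sum())
        elif f.kind == "gdd":
            t_base = f.params.get("t_base", 10.0)
            out[f.name] = float(np.sum(np.maximum(0.0, tmean - t_base)))
        else:
            raise ValueError(f"unknown weather kind {f.kind!r}")
    return out


# ---------------------------------------------------------------------------
# tensor assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureTensor:
    """plots x features x dates array with names, dates and imputation flags."""

    values: np.ndarray            # (P, F, T)
    plot_ids: list[str]
    feature_names: list[str]
    feature_sources: list[str]
    dates: list[int]              # day-of-season per observation date
    gdd: list[float]              # cumulative GDD per observation date
    imputed: np.ndarray           # (P, F, T) bool

    def __post_init__(self) -> None:
        P, F, T = self.values.shape
        if (len(self.plot_ids), len(self.feature_names), len(self.dates)) != (P, F, T):
            raise ValueError("FeatureTensor axis lengths are inconsistent")
        if len(self.feature_sources) != F:
            raise ValueError("feature_sources must align with feature_names")
        if np.isnan(self.values).any():
            raise ValueError("FeatureTensor must have no missing values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def matrix_for_date(self, t: int, features: Sequence[str] | None = None) -> np.ndarray:
        """plots x features matrix at one date (optionally a feature subset)."""
        if features is None:
            return self.values[:, :, t]
        idx = [self.feature_index(f) for f in features]
        return self.values[:, idx, t]

    def subset_plots(self, plot_ids: Sequence[str]) -> "FeatureTensor":
        pos = {p: i for i, p in enumerate(self.plot_ids)}
        idx = [pos[p] for p in plot_ids]
        return FeatureTensor(self.values[idx], list(plot_ids),
                             list(self.feature_names), list(self.feature_sources),
                             list(self.dates), list(self.gdd),
                             self.imputed[idx])

    def drop_features(self, names: Iterable[str]) -> "FeatureTensor":
        names = set(names)
        unknown = names - set(self.feature_names)
        if unknown:
            raise KeyError(f"unknown features: {sorted(unknown)}")
        keep = [i for i, n in enumerate(self.feature_names) if n not in names]
        return FeatureTensor(self.values[:, keep, :], list(self.plot_ids),
                             [self.feature_names[i] for i in keep],
                             [self.feature_sources[i] for i in keep],
                             list(self.dates), list(self.gdd),
                             self.imputed[:, keep, :])

    def to_long_csv(self, path: str | Path) -> None:
        P, F, T = self.values.shape
        rows = []
        for i in range(P):
            for j in range(F):
                for t in range(T):
                    rows.append((self.plot_ids[i], t, self.feature_names[j],
                                 self.values[i, j, t], int(self.imputed[i, j, t])))
        pd.DataFrame(rows, columns=["plot_id", "date_index", "feature",
                                    "value", "imputed"]).to_csv(path, index=False)
        schema = {"feature_names": self.feature_names,
                  "feature_sources": self.feature_sources,
                  "dates": self.dates, "gdd": self.gdd}
        Path(str(path) + ".schema.json").write_text(json.dumps(schema, indent=1))

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "FeatureTensor":
        df = pd.read_csv(path)
        schema = json.loads(Path(str(path) + ".schema.json").read_text())
        plots = list(dict.fromkeys(df["plot_id"].astype(str)))
        names = schema["feature_names"]
        T = len(schema["dates"])
        P, F = len(plots), len(names)
        vals = np.full((P, F, T), np.nan)
        imp = np.zeros((P, F, T), dtype=bool)
        pi = {p: i for i, p in enumerate(plots)}
        fi = {f: i for i, f in enumerate(names)}
        for pid, t, feat, val, flag in df.itertuples(index=False):
            vals[pi[str(pid)], fi[feat], int(t)] = val
            imp[pi[str(pid)], fi[feat], int(t)] = bool(flag)
        return cls(vals, plots, names, schema["feature_sources"],
                   schema["dates"], schema["gdd"], imp)


def assemble_feature_tensor(
    catalog: FeatureCatalog,
    plot_ids: Sequence[str],
    dates: Sequence[int],
    gdd: Sequence[float],
    hyper: Mapping[tuple[str, int], Mapping[str, float]],
    weather_feats: Mapping[tuple[str, int], Mapping[str, float]],
    lidar: Mapping[tuple[str, int], Mapping[str, float]] | None = None,
) -> FeatureTensor:
    """Assemble per-(plot, date) feature dicts into a FeatureTensor.

    Hyperspectral and weather features must be present for every (plot,
    date) cell; LiDAR blocks may be missing for some dates and are imputed
    by carrying the nearest available date's block (ties toward the earlier
    date), flagged in ``imputed``.
    """
    lidar = lidar or {}
    names = catalog.names
    sources = [f.source for f in catalog.features]
    P, F, T = len(plot_ids), len(names), len(dates)
    vals = np.full((P, F, T), np.nan)
    imp = np.zeros((P, F, T), dtype=bool)
    lidar_idx = [j for j, s in enumerate(sources) if s == "lidar"]

    for i, pid in enumerate(plot_ids):
        has_any = any((pid, t) in hyper for t in range(T))
        if not has_any:
            raise ValueError(f"plot {pid} absent from all feature inputs")
        for t in range(T):
            if (pid, t) not in hyper:
                raise ValueError(f"missing hyperspectral features for "
                                 f"({pid}, date {t})")
            if (pid, t) not in weather_feats:
                raise ValueError(f"missing weather features for ({pid}, date {t})")
            cell = dict(hyper[(pid, t)])
            cell.update(weather_feats[(pid, t)])
            if (pid, t) in lidar:
                cell.update(lidar[(pid, t)])
            for j, name in enumerate(names):
                if name in cell:
                    vals[i, j, t] = cell[name]
        # impute missing LiDAR date blocks from the nearest available date
        have = [t for t in range(T) if (pid, t) in lidar]
        if lidar_idx and have:
            for t in range(T):
                if t in have:
                    continue
                near = min(have, key=lambda s: (abs(dates[s] - dates[t]), s))
                for j in lidar_idx:
                    vals[i, j, t] = vals[i, j, near]
                    imp[i, j, t] = True
        elif lidar_idx and not have and lidar:
            raise ValueError(f"plot {pid} has no LiDAR data on any date")

    if lidar_idx and not lidar:
        raise ValueError("catalog contains LiDAR features but no LiDAR input "
                         "was provided")
    return FeatureTensor(vals, list(plot_ids), names, sources,
                         list(dates), list(gdd), imp)


def extract_trial_features(trial: TrialData, weather: pd.DataFrame,
                           catalog: FeatureCatalog,
                           lidar_dates: Sequence[int] | None = None) -> FeatureTensor:
    """Run all three extractors over a simulated trial and assemble the tensor.

    ``lidar_dates`` restricts which observation dates have LiDAR (emulating
    sparse LiDAR campaigns); missing dates are imputed by carry-nearest.
    """
    plot_ids = trial.records["plot_id"].tolist()
    T = len(trial.obs_days)
    if lidar_dates is None:
        lidar_dates = range(T)
    lidar_dates = set(lidar_dates)

    gdd_def = [f for f in catalog.by_source("weather") if f.kind == "gdd"]
    t_base = gdd_def[0].params.get("t_base", 10.0) if gdd_def else 10.0
    tmean = 0.5 * (weather["t_min"].to_numpy() + weather["t_max"].to_numpy())
    cum_gdd = np.cumsum(np.maximum(0.0, tmean - t_base))
    gdd_at = [float(cum_gdd[d]) for d in trial.obs_days]

    hyper: dict[tuple[str, int], dict[str, float]] = {}
    wfeat: dict[tuple[str, int], dict[str, float]] = {}
    lid: dict[tuple[str, int], dict[str, float]] = {}
    for t, day in enumerate(trial.obs_days):
        wvec = extract_weather_features(weather, 0, day, catalog)
        for i, pid in enumerate(plot_ids):
            hyper[(pid, t)] = extract_hyperspectral_features(
                trial.wavelengths, trial.spectra[i, t, :], catalog)
            wfeat[(pid, t)] = dict(wvec)
            if t in lidar_dates and (pid, t) in trial.clouds:
                lid[(pid, t)] = extract_lidar_features(
                    trial.clouds[(pid, t)], catalog).values
    return assemble_feature_tensor(catalog, plot_ids, trial.obs_days, gdd_at,
                                   hyper, wfeat, lid)
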