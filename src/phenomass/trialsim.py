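"""Synthetic multi-trial sorghum breeding-experiment generator.

Emulates the data layout of a UAV high-throughput phenotyping campaign over
a testcross ("Tc") panel and a small calibration ("Cal") panel: a hybrids x
markers genotype matrix with latent subpopulation structure, daily weather,
per-plot reflectance spectra (272 bands, 400-1000 nm) and labelled 3-D point
clouds on a few observation dates, and end-of-season fresh biomass.

The generative model is a per-plot logistic growth curve in thermal time
(GDD) that drives canopy height, canopy cover, a two-endmember soil /
vegetation spectral mixture, and fresh biomass.  Genotype-cluster effects
enter biomass additively and are *not* expressed in the canopy signal, so a
genotype-blind model cannot recover them from remote sensing alone.  Hidden
truth (growth parameters, subpopulation labels, planted-redundant feature
regions) is returned for oracle tests.

All randomness flows from ``SimConfig.seed`` through named substreams, so
markers, weather and trials can be re-simulated independently.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "MarkerMatrix",
    "PlotPointCloud",
    "TrialData",
    "SimTruth",
    "simulate_markers",
    "simulate_weather",
    "select_cal_hybrids",
    "simulate_trial",
    "simulate_study",
    "write_trial_csvs",
]

# Wavelength grid of the emulated VNIR imaging spectrometer.
N_BANDS = 272
WL_MIN, WL_MAX = 400.0, 1000.0

# Paired NIR sub-ranges reserved for planted-redundant features.  Each pair
# shares one latent per-plot-date factor and carries no canopy signal, so the
# integration features over them are mutually near-duplicate and carry low
# PCA importance.  Order: (parent, clone) per pair.
REDUNDANT_REGIONS: list[tuple[float, float]] = [
    (905.0, 925.0),
    (930.0, 950.0),
    (955.0, 975.0),
    (980.0, 1000.0),
]

# Reference maximum canopy height (m) that scales the growth model.
K0 = 2.5


@dataclass
class SimConfig:
    """Configuration of a synthetic breeding study.

    Default panel sizes mirror a large testcross trial (630 hybrids, two
    replicates) with a 72-hybrid calibration subset; marker width defaults
    to 2,000 columns (clustering behaviour is width-invariant).
    """

    n_hybrids: int = 630
    n_markers: int = 2000
    n_subpops: int = 5
    n_cal_hybrids: int = 72
    replicates: int = 2
    n_tc_plots: int | None = None  # defaults to n_hybrids * replicates
    n_dates: int = 4
    sowing_date: str = "2019-05-15"
    season_length: int = 120  # days
    # effect sizes (g/m^2 except gxe/env which are additive g/m^2 scales)
    subpop_effect: float = 300.0
    env_effect: float = 150.0
    gxe_scale: float = 80.0
    # noise scales
    spectral_noise: float = 0.01   # reflectance units
    structural_noise: float = 0.05  # relative canopy-height jitter
    biomass_noise: float = 100.0   # g/m^2
    weather_noise: float = 1.0     # multiplier on weather day-to-day noise
    n_planted_redundant_features: int = 4
    # domain shift applied to target-trial sensor data and biomass
    shift_feature_add: float = 0.02
    shift_feature_mult: float = 1.10
    shift_height_mult: float = 1.15
    shift_biomass_mult: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hybrids", "n_markers", "n_subpops", "n_cal_hybrids",
                     "replicates", "season_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"SimConfig.{name} must be positive")
        if self.n_dates < 2:
            raise ValueError("SimConfig.n_dates must be >= 2")
        if self.n_cal_hybrids > self.n_hybrids:
            raise ValueError(
                "SimConfig.n_cal_hybrids must be a subset of the hybrid panel "
                "(n_cal_hybrids <= n_hybrids)")
        if self.season_length < self.n_dates:
            raise ValueError("SimConfig.season_length must cover n_dates")
        for name in ("subpop_effect", "env_effect", "gxe_scale",
                     "spectral_noise", "structural_noise", "biomass_noise",
                     "weather_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimConfig.{name} must be >= 0")
        n_red = self.n_planted_redundant_features
        if n_red < 0 or n_red > len(REDUNDANT_REGIONS) or n_red % 2:
            raise ValueError(
                "SimConfig.n_planted_redundant_features must be an even count "
                f"in 0..{len(REDUNDANT_REGIONS)} (features are planted in "
                "correlated pairs)")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int, *names) -> np.random.Generator:
    """Named deterministic substream of the top-level seed."""
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


@dataclass
class MarkerMatrix:
    """Hybrids x markers genotype matrix, coded {0, 1, 2} when synthetic."""

    hybrid_ids: list[str]
    values: np.ndarray  # (n_hybrids, n_markers)
    marker_names: list[str]
    subpop_truth: np.ndarray | None = None  # hidden subpopulation labels

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.hybrid_ids):
            raise ValueError("MarkerMatrix values must be (hybrids, markers)")
        if len(self.hybrid_ids) < 2:
            raise ValueError("MarkerMatrix needs >= 2 hybrids")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.marker_names)
        df.insert(0, "hybrid_id", self.hybrid_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMatrix":
        hybrids = df["hybrid_id"].astype(str).tolist()
        cols = [c for c in df.columns if c != "hybrid_id"]
        vals = df[cols].to_numpy(dtype=float)
        # load-time imputation of missing entries by column mean
        if np.isnan(vals).any():
            mean = np.nanmean(vals, axis=0)
            idx = np.where(np.isnan(vals))
            vals[idx] = np.take(mean, idx[1])
        return cls(hybrids, vals, cols)


@dataclass
class PlotPointCloud:
    """LiDAR-like point set for one plot on one date (x, y, z in metres)."""

    points: np.ndarray          # (n, 3)
    is_ground: np.ndarray       # (n,) bool
    plot_id: str
    date_index: int

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("PlotPointCloud must be non-empty")


@dataclass
class SimTruth:
    """Hidden generative state returned for oracle tests."""

    subpop_of_hybrid: dict[str, int]
    growth: pd.DataFrame            # per plot: K, r, m, h_end
    latent_biomass: pd.Series       # per plot, before observation noise
    redundant_regions: list[tuple[float, float]]
    env_effect: float
    cal_hybrids: list[str]


@dataclass
class TrialData:
    """One simulated trial: metadata, sensor data and ground reference."""

    trial_id: str
    year: str
    records: pd.DataFrame           # trial, year, plot_id, hybrid_id, replicate
    wavelengths: np.ndarray         # (n_bands,)
    spectra: np.ndarray             # (n_plots, n_dates, n_bands)
    clouds: dict[tuple[str, int], PlotPointCloud]
    biomass: pd.DataFrame           # plot_id, biomass, harvest_day
    obs_days: list[int]             # day-of-season of each observation date
    truth: SimTruth


def simulate_markers(config: SimConfig) -> MarkerMatrix:
    """Draw a hybrids x markers matrix with latent subpopulation structure.

    Each subpopulation has its own allele-frequency profile (Balding-Nichols
    style: frequencies drawn around a common ancestral frequency with
    between-subpopulation differentiation), and each hybrid's marker dosage
    is Binomial(2, p_subpop).  The subpopulation label of every hybrid is
    retained as hidden truth.
    """
    if config.n_subpops < 1:
        raise ValueError("SimConfig.n_subpops must be >= 1")
    if config.n_subpops >= 2 and config.n_markers < 10 * config.n_subpops:
        raise ValueError("SimConfig.n_markers must be >= 10 * n_subpops")
    rng = _rng(config.seed, "markers")
    anc = rng.uniform(0.1, 0.9, size=config.n_markers)
    # strong differentiation: subpop frequencies scattered widely around anc
    fst = 0.25
    a = anc * (1 - fst) / fst
    b = (1 - anc) * (1 - fst) / fst
    freqs = rng.beta(a, b, size=(config.n_subpops, config.n_markers))
    labels = rng.integers(0, config.n_subpops, size=config.n_hybrids)
    geno = rng.binomial(2, freqs[labels, :]).astype(np.int8)
    hybrids = [f"H{i:04d}" for i in range(config.n_hybrids)]
    names = [f"M{j:05d}" for j in range(config.n_markers)]
    return MarkerMatrix(hybrids, geno, names, subpop_truth=labels)


def simulate_weather(config: SimConfig, year: str | None = None) -> pd.DataFrame:
    """Daily weather for one season: Tmin/Tmax (C), precipitation (mm),
    solar radiation (MJ m^-2).

    Smooth mid-season temperature and radiation peaks plus day-to-day noise
    (scaled by ``weather_noise``) and sparse gamma-distributed rain events.
    """
    rng = _rng(config.seed, "weather", year or "base")
    n = config.season_length
    day = np.arange(n)
    w = config.weather_noise
    tmean = 18.0 + 10.0 * np.sin(np.pi * (day + 5) / (n + 10)) + w * rng.normal(0, 1.5, n)
    spread = np.clip(5.0 + w * rng.normal(0, 1.0, n), 1.0, None)
    rain = (rng.random(n) < 0.25) * rng.gamma(1.5, 8.0, n)
    if config.weather_noise == 0:
        rain = np.zeros(n)
    rad = np.clip(22.0 + 6.0 * np.sin(np.pi * (day + 5) / (n + 10))
                  + w * rng.normal(0, 2.0, n), 1.0, None)
    start = pd.Timestamp(config.sowing_date)
    if year is not None and year.isdigit():
        start = start.replace(year=int(year))
    return pd.DataFrame({
        "day": day,
        "date": pd.date_range(start, periods=n, freq="D").strftime("%Y-%m-%d"),
        "t_min": tmean - spread,
        "t_max": tmean + spread,
        "precipitation": rain,
        "radiation": rad,
    })


def select_cal_hybrids(markers: MarkerMatrix, config: SimConfig) -> list[str]:
    """Calibration-panel hybrids: a stratified sample across subpopulations.

    Mirrors a breeder's choice of a representative subset — roughly equal
    coverage of every genotype group.
    """
    rng = _rng(config.seed, "calpanel")
    labels = markers.subpop_truth
    if labels is None:
        idx = rng.choice(len(markers.hybrid_ids), config.n_cal_hybrids, replace=False)
        return sorted(markers.hybrid_ids[i] for i in idx)
    chosen: list[int] = []
    groups = [np.flatnonzero(labels == s) for s in range(config.n_subpops)]
    quota = np.full(config.n_subpops, config.n_cal_hybrids // config.n_subpops)
    quota[: config.n_cal_hybrids % config.n_subpops] += 1
    for grp, q in zip(groups, quota):
        take = min(len(grp), int(q))
        chosen.extend(rng.choice(grp, take, replace=False))
    # top up from the full panel if some subpopulation was too small
    while len(chosen) < config.n_cal_hybrids:
        i = int(rng.integers(0, len(markers.hybrid_ids)))
        if i not in chosen:
            chosen.append(i)
    return sorted(markers.hybrid_ids[i] for i in sorted(chosen))


# ---------------------------------------------------------------------------
# growth, optics and point-cloud kernels
# ---------------------------------------------------------------------------

def _gdd_series(weather: pd.DataFrame, t_base: float = 10.0) -> np.ndarray:
    tmean = 0.5 * (weather["t_min"].to_numpy() + weather["t_max"].to_numpy())
    return np.cumsum(np.maximum(0.0, tmean - t_base))


def _hybrid_params(config: SimConfig, hybrids: Sequence[str],
                   subpop: np.ndarray | None = None) -> pd.DataFrame:
    """Intrinsic per-hybrid growth parameters, shared across trials.

    Subpopulations carry a modest phenology/stature signature (maturity
    timing and maximum height), so genotype clusters are partially visible
    in the canopy — while their main biomass effect stays out of the
    remote-sensing signal (see ``simulate_trial``).
    """
    rng = _rng(config.seed, "hybrids")
    n = config.n_hybrids
    eta = rng.normal(size=(n, 4))
    if subpop is not None and config.n_subpops > 1:
        lev = np.linspace(-1.0, 1.0, config.n_subpops)[subpop]
    else:
        lev = np.zeros(n)
    df = pd.DataFrame({
        "hybrid_id": [f"H{i:04d}" for i in range(n)],
        "K": K0 * (1 + 0.15 * eta[:, 0]) * (1 + 0.05 * lev),
        "r": 0.006 * (1 + 0.10 * eta[:, 1]),
        "m": 780.0 * (1 + 0.08 * eta[:, 2]) + 80.0 * lev,
        "beta": 120.0 * eta[:, 3],   # hybrid-specific biomass deviation
    }).set_index("hybrid_id")
    df["K"] = df["K"].clip(lower=0.5)
    return df.loc[list(hybrids)]


def _soil_endmember(wl: np.ndarray) -> np.ndarray:
    return 0.15 + 0.00025 * (wl - 400.0)


def _cover_fraction(h: np.ndarray) -> np.ndarray:
    # Beer-Lambert-style light interception: approaches but never reaches
    # full cover, so soil-driven variance persists late in the season
    return np.clip(1.0 - np.exp(-0.9 * h), 0.02, 0.99)


def simulate_trial(
    config: SimConfig,
    markers: MarkerMatrix,
    weather: pd.DataFrame,
    trial_id: str = "Tc",
    year: str = "2019",
    panel: str = "tc",
    domain_shift: bool = False,
) -> TrialData:
    """Simulate one trial (plots, spectra, point clouds, biomass, truth).

    ``panel="tc"`` lays out the full hybrid panel with ``config.replicates``
    replicates; ``panel="cal"`` uses the stratified calibration subset.
    ``domain_shift=True`` applies the configured affine shift to reflectance
    and canopy heights and the multiplicative shift to biomass, emulating a
    different field / year.
    """
    if panel not in ("tc", "cal"):
        raise ValueError("panel must be 'tc' or 'cal'")
    cal_hybrids = select_cal_hybrids(markers, config)
    missing = set(cal_hybrids) - set(markers.hybrid_ids)
    if missing:
        raise ValueError(f"Cal hybrids not in marker set: {sorted(missing)[:5]}")

    hybrids = cal_hybrids if panel == "cal" else list(markers.hybrid_ids)
    plot_hybrids = [h for h in hybrids for _ in range(config.replicates)]
    plot_reps = [r + 1 for _ in hybrids for r in range(config.replicates)]
    if panel == "tc" and config.n_tc_plots is not None:
        plot_hybrids = plot_hybrids[: config.n_tc_plots]
        plot_reps = plot_reps[: config.n_tc_plots]
    n_plots = len(plot_hybrids)
    plot_ids = [f"{trial_id}-P{i:04d}" for i in range(n_plots)]
    records = pd.DataFrame({
        "trial": trial_id,
        "year": year,
        "plot_id": plot_ids,
        "hybrid_id": plot_hybrids,
        "replicate": plot_reps,
    })

    rng = _rng(config.seed, "trial", trial_id)
    gdd = _gdd_series(weather)
    g_end = gdd[-1]
    # observation dates at fixed thermal-time fractions of the season
    fracs = np.linspace(0.35, 0.95, config.n_dates)
    obs_days = [int(np.searchsorted(gdd, f * g_end)) for f in fracs]
    obs_days = [min(d, config.season_length - 1) for d in obs_days]

    hp = _hybrid_params(config, plot_hybrids, markers.subpop_truth)
    jit = config.structural_noise * rng.normal(size=(n_plots, 3))
    K_p = hp["K"].to_numpy() * (1 + 0.5 * jit[:, 0])
    r_p = hp["r"].to_numpy() * (1 + 0.3 * jit[:, 1])
    m_p = hp["m"].to_numpy() * (1 + 0.3 * jit[:, 2])

    def height(day: int) -> np.ndarray:
        g = gdd[day]
        h = K_p / (1.0 + np.exp(-r_p * (g - m_p)))
        return h * (config.shift_height_mult if domain_shift else 1.0)

    wl = np.linspace(WL_MIN, WL_MAX, N_BANDS)
    # field-specific sensing conditions: soil optics, heterogeneity and
    # canopy architecture differ between trials, so the relative variance
    # of individual features reshuffles from trial to trial
    trng = _rng(config.seed, "trialenv", trial_id)
    soil_base = 0.15 * (1 + 0.15 * float(trng.normal()))
    soil_slope = 0.00025 * (1 + 0.3 * float(trng.normal()))
    soil = np.clip(soil_base + soil_slope * (wl - 400.0), 0.02, None)
    edge_gain = 15.0 * float(trng.uniform(1.0, 1.5))
    expo_a = 0.3 + 0.05 * float(trng.normal())
    expo_b = float(trng.uniform(1.1, 1.6))
    wl_norm = (wl - WL_MIN) / (WL_MAX - WL_MIN)
    cos_basis = np.stack([np.cos((k + 1) * np.pi * wl_norm) for k in range(3)])
    fine_basis = np.stack([np.cos(k * np.pi * wl_norm + k) for k in range(4, 13)])

    n_red = config.n_planted_redundant_features
    red_regions = REDUNDANT_REGIONS[:n_red]
    red_masks = [(wl >= lo) & (wl <= hi) for lo, hi in red_regions]

    spectra = np.empty((n_plots, config.n_dates, N_BANDS))
    clouds: dict[tuple[str, int], PlotPointCloud] = {}
    n_canopy, n_ground = 1000, 200
    # deterministic canopy height profile (fraction of top height per point)
    s_grid = (np.arange(n_canopy) / (n_canopy - 1)) ** 0.8

    for t, day in enumerate(obs_days):
        # day-specific conditions: surface moisture, wind and physiological
        # state set how much non-growth variability each acquisition carries
        bright_amp = 0.035 * float(np.exp(0.5 * rng.normal()))
        edge_jit = 1.2 * (config.spectral_noise / 0.01) * float(np.exp(0.6 * rng.normal()))
        expo_jit = 0.2 * config.structural_noise * float(np.exp(0.5 * rng.normal()))
        h = height(day)
        cover = _cover_fraction(h)
        vigor = np.clip(h / K0, 0.1, 1.3)
        nir_amp = 0.40 * (0.7 + 0.45 * vigor)
        # red-edge inflection shifts with vigor (chlorophyll) plus a
        # day-to-day physiological jitter, so spectral slope features carry
        # real between-plot signal at every date
        edge = 705.0 + edge_gain * vigor + edge_jit * rng.normal(size=n_plots)
        # visible baseline and green peak darken with vigor (deeper
        # pigment absorption)
        base_vis = 0.05 - 0.015 * vigor
        green_amp = 0.07 - 0.025 * vigor
        veg = base_vis[:, None] \
            + green_amp[:, None] * np.exp(-((wl - 550.0) / 30.0) ** 2)[None, :] \
            + nir_amp[:, None] / (1.0 + np.exp(-(wl[None, :] - edge[:, None]) / 16.0))
        # per-plot soil brightness (moisture/texture heterogeneity): drives
        # the visible region early in the season, fades as the canopy closes
        bright = 1.0 + bright_amp * rng.normal(size=n_plots)
        refl = cover[:, None] * veg \
            + ((1 - cover) * bright)[:, None] * soil[None, :]
        coefs = rng.normal(size=(n_plots, 3))
        refl += config.spectral_noise * (coefs @ cos_basis)
        # band-dependent white-noise envelope (detector/illumination state
        # varies by acquisition), so narrow-band features decorrelate
        env = np.exp(0.7 * (rng.normal(size=9) @ fine_basis) / 3.0)
        refl += 0.01 * config.spectral_noise * env[None, :] \
            * rng.normal(size=refl.shape)
        # planted-redundant regions: pairs share one latent factor and carry
        # no canopy signal
        for pair in range(0, n_red, 2):
            u = rng.normal(size=n_plots)
            for j in (pair, pair + 1):
                mask = red_masks[j]
                base = 0.28 + 0.05 * u[:, None]
                refl[:, mask] = base + 0.008 * rng.normal(size=(n_plots, mask.sum()))
        if domain_shift:
            refl = config.shift_feature_mult * refl + config.shift_feature_add
        # 0.005 sensor floor keeps ratio features finite
        spectra[:, t, :] = np.clip(refl, 0.005, 1.2)

        # point clouds
        for i, pid in enumerate(plot_ids):
            gz = rng.normal(0.0, 0.015, n_ground)
            # canopy profile gets more top-heavy as the crop matures and
            # varies a little between plots (architecture), so
            # height-distribution shape statistics track growth stage; the
            # 0.15 h floor keeps low percentiles height-driven
            expo = np.clip(expo_a + expo_b * (h[i] / K0) ** 0.7, 0.25, 1.4)
            expo += expo_jit * float(rng.normal())
            expo = float(np.clip(expo, 0.2, 2.0))
            cz = h[i] * (0.15 + 0.85 * s_grid ** (expo / 0.8))
            if config.structural_noise > 0:
                cz = cz + h[i] * config.structural_noise * rng.normal(size=n_canopy)
            cz = np.clip(cz, 0.01, None)
            xy = rng.uniform([0, 0], [1.0, 3.0], size=(n_canopy + n_ground, 2))
            z = np.concatenate([gz, cz])
            pts = np.column_stack([xy, z])
            grd = np.zeros(n_canopy + n_ground, dtype=bool)
            grd[:n_ground] = True
            clouds[(pid, t)] = PlotPointCloud(pts, grd, pid, t)

    # biomass
    labels = markers.subpop_truth
    subpop_of = dict(zip(markers.hybrid_ids, labels)) if labels is not None else {}
    if config.n_subpops > 1 and labels is not None:
        e_levels = np.linspace(-1.0, 1.0, config.n_subpops) * config.subpop_effect
    else:
        e_levels = np.zeros(max(config.n_subpops, 1))
    # environment and GxE are properties of the year/field, not of the panel:
    # two panels grown the same year share them
    env = config.env_effect * float(_rng(config.seed, "env", year).normal())
    gxe_rng = _rng(config.seed, "gxe", year)
    gxe_of = {h: config.gxe_scale * float(g)
              for h, g in zip(markers.hybrid_ids,
                              gxe_rng.normal(size=len(markers.hybrid_ids)))}
    h_end = K_p / (1.0 + np.exp(-r_p * (gdd[-1] - m_p)))
    subpop_term = np.array([e_levels[subpop_of.get(h, 0)] for h in plot_hybrids])
    latent = (600.0 + 1600.0 * (h_end / K0)
              + subpop_term
              + hp["beta"].to_numpy()
              + env
              + np.array([gxe_of[h] for h in plot_hybrids]))
    biomass = latent + config.biomass_noise * rng.normal(size=n_plots)
    if domain_shift:
        latent = latent * config.shift_biomass_mult
        biomass = biomass * config.shift_biomass_mult
    biomass = np.clip(biomass, 50.0, None)
    biomass_df = pd.DataFrame({
        "plot_id": plot_ids,
        "biomass": biomass,
        "harvest_day": config.season_length - 1,
    })

    truth = SimTruth(
        subpop_of_hybrid={h: int(subpop_of.get(h, 0)) for h in hybrids},
        growth=pd.DataFrame({"plot_id": plot_ids, "K": K_p, "r": r_p,
                             "m": m_p, "h_end": h_end}).set_index("plot_id"),
        latent_biomass=pd.Series(latent, index=plot_ids, name="latent_biomass"),
        redundant_regions=list(red_regions),
        env_effect=env,
        cal_hybrids=cal_hybrids,
    )
    return TrialData(trial_id, year, records, wl, spectra, clouds,
                     biomass_df, obs_days, truth)


def simulate_study(config: SimConfig) -> dict:
    """Source (Cal) and domain-shifted target (Tc) trials plus shared inputs.

    Returns a dict with keys ``markers``, ``weather_source``,
    ``weather_target``, ``source`` and ``target``.
    """
    markers = simulate_markers(config)
    w_src = simulate_weather(config, year="2019")
    w_tgt = simulate_weather(config, year="2020")
    source = simulate_trial(config, markers, w_src, trial_id="Cal",
                            year="2019", panel="cal")
    target = simulate_trial(config, markers, w_tgt, trial_id="Tc",
                            year="2020", panel="tc", domain_shift=True)
    return {"markers": markers, "weather_source": w_src,
            "weather_target": w_tgt, "source": source, "target": target}


# ---------------------------------------------------------------------------
# CSV writers (plain-text external interface)
# ---------------------------------------------------------------------------

def write_trial_csvs(trial: TrialData, weather: pd.DataFrame, out_dir: str | Path,
                     config: SimConfig | None = None) -> dict[str, Path]:
    """Write one trial to CSV files plus a hidden-truth JSON and a manifest.

    Layout: ``records.csv``, ``biomass.csv``, ``weather.csv``,
    ``spectra.csv`` (one row per plot-date, columns = wavelengths),
    ``points.csv`` (plot, date, x, y, z, is_ground), ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["records"] = out / "records.csv"
    trial.records.to_csv(paths["records"], index=False)
    paths["biomass"] = out / "biomass.csv"
    trial.biomass.to_csv(paths["biomass"], index=False)
    paths["weather"] = out / "weather.csv"
    weather.to_csv(paths["weather"], index=False)

    plot_ids = trial.records["plot_id"].tolist()
    rows = []
    for i, pid in enumerate(plot_ids):
        for t in range(trial.spectra.shape[1]):
            rows.append([pid, t, trial.obs_days[t], *trial.spectra[i, t, :]])
    spec_cols = ["plot_id", "date_index", "day"] + [f"{w:.4f}" for w in trial.wavelengths]
    paths["spectra"] = out / "spectra.csv"
    pd.DataFrame(rows, columns=spec_cols).to_csv(paths["spectra"], index=False)

    pc_rows = []
    for (pid, t), cloud in trial.clouds.items():
        for (x, y, z), g in zip(cloud.points, cloud.is_ground):
            pc_rows.append((pid, t, x, y, z, int(g)))
    paths["points"] = out / "points.csv"
    pd.DataFrame(pc_rows, columns=["plot_id", "date_index", "x", "y", "z",
                                   "is_ground"]).to_csv(paths["points"], index=False)

    paths["truth"] = out / "truth.json"
    truth = trial.truth
    paths["truth"].write_text(json.dumps({
        "subpop_of_hybrid": truth.subpop_of_hybrid,
        "redundant_regions": truth.redundant_regions,
        "env_effect": truth.env_effect,
        "cal_hybrids": truth.cal_hybrids,
        "obs_days": trial.obs_days,
    }, indent=1))

    manifest = {"trial_id": trial.trial_id, "year": trial.year,
                "files": {k: p.name for k, p in paths.items()}}
    if config is not None:
        manifest["config"] = config.to_dict()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    paths["manifest"] = out / "manifest.json"
    return paths
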