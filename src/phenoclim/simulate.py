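"""Synthetic climate and flowering observations with known ground truth.

Emulates the statistical structure the analysis assumes: opportunistic,
georeferenced, time-stamped flowering observations across multiple years
and sites; sinusoidal seasonal temperature with Gaussian day-to-day noise;
zero-inflated, winter-peaked desert precipitation; a Bernoulli flowering
response whose logit is a known function of the scaled GDD × precipitation
× polynomial-daylength design; partial-plant and uncertain annotations to
exercise the confirmed-absence filter; and an injectable anomalous
fall–winter season that is colder and wetter than usual, during which the
flowering logit can be offset to suppress (or not) out-of-season blooms.

Every record carries its latent true probability so recovery can be
checked against the generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import OrthoPolyBasis
from .covariates import CovariateConfig, apply_scaler, build_covariate_table, fit_scaler
from .glm import ModelSpec, build_design

__all__ = [
    "ClimateSimConfig",
    "TrueModelConfig",
    "DEFAULT_TRUE_BETA",
    "simulate_climate",
    "simulate_observations",
]

#: Default true coefficients on the scaled 12-column design
#: (intercept, GDD, precip, poly1/poly2 daylength, pairwise, three-way):
#: strong negative GDD and curvature-dominated daylength response with
#: genuine three-way structure — spring flowering favoured by cool,
#: mid-length days, with precipitation mattering most late-season.
DEFAULT_TRUE_BETA = (
    -4.28, -3.25, 0.19, -4.10, -73.7, -0.04,
    -3.60, -32.3, -25.3, -81.0, -44.2, -63.5,
)

FULL_SPEC = ModelSpec(("gdd", "avg_precip", "daylength"), 2, 3)

_WINTER = ((12, 1), (2, 28))  # Dec 1 .. Feb 28 window used for calibration
_SUMMER = ((6, 1), (8, 31))


@dataclass(frozen=True)
class ClimateSimConfig:
    """Daily-climate generator settings.

    Temperatures in °C, precipitation in mm/day (unconditional daily
    means), angles in degrees. ``precip_winter_mean`` / ``precip_summer_mean``
    are calibrated so the empirical Dec–Feb and Jun–Aug window averages of
    the seasonal mean match them. The optional anomaly fields carve out an
    interval in which daily temperature is shifted by ``anomaly_temp_offset``
    and mean precipitation multiplied by ``anomaly_precip_factor`` —
    an unusually cold and wet fall–winter.
    """

    n_sites: int = 12
    lat_range: tuple = (33.0, 37.0)
    lon_range: tuple = (-118.0, -113.0)
    date_range: tuple = ("2015-01-01", "2019-06-30")
    temp_mean_annual: float = 18.0
    temp_seasonal_amplitude: float = 10.0
    temp_day_of_peak: int = 200
    temp_noise_sd: float = 2.0
    diurnal_range: float = 12.0
    precip_winter_mean: float = 1.5
    precip_summer_mean: float = 0.3
    precip_wet_day_prob: float = 0.25
    seed: int = 0
    anomaly_interval: tuple | None = ("2018-09-01", "2019-02-28")
    anomaly_temp_offset: float = -4.0
    anomaly_precip_factor: float = 2.5

    def __post_init__(self):
        lo, hi = self.lat_range
        if not (-90.0 <= lo <= hi <= 90.0):
            raise ValueError("lat_range must lie within [-90, 90]")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        for name in ("temp_mean_annual", "temp_seasonal_amplitude", "temp_noise_sd", "diurnal_range"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.precip_winter_mean < 0 or self.precip_summer_mean < 0:
            raise ValueError("precipitation means must be non-negative")
        if not 0.0 <= self.precip_wet_day_prob <= 1.0:
            raise ValueError("precip_wet_day_prob must lie in [0, 1]")
        start, end = pd.Timestamp(self.date_range[0]), pd.Timestamp(self.date_range[1])
        if end <= start:
            raise ValueError("empty date range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _doy_window_mask(doy: np.ndarray, window) -> np.ndarray:
    (m0, d0), (m1, d1) = window
    start = pd.Timestamp(2001, m0, d0).dayofyear
    end = pd.Timestamp(2001, m1, d1).dayofyear
    if start <= end:
        return (doy >= start) & (doy <= end)
    return (doy >= start) | (doy <= end)


def _precip_seasonal_mean(doy: np.ndarray, winter_mean: float, summer_mean: float,
                          peak_doy: float = 15.0) -> np.ndarray:
    """Seasonal unconditional mean precipitation, winter-peaked.

    A cosine with peak at mid-January, with its amplitude calibrated so
    that the Dec–Feb and Jun–Aug window averages of the curve equal the
    configured winter and summer means (a cosine through the configured
    values as extremes would overshoot the summer window average).
    """
    grid = np.arange(1.0, 366.0)
    c = np.cos(2.0 * np.pi * (grid - peak_doy) / 365.25)
    cbar_w = float(np.mean(c[_doy_window_mask(grid, _WINTER)]))
    mid = (winter_mean + summer_mean) / 2.0
    amp = (winter_mean - summer_mean) / 2.0 / cbar_w if cbar_w > 0 else 0.0
    return np.maximum(0.0, mid + amp * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25))


def simulate_climate(config: ClimateSimConfig) -> pd.DataFrame:
    """One row per site per day: site, latitude, longitude, date, tmin, tmax, precip.

    Daily mean temperature is an annual sinusoid plus Gaussian noise;
    tmin/tmax bracket it by half the diurnal range. Precipitation is a
    Bernoulli wet day times an exponential intensity whose mean tracks the
    winter-peaked seasonal cycle. Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.date_range[0], config.date_range[1], freq="D")
    n_days = len(dates)
    if n_days == 0:
        raise ValueError("empty date range")
    doy = dates.dayofyear.to_numpy(float)

    lat = rng.uniform(*config.lat_range, size=config.n_sites)
    lon = rng.uniform(*config.lon_range, size=config.n_sites)

    seasonal_t = config.temp_mean_annual + config.temp_seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - config.temp_day_of_peak) / 365.25
    )
    seasonal_p = _precip_seasonal_mean(doy, config.precip_winter_mean, config.precip_summer_mean)

    anom = np.zeros(n_days, dtype=bool)
    if config.anomaly_interval is not None:
        a0, a1 = pd.Timestamp(config.anomaly_interval[0]), pd.Timestamp(config.anomaly_interval[1])
        anom = (dates >= a0) & (dates <= a1)

    frames = []
    for i in range(config.n_sites):
        tmean = seasonal_t + rng.normal(0.0, config.temp_noise_sd, size=n_days)
        tmean = tmean + np.where(anom, config.anomaly_temp_offset, 0.0)
        p_mean = seasonal_p * np.where(anom, config.anomaly_precip_factor, 1.0)
        wet = rng.random(n_days) < config.precip_wet_day_prob
        intensity = p_mean / max(config.precip_wet_day_prob, 1e-12)
        precip = np.where(wet, rng.exponential(1.0, size=n_days) * intensity, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "site": f"S{i:03d}",
                    "latitude": lat[i],
                    "longitude": lon[i],
                    "date": dates,
                    "tmin": tmean - config.diurnal_range / 2.0,
                    "tmax": tmean + config.diurnal_range / 2.0,
                    "precip": precip,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class TrueModelConfig:
    """The generative truth: coefficients on the scaled 12-term design.

    ``beta`` acts on (intercept, scaled GDD, scaled precip, poly1 and
    poly2 of scaled daylength, all pairwise products, both three-way
    products), the same design the analysis fits. ``anomaly_logit_offset``
    (δ ≤ 0) is added to the logit inside the anomaly interval: δ = 0 means
    anomalous-season flowering follows the same climate response as
    normal-season flowering, large negative δ suppresses it.
    """

    beta: tuple = DEFAULT_TRUE_BETA
    accumulation_window: int = 120
    anomaly_logit_offset: float = -2.0
    anomaly_interval: tuple | None = ("2018-09-01", "2019-02-28")
    seed: int = 0

    def __post_init__(self):
        if len(self.beta) != 12:
            raise ValueError("beta must have 12 terms (the full three-way design)")
        if self.accumulation_window not in (30, 120):
            raise ValueError("accumulation_window must be 30 or 120")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_observations(
    climate: pd.DataFrame,
    truth: TrueModelConfig | None = None,
    n_obs: int = 3000,
    seed: int = 0,
    species: str = "synthetic Yucca",
    partial_frac: float = 0.15,
    uncertain_frac: float = 0.05,
) -> pd.DataFrame:
    """Sample observation records with Bernoulli flowering from the known truth.

    Sites and dates are drawn uniformly, with dates restricted so the full
    accumulation window precedes them within climate coverage. Covariates
    are built exactly as the analysis builds them, scaled and orthogonalised
    on this sample, and the logit is ``x·beta + δ·1[anomalous]``. A
    configurable fraction of records is marked partial-plant or uncertain
    to exercise the confirmed-absence filter.

    Returns the observation table with a latent ``true_prob`` column.
    """
    if truth is None:
        truth = TrueModelConfig()
    rng = np.random.default_rng(seed)
    clim = climate.copy()
    clim["date"] = pd.to_datetime(clim["date"])
    w = truth.accumulation_window

    site_info = clim.groupby("site").agg(
        start=("date", "min"), end=("date", "max"),
        latitude=("latitude", "first"), longitude=("longitude", "first")
    )
    earliest = site_info["start"].min() + pd.Timedelta(days=w)
    if (site_info["end"] < earliest).all():
        raise ValueError(
            f"accumulation window extends before climate coverage for every site; "
            f"earliest admissible observation date is {earliest.date()}"
        )

    sites = rng.choice(site_info.index.to_numpy(), size=n_obs)
    starts = site_info.loc[sites, "start"].to_numpy()
    ends = site_info.loc[sites, "end"].to_numpy()
    lo = starts + np.timedelta64(w, "D")
    span = ((ends - lo) / np.timedelta64(1, "D")).astype(int)
    if np.any(span < 0):
        raise ValueError(
            f"accumulation window extends before climate coverage; earliest "
            f"admissible observation date is {earliest.date()}"
        )
    offsets = rng.integers(0, span + 1)
    dates = pd.to_datetime(lo) + pd.to_timedelta(offsets, unit="D")

    records = pd.DataFrame(
        {
            "record_id": [f"obs{j:06d}" for j in range(n_obs)],
            "species": species,
            "latitude": site_info.loc[sites, "latitude"].to_numpy(),
            "longitude": site_info.loc[sites, "longitude"].to_numpy(),
            "site": sites,
            "date": dates,
            "flower_annotation": "flowers_absent",  # placeholder until y is drawn
        }
    )
    cov = build_covariate_table(records, clim, CovariateConfig(window_days=w))
    if len(cov) != n_obs:
        raise RuntimeError("internal error: admissible-date sampling left incomplete windows")

    scaler = fit_scaler(cov)
    scaled = apply_scaler(cov, scaler)
    poly = OrthoPolyBasis(degree=2).fit(scaled["scaled_daylength"].to_numpy(float))
    X, _ = build_design(scaled, FULL_SPEC, poly)

    anomalous = np.zeros(n_obs, dtype=bool)
    if truth.anomaly_interval is not None:
        a0, a1 = pd.Timestamp(truth.anomaly_interval[0]), pd.Timestamp(truth.anomaly_interval[1])
        anomalous = np.asarray((dates >= a0) & (dates <= a1))

    logit = X @ np.asarray(truth.beta, float) + np.where(anomalous, truth.anomaly_logit_offset, 0.0)
    p_true = 1.0 / (1.0 + np.exp(-logit))
    y = (rng.random(n_obs) < p_true).astype(int)

    u = rng.random(n_obs)
    whole_plant = np.where(
        u < partial_frac, "partial", np.where(u < partial_frac + uncertain_frac, "uncertain", "whole")
    )

    records["flower_annotation"] = np.where(y == 1, "flowers_present", "flowers_absent")
    records["whole_plant"] = whole_plant
    records["period"] = np.where(anomalous, "anomalous", "normal")
    records["true_prob"] = p_true
    return records
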