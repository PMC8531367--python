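"""Climate covariates for phenoclimatic models.

Turns annotated flowering observations plus a daily climate table into the
modelling table: growing degree days (GDD) and mean daily precipitation
accumulated over a fixed window before each observation, photoperiod
(daylength) from latitude and date, confirmed-absence filtering, and
z-scaling of predictors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateConfig",
    "ScalingParams",
    "compute_gdd",
    "compute_avg_precip",
    "daylength",
    "filter_records",
    "build_covariate_table",
    "fit_scaler",
    "apply_scaler",
]

#: predictors that are z-scaled before model fitting
SCALED_COLUMNS = ("gdd", "avg_precip", "daylength")


@dataclass(frozen=True)
class CovariateConfig:
    """Accumulation-window settings for climate covariates.

    Parameters
    ----------
    base_temp : float
        GDD base temperature in °C. Degree days accrue only above it;
        there is no upper cutoff.
    window_days : int
        Length of the accumulation window, in days strictly before the
        observation date (the observation day itself is excluded).
    gdd_floor : str
        ``"per_day"`` floors each day's contribution at zero (the field
        convention, and the default); ``"on_total"`` sums signed daily
        anomalies and floors the total.
    """

    base_temp: float = 5.0
    window_days: int = 120
    gdd_floor: str = "per_day"

    def __post_init__(self) -> None:
        if not np.isfinite(self.base_temp):
            raise ValueError("base_temp must be finite")
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        if self.gdd_floor not in ("per_day", "on_total"):
            raise ValueError("gdd_floor must be 'per_day' or 'on_total'")


def compute_gdd(daily_mean_temps, base_temp: float = 5.0, gdd_floor: str = "per_day") -> float:
    """Accumulated growing degree days over a window of daily mean temperatures.

    With ``gdd_floor="per_day"`` each day contributes ``max(0, T - base)``;
    with ``"on_total"`` the signed anomalies are summed and the total is
    floored at zero. Either way the result is non-negative.
    """
    t = np.asarray(daily_mean_temps, dtype=float)
    if t.size == 0:
        raise ValueError("incomplete climate: empty temperature window")
    if np.any(~np.isfinite(t)):
        raise ValueError("incomplete climate: missing daily mean temperature in window")
    if gdd_floor == "per_day":
        return float(np.sum(np.maximum(0.0, t - base_temp)))
    if gdd_floor == "on_total":
        return float(max(0.0, np.sum(t - base_temp)))
    raise ValueError("gdd_floor must be 'per_day' or 'on_total'")


def compute_avg_precip(daily_precip) -> float:
    """Mean daily precipitation (mm/day) over the accumulation window."""
    p = np.asarray(daily_precip, dtype=float)
    if p.size == 0:
        raise ValueError("incomplete climate: empty precipitation window")
    if np.any(~np.isfinite(p)):
        raise ValueError("incomplete climate: missing daily precipitation in window")
    if np.any(p < 0):
        raise ValueError("negative precipitation is not physical")
    return float(np.mean(p))


def daylength(latitude, day_of_year):
    """Photoperiod in hours from latitude and day of year.

    CBM model of Forsythe et al. (1995) with the daylight coefficient
    p = 0.8333° (sunrise/sunset defined at the top of the solar disk with
    standard refraction), the convention used by common geospatial
    daylength routines. The acos argument is clamped, so polar day and
    polar night return 24 h and 0 h exactly. Day of year is wrapped into
    1..365.

    Accepts scalars or arrays (broadcast together).
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any((lat < -90.0) | (lat > 90.0)):
        raise ValueError("latitude must lie in [-90, 90] degrees")
    doy = (np.asarray(day_of_year, dtype=float) - 1.0) % 365.0 + 1.0
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.0086 * (doy - 186.0)))
    phi = np.arcsin(0.39795 * np.cos(theta))  # solar declination
    a = (np.sin(np.radians(0.8333)) + np.sin(np.radians(lat)) * np.sin(phi)) / (
        np.cos(np.radians(lat)) * np.cos(phi)
    )
    a = np.clip(a, -1.0, 1.0)
    out = 24.0 - (24.0 / np.pi) * np.arccos(a)
    if np.isscalar(latitude) and np.isscalar(day_of_year):
        return float(out)
    return out


def _window_complete(record_date: pd.Timestamp, site: str, coverage: dict, window_days: int) -> bool:
    """Does the climate table cover the full window before this date at this site?"""
    if site not in coverage:
        return False
    start, end, n_days = coverage[site]
    w_start = record_date - pd.Timedelta(days=window_days)
    w_end = record_date - pd.Timedelta(days=1)
    if w_start < start or w_end > end:
        return False
    # contiguous daily coverage was validated when the lookup was built
    return True


def filter_records(
    records: pd.DataFrame,
    climate: pd.DataFrame | None = None,
    config: CovariateConfig | None = None,
):
    """Apply the confirmed-absence and climate-completeness filters.

    Presences are kept regardless of how much of the plant is visible: a
    flower in frame is a flower. Absences count only when the whole plant
    was visible ("confirmed absences"); partial-plant and uncertain
    absences are dropped. If a climate table and config are supplied, rows
    whose accumulation window is not fully covered by the climate record
    are dropped too.

    Returns
    -------
    (retained, log) : (DataFrame, dict)
        The retained rows (original order) and a per-reason count log.
    """
    log = {
        "n_input": int(len(records)),
        "dropped_partial_absence": 0,
        "dropped_uncertain_absence": 0,
        "dropped_incomplete_climate": 0,
    }
    is_presence = records["flower_annotation"] == "flowers_present"
    keep = is_presence | (records["whole_plant"] == "whole")
    log["dropped_partial_absence"] = int((~is_presence & (records["whole_plant"] == "partial")).sum())
    log["dropped_uncertain_absence"] = int((~is_presence & (records["whole_plant"] == "uncertain")).sum())
    out = records.loc[keep].copy()

    if climate is not None:
        if config is None:
            config = CovariateConfig()
        coverage = _site_coverage(climate)
        dates = pd.to_datetime(out["date"])
        ok = np.array(
            [
                _window_complete(d, s, coverage, config.window_days)
                for d, s in zip(dates, out["site"])
            ],
            dtype=bool,
        )
        log["dropped_incomplete_climate"] = int((~ok).sum())
        out = out.loc[ok]

    log["n_retained"] = int(len(out))
    return out, log


def _site_coverage(climate: pd.DataFrame) -> dict:
    """Per-site (start, end, n_days) with a gap check on daily coverage."""
    cov = {}
    dates = pd.to_datetime(climate["date"])
    for site, grp in dates.groupby(climate["site"].values):
        start, end = grp.min(), grp.max()
        n = grp.nunique()
        if n != (end - start).days + 1:
            raise ValueError(f"climate table for site {site!r} has gaps in daily coverage")
        cov[site] = (start, end, n)
    return cov


def build_covariate_table(
    records: pd.DataFrame,
    climate: pd.DataFrame,
    config: CovariateConfig | None = None,
) -> pd.DataFrame:
    """One modelling row per retained observation record.

    The window is the ``window_days`` days strictly before the observation
    date. Records whose window is not fully covered are silently dropped
    (use :func:`filter_records` first to log them). Daylength is computed
    from the record's latitude and day of year, and does not depend on the
    window.

    Output columns: record_id, species, site, date, day_of_year, y, gdd,
    avg_precip, daylength, period, latitude, longitude (plus ``true_prob``
    if present on input). Scaled columns are added separately by
    :func:`apply_scaler` so that scaling statistics can come from a
    training subset only.
    """
    if config is None:
        config = CovariateConfig()
    clim = climate.copy()
    clim["date"] = pd.to_datetime(clim["date"])
    clim = clim.sort_values(["site", "date"])

    # per-site daily arrays with prefix sums for O(1) window aggregation
    site_data = {}
    for site, grp in clim.groupby("site"):
        d0 = grp["date"].iloc[0]
        if len(grp) != (grp["date"].iloc[-1] - d0).days + 1:
            raise ValueError(f"climate table for site {site!r} has gaps in daily coverage")
        tmean = (grp["tmin"].to_numpy(float) + grp["tmax"].to_numpy(float)) / 2.0
        gdd_day = np.maximum(0.0, tmean - config.base_temp)
        anom_day = tmean - config.base_temp
        precip = grp["precip"].to_numpy(float)
        if np.any(precip < 0):
            raise ValueError("negative precipitation is not physical")
        site_data[site] = (
            d0,
            len(grp),
            np.concatenate([[0.0], np.cumsum(gdd_day)]),
            np.concatenate([[0.0], np.cumsum(anom_day)]),
            np.concatenate([[0.0], np.cumsum(precip)]),
        )

    rows = []
    w = config.window_days
    dates = pd.to_datetime(records["date"])
    for (_, rec), date in zip(records.iterrows(), dates):
        site = rec["site"]
        if site not in site_data:
            continue
        d0, n_days, cum_gdd, cum_anom, cum_precip = site_data[site]
        i_end = (date - d0).days  # exclusive: covers indices i_start .. i_end-1
        i_start = i_end - w
        if i_start < 0 or i_end > n_days:
            continue
        if config.gdd_floor == "per_day":
            gdd = cum_gdd[i_end] - cum_gdd[i_start]
        else:
            gdd = max(0.0, cum_anom[i_end] - cum_anom[i_start])
        avg_p = (cum_precip[i_end] - cum_precip[i_start]) / w
        doy = int(date.dayofyear)
        row = {
            "record_id": rec["record_id"],
            "species": rec.get("species", ""),
            "site": site,
            "date": date,
            "day_of_year": doy,
            "y": 1 if rec["flower_annotation"] == "flowers_present" else 0,
            "gdd": float(gdd),
            "avg_precip": float(avg_p),
            "daylength": daylength(float(rec["latitude"]), doy),
            "period": rec.get("period", "normal"),
            "latitude": float(rec["latitude"]),
            "longitude": float(rec["longitude"]),
        }
        if "true_prob" in rec.index:
            row["true_prob"] = rec["true_prob"]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScalingParams:
    """Per-covariate mean and sample standard deviation, frozen at fit time.

    Fitted on training data only; test and anomaly rows are transformed
    with these same statistics (never re-fitted), so a distribution shift
    in new data shows up as non-zero means after scaling — by design.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    n_fit: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]), n_fit=int(d["n_fit"]))


def fit_scaler(table: pd.DataFrame, columns=SCALED_COLUMNS) -> ScalingParams:
    """Learn z-scaling statistics (mean, sample sd with n-1) on a training table."""
    means, sds = {}, {}
    for col in columns:
        x = table[col].to_numpy(float)
        m = float(np.mean(x))
        s = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if s <= 0.0 or not np.isfinite(s):
            raise ValueError(f"cannot scale zero-variance column {col!r}")
        means[col], sds[col] = m, s
    return ScalingParams(means=means, sds=sds, n_fit=len(table))


def apply_scaler(table: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Append ``scaled_<col>`` columns using frozen training statistics."""
    out = table.copy()
    for col, m in params.means.items():
        out[f"scaled_{col}"] = (out[col].to_numpy(float) - m) / params.sds[col]
    return out


def invert_scaler(table: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Recover raw columns from scaled ones (round-trip utility)."""
    out = table.copy()
    for col, m in params.means.items():
        out[col] = out[f"scaled_{col}"].to_numpy(float) * params.sds[col] + m
    return out
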