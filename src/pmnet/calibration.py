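"""Collocation QC: network mean, per-sensor regressions, corrections, drift.

When all sensors sample the same air, differences between them reflect
instrument response rather than the atmosphere.  Each sensor is regressed
(OLS) against the all-sensor hourly mean; the regression slope/intercept
from the pre- and post-study collocations are averaged into a per-sensor
correction factor, applied inversely:

    corrected = (raw - intercept) / slope

so that every sensor reports a value comparable to the network mean.  When
the post-study fit is invalid (too few hours, degenerate range) the
pre-study fit alone is used.  Drift between the two collocations is
summarised by evaluating both regressions at fixed concentrations
(5...50 ug/m3) and reporting the change.

The optical counter's factory retrieval, mass = 0.518 + 0.00274 * count
(hppcf), links the raw particle-count and mass columns so either can be
the ingestion path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InsufficientDataError, ValidationError

logger = logging.getLogger("pmnet")

DRIFT_LEVELS = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0)


@dataclass(frozen=True)
class RetrievalCoefficients:
    """Factory count-to-mass retrieval: mass = intercept + slope * count."""

    intercept: float = 0.518  # ug/m3 at zero counts
    slope: float = 0.00274  # ug/m3 per hppcf

    def __post_init__(self):
        if self.slope <= 0:
            raise ValidationError("retrieval slope must be positive")


DEFAULT_RETRIEVAL = RetrievalCoefficients()


def count_to_mass(count, coeffs: RetrievalCoefficients = DEFAULT_RETRIEVAL):
    """PM2.5 mass (ug/m3) from a particle count (hppcf)."""
    arr = np.asarray(count, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("particle counts must be nonnegative")
    out = coeffs.intercept + coeffs.slope * arr
    return float(out) if out.ndim == 0 else out


def mass_to_count(mass, coeffs: RetrievalCoefficients = DEFAULT_RETRIEVAL):
    """Inverse retrieval: particle count (hppcf) from mass (ug/m3)."""
    arr = np.asarray(mass, dtype=float)
    out = (arr - coeffs.intercept) / coeffs.slope
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RegressionFit:
    sensor_id: str
    period: str  # pre | post | deployment
    slope: float
    intercept: float
    r2: float
    rmse_vs_mean: float
    n_hours: int
    valid: bool = True


@dataclass(frozen=True)
class CorrectionFactor:
    sensor_id: str
    slope: float
    intercept: float
    source: str  # averaged | pre_only

    def __post_init__(self):
        if self.slope <= 0:
            raise ValidationError("correction slope must be positive")


def network_mean(hourly_wide: pd.DataFrame, min_sensors: int | None = None) -> pd.Series:
    """Across-sensor hourly mean over hours with enough sensors reporting.

    ``hourly_wide`` is a time x sensor matrix of valid hourly means.  Hours
    with fewer than ``min_sensors`` reporting (default: 75% of the sensor
    columns) are excluded.  The sensor later regressed against this mean is
    included in it, matching the collocation construction.
    """
    if min_sensors is None:
        min_sensors = math.ceil(0.75 * hourly_wide.shape[1])
    counts = hourly_wide.notna().sum(axis=1)
    mean = hourly_wide.mean(axis=1, skipna=True)[counts >= min_sensors]
    if mean.empty:
        raise InsufficientDataError("no hours meet the network-mean sensor threshold")
    return mean


def fit_sensor_vs_mean(
    sensor: pd.Series,
    mean: pd.Series,
    sensor_id: str = "",
    period: str = "pre",
    min_hours: int = 24,
) -> RegressionFit:
    """OLS of one sensor (response) on the network mean (predictor).

    RMSE is the root mean square of the raw ``sensor - mean`` differences
    (not regression residuals), so identical series give RMSE 0 and a
    constant offset b gives RMSE |b|.
    """
    pairs = pd.concat({"s": sensor, "m": mean}, axis=1, join="inner").dropna()
    n = len(pairs)
    if n < 2 or pairs["m"].nunique() < 2:
        raise InsufficientDataError("network mean has no variance or too few hours")
    res = stats.linregress(pairs["m"], pairs["s"])
    rmse = float(np.sqrt(np.mean((pairs["s"] - pairs["m"]) ** 2)))
    return RegressionFit(
        sensor_id=sensor_id,
        period=period,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        rmse_vs_mean=rmse,
        n_hours=n,
        valid=n >= min_hours,
    )


def fit_period(
    hourly_wide: pd.DataFrame,
    period: str,
    min_sensors: int | None = None,
    min_hours: int = 24,
) -> dict[str, RegressionFit]:
    """Fit every sensor column against the shared network mean."""
    mean = network_mean(hourly_wide, min_sensors=min_sensors)
    fits = {}
    for sensor_id in hourly_wide.columns:
        try:
            fits[sensor_id] = fit_sensor_vs_mean(
                hourly_wide[sensor_id], mean, sensor_id=str(sensor_id), period=period, min_hours=min_hours
            )
        except InsufficientDataError:
            logger.warning("QC: no valid %s-period fit for sensor %s", period, sensor_id)
    return fits


def precision_summary(
    fits: dict[str, dict[str, RegressionFit]] | dict[str, RegressionFit],
    hourly_wide: pd.DataFrame | None = None,
) -> dict:
    """Per-period precision metrics plus the across-sensor CV.

    ``fits`` maps period -> {sensor -> fit} (a flat sensor -> fit mapping
    is treated as one period).  The coefficient of variation is computed
    per hour as the across-sensor sample SD divided by the across-sensor
    mean (hours with a zero or undefined mean are skipped and logged),
    then averaged; the summary reports mean and SD of the hourly CVs.
    """
    if fits and isinstance(next(iter(fits.values())), RegressionFit):
        fits = {"all": fits}
    periods = {}
    for period, period_fits in fits.items():
        r2 = [f.r2 for f in period_fits.values()]
        rmse = [f.rmse_vs_mean for f in period_fits.values()]
        if len(r2) < 2:
            raise InsufficientDataError("precision summary needs at least two sensors")
        periods[period] = {
            "r2_mean": float(np.mean(r2)),
            "r2_min": float(np.min(r2)),
            "r2_max": float(np.max(r2)),
            "rmse_mean": float(np.mean(rmse)),
            "rmse_min": float(np.min(rmse)),
            "rmse_max": float(np.max(rmse)),
            "n_sensors": len(r2),
        }
    out = {"periods": periods}
    if hourly_wide is not None:
        counts = hourly_wide.notna().sum(axis=1)
        sd = hourly_wide.std(axis=1, ddof=1, skipna=True)
        mean = hourly_wide.mean(axis=1, skipna=True)
        ok = (counts >= 2) & mean.notna() & (mean != 0)
        skipped = int((counts >= 2).sum() - ok.sum())
        if skipped:
            logger.warning("QC: skipped %d hours with zero/undefined mean in CV", skipped)
        cv = (sd / mean)[ok]
        if cv.empty:
            raise InsufficientDataError("no qualifying hours for CV")
        out["cv_mean"] = float(cv.mean())
        out["cv_sd"] = float(cv.std(ddof=1)) if len(cv) > 1 else 0.0
        out["cv_n_hours"] = int(len(cv))
    return out


def derive_correction(pre: RegressionFit, post: RegressionFit | None = None) -> CorrectionFactor:
    """Average pre/post collocation fits into a correction factor.

    Falls back to the pre-study fit alone (``source="pre_only"``) when the
    post-study fit is absent or flagged invalid.
    """
    if pre is None or not pre.valid:
        raise ValidationError("pre-study fit is required and must be valid")
    if post is not None and post.valid:
        return CorrectionFactor(
            sensor_id=pre.sensor_id,
            slope=(pre.slope + post.slope) / 2.0,
            intercept=(pre.intercept + post.intercept) / 2.0,
            source="averaged",
        )
    return CorrectionFactor(pre.sensor_id, pre.slope, pre.intercept, "pre_only")


def apply_correction(raw, cf: CorrectionFactor):
    """Invert the per-sensor affine response: (raw - intercept) / slope.

    Missing values propagate.  Negative corrected values are retained (and
    QC-logged) rather than clipped, so that means stay unbiased.
    """
    if cf.slope <= 0:
        raise ValidationError("correction slope must be positive")
    corrected = (raw - cf.intercept) / cf.slope
    n_neg = int(np.nansum(np.asarray(corrected) < 0))
    if n_neg:
        logger.info("QC: correction for %s produced %d negative values", cf.sensor_id, n_neg)
    return corrected


def corrections_table(
    pre_fits: dict[str, RegressionFit], post_fits: dict[str, RegressionFit]
) -> pd.DataFrame:
    """Per-sensor correction factors with the fit diagnostics alongside."""
    rows = []
    for sensor_id, pre in pre_fits.items():
        post = post_fits.get(sensor_id)
        cf = derive_correction(pre, post)
        rows.append(
            {
                "sensor_id": sensor_id,
                "slope": cf.slope,
                "intercept": cf.intercept,
                "source": cf.source,
                "r2_pre": pre.r2,
                "r2_post": post.r2 if post else np.nan,
                "rmse_pre": pre.rmse_vs_mean,
                "rmse_post": post.rmse_vs_mean if post else np.nan,
                "n_pre": pre.n_hours,
                "n_post": post.n_hours if post else 0,
            }
        )
    return pd.DataFrame(rows).set_index("sensor_id")


def drift_table(
    pre: RegressionFit,
    post: RegressionFit,
    levels: tuple[float, ...] = DRIFT_LEVELS,
    pct_denominator: str = "pre_reading",
) -> pd.DataFrame:
    """Change in reading fixed concentrations between the two collocations.

    For each level v, both period regressions are evaluated
    (slope * v + intercept); ``change_abs`` is post minus pre and
    ``change_pct`` is 100 |change| referenced to the pre-period reading
    (or to the level itself with ``pct_denominator="level"``).  Levels
    whose pre-period reading is nonpositive get an undefined percentage.
    """
    if not (pre.valid and post.valid):
        raise ValidationError("drift evaluation needs valid pre and post fits")
    if pct_denominator not in ("pre_reading", "level"):
        raise ValidationError("pct_denominator must be 'pre_reading' or 'level'")
    lv = np.asarray(levels, dtype=float)
    reading_pre = pre.slope * lv + pre.intercept
    reading_post = post.slope * lv + post.intercept
    change = reading_post - reading_pre
    denom = reading_pre if pct_denominator == "pre_reading" else lv
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(denom > 0, 100.0 * np.abs(change) / denom, np.nan)
    return pd.DataFrame(
        {
            "level": lv,
            "reading_pre": reading_pre,
            "reading_post": reading_post,
            "change_abs": change,
            "change_pct": pct,
            "pct_defined": denom > 0,
        }
    ).set_index("level")


def drift_fraction_below(tables: list[pd.DataFrame], threshold_pct: float = 10.0) -> float:
    """Fraction of sensor x level cases with drift below a percent threshold."""
    pct = np.concatenate([t["change_pct"].to_numpy() for t in tables])
    pct = pct[np.isfinite(pct)]
    if pct.size == 0:
        raise InsufficientDataError("no defined drift percentages")
    return float(np.mean(pct < threshold_pct))
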