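"""Sensor-versus-reference accuracy and meteorological bias regression.

A corrected sensor collocated with a regulatory monitor (hourly
beta-attenuation monitor, daily gravimetric filter sampler) gives the
network's accuracy.  Because the optical sensor does not dry its inlet
air, hygroscopic particle growth at high humidity inflates its readings;
the analysis therefore (a) stratifies the sensor/reference ratio by
meteorology, and (b) fits OLS models of the reference on the sensor plus
meteorological covariates (temperature, dew point, RH, wind speed) and
ranks covariates by the gain in adjusted R2,

    adj R2 = 1 - (1 - R2) (n - 1) / (n - k - 1),

with n observations and k predictors.  The "quadratic_full" model adds
squares and all pairwise cross terms of the four met variables
(k = 1 + 4 + 4 + 6 = 15 predictors including the sensor term).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import InsufficientDataError, ValidationError

logger = logging.getLogger("pmnet")

MET_VARS = ("temp", "dew", "rh", "ws")
MET_COLUMN_FOR = {"temp": "temp_c", "dew": "dew_point_c", "rh": "rh_pct", "ws": "ws_ms"}
MODEL_SPECS = ("initial", "+temp", "+dew", "+rh", "+ws", "all_linear", "quadratic_full")

# dew-point bins for ratio stratification: below the growth onset, the
# transition range, and the strong-growth regime (degC)
DEW_POINT_BINS = (-np.inf, 4.0, 10.0, np.inf)


@dataclass(frozen=True)
class ScatterSummary:
    n: int
    r2: float
    slope: float
    intercept: float
    mean_bias: float  # mean(sensor - reference)
    ratio_by_met: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass(frozen=True)
class RegressionResult:
    model_spec: str
    r2: float
    adjusted_r2: float
    coefficients: dict[str, float]
    p_values: dict[str, float]
    n: int
    k: int


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Penalize R2 for the number of predictors k at sample size n."""
    if n - k - 1 <= 0:
        raise ValidationError("adjusted R2 undefined: n - k - 1 <= 0")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _aligned(sensor: pd.Series, reference: pd.Series, met: pd.DataFrame | None = None) -> pd.DataFrame:
    frames = {"sensor": sensor, "reference": reference}
    if met is not None:
        met_idx = met.set_index("hour_start") if "hour_start" in met.columns else met
        for var, col in MET_COLUMN_FOR.items():
            if col in met_idx.columns:
                frames[var] = met_idx[col]
    df = pd.concat(frames, axis=1, join="inner").dropna()
    return df.sort_index()


def compare_to_reference(
    sensor: pd.Series,
    reference: pd.Series,
    met: pd.DataFrame | None = None,
    resolution: str = "hourly",
    min_overlap: int = 24,
) -> ScatterSummary:
    """Scatter summary of a sensor against a collocated reference monitor.

    Reports OLS slope/intercept (sensor on reference), R2, mean bias, and
    the mean sensor/reference ratio stratified by meteorological bins:
    fixed dew-point bins around the hygroscopic-growth onset, quartile
    bins for the other variables.
    """
    df = _aligned(sensor, reference, met)
    if len(df) < min_overlap:
        raise InsufficientDataError(f"only {len(df)} aligned points (< {min_overlap})")
    res = stats.linregress(df["reference"], df["sensor"])
    ratio_by_met = {}
    if met is not None:
        pos = df[df["reference"] > 0]
        for var in MET_VARS:
            if var not in df.columns:
                continue
            if var == "dew":
                bins = pd.cut(pos[var], list(DEW_POINT_BINS))
            else:
                bins = pd.qcut(pos[var], 4, duplicates="drop")
            grouped = pos.groupby(bins, observed=True)
            ratio_by_met[var] = pd.DataFrame(
                {
                    "ratio": grouped.apply(lambda g: g["sensor"].mean() / g["reference"].mean(), include_groups=False),
                    "n": grouped.size(),
                }
            )
    return ScatterSummary(
        n=len(df),
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        mean_bias=float((df["sensor"] - df["reference"]).mean()),
        ratio_by_met=ratio_by_met,
    )


def _design(df: pd.DataFrame, model_spec: str, response: str) -> pd.DataFrame:
    x = pd.DataFrame({"sensor": df["sensor"]} if response == "reference" else {"reference": df["reference"]})
    if model_spec == "initial":
        pass
    elif model_spec.startswith("+"):
        var = model_spec[1:]
        if var not in MET_VARS:
            raise ValidationError(f"unknown model spec {model_spec!r}")
        x[var] = df[var]
    elif model_spec == "all_linear":
        for var in MET_VARS:
            x[var] = df[var]
    elif model_spec == "quadratic_full":
        for var in MET_VARS:
            x[var] = df[var]
        for var in MET_VARS:
            x[f"{var}^2"] = df[var] ** 2
        for a, b in combinations(MET_VARS, 2):
            x[f"{a}*{b}"] = df[a] * df[b]
    else:
        raise ValidationError(f"unknown model spec {model_spec!r}")
    return x


def met_regression(
    sensor: pd.Series,
    reference: pd.Series,
    met: pd.DataFrame,
    model_spec: str = "all_linear",
    response: str = "reference",
) -> RegressionResult:
    """OLS of the reference on the sensor plus meteorological covariates.

    ``model_spec`` is one of ``initial`` (sensor only), ``+temp`` /
    ``+dew`` / ``+rh`` / ``+ws`` (one covariate added linearly),
    ``all_linear`` (all four), or ``quadratic_full`` (squares and cross
    terms as well).  ``response="sensor"`` transposes the convention.
    Covariates collinear to machine tolerance are dropped with a warning.
    """
    df = _aligned(sensor, reference, met)
    needed = set(MET_VARS) if model_spec not in ("initial",) else set()
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"met table lacks covariates: {sorted(missing)}")
    x = _design(df, model_spec, response)
    y = df["reference"] if response == "reference" else df["sensor"]
    # drop columns that add no rank (exactly collinear predictors)
    keep: list[str] = []
    for col in x.columns:
        trial = x[keep + [col]].to_numpy()
        if np.linalg.matrix_rank(trial, tol=1e-10 * max(1.0, np.abs(trial).max())) == len(keep) + 1:
            keep.append(col)
        else:
            logger.warning("QC: dropped collinear regression term %s", col)
    x = x[keep]
    if len(df) - len(keep) - 1 <= 0:
        raise InsufficientDataError("too few observations for this model")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    k = int(model.df_model)
    return RegressionResult(
        model_spec=model_spec,
        r2=float(model.rsquared),
        adjusted_r2=float(model.rsquared_adj),
        coefficients={t: float(v) for t, v in model.params.items()},
        p_values={t: float(v) for t, v in model.pvalues.items()},
        n=int(model.nobs),
        k=k,
    )


def rank_single_covariates(
    sensor: pd.Series, reference: pd.Series, met: pd.DataFrame, response: str = "reference"
) -> pd.DataFrame:
    """Rank the four met covariates by single-covariate adjusted-R2 gain."""
    base = met_regression(sensor, reference, met, "initial", response=response)
    rows = []
    for var in MET_VARS:
        res = met_regression(sensor, reference, met, f"+{var}", response=response)
        rows.append(
            {
                "covariate": var,
                "adjusted_r2": res.adjusted_r2,
                "gain": res.adjusted_r2 - base.adjusted_r2,
                "p_value": res.p_values.get(var, np.nan),
            }
        )
    return pd.DataFrame(rows).sort_values("gain", ascending=False).reset_index(drop=True)


def accuracy_table(
    sensor: pd.Series, reference: pd.Series, met: pd.DataFrame, response: str = "reference"
) -> pd.DataFrame:
    """Adjusted R2 for every model spec, one row per specification."""
    rows = []
    for spec in MODEL_SPECS:
        res = met_regression(sensor, reference, met, spec, response=response)
        rows.append({"model_spec": spec, "r2": res.r2, "adjusted_r2": res.adjusted_r2, "n": res.n, "k": res.k})
    return pd.DataFrame(rows).set_index("model_spec")
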