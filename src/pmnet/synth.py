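"""Synthetic sensor-network campaign generator (truth + observations).

Emulates a wintertime urban PM2.5 campaign: ~19 optical sensors deployed
over ~15 sites in 6 communities for two months, book-ended by whole-
network collocations at a reference site.  Everything downstream of the
generator (calibration, accuracy, spatial statistics, emissions linkage)
can be exercised against known ground truth without any field data.

The truth field is a shared regional log-normal baseline (AR(1) synoptic
persistence) modulated by a diurnal factor that rises from the configured
late-afternoon hour to an overnight plateau — the wintertime pattern in
which residential burning and a shallow nocturnal boundary layer drive
evening PM peaks — plus a site-specific nocturnal spike process with
exponential spatial correlation over distance, and an optional additive
mean shift for EJ-community sites.

Each sensor observes its site's truth through an affine instrument
response (per-sensor slope/intercept drawn from configured ranges), a
multiplicative hygroscopic-growth factor driven by dew point (the optical
bias a heated reference monitor does not share), additive noise, and
random missingness.  Particle counts and masses are linked through the
exact factory retrieval so either column can be the ingestion path.

Identical seeds produce bit-identical campaigns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import met as _met
from .calibration import mass_to_count
from .core import StudyPeriods, ValidationError, aggregate_to_hours
from .emissions import EmissionCell

DOMAIN_KM = (14.0, 16.0)  # east-west x north-south study domain
ORIGIN_LATLON = (38.47, -121.52)  # south-west corner of the domain
_KM_PER_DEG = 2 * np.pi * 6371.0 / 360.0

EJ_COMMUNITIES = ("Arden", "South Natomas", "South Sacramento")
NON_EJ_COMMUNITIES = ("Del Paso", "T St", "Tahoe Park")

# canonical 15-site layout: (site_id, community, ej, x_km, y_km, role)
_SITE_LAYOUT = [
    ("arden_1", "Arden", True, 10.5, 13.5, "community"),
    ("delpaso_1", "Del Paso", False, 11.5, 12.5, "community"),
    ("ref_north", "Del Paso", False, 12.0, 13.0, "reference-collocated"),
    ("delpaso_3", "Del Paso", False, 12.5, 12.0, "community"),
    ("natomas_1", "South Natomas", True, 2.0, 10.0, "community"),
    ("natomas_2", "South Natomas", True, 3.5, 9.0, "community"),
    ("ssac_1", "South Sacramento", True, 6.5, 3.5, "community"),
    ("ssac_2", "South Sacramento", True, 8.0, 1.0, "community"),
    ("ssac_3", "South Sacramento", True, 7.0, 1.5, "community"),
    ("ssac_4", "South Sacramento", True, 9.0, 2.0, "community"),
    ("ref_south", "T St", False, 6.0, 5.5, "reference-collocated"),
    ("tst_2", "T St", False, 6.5, 5.0, "community"),
    ("tahoe_1", "Tahoe Park", False, 9.5, 4.5, "community"),
    ("tahoe_2", "Tahoe Park", False, 10.5, 4.0, "community"),
    ("tahoe_3", "Tahoe Park", False, 11.5, 4.5, "community"),
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a simulated campaign.

    Defaults mirror the winter 2016/17 deployment: 19 sensors over 15
    sites (two of them reference-collocated with 3 sensors each), a
    7-day pre-study and 32-day post-study whole-network collocation, and
    a 62-day deployment.  Per-sensor affine biases span the observed
    collocation-table ranges; the hygroscopic growth factor is 1 below a
    4 degC dew point and reaches 3 at 14 degC; reference-monitor noise
    uses the ~22% hourly precision figure (as a multiplicative SD of
    half that, treating the figure as a two-instrument comparison).
    """

    seed: int = 0
    n_sensors: int = 19
    n_sites: int = 15
    periods: StudyPeriods = field(default_factory=StudyPeriods.study_defaults)
    sensor_slope_range: tuple[float, float] = (0.78, 1.64)
    sensor_intercept_range: tuple[float, float] = (-3.2, 2.6)  # ug/m3
    noise_sd: float = 1.0  # minute-level additive noise, ug/m3
    growth_enabled: bool = True
    growth_model: str = "piecewise_linear"  # or "rh_power"
    growth_onset_dewpoint: float = 4.0  # degC
    growth_slope: float = 0.2  # growth-factor units per degC above onset
    rh_growth_coeff: float = 0.25  # only for the rh_power alternative
    bam_noise_fraction: float = 0.22
    frm_noise_fraction: float = 0.03  # daily filter sampler treated as near-truth
    evening_rise_hour: int = 16
    nocturnal_amplitude: float = 6.0  # ug/m3 spike scale
    spatial_corr_length_km: float = 8.0  # np.inf -> perfectly correlated sites
    site_gradient_sd: float = 0.15  # log-scale SD of the static site gradient
    ej_effect: float = 0.0  # ug/m3 additive shift at EJ sites
    missing_rate: float = 0.05
    baseline_median: float = 12.0  # ug/m3 regional winter median
    baseline_log_sd: float = 0.45  # synoptic log-scale SD
    time_resolution: str = "minute"  # or "hour" (fast path for simulations)

    def __post_init__(self):
        if self.sensor_slope_range[0] <= 0:
            raise ValidationError("sensor slope range must be strictly positive")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.bam_noise_fraction < 0:
            raise ValidationError("bam_noise_fraction must be nonnegative")
        if self.spatial_corr_length_km <= 0:
            raise ValidationError("spatial correlation length must be positive")
        if self.time_resolution not in ("minute", "hour"):
            raise ValidationError("time_resolution must be 'minute' or 'hour'")
        if self.n_sensors < self.n_sites + 4:
            # 3 + 3 sensors sit at the two reference sites during deployment
            raise ValidationError("need n_sensors >= n_sites + 4 to cover every site")


@dataclass(frozen=True)
class TruthBundle:
    true_pm: pd.DataFrame  # hours x site_id, ug/m3
    met: pd.DataFrame  # hour_start-indexed met with dew point
    sites: pd.DataFrame
    sensor_params: pd.DataFrame  # sensor_id-indexed slope/intercept/site map
    ej_effect: float
    ei_cells: list[EmissionCell] | None = None


@dataclass(frozen=True)
class Campaign:
    config: GeneratorConfig
    truth: TruthBundle
    minutes: pd.DataFrame | None
    hourly: pd.DataFrame
    bam: pd.DataFrame
    frm: pd.DataFrame


# ---------------------------------------------------------------------------
# sites and meteorology


def make_sites(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Site table with lat/lon and local km coordinates.

    The default 15-site layout is a fixed geography; other site counts
    get a seeded random layout over the same domain with the six
    community labels assigned in blocks.
    """
    if config.n_sites == 15:
        rows = _SITE_LAYOUT
    else:
        rng = np.random.default_rng(config.seed) if rng is None else rng
        communities = list(EJ_COMMUNITIES + NON_EJ_COMMUNITIES)
        rows = []
        for i in range(config.n_sites):
            comm = communities[i % 6]
            role = "reference-collocated" if i < 2 else "community"
            rows.append(
                (
                    f"site_{i:02d}",
                    comm,
                    comm in EJ_COMMUNITIES,
                    float(rng.uniform(0, DOMAIN_KM[0])),
                    float(rng.uniform(0, DOMAIN_KM[1])),
                    role,
                )
            )
    lat0, lon0 = ORIGIN_LATLON
    df = pd.DataFrame(rows, columns=["site_id", "community", "ej_flag", "x_km", "y_km", "role"])
    df["lat"] = lat0 + df["y_km"] / _KM_PER_DEG
    df["lon"] = lon0 + df["x_km"] / (_KM_PER_DEG * np.cos(np.radians(lat0)))
    df["name"] = df["site_id"]
    return df[["site_id", "name", "community", "ej_flag", "lat", "lon", "role", "x_km", "y_km"]]


def simulate_met(config: GeneratorConfig, hours: pd.DatetimeIndex, rng: np.random.Generator) -> pd.DataFrame:
    """Hourly meteorology: humid winter with near-saturated nights.

    Dew point is a slow AR(1) around 6 degC (SD ~2.8 degC, spanning the
    unbiased-to-strong-growth regimes); air temperature is the dew point
    plus a diurnal gap that collapses to <1 degC overnight, which puts
    roughly two-thirds of hours at RH >= 85%.
    """
    n = len(hours)
    # decorrelation time ~2 days so a two-month run samples both the dry
    # (< 4 degC) and strong-growth (> 10 degC) dew-point regimes
    mu_dp, sd_dp, phi = 6.0, 3.0, 0.98
    eps = rng.normal(0.0, sd_dp * np.sqrt(1 - phi**2), n)
    dp = np.empty(n)
    dp[0] = mu_dp + rng.normal(0.0, sd_dp)
    for t in range(1, n):
        dp[t] = mu_dp + phi * (dp[t - 1] - mu_dp) + eps[t]
    hod = hours.hour.to_numpy()
    bump = np.exp(-0.5 * ((hod - 13.5) / 2.0) ** 2)
    # day-to-day variation of the diurnal temperature range is independent
    # of absolute moisture, so temperature is a noisy proxy for dew point
    day_idx = (hours - hours[0]).days.to_numpy()
    amp_day = np.clip(rng.normal(7.2, 3.0, int(day_idx.max()) + 1), 1.5, None)
    gap = np.clip(0.6 + amp_day[day_idx] * bump + rng.normal(0.0, 1.5, n), 0.3, None)
    temp = dp + gap
    rh = np.clip(
        100.0 * _met.saturation_vapor_pressure(dp) / _met.saturation_vapor_pressure(temp), 1.0, 100.0
    )
    ws = np.clip(1.0 + 1.3 * np.exp(-0.5 * ((hod - 15.0) / 3.0) ** 2) + rng.normal(0.0, 0.5, n), 0.05, None)
    wd = np.mod(200.0 + 60.0 * np.sin(2 * np.pi * hod / 24.0) + rng.normal(0.0, 40.0, n), 360.0)
    met = pd.DataFrame(
        {"temp_c": temp, "rh_pct": rh, "ws_ms": ws, "wd_deg": wd}, index=pd.Index(hours, name="hour_start")
    )
    met["vp_hpa"] = _met.vapor_pressure(met["temp_c"].to_numpy(), met["rh_pct"].to_numpy())
    met["dew_point_c"] = _met.dew_point(met["vp_hpa"].to_numpy())
    return met


# ---------------------------------------------------------------------------
# truth field


def _diurnal_factor(hod: np.ndarray, rise_hour: int, low: float = 0.45, high: float = 1.9) -> np.ndarray:
    """Evening rise from ``rise_hour`` to an overnight plateau (22:00-02:00),
    morning decay, afternoon minimum."""
    d = np.full(hod.shape, low, dtype=float)
    rising = (hod >= rise_hour) & (hod < 22)
    d[rising] = low + (high - low) * (1 - np.cos(np.pi * (hod[rising] - rise_hour) / (22 - rise_hour))) / 2
    d[(hod >= 22) | (hod < 2)] = high
    morning = (hod >= 2) & (hod < 11)
    d[morning] = high - (high - low) * (1 - np.cos(np.pi * (hod[morning] - 2) / 9)) / 2
    return d


def _site_correlation_chol(sites: pd.DataFrame, length_km: float) -> np.ndarray | None:
    """Cholesky factor of exp(-d/L) site correlation; None means perfectly
    correlated (infinite correlation length)."""
    if np.isinf(length_km):
        return None
    xy = sites[["x_km", "y_km"]].to_numpy()
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    corr = np.exp(-d / length_km)
    return np.linalg.cholesky(corr + 1e-9 * np.eye(len(sites)))


def _correlated_ar_field(
    n_hours: int, chol: np.ndarray | None, n_sites: int, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(phi)-in-time field of standard-normal site vectors with the given
    cross-site Cholesky factor."""
    out = np.empty((n_hours, n_sites))
    scale = np.sqrt(1 - phi**2)
    if chol is None:
        z = rng.normal(size=n_hours)  # one shared innovation per hour
        innov = np.repeat(z[:, None], n_sites, axis=1)
    else:
        innov = rng.normal(size=(n_hours, n_sites)) @ chol.T
    out[0] = innov[0]
    for t in range(1, n_hours):
        out[t] = phi * out[t - 1] + scale * innov[t]
    return out


def simulate_regional_pm(
    config: GeneratorConfig,
    sites: pd.DataFrame | None = None,
    hours: pd.DatetimeIndex | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Nonnegative hourly truth field (hours x site).

    regional log-normal baseline x diurnal factor, times a mildly
    heterogeneous site factor and plus nocturnal spikes, both spatially
    correlated with an exponential decay over distance; EJ sites get the
    configured additive mean shift.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sites = make_sites(config) if sites is None else sites
    if hours is None:
        hours = (
            config.periods.hours("pre")
            .append(config.periods.hours("deployment"))
            .append(config.periods.hours("post"))
        )
    n, m = len(hours), len(sites)
    # synoptic AR(1) on the log scale
    phi = 0.98
    s = np.empty(n)
    s[0] = rng.normal(0.0, config.baseline_log_sd)
    eps = rng.normal(0.0, config.baseline_log_sd * np.sqrt(1 - phi**2), n)
    for t in range(1, n):
        s[t] = phi * s[t - 1] + eps[t]
    regional = config.baseline_median * np.exp(s)
    diurnal = _diurnal_factor(hours.hour.to_numpy(), config.evening_rise_hour)

    chol = _site_correlation_chol(sites, config.spatial_corr_length_km)
    # static spatial gradient: persistent high/low neighborhoods, the part
    # of heterogeneity an emissions inventory can hope to mirror; demeaned
    # within each EJ group so the realized group difference is ej_effect
    # and nothing else
    if chol is None:
        gamma = np.full(m, float(rng.normal()))
    else:
        gamma = chol @ rng.normal(size=m)
    ej_mask = sites["ej_flag"].to_numpy(dtype=bool)
    for mask in (ej_mask, ~ej_mask):
        if mask.any():
            gamma[mask] -= gamma[mask].mean()
    static = np.exp(config.site_gradient_sd * gamma - config.site_gradient_sd**2 / 2)
    sigma_eta = 0.12
    eta = sigma_eta * _correlated_ar_field(n, chol, m, 0.9, rng)
    site_factor = static[None, :] * np.exp(eta - sigma_eta**2 / 2)

    hod = hours.hour.to_numpy()
    night = ((hod >= 18) | (hod < 3)).astype(float)
    g = _correlated_ar_field(n, chol, m, 0.7, rng)
    spikes = config.nocturnal_amplitude * np.clip(g - 1.0, 0.0, None) * night[:, None]

    field = (regional * diurnal)[:, None] * site_factor + spikes
    field = field + config.ej_effect * sites["ej_flag"].to_numpy(dtype=float)[None, :]
    return pd.DataFrame(
        np.clip(field, 0.0, None), index=pd.Index(hours, name="hour_start"), columns=sites["site_id"]
    )


# ---------------------------------------------------------------------------
# instrument forward model


def growth_factor(config: GeneratorConfig, met: pd.DataFrame) -> pd.Series:
    """Hygroscopic growth multiplier for the optical sensor.

    ``piecewise_linear``: 1 below the dew-point onset, rising by
    ``growth_slope`` per degC above it (1 at 4 degC, 3 at 14 degC with
    defaults).  ``rh_power``: the scattering-enhancement form
    1 + c * RH / (100 - RH).  Both are monotone in humidity.
    """
    if not config.growth_enabled:
        return pd.Series(1.0, index=met.index)
    if config.growth_model == "piecewise_linear":
        dp = met["dew_point_c"]
        g = 1.0 + config.growth_slope * np.clip(dp - config.growth_onset_dewpoint, 0.0, None)
    elif config.growth_model == "rh_power":
        rh = met["rh_pct"].clip(upper=99.0)
        g = 1.0 + config.rh_growth_coeff * rh / (100.0 - rh)
    else:
        raise ValidationError(f"unknown growth model {config.growth_model!r}")
    return pd.Series(np.asarray(g, dtype=float), index=met.index)


def sensor_forward_model(
    true_hourly: pd.Series,
    met: pd.DataFrame,
    slope: float,
    intercept: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    sensor_id: str = "sensor",
) -> pd.DataFrame:
    """Minute records one sensor would report for an hourly truth series.

    observed mass = growth(dewpoint) * (slope * truth + intercept) + noise,
    floored at 0; the particle-count column is the exact retrieval
    inverse (mass - 0.518) / 0.00274, floored at 0.  Minutes are dropped
    independently at ``missing_rate``.
    """
    if slope <= 0:
        raise ValidationError("sensor slope must be positive")
    g = growth_factor(config, met).reindex(true_hourly.index).to_numpy()
    base = g * (slope * true_hourly.to_numpy() + intercept)
    n_min = len(true_hourly) * 60
    minute_ts = np.repeat(true_hourly.index.to_numpy(), 60) + np.tile(
        np.arange(60) * np.timedelta64(1, "m"), len(true_hourly)
    )
    m = np.repeat(base, 60) + rng.normal(0.0, config.noise_sd, n_min)
    m = np.clip(m, 0.0, None)
    counts = np.clip(mass_to_count(m), 0.0, None)
    keep = rng.random(n_min) >= config.missing_rate
    return pd.DataFrame(
        {
            "sensor_id": sensor_id,
            "timestamp": minute_ts[keep],
            "particle_count_hppcf": counts[keep],
            "pm25_ugm3": m[keep],
        }
    )


def _sensor_hourly_direct(
    true_hourly: pd.Series,
    met: pd.DataFrame,
    slope: float,
    intercept: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    sensor_id: str,
) -> pd.DataFrame:
    """Fast path: hourly observations with minute-mean-equivalent noise
    (SD noise_sd / sqrt(60)); whole hours dropped at missing_rate."""
    g = growth_factor(config, met).reindex(true_hourly.index).to_numpy()
    base = g * (slope * true_hourly.to_numpy() + intercept)
    pm = np.clip(base + rng.normal(0.0, config.noise_sd / np.sqrt(60), len(base)), 0.0, None)
    keep = rng.random(len(base)) >= config.missing_rate
    return pd.DataFrame(
        {
            "sensor_id": sensor_id,
            "hour_start": true_hourly.index[keep],
            "pm25": pm[keep],
            "n_minutes": 60,
        }
    )


# ---------------------------------------------------------------------------
# full campaign


def _assign_sensors(config: GeneratorConfig, sites: pd.DataFrame) -> pd.DataFrame:
    """Per-sensor deployment map: 3 sensors at each reference site, one per
    remaining community site, extras cycling over community sites."""
    ref = sites.loc[sites["role"] == "reference-collocated", "site_id"].tolist()
    if len(ref) < 2:
        raise ValidationError("need two reference-collocated sites")
    community = sites.loc[sites["role"] != "reference-collocated", "site_id"].tolist()
    sensor_ids = [f"AB{i + 1:02d}" for i in range(config.n_sensors)]
    deploy = ref[:1] * 3 + ref[1:2] * 3
    for i in range(config.n_sensors - 6):
        deploy.append(community[i % len(community)])
    return pd.DataFrame(
        {
            "sensor_id": sensor_ids,
            "site_pre": ref[0],
            "site_deployment": deploy,
            "site_post": ref[0],
        }
    ).set_index("sensor_id")


def simulate_campaign(config: GeneratorConfig) -> Campaign:
    """Generate the full three-phase campaign: truth, sensor observations,
    and reference-monitor (hourly BAM-like, daily FRM-like) series."""
    rng = np.random.default_rng(config.seed)
    sites = make_sites(config, rng)
    hours = (
        config.periods.hours("pre").append(config.periods.hours("deployment")).append(config.periods.hours("post"))
    )
    met = simulate_met(config, hours, rng)
    true_pm = simulate_regional_pm(config, sites=sites, hours=hours, rng=rng)

    assignment = _assign_sensors(config, sites)
    lo_s, hi_s = config.sensor_slope_range
    lo_b, hi_b = config.sensor_intercept_range
    params = assignment.copy()
    params["slope"] = rng.uniform(lo_s, hi_s, config.n_sensors)
    params["intercept"] = rng.uniform(lo_b, hi_b, config.n_sensors)

    phase_hours = {p: config.periods.hours(p) for p in ("pre", "deployment", "post")}
    minute_frames, hourly_frames = [], []
    for sensor_id, row in params.iterrows():
        pieces = []
        for phase in ("pre", "deployment", "post"):
            site = row[f"site_{phase}" if phase != "deployment" else "site_deployment"]
            pieces.append(true_pm.loc[phase_hours[phase], site])
        truth_series = pd.concat(pieces)
        if config.time_resolution == "minute":
            minute_frames.append(
                sensor_forward_model(truth_series, met, row["slope"], row["intercept"], config, rng, sensor_id)
            )
        else:
            hourly_frames.append(
                _sensor_hourly_direct(truth_series, met, row["slope"], row["intercept"], config, rng, sensor_id)
            )
    if config.time_resolution == "minute":
        minutes = pd.concat(minute_frames, ignore_index=True)
        hourly = aggregate_to_hours(minutes)
    else:
        minutes = None
        hourly = pd.concat(hourly_frames, ignore_index=True)

    ref_sites = sites.loc[sites["role"] == "reference-collocated", "site_id"].tolist()
    bam_frames, frm_frames = [], []
    for site in ref_sites:
        truth_site = true_pm[site]
        noisy = np.clip(
            truth_site.to_numpy() * (1 + rng.normal(0.0, config.bam_noise_fraction / 2, len(truth_site))), 0.0, None
        )
        bam_frames.append(pd.DataFrame({"site_id": site, "hour_start": truth_site.index, "pm25": noisy}))
        daily_truth = truth_site.resample("D").mean()
        frm = daily_truth * (1 + rng.normal(0.0, config.frm_noise_fraction, len(daily_truth)))
        frm_frames.append(pd.DataFrame({"site_id": site, "date": daily_truth.index, "pm25": np.clip(frm, 0, None)}))

    truth = TruthBundle(
        true_pm=true_pm,
        met=met,
        sites=sites,
        sensor_params=params[["slope", "intercept", "site_pre", "site_deployment", "site_post"]],
        ej_effect=config.ej_effect,
    )
    return Campaign(
        config=config,
        truth=truth,
        minutes=minutes,
        hourly=hourly,
        bam=pd.concat(bam_frames, ignore_index=True),
        frm=pd.concat(frm_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# emissions inventory


def simulate_ei_grid(
    truth: TruthBundle,
    cell_size_km: float = 4.0,
    distortion: float = 0.5,
    emission_scale: float = 0.15,  # tons/day per ug/m3 of increment
    seed: int | None = None,
) -> list[EmissionCell]:
    """Gridded weekday/weekend emissions consistent with the truth field.

    Each occupied cell's emissions are proportional to its deployment-mean
    concentration increment above the lowest cell (plus a 0.5 ug/m3 base
    so the background cell still emits), distorted by multiplicative
    log-normal noise with the given log-SD.  Zero distortion makes the
    increment-vs-inventory regression exact by construction.
    """
    rng = np.random.default_rng(seed)
    sites = truth.sites
    field = truth.true_pm
    cell_of = {
        str(r.site_id): (int(np.floor(r.x_km / cell_size_km)), int(np.floor(r.y_km / cell_size_km)))
        for r in sites.itertuples()
    }
    cells_members: dict[tuple[int, int], list[str]] = {}
    for site, key in cell_of.items():
        cells_members.setdefault(key, []).append(site)

    is_weekend = field.index.dayofweek >= 5
    out = []
    for (ix, iy), members in sorted(cells_members.items()):
        emis = {}
        for day_type, mask in (("weekday", ~is_weekend), ("weekend", is_weekend)):
            cell_mean = float(field.loc[mask, members].to_numpy().mean())
            emis[day_type] = cell_mean
        out.append(((ix, iy), members, emis))
    for day_type in ("weekday", "weekend"):
        floor = min(rec[2][day_type] for rec in out)
        for rec in out:
            inc = rec[2][day_type] - floor
            rec[2][day_type] = emission_scale * (inc + 0.5) * float(np.exp(rng.normal(0.0, distortion)))
    return [
        EmissionCell(
            cell_id=f"cell_{ix}_{iy}",
            bounds=(ix * cell_size_km, iy * cell_size_km, (ix + 1) * cell_size_km, (iy + 1) * cell_size_km),
            weekday_emissions=emis["weekday"],
            weekend_emissions=emis["weekend"],
            member_sites=tuple(members),
        )
        for (ix, iy), members, emis in out
    ]


# ---------------------------------------------------------------------------
# serialization


def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["periods"] = {
        k: [str(t[0]), str(t[1])] for k, t in (("pre", config.periods.pre), ("deployment", config.periods.deployment), ("post", config.periods.post))
    }
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "periods" in d and isinstance(d["periods"], dict):
        p = d["periods"]
        d["periods"] = StudyPeriods(
            pre=tuple(pd.Timestamp(t) for t in p["pre"]),
            deployment=tuple(pd.Timestamp(t) for t in p["deployment"]),
            post=tuple(pd.Timestamp(t) for t in p["post"]),
        )
    for key in ("sensor_slope_range", "sensor_intercept_range"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)


def write_campaign(campaign: Campaign, outdir) -> None:
    """Write the campaign as the package's CSV dialects plus a manifest."""
    from pathlib import Path

    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    if campaign.minutes is not None:
        campaign.minutes.to_csv(out / "sensor_minutes.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")
    campaign.hourly.to_csv(out / "sensor_hourly.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")
    campaign.truth.sites.drop(columns=["x_km", "y_km"]).to_csv(out / "sites.csv", index=False)
    met = campaign.truth.met.reset_index()
    met.to_csv(out / "met.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")
    campaign.bam.to_csv(out / "bam.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")
    campaign.frm.to_csv(out / "frm.csv", index=False, date_format="%Y-%m-%d")
    campaign.truth.true_pm.to_csv(out / "truth" / "true_pm.csv", date_format="%Y-%m-%dT%H:%M:%S")
    campaign.truth.sensor_params.to_csv(out / "truth" / "sensor_params.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(config_to_dict(campaign.config), fh, indent=2, default=str)
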