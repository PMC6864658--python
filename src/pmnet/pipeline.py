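"""End-to-end orchestration: simulate -> calibrate -> apply -> evaluate ->
spatial -> compare-ei, with a machine-readable manifest and summary.

Every threshold that the analysis introduces (completeness fractions,
minimum overlaps, the COD heterogeneity threshold, the network-mean
quorum) is surfaced in :class:`PipelineConfig` so the choices are
auditable, and the run manifest records them next to the seed.
Re-running with the same config and seed is bit-identical for all
CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import accuracy as _accuracy
from . import calibration as _cal
from . import core as _core
from . import emissions as _emis
from . import spatial as _spatial
from . import synth as _synth
from .core import InsufficientDataError, ValidationError

logger = logging.getLogger("pmnet")

ALL_STAGES = ("simulate", "calibrate", "apply", "evaluate", "spatial", "compare-ei")


@dataclass
class Thresholds:
    hourly_min_minutes: int = _core.HOURLY_MIN_MINUTES
    daily_min_hours: int = _core.DAILY_MIN_HOURS
    min_fit_hours: int = 24
    network_mean_fraction: float = 0.75
    cod_threshold: float = _spatial.COD_HETEROGENEITY_THRESHOLD
    min_overlap_hourly: int = _spatial.MIN_OVERLAP["hourly"]
    min_overlap_daily: int = _spatial.MIN_OVERLAP["daily"]

    def __post_init__(self):
        if not (0 < self.network_mean_fraction <= 1):
            raise ValidationError("network_mean_fraction must be in (0, 1]")
        if not (0 <= self.cod_threshold <= 1):
            raise ValidationError("cod_threshold must be in [0, 1]")


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    generator: _synth.GeneratorConfig | None = None
    campaign_dir: str | None = None  # load instead of simulating
    thresholds: Thresholds = field(default_factory=Thresholds)
    ei_distortion: float = 0.5

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            seed=raw.get("seed", 0),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            generator=_synth.config_from_dict(raw["generator"]) if "generator" in raw else None,
            campaign_dir=raw.get("campaign_dir"),
            thresholds=Thresholds(**raw.get("thresholds", {})),
            ei_distortion=raw.get("ei_distortion", 0.5),
        )
        if seed is not None:
            cfg.seed = seed
            if cfg.generator is not None:
                cfg.generator = _synth.config_from_dict({**_synth.config_to_dict(cfg.generator), "seed": seed})
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if self.campaign_dir is not None and not Path(self.campaign_dir).exists():
            raise ValidationError(f"campaign_dir does not exist: {self.campaign_dir}")
        if self.campaign_dir is None and "simulate" not in self.stages and set(self.stages) & set(ALL_STAGES[1:]):
            raise ValidationError("no campaign_dir given and 'simulate' not among the stages")


def _load_campaign(campaign_dir: str) -> dict:
    """Load the CSV outputs of a previous ``simulate`` stage."""
    d = Path(campaign_dir)
    for name in ("sensor_hourly.csv", "sites.csv", "met.csv", "bam.csv"):
        if not (d / name).exists():
            raise ValidationError(f"campaign_dir is missing {name}")
    hourly = pd.read_csv(d / "sensor_hourly.csv", parse_dates=["hour_start"])
    sites = _core.read_sites_csv(d / "sites.csv")
    met = pd.read_csv(d / "met.csv", parse_dates=["hour_start"])
    bam = pd.read_csv(d / "bam.csv", parse_dates=["hour_start"])
    frm_path = d / "frm.csv"
    frm = pd.read_csv(frm_path, parse_dates=["date"]) if frm_path.exists() else None
    params_path = d / "truth" / "sensor_params.csv"
    params = pd.read_csv(params_path).set_index("sensor_id") if params_path.exists() else None
    manifest = json.loads((d / "manifest.json").read_text()) if (d / "manifest.json").exists() else None
    return {"hourly": hourly, "sites": sites, "met": met, "bam": bam, "frm": frm, "params": params, "manifest": manifest}


def _phase_slice(df: pd.DataFrame, periods: _core.StudyPeriods, phase: str, time_col: str = "hour_start") -> pd.DataFrame:
    start, end = getattr(periods, phase)
    ts = df[time_col]
    return df[(ts >= start) & (ts < end)]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the requested stages in order and write their outputs.

    Returns the summary report (also written as ``summary.json``).
    Stage failures abort with a stage-attributed error; outputs of the
    stages already finished are retained.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    report: dict = {}
    stage = "init"
    try:
        # --- inputs -------------------------------------------------------
        if config.campaign_dir is not None:
            loaded = _load_campaign(config.campaign_dir)
            hourly, sites, met = loaded["hourly"], loaded["sites"], loaded["met"]
            bam, params = loaded["bam"], loaded["params"]
            gen = (
                _synth.config_from_dict(loaded["manifest"])
                if loaded["manifest"] is not None
                else _synth.GeneratorConfig(seed=config.seed)
            )
            campaign = None
        else:
            stage = "simulate"
            gen = config.generator or _synth.GeneratorConfig(seed=config.seed)
            campaign = _synth.simulate_campaign(gen)
            _synth.write_campaign(campaign, out / "campaign")
            hourly, sites = campaign.hourly, campaign.truth.sites
            met, bam, params = campaign.truth.met.reset_index(), campaign.bam, campaign.truth.sensor_params
            report["simulate"] = {
                "n_sensors": gen.n_sensors,
                "n_sites": gen.n_sites,
                "n_hourly_records": int(len(hourly)),
            }
        periods = gen.periods
        met_idx = met.set_index("hour_start")

        corrections = None
        corrected_wide = None
        site_series_hourly = None
        site_series_daily = None

        # --- calibrate ----------------------------------------------------
        if "calibrate" in config.stages:
            stage = "calibrate"
            wide_pre = _core.to_wide(_phase_slice(hourly, periods, "pre"))
            wide_post = _core.to_wide(_phase_slice(hourly, periods, "post"))
            min_sensors = int(np.ceil(th.network_mean_fraction * wide_pre.shape[1]))
            pre_fits = _cal.fit_period(wide_pre, "pre", min_sensors=min_sensors, min_hours=th.min_fit_hours)
            post_fits = _cal.fit_period(wide_post, "post", min_sensors=min_sensors, min_hours=th.min_fit_hours)
            corrections = _cal.corrections_table(pre_fits, post_fits)
            corrections.to_csv(out / "corrections.csv")
            precision = _cal.precision_summary({"pre": pre_fits, "post": post_fits}, wide_pre)
            drift = [
                _cal.drift_table(pre_fits[s], post_fits[s])
                for s in pre_fits
                if s in post_fits and pre_fits[s].valid and post_fits[s].valid
            ]
            precision["drift_fraction_below_10pct"] = _cal.drift_fraction_below(drift) if drift else None
            report["calibrate"] = precision

        # --- apply --------------------------------------------------------
        if "apply" in config.stages:
            stage = "apply"
            if corrections is None:
                raise ValidationError("'apply' requires the 'calibrate' stage")
            deploy = _core.to_wide(_phase_slice(hourly, periods, "deployment"))
            corrected = {}
            for sensor_id in deploy.columns:
                if sensor_id not in corrections.index:
                    logger.warning("QC: no correction for sensor %s; dropped", sensor_id)
                    continue
                row = corrections.loc[sensor_id]
                cf = _cal.CorrectionFactor(str(sensor_id), row["slope"], row["intercept"], row["source"])
                corrected[sensor_id] = _cal.apply_correction(deploy[sensor_id], cf)
            corrected_wide = pd.DataFrame(corrected)
            corrected_long = corrected_wide.stack().rename("pm25").reset_index()
            corrected_long.columns = ["hour_start", "sensor_id", "pm25"]
            corrected_long.to_csv(out / "corrected_hourly.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")
            report["apply"] = {"n_sensors": int(corrected_wide.shape[1])}

            # one representative sensor per site for the site-level series
            if params is not None:
                rep = params.reset_index().drop_duplicates("site_deployment").set_index("site_deployment")["sensor_id"]
                site_series_hourly = pd.DataFrame(
                    {site: corrected_wide[rep[site]] for site in rep.index if rep[site] in corrected_wide}
                )
                daily_long = _core.aggregate_to_days(
                    site_series_hourly.stack().rename("pm25").reset_index().rename(
                        columns={"level_0": "hour_start", "level_1": "sensor_id"}
                    ),
                    min_hours=th.daily_min_hours,
                )
                site_series_daily = _core.to_wide(daily_long, index="date")

        # --- evaluate -----------------------------------------------------
        if "evaluate" in config.stages:
            stage = "evaluate"
            if corrected_wide is None:
                raise ValidationError("'evaluate' requires the 'apply' stage")
            ref_sites = sites.loc[sites["role"] == "reference-collocated", "site_id"].tolist()
            ref_site = ref_sites[0]
            bam_series = bam[bam["site_id"] == ref_site].set_index("hour_start")["pm25"]
            rep_sensor = params[params["site_deployment"] == ref_site].index[0]
            sensor_series = corrected_wide[rep_sensor]
            table = _accuracy.accuracy_table(sensor_series, bam_series, met_idx)
            table.to_csv(out / "accuracy_table.csv")
            ranking = _accuracy.rank_single_covariates(sensor_series, bam_series, met_idx)
            ranking.to_csv(out / "covariate_ranking.csv", index=False)
            scatter = _accuracy.compare_to_reference(sensor_series, bam_series, met_idx)
            report["evaluate"] = {
                "reference_site": ref_site,
                "r2_vs_reference": scatter.r2,
                "mean_bias": scatter.mean_bias,
                "best_single_covariate": str(ranking.iloc[0]["covariate"]),
            }

        # --- spatial ------------------------------------------------------
        if "spatial" in config.stages:
            stage = "spatial"
            if site_series_hourly is None:
                raise ValidationError("'spatial' requires the 'apply' stage")
            spatial_report = {}
            for stat in ("cod", "r2"):
                for resolution, series in (("hourly", site_series_hourly), ("daily", site_series_daily)):
                    min_overlap = th.min_overlap_hourly if resolution == "hourly" else th.min_overlap_daily
                    matrix = _spatial.pairwise_matrix(series, stat=stat, resolution=resolution, min_overlap=min_overlap)
                    matrix.values.to_csv(out / f"pairwise_{stat}_{resolution}.csv")
                    spatial_report[f"{stat}_{resolution}"] = _spatial.summarize_matrix(matrix)
                    if stat == "cod":
                        _, frac = _spatial.classify_homogeneity(matrix, threshold=th.cod_threshold)
                        spatial_report[f"heterogeneous_fraction_{resolution}"] = frac
            site_sub = sites[sites["site_id"].isin(site_series_hourly.columns)].reset_index(drop=True)
            dist = _spatial.distance_matrix(site_sub).loc[site_series_hourly.columns, site_series_hourly.columns]
            cod_hourly = _spatial.pairwise_matrix(site_series_hourly, "cod", "hourly", th.min_overlap_hourly)
            spatial_report["cod_distance_decay"] = _spatial.distance_decay(cod_hourly, dist)
            ej_sites = [s for s in site_series_hourly.columns if sites.set_index("site_id").loc[s, "ej_flag"]]
            nonej_sites = [s for s in site_series_hourly.columns if s not in ej_sites]
            series_map = {s: site_series_hourly[s] for s in site_series_hourly.columns}
            welch = _spatial.group_test(series_map, ej_sites, nonej_sites, "welch_t")
            spatial_report["welch_ej_vs_nonej"] = {
                "t": welch.statistic,
                "p_value": welch.p_value,
                "mean_difference": welch.mean_difference,
            }
            site_means = site_series_hourly.mean()
            weights = _spatial.spatial_weights(site_sub).loc[site_means.index, site_means.index]
            moran = _spatial.morans_i(site_means.to_numpy(), weights, seed=config.seed)
            spatial_report["morans_i"] = {"I": moran["I"], "p_value": moran["p_value"]}
            report["spatial"] = spatial_report

        # --- compare-ei ---------------------------------------------------
        if "compare-ei" in config.stages:
            stage = "compare-ei"
            if site_series_hourly is None:
                raise ValidationError("'compare-ei' requires the 'apply' stage")
            if campaign is None:
                raise ValidationError("'compare-ei' needs a simulated campaign (EI grid)")
            cells = _synth.simulate_ei_grid(campaign.truth, distortion=config.ei_distortion, seed=config.seed)
            _emis.write_ei_csv(cells, out / "ei_cells.csv")
            cells = [c for c in cells if all(s in site_series_hourly.columns for s in c.member_sites)]
            ei_report = {}
            for day_type in ("weekday", "weekend"):
                inc = _emis.cell_average(site_series_hourly, cells, day_type=day_type)
                summary = _emis.regress_increment_vs_ei(inc, cells)
                inc.to_csv(out / f"increments_{day_type}.csv")
                ei_report[day_type] = {
                    "r2": summary["r2"],
                    "slope": summary["slope"],
                    "n_cells": summary["n_cells"],
                    "largest_residual_cells": summary["largest_residual_cells"],
                }
            report["compare_ei"] = ei_report
    except (ValidationError, InsufficientDataError) as err:
        raise type(err)(f"stage '{stage}': {err}") from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "thresholds": asdict(config.thresholds),
        "generator": _synth.config_to_dict(gen) if config.campaign_dir is None else None,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str, sort_keys=True)
    return report
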