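"""End-to-end orchestration: simulate/load → covariates → CV → final model → anomaly test.

The run mirrors the analysis workflow: anomalous-period rows are split off
first and never touch calibration; the remaining rows are cross-validated
under both the 30- and the 120-day accumulation window; the window with
the higher mean test AUC wins (overridable); a final model is then
selected on all normal-period rows with the chosen window; classification
thresholds are derived from that final model's calibration predictions;
and the anomaly rows are scored and classified at each threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariates import CovariateConfig, build_covariate_table, filter_records
from .glm import enumerate_candidates
from .io import read_climate, read_observations, write_json, write_table
from .phenocurve import fit_phenocurve
from .simulate import ClimateSimConfig, TrueModelConfig, simulate_climate, simulate_observations
from .validation import (
    CVConfig,
    cv_table,
    derive_thresholds,
    evaluate_anomaly,
    fit_on_training,
    predict_rows,
    run_repeated_cv,
)

logger = logging.getLogger("phenoclim")

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a run needs; round-trips through YAML/JSON unchanged."""

    mode: str = "simulate"  # "simulate" or "files"
    climate_path: str | None = None
    observations_path: str | None = None
    climate_sim: ClimateSimConfig = field(default_factory=ClimateSimConfig)
    truth: TrueModelConfig = field(default_factory=TrueModelConfig)
    n_obs: int = 3000
    windows: tuple = (30, 120)
    base_temp: float = 5.0
    gdd_floor: str = "per_day"
    criterion: str = "aicc"
    final_criterion: str = "aic"
    n_reps: int = 10
    train_frac: float = 0.75
    window_override: int | None = None
    seed: int = 0
    output_dir: str = "phenoclim_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("climate_sim"), dict):
            cs = {k: tuple(v) if isinstance(v, list) else v for k, v in d["climate_sim"].items()}
            d["climate_sim"] = ClimateSimConfig(**cs)
        if isinstance(d.get("truth"), dict):
            t = {k: tuple(v) if isinstance(v, list) else v for k, v in d["truth"].items()}
            d["truth"] = TrueModelConfig(**t)
        if isinstance(d.get("windows"), list):
            d["windows"] = tuple(d["windows"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunReport:
    """Every number here is recomputable from config + seed."""

    config: dict
    config_hash: str
    seed: int
    version: str
    counts: dict
    cv_summaries: dict
    chosen_window: int
    final_model: dict
    selection_table: list
    thresholds: dict
    anomaly_metrics: dict
    phenocurve: dict
    timings: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_markdown(self) -> str:
        lines = [
            "# Phenoclimatic analysis run report",
            f"- package version: {self.version}; seed: {self.seed}; config hash: {self.config_hash}",
            f"- records: {self.counts}",
            f"- chosen accumulation window: {self.chosen_window} days",
            "",
            "## Cross-validation (per window)",
        ]
        for w, s in self.cv_summaries.items():
            lines.append(
                f"- {w}-day: mean AUC train {s['mean_auc_train']:.3f}, "
                f"test {s['mean_auc_test']:.3f}; modal model: {s['modal_spec']} "
                f"({s['modal_count']}/{s['n_ok']})"
            )
        lines += ["", "## Final model coefficients (estimate ± SE)"]
        fm = self.final_model
        for t, e, s, sig in zip(fm["names"], fm["params"], fm["bse"], fm["stars"]):
            lines.append(f"| {t} | {e:.2f} ± {s:.2f}{sig} |")
        lines.append(
            f"\nΔ{self.config.get('final_criterion', 'aic').upper()} (vs second-best) = "
            f"{fm['delta_ic_second_best']:.2f}; "
            f"McFadden R² = {fm['pseudo_r2_mcfadden']:.2f}; "
            f"Nagelkerke R² = {fm['pseudo_r2_nagelkerke']:.2f}"
        )
        lines += ["", "## Anomalous-period prediction",
                  "| threshold | cutoff | n | overall accuracy % | commission % | omission % |",
                  "|---|---|---|---|---|---|"]
        for name, m in self.anomaly_metrics.items():
            lines.append(
                f"| {name} | {self.thresholds[name]:.4f} | {m['n']} | "
                f"{m['overall_accuracy']:.1f} | {m['commission_rate']:.1f} | "
                f"{m['omission_rate']:.1f} |"
            )
        return "\n".join(lines)


def _stage(timings, name, t0):
    dt = time.perf_counter() - t0
    timings[name] = round(dt, 3)
    logger.info("stage %s finished in %.2fs", name, dt)
    return time.perf_counter()


def run_pipeline(config: RunConfig, write_artifacts: bool = True) -> RunReport:
    """Execute the full analysis; deterministic given ``config.seed``."""
    timings: dict = {}
    t0 = time.perf_counter()
    outdir = Path(config.output_dir)

    # --- load or simulate ---------------------------------------------------
    if config.mode == "simulate":
        climate = simulate_climate(
            dataclasses.replace(config.climate_sim, seed=config.seed)
        )
        records = simulate_observations(
            climate, config.truth, n_obs=config.n_obs, seed=config.seed + 1
        )
    elif config.mode == "files":
        climate = read_climate(config.climate_path)
        records = read_observations(config.observations_path)
        if "period" not in records.columns:
            a0, a1 = pd.Timestamp(config.truth.anomaly_interval[0]), pd.Timestamp(
                config.truth.anomaly_interval[1]
            )
            d = pd.to_datetime(records["date"])
            records["period"] = np.where((d >= a0) & (d <= a1), "anomalous", "normal")
    else:
        raise ValueError("mode must be 'simulate' or 'files'")
    counts = {"n_records": int(len(records))}
    t = _stage(timings, "load", t0)

    # --- filtering + covariates per window ----------------------------------
    candidates = enumerate_candidates()
    cov_by_window, filter_logs = {}, {}
    for w in config.windows:
        cfg = CovariateConfig(base_temp=config.base_temp, window_days=w, gdd_floor=config.gdd_floor)
        kept, log = filter_records(records, climate, cfg)
        cov = build_covariate_table(kept, climate, cfg)
        cov_by_window[w] = cov
        filter_logs[w] = log
        logger.info("window %d: %s", w, log)
    counts["filter_logs"] = filter_logs
    counts["n_normal"] = {int(w): int((c["period"] == "normal").sum()) for w, c in cov_by_window.items()}
    counts["n_anomalous"] = {int(w): int((c["period"] == "anomalous").sum()) for w, c in cov_by_window.items()}
    t = _stage(timings, "covariates", t)

    # --- seasonal curve on normal-period rows (larger window's table) -------
    wmax = max(config.windows)
    normal_max = cov_by_window[wmax][cov_by_window[wmax]["period"] == "normal"]
    curve = fit_phenocurve(normal_max["day_of_year"].to_numpy(), normal_max["y"].to_numpy())
    curve_info = {
        "lambda": curve.lambda_, "edf": curve.edf, "peak_day": curve.peak_day,
        "peak_probability": float(curve.predict([curve.peak_day])[0]),
    }
    t = _stage(timings, "phenocurve", t)

    # --- repeated CV per window ---------------------------------------------
    cv_summaries, cv_tables = {}, {}
    for w in config.windows:
        normal = cov_by_window[w][cov_by_window[w]["period"] == "normal"].reset_index(drop=True)
        reps, summary = run_repeated_cv(
            normal, candidates,
            CVConfig(config.n_reps, config.train_frac, config.criterion, config.seed + 100 + w),
        )
        cv_summaries[int(w)] = summary
        cv_tables[int(w)] = cv_table(reps)
    t = _stage(timings, "cross_validation", t)

    # --- window choice -------------------------------------------------------
    if config.window_override is not None:
        chosen = int(config.window_override)
    else:
        chosen = int(max(cv_summaries, key=lambda w: cv_summaries[w]["mean_auc_test"]))
    logger.info("chosen accumulation window: %d days", chosen)

    # --- final model on all normal-period rows -------------------------------
    normal = cov_by_window[chosen][cov_by_window[chosen]["period"] == "normal"].reset_index(drop=True)
    anomaly = cov_by_window[chosen][cov_by_window[chosen]["period"] == "anomalous"].reset_index(drop=True)
    sel, scaler, poly = fit_on_training(normal, candidates, config.final_criterion)
    res = sel.best_results
    ic_col = sel.criterion
    deltas = sel.table[f"delta_{ic_col}"].to_numpy()
    delta_second = float(deltas[1]) if len(deltas) > 1 else float("nan")
    stars = ["**" if p < 0.01 else "*" if p < 0.05 else "" for p in res.pvalues]
    final_model = {
        "spec": sel.best_spec.to_dict(),
        "names": res.model.names,
        "params": res.params.tolist(),
        "bse": res.bse.tolist(),
        "stars": stars,
        "n": int(res.nobs),
        "llf": res.llf,
        "aic": res.aic,
        "aicc": res.aicc,
        "delta_ic_second_best": delta_second,
        "pseudo_r2_mcfadden": res.prsquared_mcfadden,
        "pseudo_r2_nagelkerke": res.prsquared_nagelkerke,
        "scaler": scaler.to_dict(),
        "poly_basis": poly.to_dict(),
    }
    t = _stage(timings, "final_model", t)

    # --- thresholds from calibration, applied to the anomaly ------------------
    p_cal = predict_rows(normal, res, sel.best_spec, scaler, poly)
    thresholds = derive_thresholds(p_cal, normal["y"].to_numpy())
    if len(anomaly):
        metrics = evaluate_anomaly(anomaly, res, sel.best_spec, scaler, poly, thresholds)
        anomaly_metrics = {k: m.as_dict() for k, m in metrics.items()}
    else:
        anomaly_metrics = {}
        logger.warning("no anomalous-period rows; anomaly test skipped")
    _stage(timings, "anomaly_test", t)
    timings["total"] = round(time.perf_counter() - t0, 3)

    report = RunReport(
        config=config.to_dict(),
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        counts=counts,
        cv_summaries=cv_summaries,
        chosen_window=chosen,
        final_model=final_model,
        selection_table=sel.table.to_dict(orient="records"),
        thresholds=thresholds.as_dict(),
        anomaly_metrics=anomaly_metrics,
        phenocurve=curve_info,
        timings=timings,
    )

    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
        if config.mode == "simulate":
            write_table(climate, outdir / "climate.csv")
        write_table(records, outdir / "observations.csv")
        for w in config.windows:
            write_table(cov_by_window[w], outdir / f"covariates_{w}d.csv")
            write_table(cv_tables[int(w)], outdir / f"cv_replicates_{w}d.csv")
        write_json(counts["filter_logs"], outdir / "filter_log.json")
        write_json(final_model, outdir / "final_model.json")
        res.coefficient_table().to_csv(outdir / "coefficients.csv", index=False)
        write_json(thresholds.as_dict(), outdir / "thresholds.json")
        if anomaly_metrics:
            rows = [
                {"threshold": k, "cutoff": report.thresholds[k], **m}
                for k, m in anomaly_metrics.items()
            ]
            write_table(pd.DataFrame(rows), outdir / "anomaly_report.csv")
        write_json(report.to_dict(), outdir / "report.json")
        (outdir / "report.md").write_text(report.to_markdown())
    return report
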