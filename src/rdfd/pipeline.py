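"""End-to-end pipeline: ingest -> trim -> window -> fatigue degrees ->
slope classification -> correction-factor calibration -> revision ->
trend fits and breakpoints -> curve-agreement report.

The pipeline is configuration-driven and deterministic: every output file
embeds the configuration hash and seed, and reruns with an identical
configuration are byte-identical.  Nothing is silently imputed -- windows
dropped for low beat count or excluded from calibration are enumerated in
the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .correction import (
    classify_slope,
    curve_agreement,
    calibrate_delta,
    pointwise_delta,
    revise_dfd,
    slope_class_at,
)
from .fatigue import (
    DFDSeries,
    blink_dfd,
    compute_baselines,
    compute_fatigue_metrics,
    fit_trend,
    summarize_selection,
    select_window_length,
    window_hrv,
)
from .ingest import blink_frequency, clean_rr, trim_excitement
from .trend import detect_breakpoints

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "compare_report"]

logger = logging.getLogger("rdfd")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run.

    Input paths: either ``rr`` + (``static_rr`` or ``rrvc_static``) for the
    HRV side and either ``blinks`` + ``bf_static`` or a precomputed
    ``blink_dfd`` CSV for the reference side.  A precomputed ``hrv_dfd``
    CSV may replace the HRV ingest path entirely.
    """

    # inputs
    rr: str | None = None
    static_rr: str | None = None
    rrvc_static: float | None = None
    hrv_dfd: str | None = None
    blinks: str | None = None
    bf_static: float | None = None
    blink_dfd: str | None = None
    altitude: str | None = None
    model: str | None = None  # pre-fitted correction model JSON
    # parameters
    window_length: float = 120.0
    trim_s: float = 1000.0
    min_beats: int = 10
    k_initial: int = 1
    selection_rule: str = "default"
    run_selection: bool = False
    calibrate: bool = True
    epsilon_baseline: float = 1e-6
    epsilon_dfd: float = 0.05
    degree: int = 3
    flat_threshold: float = 0.5 / 120.0
    min_segment_s: float = 300.0
    clean_bounds_ms: tuple = (300.0, 2000.0)
    jump_fraction: float = 0.2
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.clean_bounds_ms, list):
            cfg.clean_bounds_ms = tuple(cfg.clean_bounds_ms)
        return cfg

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        logger.info("stage %s: %.3f s", name, time.perf_counter() - t0)
        return result

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full revision pipeline and return the report dict.

    When ``config.out_dir`` is set, also writes ``dfd.csv``,
    ``blink_dfd.csv``, ``rdfd.csv``, ``model.json`` and ``report.json``,
    each stamped with the config hash and seed.
    """
    meta = {"config_hash": config.digest(), "seed": config.seed}
    report: dict = {"config": dataclasses.asdict(config), **meta, "stages": {}}

    # --- HRV fatigue degree -------------------------------------------------
    dropped: dict = {}
    if config.hrv_dfd is not None:
        hrv_series = _stage("load-hrv-dfd")(rio.read_dfd_csv, config.hrv_dfd)
        hrv_frame = None
        baselines_kwargs = {}
    elif config.rr is not None:
        rr = _stage("ingest-rr")(rio.read_rr_csv, config.rr)
        rr, n_removed = _stage("clean-rr")(
            clean_rr, rr, config.clean_bounds_ms, config.jump_fraction
        )
        dropped["artifact_intervals"] = n_removed
        rr = _stage("trim")(trim_excitement, rr, config.trim_s, config.trim_s)
        windows = _stage("window-hrv")(
            window_hrv, rr, config.window_length, config.min_beats
        )
        if config.rrvc_static is not None:
            rrvc_static = float(config.rrvc_static)
        elif config.static_rr is not None:
            static = _stage("ingest-static-rr")(rio.read_rr_csv, config.static_rr)
            from .fatigue import aggregate_rrvc

            rrvc_static = aggregate_rrvc(static)[2]
        else:
            raise PipelineError(
                "stage 'baselines' failed: static_rr or rrvc_static required"
            )
        baselines_kwargs = {"rrvc_static": rrvc_static}
        if config.run_selection:
            chosen, table = _stage("window-selection")(
                select_window_length, rr, rrvc_static,
                rule=config.selection_rule, k=config.k_initial,
                min_beats=config.min_beats,
            )
            report["stages"]["window_selection"] = {
                "chosen_s": chosen,
                "table": table.to_dict(orient="list"),
                **summarize_selection(table),
            }
        baselines = _stage("baselines")(
            compute_baselines, None, windows, config.k_initial,
            rrvc_static=rrvc_static, epsilon=config.epsilon_baseline,
        )
        _, hrv_series = _stage("fatigue-metrics")(
            compute_fatigue_metrics, windows, baselines
        )
        from .fatigue import windows_to_frame

        hrv_frame = windows_to_frame(windows)
    else:
        raise PipelineError("stage 'ingest' failed: missing input rr or hrv_dfd")

    # --- blink fatigue degree ----------------------------------------------
    blink_series = None
    if config.blink_dfd is not None:
        blink_series = _stage("load-blink-dfd")(rio.read_dfd_csv, config.blink_dfd)
    elif config.blinks is not None:
        if config.bf_static is None:
            raise PipelineError("stage 'blink-dfd' failed: bf_static required")
        blinks = _stage("ingest-blinks")(rio.read_blink_csv, config.blinks)
        starts = hrv_series.times - hrv_series.window_length / 2.0
        wins = np.column_stack([starts, starts + hrv_series.window_length])
        rates = _stage("blink-frequency")(blink_frequency, blinks, wins)
        bf_initial = float(np.mean(rates[: config.k_initial]))
        from .fatigue import FatigueBaselines

        blink_base = FatigueBaselines(
            rrvc_static=0.0, rrvc_initial=1.0,  # HRV slots unused here
            bf_static=config.bf_static, bf_initial=bf_initial,
            epsilon=config.epsilon_baseline,
        )
        blink_series = _stage("blink-dfd")(
            blink_dfd, hrv_series.times, rates, blink_base,
            hrv_series.window_length,
        )

    # --- altitude, slope, calibration, revision -----------------------------
    models = None
    rdfd_series = None
    segments = None
    if config.altitude is not None:
        profile = _stage("ingest-altitude")(rio.read_altitude_csv, config.altitude)
        h_windows = profile.at(hrv_series.times)
        segments = _stage("classify-slope")(
            classify_slope, profile, config.flat_threshold,
            min_duration_s=config.min_segment_s,
        )
        classes = slope_class_at(segments, hrv_series.times)
        if config.model is not None:
            models = _stage("load-model")(rio.read_model_json, config.model)
        elif config.calibrate and blink_series is not None:
            models = {}
            calib_report = {}
            for cls_name in ("up", "down", "flat"):
                mask = classes == cls_name
                if mask.sum() == 0:
                    continue
                sub_hrv = DFDSeries(times=hrv_series.times[mask],
                                    values=hrv_series.values[mask],
                                    source="hrv",
                                    window_length=hrv_series.window_length)
                try:
                    pairs = pointwise_delta(blink_series, sub_hrv,
                                            profile.at(sub_hrv.times),
                                            epsilon=config.epsilon_dfd)
                    models[cls_name] = calibrate_delta(pairs, slope_class=cls_name,
                                                       degree=config.degree)
                    calib_report[cls_name] = {
                        "n_pairs": len(pairs),
                        "n_excluded": pairs.n_excluded,
                        "coefficients": [float(c) for c in models[cls_name].coef_],
                    }
                except ValueError as exc:
                    calib_report[cls_name] = {"skipped": str(exc)}
            report["stages"]["calibration"] = calib_report
            if not models:
                raise PipelineError(
                    "stage 'calibrate' failed: no slope class had enough "
                    "calibration support"
                )
        if models is not None:
            rdfd_series = _stage("revise")(
                revise_dfd, hrv_series, models, h_windows, classes
            )
    elif config.model is not None or (config.calibrate and blink_series is not None):
        raise PipelineError(
            "stage 'calibrate' failed: missing input: altitude profile required"
        )

    # --- trends, breakpoints, agreement ------------------------------------
    trends = {}
    for label, series in (("hrv", hrv_series), ("blink", blink_series),
                          ("revised", rdfd_series)):
        if series is None or len(series) < 5:
            continue
        model = _stage(f"trend-{label}")(fit_trend, series, config.degree)
        trends[label] = {
            "coefficients": [float(c) for c in model.coef_],
            "f_statistic": rio._jsonable(model.f_statistic_),
            "f_pvalue": rio._jsonable(model.f_pvalue_),
            "residual_ss": rio._jsonable(model.residual_ss_),
            "inflection_time_s": detect_breakpoints(model),
        }
    report["stages"]["trends"] = trends

    agreements = []
    if blink_series is not None:
        agreements.append(("hrv_vs_blink", curve_agreement(hrv_series, blink_series)))
        if rdfd_series is not None:
            agreements.append(
                ("revised_vs_blink", curve_agreement(rdfd_series, blink_series))
            )
        report["stages"]["agreement"] = {
            label: dataclasses.asdict(ca) for label, ca in agreements
        }

    report["dropped"] = dropped
    if segments is not None:
        report["stages"]["slope_segments"] = [
            dataclasses.asdict(s) for s in segments
        ]

    # --- outputs ------------------------------------------------------------
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if hrv_frame is not None:
            rio.write_table(hrv_frame, out / "hrv_windows.csv", meta)
        rio.write_dfd_csv(hrv_series, out / "dfd.csv", meta)
        if blink_series is not None:
            rio.write_dfd_csv(blink_series, out / "blink_dfd.csv", meta)
        if rdfd_series is not None:
            rio.write_dfd_csv(rdfd_series, out / "rdfd.csv", meta)
        if models is not None:
            rio.write_model_json(models, out / "model.json", meta)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
    return report


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float):
        return x
    return str(x)


def compare_report(pairs) -> str:
    """Format labeled curve-agreement statistics as an aligned text table."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no agreement pairs to report")
    header = f"{'comparison':<24}{'SS':>14}{'F':>12}{'sig. F':>12}{'R^2':>10}"
    lines = [header, "-" * len(header)]
    for label, ca in pairs:
        lines.append(
            f"{label:<24}{ca.ss_diff:>14.3f}{ca.f_statistic:>12.3f}"
            f"{ca.f_pvalue:>12.5f}{ca.r_squared:>10.3f}"
        )
    return "\n".join(lines)
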