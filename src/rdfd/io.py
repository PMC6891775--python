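"""CSV / JSON readers and writers for the pipeline's file formats.

All CSVs are headered, full double precision, and may carry ``#``-prefixed
metadata lines (config hash, seed) before the header; readers skip them.

Formats:
    R-R:       time_s, rr_ms
    ECG:       time_s, mv           (sampling rate from a flag or inferred)
    blinks:    blink_time_s
    altitude:  time_s, altitude_m
    DFD:       t_mid_s, value [, source, window_length_s]
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .correction import AltitudeCorrection
from .fatigue import DFDSeries
from .ingest import AltitudeProfile, BlinkSeries, ECGTrace, RRISeries

__all__ = [
    "read_rr_csv", "write_rr_csv",
    "read_ecg_csv",
    "read_blink_csv", "write_blink_csv",
    "read_altitude_csv", "write_altitude_csv",
    "read_dfd_csv", "write_dfd_csv",
    "read_model_json", "write_model_json",
    "write_table",
]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_rr_csv(path) -> RRISeries:
    df = _read_table(path)
    return RRISeries(times=df["time_s"].to_numpy(), intervals=df["rr_ms"].to_numpy())


def write_rr_csv(rr: RRISeries, path, metadata=None) -> None:
    write_table(pd.DataFrame({"time_s": rr.times, "rr_ms": rr.intervals}),
                path, metadata)


def read_ecg_csv(path, sampling_rate: float | None = None) -> ECGTrace:
    df = _read_table(path)
    t = df["time_s"].to_numpy()
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    return ECGTrace(sampling_rate=sampling_rate, samples=df["mv"].to_numpy(),
                    start_time=float(t[0]))


def read_blink_csv(path) -> BlinkSeries:
    df = _read_table(path)
    return BlinkSeries(times=df["blink_time_s"].to_numpy())


def write_blink_csv(blinks: BlinkSeries, path, metadata=None) -> None:
    write_table(pd.DataFrame({"blink_time_s": blinks.times}), path, metadata)


def read_altitude_csv(path) -> AltitudeProfile:
    df = _read_table(path)
    return AltitudeProfile(times=df["time_s"].to_numpy(),
                           altitudes=df["altitude_m"].to_numpy())


def write_altitude_csv(profile: AltitudeProfile, path, metadata=None) -> None:
    write_table(
        pd.DataFrame({"time_s": profile.times, "altitude_m": profile.altitudes}),
        path, metadata,
    )


def read_dfd_csv(path) -> DFDSeries:
    df = _read_table(path)
    source = str(df["source"].iloc[0]) if "source" in df else "hrv"
    wl = float(df["window_length_s"].iloc[0]) if "window_length_s" in df else 120.0
    return DFDSeries(times=df["t_mid_s"].to_numpy(), values=df["value"].to_numpy(),
                     source=source, window_length=wl)


def write_dfd_csv(series: DFDSeries, path, metadata=None) -> None:
    df = pd.DataFrame(
        {
            "t_mid_s": series.times,
            "value": series.values,
            "source": series.source,
            "window_length_s": series.window_length,
        }
    )
    write_table(df, path, metadata)


def write_model_json(models: dict[str, AltitudeCorrection], path,
                     metadata: dict | None = None) -> None:
    """Serialize per-slope-class correction models (coefficients at full
    precision, calibration range, fit diagnostics)."""
    payload = {"metadata": metadata or {}, "models": {}}
    for name, m in models.items():
        payload["models"][name] = {
            "slope_class": m.slope_class,
            "coefficients": [float(c) for c in m.coef_],
            "h_range": list(m.h_range_) if m.h_range_ is not None else None,
            "n": int(getattr(m, "n_", 0)),
            "residual_ss": _jsonable(getattr(m, "residual_ss_", None)),
            "f_statistic": _jsonable(getattr(m, "f_statistic_", None)),
            "f_pvalue": _jsonable(getattr(m, "f_pvalue_", None)),
            "r_squared": _jsonable(getattr(m, "r_squared_", None)),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_json(path) -> dict[str, AltitudeCorrection]:
    with open(path) as fh:
        payload = json.load(fh)
    models = {}
    for name, spec in payload["models"].items():
        models[name] = AltitudeCorrection.from_coefficients(
            spec["coefficients"], h_range=spec["h_range"],
            slope_class=spec["slope_class"],
        )
    return models


def _jsonable(x):
    if x is None:
        return None
    x = float(x)
    if np.isnan(x):
        return None
    if np.isinf(x):
        return "inf" if x > 0 else "-inf"
    return x
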