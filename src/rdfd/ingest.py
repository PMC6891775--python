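"""Ingestion of physiological recordings: ECG, R-R intervals, blinks, altitude.

The fatigue statistic downstream consumes beat-to-beat R-R intervals; this
module turns raw recordings into clean, trimmed, windowable series.  Field
devices (heart-rate belts, wristbands) usually emit R-R intervals directly,
so the primary ingest path is an interval series; full ECG waveforms are
supported through a Pan-Tompkins-style QRS detector.

Time convention: seconds from recording start, half-open windows
``[start, end)`` everywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "ECGTrace",
    "RRISeries",
    "BlinkSeries",
    "AltitudeProfile",
    "detect_r_peaks",
    "rr_from_peaks",
    "clean_rr",
    "trim_excitement",
    "blink_frequency",
]


def _as_float_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    return np.atleast_1d(a)


@dataclass(frozen=True)
class ECGTrace:
    """A single-lead ECG waveform.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz), > 0.
    samples : array of float
        Amplitudes in mV; all finite, at least two samples.
    start_time : float
        Time of the first sample, seconds.
    """

    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_float_array(self.samples))
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if self.samples.size < 2:
            raise ValueError("ECG trace needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sampling_rate


@dataclass(frozen=True)
class RRISeries:
    """Beat-to-beat R-R intervals.

    ``times[k]`` is the time (s) of the beat that *ends* interval ``k``;
    ``intervals[k]`` is that interval's length in ms.  Constructed from a
    peak train the two are consistent (``intervals = diff(peaks) * 1000``);
    after artifact removal the times remain the original beat times while
    the interval list becomes a subsequence.
    """

    times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", _as_float_array(self.times))
        object.__setattr__(self, "intervals", _as_float_array(self.intervals))
        if self.times.size != self.intervals.size:
            raise ValueError("times and intervals must have equal length")
        if self.times.size == 0:
            raise ValueError("empty R-R series")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.intervals <= 0) or not np.all(np.isfinite(self.intervals)):
            raise ValueError("intervals must be positive and finite")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BlinkSeries:
    """Blink event timestamps in seconds, nondecreasing (simultaneous
    events are allowed)."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).reshape(-1)
        object.__setattr__(self, "times", t)
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("blink times must be nondecreasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class AltitudeProfile:
    """Road altitude (m) sampled along the drive, indexed by time (s)."""

    times: np.ndarray
    altitudes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", _as_float_array(self.times))
        object.__setattr__(self, "altitudes", _as_float_array(self.altitudes))
        if self.times.size != self.altitudes.size:
            raise ValueError("times and altitudes must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("profile times must be strictly increasing")
        if np.any(self.altitudes < 0) or np.any(self.altitudes > 9000):
            raise ValueError("altitudes must lie within [0, 9000] m")

    def at(self, t) -> np.ndarray:
        """Linearly interpolated altitude at time(s) ``t``."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.altitudes)


# ---------------------------------------------------------------------------
# QRS detection

def detect_r_peaks(
    ecg: ECGTrace,
    min_rr_s: float = 0.3,
    band_hz: tuple[float, float] = (5.0, 15.0),
    integration_s: float = 0.15,
    threshold_frac: float = 0.3,
) -> np.ndarray:
    """Detect R-peak times with a Pan-Tompkins-style pipeline.

    Band-pass (default 5-15 Hz) -> derivative -> squaring -> moving-window
    integration -> adaptive threshold, then each candidate is refined to the
    local maximum of the band-passed signal.  A refractory period
    ``min_rr_s`` suppresses double detections.

    Returns strictly increasing peak times in seconds.
    """
    fs = ecg.sampling_rate
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz for QRS detection")
    if ecg.duration < 2 * min_rr_s:
        raise ValueError("insufficient signal: trace shorter than two beats")
    x = ecg.samples - np.mean(ecg.samples)

    sos = sps.butter(3, band_hz, btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    energy = np.gradient(filtered) ** 2
    win = max(1, int(round(integration_s * fs)))
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")

    scale = np.percentile(integrated, 99)
    if scale <= 0:
        raise ValueError("no QRS detected")
    threshold = threshold_frac * scale
    cand, _ = sps.find_peaks(
        integrated, height=threshold, distance=max(1, int(min_rr_s * fs))
    )
    if cand.size == 0:
        raise ValueError("no QRS detected")

    # refine each candidate to the local max of the band-passed signal
    half = int(round(0.1 * fs))
    peaks: list[int] = []
    for c in cand:
        lo, hi = max(0, c - half), min(filtered.size, c + half + 1)
        idx = lo + int(np.argmax(filtered[lo:hi]))
        if peaks and idx - peaks[-1] < min_rr_s * fs:
            if filtered[idx] > filtered[peaks[-1]]:
                peaks[-1] = idx
            continue
        if not peaks or idx > peaks[-1]:
            peaks.append(idx)
    if not peaks:
        raise ValueError("no QRS detected")
    return ecg.start_time + np.asarray(peaks, dtype=float) / fs


def rr_from_peaks(peaks) -> RRISeries:
    """R-R intervals (ms) from a strictly increasing train of peak times (s)."""
    p = _as_float_array(peaks)
    if p.size < 2:
        raise ValueError("need at least 2 peaks to form intervals")
    if np.any(np.diff(p) <= 0):
        raise ValueError("peak times must be strictly increasing")
    return RRISeries(times=p[1:], intervals=np.diff(p) * 1000.0)


def clean_rr(
    rr: RRISeries,
    bounds_ms: tuple[float, float] = (300.0, 2000.0),
    jump_fraction: float = 0.2,
) -> tuple[RRISeries, int]:
    """Remove artifact intervals.

    An interval is dropped when it falls outside ``bounds_ms`` or differs
    from the previous *retained* interval by more than ``jump_fraction`` of
    that interval (ectopic-beat guard).  Returns the cleaned series and the
    number of intervals removed.
    """
    lo, hi = bounds_ms
    keep = np.zeros(len(rr), dtype=bool)
    prev = None
    for k, iv in enumerate(rr.intervals):
        if iv < lo or iv > hi:
            continue
        if prev is not None and abs(iv - prev) / prev > jump_fraction:
            continue
        keep[k] = True
        prev = iv
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("no usable beats after artifact removal")
    return RRISeries(times=rr.times[keep], intervals=rr.intervals[keep]), n_removed


def trim_excitement(series, head_s: float = 1000.0, tail_s: float = 1000.0):
    """Drop the excitement periods at the start and end of a recording.

    Drivers show unreasonably elevated heart rate during roughly the first
    and last 1000 s of a drive; only samples with time in
    ``[t_start + head_s, t_end - tail_s]`` are retained.  Works on any of
    the time-indexed containers in this package (the ``times`` field and
    every equal-length array field are masked together).
    """
    t = np.asarray(series.times, dtype=float)
    if t.size == 0:
        raise ValueError("trim exceeds recording: empty series")
    t0, t1 = t[0], t[-1]
    if head_s < 0 or tail_s < 0:
        raise ValueError("trim lengths must be nonnegative")
    if (head_s or tail_s) and t1 - t0 <= head_s + tail_s:
        raise ValueError("trim exceeds recording")
    mask = (t >= t0 + head_s) & (t <= t1 - tail_s)
    changes = {}
    for f in dataclasses.fields(series):
        v = getattr(series, f.name)
        if isinstance(v, np.ndarray) and v.shape == t.shape:
            changes[f.name] = v[mask]
    return dataclasses.replace(series, **changes)


def blink_frequency(blinks: BlinkSeries, windows) -> np.ndarray:
    """Blink rate (times/min) per half-open window ``[start, end)``.

    ``windows`` is a sequence of (start, end) pairs, ordered and
    non-overlapping.  Simultaneous blink events are all counted.
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim != 2 or w.shape[1] != 2:
        raise ValueError("windows must be (n, 2) [start, end) pairs")
    if np.any(w[:, 1] <= w[:, 0]):
        raise ValueError("zero-length window")
    if np.any(w[1:, 0] < w[:-1, 1]):
        raise ValueError("windows must be ordered and non-overlapping")
    t = blinks.times
    counts = np.searchsorted(t, w[:, 1], side="left") - np.searchsorted(
        t, w[:, 0], side="left"
    )
    return counts / ((w[:, 1] - w[:, 0]) / 60.0)
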