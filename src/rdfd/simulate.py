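"""Synthetic physiological data with planted fatigue and altitude effects.

Every pipeline stage is testable without field recordings: the generator
plants a known fatigue trajectory (an S-shaped logistic in the R-R
variation coefficient), an altitude-modulated heart rate (stronger
coupling above a ~4500 m knee), blink rates that rise with fatigue, and --
for end-to-end parameter recovery -- a coupled scenario in which the blink
fatigue degree equals a chosen correction factor times the HRV fatigue
degree exactly, so the calibration stage has a known ground truth.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fatigue import DFDSeries, FatigueBaselines
from .ingest import AltitudeProfile, BlinkSeries, ECGTrace, RRISeries
from .reference import ROUTE_ALTITUDE_KNOTS

__all__ = [
    "ScenarioConfig",
    "PlantedTruth",
    "CoupledScenario",
    "gen_altitude_profile",
    "gen_rr_series",
    "gen_static_rr",
    "gen_ecg",
    "gen_blinks",
    "gen_coupled_scenario",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for the synthetic drive.

    Defaults emulate a ~2.5 h plateau drive over the 3540-4768 m route:
    a logistic fatigue trajectory reaching moderate fatigue mid-drive, a
    resting variation coefficient of 0.03 rising from 0.05 at drive start,
    heart-rate coupling to altitude with a knee at 4500 m, and blink rates
    rising from 15/min with fatigue.
    """

    duration_s: float = 9000.0
    altitude_knots: tuple = ROUTE_ALTITUDE_KNOTS
    altitude_dt_s: float = 10.0
    # heart rate and its altitude coupling
    base_hr_bpm: float = 75.0
    hr_ref_altitude_m: float = 3540.0
    hr_per_1000m: float = 5.0
    hr_per_1000m_above_knee: float = 15.0
    hr_knee_m: float = 4500.0
    # fatigue trajectory (planted HRV fatigue degree)
    rrvc_static: float = 0.03
    rrvc_initial: float = 0.05
    fatigue_plateau: float = 8.0
    fatigue_midpoint_s: float = 3000.0  # measured from the trimmed start
    fatigue_rate_per_s: float = 1.0 / 600.0
    trim_s: float = 1000.0
    # blink baselines (times/min)
    bf_static: float = 14.0
    bf_initial: float = 15.0
    # R-R artifact bounds used for truncation
    rr_bounds_ms: tuple = (300.0, 2000.0)

    def __post_init__(self):
        if self.duration_s <= 0 or self.base_hr_bpm <= 0:
            raise ValueError("duration and base heart rate must be positive")
        if self.bf_static < 0 or self.bf_initial < 0:
            raise ValueError("blink rates must be nonnegative")

    # -- planted trajectories ------------------------------------------------
    def altitude(self, t):
        knots = np.asarray(self.altitude_knots, dtype=float)
        if np.any(np.diff(knots[:, 0]) <= 0):
            raise ValueError("altitude knots must be ordered in time")
        return np.interp(t, knots[:, 0], knots[:, 1])

    def heart_rate(self, t):
        """bpm at time t: base rate plus piecewise-linear altitude coupling."""
        h = self.altitude(t)
        below = np.minimum(h, self.hr_knee_m)
        above = np.maximum(h - self.hr_knee_m, 0.0)
        return (
            self.base_hr_bpm
            + self.hr_per_1000m * (below - self.hr_ref_altitude_m) / 1000.0
            + self.hr_per_1000m_above_knee * above / 1000.0
        )

    def dfd(self, t):
        """Planted HRV fatigue degree: logistic, zero at the trimmed start."""
        t = np.asarray(t, dtype=float)
        mid = self.trim_s + self.fatigue_midpoint_s
        sig = 1.0 / (1.0 + np.exp(-self.fatigue_rate_per_s * (t - mid)))
        sig0 = 1.0 / (1.0 + np.exp(-self.fatigue_rate_per_s * (self.trim_s - mid)))
        return self.fatigue_plateau * (sig - sig0) / (1.0 - sig0)

    def rrvc(self, t):
        bdf = self.rrvc_initial - self.rrvc_static
        return self.rrvc_initial + bdf * self.dfd(t)

    def m_ms(self, t):
        return 60000.0 / self.heart_rate(t)

    def sdnn_ms(self, t):
        return self.rrvc(t) * self.m_ms(t)

    def baselines(self) -> FatigueBaselines:
        return FatigueBaselines(
            rrvc_static=self.rrvc_static, rrvc_initial=self.rrvc_initial,
            bf_static=self.bf_static, bf_initial=self.bf_initial,
        )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth trajectories sampled on the window grid."""

    times: np.ndarray
    altitudes: np.ndarray
    m_ms: np.ndarray
    sdnn_ms: np.ndarray
    rrvc: np.ndarray
    dfd: np.ndarray

    def to_dict(self) -> dict:
        return {k: np.asarray(getattr(self, k)).tolist()
                for k in ("times", "altitudes", "m_ms", "sdnn_ms", "rrvc", "dfd")}


def gen_altitude_profile(config: ScenarioConfig | None = None,
                         knots=None, duration_s=None, dt_s=10.0) -> AltitudeProfile:
    """Piecewise-linear altitude profile sampled at ``dt_s``."""
    if config is not None:
        knots = config.altitude_knots
        duration_s = config.duration_s
        dt_s = config.altitude_dt_s
    knots = np.asarray(knots, dtype=float)
    if knots.ndim == 1:
        knots = knots.reshape(1, -1)
    if knots.shape[0] > 1 and np.any(np.diff(knots[:, 0]) <= 0):
        raise ValueError("altitude knots must be ordered in time")
    if duration_s is None:
        duration_s = knots[-1, 0]
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    return AltitudeProfile(times=t, altitudes=np.interp(t, knots[:, 0], knots[:, 1]))


def _truncated_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def gen_rr_series(config: ScenarioConfig, seed: int) -> tuple[RRISeries, PlantedTruth]:
    """Beat-by-beat R-R intervals realizing the planted trajectories.

    Each interval is a truncated-Normal draw with mean M(t) and SD
    SDNN(t), so windowed estimates of (M, SDNN, RRVC) converge to the
    planted values as the window beat count grows.
    """
    rrvc_check = config.rrvc(np.linspace(0, config.duration_s, 200))
    if np.any(rrvc_check <= 0) or np.any(rrvc_check >= 1):
        raise ValueError("planted trajectory implies RRVC outside (0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = config.rr_bounds_ms
    times, intervals = [], []
    t = 0.0
    while t < config.duration_s:
        m = config.m_ms(t)
        sd = config.sdnn_ms(t)
        iv = _truncated_normal(rng, m, sd, lo, hi)
        t += iv / 1000.0
        if t >= config.duration_s:
            break
        times.append(t)
        intervals.append(iv)
    rr = RRISeries(times=np.asarray(times), intervals=np.asarray(intervals))
    grid = np.asarray(times)
    truth = PlantedTruth(
        times=grid, altitudes=config.altitude(grid), m_ms=config.m_ms(grid),
        sdnn_ms=config.sdnn_ms(grid), rrvc=config.rrvc(grid), dfd=config.dfd(grid),
    )
    return rr, truth


def gen_static_rr(config: ScenarioConfig, duration_s: float = 300.0,
                  seed: int = 0) -> RRISeries:
    """Seated-rest recording at the static baseline (RRVC_static)."""
    rng = np.random.default_rng(seed)
    m = 60000.0 / config.base_hr_bpm
    sd = config.rrvc_static * m
    lo, hi = config.rr_bounds_ms
    times, intervals = [], []
    t = 0.0
    while t < duration_s:
        iv = _truncated_normal(rng, m, sd, lo, hi)
        t += iv / 1000.0
        if t >= duration_s:
            break
        times.append(t)
        intervals.append(iv)
    return RRISeries(times=np.asarray(times), intervals=np.asarray(intervals))


def gen_ecg(
    rr: RRISeries,
    sampling_rate: float = 250.0,
    amplitude_mv: float = 1.0,
    width_s: float = 0.012,
    snr_db: float | None = None,
    baseline_wander_mv: float = 0.0,
    seed: int = 0,
) -> ECGTrace:
    """Synthetic ECG: one Gaussian R-deflection per planted beat time.

    ``snr_db`` adds white Gaussian noise at the requested signal-to-noise
    ratio (relative to the clean waveform's RMS); ``baseline_wander_mv``
    adds a slow 0.25 Hz drift.  Realistic P/T morphology is out of scope;
    a dominant R deflection is what the detector needs to see.
    """
    if sampling_rate < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    if len(rr) == 0:
        raise ValueError("empty R-R series")
    beats = np.concatenate(([rr.times[0] - rr.intervals[0] / 1000.0], rr.times))
    t_start = beats[0] - 0.5  # lead-in so the first R wave is fully rendered
    n = int(np.ceil((beats[-1] + 0.5 - t_start) * sampling_rate)) + 1
    t = t_start + np.arange(n) / sampling_rate
    x = np.zeros(n)
    half = int(np.ceil(4 * width_s * sampling_rate))
    for b in beats:
        c = int(round((b - t_start) * sampling_rate))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        x[lo:hi] += amplitude_mv * np.exp(-0.5 * ((t[lo:hi] - b) / width_s) ** 2)
    rng = np.random.default_rng(seed)
    if baseline_wander_mv:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + baseline_wander_mv * np.sin(2 * np.pi * 0.25 * t + phase)
    if snr_db is not None:
        rms = float(np.sqrt(np.mean(x**2)))
        x = x + rng.normal(0.0, rms * 10 ** (-snr_db / 20.0), size=n)
    return ECGTrace(sampling_rate=sampling_rate, samples=x, start_time=t_start)


def gen_blinks(times, rates_per_min, duration_s: float, seed: int = 0) -> BlinkSeries:
    """Inhomogeneous Poisson blink events by thinning.

    ``rates_per_min`` gives the instantaneous blink rate at the sample
    times ``times`` (linear interpolation in between).
    """
    t_knots = np.asarray(times, dtype=float)
    r_knots = np.asarray(rates_per_min, dtype=float)
    if np.any(r_knots < 0):
        raise ValueError("blink rate must be nonnegative")
    lam_max = float(r_knots.max(initial=0.0)) / 60.0  # events/s
    if lam_max == 0:
        return BlinkSeries(times=np.array([]))
    rng = np.random.default_rng(seed)
    events = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= duration_s:
            break
        lam = np.interp(t, t_knots, r_knots) / 60.0
        if rng.uniform() < lam / lam_max:
            events.append(t)
    return BlinkSeries(times=np.asarray(events))


@dataclass(frozen=True)
class CoupledScenario:
    """A full synthetic dataset with a known correction factor.

    The planted blink fatigue degree equals ``delta*(h(t))`` times the
    planted HRV fatigue degree at every window, so running the calibration
    pipeline on this dataset must recover ``delta_coefs``.  The observed
    ``blink_dfd`` carries bounded multiplicative observation noise
    (uniform within ``+-noise_level``) on the reference instrument; the
    window-level ``hrv_dfd`` is the planted trajectory itself, HRV
    estimation noise being modeled at beat level by :func:`gen_rr_series`.
    The ``truth`` attribute holds the noise-free values.
    """

    config: ScenarioConfig
    delta_coefs: tuple
    window_mid_times: np.ndarray
    window_altitudes: np.ndarray
    hrv_dfd: DFDSeries
    blink_dfd: DFDSeries
    truth: dict
    rr: RRISeries | None = None
    static_rr: RRISeries | None = None
    blinks: BlinkSeries | None = None
    altitude: AltitudeProfile | None = None


def gen_coupled_scenario(
    config: ScenarioConfig | None = None,
    delta_coefs=(1.0,),
    seed: int = 0,
    noise_level: float = 0.0,
    window_length: float = 120.0,
    include_raw: bool = False,
) -> CoupledScenario:
    """Dataset in which the true correction factor is exactly ``delta_coefs``.

    Construction inverts the revision identity: the blink fatigue-degree
    trajectory is set to ``delta*(h(t)) * hrv_dfd(t)``, then blink rates
    are back-solved through the blink fatigue-degree formula (and must
    stay nonnegative, else the coupling is infeasible).
    """
    config = config or ScenarioConfig()
    coefs = np.asarray(delta_coefs, dtype=float)
    rng = np.random.default_rng(seed)

    t0 = config.trim_s
    t1 = config.duration_s - config.trim_s
    starts = np.arange(t0, t1 - window_length + 1e-9, window_length)
    mids = starts + window_length / 2.0
    h = np.asarray(config.altitude(mids), dtype=float)

    delta_true = np.polynomial.polynomial.polyval(h, coefs)
    if np.any(delta_true <= 0):
        raise ValueError("delta* must be positive over the altitude range")
    hrv_true = config.dfd(mids)
    blink_true = delta_true * hrv_true

    blink_bdf = config.bf_initial - config.bf_static
    bf_true = config.bf_initial + blink_true * blink_bdf
    if np.any(bf_true < 0):
        raise ValueError("infeasible coupling: back-solved blink rate negative")

    hrv_obs = hrv_true
    blink_obs = blink_true * (1.0 + rng.uniform(-noise_level, noise_level, mids.size))

    truth = {
        "delta_coefs": coefs.tolist(),
        "window_mid_times": mids.tolist(),
        "window_altitudes": h.tolist(),
        "delta": delta_true.tolist(),
        "hrv_dfd": hrv_true.tolist(),
        "blink_dfd": blink_true.tolist(),
        "blink_rate_per_min": bf_true.tolist(),
    }
    raw = {}
    if include_raw:
        rr, _ = gen_rr_series(config, seed=int(rng.integers(2**31)))
        static = gen_static_rr(config, seed=int(rng.integers(2**31)))
        grid = np.linspace(0.0, config.duration_s, 400)
        bf_grid = config.bf_initial + (
            np.polynomial.polynomial.polyval(config.altitude(grid), coefs)
            * config.dfd(grid) * blink_bdf
        )
        bf_grid = np.maximum(bf_grid, 0.0)
        blinks = gen_blinks(grid, bf_grid, config.duration_s,
                            seed=int(rng.integers(2**31)))
        raw = {"rr": rr, "static_rr": static, "blinks": blinks,
               "altitude": gen_altitude_profile(config)}
    return CoupledScenario(
        config=config,
        delta_coefs=tuple(coefs.tolist()),
        window_mid_times=mids,
        window_altitudes=h,
        hrv_dfd=DFDSeries(times=mids, values=hrv_obs, source="hrv",
                          window_length=window_length),
        blink_dfd=DFDSeries(times=mids, values=blink_obs, source="blink",
                            window_length=window_length),
        truth=truth,
        **raw,
    )
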