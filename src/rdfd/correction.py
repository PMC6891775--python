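"""Altitude-dependent correction of the HRV fatigue degree.

At road segments with rapid altitude change the driver's heart rate
responds to altitude itself, so the HRV-based fatigue degree drifts away
from the true fatigue trajectory; the blink-based fatigue degree does not
share that confound.  A dimensionless correction factor, cubic in altitude
and calibrated separately per slope direction (altitude affects heart rate
oppositely on climbs and descents), rescales the HRV estimate:

    rDFD_i = delta(h_i) * DFD_i

delta is estimated pointwise as blink_DFD / hrv_DFD (both start at zero by
construction, so the ratio is meaningful away from the zero-crossing) and
smoothed by a least-squares cubic in altitude h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from numpy.polynomial import Polynomial
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .fatigue import DFDSeries
from .ingest import AltitudeProfile

__all__ = [
    "SlopeSegment",
    "DeltaPairs",
    "CurveAgreement",
    "AltitudeCorrection",
    "align_window_grids",
    "classify_slope",
    "slope_class_at",
    "pointwise_delta",
    "calibrate_delta",
    "evaluate_delta",
    "revise_dfd",
    "curve_agreement",
    "flat_segment_check",
]

#: default |smoothed gradient| below which a stretch counts as flat,
#: 0.5 m over a 120-s aggregation window
FLAT_THRESHOLD_M_PER_S = 0.5 / 120.0
DFD_RATIO_EPSILON = 0.05


@dataclass(frozen=True)
class SlopeSegment:
    """A contiguous stretch of road with one slope direction."""

    start: float
    end: float
    slope_class: str  # "up" | "down" | "flat"
    mean_gradient: float  # m/s of drive time

    @property
    def duration(self) -> float:
        return self.end - self.start


def classify_slope(
    profile: AltitudeProfile,
    flat_threshold: float = FLAT_THRESHOLD_M_PER_S,
    smoothing_s: float = 120.0,
    min_duration_s: float = 300.0,
    resample_s: float = 1.0,
) -> list[SlopeSegment]:
    """Partition the drive into up / down / flat slope segments.

    The altitude profile is resampled uniformly, smoothed by a moving
    average over ``smoothing_s``, and differentiated; the gradient sign
    against ``flat_threshold`` labels each instant.  Runs shorter than
    ``min_duration_s`` (mostly transition bands around summits) are merged
    into their longer neighbor, so the output partitions the span.
    """
    t0, t1 = float(profile.times[0]), float(profile.times[-1])
    if t1 - t0 <= 0:
        raise ValueError("altitude profile has zero duration")
    t = np.arange(t0, t1 + resample_s / 2, resample_s)
    h = profile.at(t)
    win = max(1, int(round(smoothing_s / resample_s)))
    if win > 1:
        kernel = np.ones(win) / win
        pad = win // 2
        hp = np.pad(h, pad, mode="edge")
        h_smooth = np.convolve(hp, kernel, mode="same")[pad: pad + h.size]
    else:
        h_smooth = h
    grad = np.gradient(h_smooth, t)

    labels = np.where(grad > flat_threshold, 1, np.where(grad < -flat_threshold, -1, 0))
    runs = _runs(t, labels)
    runs = _merge_short_runs(runs, min_duration_s)

    names = {1: "up", -1: "down", 0: "flat"}
    segments = []
    for (s, e, lab) in runs:
        dh = float(profile.at(e) - profile.at(s))
        segments.append(
            SlopeSegment(start=s, end=e, slope_class=names[lab],
                         mean_gradient=dh / (e - s))
        )
    return segments


def _runs(t, labels):
    out = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            out.append([float(t[start]), float(t[min(i, labels.size - 1)]),
                        int(labels[start])])
            start = i
    out[-1][1] = float(t[-1])
    # make runs contiguous: each run ends where the next begins
    for j in range(len(out) - 1):
        out[j][1] = out[j + 1][0]
    return [tuple(r) for r in out]


def _merge_short_runs(runs, min_duration):
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        durations = [r[1] - r[0] for r in runs]
        i = int(np.argmin(durations))
        if durations[i] >= min_duration:
            break
        # absorb into the longer neighbor
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i < len(runs) - 1 else None
        if right is None or (left is not None and
                             (left[1] - left[0]) >= (right[1] - right[0])):
            left[1] = runs[i][1]
        else:
            right[0] = runs[i][0]
        del runs[i]
        # coalesce equal-label neighbors
        j = 0
        while j < len(runs) - 1:
            if runs[j][2] == runs[j + 1][2]:
                runs[j][1] = runs[j + 1][1]
                del runs[j + 1]
            else:
                j += 1
    return [tuple(r) for r in runs]


def slope_class_at(segments: list[SlopeSegment], t) -> np.ndarray:
    """Slope class of each time in ``t`` (last segment is right-closed)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty(t.size, dtype=object)
    for seg in segments:
        mask = (t >= seg.start) & (t < seg.end)
        out[mask] = seg.slope_class
    out[t == segments[-1].end] = segments[-1].slope_class
    if any(v is None for v in out):
        raise ValueError("time outside the classified span")
    return out


# ---------------------------------------------------------------------------
# Correction-factor calibration

@dataclass(frozen=True)
class DeltaPairs:
    """Pointwise (altitude, correction factor) calibration pairs."""

    altitudes: np.ndarray
    deltas: np.ndarray
    times: np.ndarray
    n_excluded: int = 0

    def __len__(self) -> int:
        return int(self.altitudes.size)


def align_window_grids(a: DFDSeries, b: DFDSeries,
                       tol: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Inner-join two window grids by nearest window time.

    Grids produced by different ingest paths can be offset by a fraction
    of a window (beat times rarely start exactly on a round second), so
    windows are matched to the nearest counterpart within ``tol`` (default
    half the shorter window length).  Returns index arrays into ``a`` and
    ``b``; each window matches at most once.
    """
    if tol is None:
        tol = 0.5 * min(a.window_length, b.window_length)
    ia, ib = [], []
    pos = np.searchsorted(b.times, a.times)
    used: set[int] = set()
    for i, t in enumerate(a.times):
        best = None
        for k in (pos[i] - 1, pos[i]):
            if 0 <= k < b.times.size and abs(b.times[k] - t) <= tol:
                if best is None or abs(b.times[k] - t) < abs(b.times[best] - t):
                    best = k
        if best is not None and best not in used:
            used.add(best)
            ia.append(i)
            ib.append(best)
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int)


def pointwise_delta(
    blink: DFDSeries,
    hrv: DFDSeries,
    altitude_at_windows,
    epsilon: float = DFD_RATIO_EPSILON,
) -> DeltaPairs:
    """Pointwise correction factor blink_DFD / hrv_DFD per window.

    The two series are inner-joined on their window times.  Windows where
    ``|hrv_DFD| <= epsilon`` are excluded: near the zero-crossing the ratio
    blows up and carries no calibration information.
    """
    ia, ib = align_window_grids(blink, hrv)
    if ia.size == 0:
        raise ValueError("series share no window times")
    h = np.asarray(altitude_at_windows, dtype=float)
    if h.size == hrv.times.size:
        h = h[ib]
    elif h.size != ia.size:
        raise ValueError("altitude_at_windows length mismatch")
    bv, hv = blink.values[ia], hrv.values[ib]
    usable = np.abs(hv) > epsilon
    n_excluded = int((~usable).sum())
    if usable.sum() < 5:
        raise ValueError("insufficient calibration support (< 5 usable pairs)")
    return DeltaPairs(
        altitudes=h[usable],
        deltas=bv[usable] / hv[usable],
        times=hrv.times[ib][usable],
        n_excluded=n_excluded,
    )


class AltitudeCorrection(RegressorMixin, BaseEstimator):
    """Cubic correction-factor model delta(h) for one slope class.

    Fit on pointwise (h, delta) pairs by least squares with the design
    centered/scaled internally; coefficients are reported on the original
    altitude scale (m).  ``predict`` evaluates
    ``c0 + c1 h + c2 h^2 + c3 h^3`` and warns on extrapolation beyond the
    calibration range.

    Parameters
    ----------
    degree : int, default 3
        Polynomial degree in altitude.
    slope_class : str or None
        Slope direction the model applies to ("up", "down" or "flat").
    min_span_m : float, default 200
        Minimum altitude span of the calibration pairs; narrower designs
        make the cubic ill-conditioned and are rejected.
    """

    def __init__(self, degree: int = 3, slope_class: str | None = None,
                 min_span_m: float = 200.0):
        self.degree = degree
        self.slope_class = slope_class
        self.min_span_m = min_span_m

    @classmethod
    def from_coefficients(cls, coef, h_range=None, slope_class=None) -> "AltitudeCorrection":
        coef = np.asarray(coef, dtype=float)
        est = cls(degree=coef.size - 1, slope_class=slope_class)
        est.coef_ = coef
        est.h_range_ = (None if h_range is None
                        else (float(h_range[0]), float(h_range[1])))
        est.residual_ss_ = est.f_statistic_ = est.f_pvalue_ = est.r_squared_ = np.nan
        est.n_ = 0
        return est

    def fit(self, X, y=None):
        h = np.asarray(X, dtype=float).reshape(-1)
        d = np.asarray(y, dtype=float).reshape(-1)
        if h.size != d.size:
            raise ValueError("altitude and delta arrays must have equal length")
        if h.size < max(5, self.degree + 2):
            raise ValueError("insufficient calibration support (< 5 pairs)")
        if np.ptp(h) < self.min_span_m:
            raise ValueError(
                f"altitude span {np.ptp(h):.1f} m < {self.min_span_m} m: "
                "cubic calibration would be ill-conditioned"
            )
        poly = Polynomial.fit(h, d, self.degree)
        coef = poly.convert().coef
        self.coef_ = np.pad(coef, (0, self.degree + 1 - coef.size))
        self.h_range_ = (float(h.min()), float(h.max()))
        self.n_ = h.size
        resid = d - poly(h)
        sse = float(resid @ resid)
        sst = float(np.sum((d - d.mean()) ** 2))
        self.residual_ss_ = sse
        self.r_squared_ = 1.0 - sse / sst if sst > 0 else np.nan
        dfm, dfe = self.degree, h.size - self.degree - 1
        if sse > 0 and dfe > 0:
            self.f_statistic_ = ((sst - sse) / dfm) / (sse / dfe)
            self.f_pvalue_ = float(stats.f.sf(self.f_statistic_, dfm, dfe))
        else:
            self.f_statistic_ = np.inf
            self.f_pvalue_ = 0.0
        return self

    def predict(self, X) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(h)):
            raise ValueError("altitude must be finite")
        if self.h_range_ is not None and (
            np.any(h < self.h_range_[0]) or np.any(h > self.h_range_[1])
        ):
            warnings.warn(
                "evaluating correction factor outside its calibration "
                f"altitude range {self.h_range_}", stacklevel=2,
            )
        return np.polynomial.polynomial.polyval(h, self.coef_)


def calibrate_delta(pairs: DeltaPairs, slope_class: str | None = None,
                    degree: int = 3) -> AltitudeCorrection:
    """Fit the cubic correction-factor model to pointwise pairs."""
    return AltitudeCorrection(degree=degree, slope_class=slope_class).fit(
        pairs.altitudes, pairs.deltas
    )


def evaluate_delta(model: AltitudeCorrection, h) -> np.ndarray:
    """Correction factor delta at altitude(s) ``h`` (m)."""
    return model.predict(h)


def revise_dfd(
    hrv: DFDSeries,
    models: AltitudeCorrection | Mapping[str, AltitudeCorrection],
    altitude_at_windows,
    slope_classes=None,
) -> DFDSeries:
    """Altitude-corrected fatigue degree, ``rDFD_i = delta(h_i) * DFD_i``.

    ``models`` is either a single fitted model or a per-slope-class map;
    in the latter case ``slope_classes`` gives each window's class.  Flat
    windows without a dedicated model use delta = 1 (altitude has no
    measurable effect on the correction factor over low-variation
    stretches).
    """
    h = np.asarray(altitude_at_windows, dtype=float)
    if h.size != hrv.times.size:
        raise ValueError("altitude_at_windows must match the window grid")
    if isinstance(models, Mapping):
        if slope_classes is None:
            raise ValueError("slope_classes required with a per-class model map")
        classes = np.asarray(slope_classes, dtype=object)
        delta = np.empty(h.size, dtype=float)
        for cls_name in np.unique(classes):
            mask = classes == cls_name
            if cls_name in models:
                delta[mask] = models[cls_name].predict(h[mask])
            elif cls_name == "flat":
                delta[mask] = 1.0
            else:
                raise ValueError(f"no correction model for slope class {cls_name!r}")
    else:
        delta = models.predict(h)
    return replace(hrv, values=delta * hrv.values, source="revised")


# ---------------------------------------------------------------------------
# Agreement statistics

@dataclass(frozen=True)
class CurveAgreement:
    """How closely two fatigue-degree curves track each other."""

    n: int
    ss_diff: float  # sum of squared pointwise differences
    f_statistic: float
    f_pvalue: float
    r_squared: float


def _linear_anova(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Simple-regression slope, F, significance-F and R^2 of y on x."""
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    if sxx == 0:
        raise ValueError("degenerate regressor: no variation")
    if syy == 0:
        return 0.0, 0.0, 1.0, np.nan
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    ssr = slope * sxy
    sse = syy - ssr
    r2 = ssr / syy
    dfe = n - 2
    if sse <= 0 or dfe <= 0:
        return slope, np.inf, 0.0, 1.0
    f = (ssr / 1.0) / (sse / dfe)
    return slope, f, float(stats.f.sf(f, 1, dfe)), r2


def curve_agreement(a: DFDSeries, b: DFDSeries) -> CurveAgreement:
    """Agreement between two fatigue-degree curves on their common grid.

    Reports the sum of squared pointwise differences plus the regression
    F, significance-F and R^2 of a simple linear regression of ``b`` on
    ``a``.
    """
    ia, ib = align_window_grids(a, b)
    if ia.size < 3:
        raise ValueError("need at least 3 common points")
    av, bv = a.values[ia], b.values[ib]
    ss = float(np.sum((av - bv) ** 2))
    _, f, p, r2 = _linear_anova(av, bv)
    return CurveAgreement(n=int(ia.size), ss_diff=ss, f_statistic=f,
                          f_pvalue=p, r_squared=r2)


@dataclass(frozen=True)
class FlatSegmentReport:
    """Linear regression of delta on altitude over a flat segment."""

    n: int
    slope: float
    f_statistic: float
    f_pvalue: float
    altitude_independent: bool  # non-rejection at alpha = 0.05


def flat_segment_check(altitudes, deltas, alpha: float = 0.05) -> FlatSegmentReport:
    """Validity check on a segment with little altitude change.

    Regresses the pointwise correction factor on altitude; the method is
    consistent when no dependence is detectable there (significance-F >=
    ``alpha``), i.e. the correction reduces to a constant where altitude
    does not move.
    """
    h = np.asarray(altitudes, dtype=float).reshape(-1)
    d = np.asarray(deltas, dtype=float).reshape(-1)
    if h.size != d.size or h.size < 5:
        raise ValueError("need at least 5 (altitude, delta) pairs")
    slope, f, p, _ = _linear_anova(h, d)
    return FlatSegmentReport(n=int(h.size), slope=slope, f_statistic=f,
                             f_pvalue=p, altitude_independent=bool(p >= alpha))
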