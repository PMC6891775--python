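"""The driving-fatigue-degree (DFD) statistic and its HRV windowing.

The core HRV feature is the variation coefficient of R-R intervals,

    RRVC = SDNN / M,

with M the mean and SDNN the (sample) standard deviation of the R-R
intervals inside a time window.  Fatigue accumulation is then expressed
relative to two baselines -- the seated-rest ("static") state before the
drive and the first post-trim driving window ("initial"):

    BDF   = RRVC_initial - RRVC_static      (baseline driving fatigue)
    FC_i  = RRVC_i - RRVC_static            (cumulative fatigue)
    DFC_i = RRVC_i - RRVC_initial           (cumulative driving fatigue)
    DFD_i = DFC_i / BDF                     (driving fatigue degree)

so that FC_i - DFC_i = BDF and DFD_i * BDF = DFC_i identically.  A blink
based analogue replaces RRVC with blink frequency (times/min); its
construction forces both DFD sources to start at zero, which is what makes
them commensurable for altitude correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .ingest import RRISeries
from .trend import CubicTrendRegressor

__all__ = [
    "HRVWindow",
    "FatigueBaselines",
    "FatigueMetrics",
    "DFDSeries",
    "FatigueDegree",
    "window_hrv",
    "compute_rrvc",
    "aggregate_rrvc",
    "compute_baselines",
    "compute_fatigue_metrics",
    "cohort_average",
    "blink_dfd",
    "fit_trend",
    "select_window_length",
    "apply_selection_rule",
    "summarize_selection",
    "WindowSelectionError",
]

DEFAULT_WINDOW_S = 120.0
DEFAULT_MIN_BEATS = 10
DEFAULT_CANDIDATES = (30.0, 60.0, 120.0, 180.0, 240.0, 300.0)


@dataclass(frozen=True)
class HRVWindow:
    """Time-domain HRV summary of one aggregation window ``[start, end)``."""

    index: int  # 1-based window ordinal
    start: float
    end: float
    m_ms: float
    sdnn_ms: float
    rrvc: float
    n_beats: int
    n_drivers: int = 1

    @property
    def mid(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class FatigueBaselines:
    """Static (seated rest) and initial (first driving window) baselines.

    The HRV pair is required; the blink pair is optional and only needed
    for the blink-based DFD.  ``epsilon`` guards the DFD denominator.
    """

    rrvc_static: float
    rrvc_initial: float
    bf_static: float | None = None
    bf_initial: float | None = None
    epsilon: float = 1e-6

    def __post_init__(self):
        if abs(self.rrvc_initial - self.rrvc_static) <= self.epsilon:
            raise ValueError(
                "degenerate baseline: |RRVC_initial - RRVC_static| <= epsilon "
                "(fatigue-degree denominator ~ 0)"
            )
        if self.bf_static is not None and self.bf_initial is not None:
            if abs(self.bf_initial - self.bf_static) <= self.epsilon:
                raise ValueError(
                    "degenerate blink baseline: |BF_initial - BF_static| <= epsilon"
                )

    @property
    def bdf(self) -> float:
        """Baseline driving fatigue, RRVC_initial - RRVC_static."""
        return self.rrvc_initial - self.rrvc_static

    @property
    def blink_bdf(self) -> float:
        if self.bf_static is None or self.bf_initial is None:
            raise ValueError("blink baselines not set")
        return self.bf_initial - self.bf_static


@dataclass(frozen=True)
class FatigueMetrics:
    """Per-window fatigue statistics (all dimensionless)."""

    bdf: float
    fc: np.ndarray
    dfc: np.ndarray
    dfd: np.ndarray


@dataclass(frozen=True)
class DFDSeries:
    """A fatigue-degree time series on a window grid.

    ``times`` are window mid-times (s); ``source`` tags the estimator
    (``hrv``, ``blink`` or ``revised``).
    """

    times: np.ndarray
    values: np.ndarray
    source: str = "hrv"
    window_length: float = DEFAULT_WINDOW_S

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("window times must be strictly increasing")
        if self.source not in ("hrv", "blink", "revised"):
            raise ValueError("source must be one of hrv, blink, revised")

    def __len__(self) -> int:
        return int(self.times.size)


def compute_rrvc(sdnn_ms: float, m_ms: float) -> float:
    """Variation coefficient of R-R intervals, SDNN / M (dimensionless)."""
    if not m_ms > 0:
        raise ValueError("mean R-R interval must be > 0")
    if sdnn_ms < 0:
        raise ValueError("SDNN must be >= 0")
    return sdnn_ms / m_ms


def aggregate_rrvc(rr: RRISeries) -> tuple[float, float, float]:
    """Whole-series (M, SDNN, RRVC) aggregate, sample (n-1) SD."""
    iv = rr.intervals
    if iv.size < 2:
        raise ValueError("need at least 2 intervals to aggregate")
    m = float(np.mean(iv))
    sdnn = float(np.std(iv, ddof=1))
    return m, sdnn, compute_rrvc(sdnn, m)


def window_hrv(
    rr: RRISeries,
    window_length: float = DEFAULT_WINDOW_S,
    min_beats: int = DEFAULT_MIN_BEATS,
    origin: float | None = None,
) -> list[HRVWindow]:
    """Aggregate an R-R series into consecutive ``[start, end)`` windows.

    Each interval is assigned to exactly one window by its end-beat time;
    the grid tiles ``[origin, ...)`` in full-length windows until every
    beat is covered (the last window may extend past the final beat).
    Windows with fewer than ``min_beats`` intervals are excluded (they
    would make SDNN unreliable); window ordinals stay contiguous over the
    retained windows.
    """
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    t0 = float(rr.times[0]) if origin is None else float(origin)
    t_end = float(rr.times[-1])
    starts = np.arange(t0, t_end, window_length)
    windows: list[HRVWindow] = []
    i = 0
    for s in starts:
        e = s + window_length
        mask = (rr.times >= s) & (rr.times < e)
        n = int(mask.sum())
        if n < max(2, min_beats):
            continue
        iv = rr.intervals[mask]
        m = float(np.mean(iv))
        sdnn = float(np.std(iv, ddof=1))
        i += 1
        windows.append(
            HRVWindow(index=i, start=float(s), end=float(e), m_ms=m,
                      sdnn_ms=sdnn, rrvc=sdnn / m, n_beats=n)
        )
    if not windows:
        raise ValueError("no window reaches the minimum beat count")
    return windows


def windows_to_frame(windows: list[HRVWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "i": [w.index for w in windows],
            "start_s": [w.start for w in windows],
            "end_s": [w.end for w in windows],
            "t_mid_s": [w.mid for w in windows],
            "M_ms": [w.m_ms for w in windows],
            "SDNN_ms": [w.sdnn_ms for w in windows],
            "RRVC": [w.rrvc for w in windows],
            "n_beats": [w.n_beats for w in windows],
        }
    )


def compute_baselines(
    static_rr: RRISeries | None,
    initial_windows: list[HRVWindow],
    k: int = 1,
    rrvc_static: float | None = None,
    bf_static: float | None = None,
    bf_initial: float | None = None,
    epsilon: float = 1e-6,
) -> FatigueBaselines:
    """Build fatigue baselines.

    ``rrvc_static`` comes from a single aggregate over the whole seated
    rest recording (or is passed directly as a scalar when no such
    recording exists); ``rrvc_initial`` is the mean RRVC of the first
    ``k`` post-trim driving windows (default k = 1).
    """
    if rrvc_static is None:
        if static_rr is None:
            raise ValueError("either static_rr or rrvc_static must be given")
        _, _, rrvc_static = aggregate_rrvc(static_rr)
    if k < 1 or k > len(initial_windows):
        raise ValueError("k must be in [1, number of windows]")
    rrvc_initial = float(np.mean([w.rrvc for w in initial_windows[:k]]))
    return FatigueBaselines(
        rrvc_static=float(rrvc_static),
        rrvc_initial=rrvc_initial,
        bf_static=bf_static,
        bf_initial=bf_initial,
        epsilon=epsilon,
    )


class FatigueDegree(TransformerMixin, BaseEstimator):
    """Transformer mapping windowed RRVC values to fatigue degree.

    ``fit`` learns ``rrvc_initial_`` as the mean of the first ``k`` input
    values (the initial driving windows); ``transform`` applies
    ``(rrvc - initial) / (initial - static)``.

    Parameters
    ----------
    rrvc_static : float
        Seated-rest variation coefficient (the static baseline).
    k : int, default 1
        Number of leading windows that define the initial baseline.
    epsilon : float, default 1e-6
        Degeneracy guard on the denominator.
    """

    def __init__(self, rrvc_static: float = 0.0, k: int = 1, epsilon: float = 1e-6):
        self.rrvc_static = rrvc_static
        self.k = k
        self.epsilon = epsilon

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        if x.size < self.k or self.k < 1:
            raise ValueError("k must be in [1, n windows]")
        self.rrvc_initial_ = float(np.mean(x[: self.k]))
        self.bdf_ = self.rrvc_initial_ - self.rrvc_static
        if abs(self.bdf_) <= self.epsilon:
            raise ValueError("degenerate baseline: denominator ~ 0")
        return self

    def transform(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        return (x - self.rrvc_initial_) / self.bdf_

    def inverse_transform(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        return self.rrvc_initial_ + x * self.bdf_


def compute_fatigue_metrics(
    windows: list[HRVWindow], baselines: FatigueBaselines
) -> tuple[FatigueMetrics, DFDSeries]:
    """Per-window FC, DFC and DFD from HRV windows and baselines."""
    rrvc = np.array([w.rrvc for w in windows], dtype=float)
    fc = rrvc - baselines.rrvc_static
    dfc = rrvc - baselines.rrvc_initial
    dfd = dfc / baselines.bdf
    mids = np.array([w.mid for w in windows], dtype=float)
    wl = windows[0].end - windows[0].start if windows else DEFAULT_WINDOW_S
    metrics = FatigueMetrics(bdf=baselines.bdf, fc=fc, dfc=dfc, dfd=dfd)
    series = DFDSeries(times=mids, values=dfd, source="hrv", window_length=wl)
    return metrics, series


def cohort_average(per_driver_windows: list[list[HRVWindow]]) -> list[HRVWindow]:
    """Average HRV parameters across drivers on a common window grid.

    Per window, M and SDNN are averaged over the drivers contributing that
    window and RRVC is recomputed from the averaged values (the HRV
    parameters are averaged, not the per-driver fatigue degrees).  Windows
    are matched by their (start, end) times; the contributor count is
    recorded in ``n_drivers``.
    """
    if not per_driver_windows:
        raise ValueError("empty cohort")
    grid: dict[tuple[float, float], list[HRVWindow]] = {}
    for driver in per_driver_windows:
        for w in driver:
            grid.setdefault((round(w.start, 6), round(w.end, 6)), []).append(w)
    out: list[HRVWindow] = []
    for i, (key, group) in enumerate(sorted(grid.items()), start=1):
        m = float(np.mean([w.m_ms for w in group]))
        sdnn = float(np.mean([w.sdnn_ms for w in group]))
        out.append(
            HRVWindow(index=i, start=key[0], end=key[1], m_ms=m, sdnn_ms=sdnn,
                      rrvc=sdnn / m, n_beats=int(sum(w.n_beats for w in group)),
                      n_drivers=len(group))
        )
    return out


def blink_dfd(
    times,
    rates,
    baselines: FatigueBaselines,
    window_length: float = DEFAULT_WINDOW_S,
) -> DFDSeries:
    """Blink-based fatigue degree, the structural analogue of the HRV DFD.

    ``blink_DFD_i = (BF_i - BF_initial) / (BF_initial - BF_static)``,
    which starts at zero like the HRV DFD -- the property that lets the
    altitude correction treat blink DFD as the reference curve.
    """
    denom = baselines.blink_bdf  # raises if blink baselines missing
    if abs(denom) <= baselines.epsilon:
        raise ValueError("degenerate blink baseline")
    values = (np.asarray(rates, dtype=float) - baselines.bf_initial) / denom
    return DFDSeries(times=times, values=values, source="blink",
                     window_length=window_length)


def fit_trend(series: DFDSeries, degree: int = 3) -> CubicTrendRegressor:
    """Fit the cubic time trend of a fatigue-degree series."""
    return CubicTrendRegressor(degree=degree).fit(series.times, series.values)


# ---------------------------------------------------------------------------
# Aggregation-window selection

class WindowSelectionError(ValueError):
    """No candidate window reaches significance; carries the full table."""

    def __init__(self, message: str, table: pd.DataFrame):
        super().__init__(message)
        self.table = table


def select_window_length(
    rr: RRISeries,
    rrvc_static: float,
    candidates=DEFAULT_CANDIDATES,
    rule: str = "default",
    preferred: float = DEFAULT_WINDOW_S,
    alpha: float = 0.05,
    k: int = 1,
    min_beats: int = DEFAULT_MIN_BEATS,
) -> tuple[float, pd.DataFrame]:
    """Choose the aggregation window length from trend-fit diagnostics.

    Too short a window makes SDNN noisy; too long a window washes out the
    variability.  For every candidate the DFD series is computed, its cubic
    trend fitted, and the regression F and significance-F recorded; the
    chosen length is then decided by :func:`apply_selection_rule`.
    """
    rows = []
    for c in candidates:
        try:
            windows = window_hrv(rr, window_length=c, min_beats=min_beats)
            baselines = compute_baselines(None, windows, k=k, rrvc_static=rrvc_static)
            _, series = compute_fatigue_metrics(windows, baselines)
            model = fit_trend(series)
            rows.append((c, model.f_pvalue_, model.f_statistic_))
        except ValueError:
            rows.append((c, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["window_s", "sig_f", "f"])
    return apply_selection_rule(table, rule=rule, preferred=preferred, alpha=alpha), table


def apply_selection_rule(
    table: pd.DataFrame,
    rule: str = "default",
    preferred: float = DEFAULT_WINDOW_S,
    alpha: float = 0.05,
) -> float:
    """Apply a selection rule to a window table (columns window_s, sig_f, f).

    ``default``: among candidates significant at ``alpha``, return the
    preferred length (falling back to the minimum-F significant candidate
    if the preferred one is not significant).  ``min-F``: return the
    significant candidate with the smallest F (reading "the smaller the
    significance F and F value, the better" literally).  The two rules can
    genuinely disagree; :func:`summarize_selection` surfaces that.
    """
    eligible = table[table["sig_f"] < alpha]
    if eligible.empty:
        raise WindowSelectionError(
            f"no candidate window reaches significance {alpha}", table
        )
    if rule == "default":
        if (eligible["window_s"] == preferred).any():
            return float(preferred)
        rule = "min-F"
    if rule == "min-F":
        return float(eligible.loc[eligible["f"].idxmin(), "window_s"])
    raise ValueError(f"unknown selection rule: {rule!r}")


def summarize_selection(
    table: pd.DataFrame, preferred: float = DEFAULT_WINDOW_S, alpha: float = 0.05
) -> dict:
    """Both rules' choices plus a flag when they disagree."""
    default_choice = apply_selection_rule(table, "default", preferred, alpha)
    min_f_choice = apply_selection_rule(table, "min-F", preferred, alpha)
    return {
        "default": default_choice,
        "min_f": min_f_choice,
        "rules_agree": default_choice == min_f_choice,
    }
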