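"""Published reference models from the Qinghai-Tibet Highway field campaign.

These are the field-calibrated artifacts shipped for evaluation and
comparison: the altitude correction factors for upslope and downslope
driving (cubics in altitude, valid over the 3540-4768 m route), the
revised fatigue-degree time trends observed on the same route, and the
aggregation-window selection table (regression F and significance-F of the
fatigue-degree trend at candidate window lengths).  They are inputs to
tests and reports, never re-derived here -- the raw field recordings
behind them are not distributable.
"""

from __future__ import annotations

import pandas as pd

from .correction import AltitudeCorrection
from .trend import CubicTrendRegressor

__all__ = [
    "UPSLOPE_CORRECTION_COEFS",
    "DOWNSLOPE_CORRECTION_COEFS",
    "UPSLOPE_RDFD_TREND_COEFS",
    "DOWNSLOPE_RDFD_TREND_COEFS",
    "CALIBRATION_ALTITUDE_RANGE",
    "ROUTE_ALTITUDE_KNOTS",
    "upslope_correction_model",
    "downslope_correction_model",
    "upslope_rdfd_trend",
    "downslope_rdfd_trend",
    "reference_window_table",
]

#: delta_u(h), upslope correction factor (h in m)
UPSLOPE_CORRECTION_COEFS = (366.711, -0.302, 8.169e-5, -7.209e-9)
#: delta_d(h), downslope correction factor
DOWNSLOPE_CORRECTION_COEFS = (493.703, -0.348, 8.219e-5, -6.473e-9)
#: rDFD_u(t), revised fatigue-degree trend over drive time (t in s), upslope
UPSLOPE_RDFD_TREND_COEFS = (8.658, 0.008, -3.173e-6, 5.850e-10)
#: rDFD_d(t), downslope analogue
DOWNSLOPE_RDFD_TREND_COEFS = (4.436, 0.004, -2.173e-6, 5.348e-10)

#: altitude range (m) over which the correction factors were calibrated
CALIBRATION_ALTITUDE_RANGE = (3540.0, 4768.0)

#: route altitude template (time s, altitude m): valley start, the highest
#: pass, the dip at the basin, and the plateau terminus
ROUTE_ALTITUDE_KNOTS = ((0.0, 3540.0), (3600.0, 4768.0),
                        (7200.0, 4476.0), (9000.0, 4663.0))


def upslope_correction_model() -> AltitudeCorrection:
    return AltitudeCorrection.from_coefficients(
        UPSLOPE_CORRECTION_COEFS, h_range=CALIBRATION_ALTITUDE_RANGE,
        slope_class="up",
    )


def downslope_correction_model() -> AltitudeCorrection:
    return AltitudeCorrection.from_coefficients(
        DOWNSLOPE_CORRECTION_COEFS, h_range=CALIBRATION_ALTITUDE_RANGE,
        slope_class="down",
    )


def upslope_rdfd_trend() -> CubicTrendRegressor:
    return CubicTrendRegressor.from_coefficients(UPSLOPE_RDFD_TREND_COEFS)


def downslope_rdfd_trend() -> CubicTrendRegressor:
    return CubicTrendRegressor.from_coefficients(DOWNSLOPE_RDFD_TREND_COEFS)


def reference_window_table() -> pd.DataFrame:
    """Window-selection diagnostics observed in the field campaign.

    Regression F and significance-F of the fitted fatigue-degree trend at
    six candidate aggregation windows; input to
    :func:`rdfd.fatigue.apply_selection_rule`.
    """
    return pd.DataFrame(
        {
            "window_s": [30.0, 60.0, 120.0, 180.0, 240.0, 300.0],
            "sig_f": [0.009, 0.011, 0.012, 0.022, 0.103, 0.142],
            "f": [112.6, 82.2, 54.7, 45.3, 38.9, 21.8],
        }
    )
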