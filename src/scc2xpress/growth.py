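"""Maximal specific growth rate from OD time series.

mu_max is estimated by sliding-window log-linear regression: for every
window of consecutive time points the slope of ln(OD) versus time (per
hour) is fitted, and the steepest well-fitting window wins.  Windows whose
log-linear fit explains little of the variance (r^2 below a threshold) are
excluded as candidates because at low OD additive plate-reader noise
dominates ln(OD) and would otherwise drive the maximum; when no window
passes the threshold all windows are considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_WINDOW_POINTS = 5
DEFAULT_MIN_R_SQUARED = 0.95


@dataclass
class GrowthCurve:
    """OD600 versus time (minutes) for one strain/condition/replicate."""

    times: np.ndarray  # minutes, strictly increasing
    od: np.ndarray
    strain: str = ""
    condition: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.od = np.asarray(self.od, dtype=np.float64)
        if self.times.size != self.od.size:
            raise ValueError("times and od must have equal length")
        if self.times.size < 5:
            raise ValueError("need >= 5 time points for rate estimation")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class GrowthRateResult:
    mu_max: float  # per hour
    window: tuple[float, float]  # minutes
    r_squared: float
    strain: str = ""
    condition: str = ""


def max_growth_rate(
    curve: GrowthCurve,
    window_points: int = DEFAULT_WINDOW_POINTS,
    blank: float | str = 0.0,
    min_r_squared: float = DEFAULT_MIN_R_SQUARED,
) -> GrowthRateResult:
    """Maximal specific growth rate (per hour) of one curve.

    ``blank`` is subtracted from all OD values before fitting: a float
    (default 0 for pre-blanked data) or ``"first"`` to use the first
    time point.  Windows containing non-positive blanked OD are skipped.
    """
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    if curve.times.size < window_points:
        raise ValueError("fewer time points than the window")
    offset = curve.od[0] if blank == "first" else float(blank)
    od = curve.od - offset
    t_h = curve.times / 60.0

    candidates: list[tuple[float, float, tuple[float, float]]] = []
    for i in range(od.size - window_points + 1):
        y = od[i : i + window_points]
        if np.any(y <= 0):
            continue
        x = t_h[i : i + window_points]
        logy = np.log(y)
        if np.ptp(logy) == 0.0:
            slope, r2 = 0.0, 1.0  # flat window: exact zero-growth fit
        else:
            fit = stats.linregress(x, logy)
            slope, r2 = float(fit.slope), float(fit.rvalue**2)
        candidates.append((slope, r2, (curve.times[i], curve.times[i + window_points - 1])))
    if not candidates:
        raise ValueError("no window with positive OD values")

    qualified = [c for c in candidates if c[1] >= min_r_squared]
    pool = qualified if qualified else candidates
    slope, r2, window = max(pool, key=lambda c: c[0])
    return GrowthRateResult(
        mu_max=slope, window=window, r_squared=r2,
        strain=curve.strain, condition=curve.condition,
    )


def relative_growth(test: GrowthRateResult, reference: GrowthRateResult) -> float:
    """Test growth rate as a percentage of the reference (reference = 100%)."""
    if reference.mu_max <= 0:
        raise ValueError("reference mu_max must be > 0")
    return 100.0 * test.mu_max / reference.mu_max
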