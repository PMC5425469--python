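"""Weekly heat-index exposure: HI computation, category assignment, splines.

The heat index (HI, apparent temperature in °F) is the NWS Rothfusz
regression — a 9-coefficient polynomial in temperature and relative
humidity — with the two standard NWS adjustments (a low-humidity
subtraction and a high-humidity addition).  It is defined here only for
weekly average temperatures of 80 °F and above, matching its calibration
range.

Every modelled plant-week falls in exactly one exposure category:

=========  ==========  ===============================
axis       label       bounds (°F, integer-rounded)
=========  ==========  ===============================
BASELINE   baseline    weekly t_avg 54–79, t_min > 50
HI         moderate    HI 80–84
HI         hot         HI 85–92
HI         very_hot    HI 93–106
MIN_TEMP   cool        weekly mean t_min 40–50
MIN_TEMP   cold        weekly mean t_min 10–39
MIN_TEMP   very_cold   weekly mean t_min −17–9
=========  ==========  ===============================

Values outside the calibrated ranges (HI above 106 °F, minimum temperature
below −17 °F) raise :class:`OutOfCalibrationError`; the pipeline excludes
such weeks with a logged reason rather than extrapolating.

A smoothing-spline explorer estimates the per-head condemnation intensity
as a function of a continuous predictor, with head counts as weights (the
offset-as-weight reading of a log-total offset), and suggests high-curvature
cutpoints.  It is advisory; the pipeline's defaults use the fixed bounds
above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline


class OutOfCalibrationError(ValueError):
    """Exposure value outside the range the category scheme was built on."""


@dataclass(frozen=True)
class HeatIndexValue:
    hi: float | None
    valid: bool


@dataclass(frozen=True)
class ExposureCategory:
    axis: str      # HI | MIN_TEMP | BASELINE
    label: str     # baseline, moderate, hot, very_hot, cool, cold, very_cold
    lo: float      # °F, inclusive on the rounded scale
    hi_bound: float


#: Fixed category scheme; bounds compared on °F rounded half-up to integers.
CATEGORY_SCHEME = {
    ("HI", "moderate"): (80, 84),
    ("HI", "hot"): (85, 92),
    ("HI", "very_hot"): (93, 106),
    ("MIN_TEMP", "cool"): (40, 50),
    ("MIN_TEMP", "cold"): (10, 39),
    ("MIN_TEMP", "very_cold"): (-17, 9),
    ("BASELINE", "baseline"): (54, 79),
}

HI_LABELS = ("moderate", "hot", "very_hot")
COLD_LABELS = ("cool", "cold", "very_cold")
ALL_LABELS = ("baseline",) + HI_LABELS + COLD_LABELS


def override_category_bounds(overrides: dict) -> dict:
    """Replace bounds for selected (axis, label) pairs; returns the old ones.

    ``overrides`` maps ``"AXIS/label"`` (or ``(axis, label)`` tuples) to a
    ``(lo, hi)`` pair in °F — e.g. widening the baseline to 50–79 °F.  The
    caller is responsible for restoring the returned previous bounds.
    """
    previous = {}
    for key, bounds in overrides.items():
        k = tuple(key.split("/")) if isinstance(key, str) else tuple(key)
        if k not in CATEGORY_SCHEME:
            raise KeyError(f"unknown category {k}")
        lo, hi = bounds
        if lo > hi:
            raise ValueError(f"bounds for {k} are reversed: {bounds}")
        previous[k] = CATEGORY_SCHEME[k]
        CATEGORY_SCHEME[k] = (lo, hi)
    return previous


def _cat(axis: str, label: str) -> ExposureCategory:
    lo, hi = CATEGORY_SCHEME[(axis, label)]
    return ExposureCategory(axis=axis, label=label, lo=lo, hi_bound=hi)


def _round_deg(x: float) -> int:
    # half-up rounding so the printed integer bin labels tile the line
    return int(np.floor(float(x) + 0.5))


# Rothfusz regression coefficients (°F, %RH).
_C = (
    -42.379,
    2.04901523,
    10.14333127,
    -0.22475541,
    -6.83783e-3,
    -5.481717e-2,
    1.22874e-3,
    8.5282e-4,
    -1.99e-6,
)


def rothfusz_regression(t, rh):
    """Raw 9-term Rothfusz polynomial with NWS adjustments (vectorised)."""
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    c = _C
    h = (
        c[0]
        + c[1] * t
        + c[2] * rh
        + c[3] * t * rh
        + c[4] * t * t
        + c[5] * rh * rh
        + c[6] * t * t * rh
        + c[7] * t * rh * rh
        + c[8] * t * t * rh * rh
    )
    low = (rh < 13) & (t >= 80) & (t <= 112)
    adj_low = ((13 - rh) / 4.0) * np.sqrt(np.clip(17 - np.abs(t - 95), 0, None) / 17.0)
    high = (rh > 85) & (t >= 80) & (t <= 87)
    adj_high = ((rh - 85) / 10.0) * ((87 - t) / 5.0)
    return h - np.where(low, adj_low, 0.0) + np.where(high, adj_high, 0.0)


def heat_index(t: float, rh: float) -> HeatIndexValue:
    """Heat index for a weekly average temperature and relative humidity.

    Returns an invalid marker for t below 80 °F, where the regression is
    not calibrated; relative humidity outside [0, 100] is a hard error.
    """
    if not 0.0 <= rh <= 100.0:
        raise ValueError(f"relative humidity {rh} outside [0, 100]")
    if not np.isfinite(t):
        raise ValueError("temperature must be finite")
    if t < 80.0:
        return HeatIndexValue(hi=None, valid=False)
    return HeatIndexValue(hi=float(rothfusz_regression(t, rh)), valid=True)


def categorize_hi(hi: HeatIndexValue) -> ExposureCategory:
    """Bin a valid heat index into moderate / hot / very_hot."""
    if not hi.valid or hi.hi is None:
        raise ValueError("heat index is not valid (t_avg below 80 °F)")
    d = _round_deg(hi.hi)
    for label in HI_LABELS:
        lo, hi_b = CATEGORY_SCHEME[("HI", label)]
        if lo <= d <= hi_b:
            return _cat("HI", label)
    top = CATEGORY_SCHEME[("HI", "very_hot")][1]
    if d > top:
        raise OutOfCalibrationError(f"heat index {hi.hi:.1f} °F above {top} °F")
    # HI below 80 with t_avg >= 80 happens at very low humidity; treat as
    # the mildest heat bin rather than inventing an eighth category.
    return _cat("HI", "moderate")


def categorize_min_temp(t_min_week: float, t_avg_week: float) -> ExposureCategory | None:
    """Bin a weekly mean minimum temperature into the cold axis or baseline.

    Returns ``None`` when the week belongs on the HI axis instead
    (t_min above 50 °F with a hot weekly average).
    """
    if not (np.isfinite(t_min_week) and np.isfinite(t_avg_week)):
        raise ValueError("inputs must be finite")
    d_min = _round_deg(t_min_week)
    d_avg = _round_deg(t_avg_week)
    cold_top = CATEGORY_SCHEME[("MIN_TEMP", "cool")][1]
    cold_bottom = CATEGORY_SCHEME[("MIN_TEMP", "very_cold")][0]
    base_lo, base_hi = CATEGORY_SCHEME[("BASELINE", "baseline")]
    if d_min <= cold_top:
        for label in COLD_LABELS:
            lo, hi_b = CATEGORY_SCHEME[("MIN_TEMP", label)]
            if lo <= d_min <= hi_b:
                return _cat("MIN_TEMP", label)
        raise OutOfCalibrationError(
            f"weekly minimum {t_min_week:.1f} °F below {cold_bottom} °F"
        )
    if base_lo <= d_avg <= base_hi:
        return _cat("BASELINE", "baseline")
    if t_avg_week >= 80.0 or d_avg > base_hi:
        return None  # HI axis
    raise OutOfCalibrationError(
        f"warm-minimum week with average {t_avg_week:.1f} °F below {base_lo} °F"
    )


def classify_week(t_avg_week: float, t_min_week: float, rh_week: float):
    """Exhaustive, disjoint assignment of one plant-week to one category.

    Returns ``(ExposureCategory, None)`` or ``(None, reason)`` when the
    week is excluded (out-of-calibration exposure).
    """
    try:
        cat = categorize_min_temp(t_min_week, t_avg_week)
    except OutOfCalibrationError as e:
        return None, str(e)
    if cat is not None:
        return cat, None
    # warm week: evaluate HI from weekly average temperature and humidity
    hi = heat_index(max(t_avg_week, 80.0), rh_week)
    try:
        return categorize_hi(hi), None
    except OutOfCalibrationError as e:
        return None, str(e)


@dataclass(frozen=True)
class SplineFit:
    grid: np.ndarray            # predictor values, °F
    intensity: np.ndarray       # fitted condemnations per head on the grid
    smoothing: float | None     # lam passed to the smoother (None = GCV)
    offset_used: bool


def fit_offset_spline(x, y, total, smoothing: float | None = None) -> SplineFit:
    """Cubic smoothing spline of the per-head condemnation rate.

    The log-total offset of the count model is operationalised as smoothing
    the rate ``y/total`` with weights ``total``, so high-volume plant-weeks
    dominate the fit.  ``smoothing`` is the penalty lam; when omitted it is
    chosen by generalized cross-validation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(total < 1):
        raise ValueError("every record needs total >= 1 head")
    if np.unique(x).size < 10:
        raise ValueError("need at least 10 distinct predictor values")
    rate = y / total
    order = np.argsort(x, kind="stable")
    x, rate, total = x[order], rate[order], total[order]
    # collapse duplicate abscissae to their weighted mean rate
    ux, inv = np.unique(x, return_inverse=True)
    w = np.bincount(inv, weights=total)
    r = np.bincount(inv, weights=rate * total) / w
    spl = make_smoothing_spline(ux, r, w=w, lam=smoothing)
    grid = np.linspace(ux[0], ux[-1], 257)
    intensity = np.clip(spl(grid), 0.0, None)
    return SplineFit(grid=grid, intensity=intensity, smoothing=smoothing,
                     offset_used=True)


def suggest_breakpoints(fit: SplineFit, k: int):
    """``k`` advisory cutpoints at the largest-curvature grid positions.

    Falls back to evenly spaced quantiles of the grid when the fitted curve
    is flat (no curvature signal).  Pipeline defaults always use the fixed
    published bounds; this explorer only justifies them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grid, f = fit.grid, fit.intensity
    if k > grid.size - 2:
        raise ValueError("k exceeds grid support")
    d2 = np.gradient(np.gradient(f, grid), grid)
    curv = np.abs(d2)
    span = grid[-1] - grid[0]
    scale = max(np.max(np.abs(f)), 1e-300)
    if np.max(curv) * span**2 < 1e-6 * scale:
        qs = np.linspace(0, 1, k + 2)[1:-1]
        return list(np.quantile(grid, qs))
    # local maxima of curvature, strongest first
    interior = np.arange(1, grid.size - 1)
    is_peak = (curv[interior] >= curv[interior - 1]) & (
        curv[interior] >= curv[interior + 1]
    )
    peaks = interior[is_peak]
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(curv))])
    order = peaks[np.argsort(curv[peaks])[::-1]]
    chosen: list[float] = []
    min_sep = span / (4.0 * (k + 1))
    for idx in order:
        pos = grid[idx]
        if all(abs(pos - c) >= min_sep for c in chosen):
            chosen.append(float(pos))
        if len(chosen) == k:
            break
    return sorted(chosen)
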