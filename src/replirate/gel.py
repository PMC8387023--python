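"""Densitometry of alkaline-gel lane profiles: fork-length and fork-rate calls.

Inputs are already-extracted 1-D lane profiles (position ascending with
migration, so base-pair size decreasing). The procedure is: decode the
stored signal to linear intensity, calibrate migration to base pairs with an
exponential ladder fit ``bp(x) = a * exp(-b x)``, smooth each lane with a
local-regression smoother, subtract a low-percentile background, call the
leading fork length as the high-molecular-weight position where the signal
first reaches 20% of the lane maximum (with sub-bin interpolation of the
crossing), and fit leading length against time by ordinary least squares;
the slope is the fork rate in kb/min. ``percent_change`` compares two
condition rates as a percent slowdown.

The 20% crossing is taken from the large-product side of the smear: the
leading fork length means the longest well-populated products, so the scan
starts at the smallest migration. Background is the 2nd percentile of the
smoothed lane. The rate fit keeps a free intercept by default (initiation
lag precedes elongation); forcing the line through the origin is an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.signal import find_peaks
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError
from .simulate import LaneProfileSet

DEFAULT_SMOOTHING_SPAN = 0.02
DEFAULT_EDGE_THRESHOLD = 0.2
BACKGROUND_PERCENTILE = 2.0


def linearize_signal(values: np.ndarray, encoding: str = "linear") -> np.ndarray:
    """Decode stored lane values to linear intensity.

    "linear" is the identity; "sqrt" squares the values (phosphorimager
    exports store square-root-compressed counts) and then subtracts the
    minimum as a baseline.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValidationError("negative values in stored lane signal")
    if encoding == "linear":
        return values.copy()
    if encoding == "sqrt":
        out = values * values
        return out - out.min()
    raise ValidationError(f"unknown encoding {encoding!r}")


@dataclass(frozen=True)
class CalibrationFit:
    """Exponential migration-to-size calibration bp(x) = a * exp(-b x)."""

    a: float
    b: float
    residual_rms: float  # on log(bp)
    n_bands: int

    def bp(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.exp(-self.b * np.asarray(x, dtype=float))

    def x(self, bp: np.ndarray | float) -> np.ndarray | float:
        return np.log(self.a / np.asarray(bp, dtype=float)) / self.b


def calibrate_ladder(
    peak_positions: Sequence[float], band_sizes_bp: Sequence[float]
) -> CalibrationFit:
    """Least-squares fit of ln(bp) = ln(a) - b*x through the ladder bands."""
    x = np.asarray(peak_positions, dtype=float)
    bp = np.asarray(band_sizes_bp, dtype=float)
    if x.size != bp.size:
        raise ValidationError("peak positions and band sizes differ in length")
    if x.size < 3:
        raise ValidationError("at least 3 ladder bands are required")
    if np.any(np.diff(x) <= 0):
        raise ValidationError("ladder peak positions must be strictly ascending")
    if np.any(np.diff(bp) >= 0):
        raise ValidationError("ladder band sizes must be strictly descending")
    slope, intercept = np.polyfit(x, np.log(bp), 1)
    b = -slope
    if b <= 0:
        raise ValidationError("calibration fit is not decreasing (b <= 0)")
    resid = np.log(bp) - (intercept + slope * x)
    return CalibrationFit(
        a=float(np.exp(intercept)),
        b=float(b),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_bands=int(x.size),
    )


def detect_ladder_peaks(ladder: np.ndarray, n_bands: int) -> np.ndarray:
    """Positions of the ``n_bands`` most prominent peaks, ascending."""
    ladder = np.asarray(ladder, dtype=float)
    peaks, props = find_peaks(ladder, prominence=0.0)
    if peaks.size < n_bands:
        raise ValidationError(
            f"found only {peaks.size} ladder peaks, expected {n_bands}"
        )
    top = peaks[np.argsort(props["prominences"])[::-1][:n_bands]]
    return np.sort(top).astype(float)


def smooth_lane(values: np.ndarray, span: float = DEFAULT_SMOOTHING_SPAN) -> np.ndarray:
    """Local-regression (lowess) smoothing with a span given as a fraction of
    the profile length; output is clipped at zero.

    Robustness reweighting is disabled: on lane profiles it treats sharp
    bands as outliers and destabilises the leading-edge call.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 20:
        raise ValidationError("lane profile shorter than 20 positions")
    if not 0 < span <= 0.5:
        raise ValidationError("smoothing span must lie in (0, 0.5]")
    x = np.arange(values.size, dtype=float)
    sm = lowess(values, x, frac=span, it=0, return_sorted=False)
    return np.clip(sm, 0.0, None)


def call_leading_length(
    smoothed: np.ndarray,
    calibration: CalibrationFit,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> tuple[float, list[str]]:
    """Leading fork length: bp at the first crossing of ``threshold`` x lane
    maximum, scanning from the large-product (small-migration) end.

    The 2nd-percentile background of the smoothed lane is subtracted before
    thresholding. The crossing position is refined by linear interpolation
    between the bracketing bins. Returns (length_bp, qc_flags).
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must lie in (0, 1]")
    sm = np.asarray(smoothed, dtype=float)
    sm = np.clip(sm - np.percentile(sm, BACKGROUND_PERCENTILE), 0.0, None)
    peak = sm.max()
    if peak <= 0:
        raise ValidationError("lane is empty after background subtraction")
    level = threshold * peak
    above = sm >= level
    if not above.any():
        raise ValidationError("threshold crossing not found")
    idx = int(np.argmax(above))
    flags = []
    if idx == 0:
        flags.append("leading edge at the profile start; length may be truncated")
        x_cross = 0.0
    else:
        y0, y1 = sm[idx - 1], sm[idx]
        x_cross = (idx - 1) + (level - y0) / (y1 - y0)
    return float(calibration.bp(x_cross)), flags


@dataclass
class ForkLengthSeries:
    """Leading fork length per timepoint."""

    timepoints: tuple[float, ...]
    lengths_bp: tuple[float, ...]
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ForkRateFit:
    """OLS fit of leading length (kb) against time (min)."""

    slope: float  # kb/min
    intercept: float  # kb
    stderr: float
    r_squared: float
    n_points: int


def fit_fork_rate(series: ForkLengthSeries, through_origin: bool = False) -> ForkRateFit:
    """Ordinary least squares of leading length (kb) on time (min)."""
    t = np.asarray(series.timepoints, dtype=float)
    y = np.asarray(series.lengths_bp, dtype=float) / 1000.0
    if t.size < 2:
        raise ValidationError("at least 2 timepoints are required for the rate fit")
    if np.unique(t).size < 2:
        raise ValidationError("timepoints are all identical")
    if through_origin:
        slope = float(np.sum(t * y) / np.sum(t * t))
        resid = y - slope * t
        dof = t.size - 1
        stderr = float(np.sqrt(np.sum(resid**2) / dof / np.sum(t * t))) if dof else 0.0
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        return ForkRateFit(slope, 0.0, stderr, max(0.0, r2), int(t.size))
    res = stats.linregress(t, y)
    return ForkRateFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=int(t.size),
    )


def percent_change(rate_ref: float, rate_alt: float) -> float:
    """Percent slowdown of ``rate_alt`` relative to ``rate_ref``."""
    if rate_ref <= 0:
        raise ValidationError("reference rate must be > 0")
    return 100.0 * (rate_ref - rate_alt) / rate_ref


@dataclass
class GelAnalysis:
    """Full densitometry result for one lane set."""

    calibration: CalibrationFit
    series: ForkLengthSeries
    fit: ForkRateFit


def analyze_lane_set(
    lane_set: LaneProfileSet,
    span: float = DEFAULT_SMOOTHING_SPAN,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
    through_origin: bool = False,
) -> GelAnalysis:
    """Linearize, calibrate on the ladder, smooth, call edges, fit the rate."""
    ladder_lin = linearize_signal(lane_set.ladder, lane_set.encoding)
    ladder_sm = smooth_lane(ladder_lin, span)
    peak_pos = detect_ladder_peaks(ladder_sm, len(lane_set.ladder_bands))
    calibration = calibrate_ladder(peak_pos, lane_set.ladder_bands)
    times, lengths, flags = [], [], []
    for t, raw in lane_set.lanes:
        lin = linearize_signal(raw, lane_set.encoding)
        sm = smooth_lane(lin, span)
        length, lane_flags = call_leading_length(sm, calibration, threshold)
        times.append(t)
        lengths.append(length)
        flags.extend(f"lane t={t:g}: {f}" for f in lane_flags)
    series = ForkLengthSeries(
        timepoints=tuple(times), lengths_bp=tuple(lengths), flags=flags
    )
    return GelAnalysis(
        calibration=calibration,
        series=series,
        fit=fit_fork_rate(series, through_origin=through_origin),
    )
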