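"""Unwinding-rate estimation from restriction-protection qPCR plates.

The chain mirrors the assay's quantification: triplicate wells are averaged
per (site, timepoint) cell; cell means are divided by the control-amplicon
mean of the same sample, cancelling the shared loading factor exactly; the
ratios are rescaled by the last-timepoint value of the closest site, which
defines full unwinding; each site's time course is made monotone (isotonic
regression) and interpolated with a shape-preserving monotone cubic; the
mean arrival time at site ``d`` is the integral

    tau_d = integral_0^T (1 - f_d(t)) dt

of the fitted curve (trapezoid quadrature on a 0.1-min grid), giving a site
rate ``d / tau_d``; the reported rate is the arithmetic mean over the three
most distal sites. The arrival-time integral is the unique reading of
"integrate the fitted curve" with bp/min units: it is exact on step curves
and, under asynchronous activation with mean delay ``m``, gives
``tau_d = d / v_net + m``, so site rates increase with distance toward the
true net velocity — averaging distal sites keeps the activation-delay bias
small. The 95% confidence interval resamples replicates within each cell
with replacement and reruns the whole chain (percentile interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import isotonic_regression

from .errors import ValidationError

CONTROL_LABEL = "control"
CLIP_MAX = 1.25
WARN_ABOVE = 1.05
QUADRATURE_STEP_MIN = 0.1
SATURATION_FRACTION = 0.8


def quantities_from_cq(cq_table: pd.DataFrame, cq_ref: float) -> pd.DataFrame:
    """Convert a raw quantification-cycle table to relative quantities.

    ``quantity = 2**(cq_ref - Cq)`` with a declared reference cycle,
    assuming perfect doubling per cycle. Input columns: site_label,
    timepoint_min, replicate, Cq (plus any passthrough columns).
    """
    if "Cq" not in cq_table.columns:
        raise ValidationError("Cq table is missing the 'Cq' column")
    out = cq_table.drop(columns=["Cq"]).copy()
    out["quantity"] = np.exp2(cq_ref - cq_table["Cq"].to_numpy(dtype=float))
    return out


def summarize_triplicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Mean quantity and replicate CV per (site_label, timepoint) cell.

    Requires at least two replicates per cell and a complete
    site x timepoint grid. CV uses the sample (n-1) standard deviation.
    """
    required = {"site_label", "timepoint_min", "replicate", "quantity"}
    if not required <= set(plate.columns):
        raise ValidationError(
            f"plate is missing columns {sorted(required - set(plate.columns))}"
        )
    if (plate["quantity"] <= 0).any():
        raise ValidationError("plate contains non-positive quantities")
    g = plate.groupby(["site_label", "timepoint_min"])["quantity"]
    summary = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    single = summary[summary["n"] < 2]
    if not single.empty:
        row = single.iloc[0]
        raise ValidationError(
            f"cell (site {row['site_label']}, t={row['timepoint_min']:g}) has a "
            "single replicate; at least two are required"
        )
    sites = summary["site_label"].unique()
    times = summary["timepoint_min"].unique()
    if len(summary) != len(sites) * len(times):
        raise ValidationError("plate grid is incomplete: missing (site, timepoint) cells")
    summary["cv"] = summary["sd"] / summary["mean"]
    return summary[["site_label", "timepoint_min", "mean", "cv", "n"]]


def normalize_to_control(
    cell_means: pd.DataFrame, control_label: str = CONTROL_LABEL
) -> pd.DataFrame:
    """Divide each site's cell mean by the control-amplicon mean of the same
    sample (timepoint). Returns rows for non-control sites only."""
    if control_label not in set(cell_means["site_label"]):
        raise ValidationError(f"no {control_label!r} amplicon in the plate")
    control = (
        cell_means[cell_means["site_label"] == control_label]
        .set_index("timepoint_min")["mean"]
    )
    bad = control[control <= 0]
    if not bad.empty:
        raise ValidationError(
            f"control mean is not positive at timepoint {bad.index[0]:g}"
        )
    out = cell_means[cell_means["site_label"] != control_label].copy()
    missing = set(out["timepoint_min"]) - set(control.index)
    if missing:
        raise ValidationError(
            f"control amplicon missing at timepoint {sorted(missing)[0]:g}"
        )
    out["ratio"] = out["mean"].to_numpy() / control.loc[out["timepoint_min"]].to_numpy()
    return out[["site_label", "timepoint_min", "ratio", "cv"]]


@dataclass
class NormalizedCurves:
    """Control- and reference-normalized unwound-fraction curves."""

    sites: tuple[int, ...]
    timepoints: tuple[float, ...]
    f_hat: np.ndarray  # shape (n_sites, n_timepoints)
    reference_site: int
    qc_cv: np.ndarray  # replicate CVs, same shape
    flags: list[str] = field(default_factory=list)


def normalize_to_reference(
    ratios: pd.DataFrame,
    reference_site: int | None = None,
    reference_value: str = "fitted",
) -> NormalizedCurves:
    """Rescale control-normalized ratios by the last-timepoint value of the
    reference (closest) site, which defines the fully unwound level.

    The curves are fitted before normalization, so with the default
    ``reference_value="fitted"`` the normalizer is the isotonically fitted
    reference curve evaluated at the last timepoint — this pools the
    reference site's plateau cells and keeps a single noisy well from
    rescaling every curve (``"raw"`` uses the bare last-timepoint ratio).
    Values are clipped to [0, 1.25]; values above 1.05 raise a warning flag.
    """
    sites = sorted(int(s) for s in ratios["site_label"].unique())
    if len(sites) != len(set(sites)):
        raise ValidationError("duplicate site distances")
    if reference_site is None:
        reference_site = sites[0]
    if reference_site not in sites:
        raise ValidationError(f"reference site {reference_site} not in plate")
    times = np.sort(ratios["timepoint_min"].unique())
    wide = ratios.pivot_table(
        index="site_label", columns="timepoint_min", values="ratio", aggfunc="first"
    )
    cv = ratios.pivot_table(
        index="site_label", columns="timepoint_min", values="cv", aggfunc="first"
    )
    wide.index = wide.index.astype(int)
    cv.index = cv.index.astype(int)
    wide = wide.loc[sites, times]
    cv = cv.loc[sites, times]
    if reference_value == "fitted":
        ref_last = _reference_plateau(wide.loc[reference_site, times].to_numpy())
    elif reference_value == "raw":
        ref_last = float(wide.loc[reference_site, times[-1]])
    else:
        raise ValidationError(f"unknown reference_value {reference_value!r}")
    if ref_last <= 0:
        raise ValidationError(
            f"reference site {reference_site} has non-positive ratio at the last timepoint"
        )
    f_hat = wide.to_numpy() / ref_last
    flags = []
    n_high = int((f_hat > WARN_ABOVE).sum())
    if n_high:
        flags.append(
            f"{n_high} normalized values exceed {WARN_ABOVE:g} (max {f_hat.max():.3f}); "
            f"clipped to {CLIP_MAX:g}"
        )
    f_hat = np.clip(f_hat, 0.0, CLIP_MAX)
    return NormalizedCurves(
        sites=tuple(sites),
        timepoints=tuple(float(t) for t in times),
        f_hat=f_hat,
        reference_site=int(reference_site),
        qc_cv=cv.to_numpy(),
        flags=flags,
    )


def _reference_plateau(ref_values: np.ndarray) -> float:
    """Fitted unwound-DNA level of the reference site at the last timepoint.

    The isotonic fit of the reference curve locates the saturated region
    (fitted values within 5% of the final level); the plateau level is the
    mean of the raw ratios there. Averaging the plateau cells keeps the
    replicate noise of a single well from rescaling every curve, and avoids
    the upward bias of the raw isotonic fit at the last knot (which tracks
    the largest plateau fluctuation).
    """
    iso = isotonic_regression(np.asarray(ref_values, dtype=float)).x
    if iso[-1] <= 0:
        return float(iso[-1])
    mask = iso >= 0.95 * iso[-1]
    return float(np.asarray(ref_values, dtype=float)[mask].mean())


@dataclass
class SplineFit:
    """Monotone shape-preserving interpolant of one site's time course.

    Values are bounded in [0, 1.25] rather than [0, 1]: a fully unwound site
    fluctuates symmetrically about 1 under replicate noise, and truncating
    the fluctuation at 1 would turn it into a one-sided inflation of the
    arrival-time integral (the plateau sits below 1 more often than above).
    """

    timepoints: np.ndarray
    values: np.ndarray  # after isotonic regression and clipping
    _interp: PchipInterpolator

    @property
    def t_max(self) -> float:
        return float(self.timepoints[-1])

    @property
    def t_min(self) -> float:
        return float(self.timepoints[0])

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.t_min - 1e-12) or np.any(t_arr > self.t_max + 1e-12):
            raise ValidationError(
                f"evaluation outside [{self.t_min:g}, {self.t_max:g}]: no extrapolation"
            )
        out = np.clip(self._interp(np.clip(t_arr, self.t_min, self.t_max)), 0.0, CLIP_MAX)
        return float(out) if np.isscalar(t) else out


def fit_site_spline(
    timepoints: Sequence[float], values: Sequence[float]
) -> SplineFit:
    """Isotonic regression (pool adjacent violators) followed by a monotone
    piecewise-cubic (PCHIP) interpolant, clipped to [0, 1] on evaluation."""
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValidationError("at least 4 timepoints are required for the spline fit")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("timepoints must be strictly ascending (no duplicates)")
    iso = isotonic_regression(y).x
    iso = np.clip(iso, 0.0, CLIP_MAX)
    return SplineFit(timepoints=t, values=iso, _interp=PchipInterpolator(t, iso))


@dataclass
class RateEstimate:
    """Unwinding-rate estimate with per-site arrival times and optional CI."""

    rate: float  # bp/min
    per_site: list[tuple[int, float, float]]  # (site bp, tau min, rate bp/min)
    sites_used: tuple[int, ...]
    ci: tuple[float, float] | None = None
    ci_level: float = 0.95
    n_bootstrap: int = 0
    seed: int | None = None
    flags: list[str] = field(default_factory=list)


def estimate_unwinding_rate(
    fits: Mapping[int, Callable],
    sites_used: Sequence[int] | None = None,
    t_max: float | None = None,
    grid_step: float = QUADRATURE_STEP_MIN,
) -> RateEstimate:
    """Integral arrival-time estimator averaged over the distal sites.

    ``fits`` maps site distance (bp) to a curve evaluable on [0, t_max].
    Defaults: the three largest distances; ``t_max`` from the fit objects.
    """
    if not fits:
        raise ValidationError("no fitted sites")
    if sites_used is None:
        sites_used = sorted(fits)[-3:]
    sites_used = [int(s) for s in sites_used]
    if not sites_used:
        raise ValidationError("sites_used is empty")
    unknown = set(sites_used) - set(fits)
    if unknown:
        raise ValidationError(f"sites_used not among fitted sites: {sorted(unknown)}")
    if t_max is None:
        t_max = min(f.t_max for f in fits.values() if hasattr(f, "t_max"))
    grid = np.arange(0.0, t_max + grid_step / 2, grid_step)
    grid[-1] = t_max
    per_site = []
    flags = []
    for d in sites_used:
        # allow f > 1 (bounded by CLIP_MAX) so that symmetric plateau noise
        # cancels in the integral instead of inflating the arrival time
        f = np.clip(np.asarray(fits[d](grid), dtype=float), 0.0, CLIP_MAX)
        tau = float(np.trapezoid(1.0 - f, grid))
        if tau <= 0:
            raise ValidationError(f"site {d}: non-positive arrival time")
        if f[-1] < SATURATION_FRACTION:
            flags.append(
                f"non-saturated: site {d} reaches only {f[-1]:.2f} by t={t_max:g} min; "
                "arrival time is truncated and the rate biased upward"
            )
        per_site.append((d, tau, d / tau))
    rate = float(np.mean([r for _, _, r in per_site]))
    return RateEstimate(
        rate=rate, per_site=per_site, sites_used=tuple(sites_used), flags=flags
    )


def _plate_array(
    plate: pd.DataFrame,
) -> tuple[np.ndarray, list[str], np.ndarray, int]:
    """Reshape a plate into (n_labels, n_timepoints, n_replicates) with a
    deterministic (sorted) cell order. Requires a balanced design."""
    counts = plate.groupby(["site_label", "timepoint_min"])["quantity"].count()
    n_rep = int(counts.iloc[0])
    if (counts != n_rep).any():
        raise ValidationError("unbalanced replicate counts across cells")
    plate_sorted = plate.sort_values(
        ["site_label", "timepoint_min", "replicate"], kind="mergesort"
    )
    labels = sorted(plate["site_label"].unique())
    times = np.sort(plate["timepoint_min"].unique())
    q = plate_sorted["quantity"].to_numpy().reshape(len(labels), len(times), n_rep)
    return q, labels, times, n_rep


def _rate_from_cell_means(
    means: np.ndarray,
    site_labels: list[str],
    times: np.ndarray,
    sites_used: Sequence[int],
    reference_site: int | None,
    control_label: str,
    anchor_zero: bool,
) -> float:
    """Array fast path of the normalization + spline + integral chain, used
    by the bootstrap. Must agree with analyze_plate on unresampled means."""
    if control_label not in site_labels:
        raise ValidationError(f"no {control_label!r} amplicon in the plate")
    ctrl = means[site_labels.index(control_label)]
    if np.any(ctrl <= 0):
        raise ValidationError("control mean is not positive")
    site_idx = {int(l): i for i, l in enumerate(site_labels) if l != control_label}
    ref = reference_site if reference_site is not None else min(site_idx)
    ratios = {d: means[i] / ctrl for d, i in site_idx.items()}
    ref_last = _reference_plateau(ratios[ref])
    if ref_last <= 0:
        raise ValidationError("reference ratio is not positive at the last timepoint")
    t = times.astype(float)
    if anchor_zero and t[0] > 0:
        t = np.concatenate(([0.0], t))
    grid = np.arange(0.0, t[-1] + QUADRATURE_STEP_MIN / 2, QUADRATURE_STEP_MIN)
    grid[-1] = t[-1]
    site_rates = []
    for d in sites_used:
        y = np.clip(ratios[d] / ref_last, 0.0, CLIP_MAX)
        if anchor_zero and times[0] > 0:
            y = np.concatenate(([0.0], y))
        iso = np.clip(isotonic_regression(y).x, 0.0, CLIP_MAX)
        f = np.clip(PchipInterpolator(t, iso)(grid), 0.0, CLIP_MAX)
        tau = float(np.trapezoid(1.0 - f, grid))
        if tau <= 0:
            raise ValidationError(f"site {d}: non-positive arrival time")
        site_rates.append(d / tau)
    return float(np.mean(site_rates))


def _curves_from_plate(
    plate: pd.DataFrame,
    control_label: str = CONTROL_LABEL,
    reference_site: int | None = None,
) -> NormalizedCurves:
    cells = summarize_triplicates(plate)
    ratios = normalize_to_control(cells, control_label=control_label)
    return normalize_to_reference(ratios, reference_site=reference_site)


def _rate_from_curves(
    curves: NormalizedCurves,
    sites_used: Sequence[int] | None,
    anchor_zero: bool,
) -> RateEstimate:
    fits = {}
    for i, d in enumerate(curves.sites):
        t = np.asarray(curves.timepoints)
        y = curves.f_hat[i]
        if anchor_zero and t[0] > 0:
            # no unwinding before activation: anchor the curve at the origin
            t = np.concatenate(([0.0], t))
            y = np.concatenate(([0.0], y))
        fits[d] = fit_site_spline(t, y)
    est = estimate_unwinding_rate(fits, sites_used=sites_used)
    est.flags = curves.flags + est.flags
    return est


def analyze_plate(
    plate: pd.DataFrame,
    sites_used: Sequence[int] | None = None,
    reference_site: int | None = None,
    control_label: str = CONTROL_LABEL,
    anchor_zero: bool = True,
) -> RateEstimate:
    """Run the full chain on one plate (no confidence interval)."""
    curves = _curves_from_plate(plate, control_label, reference_site)
    return _rate_from_curves(curves, sites_used, anchor_zero)


def bootstrap_rate_ci(
    plate: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    sites_used: Sequence[int] | None = None,
    reference_site: int | None = None,
    control_label: str = CONTROL_LABEL,
    anchor_zero: bool = True,
    ci_level: float = 0.95,
    max_failure_fraction: float = 0.1,
    small_sample_correction: bool = True,
) -> RateEstimate:
    """Point estimate from the unresampled chain plus a percentile bootstrap
    CI from resampling replicates within each (site, timepoint) cell.

    With only three replicates per cell the naive resampled cell mean has
    variance (n-1)/n times the true sampling variance, so the raw percentile
    interval is systematically narrow; ``small_sample_correction`` rescales
    the bootstrap draws about their mean by sqrt(n/(n-1)) to undo this.
    """
    if B < 100:
        raise ValidationError("B must be >= 100")
    est = analyze_plate(
        plate,
        sites_used=sites_used,
        reference_site=reference_site,
        control_label=control_label,
        anchor_zero=anchor_zero,
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x626F6F74]))
    # array layout (cells x replicates) in a fixed order so the draw sequence
    # is independent of input row order
    quantities, site_labels, times, n_rep = _plate_array(plate)
    rates = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n_rep, size=quantities.shape)
        means = np.take_along_axis(quantities, idx, axis=-1).mean(axis=-1)
        try:
            rates.append(
                _rate_from_cell_means(
                    means,
                    site_labels,
                    times,
                    sites_used=est.sites_used,
                    reference_site=reference_site,
                    control_label=control_label,
                    anchor_zero=anchor_zero,
                )
            )
        except ValidationError:
            failures += 1
    if failures > max_failure_fraction * B:
        raise ValidationError(
            f"{failures}/{B} bootstrap draws failed; plate is too degenerate for a CI"
        )
    rates = np.asarray(rates)
    if small_sample_correction and n_rep > 1:
        rates = rates.mean() + (rates - rates.mean()) * np.sqrt(n_rep / (n_rep - 1))
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(rates, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    est.ci = (float(lo), float(hi))
    est.ci_level = ci_level
    est.n_bootstrap = B
    est.seed = int(seed)
    if failures:
        est.flags.append(f"{failures}/{B} bootstrap draws failed and were skipped")
    return est


def normalized_curves_frame(curves: NormalizedCurves) -> pd.DataFrame:
    """Long-format table of the normalized curves, for plotting."""
    rows = []
    for i, d in enumerate(curves.sites):
        for j, t in enumerate(curves.timepoints):
            rows.append((d, t, curves.f_hat[i, j], curves.qc_cv[i, j]))
    return pd.DataFrame(rows, columns=["site_bp", "timepoint_min", "f_hat", "replicate_cv"])
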