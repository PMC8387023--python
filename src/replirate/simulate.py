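"""Seeded stochastic generators for the two assay read-outs.

Unwinding side: each template carries one helicase that activates after a
random delay and then translocates as a two-state motor — moving at velocity
``v`` and falling into pauses at rate ``k_in`` (per minute of moving time),
leaving them at rate ``k_out``. Pauses subsume the non-productive
duplex-engaged state; backtracking is not modelled as negative displacement
because the protection assay only observes net forward unwinding. The
long-run net velocity is ``v_net = v * k_out / (k_in + k_out)``. Restriction
digestion at each sampling time is treated as instantaneous: a motif site is
protected exactly when the unwound extent has reached it. The qPCR read-out
multiplies the uncut fraction by a per-sample loading factor (shared by all
amplicons of the sample — the normalization chain is designed to cancel
exactly this term) and per-replicate multiplicative lognormal noise.

Gel side: nascent leading strands elongate at a constant fork rate after a
truncated-normal initiation delay, incorporate label in proportion to their
length, and migrate on a denaturing gel where length maps to position as
``bp(x) = a * exp(-b x)``. Lanes are 1-D intensity profiles: Gaussian band
spread, additive background and multiplicative pixel noise. The pulse-chase
variant fixes a labelled segment at the end of the pulse (constant intensity
per molecule thereafter) and extends products at a strain-specific chase
rate. Stored profiles can be square-root compressed ("sqrt" encoding), the
convention of phosphorimager exports.

All generators derive per-lane/per-plate RNG streams from one root seed by
stable label hashing, so outputs are bit-reproducible and independent of
record ordering.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

MSEI_SITES_BP = (200, 500, 1000, 1500, 2000)
DEFAULT_TIMEPOINTS_MIN = (2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)
LAMBDA_HINDIII_BANDS_BP = (23130.0, 9416.0, 6557.0, 4361.0, 2322.0, 2027.0, 564.0)


def child_rng(seed: int, *labels: object) -> np.random.Generator:
    """A reproducible sub-stream keyed by (seed, labels)."""
    keys = [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


def _lognormal_factors(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


# ---------------------------------------------------------------------------
# two-state unwinding simulator


@dataclass(frozen=True)
class UnwindingParams:
    """Generative parameters of the two-state translocation model.

    Rates are per minute, velocities bp/min, positions bp, times min.
    ``activation_rate`` is the rate of the exponential activation delay
    (None disables the random delay); ``activation_offset`` is an optional
    fixed dead time added to every molecule's delay.
    """

    n_molecules: int = 2000
    v: float = 100.0
    k_in: float = 1.0
    k_out: float = 4.0
    activation_rate: float | None = 2.0
    activation_offset: float = 0.0
    duration: float = 50.0
    sites: tuple[int, ...] = MSEI_SITES_BP
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")
        for name in ("v", "k_in", "k_out", "activation_offset", "duration"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.activation_rate is not None and self.activation_rate < 0:
            raise ValidationError("activation_rate must be >= 0 or None")
        tp = np.asarray(self.timepoints, dtype=float)
        if np.any(np.diff(tp) <= 0):
            raise ValidationError("timepoints must be strictly ascending")
        if tp.size and (tp[0] < 0 or tp[-1] > self.duration):
            raise ValidationError("timepoints must lie within [0, duration]")
        if any(s <= 0 for s in self.sites):
            raise ValidationError("sites must be positive distances in bp")

    @property
    def v_net(self) -> float:
        """Long-run mean velocity of the two-state motor, bp/min."""
        if self.k_in > 0:
            if self.k_out == 0:
                return 0.0
            return self.v * self.k_out / (self.k_in + self.k_out)
        return self.v

    @classmethod
    def from_net_velocity(cls, v_net: float, **kwargs) -> "UnwindingParams":
        """Build params whose net velocity equals ``v_net``, keeping the
        default pause kinetics (duty ratio k_out/(k_in+k_out))."""
        probe = cls(**kwargs)
        duty = (
            probe.k_out / (probe.k_in + probe.k_out) if probe.k_in > 0 else 1.0
        )
        return cls(v=v_net / duty, **kwargs)


@dataclass(frozen=True)
class SiteFractionCurves:
    """Per-site fraction of molecules whose unwound extent has reached the site."""

    sites: tuple[int, ...]
    timepoints: tuple[float, ...]
    fractions: np.ndarray  # shape (n_sites, n_timepoints)

    def __post_init__(self) -> None:
        f = self.fractions
        if f.shape != (len(self.sites), len(self.timepoints)):
            raise ValidationError("fractions shape does not match sites x timepoints")
        if np.any(f < 0) or np.any(f > 1):
            raise ValidationError("fractions must lie in [0, 1]")


def _draw_delays(params: UnwindingParams, rng: np.random.Generator) -> np.ndarray:
    delays = np.full(params.n_molecules, params.activation_offset, dtype=float)
    if params.activation_rate:
        delays += rng.exponential(1.0 / params.activation_rate, params.n_molecules)
    return delays


def _pause_process(
    params: UnwindingParams, max_clock: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pause entries on the moving-time clock, up to ``max_clock`` minutes of
    moving time. Returns (molecule index, entry clock, pause duration)."""
    n = params.n_molecules
    if params.k_in == 0 or max_clock <= 0:
        empty = np.empty(0)
        return empty.astype(int), empty, empty
    counts = rng.poisson(params.k_in * max_clock, n)
    mol = np.repeat(np.arange(n), counts)
    entries = rng.uniform(0.0, max_clock, mol.size)
    if params.k_out == 0:
        pauses = np.full(mol.size, np.inf)
    else:
        pauses = rng.exponential(1.0 / params.k_out, mol.size)
    return mol, entries, pauses


def simulate_unwinding(params: UnwindingParams) -> SiteFractionCurves:
    """Simulate the per-site unwound-fraction time courses.

    A molecule has reached site ``d`` by wall time ``t`` iff its activation
    delay plus ``d / v`` minutes of moving time plus all pauses entered
    before accumulating that moving time fit within ``t``. Positions never
    decrease, so the curves are exactly nondecreasing in time.
    """
    rng = child_rng(params.seed, "unwinding")
    n = params.n_molecules
    sites = np.asarray(params.sites, dtype=float)
    tps = np.asarray(params.timepoints, dtype=float)
    delays = _draw_delays(params, rng)
    if params.v == 0:
        fractions = np.zeros((sites.size, tps.size))
        return SiteFractionCurves(tuple(params.sites), tuple(params.timepoints), fractions)
    max_clock = min(float(sites.max()) / params.v, params.duration)
    mol, entries, pauses = _pause_process(params, max_clock, rng)
    fractions = np.empty((sites.size, tps.size))
    for i, d in enumerate(sites):
        m_needed = d / params.v
        if mol.size:
            mask = entries < m_needed
            pause_sum = np.bincount(mol[mask], weights=pauses[mask], minlength=n)
        else:
            pause_sum = np.zeros(n)
        arrival = delays + m_needed + pause_sum
        fractions[i] = (arrival[None, :] <= tps[:, None]).mean(axis=1)
    return SiteFractionCurves(tuple(params.sites), tuple(params.timepoints), fractions)


def simulate_positions(params: UnwindingParams, at_time: float) -> np.ndarray:
    """Unwound extent (bp) of every molecule at wall time ``at_time``.

    Slower per-molecule path used for checking the long-run velocity; the
    fraction curves use the vectorised arrival-time path instead.
    """
    if not 0 <= at_time <= params.duration:
        raise ValidationError("at_time must lie in [0, duration]")
    rng = child_rng(params.seed, "unwinding")
    delays = _draw_delays(params, rng)
    if params.v == 0:
        return np.zeros(params.n_molecules)
    max_clock = min(
        max(np.max(params.sites) / params.v, params.duration), params.duration
    )
    mol, entries, pauses = _pause_process(params, max_clock, rng)
    order = np.lexsort((entries, mol))
    mol, entries, pauses = mol[order], entries[order], pauses[order]
    bounds = np.searchsorted(mol, np.arange(params.n_molecules + 1))
    positions = np.empty(params.n_molecules)
    for i in range(params.n_molecules):
        t = at_time - delays[i]
        if t <= 0:
            positions[i] = 0.0
            continue
        e = entries[bounds[i] : bounds[i + 1]]
        p = pauses[bounds[i] : bounds[i + 1]]
        # wall time at which each pause starts, given all earlier pauses
        w_start = e + np.concatenate(([0.0], np.cumsum(p)[:-1]))
        j = np.searchsorted(w_start, t, side="right") - 1
        if j < 0:
            m = t
        else:
            w_end = w_start[j] + p[j]
            m = e[j] if t < w_end else e[j] + (t - w_end)
        positions[i] = params.v * min(m, max_clock)
    return positions


# ---------------------------------------------------------------------------
# qPCR read-out


@dataclass(frozen=True)
class QpcrNoiseModel:
    """Multiplicative noise model of the restriction-protection qPCR read-out.

    ``detection_floor`` is the residual relative quantity of a fully digested
    amplicon (incomplete cutting plus off-target amplification keep real qPCR
    signals positive); it bounds every uncut fraction from below.
    """

    cv: float = 0.02
    loading_cv: float = 0.05
    digestion_efficiency: float = 1.0
    detection_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.cv < 0 or self.loading_cv < 0:
            raise ValidationError("cv and loading_cv must be >= 0")
        if not 0 <= self.digestion_efficiency <= 1:
            raise ValidationError("digestion_efficiency must lie in [0, 1]")
        if self.detection_floor <= 0:
            raise ValidationError("detection_floor must be > 0")


def simulate_qpcr_readout(
    curves: SiteFractionCurves,
    noise: QpcrNoiseModel = QpcrNoiseModel(),
    replicates: int = 3,
    seed: int = 0,
    condition: str = "assay",
    control_label: str = "control",
):
    """Long-format triplicate qPCR plate from true unwound-fraction curves.

    The uncut (amplifiable) fraction at a motif site is the unwound fraction
    plus the escape fraction ``(1 - f) * (1 - digestion_efficiency)``; the
    control amplicon is never cut. Each sample (timepoint) draws one loading
    factor shared by all of its amplicons; each well draws independent
    lognormal replicate noise. Returns a pandas DataFrame with columns
    condition, site_label, timepoint_min, replicate, quantity.
    """
    import pandas as pd

    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = child_rng(seed, "qpcr", condition)
    labels = [str(s) for s in curves.sites] + [control_label]
    records = []
    for j, t in enumerate(curves.timepoints):
        loading = _lognormal_factors(noise.loading_cv, None, rng)
        for label, site_idx in zip(labels, list(range(len(curves.sites))) + [None]):
            if site_idx is None:
                uncut = 1.0
            else:
                f = curves.fractions[site_idx, j]
                uncut = max(
                    f + (1.0 - f) * (1.0 - noise.digestion_efficiency),
                    noise.detection_floor,
                )
            for r in range(1, replicates + 1):
                q = uncut * loading * _lognormal_factors(noise.cv, None, rng)
                records.append((condition, label, float(t), r, float(q)))
    return pd.DataFrame.from_records(
        records,
        columns=["condition", "site_label", "timepoint_min", "replicate", "quantity"],
    )


# ---------------------------------------------------------------------------
# gel lane simulators


@dataclass(frozen=True)
class GelSimParams:
    """Generative parameters of the alkaline-gel lane simulator.

    ``calib_a`` (bp) and ``calib_b`` (per position unit) define the true
    migration mapping ``bp(x) = a * exp(-b x)``; ``band_sigma`` is the
    Gaussian band spread in position units; ``background`` is the additive
    floor as a fraction of the lane maximum; ``noise_cv`` is multiplicative
    per-position noise.
    """

    fork_rate: float = 0.7  # kb/min
    initiation_jitter: float = 1.0  # min
    timepoints: tuple[float, ...] = (6.0, 10.0, 14.0, 18.0)
    calib_a: float = 25000.0
    calib_b: float = 0.0077
    band_sigma: float = 2.0
    background: float = 0.02
    noise_cv: float = 0.03
    ladder_bands: tuple[float, ...] = LAMBDA_HINDIII_BANDS_BP
    n_positions: int = 600
    n_molecules: int = 1000
    encoding: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fork_rate <= 0:
            raise ValidationError("fork_rate must be > 0")
        if self.calib_a <= 0 or self.calib_b <= 0:
            raise ValidationError("calibration truth requires a > 0 and b > 0")
        if self.initiation_jitter < 0 or self.band_sigma <= 0:
            raise ValidationError("initiation_jitter >= 0 and band_sigma > 0 required")
        if self.background < 0 or self.noise_cv < 0:
            raise ValidationError("background and noise_cv must be >= 0")
        if np.any(np.diff(self.ladder_bands) >= 0):
            raise ValidationError("ladder_bands must be strictly descending in bp")
        if self.n_positions < 20 or self.n_molecules < 1:
            raise ValidationError("n_positions >= 20 and n_molecules >= 1 required")
        if self.encoding not in ("linear", "sqrt"):
            raise ValidationError(f"unknown encoding {self.encoding!r}")

    def migration_of(self, bp: np.ndarray | float) -> np.ndarray | float:
        return np.log(self.calib_a / np.asarray(bp, dtype=float)) / self.calib_b


@dataclass
class LaneProfileSet:
    """A ladder profile plus sample lanes on a shared position grid."""

    positions: np.ndarray
    ladder: np.ndarray
    ladder_bands: tuple[float, ...]
    ladder_band_positions: tuple[float, ...]  # generative truth
    lanes: list[tuple[float, np.ndarray]]  # (timepoint min, intensities)
    encoding: str = "linear"
    flags: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _deposit(
    x: np.ndarray, weights: np.ndarray, n_positions: int, band_sigma: float
) -> np.ndarray:
    """Sum of Gaussian bands centred at migrations ``x`` with given weights."""
    pos = np.arange(n_positions, dtype=float)
    if x.size == 0:
        return np.zeros(n_positions)
    z = (pos[:, None] - x[None, :]) / band_sigma
    return (weights[None, :] * np.exp(-0.5 * z * z)).sum(axis=1)


def _finish_lane(
    profile: np.ndarray, params: GelSimParams, rng: np.random.Generator
) -> np.ndarray:
    peak = profile.max()
    out = profile + params.background * (peak if peak > 0 else 1.0)
    out = out * _lognormal_factors(params.noise_cv, out.size, rng)
    if params.encoding == "sqrt":
        out = np.sqrt(out)
    return out


def _ladder_lane(params: GelSimParams, rng: np.random.Generator) -> tuple[np.ndarray, tuple[float, ...]]:
    band_x = np.asarray(params.migration_of(np.asarray(params.ladder_bands)))
    profile = _deposit(band_x, np.ones(band_x.size), params.n_positions, params.band_sigma)
    return _finish_lane(profile, params, rng), tuple(float(x) for x in band_x)


def simulate_gel_lanes(params: GelSimParams) -> LaneProfileSet:
    """Radiolabelled leading-strand lanes for a replication time course.

    Per molecule the nascent length at time ``t`` is ``fork_rate * (t - t0)``
    with ``t0 ~ |Normal(0, initiation_jitter)|``; each product contributes
    intensity proportional to its length (label incorporation scales with
    synthesised length). A timepoint at which no molecule has positive
    length yields a background-only lane and a QC flag.
    """
    ladder, band_x = _ladder_lane(params, child_rng(params.seed, "ladder"))
    lanes = []
    flags: list[str] = []
    for t in params.timepoints:
        rng = child_rng(params.seed, "lane", f"{t:g}")
        t0 = (
            np.abs(rng.normal(0.0, params.initiation_jitter, params.n_molecules))
            if params.initiation_jitter > 0
            else np.zeros(params.n_molecules)
        )
        lengths = params.fork_rate * 1000.0 * (t - t0)
        lengths = lengths[lengths > 0]
        if lengths.size == 0:
            flags.append(f"lane t={t:g}: no labelled products, background only")
            profile = np.zeros(params.n_positions)
        else:
            x = np.asarray(params.migration_of(lengths))
            profile = _deposit(x, lengths, params.n_positions, params.band_sigma)
        lanes.append((float(t), _finish_lane(profile, params, rng)))
    return LaneProfileSet(
        positions=np.arange(params.n_positions, dtype=float),
        ladder=ladder,
        ladder_bands=params.ladder_bands,
        ladder_band_positions=band_x,
        lanes=lanes,
        encoding=params.encoding,
        flags=flags,
        meta={
            "seed": params.seed,
            "truth": {
                "fork_rate_kb_per_min": params.fork_rate,
                "calib_a": params.calib_a,
                "calib_b": params.calib_b,
            },
        },
    )


def simulate_pulse_chase(
    chase_rates: Mapping[str, float],
    pulse_rate: float = 0.05,
    pulse_duration: float = 60.0,
    pulse_length_cv: float = 0.05,
    chase_timepoints: Sequence[float] = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0),
    gel: GelSimParams | None = None,
    n_molecules: int = 800,
    seed: int = 0,
) -> dict[str, LaneProfileSet]:
    """Labelled pulse-chase lanes for several strains.

    Each molecule fixes a labelled segment of ``pulse_rate * pulse_duration``
    kb (with multiplicative jitter) at the end of the pulse; during the chase
    the product grows at the strain's chase rate but its label content stays
    constant, so every molecule contributes unit intensity.
    """
    if pulse_rate <= 0 or pulse_duration <= 0:
        raise ValidationError("pulse_rate and pulse_duration must be > 0")
    if any(r <= 0 for r in chase_rates.values()):
        raise ValidationError("chase rates must be > 0")
    base = gel if gel is not None else GelSimParams(seed=seed)
    out: dict[str, LaneProfileSet] = {}
    pulse_bp = pulse_rate * 1000.0 * pulse_duration
    for strain, rate in chase_rates.items():
        ladder, band_x = _ladder_lane(base, child_rng(seed, "pc-ladder", strain))
        lanes = []
        for t in chase_timepoints:
            rng = child_rng(seed, "pc-lane", strain, f"{t:g}")
            pulses = pulse_bp * np.clip(
                1.0 + pulse_length_cv * rng.standard_normal(n_molecules), 1e-3, None
            )
            lengths = pulses + rate * 1000.0 * t
            x = np.asarray(base.migration_of(lengths))
            profile = _deposit(x, np.ones(lengths.size), base.n_positions, base.band_sigma)
            lanes.append((float(t), _finish_lane(profile, base, rng)))
        out[strain] = LaneProfileSet(
            positions=np.arange(base.n_positions, dtype=float),
            ladder=ladder,
            ladder_bands=base.ladder_bands,
            ladder_band_positions=band_x,
            lanes=lanes,
            encoding=base.encoding,
            meta={
                "seed": seed,
                "strain": strain,
                "truth": {
                    "chase_rate_kb_per_min": rate,
                    "pulse_bp": pulse_bp,
                    "calib_a": base.calib_a,
                    "calib_b": base.calib_b,
                },
            },
        )
    return out
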