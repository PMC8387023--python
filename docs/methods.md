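# Methods

This note documents the models, estimators, parameter defaults and numerical
choices behind `replirate`, and states what the synthetic-data round trips
do and do not demonstrate.

## 1. Two-state unwinding model

Each linear template carries one helicase. A molecule activates after a
delay `t₀ = offset + Exp(λ)` and then translocates as a two-state motor:
it moves at velocity `v` (bp/min) and, while moving, enters pauses at rate
`k_in` (per minute of moving time); pauses end at rate `k_out`. Pauses stand
in for the non-productive duplex-engaged state; backtracking is not modelled
as negative displacement because the protection read-out only observes net
forward unwinding. The long-run net velocity is

    v_net = v · k_out / (k_in + k_out).

The simulator never integrates trajectories step by step. The arrival time
at site `d` is exactly

    arrival(d) = t₀ + d/v + Σ {pauses entered before d/v of moving time},

where pause entries form a Poisson process of rate `k_in` on the moving-time
clock and pause lengths are iid Exp(k_out). This is sampled directly
(Poisson count, uniform entry clocks, exponential durations), which makes
the per-site fraction curves exact and fast, and guarantees monotonicity in
time by construction. A slower per-molecule path (`simulate_positions`)
inverts the same trajectory representation for position-at-time queries and
is used to check the long-run velocity.

Defaults: `k_in = 1.0 /min`, `k_out = 4.0 /min` (duty ratio 0.8 — frequent
but short pauses), activation `λ = 2.0 /min` (mean delay 0.5 min, the
firing-factor step is fast but not instantaneous), 2000 molecules, sites
200/500/1000/1500/2000 bp, eleven timepoints from 2 to 50 min.
`UnwindingParams.from_net_velocity` fixes `v` so that `v_net` hits a desired
value while keeping the default pause kinetics.

### qPCR read-out

At each sampling time digestion is treated as instantaneous (the real
3-minute digestion window is absorbed into the nominal timepoint; a fixed
dead-time offset parameter is available). The uncut fraction of a cassette
amplicon is `f + (1−f)(1−digestion_efficiency)`, floored at a detection
floor of 1e−6 (residual amplification of fully cut template keeps real
quantities positive); the control amplicon is never cut. Each sample draws
one lognormal loading factor (CV 0.05) shared by all its amplicons, and
each well independent lognormal replicate noise (CV 0.02, triplicate). The
normalization chain is designed to cancel the loading factor exactly, and a
unit test asserts that identity to machine precision.

## 2. Unwinding-rate estimator

Chain (per plate): triplicate means per (site, timepoint) cell → divide by
the control-amplicon mean of the same sample → divide by the reference
(closest-site) saturation level → isotonic regression (pool adjacent
violators) per site → monotone PCHIP interpolant → mean arrival time

    τ_d = ∫₀ᵀ (1 − f̂_d(t)) dt      (trapezoid, 0.1-min grid)

→ site rate `d/τ_d` → mean over the three distal sites (1000, 1500,
2000 bp). The arrival-time integral is the unique reading of "integrate the
fitted curve" with bp/min units: for a step curve it returns the arrival
time exactly, and for an asynchronously activated population it returns
`d/v_net + E[t₀]`. Two consequences are documented and tested:

* **Activation-delay bias.** Site rates are `d/(d/v_net + E[t₀])`, rising
  with distance toward `v_net`; averaging the distal sites (rather than all
  five) keeps the bias small. At the defaults this predicts −2.7% at
  79 bp/min and −4.6% at 135 bp/min; the pipeline reproduces the analytic
  curve within Monte-Carlo error.
* **Truncation.** τ is truncated at the last timepoint; if a used site has
  not saturated (f̂(T) < 0.8) the estimate is flagged `non-saturated` and
  the rate is biased upward.

Numerical choices that matter:

* **Reference normalizer.** The curves are fitted before normalization, so
  the normalizer is the *fitted* saturation level of the reference site:
  the mean of its raw ratios over the region where the isotonic fit is
  within 5% of its final value. A single raw well would rescale every curve
  with its own replicate noise (and the bare isotonic value at the last
  knot tracks the largest plateau fluctuation, a systematic overestimate);
  both effects measurably bias τ upward. The raw single-well convention is
  available as `reference_value="raw"`.
* **Bounds.** Normalized values are clipped to [0, 1.25] with a warning
  above 1.05. The spline is bounded by the same 1.25 ceiling, not by 1: a
  saturated site fluctuates symmetrically about 1, and truncating at 1
  would convert that noise into a one-sided inflation of τ. With the
  symmetric bound the plateau noise cancels in the integral.
* **Zero anchor.** When the first timepoint is positive the pipeline
  prepends f̂(0) = 0 (no unwinding before activation) so the integral runs
  from zero; disable with `anchor_zero=False`.
* Duplicate timepoints are rejected rather than averaged; splines never
  extrapolate outside the sampled window.

### Bootstrap confidence interval

Replicates are resampled with replacement within each (site, timepoint)
cell, the full chain is rerun, and the 95% interval is the 2.5/97.5
percentile of the B = 1000 rates (point estimate from the unresampled
chain). With three replicates the naive resampled mean carries (n−1)/n of
the true sampling variance, so draws are rescaled about their mean by
√(n/(n−1)) by default. Coverage measured on independent synthetic plates
(2000 molecules, CV 0.02, zero activation delay so the point estimate is
unbiased) is ~85–91 per 100 at nominal 95%. The residual undercoverage is
structural: the finite-population trajectory noise (2000 molecules shared
by all cells of a plate) is invisible to replicate resampling. On real
plates, where the template population is effectively infinite, replicate
noise is the only stochastic term and the interval should be closer to
nominal.

## 3. Gel simulator and densitometry

Nascent-strand lanes: each molecule initiates at `t₀ ~ |N(0, jitter)|`
(jitter 1 min) and elongates at the fork rate; its label content — hence
intensity — is proportional to synthesised length. Pulse-chase lanes fix a
labelled segment (pulse 0.05 kb/min × 60 min = 3 kb, 5% CV) and extend at
the strain's chase rate with constant per-molecule intensity. Lengths map
to migration through `bp(x) = a·e^(−bx)` with `a = 25 000 bp`,
`b = 0.0077 /position` on a 600-position profile (a λ/HindIII-style ladder
spans the range); bands spread as Gaussians of σ = 2 positions; lanes get a
background floor of 2% of the lane maximum and 3% multiplicative position
noise. The `sqrt` encoding stores square-root-compressed values, the
convention of phosphorimager exports; the linearizer squares them back
(exact inverse, tested to 1e−9).

Densitometry: linearize → smooth → detect the ladder peaks (top-prominence)
→ least-squares fit of ln(bp) on position (monotonicity enforced; a
non-decreasing fit is rejected) → subtract the 2nd-percentile background →
call the leading fork length at the first 20%-of-maximum crossing scanning
from the large-product (small-migration) end, with linear sub-bin
interpolation → OLS of length (kb) on time (min) with a free intercept
(initiation lag precedes elongation; through-origin is an option).

* **Edge side.** "Leading fork length" means the longest well-populated
  products, so the crossing is taken on the high-molecular-weight flank.
* **Smoother.** Lowess (local linear regression) with *zero robustness
  iterations* — the robust reweighting treats sharp bands as outliers and
  destabilises the edge call. The default span is 2% of the profile: lane
  features here are 10–30 positions wide, and a wider window (e.g. 5%)
  flattens narrow peaks, lowering the lane maximum and pushing the 20%
  crossing outward by ~5% in bp — enough to violate the round-trip
  tolerance. The span is configurable per call.
* **Inherent edge offset.** Even noise-free, the 20% crossing sits on the
  blurred flank slightly beyond the longest product
  (≈ e^(1.794·b·σ_eff) in bp); at the defaults this contributes a stable
  +2–3% to recovered rates, inside the ±10% recovery tolerance, and the
  test suite verifies convergence to <1% as band spread, noise and grid
  coarseness all shrink.

Pulse-chase comparisons are robust to this multiplicative offset because it
cancels (to first order) in the rate ratio; the percent slowdown recovers
the generative 25% within ~±1 point at the defaults.

## 4. What the synthetic round trips show — and what they do not

The generators emulate: asynchronous activation, pausing kinetics,
protection thresholds at cassette positions, triplicate lognormal qPCR
noise with shared loading factors, label-proportional smear intensity,
exponential migration with band spread, background and pixel noise, and
square-root signal compression. They do **not** emulate: sequence-dependent
helicase kinetics, incomplete or time-extended digestion (beyond a constant
efficiency), primer efficiency differences, sister forks or re-firing,
lagging-strand structure, lane-to-lane migration distortion ("smiling"), or
2-D image artefacts. Passing round trips therefore demonstrate that the
estimators are unbiased (to the documented tolerances) under the stated
noise model — not that real gels or plates are free of the unmodelled
effects.

Problem sizes were chosen to keep every check comfortably interactive:
2000 molecules per plate, 100 plates for the coverage experiment (B = 200
per plate), 20 seeds per gel round trip, 400–1000 molecules per lane.

## 5. Template toolkit conventions

Coordinates are 0-based, half-open, plus-strand; the template is linear
(ScaI-linearised), so no wraparound matches. Primer matching is exact —
the assay was designed on an exactly known synthetic sequence — and each
primer must match exactly once (ambiguity is an error naming the primer).
The amplicon extends through the reverse-primer binding site, i.e. the full
qPCR product. Cassette calling groups motif hits whose consecutive offsets
differ by at most `max_span/min_sites` (defaults 30/4) and reports clusters
with at least `min_sites` hits spanning at most `max_span`; clusters
outside the assayed amplicons are reported, not suppressed. The
distance-from-origin labels (200…2000) are carried as metadata from the
primer table; the origin's own coordinates inside the plasmid are not
re-derived from sequence.

## 6. Known limitations

* The unwinding rate inherits a small negative bias from activation
  asynchrony (see §2); deconvolving the delay distribution is out of scope.
* The bootstrap CI is slightly anti-conservative on synthetic plates with
  few molecules (see §2).
* The 20%-of-maximum rule is sensitive to the smoothing span on narrow
  bands; use smaller spans for sharp pulse bands.
* Mechanistic parameters (k_in, k_out) are not fitted from curve shape;
  the pipeline estimates net rates only.
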