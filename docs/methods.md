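# Methods

`dxblink` implements diffracted X-ray blinking (DXB): inferring molecular
motion from the temporal fluctuation of diffraction intensity at fixed
detector pixels under monochromatic X-rays. A crystallite (or a gold
nanocrystal label on a protein) diffracts only while its orientation
satisfies the Bragg condition; rotational diffusion and lattice
fluctuations therefore make diffraction spots on the Debye–Scherrer ring
blink on and off. The blinking rate is read out per pixel from the decay
of the intensity autocorrelation, and converted into a picometer-scale
rotational diffusion coefficient.

## The estimator

For a pixel's photon-count series I(t), sampled at the frame interval dt,
the normalized autocorrelation is

    ACF(tau) = < I(t) I(t + tau) > / < I(t) >^2,

with the time average over the recording and the *single global mean* in
the denominator (not windowed means per lag). Lag 0 is excluded: it
carries shot noise, not dynamics. Lags run from dt to `max_lag_fraction`
of the trace length (default 1/4; beyond that too few products are
averaged and the curve is dominated by finite-record noise).

Each curve is fit by constrained nonlinear least squares to

    decay:  ACF(t) = y + A exp(-Gamma t)
    growth: ACF(t) = y - A exp(-Gamma t)

with A, y, Gamma > 0 (optimizer lower bounds 1e-12). A pixel is labeled
decay or growth by the sign of the least-squares slope of the first
quarter of its lags (exact zero ties to decay). The growth branch is the
decay curve mirrored about its plateau: pixels dominated by the *entry* of
spots into the Bragg condition show ACFs that rise and saturate, and the
mirrored model recovers the same decay constant from them. This stands in
for "time-reversal processing" of traces: the autocorrelation is an even
function, so literally reversing the trace cannot change this estimator
(the set of lag-m products is reversal-symmetric — asserted exactly by a
test); what distinguishes the two pixel populations is the curve shape,
which the two mirrored models capture. Each pixel receives exactly one
direction.

A fit is accepted iff A > 0, y > 0, Gamma > 0, and the residual —
the *sum* of squared differences between fit and data over all fitted
lags (configurable to the mean) — is below 1.0. Two numerical guards
implement "strictly positive" on the amplitude: a converged A below 1e-6,
or a model amplitude at the first lag (A e^{-Gamma dt}) below 1e-6 (the
large-Gamma ridge on which A is unidentifiable), are both treated as
violating A > 0. Optimizer failure is recorded as a rejected fit, never an
exception. Note the acceptance rules are deliberately permissive: pixels
with no real dynamics can still be accepted with noise-scale amplitudes
and essentially arbitrary decay constants. On background-only synthetic
movies roughly half the pixels are accepted this way; their fitted curves
change by only shot-noise scale over the window (a test asserts this), but
their decay constants scatter broadly. Ensemble medians over
predominantly signal-bearing pixels are robust to this contamination;
medians over mostly-background regions are not — choose the ring ROI
accordingly.

The per-pixel decay constant estimates the rate sum k_on + k_off of the
underlying on/off kinetics. With a 100 s recording a spot undergoes only
tens of transitions, so individual estimates are noisy and right-skewed;
condition-level inference always goes through the ensemble.

## Detrending

Slow source or alignment drifts add a near-linear trend that masquerades
as long-lag correlation. An ordinary-least-squares line is subtracted and
the original mean added back (preserving the normalization and the trace
mean to machine precision). Policy `always` removes the line
unconditionally, `never` not at all; the default `auto` removes it only
when the slope differs from zero at the 5% level. The slope test inflates
the usual t-statistic variance by the effective-sample-size factor
1 + 2 Σ ρ_k (residual autocorrelations, truncated at the first
nonpositive lag): blinking traces are strongly autocorrelated, and the
naive iid t-test fires on most trend-free blinking pixels, stripping
exactly the low-frequency power the correlation analysis measures. The
published procedure removed trends "when present" without a criterion;
the test form and threshold are this package's choice.

## Preprocessing

* **Binning** sums non-overlapping b×b blocks (b ∈ {1,2,3}), dropping
  trailing rows/cols that do not fill a block (padding would bias the ACF
  normalization). A binned pixel is valid only if all b² constituents are
  valid — conservative near detector module gaps. Counts over covered
  blocks are conserved exactly, and binning commutes with frame splitting.
* **Ring ROI**: flat-detector small-angle mapping r = L·tan(2θ)/pitch; a
  binned pixel is selected when its center radius from the beam center
  falls inside [2θ_c ± halfwidth]. No polarization or solid-angle
  correction is applied — the ACF normalization cancels static per-pixel
  factors. Selection is monotone in the halfwidth.
* **Frame splitting** divides a recording into k contiguous equal
  substacks (floor division, tail remainder dropped) for observation-time
  robustness studies.

## Ensemble statistics and physics conversions

Accepted decay constants form a heavy-tailed unimodal distribution,
summarized two ways because both are in common use: the sample median
(which feeds the D_R conversion) and the mode of a Cauchy–Lorentz fit.
The Lorentz fit is by maximum likelihood by default (works from 5 values);
a histogram least-squares variant with Freedman–Diaconis bins (≥ 20
values) mirrors histogram-figure fitting and agrees with the MLE to
within a bin width on large samples. Below 20 accepted pixels the Lorentz
fit is skipped and only boxplot statistics (1.5·IQR whiskers) are
reported. Conditions are compared with the two-sided Wilcoxon rank-sum
test: exact enumeration for tie-free samples with n ≤ 20 per side, normal
approximation with tie correction (no continuity correction, so identical
samples give p = 1) otherwise. Pairwise comparisons are reported raw; a
Holm correction is available but off by default.

The physics layer converts the ensemble median Γ (1/s) to a rotational
diffusion coefficient

    D_R = Γ · Φ_θ² / 4   [pm²/s],

where Φ_θ (pm) is the rotational displacement — the picometer-scale arc
of one resolvable angular step. Φ_θ is a *required configuration input*:
its calibration is experiment-specific and not recoverable from the
detector geometry alone (a pixel-subtense estimate d·pitch·b/L is logged
as a clearly non-normative diagnostic). Bragg spacing d = λ/(2 sin θ) is
computed from 2θ in degrees.

## The synthetic movie generator

The simulator exists so every stage has a ground-truth oracle. Defaults
emulate the laboratory measurement conditions: 2000 frames at 50 ms,
~3×3-pixel spots on a Debye–Scherrer ring, photon-counting statistics.

* **Telegraph mode** (default): each spot is an independent two-state
  Markov process with entry/exit rates k_on, k_off, sampled at frame
  times with the *exact* one-interval propagator (no small-dt bias); the
  initial state is stationary. The state autocovariance decays at
  k_on + k_off — the quantity the analysis must recover.
* **Angular-diffusion mode**: each spot's orientation performs a reflected
  Brownian walk in a bounded window; the spot is on while the orientation
  is inside the Bragg acceptance half-width. Reflecting walls keep the
  stationary density uniform, so the on-fraction is predictable
  (halfwidth / range).
* **Rendering**: each on spot spreads its flux uniformly over a
  psf×psf footprint (default 3×3, matching observed spot sizes); a
  uniform background and optional linear drift at spot pixels are added,
  and counts are drawn per pixel from a Poisson law (background and spot
  photons drawn independently — exact by Poisson additivity). The spot
  flux/background ratio defaults to a blinking contrast Var/E² ≈ 0.1 per
  single-spot pixel, the amplitude scale of measured single-pixel ACF
  exemplars; laboratory sources leave substantial diffuse background
  under the ring.
* **Placement**: default is a jittered angular grid along the ring —
  evenly spaced angles with random angular jitter and radial jitter
  within the ring halfwidth. Measured ring images are densely covered
  with spots, and random sequential placement jams well below that
  coverage; the grid is deterministically feasible at any density up to
  one spot per psf arc while keeping continuous-coordinate separations
  ≥ psf (after rounding to the pixel grid, tangent neighbors may share a
  corner pixel, which leaves the decay constant unchanged because
  co-located spots share the same kinetics). Classic rejection-sampling
  placement remains available (`placement="rejection"`).
* **Timing**: counts represent the full 50 ms interval; the 42 ms
  exposure (16% dead time) is not modeled — it rescales intensities only,
  and the normalized ACF is scale-invariant. Documented simplification.

What the generator does *not* emulate: spot-shape structure beyond the
uniform footprint, inter-spot kinetic heterogeneity within a condition,
detector artifacts other than a static validity mask, beam-intensity
fluctuations beyond a linear trend, and radiation damage. Passing
recovery tests therefore demonstrate estimator correctness under the
stated model, not robustness to every instrumental effect in real data.

## Study sizes and numerical choices

* End-to-end recovery studies use 200 spots on a thin ring (radius 102 px,
  radial jitter ±0.5 px) in a 220×220 frame, 2000 frames at 50 ms, and an
  analysis annulus of ±1.5 px around the ring, giving ~1900 analyzed
  pixels of which ~90% view a spot. Recovery runs disable detrending:
  the simulated movies are drift-free, so a fitted trend can only remove
  genuine low-frequency blinking signal (drift handling is validated
  separately on traces with an explicit ramp). Per-pixel decay constants
  from one spot's nine footprint pixels share the spot's state history,
  so the effective sample is the number of spots; medians over such
  ensembles carry several percent sampling scatter across seeds, and the
  per-pixel least-squares skew biases the median upward by ~5–15% at the
  slowest rates (tens of transitions per spot in 100 s), so the 15%
  recovery band is met with modest margin there.
* The observation-time study uses two conditions (rate sums 0.4 and
  0.6 /s) on a radius-60 ring with 112 spots, splitting 2000 frames into
  2/4/10 subsets. Per split, the accepted decay constants of all
  substacks are pooled and subsampled to a fixed size (every k-th value),
  so every split level is compared at equal sample size and the rank-sum
  p-value isolates the observation-length effect (pooling without
  subsampling lets the growing sample size mask the per-pixel information
  loss).
* Batch ACF computation uses FFT correlation (round-off ~1e-12 relative
  to the direct form, which is kept for single traces and asserted
  equivalent); the direct form uses forward+backward symmetrized sums so
  trace reversal gives bit-identical curves.
* Exponential fits run a projected Levenberg–Marquardt (damped
  Gauss–Newton with the Marquardt λ schedule, parameters projected onto
  the positivity bounds after each step, analytic Jacobian), vectorized
  across all pixels of a stack at once; the same engine fits single
  curves. Initialization is data-driven: plateau from the last quartile
  of lags, amplitude from the first lag, rate from the half-crossing lag
  (fallback 1/τ_max). The local descent from that start is deliberate —
  on noisy single-pixel curves the globally minimal sum of squares often
  sits in a degenerate noise-chasing basin, while the half-crossing basin
  tracks the visible decay; a global variable-projection search was
  evaluated and found to inflate ensemble medians at slow rates.
* The Lorentz MLE optimizes location and log-scale by Nelder–Mead from
  the median and half-IQR.
* All randomness flows from a single top-level seed through named
  substreams (state sampling vs rendering), so any stage is independently
  reproducible and equal seeds give bit-identical movies.

## Known limitations

* The printed acceptance rules accept noise-artifact fits on pixels
  without dynamics (see above); summaries over ROIs that are mostly
  background are unreliable.
* Per-pixel decay constants are biased and skewed at small transition
  counts (short recordings or slow kinetics); the ensemble median
  inherits a few-percent bias at 2000 frames.
* The published results table rounds its inputs: one row's D_R differs in
  the last printed digit from the value recomputed from its own rounded
  Γ and Φ_θ (3.28 vs 3.29 pm²/s); the package reports the recomputed
  value. Similarly, the gold (111) row's printed 2θ/d pair is mutually
  inconsistent with Bragg's law at λ = 1.54 Å by ~0.03 Å; the Bragg
  helper is validated against the self-consistent rows.
* Φ_θ cannot be derived inside the package; without a calibrated value,
  only decay-constant statistics are reported.
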