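# Methods

## The measurement being modelled

Whole seedlings expressing cytosolic apo-aequorin are reconstituted with
coelenterazine and placed in a luminometer. A stimulus solution (NaCl,
iso-osmotic sorbitol, cold, or plain base solution) is applied at t = 0 and
photon counts are integrated per sampling interval; at the end of the run the
remaining aequorin is discharged so that every trace carries its own
normalisation total. Photon emission consumes aequorin, so the emission rate
constant — not the raw count rate — is the quantity that tracks [Ca²⁺]_cyt.

## Calibration

For interval t with counts c_t, the remaining pool is
R_t = discharge + Σ_{s≥t} c_s (the convention here *includes* the current
interval, i.e. the pool consumed by the photons being normalised), and
k_t = c_t / (R_t · Δt). The empirical calibration

    pCa = slope · (−log₁₀ k) + intercept,   [Ca²⁺] = 10^(−pCa)

uses slope 0.332588 and intercept 5.5593, the standard constants of the
cytosolic-aequorin calibration lineage; they are fields of
`CalibrationParams` so laboratory-specific recalibrations are injectable.
Two guards handle degenerate intervals: a zero count would give k = 0
(pCa = ∞), so zero-count intervals are assigned the one-count pseudo-rate
`1/(total counts · Δt)` — below any observed rate in the trace — and pCa is
capped at `pca_cap` (default 8, i.e. a 10 nM floor). Non-uniform time grids
are rejected rather than resampled. The pointwise map and its inverse
`calcium_to_rate` are exact inverses; the simulator uses the inverse as its
forward model, which is why a noise-free simulate→calibrate round trip is
exact to floating-point error.

## Synthetic signatures

Each transient is an alpha pulse a(x) = x·e^(1−x), x = (t − onset)/τ: zero
before onset, unit peak at x = 1, smooth single-peaked decay — the morphology
of measured whole-seedling transients. τ is set so the width at 10% of peak
equals the stated transient duration (≈20 s first, ≈30 s second, 10 s touch).

Default profile parameters (all amplitudes in nM above a 100 nM resting
baseline, the typical plant cytosolic resting level):

| parameter | col0_like | c24_like | meaning |
|---|---|---|---|
| first_amp_max_nM | 1800 | 1923.75 | dose-response saturation amplitude |
| first_amp_K_mM | 250 | 250 | half-saturation concentration |
| sorbitol_scale | 737/800 | 750/855 | osmotic fraction of the NaCl response |
| second_amp_mean_nM | 656 | 0 | delayed-transient mean amplitude |
| biphasic | true | false | second transient present under NaCl |
| second_time_range_s | (35, 100) | — | uniform onset of the second transient |
| touch_amp_nM | 284 | 219 | base-solution (touch) peak |
| cold_amp_nM | 1052 | 914 | cold-shock peak |
| amp_cv | 0.08 | 0.08 | between-seedling amplitude CV |

The dose response is hyperbolic, A₁(c) = A_max·c/(c+K) (Hill exponent 1),
strictly increasing with A₁(0) = 0. The maxima are anchored so that
A₁(200 mM NaCl) equals the reference first-peak heights (800 and 855 nM);
K = 250 mM places the curve's bend inside the 20–1000 mM design. Sorbitol at
twice the NaCl molarity is iso-osmotic, so sorbitol concentrations are mapped
to c/2 and scaled by `sorbitol_scale`, making NaCl ≥ sorbitol at matched
osmolarity whenever the scale is below 1. Amplitudes are jittered
multiplicatively by 1 + CV·Z truncated at zero; the CV of 0.08 matches a
standard error near 5% of the mean for triplicate averages.

Two modelling choices deserve emphasis:

* **The touch pulse is not stacked onto stress stimuli.** A measured stress
  peak already contains whatever mechanical component the application adds,
  and dose-response points are measured total peak heights; the generator
  therefore treats A₁(c) as the total first-transient amplitude and emits a
  separate touch transient only for base-solution runs. Stacking an extra
  ~280 nM pulse onto every stress trace would make extracted first
  amplitudes systematically unrecoverable from the injected dose response.
* **The monophasic genotype gets no second pulse at all.** Its second-window
  amplitude is *emergent*: the max−min range of the decaying first transient
  plus calibration/shot noise. It is positive but small, which is exactly
  what makes the log-amplitude plane separable.

The photon forward model inverts the calibration: per interval,
expected counts = k(ca_t)·R_t·Δt with the pool R consumed by every emitted
count, and the terminal discharge releases the remainder, so counts plus
discharge equal the initial pool exactly (integer-exactly in Poisson mode).
A pool exhausted mid-trace is flagged in the output, not raised. The default
pool of 10⁶ expected counts keeps shot noise at the first peak well below 1%
of amplitude while leaving visible noise at baseline — comparable to a
healthy reconstitution.

What the generator does **not** emulate: calcium wave propagation along the
root, cell-type heterogeneity, oscillatory signatures beyond two transients,
temperature/pH effects on aequorin, and drift in the luminometer background.
Passing tests on synthetic data therefore demonstrate correctness of the
analysis chain and its statistical behaviour under the stated noise model —
not that real C24 seedlings would yield the same posterior table.

## Features

Replicates are averaged pointwise first (canonically ordered by replicate id
so permutations are bit-identical), then the averaged curve is reduced to
within-window ranges on (0, 30] s and (30, 120] s. Half-open windows
generalise the 1–30/31–120 s integer convention to any sampling interval;
ties in a window maximum break to the earliest time. Order matters: because
second-transient onsets differ between seedlings, the peak of the average is
below the average of the peaks, and the pipeline deliberately averages
first (a regression test pins this). A window with zero range yields no log
feature; such rows are excluded with a warning, never clamped — fabricating
a log amplitude for a flat window would inject an arbitrary outlier into the
discriminant. Whether measured amplitudes should instead subtract a
pre-stimulus baseline is untestable from the reference description; the
range definition is recorded as a design choice (it is also what produces a
positive second amplitude for monophasic curves, matching the observed
behaviour).

## Discriminant and jackknife

Standard two-group Gaussian LDA on x = (log₁₀A₁, log₁₀A₂): per-group sample
means, pooled within-group covariance with the unbiased divisor n₁+n₂−2
(stated explicitly because the ML convention divides by n), priors equal by
default (the design is balanced; empirical priors are configurable). The
sample linear functions d_g and their difference D are evaluated through a
Cholesky-backed solve; a singular pooled covariance (duplicated or collinear
within-group points) raises an error naming the geometry rather than
regularising silently. Posteriors are the softmax of the d_g, i.e. the Bayes
posterior under equal-covariance Gaussian classes; D = 0 ties classify to
group 1 by convention with posterior 0.5 either way. The jackknife refits
the model without each observation in turn (requiring ≥ 3 per group so every
refit retains ≥ 2) and records the held-out point's own-group posterior; a
singular refit flags that row instead of dropping it.

## Pipeline defaults and problem sizes

The default simulated design mirrors the reference experiment: 12 NaCl
concentrations (20, 50, 75, 100, 150, 200, 250, 300, 400, 500, 750,
1000 mM) × 2 genotypes × 3 replicates, plus iso-osmotic sorbitol (2× each
NaCl concentration), one cold and one base condition — 156 traces of 311
samples at Δt = 1 s on a −10…300 s grid, which runs in about a second.
Sorbitol/cold/base traces feed the dose-response and control outputs only;
the discriminant uses the NaCl rows. Per-condition RNG substreams are spawned
from (seed, genotype, stimulus, concentration, replicate), so any single
trace is reproducible in isolation and replicates are independent. All report
files are plain CSV/YAML with no timestamps, making identical (config, seed)
runs byte-identical.

## Known limitations

* The calibration constants are injected, not fitted; traces calibrated with
  a different aequorin lineage need their own slope/intercept.
* The alpha-pulse shape and uniform second-onset law are conventions; real
  second transients may be skewed or multimodal across seedlings.
* The sampling interval and trace length of the original instrument are not
  specified anywhere; Δt = 1 s and 310 s are package defaults, configurable.
* With only three replicates per condition the feature table inherits
  noticeable variance; posteriors from a single seeded run should be read as
  one realisation, not an expectation.
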