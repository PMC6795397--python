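# Methods

## Measurement model

A beating monolayer is imaged as a grayscale stack at frame rate *f* (20 Hz
default). Material that sits at position **x** in the diastolic reference
frame is found at **x** + **u**(**x**, t) in frame t. The local relative
area change of the tissue between the reference and frame t is, to first
order, div **u** = ∂u/∂x + ∂v/∂y — a nondimensional quantity, negative
under contraction. Averaging over the field of view gives the
contractility tracing D(t); its square root can be read as a linear
cell-shortening measure.

Two averaging conventions exist because contraction of one region forces
expansion elsewhere, so the signed spatial mean partially cancels. The
default is the **absolute** convention, D(t) = ⟨|div u|⟩, which is
nonnegative and is what the color maps of typical monolayer-force analyses
display; the signed convention ⟨−div u⟩ (contraction positive) is kept
behind a flag. Which of the two a given published analysis used is rarely
stated; the absolute convention is this package's documented choice.

## PIV

Displacements are estimated per interrogation window (32 px, 16 px
overlap) as the argmax of the normalized cross-correlation between the
reference window and a search region extended 8 px on every side, refined
to subpixel precision by a three-point Gaussian fit of the correlation
peak (log-parabola in each axis; plain parabolic fit as fallback when a
correlation sample is nonpositive). Normalized correlation
(`skimage.feature.match_template`) makes the estimate robust to
illumination drift. Vectors deviating more than 2 px from their 3×3
neighborhood median are replaced by that median.

Windows are invalid — excluded rather than zero-padded — when they are
flat (zero variance, correlation undefined) or when the full search margin
does not fit inside the image; zero-padding would bias the divergence at
the border. Window centers are at top-left + window_size/2; the grid
spacing (window_size − overlap) is the h of all finite differences.

The diastolic reference frame is the frame minimizing a centered two-sided
consecutive-frame speed (mean of the speeds to the previous and next
frame, one-sided at the ends; ties to the smallest index). One fixed
reference serves the whole recording: deformation is defined "with respect
to diastolic relaxation", and per-beat re-referencing would make D(t)
discontinuous at beat boundaries. The reference-selection pass may use a
coarser PIV grid (overlap 0 by default in the pipeline) since only the
location of the speed minimum matters; this halves the runtime.

The reference-frame displacement field is set identically to zero (a frame
correlated against itself), so D(t) is exactly zero at the reference — a
useful invariant for testing.

## Divergence and D(t)

div is computed by central differences on the window grid: exact for
fields affine in position, and the displacement fields of interest are
close to affine at the grid scale. Cells whose five-point stencil touches
an invalid window are invalid; the result loses a one-cell border. D(t)
averages over the remaining valid cells, and the per-frame valid-cell
count is recorded alongside the trace.

## Beat metrics

Peaks of D(t) are local maxima with prominence ≥ 0.3 × max D(t) and
separation ≥ 0.4 s (beats in these preparations are ≥ 0.5 s apart; both
parameters are exposed). Metrics:

- D_peak: global maximum over the recording (the literal definition), with
  per-beat peaks also reported;
- D_mean: time average over the entire recording, rest phases included;
- T_cycle: mean inter-peak interval; reported as missing with < 2 peaks;
- T_contract: mean over beats of Σ H Δt within each cycle, H(t) = 1 where
  D(t) > 0.1 D_peak (strict), Δt = 1/f, cycles spanning midpoint-to-midpoint
  between adjacent peaks with the first/last clipped to the recording.

T_contract is a Riemann sum at the frame interval, so it is quantized to
Δt and is biased low by up to one frame per threshold crossing relative to
the continuous-time value: for D(t) = 0.02 sin²(πt/1 s) sampled at 20 Hz
the sum gives 0.750 s where dense sampling of the continuous signal gives
0.795 s (−5.7%). Sub-frame crossing interpolation would remove this bias
but would silently disagree with the stated integrand; the discretization
is kept and documented instead, and recovery tests compare against the
dense oracle with a 10% band.

## Synthetic ground truth

The generator warps a static speckle texture (Gaussian blobs of width
1.5 px, uniform centers, random amplitudes — mimicking membrane-bound
lectin speckles that give PIV-trackable local contrast everywhere) through
a prescribed motion:

- affine contraction: u* = −s(t)(x − c), div u* = −2s(t) uniformly; with
  s(t) = a(t)/2 the amplitude waveform a(t) *is* the ground-truth |div|
  trace;
- radial Gaussian: u* = −s(t)(x − c)exp(−r²/2σ²), a localized contraction
  focus with closed-form divergence, for testing spatial nonuniformity.

Waveforms start each cycle with a rest segment (fraction `rest_fraction`
of the period) followed by a raised-sin² pulse (triangle and custom
sampled waveforms are available); a(0) = 0, so recordings begin at
diastolic rest. Frames are rendered by inverse mapping (exact inverse for
the affine model, fixed-point iteration for the radial one) with bilinear
(default) or cubic interpolation — forward splatting would leave holes —
plus zero-mean Gaussian intensity noise. At rest with zero noise a frame
is bit-identical to the texture, making periodicity and determinism
exactly testable.

Default regime: 256×256 px, 20 Hz, 10 s (200 frames), period 1.1 s, peak
divergence 0.02, noise σ = 0.01, rest_fraction 0.7. Period and peak match
the magnitudes reported for embryonic-mouse cardiomyocyte monolayers
(T_cycle ≈ 1.1–1.2 s, D_peak ≈ 0.014–0.019); rest_fraction 0.7 gives a
0.33 s active pulse and hence a ground-truth T_contract ≈ 0.26 s, matching
the ≈0.27 s reported for such preparations. Image magnification is not
part of the model: divergence is nondimensional, so pixel size only scales
the displacement magnitudes (≤ ~1.3 px at the default amplitude), and the
synthetic scale was chosen to keep them within the 8 px search margin.

What the generator does *not* emulate: photorealistic phase-contrast
optics, cell boundaries and heterogeneous tissue texture, out-of-plane
motion, stage drift, photobleaching, or beat-to-beat variability. Passing
recovery tests therefore demonstrate correctness of the estimation chain
under known motion, not robustness to every artifact of real recordings.

The Cq-table generator draws per-sample target Cq values around per-group
means with a common SD, plus an endogenous-control assay at a constant
mean shared across groups, so the group ΔΔCt equals the difference of
target group means and worked examples with published group means are
reproduced exactly at SD 0.

## Expression and group statistics

ΔCt = Cq(target) − Cq(control) per sample; ΔΔCt = mean ΔCt difference
between groups; fold = 2^−ΔΔCt. Published figure legends often print
already-normalized per-group mean "cQ" values (negative values and
magnitudes ≪ raw Cq give this away); `fold_from_mean_cq` consumes those
directly as fold = 2^(Cq_control − Cq_treated), alongside the full
per-sample path. Percent difference is 100·(alt − ref)/ref. SEM uses the
n−1 denominator and is reported as missing for n = 1. The unpaired t-test
defaults to the pooled-variance (Student) form with Welch behind a flag;
one-tailed p is half the two-tailed p for the observed direction. Two
groups that are each constant and equal yield t = 0, p = 1; constant but
unequal groups raise (the statistic is undefined), a documented choice.
No multiple-testing correction is applied to these single comparisons.
Report rounding follows presentation practice: folds and percents to one
decimal.

## Numerical and runtime choices

Seeds: every stochastic component (texture, noise, Cq draws) takes an
explicit seed; the pipeline derives independent child streams via
`numpy.random.SeedSequence`. Reruns with identical configuration are
bit-identical, and each run writes a manifest of all parameters from which
it can be reconstructed.

Test problem sizes: module tests use 128 px recordings of 3.3 s (three
beats) so the full suite stays fast; the recovery validation runs the full
default regime (256 px, 10 s) over five seeds, about a minute per seed on
one CPU. The acceptance script averages three seeded full-regime runs.

## Known limitations

- Window-scale smoothing biases D_peak slightly low when the divergence
  varies within a window (the affine default does not; the radial model
  quantifies the effect at ~5% at 16 px spacing).
- The frame-rate quantization of T_contract (above) dominates its error
  budget at 20 Hz.
- The single fixed diastolic reference assumes negligible slow drift over
  the recording; long recordings with stage drift would need the
  out-of-scope registration step.
- Correlation-based PIV measures the dominant local translation; strong
  within-window shear or rotation degrades the estimate before the
  validation step catches it.
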