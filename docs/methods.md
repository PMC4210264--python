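# Methods

This note documents the models, parameter choices and numerical conventions
behind `synthprint`, and what the synthetic fixtures do and do not show
about real data.

## Preprocessing

Images are 2-D arrays of gray values in [0, 255], row-major, origin top-left
(multi-channel input is reduced by BT.601 luminance and rounded).

**Foreground.** A 16×16 block is foreground when its gray variance reaches
100 gray² (both configurable). The rule is deliberately crude: the ridge
area of any usable print oscillates between ridge and valley levels, so its
block variance is orders of magnitude above the floor, while blank sensor
background is nearly constant. The foreground centroid anchors the analysis
region; an empty mask is a legal result that downstream operations must
reject ("no foreground").

**Orientation.** Ridge direction is estimated per 16×16 block by gradient
least squares: Sobel gradients are accumulated in doubled-angle form
(`gxx − gyy`, `2 gxy`) so that opposite gradient vectors reinforce; the
ridge direction is perpendicular to the dominant gradient direction, defined
modulo π. Coherence — the length of the averaged doubled-angle vector over
the total gradient energy — is 1 for a perfect grating and 0 for isotropic
or flat blocks; blocks under a coherence floor of 0.1 are treated as having
no usable direction. Block size 16 trades angular noise against curvature
blur and is the standard choice for ~500 dpi ridge imagery.

**Analysis region.** The centroid is rounded half-up to a pixel `c` and the
region is the half-open square `[c−48, c+48)` per axis, shifted minimally to
stay in bounds, giving exactly 96×96 = 9,216 candidate sample points.

## Ridge-distance features

At each candidate point, a 32×16 window is rotated so its long axis crosses
the ridges; each of the 32 columns averages 16 bilinearly interpolated
samples taken along the ridge direction. Windows that would leave the image
are skipped, never padded, and points in blocks with unreliable orientation
are skipped as well.

Peaks of the profile define the local ridge distance. Raw local maxima on
noisy profiles produce spurious 1-px gaps, so the profile is first smoothed
with a 3-point moving average and a peak must be a strict local maximum with
prominence ≥ 2 gray levels (prominence measured to the nearest strictly
higher sample or the profile edge, the standard definition). The sample's
distance is the mean gap between consecutive peaks — more stable than any
single gap — and a sample with fewer than two peaks is invalid. If fewer
than 1% of the 9,216 candidates are valid the image has no measurable ridge
structure and the extraction fails loudly rather than returning a number.

`q_disavg`/`q_disstd` are the mean and *population* standard deviation over
the valid samples, matching the summation-over-all-points form of the
definitions. On analytic gratings with periods 6–14 px at 0°–90°, the
recovered mean is within ~0.01 px of the true period and the spread is
essentially zero (the peak positions quantize to the pixel grid, and gap
averaging cancels the sub-pixel phase).

## Global gray, spectral and corner features

`q_grayavg`/`q_grayvar` are the mean and population variance of the whole
frame — deliberately *not* contrast-normalized, since the absolute
background level is the signal.

`q_fft` averages the centered DFT magnitude over bins with polar radius
`r ∈ (r₀, m/2]`, `m = min(H, L)`, `r₀ = 0.25·m` by default. The inner
radius excludes the bright central ring that carries the ridge fundamental
(ridge periods ≥ 4 px keep the fundamental within radius m/4). Magnitude
rather than squared power is averaged; "energy" here is read as spectral
magnitude, and both the radius fraction and the choice are exposed in the
feature configuration.

`q_harris` uses unnormalized Sobel gradients, Gaussian smoothing with
σ = 1 px (truncated at 4σ) of the tensor products, response
`R = (I_x'I_y' − I_{x'y'}²) − 0.04·(I_x' + I_y')²`, and counts pixels with
`R > 5500` that are the maximum of their 8×8 tile (non-overlapping tiling;
edge tiles may be partial). The threshold 5,500 and tile size 8 are the
method's published operating point; `k = 0.04` and σ = 1 are the
conventional values for the constants the description leaves open. Note the
tile-maximum rule caps the count at one corner per tile up to ties.

All filtering uses replicate ("nearest") boundary handling; the test-suite
oracles recompute the same quantities with explicit loops and edge-padded
direct convolutions.

## Classification

Labels are +1 (real) / −1 (synthetic). Features are z-scored with the
training split's statistics — `q_grayvar` is of order 10³ and would
otherwise dominate RBF distances — and a soft-margin SVM is fitted via
libsvm with C = 1, γ = 1/6 (one over the number of features), polynomial
offset r = 0 and degree d = 3, the libsvm conventions; all are overridable.
Splits are stratified per class with round-half-up training counts, so the
class balance survives even at a 5% proportion. Evaluation repeats the
split–train–test cycle with seeds derived from one master seed and averages
accuracy, wall times and AUC; the ROC is swept over the SVM's continuous
decision values, AUC by the trapezoidal rule (equal to the Mann–Whitney
pairwise statistic). The pooled-across-repetitions ROC is reported for the
averaged result.

## Performance-factor optimization

The scoring form is `P = (Acc − Acc_min)·(T_ref/T)^n`. Its contract: P = 0
at the accuracy standard and negative exactly below it; increasing in
accuracy at fixed time; decreasing in training time above the standard; a
larger sensitivity n penalizes slow training more. The algebra is isolated
in one function so an alternative form satisfying the same contract is a
one-line change; every property test targets the contract, not the algebra.
`T_ref` is calibrated per kernel as the training time at the smallest swept
proportion whose mean accuracy reaches `Acc_min`, linearly interpolated in
accuracy between the bracketing grid points. Kernels that never reach the
standard are carried as infeasible, flagged, never silently dropped. Ties
at the peak break toward the smaller proportion (cheaper training), then
the fixed kernel order linear, poly, rbf.

Mean times are averaged over repetitions before P is computed. Wall-clock
time is physically non-reproducible, so sweeps also offer a deterministic
timing mode (`timing="model"`, a quadratic training-cost model
`(n_train/100)² + 10⁻³`) that makes the entire optimization output a pure
function of the seed; only time ratios enter P, so the model's scale is
irrelevant. Reproducibility checks and any workflow that must be
bit-stable should use this mode; wall timing remains the default for
measuring real kernels on real hardware.

## Synthetic fixtures

The generator renders only the cues the features measure, for three
populations:

| parameter | real_like | db4_like | fpgen_like |
|---|---|---|---|
| ridge period (px) | N(10, 1) per image | 8, fixed | 8, fixed |
| within-image period modulation | ±10% | ±2% | ±2% |
| duty cycle (ridge width / period) | 0.42 | 0.50 | 0.35 |
| background gray | N(215, 10) | N(175, 10) | N(180, 10) |
| contrast | 110 | 120 | 120 |
| edge softness / blur | soft, σ=1 blur | crisp | crisp |
| sensor noise σ (gray) | 1.5 | 1 | 1 |
| white blobs per 10⁴ px² | 0 | 1.2 (r = 1.5) | 1.5 (r = 2) |
| discrete HF cosine amplitude | 0 | 0 | 15 |

Ridges are level sets of a smooth potential (a tilted plane plus three
low-frequency harmonics), so orientation varies smoothly and the local
period is the nominal period divided by the potential's gradient magnitude;
the harmonic amplitude budget realizes the stated period modulation. The
ridge profile is a logistic-softened square wave whose threshold
`cos(π·duty)` makes the dark fraction of each period exactly the duty
cycle. fpgen_like adds Poisson-placed white disks and four fixed
high-frequency cosines whose spectral radii fall inside the `q_fft`
annulus. db4_like carries a smaller blob density: blob noising is part of
that generation pipeline too, and it is what makes both synthetic styles
rougher than a real capture at the Harris scale. Defaults were chosen so
each population separation holds with margin while classes remain
realistic distributions rather than disjoint point masses.

Per-image seeds are hashes of (master seed, image index), so any subset of
a batch is reproducible independently; images are 8-bit PNGs and
byte-stable under a fixed seed.

**What the fixtures do not show.** They contain no minutiae, cores, deltas,
curvature singularities, partial contact, skin distortion or real sensor
artifacts, and their class separations are by construction clearer than
FVC-grade data. Passing the end-to-end tests demonstrates that the pipeline
measures the intended cues and that the optimization machinery behaves per
its contract — not that the absolute accuracies transfer to real captures.

## Problem sizes

The default test/verification scale is a 400-image fixture set (200 real,
100 + 100 synthetic) for discrimination checks and 20-seed batches per
style for separation checks; the acceptance script uses a 240-image mixed
database, 50 evaluation repetitions and 20 repetitions per sweep point over
proportions 5%–50%. These sizes give stable means (repetition standard
errors well under the asserted margins) at single-CPU minutes.

## Known limitations

* The ridge-distance estimator assumes a locally parallel ridge flow; it
  under-samples regions of high curvature (windows there disagree with the
  block orientation, lowering the valid-sample count).
* Harris counts depend on the unnormalized-Sobel convention; a different
  gradient scaling would require re-deriving the 5,500 threshold.
* Wall-clock timings (and therefore wall-mode performance factors) are
  hardware-dependent by nature; only their ratios within one run are
  meaningful.
* The annulus inner radius 0.25·min(H, L) presumes ridge periods ≥ 4 px;
  much finer ridges would leak fundamental energy into the annulus.
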