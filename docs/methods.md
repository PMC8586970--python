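# Methods

## Problem and model

A focal stack is an ordered set of N co-registered grayscale frames of the
same scene, each focused at a different axial depth; the goal is a single
image in which every region is as sharp as it is in the best-focused frame.
The pipeline assumes (i) the frames are registered (axially swept
acquisition, no lateral drift), (ii) defocus is locally well described by an
isotropic Gaussian blur whose width grows with the distance between local
depth and the frame's focal plane, and (iii) in-focus regions carry more
mid/high spatial-frequency energy than defocused ones. It makes no
assumption about how many frames cover each region — overlapping focus areas
are resolved by weighted averaging, absent coverage by an explicit fallback.

## Focus detection

**Band-pass.** The transfer function is a difference of two frequency-domain
Gaussians, `H(D) = exp(-D^2 / 2 d_high^2) - exp(-D^2 / 2 d_low^2)`, on
centered normalized radial frequency (sampling frequency 1, Nyquist 0.5).
Defaults `d_low = 0.02`, `d_high = 0.25` cycles/pixel: DC gain is exactly
zero, so constant offsets and slow illumination gradients vanish; structure
above ~4 px period is attenuated, which suppresses single-pixel noise before
the Laplacian amplifies it. The filter is applied by plain (non-padded) FFT;
the DC bin sits at index 0 of `fftfreq`, equivalent to centering with the DC
bin at `floor(dim/2)` after a shift, for even and odd dimensions alike.

**Laplacian.** The r×r zero-sum mask (off-center 1, center `-(r^2-1)`),
r = 3 by default, convolved under replicate padding. Zero-sum guarantees
constant and linear intensity fields map to zero response.

**Thresholding.** The two-sided interval is applied to the response
*magnitude*: Laplacian responses are signed while focus energy is a
magnitude, and the upper bound rejects impulsive spikes. A `signed` operand
is exposed for the literal one-sided reading. Defaults are per-frame
percentiles of |response| — lower 70, upper 99.9 — because absolute
thresholds transfer poorly across specimens and cameras; absolute mode
remains available and is the right choice when calibrating across frames of
one acquisition (the blurred-frame rejection test uses it).

**Cleanup.** Components smaller than `0.0005 * H * W` pixels
(8-connectivity) are removed; the surviving regions are dilated with a disk
of radius equal to the Laplacian mask size, because the Laplacian marks only
the center line of an intensity transition while the in-focus region
extends beyond it.

## Guided-filter weighting

For frame n the filter input is the masked source `I_n * mask_n` and the
guidance is the binary dilated mask itself (an alternative
`guidance_mode="image"` uses `I_n`, not default). Per window
`a = cov(G, p) / (var(G) + eps)`, `b = mean(p) - a mean(G)`; the output
averages the overlapping per-window estimates. Box means use replicate
padding so every pixel sees a full `(2r+1)^2` count — this choice, rather
than truncated border windows, makes results bit-reproducible and is pinned
by a brute-force per-window least-squares oracle in the tests (agreement
max |diff| < 1e-10). `eps = 0` with a zero-variance window takes `a = 0`
(the regression limit), so constant patches pass through as their mean.
Default `eps = 1e-3`; larger values smooth the weight maps monotonically
(a tested invariant).

**Window selection.** Radii follow `r_n = 1 + (n-1) s` with `s = 2`
(1, 3, 5, ...), capped at `m = min(H, W) // 4` (512 for a 2048×2048 frame).
How the stopping index is chosen had to be operationalized: this package
walks the schedule and accepts the first radius at which the fraction of
pixels whose max-over-frames weight exceeds `coverage_tau = 1e-3` reaches
`coverage_frac = 0.999`, else the cap. Rationale: a too-small radius leaves
uncovered gaps between fused areas (the coverage fraction measures exactly
this), while stopping at the first covering radius avoids bleeding weight
into defocused regions. A fixed radius is available (`--window-size`).

## Fusion rule

Per pixel the raw weights are sum-normalized and the fused value is the
convex combination `F = sum_n w~_n I_n`; consequently
`min_n I_n <= F <= max_n I_n` everywhere the weights are not all zero.
All-zero pixels take the unweighted frame mean and are flagged in
`fallback_mask`. The dominant-frame index map uses a stable argmax (ties go
to the lower frame index) so results are deterministic and permutation
equivariant up to exact ties.

## Quality metrics

* **QMI** `= 2 [MI(A,F)/(H(A)+H(F)) + MI(B,F)/(H(B)+H(F))]` from 256-bin
  equal-width joint histograms over [0, 1]. The log base cancels.
* **QNCIE** `= 1 + sum_i (lam_i/3) log_256 (lam_i/3)` over the eigenvalues
  of the 3×3 nonlinear-correlation matrix of (A, B, F). The off-diagonal
  nonlinear correlation coefficient is `2 + sum p_ij log_256 p_ij` computed
  on *equal-count* (rank-uniform) 256-level codes, the convention under
  which identical images score exactly 1 and independent ones approach 0;
  equal-width binning would not satisfy either anchor. Rank codes use a
  stable sort, so the metric is invariant to monotone intensity remapping.
* **QG** — Sobel gradient magnitude and orientation per image;
  edge-strength preservation = min/max magnitude ratio, orientation
  preservation = 1 − |Δα|/(π/2); both pass through the canonical sigmoid
  preservation model (Γ_g = 0.9994, κ_g = −15, σ_g = 0.5; Γ_α = 0.9879,
  κ_α = −22, σ_α = 0.8), each sigmoid normalized by its value at perfect
  preservation so that F = A = B scores exactly 1; source gradient
  magnitudes are the weights. All constants are recorded in the report.
* **PSNR** `10 log10(MAX^2 / MSE)`; MSE = 0 is undefined and surfaces as a
  flagged +inf. **SSIM** with an 11×11, σ = 1.5 Gaussian window,
  `C1 = (0.01 L)^2`, `C2 = (0.03 L)^2`, L = 1 for normalized intensities;
  population (not sample) local covariances; cross-checked against the
  scikit-image implementation on window interiors.
* **MSCN / GGD** — `(I - mu)/(sd + c)` under a 7×7, σ = 7/6 Gaussian window
  with `c = 1/255`, and a moment-matching generalized-Gaussian fit
  (ratio `E[x^2]/E[|x|]^2` inverted on a ν ∈ [0.2, 10] grid). These are
  building blocks only; full no-reference scores require trained
  natural-scene corpora and are out of scope. Note the MSCN variance of
  i.i.d. noise under the canonical 7×7 window is ≈ 0.73, not 1: the local
  mean/SD are estimated from few, shared samples. It approaches 1 only as
  the window grows; the tests assert exactly that behaviour.
* Undefined cases (zero entropy, constant inputs, zero MSE, gradient-free
  sources) return flagged sentinels with warnings rather than raising, so
  batch evaluation over stacks completes.
* For N > 2 sources every unordered source pair is scored against the fused
  image and the pair values are averaged.

## Synthetic data

The generator emulates an axially swept acquisition of a non-flat specimen:

* **Scenes** — `cells` (soft-edged elliptical bright blobs on a dark
  background with a mild illumination gradient), `texture` (band-limited
  random texture), `bars` (resolution bars). Depth maps: planar tilt,
  piecewise-constant bands, or a spherical cap (deepest at center, the
  ocular-curvature analogue). Deterministic per seed.
* **Depth-driven defocus** — per frame k, per pixel,
  `sigma = clip(slope * |depth - focal_plane_k|, 0, sigma_max)` with
  focal planes spanning the depth range. Default slope 6 per unit depth
  range keeps the in-focus band (σ < 0.5 px) to roughly one sixth of the
  range — a shallow depth-of-field regime. Spatially varying blur blends a
  σ-ladder of uniformly blurred copies (0.5 px spacing, linear
  interpolation): exact per-pixel convolution is quadratically more
  expensive and indistinguishable at test scale. Optional additive Gaussian
  read noise and Poisson shot noise are applied after blurring.
* **Region protocol** (`fig4_protocol`) — the full-reference experiment
  design: each frame blurs the whole reference with a fixed σ (default 3 px)
  and restores one region (vertical bands or a seeded Voronoi tiling) to the
  exact reference values, so the original image is the unambiguous ground
  truth for PSNR/SSIM.

What the generator does *not* model: physically accurate defocus PSFs
(Airy rings, aberrations), fluorescence photophysics (bleaching, shot-noise
correlations), registration error, or depth discontinuity occlusions.
Passing tests therefore demonstrate the pipeline's behaviour under
Gaussian-defocus geometry with known ground truth, not performance on any
particular instrument's data.

## Problem sizes and determinism

The validation suite runs the end-to-end experiment at 512×512 with 3
frames, robustness at 512×512 with noise and at 256×256 with 20 frames, and
oracle equivalence on ≤ 15×15 instances — sizes at which every property of
interest (coverage-driven window growth, seam-free fusion, convexity,
monotonicity) is already expressed. All randomness is seeded; repeated runs
are bit-identical.

## Known limitations

* Percentile thresholds always label ~30 % of a frame's pixels before
  cleanup, so a frame with *no* in-focus content still yields a mask;
  absolute thresholds calibrated on a sharp frame are the remedy and are
  what the blurred-frame rejection test exercises.
* The coverage-based stopping rule can run to the radius cap on scenes with
  large textureless regions (weights decay with distance from any mask), in
  which case weight maps are very smooth; fusion quality is unaffected in
  such flat regions but the chosen radius is then scene-global, not local.
* Binary-mask guidance means the guided filter softens mask geometry but
  ignores image edges inside the mask; `guidance_mode="image"` trades seam
  smoothness for edge awareness.
* Metrics assume intensities in [0, 1]; pass `max_value` explicitly when
  scoring 8-bit data without normalization.
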