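# Methods

## The model

An observed frame is modelled as y = x + ε with x the noise-free [0, 1]
image and ε i.i.d. Gaussian with standard deviation σ (the additive model
under which the universal threshold is derived). Real B-mode speckle is
multiplicative; the phantom simulator offers a unit-mean Rayleigh-derived
speckle field to stress the pipeline beyond the additive assumption, but
the threshold itself is always the additive-model formula.

In an orthonormal wavelet basis the noise stays i.i.d. Gaussian with the
same σ in every subband, while the image content concentrates in a few
large coefficients (the smooth background and cyst interiors land almost
entirely in the approximation). The VisuShrink threshold
S = σ·√(2 ln M) (M = pixel count) is the asymptotic maximum of M Gaussian
noise deviates, so thresholding at S removes essentially all noise
coefficients at the cost of slight oversmoothing — the standard
bias/variance trade of the universal rule. Detail enhancement is the
linear map c → H·c + f applied after thresholding.

## Pipeline conventions and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| wavelet | `db4` | — | conventional choice for VisuShrink-style denoising; `haar` used wherever exact hand-checked values matter |
| levels | 3 | — | deep enough that a 128×128 image's smooth content reaches the approximation; admissible for images ≥ 8 px |
| mode | `soft` | — | continuous shrinkage avoids the ringing of keep-or-kill at the threshold boundary |
| σ | estimated | intensity | MAD of the finest diagonal subband / 0.6745; override with a known value |
| M | rows·cols | px | "signal length" read as total pixel count, the universal-threshold convention for images |
| H, f | 1, 0 | — | identity enhancement: pure denoising unless contrast boost is requested |
| boundary | symmetric | — | half-sample extension avoids edge discontinuities; `periodic` (non-expansive periodisation) provided because it is the mode under which orthonormal filters are exactly energy-preserving |
| clip | on | — | enhancement can overshoot [0, 1]; reconstruction is clipped |

Further fixed choices:

- **Threshold scope.** Only detail subbands are thresholded; the
  approximation is never touched. One global S is used for all levels
  (per-level rescaling deliberately not implemented — one formula, one
  threshold).
- **Order.** Threshold first, then enhance: the gain acts on
  noise-suppressed coefficients.
- **Offset hazard.** f ≠ 0 is applied to every targeted coefficient,
  including zeroed ones, re-introducing a constant into flat regions;
  hence the f = 0 default.
- **Admissible depth.** `levels` may not exceed ⌊log₂(min(rows, cols))⌋,
  i.e. the dyadic grid must fit the shortest axis; errors name the
  maximum. This is more permissive than the filter-length rule some
  libraries default to — with boundary extension, perfect reconstruction
  holds at these depths (verified to 1e-8 in the tests), at the price of
  extension-dominated coarse subbands.
- **Subband naming and signs.** Subbands are named approximation /
  horizontal / vertical / diagonal per level (level 1 finest). The detail
  sign convention is the declared filter's: for Haar, a pair (x₀, x₁)
  yields detail (x₀ − x₁)/√2. Tests compare against this declared
  convention, not an absolute sign.
- **Degenerate inputs.** Constant images estimate σ = 0 and pass through
  unchanged; S = 0 or H = 1, f = 0 are exact identities; non-2-D,
  out-of-range, or non-finite inputs raise before any work is done.

## Phantom simulator

The generator emulates the gross appearance of gynecological B-mode
targets at toy scale — a dark anechoic cyst and a bright echogenic spot on
a mid-gray background — with a smooth low-frequency texture (Gaussian
random field, smoothing length min(shape)/16, normalised to the requested
amplitude, default 0.04). Defaults: 128×128, background 0.5, additive
Gaussian noise σ = 0.1. The multiplicative option multiplies the clean
image by 1 + σ·(R − μ_R)/sd_R with R Rayleigh(1), a unit-mean field with
standard deviation σ whose local noise power scales with intensity.

What it does *not* model: point-spread functions, attenuation, shadowing,
scan conversion, log compression. Passing tests therefore demonstrate the
pipeline's behaviour under controlled, near-sparse-detail conditions, not
clinical image quality; on real frames the speckle is correlated and the
additive-Gaussian σ estimate is only an effective value.

## Summary-statistics inference

No patient-level data exist for the accompanying two-arm study (n = 28
per arm), so its comparisons are reconstructed from the printed tables:

- **Continuous outcomes** (propofol dose, hospital stay, VAS and PONV
  scores): Welch's t from (mean, SD, n), Welch–Satterthwaite df,
  two-sided p. The source analysed these "by variance"; for two groups a
  one-way ANOVA is p-identical to the pooled t-test (F = t²), which is
  available via `continuous_method="pooled"`. Welch is the default
  because the printed SDs are visibly unequal; both routes agree on every
  significance verdict here (checked in the tests).
- **Count outcomes** (rescue tramadol): Fisher's exact two-sided test
  (sum of hypergeometric point probabilities ≤ the observed one), chosen
  over chi-square for expected counts well below 5; chi-square without
  continuity correction is available as an alternative.
- The study's abstract swaps the group labels for the propofol and stay
  rows; the results section's labelling (block group lower) is used.
- Surgery time was claimed non-significant but its summaries were never
  printed: reported as NOT COMPUTABLE rather than guessed.
- Recomputation verdicts: all nine computable continuous rows and the 3 h
  tramadol table reproduce the published p < 0.05; the 6 h (1 vs 7
  events, p ≈ 0.051) and 12 h (1 vs 3, p ≈ 0.61) tramadol tables do not.
  The report flags these rows as inconsistent instead of resolving the
  contradiction.

## Numerical and testing choices

- Transform exactness: round-trip identity asserted at 1e-8 over 200
  seeded images (both families, all three boundary modes, levels 1–3);
  Parseval at 1e-6 relative under periodisation; the Haar path is checked
  against an explicit orthogonal-matrix oracle at 1e-12.
- Fisher's p is verified against an exact-rational hypergeometric
  enumeration: exhaustively for every table with N ≤ 20, by seeded sample
  for 20 < N ≤ 60.
- Type-I calibration of the summary-based Welch test: 2000 null
  simulations of two n = 28 Gaussian groups; the rejection rate at
  α = 0.05 must land in 5% ± 1.5% (binomial SD ≈ 0.5%, so a ±3 SD band).
- Denoising efficacy: soft VisuShrink must gain ≥ 2 dB PSNR over the
  noisy input on ≥ 9 of 10 seeded σ = 0.1 phantoms (it typically gains
  8–9 dB).
- Problem sizes (128×128 phantoms, 200 round-trip images, 2000 null
  replicates) keep the full suite in a few seconds while leaving every
  statistical margin wide.

## Known limitations

- VisuShrink oversmooths fine texture by construction; adaptive rules
  (SureShrink, BayesShrink) are out of scope.
- One global threshold across levels; no cycle spinning / undecimated
  transform, so mild ringing near strong edges is possible.
- The σ estimator assumes the finest diagonal subband is noise-dominated;
  it overestimates on images with strong fine texture.
- Multiplicative speckle violates the additive noise model; the pipeline
  still helps (thresholding is signal-agnostic) but the threshold is no
  longer the theoretically motivated one.
- Grayscale PNG/TIFF only; DICOM is a documented extension point, not a
  dependency.
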