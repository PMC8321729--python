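# wtie — wavelet-transform image enhancement for grayscale ultrasound

Ultrasound B-mode frames are corrupted by granular speckle and electronic
noise that obscure low-contrast targets such as anechoic cysts. `wtie`
implements the classical wavelet-shrinkage answer for single-channel
images:

1. **Decompose** the image with a multilevel separable 2-D discrete
   wavelet transform (DWT) into an approximation grid plus horizontal /
   vertical / diagonal detail grids per level.
2. **Shrink** the detail coefficients with a hard or soft threshold at the
   VisuShrink universal level

   S = σ·√(2 ln M),

   where σ is the noise standard deviation (given, or estimated robustly
   as median(|d₁,diag|)/0.6745 from the finest diagonal subband) and M is
   the pixel count. Hard thresholding keeps a coefficient A unchanged when
   |A| ≥ S and zeroes it otherwise; soft thresholding additionally shrinks
   survivors to sign(A)·(|A| − S).
3. **Enhance** the surviving details with the linear map c → H·c + f
   (gain H, offset f) to raise edge contrast.
4. **Reconstruct** with the inverse DWT and clip to [0, 1].

The approximation — which carries the anatomy — is never thresholded.
Orthonormal filters (default `db4`; `haar` for hand-checkable numbers) make
analysis and synthesis mutually inverse to machine precision.

The package also ships:

- a **seeded phantom simulator** (`wtie.phantom`): cyst targets on a
  smooth textured background with additive Gaussian noise or unit-mean
  multiplicative speckle, so every property of the pipeline is testable
  without any data download;
- **quality metrics** (`wtie.metrics`): peak-1 PSNR and cyst
  contrast-to-noise ratio (CNR);
- **summary-statistics inference** (`wtie.clinical`): Welch's t-test from
  (mean, SD, n) and Fisher's exact test on 2×2 counts, used to recompute
  the two-group clinical comparisons of the accompanying study (two arms
  of 28 patients undergoing gynecological laparoscopy) from its printed
  tables — including flagging the published claims that do **not** survive
  recomputation.

## Worked example

`python examples/denoise_phantom.py` generates a 128×128 phantom with
noise σ = 0.1 and runs the soft-threshold pipeline:

```
estimated noise sigma : 0.0941  (true 0.1000)
universal threshold S : 0.4144
PSNR noisy    vs clean:  20.12 dB
PSNR enhanced vs clean:  28.75 dB
CNR of the cyst, noisy    :  2.90
CNR of the cyst, enhanced :  6.69
```

The MAD estimator recovers the injected noise level within 6%; denoising
buys ~8.6 dB of PSNR and more than doubles the cyst's contrast-to-noise
ratio. `python examples/clinical_comparisons.py` prints the reproduced
study table; the propofol row, for instance, gives Welch t = −11.68,
df = 53.6, p = 2.4·10⁻¹⁶, consistent with the published p < 0.05, while
the 6 h and 12 h tramadol count tables come out at p = 0.051 and p = 0.61
— *inconsistent* with the published blanket significance claim.

The same pipeline is available from the shell:

```sh
wtie phantom out/ --seed 7 --sigma 0.1      # write clean/noisy PNG pair
wtie enhance out/noisy.png out/enhanced.png # denoise with defaults
wtie evaluate out/clean.png out/noisy.png out/enhanced.png
wtie stats                                  # reproduced clinical table
```

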