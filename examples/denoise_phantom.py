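"""Denoise a seeded synthetic cyst phantom and measure the improvement.

Generates a 128x128 phantom (dark anechoic cyst + bright echogenic spot on
a textured background) with additive Gaussian noise sigma = 0.1, runs the
soft-threshold VisuShrink pipeline, and prints PSNR against the clean
ground truth plus the contrast-to-noise ratio of the cyst. Higher PSNR
means the output is closer to the noise-free image; higher CNR means the
cyst stands out more clearly from the background.
"""

from wtie import PhantomSpec, WtieConfig, cnr, make_phantom, psnr, wtie_enhance
from wtie.phantom import background_mask, cyst_mask

spec = PhantomSpec(noise_sigma=0.1, seed=7)
clean, noisy = make_phantom(spec)

enhanced, report = wtie_enhance(noisy, WtieConfig(mode="soft"), return_report=True)

print(f"estimated noise sigma : {report['sigma']:.4f}  (true 0.1000)")
print(f"universal threshold S : {report['threshold']:.4f}")
print(f"PSNR noisy    vs clean: {psnr(clean, noisy):6.2f} dB")
print(f"PSNR enhanced vs clean: {psnr(clean, enhanced):6.2f} dB")

cm = cyst_mask(spec.shape, spec.cysts[0], shrink=2.0)
bm = background_mask(spec)
print(f"CNR of the cyst, noisy    : {cnr(noisy, cm, bm):5.2f}")
print(f"CNR of the cyst, enhanced : {cnr(enhanced, cm, bm):5.2f}")
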