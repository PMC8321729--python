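"""File-to-file enhancement: the library path behind `wtie enhance`.

Writes a noisy phantom to a 16-bit PNG, reads it back, runs the pipeline
with a mild detail gain, and saves the result — the round trip a user
would do with real ultrasound frames exported as PNG/TIFF.
"""

import tempfile
from pathlib import Path

from wtie import (
    PhantomSpec, WtieConfig, make_phantom, psnr, read_image, write_image, wtie_enhance,
)

workdir = Path(tempfile.mkdtemp(prefix="wtie_"))
clean, noisy = make_phantom(PhantomSpec(noise_sigma=0.1, seed=3))
write_image(noisy, workdir / "frame.png", bitdepth=16)

img = read_image(workdir / "frame.png")
out = wtie_enhance(img.pixels, WtieConfig(mode="soft", gain=1.2))
write_image(out, workdir / "frame_enhanced.png", bitdepth=16)

print(f"input : {workdir / 'frame.png'} ({img.rows}x{img.cols}, {img.source_bitdepth}-bit)")
print(f"output: {workdir / 'frame_enhanced.png'}")
print(f"PSNR vs ground truth: noisy {psnr(clean, noisy):.2f} dB -> "
      f"enhanced {psnr(clean, out):.2f} dB")
print("gain=1.2 amplifies the surviving detail coefficients by 20% to")
print("sharpen edges after the noise has been thresholded away.")
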