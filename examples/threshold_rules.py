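"""The three building blocks of wavelet shrinkage, on hand-checkable numbers.

Hard thresholding keeps a coefficient untouched when |A| >= S and zeroes it
otherwise; soft thresholding additionally shrinks survivors by S; the
VisuShrink universal threshold S = sigma * sqrt(2 ln M) scales with the
noise level sigma and (slowly) with the signal length M.
"""

from wtie import hard_threshold, soft_threshold, visu_shrink_threshold

print("hard_threshold( 5, 3) =", hard_threshold(5.0, 3.0), " (kept: |5| >= 3)")
print("hard_threshold( 2, 3) =", hard_threshold(2.0, 3.0), " (zeroed: |2| < 3)")
print("soft_threshold( 5, 3) =", soft_threshold(5.0, 3.0), " (shrunk by S)")
print("soft_threshold(-5, 3) =", soft_threshold(-5.0, 3.0), "(sign preserved)")

s = visu_shrink_threshold(2.0, 65536)
print(f"visu_shrink_threshold(sigma=2, M=256*256) = {s:.4f}")
print("  -> for a 256x256 image with noise SD 2, coefficients smaller in")
print("     magnitude than ~9.42 are treated as noise")
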