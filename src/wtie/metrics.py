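"""Image-quality metrics for denoising and contrast enhancement.

All images are [0, 1] floats, so PSNR uses peak 1.0 throughout — no
bit-depth ambiguity. A zero-MSE comparison reports infinite PSNR;
likewise zero-variance regions give infinite CNR.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np


def mse(reference, test) -> float:
    """Mean squared error between two same-shape images."""
    a = np.asarray(reference, dtype=float)
    b = np.asarray(test, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(reference, test) -> float:
    """Peak signal-to-noise ratio in dB, peak = 1.0; inf for identical images."""
    m = mse(reference, test)
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / m)


def cnr(image, cyst_mask, background_mask) -> float:
    """Contrast-to-noise ratio between a target region and the background.

    ``|mean_bg - mean_cyst| / sqrt(var_bg + var_cyst)``; infinite when both
    regions are exactly uniform but differ in mean, 0 for equal means.
    """
    a = np.asarray(image, dtype=float)
    cm = np.asarray(cyst_mask, dtype=bool)
    bm = np.asarray(background_mask, dtype=bool)
    if cm.shape != a.shape or bm.shape != a.shape:
        raise ValueError("masks must match the image shape")
    if not cm.any() or not bm.any():
        raise ValueError("masks must be non-empty")
    if (cm & bm).any():
        raise ValueError("cyst and background masks must be disjoint")
    mc, mb = a[cm].mean(), a[bm].mean()
    vc, vb = a[cm].var(), a[bm].var()
    contrast = abs(mb - mc)
    denom = math.sqrt(vb + vc)
    if denom == 0.0:
        return math.inf if contrast > 0 else 0.0
    return contrast / denom


@dataclass(frozen=True)
class QualityReport:
    """MSE, PSNR and (optionally) CNR of an image against a reference."""

    mse: float
    psnr_db: float
    contrast_cnr: Optional[float] = None

    def to_json(self) -> str:
        d = {"mse": self.mse, "psnr_db": self.psnr_db}
        if self.contrast_cnr is not None:
            d["contrast_cnr"] = self.contrast_cnr
        # single-line JSON; infinities serialized as strings for portability
        return json.dumps(
            {k: ("inf" if v == math.inf else v) for k, v in d.items()}
        )


def quality_report(reference, test, cyst_mask=None, background_mask=None) -> QualityReport:
    """Bundle MSE/PSNR (and CNR when masks are supplied) into one report."""
    c = None
    if cyst_mask is not None and background_mask is not None:
        c = cnr(test, cyst_mask, background_mask)
    return QualityReport(mse=mse(reference, test), psnr_db=psnr(reference, test), contrast_cnr=c)
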