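"""Reading and writing 8/16-bit grayscale PNG/TIFF as [0, 1] float images.

Ultrasound frames are single-channel; RGB input is accepted only with an
explicit luminance-conversion flag (ITU-R BT.601 weights). DICOM is
deliberately out of scope — convert to 16-bit PNG/TIFF upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff"}

#: BT.601 luminance weights for optional RGB conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A [0, 1] float grayscale image plus its source bit depth (8, 16, or 'float')."""

    pixels: np.ndarray
    source_bitdepth: Union[int, str]

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2 or p.size < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {p.shape}")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError(
                f"pixel values must lie in [0, 1]; got range [{p.min():.4g}, {p.max():.4g}]"
            )

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


def _check_suffix(path: Path) -> None:
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported image format {path.suffix!r} for {path.name}; "
            f"expected one of {sorted(_SUPPORTED_SUFFIXES)}"
        )


def read_image(path, *, rgb_to_luminance: bool = False) -> GrayImage:
    """Read a PNG/TIFF into a [0, 1] GrayImage, recording the bit depth.

    Integer images are scaled by 1/(2^depth - 1). Multi-channel input
    raises unless ``rgb_to_luminance`` is set, in which case 3-channel RGB
    is collapsed with BT.601 weights.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    _check_suffix(path)
    arr = iio.imread(path)

    if arr.dtype == np.uint8:
        scale, depth = 255.0, 8
    elif arr.dtype == np.uint16:
        scale, depth = 65535.0, 16
    elif arr.dtype.kind == "f":
        scale, depth = 1.0, "float"
    else:
        raise ValueError(f"{path.name}: unsupported pixel dtype {arr.dtype}")

    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0].astype(float)
        elif arr.shape[2] in (3, 4) and rgb_to_luminance:
            arr = arr[:, :, :3].astype(float) @ _LUMA
        else:
            raise ValueError(
                f"{path.name} has {arr.shape[2]} channels; grayscale expected "
                "(pass rgb_to_luminance=True to convert RGB)"
            )
    elif arr.ndim == 2:
        arr = arr.astype(float)
    else:
        raise ValueError(f"{path.name}: expected a 2-D image, got {arr.ndim}-D data")

    a = arr / scale
    if a.min() < 0.0 or a.max() > 1.0:
        raise ValueError(f"{path.name}: image values must lie in [0, 1] after scaling")
    return GrayImage(a, depth)


def write_image(image, path, bitdepth: int = 8) -> None:
    """Quantize to 8 or 16 bits, clip to [0, 1], and write PNG/TIFF."""
    path = Path(path)
    _check_suffix(path)
    if bitdepth not in (8, 16):
        raise ValueError(f"bitdepth must be 8 or 16, got {bitdepth}")
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {pixels.ndim}-D data")
    peak = 2**bitdepth - 1
    q = np.rint(np.clip(pixels, 0.0, 1.0) * peak)
    out = q.astype(np.uint8 if bitdepth == 8 else np.uint16)
    try:
        iio.imwrite(path, out)
    except OSError as exc:
        raise OSError(f"cannot write image to {path}: {exc}") from exc
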