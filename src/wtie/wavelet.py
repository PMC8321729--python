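"""Multilevel 2-D discrete wavelet decomposition and exact reconstruction.

A grayscale image is decomposed by a separable filter bank into one
approximation grid plus three oriented detail grids (horizontal, vertical,
diagonal) per level; level 1 is the finest scale. The transform and its
inverse are delegated to PyWavelets; this module fixes the conventions the
rest of the pipeline relies on:

* orthonormal filter normalisation, so that analysis and synthesis are
  mutually inverse and (with periodic boundaries) energy-preserving;
* dyadic scale steps (each level halves the grid, ceiling division);
* the detail-sign convention of the declared filter coefficients
  (for Haar, the detail of a pair ``(x0, x1)`` is ``(x0 - x1)/sqrt(2)``).

Boundary handling is symmetric (half-sample) extension by default;
``periodic`` (non-expansive periodisation) and ``zero`` padding are also
available. With symmetric or zero extension the subband grids are slightly
larger than ``ceil(n/2)`` because the extension adds ``filter_length - 2``
samples before decimation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
import pywt

ORIENTATIONS: Tuple[str, str, str] = ("horizontal", "vertical", "diagonal")

BOUNDARY_MODES = ("symmetric", "periodic", "zero")

# pywt's "periodization" is the non-expansive periodic DWT (orthonormal for
# orthonormal filters); its "periodic" padding mode is expansive and unused.
_PYWT_MODE = {"symmetric": "symmetric", "periodic": "periodization", "zero": "zero"}


@dataclass(frozen=True)
class WaveletSpec:
    """A discrete wavelet: its four filters plus a boundary-extension mode.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"haar"`` or ``"db4"``.
    dec_lo, dec_hi, rec_lo, rec_hi:
        Decomposition / reconstruction low- and high-pass filter
        coefficients. For orthonormal families ``sum(dec_lo**2) == 1``.
    boundary_mode:
        One of ``"symmetric"``, ``"periodic"``, ``"zero"``.
    """

    name: str
    dec_lo: Tuple[float, ...]
    dec_hi: Tuple[float, ...]
    rec_lo: Tuple[float, ...]
    rec_hi: Tuple[float, ...]
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ValueError(
                f"unknown boundary_mode {self.boundary_mode!r}; "
                f"expected one of {BOUNDARY_MODES}"
            )
        if len(self.dec_lo) < 2:
            raise ValueError("filters must have length >= 2")

    @classmethod
    def from_name(cls, name: str, boundary_mode: str = "symmetric") -> "WaveletSpec":
        """Build from a PyWavelets family name (``haar``, ``db4``, ...)."""
        try:
            w = pywt.Wavelet(name)
        except ValueError as exc:
            raise ValueError(f"unknown wavelet name {name!r}") from exc
        return cls(
            name=name,
            dec_lo=tuple(w.dec_lo),
            dec_hi=tuple(w.dec_hi),
            rec_lo=tuple(w.rec_lo),
            rec_hi=tuple(w.rec_hi),
            boundary_mode=boundary_mode,
        )

    @property
    def filter_length(self) -> int:
        return len(self.dec_lo)

    @property
    def is_orthonormal(self) -> bool:
        """Sum of squares of the analysis low-pass equals 1 (within 1e-10)."""
        return abs(sum(c * c for c in self.dec_lo) - 1.0) < 1e-10

    def with_boundary(self, boundary_mode: str) -> "WaveletSpec":
        return replace(self, boundary_mode=boundary_mode)

    def _pywt(self) -> pywt.Wavelet:
        fb = [list(self.dec_lo), list(self.dec_hi), list(self.rec_lo), list(self.rec_hi)]
        return pywt.Wavelet(self.name, filter_bank=fb)

    @property
    def _mode(self) -> str:
        return _PYWT_MODE[self.boundary_mode]

    def reconstruction_error(self, length: int = 32, seed: int = 0) -> float:
        """Max |x - idwt(dwt(x))| on a random signal; ~0 for a valid pair."""
        x = np.random.default_rng(seed).standard_normal(max(length, self.filter_length))
        a, d = pywt.dwt(x, self._pywt(), mode=self._mode)
        y = pywt.idwt(a, d, self._pywt(), mode=self._mode)[: x.size]
        return float(np.max(np.abs(x - y)))


#: default family for the pipeline; haar is used where hand-checked numbers matter
DEFAULT_WAVELET = "db4"


@dataclass
class SubbandSet:
    """Wavelet coefficients of a 2-D image: approximation + oriented details.

    ``details[j][o]`` holds the level-``j`` detail grid for orientation
    ``o`` in :data:`ORIENTATIONS`; ``j`` runs from 1 (finest) to ``levels``
    (coarsest). ``approx`` is the level-``levels`` approximation.
    """

    levels: int
    approx: np.ndarray
    details: Dict[int, Dict[str, np.ndarray]]
    original_shape: Tuple[int, int]
    wavelet: WaveletSpec = field(repr=False)

    def detail(self, level: int, orientation: str) -> np.ndarray:
        try:
            return self.details[level][orientation]
        except KeyError:
            raise KeyError(
                f"no detail subband at level {level}, orientation {orientation!r}; "
                f"levels 1..{self.levels}, orientations {ORIENTATIONS}"
            ) from None

    def copy(self) -> "SubbandSet":
        return SubbandSet(
            levels=self.levels,
            approx=self.approx.copy(),
            details={
                j: {o: g.copy() for o, g in grids.items()}
                for j, grids in self.details.items()
            },
            original_shape=self.original_shape,
            wavelet=self.wavelet,
        )

    def iter_details(self):
        """Yield (level, orientation, grid) over all detail subbands."""
        for j in range(1, self.levels + 1):
            for o in ORIENTATIONS:
                yield j, o, self.details[j][o]

    def energy(self) -> float:
        """Sum of squared coefficients across all subbands."""
        e = float(np.sum(self.approx**2))
        for _, _, g in self.iter_details():
            e += float(np.sum(g**2))
        return e

    # -- shape bookkeeping -------------------------------------------------

    def _expected_shapes(self) -> Dict[int, Tuple[int, int]]:
        """Subband shape at each level, cascading from the original image."""
        shapes = {}
        r, c = self.original_shape
        for j in range(1, self.levels + 1):
            r = _dwt_out_len(r, self.wavelet)
            c = _dwt_out_len(c, self.wavelet)
            shapes[j] = (r, c)
        return shapes

    def validate_shapes(self) -> None:
        """Raise if any subband grid disagrees with the declared geometry."""
        expected = self._expected_shapes()
        if self.approx.shape != expected[self.levels]:
            raise ValueError(
                f"approximation shape {self.approx.shape} != expected "
                f"{expected[self.levels]} at level {self.levels}"
            )
        for j, o, g in self.iter_details():
            if g.shape != expected[j]:
                raise ValueError(
                    f"detail subband at level {j}, orientation {o!r} has shape "
                    f"{g.shape}, expected {expected[j]}"
                )

    def _to_pywt(self):
        coeffs = [self.approx]
        for j in range(self.levels, 0, -1):
            d = self.details[j]
            coeffs.append((d["horizontal"], d["vertical"], d["diagonal"]))
        return coeffs

    @classmethod
    def _from_pywt(cls, coeffs, original_shape, wavelet) -> "SubbandSet":
        levels = len(coeffs) - 1
        details: Dict[int, Dict[str, np.ndarray]] = {}
        # pywt orders coarsest-to-finest after the approximation
        for i, (ch, cv, cd) in enumerate(coeffs[1:]):
            j = levels - i
            details[j] = {"horizontal": ch, "vertical": cv, "diagonal": cd}
        return cls(
            levels=levels,
            approx=coeffs[0],
            details=details,
            original_shape=original_shape,
            wavelet=wavelet,
        )


def _dwt_out_len(n: int, wavelet: WaveletSpec) -> int:
    if wavelet.boundary_mode == "periodic":
        return -(-n // 2)
    return (n + wavelet.filter_length - 1) // 2


def _as_wavelet(wavelet) -> WaveletSpec:
    if isinstance(wavelet, WaveletSpec):
        return wavelet
    return WaveletSpec.from_name(str(wavelet))


def max_levels(shape, wavelet=None) -> int:
    """Maximum admissible decomposition depth: the deepest J such that the
    dyadic grid 2^J still fits along the shortest axis."""
    n = min(int(s) for s in np.atleast_1d(shape).ravel()) if np.ndim(shape) else int(shape)
    if n < 2:
        return 0
    return int(math.floor(math.log2(n)))


def _check_levels(shape, wavelet: WaveletSpec, levels: int) -> None:
    if not isinstance(levels, (int, np.integer)) or levels < 1:
        raise ValueError(f"levels must be a positive integer, got {levels!r}")
    admissible = max_levels(shape, wavelet)
    if levels > admissible:
        raise ValueError(
            f"levels={levels} too deep for input of shape {tuple(np.atleast_1d(shape))} "
            f"with wavelet {wavelet.name!r} (filter length {wavelet.filter_length}); "
            f"maximum admissible level is {admissible}"
        )


def dwt1(signal, wavelet="haar", levels: int = 1):
    """Multilevel 1-D DWT.

    Returns ``(approx, details)`` where ``approx`` is the coarsest
    approximation and ``details`` maps level (1 = finest) to the detail
    coefficient array at that level.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got {x.ndim}-D input")
    w = _as_wavelet(wavelet)
    if x.size < w.filter_length:
        raise ValueError(
            f"signal length {x.size} shorter than filter length {w.filter_length}"
        )
    _check_levels(x.size, w, levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, w._pywt(), mode=w._mode, level=levels)
    details = {levels - i: d for i, d in enumerate(coeffs[1:])}
    return coeffs[0], details


def dwt2(image, wavelet="db4", levels: int = 1) -> SubbandSet:
    """Multilevel separable 2-D DWT of a grayscale image.

    The input is filtered along rows then columns with the declared
    analysis filters, decimated dyadically, and recursed on the
    approximation. The input array is never modified.
    """
    a = np.asarray(image, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {a.ndim}-D input")
    w = _as_wavelet(wavelet)
    _check_levels(a.shape, w, levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(a, w._pywt(), mode=w._mode, level=levels)
    return SubbandSet._from_pywt(coeffs, a.shape, w)


def idwt2(subbands: SubbandSet) -> np.ndarray:
    """Inverse multilevel 2-D DWT; exact inverse of :func:`dwt2`.

    Raises if any subband grid is inconsistent with the recorded geometry,
    naming the offending level and orientation.
    """
    subbands.validate_shapes()
    w = subbands.wavelet
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rec = pywt.waverec2(subbands._to_pywt(), w._pywt(), mode=w._mode)
    r, c = subbands.original_shape
    return np.ascontiguousarray(rec[:r, :c])
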