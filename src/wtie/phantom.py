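"""Seeded synthetic ultrasound-like phantoms for testing the pipeline.

A phantom is a textured background carrying filled circular "cyst" targets
— dark disks mimic anechoic cysts, bright ones dense echogenic spots — to
which either additive Gaussian noise or multiplicative unit-mean speckle is
applied. The texture is a smooth low-frequency field, so the clean
phantom's detail subbands are near-sparse: the regime where wavelet
shrinkage helps.

Everything is driven by a single integer seed through ``numpy``'s PCG64
generator, so identical specs give bit-identical images across runs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

NOISE_MODELS = ("gaussian_additive", "speckle_multiplicative")


@dataclass(frozen=True)
class Cyst:
    """A filled disk target: center (row, col), radius in px, intensity in [0,1]."""

    row: float
    col: float
    radius: float
    intensity: float


#: two targets: a large dark (anechoic) cyst and a small bright echogenic spot
DEFAULT_CYSTS: Tuple[Cyst, ...] = (
    Cyst(row=52.0, col=44.0, radius=18.0, intensity=0.08),
    Cyst(row=92.0, col=92.0, radius=9.0, intensity=0.88),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom; equal specs yield identical images."""

    shape: Tuple[int, int] = (128, 128)
    background_level: float = 0.5
    cysts: Tuple[Cyst, ...] = DEFAULT_CYSTS
    texture_amplitude: float = 0.04
    noise_model: str = "gaussian_additive"
    noise_sigma: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.shape
        if rows < 1 or cols < 1:
            raise ValueError(f"invalid shape {self.shape}")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError(f"background_level must be in [0,1], got {self.background_level}")
        if self.texture_amplitude < 0:
            raise ValueError(f"texture_amplitude must be >= 0, got {self.texture_amplitude}")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(
                f"unknown noise_model {self.noise_model!r}; expected one of {NOISE_MODELS}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        for k, c in enumerate(self.cysts):
            if not 0.0 <= c.intensity <= 1.0:
                raise ValueError(f"cyst {k}: intensity must be in [0,1], got {c.intensity}")
            if c.radius <= 0:
                raise ValueError(f"cyst {k}: radius must be positive, got {c.radius}")
            if (
                c.row - c.radius < 0
                or c.row + c.radius > rows - 1
                or c.col - c.radius < 0
                or c.col + c.radius > cols - 1
            ):
                raise ValueError(
                    f"cyst {k} at ({c.row}, {c.col}) radius {c.radius} does not fit "
                    f"inside image of shape {self.shape}"
                )

    def as_flat_dict(self) -> dict:
        d = asdict(self)
        d["cysts"] = ";".join(
            f"{c.row},{c.col},{c.radius},{c.intensity}" for c in self.cysts
        )
        d["shape"] = f"{self.shape[0]}x{self.shape[1]}"
        return d


def cyst_mask(shape, cyst: Cyst, shrink: float = 0.0) -> np.ndarray:
    """Boolean mask of the disk, optionally shrunk by ``shrink`` px (for CNR)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r = max(cyst.radius - shrink, 0.0)
    return (rr - cyst.row) ** 2 + (cc - cyst.col) ** 2 <= r**2


def background_mask(spec: PhantomSpec, margin: float = 4.0) -> np.ndarray:
    """Pixels outside every cyst plus a safety margin."""
    m = np.ones(spec.shape, dtype=bool)
    for c in spec.cysts:
        grown = Cyst(c.row, c.col, c.radius + margin, c.intensity)
        m &= ~cyst_mask(spec.shape, grown)
    return m


def _texture(rng: np.random.Generator, shape, amplitude: float) -> np.ndarray:
    if amplitude == 0:
        return np.zeros(shape)
    field = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(field, sigma=min(shape) / 16.0, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return amplitude * smooth / sd


# Rayleigh(scale=1) moments, used to standardise the speckle field
_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)
_RAYLEIGH_SD = math.sqrt(2.0 - math.pi / 2.0)


def speckle_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-mean Rayleigh-derived multiplicative speckle with SD ``sigma``."""
    r = rng.rayleigh(scale=1.0, size=shape)
    return 1.0 + sigma * (r - _RAYLEIGH_MEAN) / _RAYLEIGH_SD


def make_phantom(spec: PhantomSpec):
    """Generate ``(clean, noisy)`` images in [0, 1] from a phantom spec.

    ``clean`` is background + smooth texture with cyst disks painted at
    their intensity. ``noisy`` adds the configured noise and is clipped to
    [0, 1]; with ``noise_sigma == 0`` it equals ``clean`` exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    clean = spec.background_level + _texture(rng, spec.shape, spec.texture_amplitude)
    for c in spec.cysts:
        clean[cyst_mask(spec.shape, c)] = c.intensity
    clean = np.clip(clean, 0.0, 1.0)

    if spec.noise_sigma == 0:
        return clean, clean.copy()

    if spec.noise_model == "gaussian_additive":
        noisy = clean + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    else:
        noisy = clean * speckle_field(rng, spec.shape, spec.noise_sigma)
    return clean, np.clip(noisy, 0.0, 1.0)
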