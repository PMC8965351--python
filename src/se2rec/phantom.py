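"""Synthetic 8-bit test images ("phantoms").

Stand-ins for natural photographs with two ingredients that matter for
this pipeline: an isotropic Fourier amplitude spectrum decaying like a
power law ``(1 + |xi|)^(-beta)`` (so bandlimiting at a generous radius
loses almost no energy), and, optionally, anti-aliased geometric shapes
(oriented bars and disks) that exercise all orientation channels.  Output
images are deterministic given the seed and quantised to ``{0..255}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bank import freq_lattice
from .exceptions import ConfigurationError

__all__ = ["PhantomSpec", "phantom", "PHANTOM_KINDS"]

PHANTOM_KINDS = ("powerlaw", "shapes", "mixed")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic test image.

    ``beta`` is the spectral amplitude decay exponent (1.2 by default, a
    natural-image-like roughly ``1/|xi|`` amplitude fall-off).
    """

    n: int
    kind: str = "powerlaw"
    beta: float = 1.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 4 or self.n % 2 != 0:
            raise ConfigurationError(f"n must be an even integer >= 4, got {self.n!r}")
        if self.kind not in PHANTOM_KINDS:
            raise ConfigurationError(
                f"kind must be one of {PHANTOM_KINDS}, got {self.kind!r}"
            )
        if self.kind in ("powerlaw", "mixed") and not (self.beta > 0):
            raise ConfigurationError(f"beta must be > 0, got {self.beta!r}")


def _powerlaw_field(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    # random-phase field: deterministic isotropic amplitude, random phases.
    # Normalising the spectrum of a real white-noise field yields uniform
    # phases with exact Hermitian symmetry (so the result is real).
    white_hat = np.fft.fft2(rng.standard_normal((n, n)))
    mags = np.abs(white_hat)
    mags[mags == 0] = 1.0
    xi1, xi2 = freq_lattice(n)
    amplitude = (1.0 + np.hypot(xi1, xi2)) ** (-beta)
    return np.fft.ifft2((white_hat / mags) * amplitude).real


def _smooth_step(signed: np.ndarray, width: float = 1.0) -> np.ndarray:
    """Anti-aliasing profile: 0 outside, 1 inside, linear ramp of ``width`` px."""
    return np.clip(signed / width + 0.5, 0.0, 1.0)


def _shapes_field(n: int, rng: np.random.Generator) -> np.ndarray:
    x1 = np.arange(n, dtype=float)[:, None]
    x2 = np.arange(n, dtype=float)[None, :]
    canvas = np.zeros((n, n))
    # oriented bars at varied angles, lengths and contrasts
    for _ in range(8):
        c1, c2 = rng.uniform(0.15 * n, 0.85 * n, size=2)
        angle = rng.uniform(0.0, np.pi)
        half_len = rng.uniform(0.08 * n, 0.3 * n)
        half_w = rng.uniform(0.005 * n, 0.02 * n) + 1.0
        contrast = rng.uniform(-1.0, 1.0)
        u = (x1 - c1) * np.cos(angle) + (x2 - c2) * np.sin(angle)
        v = -(x1 - c1) * np.sin(angle) + (x2 - c2) * np.cos(angle)
        bar = _smooth_step(half_w - np.abs(v)) * _smooth_step(half_len - np.abs(u))
        canvas += contrast * bar
    # disks
    for _ in range(4):
        c1, c2 = rng.uniform(0.15 * n, 0.85 * n, size=2)
        radius = rng.uniform(0.04 * n, 0.15 * n)
        contrast = rng.uniform(-1.0, 1.0)
        dist = np.hypot(x1 - c1, x2 - c2)
        canvas += contrast * _smooth_step(radius - dist)
    # gentle illumination gradient so the background is not flat
    g = rng.uniform(-1.0, 1.0, size=2)
    canvas += 0.3 * (g[0] * (x1 - n / 2) + g[1] * (x2 - n / 2)) / n
    return canvas


def _rescale_to_8bit(field: np.ndarray) -> np.ndarray:
    lo, hi = field.min(), field.max()
    if hi == lo:
        return np.zeros_like(field)
    return np.rint((field - lo) / (hi - lo) * 255.0)


def phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate the phantom image: float array with integer values in {0..255}."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "powerlaw":
        field = _powerlaw_field(spec.n, spec.beta, rng)
    elif spec.kind == "shapes":
        field = _shapes_field(spec.n, rng)
    else:  # mixed
        a = _powerlaw_field(spec.n, spec.beta, rng)
        b = _shapes_field(spec.n, rng)
        field = a / max(np.abs(a).max(), np.finfo(float).tiny) + b
    return _rescale_to_8bit(field)
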