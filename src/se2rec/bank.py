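"""Gabor filter banks on the DFT frequency lattice.

The discrete SE(2) wavelet transform analyses an ``N x N`` image with ``M``
rotated copies of a complex Gabor receptive field.  In the frequency domain
each filter is a real Gaussian of width ``s`` centred at radius ``p`` along
one of ``M`` uniformly spaced orientations ``theta_j = 2*pi*j/M``:

    psi_hat_j(xi) = exp(-|xi + p*(cos theta_j, sin theta_j)|^2 / (2 s^2))

on the centered integer lattice ``{-N/2 .. N/2-1}^2`` (standard DFT
index <-> frequency mapping).  The sum of squared filter magnitudes is the
Calderon profile ``C(xi)``; its extrema over a frequency ball of radius
``R`` are the frame bounds ``A <= B`` that govern invertibility and
conditioning of the transform on images bandlimited to that ball.  The dual
filters ``gamma_hat_j = chi_B * psi_hat_j / C`` invert the transform there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import (
    ConfigurationError,
    DomainError,
    NumericalDegeneracyError,
)

__all__ = [
    "BankParams",
    "GaborBank",
    "CalderonProfile",
    "DualBank",
    "FrameBounds",
    "freq_lattice",
    "ball_mask",
    "gabor_bank",
    "calderon",
    "frame_bounds",
    "dual_bank",
]


@dataclass(frozen=True)
class BankParams:
    """Parameters of a Gabor filter bank.

    Attributes
    ----------
    n : int
        Side length of the (square, even) pixel grid.
    m : int
        Number of orientations; angles are ``2*pi*j/m`` for ``j = 0..m-1``.
    s : float
        Gaussian width of the frequency-domain filter, in DFT index units.
    p : float
        Radial centre frequency of the filter, in DFT index units.
    """

    n: int
    m: int
    s: float
    p: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 4 or self.n % 2 != 0:
            raise ConfigurationError(f"n must be an even integer >= 4, got {self.n!r}")
        if int(self.m) != self.m or self.m < 1:
            raise ConfigurationError(f"m must be an integer >= 1, got {self.m!r}")
        if not (self.s > 0):
            raise ConfigurationError(f"s must be > 0, got {self.s!r}")
        if not (self.p >= 0):
            raise ConfigurationError(f"p must be >= 0, got {self.p!r}")

    @property
    def angles(self) -> np.ndarray:
        """Orientation angles ``theta_j = 2*pi*j/m``, shape ``(m,)``."""
        return 2.0 * np.pi * np.arange(self.m) / self.m


def freq_lattice(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer frequency coordinates of the DFT lattice.

    Returns arrays ``(xi1, xi2)`` of shape ``(n, n)`` holding, at array
    index ``(k1, k2)``, the centered frequency ``k`` for ``k < n/2`` and
    ``k - n`` otherwise (the standard DFT convention, axis 0 first).
    """
    freqs = np.fft.fftfreq(n, d=1.0 / n)
    return np.meshgrid(freqs, freqs, indexing="ij")


def ball_mask(n: int, radius: float) -> np.ndarray:
    """Boolean indicator of the open frequency ball ``xi1^2 + xi2^2 < R^2``."""
    xi1, xi2 = freq_lattice(n)
    return xi1 * xi1 + xi2 * xi2 < float(radius) ** 2


@dataclass(frozen=True, eq=False)
class GaborBank:
    """The ``M`` frequency-domain Gabor filters of a parameter set.

    ``filters`` has shape ``(m, n, n)``; plane ``j`` is the real Gaussian
    ``psi_hat_j`` sampled on the DFT lattice, peaking at 1 exactly when the
    Gaussian centre ``-p*(cos theta_j, sin theta_j)`` is a lattice point.
    """

    params: BankParams
    filters: np.ndarray


def gabor_bank(params: BankParams) -> GaborBank:
    """Build the Gabor filter bank for ``params``."""
    xi1, xi2 = freq_lattice(params.n)
    angles = params.angles
    centers = params.p * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    filters = np.empty((params.m, params.n, params.n))
    two_s2 = 2.0 * params.s**2
    for j in range(params.m):
        d2 = (xi1 + centers[j, 0]) ** 2 + (xi2 + centers[j, 1]) ** 2
        filters[j] = np.exp(-d2 / two_s2)
    return GaborBank(params=params, filters=filters)


@dataclass(frozen=True, eq=False)
class CalderonProfile:
    """The Calderon function ``C(xi) = sum_j |psi_hat_j(xi)|^2`` on the lattice."""

    values: np.ndarray
    params: BankParams


class FrameBounds(NamedTuple):
    """Frame bounds of the transform over a frequency ball."""

    lower: float  # A = min of C over the open ball
    upper: float  # B = max of C over the open ball
    ratio: float  # B / A
    condition_number: float  # sqrt(B / A); A, B bound squared norms


def calderon(bank: GaborBank) -> CalderonProfile:
    """Sum of squared filter magnitudes; strictly positive everywhere."""
    values = np.sum(bank.filters**2, axis=0)
    return CalderonProfile(values=values, params=bank.params)


def frame_bounds(profile: CalderonProfile, radius: float) -> FrameBounds:
    """Extrema of the Calderon profile over the open ball of ``radius``.

    Raises
    ------
    DomainError
        If the open ball contains no lattice frequency.
    """
    if not (radius > 0):
        raise DomainError(f"radius must be > 0, got {radius!r}")
    mask = ball_mask(profile.params.n, radius)
    if not mask.any():
        raise DomainError(f"no lattice frequency inside the open ball of radius {radius!r}")
    inside = profile.values[mask]
    lower = float(inside.min())
    upper = float(inside.max())
    return FrameBounds(lower, upper, upper / lower, float(np.sqrt(upper / lower)))


@dataclass(frozen=True, eq=False)
class DualBank:
    """Dual filters ``gamma_hat_j = chi_B(xi) * psi_hat_j(xi) / C(xi)``.

    Vanish identically outside the open ball of ``radius``; inside, they
    satisfy ``C * gamma_hat_j = psi_hat_j``, so the adjoint transform taken
    with the dual bank inverts the forward transform on images bandlimited
    to the ball.
    """

    params: BankParams
    radius: float
    filters: np.ndarray


def dual_bank(bank: GaborBank, radius: float) -> DualBank:
    """Build the dual filter bank for inversion on the ball of ``radius``."""
    profile = calderon(bank)
    bounds = frame_bounds(profile, radius)  # validates the ball
    if bounds.lower <= 0:
        raise NumericalDegeneracyError(
            "Calderon profile is not strictly positive on the ball; "
            "the dual filters are undefined"
        )
    mask = ball_mask(bank.params.n, radius)
    filters = np.where(mask[None, :, :], bank.filters / profile.values[None, :, :], 0.0)
    return DualBank(params=bank.params, radius=float(radius), filters=filters)
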