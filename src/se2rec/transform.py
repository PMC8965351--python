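"""Forward and adjoint discrete SE(2) wavelet transforms, and bandlimiting.

The forward transform correlates an image with every rotated receptive
field: plane ``j`` of the output stack is the circular convolution
``f * psi_theta_j``, computed in the frequency domain as
``F_hat(xi, j) = f_hat(xi) * psi_hat_j(xi)``.  Stacks are complex arrays of
shape ``(n, n, m)`` (space x space x orientation).

The adjoint sums the planes against the (real) filters,
``g_hat(xi) = sum_j F_hat(xi, j) * psi_hat_j(xi)``; taken with the dual
bank it inverts the forward transform exactly on images whose spectrum is
supported inside the ball of radius ``R``.

DFT normalisation is fixed once for the whole package: unnormalised
forward FFT, ``1/n^2`` inverse (numpy's default pair).
"""

from __future__ import annotations

import numpy as np

from .bank import DualBank, GaborBank, ball_mask
from .exceptions import DimensionError

__all__ = ["se2_forward", "se2_adjoint", "bandlimit", "stack_norm"]


def _check_image(image: np.ndarray, n: int) -> np.ndarray:
    image = np.asarray(image)
    if image.shape != (n, n):
        raise DimensionError(f"expected an image of shape ({n}, {n}), got {image.shape}")
    return image


def _check_stack(stack: np.ndarray, n: int, m: int) -> np.ndarray:
    stack = np.asarray(stack)
    if stack.shape != (n, n, m):
        raise DimensionError(
            f"expected a stack of shape ({n}, {n}, {m}), got {stack.shape}"
        )
    return stack


def se2_forward(image: np.ndarray, bank: GaborBank) -> np.ndarray:
    """SE(2) wavelet transform of ``image``: stack of shape ``(n, n, m)``.

    Plane ``j`` is the circular convolution of the image with the rotated
    wavelet ``psi_theta_j`` (frequency-domain product with the bank filter).
    """
    n, m = bank.params.n, bank.params.m
    image = _check_image(image, n)
    fhat = np.fft.fft2(image)
    stack_hat = fhat[None, :, :] * bank.filters
    return np.moveaxis(np.fft.ifft2(stack_hat, axes=(1, 2)), 0, -1)


def se2_adjoint(stack: np.ndarray, bank: GaborBank | DualBank) -> np.ndarray:
    """Adjoint transform: complex image with ``g_hat = sum_j F_hat_j * filter_j``.

    With a :class:`~se2rec.bank.DualBank` this is the inverse transform on
    images bandlimited to the dual's ball.
    """
    n, m = bank.params.n, bank.params.m
    stack = _check_stack(stack, n, m)
    stack_hat = np.fft.fft2(stack, axes=(0, 1))
    # filters are real, so no conjugation is needed
    ghat = np.einsum("ijm,mij->ij", stack_hat, bank.filters)
    return np.fft.ifft2(ghat)


def bandlimit(image: np.ndarray, radius: float) -> np.ndarray:
    """Project an image onto the span of frequencies strictly inside the ball.

    Idempotent; a real input yields a real output (the ball indicator is
    symmetric under frequency negation on the even lattice).
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise DimensionError(f"expected a square image, got shape {image.shape}")
    mask = ball_mask(image.shape[0], radius)
    out = np.fft.ifft2(np.fft.fft2(image) * mask)
    return out.real if np.isrealobj(image) else out


def stack_norm(stack: np.ndarray) -> float:
    """Euclidean norm of a transform stack (flat complex vector norm)."""
    return float(np.linalg.norm(np.asarray(stack).ravel()))
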