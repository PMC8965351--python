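"""Orthogonal projection onto the range of the SE(2) transform.

The range of the forward transform on bandlimited images is a reproducing
kernel subspace of stacks.  The orthogonal projection onto it factors
through the inversion formula,

    P F = forward( adjoint(F, dual) ),

which in the frequency domain is diagonal over frequencies:

    (P F)_hat(xi, j) = gamma_hat_j(xi) * sum_l F_hat(xi, l) * psi_hat_l(xi),

with ``gamma_hat_j = chi_B * psi_hat_j / C`` the dual filters.  The
projection is idempotent, self-adjoint and non-expansive; its rank equals
the number of lattice frequencies strictly inside the ball.
"""

from __future__ import annotations

import numpy as np

from .bank import DualBank, GaborBank
from .exceptions import ConfigurationError, DomainError
from .transform import _check_stack

__all__ = ["project", "kernel_slices"]


def _check_pair(bank: GaborBank, dual: DualBank) -> None:
    if bank.params != dual.params:
        raise ConfigurationError(
            "bank and dual were built from different parameters: "
            f"{bank.params} vs {dual.params}"
        )


def project(stack: np.ndarray, bank: GaborBank, dual: DualBank) -> np.ndarray:
    """Project a stack onto the range of the SE(2) transform."""
    _check_pair(bank, dual)
    n, m = bank.params.n, bank.params.m
    stack = _check_stack(stack, n, m)
    stack_hat = np.fft.fft2(stack, axes=(0, 1))
    pooled = np.einsum("ijm,mij->ij", stack_hat, bank.filters)
    out_hat = dual.filters * pooled[None, :, :]
    return np.moveaxis(np.fft.ifft2(out_hat, axes=(1, 2)), 0, -1)


def kernel_slices(bank: GaborBank, dual: DualBank, j_ref: int) -> np.ndarray:
    """Spatial reproducing-kernel column generated by an impulse in plane ``j_ref``.

    Returns an ``(m, n, n)`` complex array; slice ``j`` is the inverse DFT
    of ``gamma_hat_j * psi_hat_{j_ref}``, i.e. the image under the
    projection of a unit impulse at the origin of plane ``j_ref``.
    """
    _check_pair(bank, dual)
    m = bank.params.m
    if not (0 <= j_ref < m):
        raise DomainError(f"j_ref must lie in [0, {m}), got {j_ref}")
    slices_hat = dual.filters * bank.filters[j_ref][None, :, :]
    return np.fft.ifft2(slices_hat, axes=(1, 2))
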