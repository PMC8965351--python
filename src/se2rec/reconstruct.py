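"""The project-and-replace iteration and its error trace.

Starting from the restricted data ``F0 = O_Theta W_psi f`` (the transform
values on the graph of a feature map), the iteration alternates

    H_n = P F_{n-1}            (project onto the transform's range)
    F_n = H_n - O_Theta H_n + F0   (replace the known values)

and, when the graph is a set of uniqueness for the range, converges to the
full transform ``W_psi f`` at the geometric rate ``|Q_perp P| < 1``.  Images
are read out by the inverse transform applied to ``H_n``; reconstruction
quality is tracked by the percent error

    Delta_n = 100 * ||f - real(W*_gamma H_n)||_2 / (255 * n),

i.e. the RMS pixel difference as a percentage of the 8-bit dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bank import DualBank, GaborBank
from .exceptions import ConfigurationError, DimensionError, PreconditionError
from .maps import FeatureMap, apply_selection, graph_mask
from .projection import _check_pair
from .transform import _check_stack

__all__ = [
    "IterationConfig",
    "ReconstructionTrace",
    "error_delta",
    "restrict",
    "project_and_replace",
    "reconstruct_image",
]


@dataclass(frozen=True)
class IterationConfig:
    """Schedule of the project-and-replace iteration.

    ``max_iter`` is the iteration count ``nu``; the error is recorded at
    steps ``1, 1+stride, 1+2*stride, ...`` (``ceil(nu/stride)`` records).
    ``stop_tol``, if set, stops early once ``||F_n - F_{n-1}||`` falls
    below it.
    """

    max_iter: int = 500
    record_stride: int = 1
    stop_tol: float | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ConfigurationError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.record_stride < 1:
            raise ConfigurationError(
                f"record_stride must be >= 1, got {self.record_stride}"
            )


@dataclass(eq=False)
class ReconstructionTrace:
    """Outcome of a project-and-replace run."""

    iterations: np.ndarray  # recorded step indices (1-based)
    deltas: np.ndarray | None  # percent errors at the recorded steps, if a reference was given
    projected: np.ndarray  # H_nu, the last projected stack
    completed: np.ndarray  # F_nu, the last replaced stack
    image: np.ndarray  # real part of the inverse transform of H_nu
    max_imag: float  # largest |imaginary part| discarded in the read-out
    n_iter: int  # iterations actually run
    first_image: np.ndarray | None = None  # read-out of H_1 (the raw projection)


def error_delta(reference: np.ndarray, reconstruction: np.ndarray) -> float:
    """Percent RMS pixel error, ``100 * ||ref - rec||_2 / (255 * n)``."""
    reference = np.asarray(reference)
    reconstruction = np.asarray(reconstruction)
    if reference.shape != reconstruction.shape or reference.ndim != 2:
        raise DimensionError(
            f"images must share a square shape, got {reference.shape} and "
            f"{reconstruction.shape}"
        )
    n = reference.shape[0]
    return float(100.0 * np.linalg.norm(reference - reconstruction) / (255.0 * n))


def restrict(stack: np.ndarray, theta: FeatureMap) -> np.ndarray:
    """Restrict a transform stack to the graph of a feature map (``F0``)."""
    return apply_selection(stack, theta)


def reconstruct_image(stack: np.ndarray, dual: DualBank) -> tuple[np.ndarray, float]:
    """Inverse transform read-out: real image and the peak imaginary residual."""
    from .transform import se2_adjoint

    out = se2_adjoint(stack, dual)
    return out.real, float(np.abs(out.imag).max())


def project_and_replace(
    f0: np.ndarray,
    theta: FeatureMap,
    bank: GaborBank,
    dual: DualBank,
    config: IterationConfig = IterationConfig(),
    reference: np.ndarray | None = None,
) -> ReconstructionTrace:
    """Run the project-and-replace iteration from restricted data ``f0``.

    ``f0`` must be supported on the graph of ``theta`` (it is the output of
    :func:`restrict`); the replacement step keeps ``O_Theta F_n = F0``
    exact at every iteration.  When ``reference`` is given, the percent
    error of the read-out of ``H_n`` against it is recorded on the
    schedule of ``config``.
    """
    _check_pair(bank, dual)
    n, m = bank.params.n, bank.params.m
    f0 = _check_stack(f0, n, m).astype(complex)
    if theta.n != n or theta.m != m:
        raise DimensionError(
            f"feature map ({theta.n}, m={theta.m}) does not match bank "
            f"(n={n}, m={m})"
        )
    mask = graph_mask(theta)
    off_graph = np.abs(f0[~mask])
    if off_graph.size and off_graph.max() > 0:
        raise PreconditionError(
            "restricted data has nonzero entries off the graph of the feature map"
        )
    if reference is not None:
        reference = np.asarray(reference)
        if reference.shape != (n, n):
            raise DimensionError(
                f"reference shape {reference.shape} does not match images of side {n}"
            )

    # planes-first layout for the FFT loop
    f0_p = np.ascontiguousarray(np.moveaxis(f0, -1, 0))
    mask_p = np.moveaxis(mask, -1, 0)
    psi = bank.filters
    gamma = dual.filters

    current = f0_p.copy()
    proj_hat = None
    recorded: list[int] = []
    deltas: list[float] = []
    first_image: np.ndarray | None = None
    n_done = 0
    for step in range(1, config.max_iter + 1):
        cur_hat = np.fft.fft2(current, axes=(1, 2))
        pooled = np.einsum("mij,mij->ij", cur_hat, psi)
        proj_hat = gamma * pooled[None, :, :]
        projected = np.fft.ifft2(proj_hat, axes=(1, 2))
        replaced = projected.copy()
        replaced[mask_p] = f0_p[mask_p]
        record = (step - 1) % config.record_stride == 0
        if step == 1 or (record and reference is not None):
            readout = np.fft.ifft2(np.einsum("mij,mij->ij", proj_hat, gamma))
            if step == 1:
                first_image = readout.real.copy()
        if record:
            recorded.append(step)
            if reference is not None:
                deltas.append(error_delta(reference, readout.real))
        n_done = step
        if config.stop_tol is not None:
            change = np.linalg.norm((replaced - current).ravel())
            current = replaced
            if change <= config.stop_tol:
                break
        else:
            current = replaced

    readout = np.fft.ifft2(np.einsum("mij,mij->ij", proj_hat, gamma))
    image = readout.real
    max_imag = float(np.abs(readout.imag).max())
    return ReconstructionTrace(
        iterations=np.asarray(recorded),
        deltas=np.asarray(deltas) if reference is not None else None,
        projected=np.moveaxis(projected, 0, -1),
        completed=np.moveaxis(current, 0, -1),
        image=image,
        max_imag=max_imag,
        n_iter=n_done,
        first_image=first_image,
    )
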