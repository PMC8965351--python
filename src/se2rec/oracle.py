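"""Dense-matrix oracle for solvability and convergence, at desk scale.

On small grids the projection onto the transform's range (``P``) and the
feature-map selection (``Q``) can be assembled as explicit matrices on
``C^(n*n*m)``.  Reconstruction from the restricted data has a unique
solution iff ``Ker(Q) & Ran(P) = {0}``, equivalently iff the smallest
singular value of ``Q`` restricted to ``Ran(P)`` is positive, equivalently
iff the contraction factor ``|Q_perp P| < 1``.  The error then obeys the
recursion ``F~ - F_n = Q_perp P (F~ - F_{n-1})``, so the iteration
converges geometrically; the sharp per-step rate is the spectral radius
of ``Q_perp P``, which for a product of two orthogonal projections equals
``|Q_perp P|^2`` (the squared cosine of the smallest principal angle
between ``Ran(P)`` and ``Ker(Q)``).

This module decides solvability for concrete instances and cross-validates
the FFT pipeline against the dense matrices, trajectory by trajectory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .bank import BankParams, ball_mask, dual_bank, gabor_bank
from .exceptions import PreconditionError, ResourceError
from .maps import FeatureMap, graph_mask
from .projection import project
from .reconstruct import restrict
from .transform import se2_forward

__all__ = [
    "MAX_DENSE_DIM",
    "DenseOperators",
    "SolvabilityReport",
    "IterationComparison",
    "build_dense_operators",
    "check_uniqueness",
    "verify_convergence",
]

MAX_DENSE_DIM = 4096

#: singular values below this are treated as zero when declaring solvability
SOLVABILITY_TOL = 1e-9
#: solvable instances with sigma_min below this are flagged as ill-conditioned
ILL_CONDITIONED_TOL = 1e-6


@dataclass(eq=False)
class DenseOperators:
    """Explicit matrices of the range projection and the graph selection.

    ``projector`` is the ``(d, d)`` complex matrix of ``P`` (``d = n*n*m``,
    stacks flattened in C order); ``selector`` is the boolean diagonal of
    ``Q``.
    """

    projector: np.ndarray
    selector: np.ndarray
    params: BankParams
    theta: FeatureMap
    radius: float

    @property
    def dim(self) -> int:
        return self.projector.shape[0]


@dataclass
class SolvabilityReport:
    """Verdict on ``Ker(Q) & Ran(P) = {0}`` for a dense instance."""

    dims: int
    rank_p: int
    sigma_min: float  # smallest singular value of Q on an orthonormal basis of Ran(P)
    contraction: float  # spectral norm of Q_perp P
    asymptotic_rate: float  # spectral radius of Q_perp P = contraction^2, the sharp per-step error decay
    solvable: bool
    ill_conditioned: bool

    def to_dict(self) -> dict:
        return asdict(self)


def build_dense_operators(
    params: BankParams, theta: FeatureMap, radius: float
) -> DenseOperators:
    """Assemble ``P`` column-by-column through the FFT projection, and ``Q``.

    Guarded to ``n*n*m <= MAX_DENSE_DIM`` to prevent accidental large
    builds.
    """
    n, m = params.n, params.m
    dim = n * n * m
    if dim > MAX_DENSE_DIM:
        raise ResourceError(
            f"dense build of dimension {dim} exceeds the guard MAX_DENSE_DIM="
            f"{MAX_DENSE_DIM}"
        )
    bank = gabor_bank(params)
    dual = dual_bank(bank, radius)
    projector = np.empty((dim, dim), dtype=complex)
    basis = np.zeros(dim)
    for col in range(dim):
        basis[col] = 1.0
        projector[:, col] = project(basis.reshape(n, n, m), bank, dual).ravel()
        basis[col] = 0.0
    selector = graph_mask(theta).ravel()
    return DenseOperators(
        projector=projector,
        selector=selector,
        params=params,
        theta=theta,
        radius=float(radius),
    )


def check_uniqueness(ops: DenseOperators) -> SolvabilityReport:
    """Decide solvability by two independent singular-value computations.

    ``sigma_min`` comes from the SVD of ``Q V`` with ``V`` an orthonormal
    eigenbasis of ``Ran(P)``; the contraction factor is the spectral norm
    of ``Q_perp P``.  In finite dimension ``sigma_min > 0`` iff the
    contraction is < 1 (indeed ``contraction^2 = 1 - sigma_min^2``).
    """
    eigvals, eigvecs = np.linalg.eigh(ops.projector)
    in_range = eigvals > 0.5  # projector spectra sit near {0, 1}
    rank_p = int(in_range.sum())
    if rank_p == 0:
        return SolvabilityReport(
            dims=ops.dim,
            rank_p=0,
            sigma_min=1.0,
            contraction=0.0,
            asymptotic_rate=0.0,
            solvable=True,
            ill_conditioned=False,
        )
    basis = eigvecs[:, in_range]
    restricted = np.where(ops.selector[:, None], basis, 0.0)
    sigma_min = float(np.linalg.svd(restricted, compute_uv=False).min())
    complement = np.where(ops.selector[:, None], 0.0, ops.projector)
    contraction = float(np.linalg.norm(complement, ord=2))
    solvable = sigma_min > SOLVABILITY_TOL
    return SolvabilityReport(
        dims=ops.dim,
        rank_p=rank_p,
        sigma_min=sigma_min,
        contraction=contraction,
        asymptotic_rate=contraction**2,
        solvable=solvable,
        ill_conditioned=solvable and sigma_min < ILL_CONDITIONED_TOL,
    )


@dataclass
class IterationComparison:
    """Dense vs FFT trajectories of the project-and-replace iteration."""

    trajectory_max_diff: float  # largest entrywise |dense - FFT| over all steps
    first_divergent_step: int | None  # first step exceeding the tolerance, if any
    errors: np.ndarray  # dense ||F~ - F_n|| per step
    decay_slope: float  # fitted slope of log ||F~ - F_n|| over the tail
    log_rate: float  # log of the dense asymptotic rate rho(Q_perp P)
    final_error: float
    replacement_exact: bool  # O_Theta F_n == F0 at every step, both paths
    report: SolvabilityReport

    #: tolerance used to flag dense/FFT disagreement
    tol: float = 1e-10


def verify_convergence(
    ops: DenseOperators, image: np.ndarray, n_iter: int
) -> IterationComparison:
    """Run the iteration through the dense matrices and the FFT pipeline.

    The input image must be bandlimited to the oracle's ball radius.  The
    comparison records the largest trajectory disagreement, the fitted
    exponential decay rate of the dense error (to be compared with the
    asymptotic rate ``rho(Q_perp P)``), and the final distance to the
    target stack ``F~ = W_psi f``.
    """
    params = ops.params
    bank = gabor_bank(params)
    dual = dual_bank(bank, ops.radius)
    image = np.asarray(image, dtype=float)
    spectrum = np.fft.fft2(image)
    outside = ~ball_mask(params.n, ops.radius)
    total = np.linalg.norm(spectrum)
    if total > 0 and np.linalg.norm(spectrum[outside]) > 1e-10 * total:
        raise PreconditionError(
            f"image is not bandlimited to the oracle radius R={ops.radius}"
        )

    target = se2_forward(image, bank).ravel()
    f0 = np.where(ops.selector, target, 0.0)
    q_perp = ~ops.selector

    # dense path
    current = f0.copy()
    dense_states = []
    errors = []
    for _ in range(n_iter):
        projected = ops.projector @ current
        current = np.where(q_perp, projected, 0.0) + f0
        dense_states.append(current.copy())
        errors.append(np.linalg.norm(target - current))
    errors = np.asarray(errors)

    # FFT path, one step at a time so trajectories can be compared exactly
    n, m = params.n, params.m
    theta = ops.theta
    f0_stack = f0.reshape(n, n, m)
    fft_current = f0_stack.copy()
    max_diff = 0.0
    first_divergent = None
    replacement_exact = True
    tol = IterationComparison.tol
    off_graph = ~graph_mask(theta)
    for step, dense_state in enumerate(dense_states, start=1):
        projected = project(fft_current, bank, dual)
        fft_current = projected.copy()
        fft_current[~off_graph] = f0_stack[~off_graph]
        diff = float(np.abs(dense_state.reshape(n, n, m) - fft_current).max())
        max_diff = max(max_diff, diff)
        if diff > tol and first_divergent is None:
            first_divergent = step
        if np.abs(restrict(fft_current, theta) - f0_stack).max() != 0.0:
            replacement_exact = False
        if np.abs(np.where(ops.selector, dense_state, 0.0) - f0).max() > tol:
            replacement_exact = False

    report = check_uniqueness(ops)
    # fit the decay rate after burn-in but before the round-off floor:
    # use the second half of the steps still clearly above machine noise
    above_floor = np.nonzero(errors > 1e-11)[0]
    usable = above_floor[len(above_floor) // 2 :]
    if len(usable) >= 2:
        steps = np.arange(1, n_iter + 1)[usable]
        slope = float(np.polyfit(steps, np.log(errors[usable]), 1)[0])
    else:
        slope = float("-inf")
    return IterationComparison(
        trajectory_max_diff=max_diff,
        first_divergent_step=first_divergent,
        errors=errors,
        decay_slope=slope,
        log_rate=float(np.log(report.asymptotic_rate))
        if report.asymptotic_rate > 0
        else float("-inf"),
        final_error=float(errors[-1]),
        replacement_exact=replacement_exact,
        report=report,
    )
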