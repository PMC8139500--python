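"""Sparsity-promoting (Laplace-prior MAP) reconstruction via FISTA.

An i.i.d. Laplace(0, 1/delta) prior on the signal turns the MAP problem
into l1-regularized least squares,

    min_x (1/2) ||H x - b||^2 + lambda1 ||x||_1,

with effective parameter ``lambda1 = 2 delta / sigma^2`` (delta the
Laplace rate, sigma the noise precision scale; the quotient form follows
from dividing the negative log posterior by sigma^2).  FISTA solves this
with one gradient step and one soft-thresholding per iteration plus the
t_k momentum recurrence, at the accelerated O(1/k^2) rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConvolutionOperator

__all__ = [
    "LaplacePrior",
    "soft_threshold",
    "estimate_lipschitz",
    "fista",
    "fista_objective",
]


@dataclass(frozen=True)
class LaplacePrior:
    """Laplace prior; specify exactly one of ``delta`` (rate) or ``lambda1``.

    The conversion ``lambda1 = 2 * delta / sigma**2`` uses the noise
    precision-scale ``sigma`` of the Gaussian likelihood.
    """

    delta: float | None = None
    lambda1: float | None = None
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if (self.delta is None) == (self.lambda1 is None):
            raise ValueError("specify exactly one of delta or lambda1")
        primitive = self.delta if self.delta is not None else self.lambda1
        if not (primitive > 0 and self.sigma > 0):
            raise ValueError("prior parameters must be positive")

    @property
    def effective_lambda1(self) -> float:
        if self.lambda1 is not None:
            return self.lambda1
        return 2.0 * self.delta / self.sigma**2

    @property
    def effective_delta(self) -> float:
        if self.delta is not None:
            return self.delta
        return self.lambda1 * self.sigma**2 / 2.0


def soft_threshold(v: np.ndarray, threshold: float) -> np.ndarray:
    """Elementwise ``sign(v) * max(|v| - threshold, 0)``.

    Closed-form solution of the proximal subproblem
    ``argmin_x (1/2)||x - v||^2 + threshold * ||x||_1``.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - threshold, 0.0)


def estimate_lipschitz(H: ConvolutionOperator, tol: float = 1e-6,
                       max_iter: int = 500, seed: int = 0) -> float:
    """Lipschitz constant of the gradient of ``(1/2)||Hx-b||^2``.

    Power iteration on ``H^T H`` estimates its largest eigenvalue; a 1%
    safety factor guards against under-estimation so the FISTA step
    ``1/L`` remains valid.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(H.dim_m)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = H.rmatvec(H.matvec(v))
        lam_new = float(np.linalg.norm(w))
        if lam_new == 0:
            return 1e-30  # zero operator; any positive step is valid
        v = w / lam_new
        if abs(lam_new - lam) <= tol * lam_new:
            lam = lam_new
            break
        lam = lam_new
    return 1.01 * lam


def fista_objective(H: ConvolutionOperator, b: np.ndarray, x: np.ndarray,
                    lambda1: float) -> float:
    """``(1/2)||Hx - b||^2 + lambda1 ||x||_1``."""
    return 0.5 * float(np.linalg.norm(H.matvec(x) - b) ** 2) \
        + lambda1 * float(np.abs(x).sum())


def fista(H: ConvolutionOperator, b: np.ndarray, lambda1: float,
          L: float | None = None, max_iter: int = 500,
          x0: np.ndarray | None = None, x_true: np.ndarray | None = None,
          rel_tol: float = 1e-8, monotone: bool = False):
    """FISTA with constant step size.

    Starting from ``y_1 = x_0`` (zero by default) and ``t_1 = 1``, each
    iteration takes a gradient step at the extrapolated point, soft-
    thresholds with level ``lambda1 / L``, updates the momentum scalar
    ``t_{k+1} = (1 + sqrt(1 + 4 t_k^2)) / 2`` and extrapolates.  The
    default is the plain non-monotone method; ``monotone=True`` adds a
    restart whenever the objective increases, which is more robust inside
    alternating (semi-blind) loops.

    Returns a :class:`~respyro.tikhonov.SolverReport` whose ``info`` holds
    the per-iteration objective values.
    """
    from .tikhonov import SolverReport  # local import avoids a cycle

    if lambda1 <= 0:
        raise ValueError("lambda1 must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    b = np.asarray(b, dtype=float)
    m = H.dim_m
    if L is None:
        L = estimate_lipschitz(H)
    if L <= 0:
        raise ValueError("Lipschitz constant must be positive")

    x_prev = np.zeros(m) if x0 is None else np.asarray(x0, dtype=float).copy()
    y = x_prev.copy()
    t = 1.0
    objective: list[float] = []
    residual_norms: list[float] = []
    relative_errors: list[float] = []
    converged = False
    obj_prev = fista_objective(H, b, x_prev, lambda1)
    it = 0
    for it in range(1, max_iter + 1):
        grad = H.rmatvec(H.matvec(y) - b)
        x = soft_threshold(y - grad / L, lambda1 / L)
        obj = fista_objective(H, b, x, lambda1)
        if monotone and obj > obj_prev:
            # restart the momentum from the last accepted iterate
            t = 1.0
            y = x_prev.copy()
            grad = H.rmatvec(H.matvec(y) - b)
            x = soft_threshold(y - grad / L, lambda1 / L)
            obj = fista_objective(H, b, x, lambda1)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t**2)) / 2.0
        # the recurrence guarantees t_k >= (k+1)/2, the engine of the O(1/k^2)
        # rate (restarts reset the counter, so only the plain variant asserts)
        assert monotone or t_next >= (it + 2) / 2.0
        y = x + ((t - 1.0) / t_next) * (x - x_prev)

        objective.append(obj)
        residual_norms.append(float(np.linalg.norm(H.matvec(x) - b)))
        if x_true is not None:
            relative_errors.append(
                float(np.linalg.norm(x - x_true) / np.linalg.norm(x_true))
            )
        dx = np.linalg.norm(x - x_prev)
        nx = np.linalg.norm(x)
        x_prev, t, obj_prev = x, t_next, obj
        if nx > 0 and dx / nx < rel_tol:
            converged = True
            break
        if nx == 0 and dx == 0:
            converged = True
            break

    return SolverReport(solution=x_prev, lambda_used=lambda1, iterations=it,
                        residual_norms=residual_norms,
                        relative_errors=relative_errors, converged=converged,
                        info={"objective": objective, "L": L})
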