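"""Circulant TSVD-like preconditioning for the Toeplitz forward operator.

The circulant matrix M whose first column equals the kernel (H's first
column) matches H on its lower triangle and is diagonalized by the DFT:
``M = F* diag(theta) F`` with ``theta = fft(kernel)``.  Because M — like
H — is severely ill-conditioned, eigenvalues below a tolerance ``tau``
are replaced by exactly 1 rather than inverted:

    theta_hat_i = theta_i  if |theta_i| >= tau,  else 1.

The preconditioner then approximates a *regularized* pseudoinverse of H:
retained modes are whitened (clustering the corresponding singular values
of M^-1 H near one) while noise-dominated modes pass through untouched,
so the preconditioner cannot amplify noise before regularization acts.
``tau`` can be chosen by GCV on the circulant surrogate problem M x = b,
which is diagonal in Fourier space and hence cheap to scan exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.linalg import circulant

from .core import ConvolutionOperator, build_operator

__all__ = [
    "CirculantPreconditioner",
    "build_preconditioner",
    "gcv_select_tau",
    "preconditioned_spectrum",
]


@dataclass
class CirculantPreconditioner:
    """Regularized circulant approximation of the Toeplitz operator.

    ``theta`` are the eigenvalues of the circulant completion (DFT of the
    kernel first column); ``theta_hat`` the regularized eigenvalues used
    in all solves.  ``theta_hat`` has no zero entries by construction.
    """

    theta: np.ndarray
    theta_hat: np.ndarray
    tau: float
    dim_m: int

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.theta_hat == 1.0))

    def _fft(self, v):
        return np.fft.fft(np.asarray(v, dtype=float))

    def apply(self, v: np.ndarray) -> np.ndarray:
        """``M v`` with the regularized eigenvalues."""
        return np.fft.ifft(self._fft(v) * self.theta_hat).real

    def apply_inverse(self, y: np.ndarray) -> np.ndarray:
        """``M^-1 y = ifft(fft(y) / theta_hat)``."""
        return np.fft.ifft(self._fft(y) / self.theta_hat).real

    def apply_adjoint(self, v: np.ndarray) -> np.ndarray:
        return np.fft.ifft(self._fft(v) * np.conj(self.theta_hat)).real

    def apply_inverse_adjoint(self, y: np.ndarray) -> np.ndarray:
        """``M^-T y``, needed by preconditioned adjoint solves."""
        return np.fft.ifft(self._fft(y) / np.conj(self.theta_hat)).real

    def to_dense(self) -> np.ndarray:
        """Dense regularized circulant matrix (diagnostics only)."""
        F = np.fft.fft(np.eye(self.dim_m))
        return (np.conj(F.T) @ np.diag(self.theta_hat) @ F).real / self.dim_m


def build_preconditioner(kernel: np.ndarray, tau: float | str = "gcv",
                         b: np.ndarray | None = None) -> CirculantPreconditioner:
    """Build the circulant preconditioner for a given kernel.

    ``tau`` is the eigenvalue truncation tolerance, or ``"gcv"`` to select
    it automatically from the data ``b`` via :func:`gcv_select_tau`.  If
    every ``|theta_i|`` falls below ``tau`` the preconditioner degenerates
    to the identity (no preconditioning) and a warning is raised.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or kernel.size == 0 or not np.any(kernel):
        raise ValueError("kernel must be a non-empty, nonzero 1-d vector")
    if isinstance(tau, str):
        if tau != "gcv":
            raise ValueError(f"tau must be a positive real or 'gcv', got {tau!r}")
        if b is None:
            raise ValueError("tau='gcv' requires the observed data b")
        tau = gcv_select_tau(kernel, b)
    if not (tau > 0):
        raise ValueError("tau must be positive")
    theta = np.fft.fft(kernel)
    keep = np.abs(theta) >= tau
    theta_hat = np.where(keep, theta, 1.0 + 0.0j)
    if not np.any(keep):
        warnings.warn("tau exceeds max |theta|: M = I, no preconditioning",
                      stacklevel=2)
    return CirculantPreconditioner(theta=theta, theta_hat=theta_hat,
                                   tau=float(tau), dim_m=kernel.size)


def gcv_select_tau(kernel: np.ndarray, b: np.ndarray) -> float:
    """GCV truncation tolerance for the circulant surrogate ``M x = b``.

    In the Fourier basis the surrogate is diagonal with singular values
    ``|theta_i|``, so the TSVD GCV objective can be scanned over every
    truncation level k (keep the k largest ``|theta_i|``):

        G(k) = m * sum_{dropped} |bhat_i|^2 / (m - k)^2,

    with ``bhat`` the (unitary) Fourier coefficients of b.  Returns the
    magnitude of the smallest retained eigenvalue at the minimizing k.
    """
    kernel = np.asarray(kernel, dtype=float)
    b = np.asarray(b, dtype=float)
    if not np.any(b):
        raise ValueError("cannot select tau from an all-zero signal")
    theta = np.fft.fft(kernel)
    bhat = np.fft.fft(b) / np.sqrt(b.size)
    mags = np.abs(theta)
    order = np.argsort(mags)[::-1]  # descending |theta|
    m = theta.size
    sorted_mags = mags[order]
    energy = np.abs(bhat[order]) ** 2
    # tail[k] = sum of |bhat|^2 over the m-k dropped (smallest) modes
    tail = np.concatenate([np.cumsum(energy[::-1])[::-1], [0.0]])
    # cut only at distinct-magnitude boundaries: conjugate pairs share |theta|
    # and splitting a tied group is basis-dependent, hence ill-defined
    ks = np.array([k for k in range(1, m)
                   if sorted_mags[k] < sorted_mags[k - 1] * (1 - 1e-12)])
    if ks.size == 0:
        return float(sorted_mags[-1])
    gcv = m * tail[ks] / (m - ks) ** 2
    k_best = int(ks[np.argmin(gcv)])
    return float(sorted_mags[k_best - 1])


def preconditioned_spectrum(h_kernel: np.ndarray, M: CirculantPreconditioner,
                            m_cap: int = 1024) -> np.ndarray:
    """Singular values of the dense ``M^-1 H`` (diagnostic, small m only)."""
    h_kernel = np.asarray(h_kernel, dtype=float)
    m = h_kernel.size
    if m != M.dim_m:
        raise ValueError("kernel and preconditioner dimensions differ")
    if m > m_cap:
        raise ValueError(
            f"m={m} exceeds the densification cap {m_cap}; "
            "raise m_cap explicitly if you really want a dense SVD this large"
        )
    Hd = build_operator(h_kernel).to_dense()
    Minv_H = np.column_stack([M.apply_inverse(Hd[:, j]) for j in range(m)])
    return np.linalg.svd(Minv_H, compute_uv=False)


def dense_circulant(kernel: np.ndarray) -> np.ndarray:
    """Unregularized dense circulant completion of the Toeplitz operator."""
    return circulant(np.asarray(kernel, dtype=float))
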