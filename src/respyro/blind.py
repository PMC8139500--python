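"""Semi-blind deconvolution: joint kernel/signal estimation.

When only the delay d and support s of the impulse response are known,
signal and kernel are estimated together on the reduced system by
alternating optimization of

    min_{x~, h~} ||H~(h~) x~ - b~||^2 + lambda1 ||x~||_1 + lambda_h ||h~||^2
    s.t.  h~ >= 0,  sum(h~) = 1,

(the mass constraint is on the dt-scaled kernel samples, i.e. the
discrete kernel integrates to one).  The two blocks are exchangeable
through the identity ``H~(h~) x~ = Hhat_s(x~) h~``, where ``Hhat_s(x~)``
holds the first s columns of the causal Toeplitz matrix built from x~, so
each half-step is a *linear* problem: FISTA for the sparse signal update
and a simplex-constrained regularized least-squares solve for the kernel.
The constraints matter: without them the data misfit alone does not pin
down (x, h) — very different pairs produce nearly identical observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gammaln

from .core import ConvolutionOperator, build_operator
from .l1 import fista

__all__ = [
    "BlindProblemSpec",
    "BlindReport",
    "SignalColumnOperator",
    "build_signal_column_operator",
    "project_simplex",
    "solve_h_step",
    "initialize_h",
    "alternating_optimization",
]


class SignalColumnOperator:
    """Matrix-free ``Hhat_s(x~)``: first s columns of Toeplitz(x~), (n-d) x s."""

    def __init__(self, x_tilde: np.ndarray, support_s: int):
        x = np.asarray(x_tilde, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("x_tilde must be a non-empty 1-d vector")
        if not (1 <= support_s <= x.size):
            raise ValueError(f"support_s={support_s} out of range for length {x.size}")
        self.x_tilde = x
        self.support_s = int(support_s)
        self.m = x.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.m, self.support_s)

    def matvec(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if h.shape != (self.support_s,):
            raise ValueError(f"expected kernel of length {self.support_s}, got {h.shape}")
        return fftconvolve(self.x_tilde, h)[: self.m]

    def rmatvec(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.m,):
            raise ValueError(f"expected vector of length {self.m}, got {y.shape}")
        return fftconvolve(self.x_tilde[::-1], y)[self.m - 1 : self.m - 1 + self.support_s]

    def to_dense(self) -> np.ndarray:
        return build_operator(self.x_tilde).to_dense()[:, : self.support_s]


def build_signal_column_operator(x_tilde: np.ndarray, support_s: int) -> SignalColumnOperator:
    return SignalColumnOperator(x_tilde, support_s)


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort-based)."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, v.size + 1)
    rho = np.max(np.nonzero(u - css / idx > 0)[0]) + 1
    theta = css[rho - 1] / rho
    return np.maximum(v - theta, 0.0)


def solve_h_step(x_tilde: np.ndarray, b_tilde: np.ndarray, lambda_h: float,
                 support_s: int, kkt_tol: float = 1e-10,
                 max_iter: int = 20000,
                 h0: np.ndarray | None = None) -> np.ndarray:
    """Kernel half-step: regularized LS over the probability simplex.

    Minimizes ``||Hhat_s(x~) h - b~||^2 + lambda_h ||h||^2`` subject to
    ``h >= 0, sum(h) = 1`` by accelerated projected gradient with exact
    simplex projection, run to a fixed-point (KKT) residual below
    ``kkt_tol``.  With ``support_s = 1`` the constraints force h = [1].
    """
    if support_s == 1:
        return np.ones(1)
    x_tilde = np.asarray(x_tilde, dtype=float)
    if not np.any(x_tilde):
        raise ValueError("x_tilde is identically zero; kernel step is degenerate")
    A = SignalColumnOperator(x_tilde, support_s)
    Ad = A.to_dense()
    G = Ad.T @ Ad + lambda_h * np.eye(support_s)
    c = Ad.T @ np.asarray(b_tilde, dtype=float)
    L = 2.0 * float(np.linalg.norm(G, 2))

    def grad(h):
        return 2.0 * (G @ h - c)

    def obj(h):
        return float(h @ (G @ h)) - 2.0 * float(c @ h)

    h = project_simplex(h0.copy() if h0 is not None else np.full(support_s, 1.0 / support_s))
    y = h.copy()
    t = 1.0
    f_prev = obj(h)
    for _ in range(max_iter):
        h_new = project_simplex(y - grad(y) / L)
        f_new = obj(h_new)
        if f_new > f_prev:  # monotone restart
            t = 1.0
            y = h.copy()
            h_new = project_simplex(y - grad(y) / L)
            f_new = obj(h_new)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = h_new + ((t - 1.0) / t_next) * (h_new - h)
        h, t, f_prev = h_new, t_next, f_new
        # fixed-point residual of the projected-gradient map at h
        if np.linalg.norm(h - project_simplex(h - grad(h) / L)) <= kkt_tol:
            break
    return h


def initialize_h(kind: str, support_s: int, dt: float = 1.0,
                 gamma_params: dict | None = None) -> np.ndarray:
    """Feasible initial kernel on the support (nonnegative, sums to one).

    ``uniform`` gives the flat kernel; ``gamma_pdf`` evaluates the Gamma
    density ``beta^alpha / Gamma(alpha) * t^(alpha-1) exp(-beta t)`` on
    the support grid and renormalizes.  Preset pairs used as starting
    guesses in practice: (alpha=4, beta=3) and (alpha=2, beta=0.5).
    """
    if support_s < 1:
        raise ValueError("support_s must be >= 1")
    if kind == "uniform":
        return np.full(support_s, 1.0 / support_s)
    if kind == "gamma_pdf":
        params = gamma_params or {"alpha": 4.0, "beta": 3.0}
        alpha, beta = params["alpha"], params["beta"]
        if alpha <= 0 or beta <= 0:
            raise ValueError("gamma_pdf needs alpha, beta > 0")
        t = (np.arange(support_s) + 1.0) * dt
        logf = alpha * np.log(beta) - gammaln(alpha) + (alpha - 1.0) * np.log(t) - beta * t
        f = np.exp(logf - logf.max())
        return f / f.sum()
    raise ValueError(f"unknown initialization kind {kind!r}")


@dataclass
class BlindProblemSpec:
    """Inputs for the alternating solver (full-length observation b)."""

    b: np.ndarray
    delay_d: int
    support_s: int
    lambda1: float = 0.002
    lambda_h: float = 0.01
    h0: np.ndarray | None = None  # length s, feasible; default uniform
    tol: float = 1e-6
    max_outer: int = 50
    inner_max_iter: int = 200
    x_step: str = "l1"  # "l1" (FISTA, default) or "l2" (Tikhonov CGLS)
    lambda2: float = 0.01  # only used by the l2 x-step

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        n = self.b.size
        if self.delay_d < 0 or self.support_s < 1 or self.delay_d + self.support_s > n:
            raise ValueError(
                f"invalid delay/support (d={self.delay_d}, s={self.support_s}, n={n})"
            )
        if self.lambda1 <= 0 or self.lambda_h <= 0:
            raise ValueError("lambda1 and lambda_h must be positive")
        if self.x_step not in ("l1", "l2"):
            raise ValueError(f"x_step must be 'l1' or 'l2', got {self.x_step!r}")
        if self.h0 is None:
            self.h0 = initialize_h("uniform", self.support_s)
        else:
            self.h0 = np.asarray(self.h0, dtype=float)
            if self.h0.shape != (self.support_s,):
                raise ValueError("h0 must have length support_s")
            if np.any(self.h0 < 0) or abs(self.h0.sum() - 1.0) > 1e-8:
                raise ValueError("h0 must be nonnegative and sum to one")


@dataclass
class BlindReport:
    """Alternating-optimization history and result."""

    x_tilde: np.ndarray
    h_tilde: np.ndarray
    residual_norms: list = field(default_factory=list)
    h_change_norms: list = field(default_factory=list)
    objective_history: list = field(default_factory=list)
    h_iterates: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    reason: str = ""


def _reduced_operator(h_tilde: np.ndarray, m: int) -> ConvolutionOperator:
    col = np.zeros(m)
    col[: h_tilde.size] = h_tilde
    return build_operator(col)


def joint_objective(h_tilde: np.ndarray, x_tilde: np.ndarray, b_tilde: np.ndarray,
                    lambda1: float, lambda_h: float) -> float:
    """``||H~(h~) x~ - b~||^2 + lambda1 ||x~||_1 + lambda_h ||h~||^2``."""
    r = _reduced_operator(h_tilde, b_tilde.size).matvec(x_tilde) - b_tilde
    return float(r @ r) + lambda1 * float(np.abs(x_tilde).sum()) \
        + lambda_h * float(h_tilde @ h_tilde)


def alternating_optimization(spec: BlindProblemSpec) -> BlindReport:
    """Alternate sparse signal updates and constrained kernel updates.

    Each outer iteration runs FISTA (warm-started, ``inner_max_iter``
    inner iterations) on ``min ||H~(h~_k) x~ - b~||^2 + lambda1 ||x~||_1``
    and then the simplex-constrained kernel step; it stops when the kernel
    stops moving (``||h_{k+1} - h_k|| < tol * ||h_k||``) or the residual
    stops changing (``||r_k - r_{k-1}|| < tol * ||b~||``, skipped on the
    first iteration where no previous residual exists), or at
    ``max_outer``.
    """
    b_tilde = spec.b[spec.delay_d :].copy()
    m = b_tilde.size
    h = spec.h0.copy()
    x = np.zeros(m)
    report = BlindReport(x_tilde=x, h_tilde=h)
    report.h_iterates.append(h.copy())
    r_prev = None
    norm_b = np.linalg.norm(b_tilde)

    for k in range(spec.max_outer):
        Hk = _reduced_operator(h, m)
        if spec.x_step == "l1":
            # the joint objective carries no 1/2 on the misfit; FISTA's does,
            # so the equivalent FISTA parameter is lambda1 / 2
            x_rep = fista(Hk, b_tilde, lambda1=spec.lambda1 / 2.0,
                          max_iter=spec.inner_max_iter, x0=x)
        else:
            from .tikhonov import GaussianPrior, solve_cgls
            x_rep = solve_cgls(Hk, b_tilde, GaussianPrior(lambda2=spec.lambda2),
                               max_iter=spec.inner_max_iter, tol=1e-12)
        x = x_rep.solution
        h_new = solve_h_step(x, b_tilde, spec.lambda_h, spec.support_s, h0=h)
        r = Hk.matvec(x) - b_tilde

        report.h_iterates.append(h_new.copy())
        report.residual_norms.append(float(np.linalg.norm(r)))
        dh = float(np.linalg.norm(h_new - h))
        report.h_change_norms.append(dh)
        report.objective_history.append(
            joint_objective(h_new, x, b_tilde, spec.lambda1, spec.lambda_h)
        )
        report.iterations = k + 1

        if dh < spec.tol * max(np.linalg.norm(h), 1e-300):
            h = h_new
            report.converged, report.reason = True, "kernel update below tolerance"
            break
        if r_prev is not None and np.linalg.norm(r - r_prev) < spec.tol * norm_b:
            h = h_new
            report.converged, report.reason = True, "residual change below tolerance"
            break
        h, r_prev = h_new, r

    if not report.converged:
        report.reason = "max_outer reached"
    report.x_tilde = x
    report.h_tilde = h
    return report
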