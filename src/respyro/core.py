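"""Discrete forward model for flow-through respirometry.

A chamber/analyzer system smears the animal's instantaneous gas-release
signal ``x`` into the recorded concentration trace ``b`` by convolution
with the system's impulse response ``h``:

    b = H(h) x + noise,

where ``H(h)`` is the lower-triangular Toeplitz matrix whose first column
is the sampled, dt-scaled impulse response.  This module provides the
matrix-free operator, the dt-scaling convention used throughout the
package, and the delay/support reduction that underlies semi-blind
estimation.

Conventions
-----------
* All vectors are 0-based; slices are half-open.
* ``ImpulseResponse.values`` store *dt-scaled* samples, i.e. the first
  column of ``H``.  Mass preservation (the continuous kernel integrating
  to one) therefore reads ``values.sum() == 1`` on the stored vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz
from scipy.signal import fftconvolve

__all__ = [
    "TimeGrid",
    "ImpulseResponse",
    "ConvolutionOperator",
    "ReducedProblem",
    "build_operator",
    "reduce_system",
    "estimate_support_seconds",
]

# below this size a direct summation beats the FFT round trip
_DIRECT_CONV_MAX = 32


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid: ``n`` samples at interval ``dt`` seconds."""

    n: int
    dt: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"need n >= 2 samples, got {self.n}")
        if not (self.dt > 0 and np.isfinite(self.dt)):
            raise ValueError(f"sampling interval must be positive, got {self.dt}")

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t_k = k * dt``."""
        return np.arange(self.n) * self.dt

    @property
    def duration(self) -> float:
        return self.n * self.dt


class ConvolutionOperator:
    """Matrix-free m-by-m lower-triangular Toeplitz (causal convolution) map.

    ``matvec`` returns the first ``m`` samples of the linear convolution of
    the first column with the input; ``rmatvec`` applies the transpose
    (upper-triangular Toeplitz with the same first column).
    """

    def __init__(self, first_column: np.ndarray):
        col = np.asarray(first_column, dtype=float)
        if col.ndim != 1 or col.size == 0:
            raise ValueError("kernel must be a non-empty 1-d vector")
        if not np.all(np.isfinite(col)):
            raise ValueError("kernel contains non-finite entries")
        self.first_column = col
        self.dim_m = col.size
        # leading zeros of the kernel (transit delay) are handled by shifting,
        # so delayed kernels produce *exactly* zero output heads
        nz = np.nonzero(col)[0]
        self._lead = int(nz[0]) if nz.size else self.dim_m

    @property
    def shape(self) -> tuple[int, int]:
        return (self.dim_m, self.dim_m)

    def _check(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.shape != (self.dim_m,):
            raise ValueError(
                f"dimension mismatch: operator is {self.dim_m}x{self.dim_m}, "
                f"vector has shape {v.shape}"
            )
        return v

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """Forward map ``H x``."""
        x = self._check(x)
        m, d = self.dim_m, self._lead
        if d == m:
            return np.zeros(m)
        trimmed = self.first_column[d:]
        if m < _DIRECT_CONV_MAX:
            body = np.convolve(trimmed, x)[: m - d]
        else:
            body = fftconvolve(trimmed, x)[: m - d]
        out = np.zeros(m)
        out[d:] = body
        return out

    def rmatvec(self, y: np.ndarray) -> np.ndarray:
        """Adjoint map ``H^T y`` (correlation with the kernel)."""
        y = self._check(y)
        m, d = self.dim_m, self._lead
        if d == m:
            return np.zeros(m)
        rev = self.first_column[d:][::-1]
        if m < _DIRECT_CONV_MAX:
            full = np.convolve(rev, y)
        else:
            full = fftconvolve(rev, y)
        # H^T y correlates y with the kernel shifted by the delay; the last
        # d coordinates receive no contribution and are exactly zero
        out = np.zeros(m)
        out[: m - d] = full[m - 1 : 2 * m - d - 1]
        return out

    # aliases used throughout the solvers
    __call__ = matvec

    def to_dense(self) -> np.ndarray:
        """Explicit dense matrix; intended for small diagnostics/oracles."""
        return toeplitz(self.first_column, np.zeros(self.dim_m))


def build_operator(kernel: np.ndarray) -> ConvolutionOperator:
    """Build the causal Toeplitz operator with ``kernel`` as first column."""
    return ConvolutionOperator(kernel)


@dataclass(frozen=True)
class ImpulseResponse:
    """Sampled impulse response with known delay and compact support.

    ``values`` has length ``grid.n`` and stores dt-scaled samples; only
    entries ``delay_d : delay_d + support_s`` may be nonzero.  ``delay_d``
    counts leading zero samples (gas transit time before any response is
    seen), ``support_s`` the length of the nonzero washout block.
    """

    values: np.ndarray
    delay_d: int
    support_s: int
    grid: TimeGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        d, s, n = self.delay_d, self.support_s, self.grid.n
        if d < 0 or s < 1:
            raise ValueError(f"need delay_d >= 0 and support_s >= 1, got d={d}, s={s}")
        if d + s > n:
            raise ValueError(f"delay {d} + support {s} exceeds signal length {n}")
        if values.shape != (n,):
            raise ValueError(f"values must have length n={n}, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("impulse response contains non-finite values")
        if np.any(values[:d] != 0) or np.any(values[d + s :] != 0):
            raise ValueError("values must vanish outside [delay_d, delay_d + support_s)")

    @property
    def nonzero_part(self) -> np.ndarray:
        """The dt-scaled samples on the support, ``h~`` of the reduced system."""
        return self.values[self.delay_d : self.delay_d + self.support_s]

    @property
    def mass(self) -> float:
        """Discrete integral of the kernel under the dt-scaling convention."""
        return float(self.values.sum())

    def operator(self) -> ConvolutionOperator:
        return build_operator(self.values)

    def to_dict(self) -> dict:
        return {
            "dt": self.grid.dt,
            "delay_d": int(self.delay_d),
            "support_s": int(self.support_s),
            "values": self.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImpulseResponse":
        values = np.asarray(d["values"], dtype=float)
        grid = TimeGrid(n=values.size, dt=float(d["dt"]))
        return cls(values=values, delay_d=int(d["delay_d"]),
                   support_s=int(d["support_s"]), grid=grid)


@dataclass
class ReducedProblem:
    """Delay/support-trimmed system ``b~ = H~(h~) x~ + e~``.

    Dropping the ``d`` leading samples of ``b`` (pure transit delay, no
    information) shrinks the system to dimension ``n - d`` and the unknown
    kernel to its ``s`` nonzero samples.  The final ``d`` entries of the
    original signal ``x`` are not recoverable from the trimmed data: gas
    released there has not yet reached the analyzer when recording stops.
    """

    b_tilde: np.ndarray
    kernel_tilde: np.ndarray
    operator: ConvolutionOperator
    delay_d: int
    support_s: int
    grid: TimeGrid
    x_tail_unrecovered: int = field(init=False)

    def __post_init__(self) -> None:
        self.x_tail_unrecovered = self.delay_d


def reduce_system(b: np.ndarray, h: ImpulseResponse) -> ReducedProblem:
    """Trim the delay from ``b`` and the zero padding from ``h``.

    Returns the reduced system whose operator is the (n-d)-dimensional
    causal Toeplitz map built from the s nonzero kernel samples padded
    with zeros.
    """
    b = np.asarray(b, dtype=float)
    n, d, s = h.grid.n, h.delay_d, h.support_s
    if b.shape != (n,):
        raise ValueError(f"signal length {b.shape} does not match grid n={n}")
    m = n - d
    kernel_tilde = h.nonzero_part.copy()
    first_col = np.zeros(m)
    first_col[:s] = kernel_tilde
    return ReducedProblem(
        b_tilde=b[d:].copy(),
        kernel_tilde=kernel_tilde,
        operator=build_operator(first_col),
        delay_d=d,
        support_s=s,
        grid=h.grid,
    )


def estimate_support_seconds(volume_v: float, flow_f: float, factor: float = 4.0) -> float:
    """Rule-of-thumb kernel support from chamber volume and flow rate.

    The washout time constant of a well-mixed chamber is about V/F; the
    impulse response has effectively died out after 3-5 time constants.

    Parameters
    ----------
    volume_v : chamber volume in ml.
    flow_f : air inflow rate in ml/min.
    factor : multiple of the time response, in [3, 5].
    """
    if not (volume_v > 0 and flow_f > 0):
        raise ValueError("chamber volume and flow rate must be positive")
    if not (3.0 <= factor <= 5.0):
        raise ValueError(f"factor must lie in [3, 5], got {factor}")
    return factor * (volume_v / flow_f) * 60.0
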