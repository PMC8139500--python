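"""Simulated respirometry test problems.

Real metabolic traces vary slowly, but several insect species ventilate in
discontinuous bursts with quiet interludes; rectangular pulse trains are
the harder test case because of their high-frequency edges.  The default
problem here is a 512-sample trace built from six pulses of varying width,
convolved with a delayed gamma-shaped impulse response
``h(t) ~ t^m exp(-beta t)`` and observed under white Gaussian noise at a
0.5% relative level.

All randomness flows through :func:`numpy.random.default_rng` (PCG64), so
a fixed seed reproduces a problem bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConvolutionOperator, ImpulseResponse, TimeGrid, build_operator

__all__ = [
    "PulseSpec",
    "NoiseSpec",
    "generate_pulse_signal",
    "generate_impulse_response",
    "add_noise",
    "make_test_problem",
    "TestProblem",
]


@dataclass(frozen=True)
class PulseSpec:
    """Rectangular pulse train: per-pulse start time, duration, amplitude (s, s, signal units)."""

    starts: tuple
    durations: tuple
    amplitudes: tuple

    def __post_init__(self) -> None:
        if not (len(self.starts) == len(self.durations) == len(self.amplitudes)):
            raise ValueError("starts, durations, amplitudes must have equal length")
        if any(w <= 0 for w in self.durations):
            raise ValueError("pulse durations must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Relative white-noise level (e.g. 0.005 for 0.5%) and RNG seed."""

    level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be non-negative")


def generate_pulse_signal(grid: TimeGrid, spec: PulseSpec) -> np.ndarray:
    """Sample a pulse train on the grid; overlapping pulses sum."""
    x = np.zeros(grid.n)
    horizon = grid.n * grid.dt
    for t0, width, amp in zip(spec.starts, spec.durations, spec.amplitudes):
        if t0 < 0 or t0 + width > horizon:
            raise ValueError(
                f"pulse [{t0}, {t0 + width}) s falls outside the grid [0, {horizon}) s"
            )
        i0 = int(round(t0 / grid.dt))
        i1 = int(round((t0 + width) / grid.dt))
        x[i0:i1] += amp
    return x


def generate_impulse_response(
    grid: TimeGrid,
    form: str = "gamma_kernel",
    params: dict | None = None,
    delay_d: int = 0,
    support_s: int | None = None,
    normalize: bool = True,
) -> ImpulseResponse:
    """Parameterized impulse response with delay and compact support.

    Forms
    -----
    ``gamma_kernel``
        ``h(t) = alpha * t**m * exp(-beta*t)`` with ``t`` measured from the
        end of the delay; peak at ``t = m / beta``.  Params: alpha, m, beta.
    ``exp_kernel``
        ``h(t) = alpha * exp(-beta*t)`` — the classical single-compartment
        washout.  Params: alpha, beta.
    ``uniform``
        Constant on the support.

    With ``normalize=True`` the stored (dt-scaled) samples are rescaled to
    sum to one, the discrete mass-preservation convention.
    """
    if support_s is None:
        raise ValueError("support_s is required")
    if support_s < 1:
        raise ValueError("support_s must be >= 1")
    if delay_d < 0 or delay_d + support_s > grid.n:
        raise ValueError(
            f"delay {delay_d} + support {support_s} exceeds n={grid.n}"
        )
    params = dict(params or {})
    # local time on the support, measured from the end of the delay
    t = (np.arange(support_s) + 1.0) * grid.dt
    if form == "gamma_kernel":
        alpha = params.get("alpha", 1.0)
        m = params.get("m", 2.0)
        beta = params.get("beta", 1.0)
        if alpha <= 0 or beta <= 0 or m < 0:
            raise ValueError("gamma_kernel needs alpha, beta > 0 and m >= 0")
        block = alpha * t**m * np.exp(-beta * t)
    elif form == "exp_kernel":
        alpha = params.get("alpha", 1.0)
        beta = params.get("beta", 1.0)
        if alpha <= 0 or beta <= 0:
            raise ValueError("exp_kernel needs alpha, beta > 0")
        block = alpha * np.exp(-beta * t)
    elif form == "uniform":
        block = np.ones(support_s)
    else:
        raise ValueError(f"unknown impulse-response form {form!r}")

    values = np.zeros(grid.n)
    values[delay_d : delay_d + support_s] = block * grid.dt
    if normalize:
        total = values.sum()
        if total <= 0:
            raise ValueError("cannot normalize a zero-mass kernel")
        values /= total
    return ImpulseResponse(values=values, delay_d=delay_d, support_s=support_s, grid=grid)


def add_noise(b_clean: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Add white Gaussian noise rescaled to an exact relative level.

    The realized noise vector satisfies ``||e|| / ||b_clean|| == level``
    exactly, so discrepancy-style checks are reproducible to rounding.
    """
    b_clean = np.asarray(b_clean, dtype=float)
    if noise.level == 0:
        return b_clean.copy()
    norm_b = np.linalg.norm(b_clean)
    if norm_b == 0:
        raise ValueError("cannot set a relative noise level on an all-zero signal")
    rng = np.random.default_rng(noise.seed)
    e = rng.standard_normal(b_clean.size)
    e *= noise.level * norm_b / np.linalg.norm(e)
    return b_clean + e


@dataclass
class TestProblem:
    """Reproducible simulated problem bundle."""

    grid: TimeGrid
    x_true: np.ndarray
    h: ImpulseResponse
    b_clean: np.ndarray
    b: np.ndarray
    noise_level: float
    seed: int
    noise_sigma: float = field(init=False)

    def __post_init__(self) -> None:
        # realized per-sample noise standard deviation
        self.noise_sigma = float(
            np.linalg.norm(self.b - self.b_clean) / np.sqrt(self.grid.n)
        )

    @property
    def operator(self) -> ConvolutionOperator:
        return self.h.operator()


# default pulse pattern: six pulses of widths 30 down to 2 samples (dt = 1 s),
# unit amplitude, clear of the delayed tail
_DEFAULT_STARTS = (20.0, 80.0, 150.0, 220.0, 300.0, 380.0)
_DEFAULT_DURATIONS = (30.0, 20.0, 12.0, 8.0, 4.0, 2.0)


def default_pulse_spec(grid: TimeGrid) -> PulseSpec:
    """Six unit pulses of widths 2-30 samples, scaled to the grid horizon."""
    scale = grid.n * grid.dt / 512.0
    return PulseSpec(
        starts=tuple(t * scale for t in _DEFAULT_STARTS),
        durations=tuple(max(w * scale, grid.dt) for w in _DEFAULT_DURATIONS),
        amplitudes=(1.0,) * len(_DEFAULT_STARTS),
    )


def default_kernel(grid: TimeGrid) -> ImpulseResponse:
    """Delayed unimodal washout kernel: delay ~0.05 n, support ~0.25 n."""
    delay_d = max(1, int(round(0.05 * grid.n)))
    support_s = max(4, int(round(0.25 * grid.n)))
    # peak about one fifth into the support
    beta = 2.0 / (0.2 * support_s * grid.dt)
    return generate_impulse_response(
        grid,
        form="gamma_kernel",
        params={"alpha": 1.0, "m": 2.0, "beta": beta},
        delay_d=delay_d,
        support_s=support_s,
        normalize=True,
    )


def make_test_problem(
    n: int = 512,
    level: float = 0.005,
    seed: int = 0,
    dt: float = 1.0,
    pulse_spec: PulseSpec | None = None,
    h: ImpulseResponse | None = None,
) -> TestProblem:
    """Build the default simulated problem: pulses + delayed kernel + noise."""
    grid = TimeGrid(n=n, dt=dt)
    if pulse_spec is None:
        pulse_spec = default_pulse_spec(grid)
    if h is None:
        h = default_kernel(grid)
    x_true = generate_pulse_signal(grid, pulse_spec)
    b_clean = build_operator(h.values).matvec(x_true)
    b = add_noise(b_clean, NoiseSpec(level=level, seed=seed))
    return TestProblem(grid=grid, x_true=x_true, h=h, b_clean=b_clean, b=b,
                       noise_level=level, seed=seed)
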