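"""Linear temporal kernels for the steering system.

The steering response is modeled as a causal linear functional of the recent
history of steering errors,

    r(t) = integral_0^inf k(tau) x(t - tau) dtau,

where ``k`` is the sensorimotor kernel.  Two parameterizations are provided:

* a nonparametric expansion on a causal raised half-cosine basis,
  ``k(tau) = sum_i w_i b_i(tau)`` with
  ``b_i(tau) = cos(2 pi f (tau - phi_i))`` on ``|2 pi f (tau - phi_i)| < pi/2``
  and zero elsewhere — smooth, finite-memory, and exactly zero at
  non-positive lags;
* the impulse response of a second-order (damped-oscillator) controller,
  in which hand acceleration is driven by the time-delayed error against
  viscous and spring-like resistance:

      k(tau) = G sin(wd (tau - delay)) exp(-zeta wn (tau - delay)),  tau >= delay

  with damped frequency ``wd = wn sqrt(1 - zeta^2)`` and amplitude
  ``G = g / (wn sqrt(1 - zeta^2))``.

All kernels are sampled on a uniform lag grid starting at one frame
(``dt``), never at lag zero: the response may not depend on the
instantaneous error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BasisSet",
    "Kernel",
    "SecondOrderParams",
    "build_basis",
    "default_lag_grid",
    "kernel_from_weights",
    "convolve",
    "second_order_kernel",
]

#: Default basis size and center range (seconds), and bump frequency (Hz).
DEFAULT_N_BASIS = 56
DEFAULT_PHI_MIN = 0.125
DEFAULT_PHI_MAX = 4.708
DEFAULT_BUMP_FREQ = 2.0
#: Kernels are forced to zero beyond this lag (seconds) to suppress edge
#: artifacts from the asymmetric overlap of the final basis functions.
DEFAULT_TRUNCATION_LAG = 4.835
#: Display frame rate (Hz) at which the loop closes.
FRAME_RATE = 85.0


@dataclass
class BasisSet:
    """Causal half-cosine temporal basis sampled on a uniform lag grid.

    Attributes
    ----------
    centers : ndarray
        Bump centers ``phi_i`` in seconds, linearly spaced.
    f : float
        Bump frequency in Hz; each bump spans ``(phi_i - 1/(4f), phi_i + 1/(4f))``.
    lag_grid : ndarray
        Uniform lag grid in seconds, starting at ``dt`` (lag zero excluded).
    B : ndarray, shape (len(lag_grid), N)
        Basis functions sampled on the lag grid.
    """

    centers: np.ndarray
    f: float
    lag_grid: np.ndarray
    B: np.ndarray

    @property
    def N(self) -> int:
        return self.B.shape[1]

    @property
    def dt(self) -> float:
        return float(self.lag_grid[1] - self.lag_grid[0])


@dataclass
class Kernel:
    """A sampled linear temporal response function k(tau).

    ``k[j]`` is the weight at lag ``lag_grid[j]``; the kernel is causal by
    construction (the grid starts at one frame) and zero beyond
    ``truncation_lag``.
    """

    lag_grid: np.ndarray
    k: np.ndarray
    weights: np.ndarray | None = None
    truncation_lag: float = DEFAULT_TRUNCATION_LAG
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lag_grid = np.asarray(self.lag_grid, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.lag_grid.shape != self.k.shape:
            raise ValueError("lag_grid and k must have the same shape")
        if not np.all(np.isfinite(self.k)):
            raise ValueError("kernel values must be finite")

    @property
    def dt(self) -> float:
        if len(self.lag_grid) > 1:
            return float(self.lag_grid[1] - self.lag_grid[0])
        return float(self.lag_grid[0])


@dataclass
class SecondOrderParams:
    """Parameters of the second-order damped-oscillator controller.

    zeta : damping ratio (dimensionless, underdamped: 0 <= zeta < 1)
    omega_n : undamped natural frequency (rad/s)
    g : error gain (response units per deg per s^2)
    delay : sensorimotor time delay tau' (s)
    """

    zeta: float
    omega_n: float
    g: float
    delay: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zeta < 1.0:
            raise ValueError(f"damping ratio must be in [0, 1), got {self.zeta}")
        if self.omega_n <= 0:
            raise ValueError("natural frequency must be positive")
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")

    @property
    def omega_d(self) -> float:
        """Damped oscillation frequency wn*sqrt(1 - zeta^2), rad/s."""
        return self.omega_n * np.sqrt(1.0 - self.zeta**2)

    @property
    def G(self) -> float:
        """Impulse-response amplitude g / (wn sqrt(1 - zeta^2))."""
        return self.g / self.omega_d

    @classmethod
    def from_amplitude(
        cls, zeta: float, omega_n: float, G: float, delay: float
    ) -> "SecondOrderParams":
        """Construct from the amplitude G instead of the gain g."""
        g = G * omega_n * np.sqrt(1.0 - zeta**2)
        return cls(zeta=zeta, omega_n=omega_n, g=g, delay=delay)


def default_lag_grid(
    dt: float = 1.0 / FRAME_RATE,
    max_lag: float = DEFAULT_PHI_MAX + 1.0 / (4 * DEFAULT_BUMP_FREQ),
) -> np.ndarray:
    """Uniform lag grid dt, 2*dt, ... covering ``max_lag``."""
    n = int(np.ceil(max_lag / dt - 1e-9))
    return dt * np.arange(1, n + 1)


def build_basis(
    N: int = DEFAULT_N_BASIS,
    phi_min: float = DEFAULT_PHI_MIN,
    phi_max: float = DEFAULT_PHI_MAX,
    f: float = DEFAULT_BUMP_FREQ,
    lag_grid: np.ndarray | None = None,
) -> BasisSet:
    """Build the causal half-cosine basis on a lag grid.

    Each bump is ``cos(2 pi f (tau - phi_i))`` where the cosine argument is
    within (-pi/2, pi/2) and zero otherwise, so the support half-width is
    ``1/(4f)`` (0.125 s at the default f = 2 Hz).
    """
    if N < 1:
        raise ValueError("need at least one basis function")
    if not phi_min < phi_max:
        raise ValueError("phi_min must be below phi_max")
    if lag_grid is None:
        lag_grid = default_lag_grid(max_lag=phi_max + 1.0 / (4 * f))
    lag_grid = np.asarray(lag_grid, dtype=float)
    if len(lag_grid) > 1:
        steps = np.diff(lag_grid)
        if not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValueError("lag grid must be uniform")
    if lag_grid[-1] < phi_max + 1.0 / (4 * f) - lag_grid[0] * (1 + 1e-9):
        raise ValueError(
            "lag grid does not cover the basis support "
            f"(need max lag >= {phi_max + 1.0 / (4 * f):.4f} s)"
        )
    centers = np.linspace(phi_min, phi_max, N)
    arg = 2 * np.pi * f * (lag_grid[:, None] - centers[None, :])
    B = np.where(np.abs(arg) < np.pi / 2, np.cos(arg), 0.0)
    return BasisSet(centers=centers, f=f, lag_grid=lag_grid, B=B)


def kernel_from_weights(
    w: np.ndarray,
    basis: BasisSet,
    truncation_lag: float = DEFAULT_TRUNCATION_LAG,
) -> Kernel:
    """Assemble k = B @ w and zero it beyond the truncation lag."""
    w = np.asarray(w, dtype=float)
    if w.shape != (basis.N,):
        raise ValueError(f"expected {basis.N} weights, got shape {w.shape}")
    k = basis.B @ w
    k = np.where(basis.lag_grid > truncation_lag, 0.0, k)
    return Kernel(
        lag_grid=basis.lag_grid.copy(),
        k=k,
        weights=w.copy(),
        truncation_lag=truncation_lag,
        meta={"basis": {"N": basis.N, "f": basis.f,
                        "phi_min": float(basis.centers[0]),
                        "phi_max": float(basis.centers[-1])}},
    )


def convolve(kernel: Kernel, x: np.ndarray, dt: float) -> np.ndarray:
    """Deterministic response: r_hat[i] = sum_j k[j] x[i - j] dt.

    The sum runs over lags j = 1..L (rectangle rule with the dt factor; lag
    zero is excluded because the kernel is causal).  History before the
    series start is treated as zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input series")
    if abs(dt - kernel.dt) > 1e-9 * kernel.dt:
        raise ValueError(f"dt {dt} does not match kernel grid spacing {kernel.dt}")
    full = np.convolve(x, kernel.k) * dt
    out = np.empty_like(x)
    out[0] = 0.0
    out[1:] = full[: len(x) - 1]
    return out


def second_order_kernel(
    params: SecondOrderParams, lag_grid: np.ndarray
) -> Kernel:
    """Sample the underdamped second-order impulse response on a lag grid.

    k(tau) = G sin(wd (tau - delay)) exp(-zeta wn (tau - delay)) for
    tau >= delay, zero before the delay.  Only the underdamped branch
    (zeta < 1) exists; ``SecondOrderParams`` rejects zeta >= 1.
    """
    lag_grid = np.asarray(lag_grid, dtype=float)
    u = lag_grid - params.delay
    k = np.where(
        u >= 0,
        params.G * np.sin(params.omega_d * u) * np.exp(-params.zeta * params.omega_n * u),
        0.0,
    )
    return Kernel(
        lag_grid=lag_grid.copy(),
        k=k,
        truncation_lag=float(lag_grid[-1]),
        meta={"second_order": {"zeta": params.zeta, "omega_n": params.omega_n,
                               "g": params.g, "G": params.G, "delay": params.delay}},
    )
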