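"""Surrogate BOLD-like signals from a multivariate Ornstein-Uhlenbeck process.

Node activity follows the linear stochastic differential equation

    dx(t) = A x(t) dt + dW(t),     A = (G - 1) / tau,

driven by a unit-intensity Wiener process, where ``G`` is the ground-truth
coupling matrix and ``tau`` the activity time constant.  The process is
stable whenever every eigenvalue of A has negative real part (spectral
radius of G below 1 for the bulk).  Sampling uses the exact discretization

    x(t + dt) = e^{A dt} x(t) + n(t),   n(t) ~ N(0, Sigma_dt),
    Sigma_dt  = Sigma - e^{A dt} Sigma e^{A^T dt},

with Sigma the stationary covariance from the continuous Lyapunov equation
``A Sigma + Sigma A^T = -1``; the chain is then marginally identical to the
continuous process at all sampling times, so no burn-in is needed when the
initial state is drawn from N(0, Sigma).  (A "stationary" noise mode that
draws the update noise from N(0, Sigma) itself is available for comparison;
it inflates the marginal variance and is not the default.)  To emulate BOLD
recordings the series can be convolved with the canonical double-gamma
hemodynamic response function and corrupted by i.i.d. Gaussian observation
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.signal
from scipy.stats import gamma as gamma_dist

__all__ = [
    "OUModel",
    "TimeSeries",
    "NoiseSpec",
    "stationary_covariance",
    "simulate",
    "hrf_kernel",
    "apply_hrf",
    "add_observation_noise",
    "observe_subset",
]


@dataclass
class OUModel:
    """An Ornstein-Uhlenbeck network model with drift A = (G - 1)/tau.

    ``tau`` and ``dt`` are in seconds; ``T`` is the total simulated
    duration, so the series has ``round(T / dt)`` samples.
    """

    G: np.ndarray
    T: float
    tau: float = 0.1
    dt: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        n = self.G.shape[0]
        if self.G.shape != (n, n):
            raise ValueError(f"G must be square, got shape {self.G.shape}")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.T < self.dt:
            raise ValueError("T must be at least one sampling interval")

    @property
    def n_nodes(self) -> int:
        return self.G.shape[0]

    @property
    def n_samples(self) -> int:
        return int(round(self.T / self.dt))

    @property
    def drift(self) -> np.ndarray:
        """Drift matrix A = (G - 1) / tau."""
        return (self.G - np.eye(self.n_nodes)) / self.tau

    def is_stable(self) -> bool:
        return bool(np.max(np.linalg.eigvals(self.drift).real) < 0)


@dataclass
class TimeSeries:
    """Node activity record: ``values`` is (n_nodes, n_samples), dt in seconds."""

    values: np.ndarray
    dt: float
    hrf_applied: bool = False
    sigma_obs: float = 0.0
    snr: float | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a (n_nodes, n_samples) matrix")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class NoiseSpec:
    """Observation-noise level and the signal-to-noise ratio it produced."""

    sigma_obs: float
    snr: float = float("inf")


def stationary_covariance(model: OUModel) -> np.ndarray:
    """Stationary covariance Sigma of the OU process.

    Solves the continuous Lyapunov equation ``A Sigma + Sigma A^T = -1``
    (unit-intensity driving noise); the solution is symmetric positive
    definite exactly when A is stable.
    """
    A = model.drift
    if not model.is_stable():
        raise ValueError(
            "drift matrix is unstable (an eigenvalue has nonnegative real part): "
            "no stationary covariance exists; reduce the spectral radius of G"
        )
    Sigma = scipy.linalg.solve_continuous_lyapunov(A, -np.eye(model.n_nodes))
    return 0.5 * (Sigma + Sigma.T)


def simulate(
    model: OUModel,
    *,
    noise_mode: str = "exact",
    dtype: np.dtype | type = np.float64,
    chunk: int = 100_000,
) -> TimeSeries:
    """Sample a stationary OU trajectory with the exact update formula.

    The initial state is drawn from the stationary law N(0, Sigma) and the
    recursion ``x <- e^{A dt} x + n`` is iterated; with the default
    ``noise_mode="exact"`` the update noise has covariance
    ``Sigma - e^{A dt} Sigma e^{A^T dt}``, making every marginal exactly
    stationary.  ``noise_mode="stationary"`` draws the update noise from
    N(0, Sigma) instead.  ``dtype`` controls the storage precision of the
    output (float32 halves the footprint of long runs; the recursion state
    is always float64).
    """
    if noise_mode not in ("exact", "stationary"):
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    n, m = model.n_nodes, model.n_samples
    Sigma = stationary_covariance(model)
    E = scipy.linalg.expm(model.drift * model.dt)
    if noise_mode == "exact":
        Sigma_dt = Sigma - E @ Sigma @ E.T
        Sigma_dt = 0.5 * (Sigma_dt + Sigma_dt.T)
    else:
        Sigma_dt = Sigma
    try:
        L_dt = np.linalg.cholesky(Sigma_dt)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "update-noise covariance is not positive definite (numerically); "
            "reduce dt so the exact discretization is well conditioned"
        ) from exc
    L0 = np.linalg.cholesky(Sigma)

    rng = np.random.default_rng(model.seed)
    out = np.empty((n, m), dtype=dtype)
    x = L0 @ rng.standard_normal(n)
    out[:, 0] = x
    filled = 1
    while filled < m:
        size = min(chunk, m - filled)
        noise = L_dt @ rng.standard_normal((n, size))
        for t in range(size):
            x = E @ x + noise[:, t]
            out[:, filled + t] = x
        filled += size
    return TimeSeries(values=out, dt=model.dt)


def hrf_kernel(dt: float, *, support: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function sampled at dt.

    Positive gamma lobe (shape 6, unit dispersion, mode at 5 s) minus 1/6
    of an undershoot lobe (shape 16, mode at 15 s), evaluated on
    [0, ``support``] seconds and normalized to unit peak.  The kernel
    vanishes at t = 0 and changes sign exactly once.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, support + dt / 2, dt)
    k = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return k / np.max(k)


def apply_hrf(ts: TimeSeries, kernel: np.ndarray | None = None, *, row_chunk: int = 8) -> TimeSeries:
    """Causally convolve each node's series with the HRF kernel.

    The output is truncated to the input length, so sample t of the output
    depends only on inputs at times <= t.  Refuses to filter twice.
    """
    if ts.hrf_applied:
        raise ValueError("HRF has already been applied to this series")
    if kernel is None:
        kernel = hrf_kernel(ts.dt)
    kernel = np.asarray(kernel, dtype=float)
    x = ts.values
    out = np.empty_like(x)
    m = ts.n_samples
    # row-chunked FFT convolution keeps the float64 scratch small for long runs
    for lo in range(0, ts.n_nodes, row_chunk):
        block = np.asarray(x[lo : lo + row_chunk], dtype=float)
        conv = scipy.signal.fftconvolve(block, kernel[None, :], mode="full", axes=1)
        out[lo : lo + row_chunk] = conv[:, :m]
    return replace(ts, values=out, hrf_applied=True)


def add_observation_noise(ts: TimeSeries, sigma_obs: float, seed: int | None = None) -> TimeSeries:
    """Add i.i.d. N(0, sigma_obs^2) measurement noise to every sample.

    Records SNR = mean over nodes of var(signal)/sigma_obs^2 on the
    returned series (infinite for sigma_obs = 0).
    """
    if sigma_obs < 0:
        raise ValueError("sigma_obs must be nonnegative")
    signal_var = float(np.mean(np.var(np.asarray(ts.values, dtype=float), axis=1)))
    if sigma_obs == 0:
        return replace(ts, sigma_obs=0.0, snr=float("inf"))
    rng = np.random.default_rng(seed)
    noisy = ts.values + sigma_obs * rng.standard_normal(ts.values.shape).astype(ts.values.dtype, copy=False)
    return replace(ts, values=noisy, sigma_obs=sigma_obs, snr=signal_var / sigma_obs**2)


def observe_subset(
    ts: TimeSeries, fraction: float, seed: int | None = None
) -> tuple[TimeSeries, np.ndarray]:
    """Retain a uniformly random subset of nodes, as when part of a network
    is unrecorded.

    Returns the reduced series and the sorted indices of the observed nodes,
    which map estimates back onto the ground-truth submatrix
    ``G[np.ix_(idx, idx)]``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = ts.n_nodes
    k = int(round(fraction * n))
    if k < 1:
        raise ValueError(f"fraction {fraction} keeps no node out of {n}")
    if k == n:
        return replace(ts), np.arange(n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return replace(ts, values=ts.values[idx]), idx

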