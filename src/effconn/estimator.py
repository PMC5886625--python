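"""End-to-end estimation of directed, signed connectivity from zero-lag data.

The pipeline is: standardize the series (per-node mean 0, variance 1) ->
zero-lag sample covariance C -> unique positive-definite square root B0 of
C^-1 -> geodesic L1 minimization over unitaries -> signed-permutation
canonicalization -> coupling estimate G_est = 1 - B with the (undefined)
diagonal zeroed.  A covariance or precision matrix may be supplied directly,
skipping the sample stages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ou_simulator import TimeSeries
from .unitary_optimizer import OptimizerConfig, OptimizerTrace, canonicalize, optimize

__all__ = [
    "EstimationResult",
    "standardize",
    "sample_covariance",
    "initial_factor",
    "estimate_connectivity",
    "threshold_network",
]

_MAX_CONDITION = 1e10


@dataclass
class EstimationResult:
    """Outcome of one connectivity estimation.

    ``G_est`` has a zero diagonal (self-connections are not identifiable
    under the model); ``U_final @ B0`` is the L1-minimal precision factor
    before canonicalization.
    """

    G_est: np.ndarray
    U_final: np.ndarray
    B0: np.ndarray
    trace: OptimizerTrace
    n_samples: int | None = None
    standardized: bool = True


def standardize(ts: TimeSeries) -> TimeSeries:
    """Shift and scale each node to mean 0 and (population) variance 1."""
    x = np.asarray(ts.values)
    mean = x.mean(axis=1, dtype=np.float64)
    var = x.var(axis=1, dtype=np.float64)
    bad = np.flatnonzero(var == 0)
    if bad.size:
        raise ValueError(f"node(s) {bad.tolist()} are constant and cannot be standardized")
    out = (x - mean[:, None].astype(x.dtype)) / np.sqrt(var)[:, None].astype(x.dtype)
    return replace(ts, values=out, standardized=True)


def sample_covariance(ts: TimeSeries, *, col_chunk: int = 200_000) -> np.ndarray:
    """Zero-lag sample covariance C = (1/M) sum_t x(t) x(t)^T.

    Assumes the series has already been standardized (the second-moment
    form is then the correlation matrix).  Accumulates in float64 in column
    chunks, so float32 storage of long runs does not degrade the result.
    """
    x = np.asarray(ts.values)
    n, m = x.shape
    if m <= n:
        raise ValueError(
            f"need more time points than nodes for an invertible covariance "
            f"(got {m} samples for {n} nodes); use a longer series"
        )
    C = np.zeros((n, n))
    for lo in range(0, m, col_chunk):
        block = np.asarray(x[:, lo : lo + col_chunk], dtype=np.float64)
        C += block @ block.T
    C /= m
    return 0.5 * (C + C.T)


def initial_factor(C: np.ndarray, *, ridge: float = 0.0) -> np.ndarray:
    """Unique positive-definite square root B0 of the precision C^-1.

    With the eigendecomposition ``C^-1 = W E W*``, ``B0 = W sqrt(E) W*`` is
    the one positive-definite factor satisfying ``B0* B0 = C^-1``; it seeds
    the unitary search.  Raises for non-positive-definite or severely
    ill-conditioned input; ``ridge > 0`` adds ``ridge * trace(C)/N`` to the
    diagonal first (off by default — estimation assumes plain inversion).
    """
    C = np.asarray(C)
    n = C.shape[0]
    if C.shape != (n, n):
        raise ValueError(f"covariance must be square, got shape {C.shape}")
    herm_err = np.linalg.norm(C - C.conj().T)
    if herm_err > 1e-10 * max(1.0, np.linalg.norm(C)):
        raise ValueError("covariance is not symmetric/Hermitian")
    if ridge > 0:
        C = C + (ridge * np.trace(C).real / n) * np.eye(n)
    evals, W = np.linalg.eigh(C)
    if evals[0] <= 0:
        raise np.linalg.LinAlgError(
            f"covariance is not positive definite (smallest eigenvalue {evals[0]:.3e})"
        )
    if evals[-1] / evals[0] > _MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"covariance condition number {evals[-1] / evals[0]:.3e} exceeds "
            f"{_MAX_CONDITION:.0e}; consider a longer series or a ridge"
        )
    B0 = (W / np.sqrt(evals)) @ W.conj().T
    return 0.5 * (B0 + B0.conj().T)


def estimate_connectivity(
    data: TimeSeries | np.ndarray,
    config: OptimizerConfig | None = None,
    *,
    role: str = "covariance",
) -> EstimationResult:
    """Estimate the directed signed coupling matrix from zero-lag statistics.

    ``data`` may be a :class:`TimeSeries` (standardized and reduced to its
    sample covariance first), a covariance matrix (``role="covariance"``),
    or a precision matrix (``role="precision"``).  The estimate is
    ``G_est = 1 - canonicalize(U B0)`` with the diagonal zeroed.
    """
    n_samples = None
    if isinstance(data, TimeSeries):
        ts = data if data.standardized else standardize(data)
        C = sample_covariance(ts)
        n_samples = ts.n_samples
        B0 = initial_factor(C)
    else:
        M = np.asarray(data)
        if role == "covariance":
            B0 = initial_factor(M)
        elif role == "precision":
            B0 = initial_factor(np.linalg.inv(M))
        else:
            raise ValueError(f"role must be 'covariance' or 'precision', got {role!r}")

    U, trace = optimize(B0, config)
    B_canon = canonicalize(U @ B0)
    G_est = np.eye(B0.shape[0]) - B_canon
    np.fill_diagonal(G_est, 0.0)
    return EstimationResult(
        G_est=G_est, U_final=U, B0=B0, trace=trace, n_samples=n_samples
    )


def threshold_network(G_est: np.ndarray, keep_fraction: float = 0.1) -> np.ndarray:
    """Keep only the strongest connections, zeroing the rest.

    Retains the ``floor(keep_fraction * N^2)`` entries of largest absolute
    value over the full N x N grid (the zero diagonal is never selected for
    a nontrivial fraction), preserving their signs.  For a 90-node estimate
    at the default 10% this keeps exactly 810 connections.  Ties at the
    cutoff magnitude are broken deterministically by row-major index order.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    G = np.asarray(G_est, dtype=float)
    if keep_fraction == 1:
        return G.copy()
    k = int(np.floor(keep_fraction * G.size))
    flat = np.abs(G).ravel()
    # stable sort on -|g|: ties resolved by ascending flat (row-major) index
    order = np.argsort(-flat, kind="stable")
    out = np.zeros_like(G)
    keep = order[:k]
    out.ravel()[keep] = G.ravel()[keep]
    return out
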