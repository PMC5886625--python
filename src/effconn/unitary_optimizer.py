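"""L1-minimization over the unitary group by geodesic subgradient descent.

Any factor B with ``B* B = C^-1`` determines the precision matrix, and the
whole solution set is the orbit ``{U B : U unitary}``.  Assuming the true
network is sparse, the factor of minimal off-diagonal L1 norm identifies the
coupling matrix through ``B = 1 - G``.  This module minimizes

    Gamma(U) = sum_{i != j} |(U B)_{ij}|

over the unitary group (the orthogonal group for real input) by following
geodesics ``U -> exp(-delta a) U`` generated by skew-Hermitian descent
directions, with the step size tied to the spectral period of the direction
(a 1/kappa fraction of 2 pi / |lambda_max|).

The cost is piecewise linear in the entries of UB, so this is a subgradient
method, not a smooth descent: the cost along the iterates oscillates around
a slowly decreasing level, and forcing per-step monotonicity would freeze
the iteration at the first kink.  The optimizer therefore takes the
kappa-scaled step unconditionally, remembers the best iterate seen, and
anneals: whenever a phase of iterations stops improving on the best cost,
the step size is halved (kappa doubled) and the search resumes from the
best point, the standard diminishing-step schedule under which subgradient
methods converge.  The reported cost sequence (best-so-far) is
non-increasing by construction.  A final one-dimensional line search along
the last direction polishes the result.

The minimizer is unique only up to a signed permutation of rows (which
preserves both the constraint and the cost); :func:`canonicalize` fixes
this gauge by making the factor diagonally dominant with a nonnegative
diagonal, as expected of ``1 - G`` for a sparse G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import linear_sum_assignment, minimize_scalar

__all__ = [
    "OptimizerConfig",
    "OptimizerTrace",
    "l1_cost",
    "l1_gradient",
    "descent_direction",
    "step_size",
    "line_search",
    "plane_refine",
    "optimize",
    "canonicalize",
]

_TWO_PI = 2.0 * np.pi


@dataclass
class OptimizerConfig:
    """Convergence tolerances and step-size policy of the geodesic descent.

    ``xtol``, ``ftol`` and ``gtol`` are the iterate-change, relative
    cost-change and gradient-norm tolerances; ``kappa`` sets the step size
    to a 1/kappa fraction of the spectral period of the descent direction.
    ``patience`` is the number of iterations without improvement on the
    best cost that ends an annealing phase (each phase halves the step);
    ``max_halvings`` caps the number of phases.  The ``xtol``/``ftol``
    criterion is evaluated at phase boundaries, where the oscillating raw
    cost has been reduced to its best representative.
    """

    xtol: float = 0.7e-2
    ftol: float = 0.7e-4
    gtol: float = 0.7e-2
    kappa: float = 500.0
    max_iter: int = 10000
    reorthonormalize_every: int = 100
    patience: int = 30
    max_halvings: int = 20
    line_search: bool = True
    refine: bool = True  # final Givens-plane coordinate-descent polish
    seed: int | None = None  # reserved for randomized restarts; default start is U = 1

    def __post_init__(self) -> None:
        for name in ("xtol", "ftol", "gtol", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class OptimizerTrace:
    """Per-iteration diagnostics of one optimization run.

    ``gamma`` is the best-so-far (monotone non-increasing) cost sequence;
    ``gamma_raw`` the oscillating cost of the raw iterates.
    """

    gamma: list[float] = field(default_factory=list)
    gamma_raw: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    delta: list[float] = field(default_factory=list)
    n_iter: int = 0
    n_phases: int = 0
    converged: bool = False
    stop_reason: str = ""


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def l1_cost(U: np.ndarray, B: np.ndarray) -> float:
    """Off-diagonal L1 norm Gamma(U) = sum_{i != j} |(U B)_{ij}|."""
    M = U @ B
    n = M.shape[0]
    if M.shape != (n, n):
        raise ValueError(f"U @ B must be square, got shape {M.shape}")
    return float(np.sum(np.abs(M[_offdiag_mask(n)])))


def _phase_matrix(M: np.ndarray) -> np.ndarray:
    """Entrywise phase of M with zeros (and the diagonal) mapped to 0.

    The subgradient of |z| at z = 0 is taken as 0, the minimal-norm element.
    """
    absM = np.abs(M)
    if np.iscomplexobj(M):
        S = np.where(absM > 0, M / np.where(absM > 0, absM, 1.0), 0.0)
    else:
        S = np.sign(M)
    np.fill_diagonal(S, 0)
    return S


def l1_gradient(U: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Euclidean (sub)gradient d of Gamma at U: d = phase(UB) B*.

    The diagonal of UB is excluded from the cost, so the corresponding
    phase entries are zeroed before the product with B*.
    """
    S = _phase_matrix(U @ B)
    return S @ B.conj().T


def descent_direction(d: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Skew-Hermitian direction a = (d U* - U d*)/2 generating the geodesic.

    This is the left-translated Riemannian gradient for the update
    ``U -> exp(-delta a) U``; its Frobenius norm is half the residual
    ``||d - U d* U||_F`` used in the gradient stopping rule.
    """
    return 0.5 * (d @ U.conj().T - U @ d.conj().T)


def _skew_spectrum(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of skew-Hermitian a via the Hermitian matrix i*a.

    Returns (w, V) with ``a = V diag(-i w) V*`` and real w, so that
    ``exp(-t a) = V diag(exp(i t w)) V*``.
    """
    w, V = np.linalg.eigh(1j * a)
    return w, V


def _geodesic(w: np.ndarray, V: np.ndarray, t: float, real: bool) -> np.ndarray:
    """exp(-t a) from the spectrum of a; real part taken for real input."""
    R = (V * np.exp(1j * t * w)) @ V.conj().T
    return R.real if real else R


def step_size(a: np.ndarray, kappa: float = 500.0) -> float:
    """Adaptive step delta = 2 pi / (|lambda_max| kappa).

    Cost functions along a geodesic on the unitary group are nearly
    periodic with period 2 pi / |lambda_max|, where lambda_max is the
    eigenvalue of largest magnitude of the direction; the step is a
    1/kappa fraction of that period.  Raises for a zero direction, which
    signals convergence.
    """
    w, _ = _skew_spectrum(np.asarray(a))
    lam = float(np.max(np.abs(w)))
    if lam == 0.0:
        raise ValueError("zero descent direction: already converged, no step to take")
    return _TWO_PI / (lam * kappa)


def line_search(
    U: np.ndarray,
    a: np.ndarray,
    B: np.ndarray,
    *,
    n_grid: int = 50,
    rel_tol: float = 1e-6,
) -> np.ndarray:
    """Minimize Gamma(exp(-t a) U) for t over one spectral period of a.

    A coarse grid over [0, 2 pi / |lambda_max|] locates the basin, then
    golden-section/Brent refinement resolves the minimizer to ``rel_tol``
    of the period.  The cost is never increased: the input U is returned
    if no grid point improves on it.
    """
    real = not (np.iscomplexobj(U) or np.iscomplexobj(B))
    w, V = _skew_spectrum(a)
    lam = float(np.max(np.abs(w)))
    if lam == 0.0:
        return U

    period = _TWO_PI / lam

    def cost_at(t: float) -> float:
        return l1_cost(_geodesic(w, V, t, real) @ U, B)

    ts = np.linspace(0.0, period, n_grid)
    costs = np.array([cost_at(t) for t in ts])
    k = int(np.argmin(costs))
    lo = ts[max(k - 1, 0)]
    hi = ts[min(k + 1, n_grid - 1)]
    res = minimize_scalar(
        cost_at, bounds=(lo, hi), method="bounded", options={"xatol": rel_tol * period}
    )
    t_best, c_best = res.x, res.fun
    if costs[k] < c_best:
        t_best, c_best = ts[k], costs[k]
    if c_best >= costs[0]:  # t = 0 is the incoming iterate
        return U
    return _geodesic(w, V, float(t_best), real) @ U


def _reorthonormalize(U: np.ndarray) -> np.ndarray:
    """Project U back onto the unitary group (polar factor)."""
    P, _ = scipy.linalg.polar(U)
    return P


def _plane_cost(theta: np.ndarray, Mi: np.ndarray, Mj: np.ndarray, i: int, j: int) -> np.ndarray:
    """Off-diagonal L1 mass of rows i, j after a left rotation by theta.

    Vectorized over theta; only these two rows change under a planar
    rotation, so the rest of the cost is a constant offset.
    """
    c, s = np.cos(theta)[:, None], np.sin(theta)[:, None]
    new_i = c * Mi - s * Mj
    new_j = s * Mi + c * Mj
    total = np.abs(new_i).sum(axis=1) + np.abs(new_j).sum(axis=1)
    return total - np.abs(new_i[:, i]) - np.abs(new_j[:, j])


def plane_refine(
    U: np.ndarray,
    B: np.ndarray,
    *,
    max_sweeps: int = 30,
    n_grid: int = 64,
    rel_tol: float = 1e-12,
    escape_tries: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Coordinate descent over planar (Givens) rotations to polish a minimizer.

    Cyclically minimizes Gamma over each left rotation plane (i, j) by a
    periodic grid search plus golden-section refinement; a plane rotation
    only mixes rows i and j of UB, so each 1-D problem costs O(N).  Sweeps
    repeat until the cost improvement falls below ``rel_tol`` (relative) or
    ``max_sweeps`` is reached.  When a sweep stalls, up to ``escape_tries``
    line searches along seeded random skew directions (random pursuit) are
    attempted, which can step over kinks that block every single-plane
    move; sweeping resumes if one succeeds.  Deterministic for a fixed
    seed, monotone, and exact enough to land on the kinks where sparse
    minimizers live.  Real input only (complex factors would need phase
    rotations as well).
    """
    if np.iscomplexobj(U) or np.iscomplexobj(B):
        return U
    n = U.shape[0]
    M = U @ B
    U = U.copy()
    gamma = float(np.sum(np.abs(M)) - np.sum(np.abs(np.diagonal(M))))
    grid = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    rng = np.random.default_rng(seed)
    for _ in range(max_sweeps):
        start_gamma = gamma
        for i in range(n - 1):
            for j in range(i + 1, n):
                Mi, Mj = M[i], M[j]
                base = _plane_cost(np.array([0.0]), Mi, Mj, i, j)[0]
                vals = _plane_cost(grid, Mi, Mj, i, j)
                k = int(np.argmin(vals))
                if vals[k] >= base - 1e-15 * (1.0 + base):
                    continue
                # golden-section refinement around the best grid point
                step = 2.0 * np.pi / n_grid
                lo, hi = grid[k] - step, grid[k] + step
                x1 = hi - gr * (hi - lo)
                x2 = lo + gr * (hi - lo)
                f1 = _plane_cost(np.array([x1]), Mi, Mj, i, j)[0]
                f2 = _plane_cost(np.array([x2]), Mi, Mj, i, j)[0]
                for _ in range(40):
                    if f1 < f2:
                        hi, x2, f2 = x2, x1, f1
                        x1 = hi - gr * (hi - lo)
                        f1 = _plane_cost(np.array([x1]), Mi, Mj, i, j)[0]
                    else:
                        lo, x1, f1 = x1, x2, f2
                        x2 = lo + gr * (hi - lo)
                        f2 = _plane_cost(np.array([x2]), Mi, Mj, i, j)[0]
                theta = x1 if f1 < f2 else x2
                fbest = min(f1, f2)
                if fbest >= base - 1e-15 * (1.0 + base):
                    continue
                c, s = np.cos(theta), np.sin(theta)
                M[i], M[j] = c * Mi - s * Mj, s * Mi + c * Mj
                Ui, Uj = U[i].copy(), U[j].copy()
                U[i], U[j] = c * Ui - s * Uj, s * Ui + c * Uj
                gamma += fbest - base
        if start_gamma - gamma <= rel_tol * (1.0 + abs(start_gamma)):
            escaped = False
            for _ in range(escape_tries):
                W = rng.standard_normal((n, n))
                a = 0.5 * (W - W.T)
                U_try = line_search(U, a, B)
                g_try = l1_cost(U_try, B)
                if g_try < gamma - rel_tol * (1.0 + abs(gamma)):
                    U = U_try
                    M = U @ B
                    gamma = g_try
                    escaped = True
                    break
            if not escaped:
                break
    return _reorthonormalize(U)


def _spectral_norm(a: np.ndarray, q: np.ndarray, n_iter: int) -> tuple[float, np.ndarray]:
    """Power-iteration estimate of |lambda_max| = ||a||_2 for skew-Hermitian a.

    ``q`` warm-starts the iteration (the descent direction changes slowly
    between steps); returns the estimate and the updated vector.
    """
    aH = a.conj().T
    for _ in range(n_iter):
        q = aH @ (a @ q)
        nrm = np.linalg.norm(q)
        if nrm == 0.0:
            return 0.0, q
        q = q / nrm
    return float(np.linalg.norm(a @ q)), q


def optimize(
    B0: np.ndarray,
    config: OptimizerConfig | None = None,
    *,
    callback=None,
) -> tuple[np.ndarray, OptimizerTrace]:
    """Annealed geodesic subgradient descent for the L1-minimal rotation of B0.

    Starting from U = 1, iterates ``U <- exp(-delta a) U`` with
    ``delta = 2 pi / (|lambda_max| kappa)``, tracking the best iterate seen.
    Whenever ``patience`` consecutive iterations fail to improve on the best
    cost, one annealing phase ends: kappa is doubled (the step halved, up
    to ``max_halvings`` times) and the search resumes from the best point.
    Stops when the Riemannian subgradient residual ``||d - U d* U||_F``
    falls below ``gtol``; or, at a phase boundary, when the best iterate
    moved by less than ``xtol`` (Frobenius norm over N) during the phase
    while the relative best-cost change stayed below ``ftol``; or after
    ``max_iter`` iterations (flagged as not converged).  A final line
    search along the last direction polishes the result.

    ``callback``, if given, is invoked as ``callback(U, iteration)`` after
    every accepted iterate (diagnostics/invariant monitoring).

    Returns the final unitary U and the iteration trace; the L1-minimal
    factor is ``U @ B0``.
    """
    config = config or OptimizerConfig()
    B = np.asarray(B0)
    n = B.shape[0]
    if B.shape != (n, n):
        raise ValueError(f"B0 must be square, got shape {B.shape}")
    real = not np.iscomplexobj(B)
    dtype = float if real else complex

    U = np.eye(n, dtype=dtype)
    gamma = l1_cost(U, B)
    trace = OptimizerTrace()
    last_direction: np.ndarray | None = None

    best_g, best_U = gamma, U
    phase_ref_g, phase_ref_U = gamma, U
    kappa = config.kappa
    since_improve = 0
    q = np.ones(n, dtype=dtype) / np.sqrt(n)  # power-iteration warm start
    power_steps = 12

    for it in range(config.max_iter):
        trace.n_iter = it
        d = l1_gradient(U, B)
        grad_res = float(np.linalg.norm(d - U @ d.conj().T @ U))
        trace.grad_norm.append(grad_res)
        if grad_res < config.gtol:
            trace.converged = True
            trace.stop_reason = "gradient"
            break

        a = descent_direction(d, U)
        lam, q = _spectral_norm(a, q, power_steps)
        power_steps = 3
        if lam <= np.finfo(float).eps * max(1.0, float(np.linalg.norm(d))):
            trace.converged = True
            trace.stop_reason = "gradient"
            break
        last_direction = a

        delta = _TWO_PI / (lam * kappa)
        trace.delta.append(delta)
        U = scipy.linalg.expm(-delta * a) @ U
        if (it + 1) % config.reorthonormalize_every == 0:
            U = _reorthonormalize(U)
        gamma = l1_cost(U, B)
        trace.gamma_raw.append(gamma)
        if callback is not None:
            callback(U, it)

        if gamma < best_g - 1e-12 * (1.0 + abs(best_g)):
            best_g, best_U = gamma, U
            since_improve = 0
        else:
            since_improve += 1
            if since_improve > config.patience:
                x_change = float(np.linalg.norm(best_U - phase_ref_U)) / n
                f_change = abs(phase_ref_g - best_g) / (abs(phase_ref_g) + 1.0)
                trace.n_phases += 1
                if x_change < config.xtol and f_change < config.ftol:
                    trace.converged = True
                    trace.stop_reason = "xtol/ftol"
                    break
                if trace.n_phases >= config.max_halvings:
                    trace.converged = True
                    trace.stop_reason = "step-floor"
                    break
                kappa *= 2.0
                U, gamma = best_U, best_g
                phase_ref_g, phase_ref_U = best_g, best_U
                since_improve = 0
        trace.gamma.append(best_g)
    else:
        trace.stop_reason = "max_iter"

    U = _reorthonormalize(best_U)
    if config.line_search and last_direction is not None:
        U = line_search(U, last_direction, B)
        U = _reorthonormalize(U)
    if config.refine:
        U = plane_refine(U, B)
    trace.gamma.append(min(best_g, l1_cost(U, B)))
    return U, trace


def canonicalize(B_opt: np.ndarray) -> np.ndarray:
    """Fix the signed-permutation gauge of an L1-minimal factor.

    Rotating a factor by any signed permutation preserves both the
    constraint ``B* B = C^-1`` and the off-diagonal L1 cost, so the
    optimizer's output is one arbitrary representative of that orbit.  For
    a sparse network the sought representative is ``1 - G``, which is
    diagonally dominant with a positive diagonal.  A linear assignment
    maximizing ``sum_i |B_{pi(i), i}|`` permutes the rows so the dominant
    entries land on the diagonal, then row signs are flipped to make every
    diagonal entry nonnegative (for complex input, rows are rotated by the
    conjugate phase of their diagonal entry).
    """
    B = np.asarray(B_opt)
    n = B.shape[0]
    if B.shape != (n, n):
        raise ValueError(f"input must be square, got shape {B.shape}")
    rows, cols = linear_sum_assignment(-np.abs(B))
    out = np.empty_like(B)
    out[cols] = B[rows]
    diag = np.diagonal(out).copy()
    if np.iscomplexobj(B):
        absd = np.abs(diag)
        phase = np.where(absd > 0, diag / np.where(absd > 0, absd, 1.0), 1.0)
        out = out / phase[:, None]
    else:
        sign = np.where(diag < 0, -1.0, 1.0)
        out = out * sign[:, None]
    return out
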