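"""Sparse signed random networks and the covariance structure they imply.

Nodes interact through the stationary linear consistency model

    x = G x + v,

where ``G`` is the coupling matrix (row = target, column = source) and the
external drives ``v`` are pairwise independent with unit variance.  Under
these assumptions the precision (inverse covariance) matrix of the activity
is exactly

    C^-1 = (1 - G)^T (1 - G) = 1 - G - G^T + G^T G,

whose last term encodes collider structure: entry (i, j) of ``G^T G`` is
nonzero iff nodes i and j send connections to at least one common target.
This module samples Erdős-Rényi coupling matrices with equal-magnitude
signed weights at a prescribed bulk spectral radius and evaluates the
noise-free precision implied by the model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "strength_for_radius",
    "sample_er_network",
    "add_background",
    "noise_free_precision",
    "noise_free_covariance",
]


def strength_for_radius(n_nodes: int, connection_prob: float, spectral_radius: float) -> float:
    """Uniform connection magnitude |J| that yields a given bulk spectral radius.

    For a sparse random matrix with i.i.d. entries of magnitude |J| present
    with probability p, the bulk eigenvalue spectrum has radius
    ``rho = |J| * sqrt(p (1 - p) N)``, so ``|J| = rho / sqrt(p (1 - p) N)``.
    The relation is asymptotic in N; sampled matrices scatter around it.

    Parameters
    ----------
    n_nodes : int
        Network size N (>= 2).
    connection_prob : float
        Edge probability p, strictly inside (0, 1).
    spectral_radius : float
        Desired bulk spectral radius rho >= 0.
    """
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {n_nodes}")
    if not 0.0 < connection_prob < 1.0:
        raise ValueError(
            f"connection probability must lie strictly in (0, 1) to set a "
            f"strength from the spectral radius, got {connection_prob}"
        )
    if spectral_radius < 0:
        raise ValueError("spectral radius must be nonnegative")
    return spectral_radius / math.sqrt(connection_prob * (1.0 - connection_prob) * n_nodes)


@dataclass
class NetworkSpec:
    """Parameters of a signed Erdős-Rényi coupling matrix.

    Attributes
    ----------
    n_nodes : int
        Network size N.
    connection_prob : float
        Independent edge probability p for every ordered off-diagonal pair.
    spectral_radius : float
        Target bulk spectral radius rho of G; rho < 1 is required for a
        stable dynamical interpretation (a warning is emitted otherwise,
        since the static noise-free covariance only needs 1 - G invertible).
    inhibitory_fraction : float
        Probability that a sampled connection is negative (default 0.5).
    connection_strength : float or None
        Uniform magnitude |J|; derived from the spectral radius when None.
    exact_half_inhibitory : bool
        If True, assign exactly ``round(f * k)`` negative signs among the k
        sampled edges instead of i.i.d. Bernoulli signs.
    rescale_to_radius : bool
        If True, rescale the sampled matrix so its empirical spectral radius
        equals ``spectral_radius`` exactly (useful for tightly controlled
        sweeps); by default the asymptotic strength formula is used as is.
    seed : int or None
        Seed for reproducible sampling.
    """

    n_nodes: int
    connection_prob: float
    spectral_radius: float
    inhibitory_fraction: float = 0.5
    connection_strength: float | None = None
    exact_half_inhibitory: bool = False
    rescale_to_radius: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0.0 <= self.connection_prob <= 1.0:
            raise ValueError("connection_prob must lie in [0, 1]")
        if not 0.0 <= self.inhibitory_fraction <= 1.0:
            raise ValueError("inhibitory_fraction must lie in [0, 1]")
        if self.spectral_radius < 0:
            raise ValueError("spectral_radius must be nonnegative")
        if self.spectral_radius >= 1:
            warnings.warn(
                "spectral radius >= 1: the network has no stable dynamical "
                "interpretation (noise-free covariances may still be valid)",
                stacklevel=2,
            )

    @property
    def strength(self) -> float:
        """Connection magnitude |J|, derived from the spectral radius if unset."""
        if self.connection_strength is not None:
            return self.connection_strength
        if self.spectral_radius == 0:
            return 0.0
        return strength_for_radius(self.n_nodes, self.connection_prob, self.spectral_radius)


def sample_er_network(spec: NetworkSpec) -> np.ndarray:
    """Sample a signed Erdős-Rényi coupling matrix G.

    Each ordered off-diagonal pair carries a connection independently with
    probability ``spec.connection_prob``; all connections have the same
    magnitude and are negative (inhibitory) with probability
    ``spec.inhibitory_fraction``.  The diagonal is identically zero
    (self-connections are outside the model).

    Returns an (N, N) array; entry (i, j) is the influence of node j on
    node i.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    mask = rng.random((n, n)) < spec.connection_prob
    np.fill_diagonal(mask, False)

    signs = np.ones((n, n))
    if spec.exact_half_inhibitory:
        idx = np.flatnonzero(mask)
        k_neg = int(round(spec.inhibitory_fraction * idx.size))
        neg = rng.permutation(idx.size)[:k_neg]
        flat = signs.ravel()
        flat[idx[neg]] = -1.0
    else:
        signs[rng.random((n, n)) < spec.inhibitory_fraction] = -1.0

    G = np.where(mask, spec.strength * signs, 0.0)
    if spec.rescale_to_radius and spec.spectral_radius > 0:
        radius = np.max(np.abs(np.linalg.eigvals(G)))
        if radius > 0:
            G *= spec.spectral_radius / radius
    return G


def add_background(
    skeleton: np.ndarray,
    background_prob: float,
    background_radius: float,
    *,
    inhibitory_fraction: float = 0.5,
    seed: int | None = None,
) -> np.ndarray:
    """Superimpose a dense weak background network on a sparse skeleton.

    An independent Erdős-Rényi network with edge probability
    ``background_prob`` and magnitude set from ``background_radius`` is
    sampled and added elementwise.  The skeleton alone remains the ground
    truth when evaluating estimates of the strong connections.
    """
    skeleton = np.asarray(skeleton, dtype=float)
    n = skeleton.shape[0]
    if skeleton.shape != (n, n):
        raise ValueError(f"skeleton must be square, got shape {skeleton.shape}")
    if background_prob == 0 or background_radius == 0:
        return skeleton.copy()
    bg_spec = NetworkSpec(
        n_nodes=n,
        connection_prob=background_prob,
        spectral_radius=background_radius,
        inhibitory_fraction=inhibitory_fraction,
        seed=seed,
    )
    return skeleton + sample_er_network(bg_spec)


def noise_free_precision(G: np.ndarray) -> np.ndarray:
    """Exact precision matrix (1 - G)^T (1 - G) implied by the linear model.

    Positive definite whenever ``1 - G`` is nonsingular.  Raises for a
    (numerically) singular ``1 - G``, which signals a degenerate network at
    the edge of instability.
    """
    G = np.asarray(G)
    n = G.shape[0]
    if G.shape != (n, n):
        raise ValueError(f"G must be square, got shape {G.shape}")
    eye = np.eye(n)
    A = eye - G
    # rcond ~ 1/cond; a singular 1 - G means the consistency equation has no
    # unique stationary solution.
    if np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError(
            "1 - G is singular or near-singular: the network is degenerate/unstable"
        )
    if np.iscomplexobj(G):
        return A.conj().T @ A
    return A.T @ A


def noise_free_covariance(G: np.ndarray) -> np.ndarray:
    """Exact covariance (1 - G)^{-1} (1 - G)^{-T} of the linear model."""
    G = np.asarray(G)
    n = G.shape[0]
    inv = np.linalg.inv(np.eye(n) - G)
    if np.iscomplexobj(G):
        return inv @ inv.conj().T
    return inv @ inv.T
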