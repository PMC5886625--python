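"""Geodesic L1 subgradient descent on the orthogonal/unitary group."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effconn import (
    NetworkSpec,
    OptimizerConfig,
    canonicalize,
    descent_direction,
    l1_cost,
    l1_gradient,
    line_search,
    noise_free_precision,
    optimize,
    sample_er_network,
    step_size,
)
from effconn.estimator import initial_factor


def offdiag_l1(M):
    return np.sum(np.abs(M)) - np.sum(np.abs(np.diagonal(M)))


def rotation_direction(theta, n=2):
    """Skew matrix whose geodesic is a rotation by angle theta per unit time."""
    a = np.zeros((n, n))
    a[0, 1], a[1, 0] = theta, -theta
    return a


class TestCost:
    def test_identity_has_zero_cost(self):
        assert l1_cost(np.eye(4), np.eye(4)) == 0.0

    def test_matches_direct_summation(self, rng):
        G = np.zeros((2, 2))
        G[1, 0] = 0.5
        B = initial_factor(np.linalg.inv(noise_free_precision(G)))
        assert l1_cost(np.eye(2), B) == pytest.approx(offdiag_l1(B), abs=1e-14)
        U, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        B5 = rng.standard_normal((5, 5))
        assert l1_cost(U, B5) == pytest.approx(offdiag_l1(U @ B5), abs=1e-12)

    def test_diagonal_exclusion_applied_after_rotation(self, rng):
        # the excluded diagonal is that of the rotated product P @ U @ B,
        # so permuting rows generally changes the cost
        B = rng.standard_normal((4, 4))
        P = np.eye(4)[[1, 0, 3, 2]]
        assert l1_cost(P, B) == pytest.approx(offdiag_l1(P @ B), abs=1e-12)
        assert l1_cost(P, B) != pytest.approx(l1_cost(np.eye(4), B), abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l1_cost(np.eye(3), np.ones((3, 4)))


class TestGradient:
    def test_all_positive_product_gives_ones_pattern(self, rng):
        B = rng.uniform(1.0, 2.0, size=(4, 4))
        S = np.ones((4, 4))
        np.fill_diagonal(S, 0)
        assert np.allclose(l1_gradient(np.eye(4), B), S @ B.T)

    def test_matches_central_finite_differences(self, rng):
        # smooth away from kinks: random dense B keeps |UB| entries off zero
        B = rng.standard_normal((5, 5)) + 3 * np.eye(5)
        U, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        assert np.min(np.abs((U @ B)[~np.eye(5, dtype=bool)])) > 1e-3
        d = l1_gradient(U, B)
        h = 1e-6
        for i in range(5):
            for j in range(5):
                Up, Um = U.copy(), U.copy()
                Up[i, j] += h
                Um[i, j] -= h
                fd = (l1_cost(Up, B) - l1_cost(Um, B)) / (2 * h)
                assert d[i, j] == pytest.approx(fd, abs=1e-5)

    def test_zero_entries_use_zero_subgradient(self):
        B = np.eye(3)  # UB = I: all off-diagonal entries sit at the kink
        assert np.all(l1_gradient(np.eye(3), B) == 0)


class TestDescentDirection:
    def test_direction_vanishes_when_gradient_equals_iterate(self, rng):
        U, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert np.allclose(descent_direction(U, U), 0)

    def test_symmetric_gradient_at_identity_gives_no_direction(self, rng):
        d = rng.standard_normal((4, 4))
        d = d + d.T
        assert np.allclose(descent_direction(d, np.eye(4)), 0)

    def test_skew_and_gradient_norm_identity(self, rng):
        d = rng.standard_normal((6, 6))
        U, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        a = descent_direction(d, U)
        assert np.linalg.norm(a + a.T) < 1e-12
        # ||d - U d* U||_F = ||(d U* - U d*) U||_F = 2 ||a||_F
        assert np.linalg.norm(d - U @ d.T @ U) == pytest.approx(
            2 * np.linalg.norm(a), rel=1e-10
        )


class TestStepSize:
    def test_direct_substitution(self):
        a = rotation_direction(2 * np.pi)
        assert step_size(a, kappa=500.0) == pytest.approx(1 / 500.0)

    def test_inverse_proportional_to_kappa(self):
        a = rotation_direction(1.3)
        assert step_size(a, kappa=1000.0) == pytest.approx(step_size(a, kappa=500.0) / 2)

    def test_rotation_block_period_fraction(self):
        # a 2x2 rotation block with angle theta has |lambda_max| = theta and
        # geodesic period 2 pi / theta; delta is 1/kappa of that period
        theta = 0.77
        a = rotation_direction(theta)
        assert step_size(a, kappa=500.0) == pytest.approx((2 * np.pi / theta) / 500.0)

    def test_zero_direction_signals_convergence(self):
        with pytest.raises(ValueError):
            step_size(np.zeros((3, 3)))


class TestLineSearch:
    def test_constant_cost_returns_input(self):
        U = np.eye(2)
        a = rotation_direction(1.0)
        out = line_search(U, a, np.zeros((2, 2)))
        assert out is U

    def test_two_by_two_matches_scalar_brute_force(self):
        B = np.array([[1.0, 1.0], [0.0, 1.0]])
        U = np.eye(2)
        a = rotation_direction(1.0)
        out = line_search(U, a, B)

        # brute-force 1-D oracle: exp(-t a) is a closed-form planar rotation
        def gamma(t):
            c, s = np.cos(t), np.sin(t)
            R = np.array([[c, -s], [s, c]])
            return l1_cost(R @ U, B)

        brute = min(gamma(t) for t in np.linspace(0, 2 * np.pi, 200001))
        assert l1_cost(out, B) == pytest.approx(brute, abs=1e-4)

    def test_never_increases_cost(self, rng):
        B = rng.standard_normal((4, 4))
        U, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        d = l1_gradient(U, B)
        a = descent_direction(d, U)
        out = line_search(U, a, B)
        assert l1_cost(out, B) <= l1_cost(U, B) + 1e-12


class TestOptimize:
    def test_identity_input_converges_immediately(self):
        U, trace = optimize(np.eye(6))
        assert trace.n_iter == 0
        assert trace.converged and trace.stop_reason == "gradient"
        assert np.array_equal(U, np.eye(6))
        assert trace.gamma[-1] == 0.0

    def test_cost_reduced_and_unitary(self, small_precision):
        B0 = initial_factor(np.linalg.inv(small_precision))
        U, trace = optimize(B0)
        assert l1_cost(U, B0) <= l1_cost(np.eye(20), B0)
        assert np.linalg.norm(U.T @ U - np.eye(20)) <= 1e-8

    def test_invariants_hold_at_every_iterate(self, small_precision):
        B0 = initial_factor(np.linalg.inv(small_precision))
        BtB = B0.T @ B0
        ref = np.linalg.norm(BtB)
        worst = {"unitary": 0.0, "constraint": 0.0}

        def check(U, it):
            worst["unitary"] = max(worst["unitary"], np.linalg.norm(U.T @ U - np.eye(20)))
            M = U @ B0
            worst["constraint"] = max(
                worst["constraint"], np.linalg.norm(M.T @ M - BtB) / ref
            )

        optimize(B0, OptimizerConfig(max_iter=2000), callback=check)
        assert worst["unitary"] <= 1e-8
        assert worst["constraint"] <= 1e-8

    def test_reported_cost_sequence_is_monotone(self, small_precision):
        B0 = initial_factor(np.linalg.inv(small_precision))
        _, trace = optimize(B0)
        gamma = np.array(trace.gamma)
        assert np.all(np.diff(gamma) <= 1e-12)

    def test_small_instance_matches_dense_sampling_oracle(self, rng):
        # minimize over O(3) by dense sampling as an independent oracle
        Q = rng.standard_normal((100_000, 3, 3))
        Qs, Rs = np.linalg.qr(Q)
        signs = np.sign(np.einsum("nii->ni", Rs))
        rotations = Qs * signs[:, None, :]  # Haar on SO(3); row flips are cost-neutral
        n_pass = 0
        for seed in range(20):
            G = sample_er_network(NetworkSpec(3, 0.4, 0.0, connection_strength=0.5, seed=seed))
            B = initial_factor(np.linalg.inv(noise_free_precision(G)))
            prods = rotations @ B
            costs = np.abs(prods).sum(axis=(1, 2)) - np.abs(
                np.diagonal(prods, axis1=1, axis2=2)
            ).sum(axis=1)
            U, _ = optimize(B)
            if l1_cost(U, B) <= costs.min() + 1e-3:
                n_pass += 1
        assert n_pass == 20

    def test_collider_motif_global_minimizer_is_the_truth(self, rng):
        # a collider pins the orientation: the true factor 1 - G attains a
        # strictly lower off-diagonal L1 cost than any sampled rotation and
        # than the descent result (which may sit in the reversed-motif
        # local minimum on a bare 3-node graph)
        g = 0.6
        G = np.zeros((3, 3))
        G[0, 1] = g
        G[0, 2] = -g  # 2 -> 1 <- 3 with mixed signs
        B0 = initial_factor(np.linalg.inv(noise_free_precision(G)))
        truth_cost = l1_cost(np.eye(3), np.eye(3) - G)
        assert truth_cost == pytest.approx(2 * g, abs=1e-12)
        Q = rng.standard_normal((100_000, 3, 3))
        Qs, Rs = np.linalg.qr(Q)
        signs = np.sign(np.einsum("nii->ni", Rs))
        prods = (Qs * signs[:, None, :]) @ B0
        sampled_min = float(
            (np.abs(prods).sum(axis=(1, 2))
             - np.abs(np.diagonal(prods, axis1=1, axis2=2)).sum(axis=1)).min()
        )
        assert truth_cost <= sampled_min + 1e-12
        U, _ = optimize(B0)
        assert truth_cost <= l1_cost(U, B0) + 1e-12
        # row sign flips preserve the off-diagonal cost exactly (the
        # permutation part of the gauge moves the diagonal, so only the
        # sign flips are cost-neutral under the diagonal exclusion)
        D = np.diag([-1.0, 1.0, -1.0])
        assert l1_cost(D @ (np.eye(3) - G) @ np.linalg.inv(B0), B0) == pytest.approx(
            truth_cost, abs=1e-10
        )

    def test_collider_free_motif_orientations_tie(self):
        # a chain and its reversal have identical off-diagonal L1 cost, so the
        # direction of such links is not identifiable from the cost
        g = 0.7
        chain = np.zeros((3, 3))
        chain[1, 0] = chain[2, 1] = g  # 1 -> 2 -> 3
        reverse = chain.T
        c1 = l1_cost(np.eye(3), np.eye(3) - chain)
        c2 = l1_cost(np.eye(3), np.eye(3) - reverse)
        assert abs(c1 - c2) <= 1e-9

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_random_instances_respect_constraint_and_descend(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((5, 5))
        C = A @ A.T + 5 * np.eye(5)
        B0 = initial_factor(C)
        U, trace = optimize(B0, OptimizerConfig(max_iter=500))
        assert np.linalg.norm(U.T @ U - np.eye(5)) <= 1e-8
        M = U @ B0
        ref = np.linalg.norm(B0.T @ B0)
        assert np.linalg.norm(M.T @ M - B0.T @ B0) / ref <= 1e-8
        assert trace.gamma[-1] <= trace.gamma[0] + 1e-12


class TestCanonicalize:
    def test_negative_identity(self):
        assert np.array_equal(canonicalize(-np.eye(4)), np.eye(4))

    def test_permutation_matrix(self):
        P = np.eye(5)[[2, 0, 4, 1, 3]]
        assert np.array_equal(canonicalize(P), np.eye(5))

    def test_recovers_signed_permuted_factor(self, small_network, rng):
        B_true = np.eye(20) - small_network
        perm = rng.permutation(20)
        signs = rng.choice([-1.0, 1.0], size=20)
        scrambled = (signs[:, None] * B_true)[perm]
        assert np.allclose(canonicalize(scrambled), B_true, atol=1e-14)
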