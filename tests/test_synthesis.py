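"""The constraint system and the networks it produces."""

import numpy as np
import pytest

from empj.dynamics import DriftSpec, eigenspec_at_setpoint
from empj.manifolds import RingSpec, embed_state, make_embedding_basis, make_setpoints
from empj.metrics import circ_diff, decode_angle, fit_decoder
from empj.simulate import SimConfig, simulate_rnn
from empj.synthesis import (
    RNN,
    ConstraintSystem,
    SynthesisConfig,
    assemble,
    constraint_rows,
    fixed_point_rows,
    phi_prime_diag,
    solve_weights,
    synthesize_input_controlled_rnn,
    synthesize_ring_rnn,
    tonic_input_for_offset,
    verify_jacobian,
)

TAU = 0.1


class TestPhiPrime:
    def test_unit_slope_at_origin(self):
        assert np.allclose(phi_prime_diag(np.zeros(5)), 1.0)

    def test_saturation(self):
        assert np.all(phi_prime_diag(np.array([10.0, -10.0])) < 1e-8)

    def test_matches_finite_difference(self):
        x = np.linspace(-3, 3, 13)
        h = 1e-6
        numeric = (np.tanh(x + h) - np.tanh(x - h)) / (2 * h)
        assert np.allclose(phi_prime_diag(x), numeric, atol=1e-8)


class TestConstraintRows:
    def test_leak_eigenvalue_zeroes_target_row(self, planar_ring, drift6):
        sp = make_setpoints(8, planar_ring)[2]
        es = eigenspec_at_setpoint(sp, drift6, lambda_normal=-1.0 / TAU)
        _, b = constraint_rows(sp, es, TAU)
        assert np.allclose(b[1], 0.0)

    def test_neutral_eigenvalue_gives_identity_scaling(self, planar_ring):
        sp = make_setpoints(8, planar_ring)[0]
        es = eigenspec_at_setpoint(sp, DriftSpec(0.0, 0), lambda_normal=-1.0 / TAU)
        _, b = constraint_rows(sp, es, TAU)
        assert np.allclose(b[0], sp.frame.tangent)

    def test_a_block_is_frame_times_gain(self, planar_ring, drift6):
        sp = make_setpoints(8, planar_ring)[1]
        es = eigenspec_at_setpoint(sp, drift6, -10.0)
        a, _ = constraint_rows(sp, es, TAU)
        assert np.allclose(a, es.eigvecs.T * phi_prime_diag(sp.state)[None, :])


class TestFixedPointRows:
    def test_solution_of_fp_rows_is_equilibrium(self, planar_ring):
        thetas = [f * np.pi / 3 for f in range(6)]
        blocks = [fixed_point_rows(embed_state(t, planar_ring)) for t in thetas]
        W, _ = solve_weights(assemble(blocks), sigma_reg=0.0)
        rnn = RNN(weights=W, tau=TAU)
        for t in thetas:
            x = embed_state(t, planar_ring)
            assert np.linalg.norm(rnn.dxdt(x)) < 1e-6

    def test_origin_row_warns(self):
        with pytest.warns(UserWarning, match="origin"):
            fixed_point_rows(np.zeros(10))


class TestAssembleAndSolve:
    def test_row_counting(self, planar_ring, drift6):
        sps = make_setpoints(64, planar_ring)
        blocks = [
            constraint_rows(sp, eigenspec_at_setpoint(sp, drift6, -10.0), TAU)
            for sp in sps
        ]
        system = assemble(blocks)
        assert system.A.shape == (128, planar_ring.n_units)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assemble([])

    def test_mismatched_columns_rejected(self):
        with pytest.raises(ValueError):
            assemble([(np.ones((1, 4)), np.ones((1, 4))), (np.ones((1, 5)), np.ones((1, 5)))])

    def test_identity_system_returns_target(self):
        B = np.arange(12.0).reshape(3, 4)
        system = ConstraintSystem(A=np.eye(4)[:3], B=B, row_tags=["r"] * 3)
        W, report = solve_weights(system, sigma_reg=0.0)
        assert np.allclose(W[:3], B) and np.allclose(W[3], 0.0)
        assert report.residual_norm < 1e-12


class TestVerifyJacobian:
    def test_exact_linear_system(self):
        # a weight matrix built directly from a known eigendecomposition at x=0
        rng = np.random.default_rng(0)
        n, d = 30, 3
        u, _ = np.linalg.qr(rng.standard_normal((n, d)))
        lams = np.array([-2.0, -5.0, 0.5])
        W = u @ np.diag(TAU * lams + 1.0) @ u.T  # Phi(0) = I
        rnn = RNN(weights=W, tau=TAU)
        from empj.dynamics import EigenSpec
        from empj.manifolds import Frame, Setpoint

        sp = Setpoint(theta=0.0, latent=np.zeros(d), state=np.zeros(n),
                      frame=Frame(tangent=u[:, 0], normals=u[:, 1:]))
        es = EigenSpec(eigvecs=u, eigvals=lams, setpoint_theta=0.0)
        assert np.max(np.abs(verify_jacobian(rnn, sp, es))) < 1e-6

    def test_discriminates_random_weights(self, planar_ring, drift6):
        rng = np.random.default_rng(3)
        rnn = RNN(weights=rng.standard_normal((planar_ring.n_units,) * 2) * 0.1, tau=TAU)
        sp = make_setpoints(8, planar_ring)[0]
        es = eigenspec_at_setpoint(sp, drift6, -10.0)
        assert np.max(np.abs(verify_jacobian(rnn, sp, es))) > 1.0


class TestRingSynthesis:
    def test_jacobian_errors_within_five_percent(self, ring_network):
        _, report = ring_network
        # tangential eigenvalue amplitude is 0.6 1/s for this drift
        assert max(report.jacobian_errors.values()) < 0.05 * 0.6

    def test_trajectories_converge_to_stable_fixed_points(
        self, ring_network, planar_ring, planar_decoder, drift6
    ):
        from empj.dynamics import drift_fixed_points

        rnn, _ = ring_network
        stable = np.array(
            [f.theta for f in drift_fixed_points(drift6) if f.stability == "stable"]
        )
        starts = 2 * np.pi * np.arange(12) / 12 + 0.2
        traj = simulate_rnn(
            rnn, embed_state(starts, planar_ring),
            SimConfig(dt=0.01, duration=30.0, record_every=3000),
        )
        ends = decode_angle(planar_decoder, traj.final)
        dist = np.min(np.abs(circ_diff(ends[:, None], stable[None, :])), axis=1)
        assert dist.max() < 0.05

    def test_continuous_attractor_holds_angle(
        self, attractor_network, planar_ring, planar_decoder
    ):
        rnn, _ = attractor_network
        starts = 2 * np.pi * np.arange(10) / 10 + 0.05
        traj = simulate_rnn(
            rnn, embed_state(starts, planar_ring),
            SimConfig(dt=0.01, duration=5.0, record_every=500),
        )
        moved = np.abs(circ_diff(decode_angle(planar_decoder, traj.final), starts))
        assert moved.max() < 0.05

    def test_rank_equals_embedding_dimension(self, ring_network, attractor_network):
        assert ring_network[1].weight_rank == 2
        assert attractor_network[1].weight_rank == 2

    def test_baseline_above_zero_drift_stays_positive(self, planar_ring, planar_decoder):
        from empj.metrics import measure_drift

        dspec = DriftSpec(0.1, 6, baseline=0.1)
        rnn, _ = synthesize_ring_rnn(
            planar_ring, dspec, SynthesisConfig(tau=TAU, seed=1, verify=False)
        )
        grid = 2 * np.pi * np.arange(64) / 64
        measured = measure_drift(rnn, planar_decoder, planar_ring, grid)
        assert measured.min() > -0.02

    def test_half_setpoints_changes_weights_little(self, planar_ring, drift6):
        # tanh oddness makes the theta and theta+pi blocks redundant; solve
        # without the noise regularizer so redundant rows stay redundant
        full, _ = synthesize_ring_rnn(
            planar_ring, drift6,
            SynthesisConfig(tau=TAU, seed=1, sigma_reg=0.0, verify=False),
        )
        half, _ = synthesize_ring_rnn(
            planar_ring, drift6,
            SynthesisConfig(tau=TAU, seed=1, sigma_reg=0.0, half_setpoints=True, verify=False),
        )
        rel = np.linalg.norm(full.weights - half.weights) / np.linalg.norm(full.weights)
        assert rel < 0.01

    def test_offmanifold_perturbation_decays(self, attractor_network, planar_ring):
        rnn, _ = attractor_network
        basis = planar_ring.basis.basis_vectors
        rng = np.random.default_rng(0)
        v = rng.standard_normal(planar_ring.n_units)
        v -= basis @ (basis.T @ v)
        v /= np.linalg.norm(v)
        x0 = embed_state(0.7, planar_ring) + (planar_ring.radius / 2) * v
        traj = simulate_rnn(rnn, x0, SimConfig(dt=0.01, duration=5 * rnn.tau, record_every=50))
        off = traj.final @ v
        assert abs(off) < 0.05 * (planar_ring.radius / 2)


class TestInputControl:
    def test_closed_form_input(self):
        assert tonic_input_for_offset(6.0, -1.0 / TAU, TAU) == pytest.approx(6.0)
        assert tonic_input_for_offset(6.0, -1.0, TAU) == pytest.approx(0.6)

    def test_equilibrium_and_monotone_speed(self):
        ring = RingSpec(basis=make_embedding_basis(500, 2, 2), radius=8.0)
        levels = [0.0, 1.0, 2.0]
        rnn, _ = synthesize_input_controlled_rnn(
            ring, DriftSpec(0.1, 6), levels, level_spacing=6.0,
            config=SynthesisConfig(n_setpoints=40, tau=TAU, seed=2),
        )
        v = rnn.input_vector
        lam = rnn.metadata["lambda_input"]
        from empj.metrics import measure_drift

        amps = []
        for k, level in enumerate(levels):
            offset = 6.0 * k
            tonic = tonic_input_for_offset(offset, lam, TAU) * v
            decoder = fit_decoder(ring, offset=offset * v)
            x0 = embed_state(np.array([0.3, 2.0, 4.0]), ring) + offset * v
            traj = simulate_rnn(
                rnn, x0, SimConfig(dt=0.01, duration=5.0, record_every=500),
                tonic_input=tonic,
            )
            eq = (traj.final @ v).mean()
            assert eq == pytest.approx(offset, abs=0.05 * max(offset, 1.0))
            measured = measure_drift(
                rnn, decoder, ring, 2 * np.pi * np.arange(16) / 16,
                tonic_input=tonic, offset=offset * v,
            )
            amps.append(0.5 * (measured.max() - measured.min()))
        assert amps[0] < 0.05
        assert amps[0] < amps[1] < amps[2]

    def test_bad_spacing_rejected(self, planar_ring):
        with pytest.raises(ValueError):
            synthesize_input_controlled_rnn(planar_ring, DriftSpec(0.1, 6), [0.0, 1.0], 0.0)
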