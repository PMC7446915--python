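"""Decoding, drift measurement, end-state statistics and deviation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from empj.dynamics import DriftSpec, drift
from empj.manifolds import RingSpec, embed_state, make_embedding_basis, tangent_normal_frame
from empj.metrics import (
    Trajectory,
    UndefinedAngleError,
    circ_diff,
    circular_mean,
    circular_variance,
    decode_angle,
    deviation,
    endstate_stats,
    fit_decoder,
    measure_drift,
    wrap_angle,
)
from empj.simulate import SimConfig, simulate_ddm


class TestCircularHelpers:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.floats(-20, 20), b=st.floats(-20, 20))
    def test_circ_diff_range_and_consistency(self, a, b):
        d = float(circ_diff(a, b))
        assert -np.pi < d <= np.pi + 1e-12
        assert abs(float(circ_diff(b + d, a))) < 1e-9

    def test_circular_mean_of_tight_cluster(self):
        angles = 0.1 * np.array([-1, 0, 1]) + 6.2  # wraps through zero
        assert circ_diff(circular_mean(angles), 6.2) == pytest.approx(0.0, abs=1e-9)

    def test_variance_conventions_agree_for_small_spread(self):
        rng = np.random.default_rng(0)
        angles = rng.normal(1.0, 0.1, 5000)
        assert circular_variance(angles, method="log") == pytest.approx(
            circular_variance(angles, method="one_minus_r"), rel=0.02
        )

    def test_log_variance_recovers_wrapped_normal_sigma(self):
        rng = np.random.default_rng(1)
        angles = rng.normal(0.0, 0.7, 20000) % (2 * np.pi)
        assert circular_variance(angles, method="log") == pytest.approx(0.49, rel=0.05)


class TestDecoder:
    def test_planar_round_trip(self, planar_ring, planar_decoder):
        thetas = np.linspace(0, 2 * np.pi, 37)
        decoded = decode_angle(planar_decoder, embed_state(thetas, planar_ring))
        assert np.max(np.abs(circ_diff(decoded, thetas))) < 1e-6

    def test_highdim_round_trip(self, highdim_ring):
        decoder = fit_decoder(highdim_ring, n_train=360)
        thetas = np.linspace(0, 2 * np.pi, 101)
        decoded = decode_angle(decoder, embed_state(thetas, highdim_ring))
        assert np.max(np.abs(circ_diff(decoded, thetas))) < 1e-3

    def test_robust_to_radial_rescaling(self, planar_ring, planar_decoder):
        states = 1.1 * embed_state(np.linspace(0, 2 * np.pi, 19), planar_ring)
        decoded = decode_angle(planar_decoder, states)
        assert np.max(np.abs(circ_diff(decoded, np.linspace(0, 2 * np.pi, 19)))) < 0.05

    def test_antipodal_states_decode_pi_apart(self, planar_ring, planar_decoder):
        a = decode_angle(planar_decoder, embed_state(1.0, planar_ring))
        b = decode_angle(planar_decoder, embed_state(1.0 + np.pi, planar_ring))
        assert abs(abs(circ_diff(a, b)) - np.pi) < 1e-6

    def test_zero_state_rejected(self, planar_ring, planar_decoder):
        with pytest.raises(UndefinedAngleError):
            decode_angle(planar_decoder, np.zeros(planar_ring.n_units))

    def test_too_few_training_points_rejected(self, highdim_ring):
        with pytest.raises(ValueError):
            fit_decoder(highdim_ring, n_train=10)


class TestMeasureDrift:
    def test_self_consistency_against_ddm_integrator(self):
        # measuring drift on the deterministic circular integrator itself
        # recovers G(theta)
        spec = DriftSpec(0.1, 6)
        grid = 2 * np.pi * np.arange(32) / 32
        window = 0.05
        traj = simulate_ddm(spec, grid, 0.0, SimConfig(dt=0.001, duration=window))
        measured = circ_diff(traj.final, grid) / window
        assert np.max(np.abs(measured - drift(grid, spec))) < 1e-3

    def test_synthesized_network_drift_overlay(
        self, ring_network, planar_ring, planar_decoder, drift6
    ):
        rnn, _ = ring_network
        grid = 2 * np.pi * np.arange(64) / 64
        measured = measure_drift(rnn, planar_decoder, planar_ring, grid)
        assert np.max(np.abs(measured - drift(grid, drift6))) < 0.02

    def test_zero_at_stable_fixed_points(
        self, ring_network, planar_ring, planar_decoder, drift6
    ):
        from empj.dynamics import drift_fixed_points

        rnn, _ = ring_network
        stable = np.array(
            [f.theta for f in drift_fixed_points(drift6) if f.stability == "stable"]
        )
        measured = measure_drift(rnn, planar_decoder, planar_ring, stable)
        assert np.max(np.abs(measured)) < 5e-3


class TestEndStateStats:
    def test_perfect_memory_gives_zero_errors(self):
        init = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        ends = np.tile(init[:, None], (1, 5))
        stats = endstate_stats(ends, init)
        assert stats.bias == pytest.approx(0.0, abs=1e-7)
        assert stats.sqrt_var == pytest.approx(0.0, abs=1e-7)
        assert stats.rmse == pytest.approx(0.0, abs=1e-7)

    def test_known_dispersion_recovered(self):
        rng = np.random.default_rng(2)
        init = np.linspace(0, 2 * np.pi, 18, endpoint=False)
        ends = rng.normal(init[:, None], 0.5, (18, 30)) % (2 * np.pi)
        stats = endstate_stats(ends, init)
        assert stats.sqrt_var == pytest.approx(0.5, rel=0.1)
        assert stats.bias < 0.2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ends=arrays(np.float64, (6, 4), elements=st.floats(0, 2 * np.pi - 1e-9)),
    )
    def test_quarter_circle_identity(self, ends):
        init = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        stats = endstate_stats(ends, init)
        assert stats.rmse**2 == pytest.approx(stats.bias**2 + stats.sqrt_var**2, abs=1e-10)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            endstate_stats(np.zeros((3, 1)), np.zeros(3))


class TestDeviation:
    def test_on_ring_states_have_zero_deviation(self, planar_ring, planar_decoder):
        thetas = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        states = embed_state(thetas, planar_ring)[None, :, :]
        traj = Trajectory(times=np.array([0.0]), states=states)
        result = deviation(traj, planar_ring, planar_decoder)
        assert result.mean_deviation < 1e-6

    def test_orthogonal_offset_measured_exactly(self, planar_ring, planar_decoder):
        delta = 1.3
        frame = tangent_normal_frame(0.8, planar_ring)
        basis = planar_ring.basis.basis_vectors
        rng = np.random.default_rng(0)
        v = rng.standard_normal(planar_ring.n_units)
        v -= basis @ (basis.T @ v)
        v /= np.linalg.norm(v)
        state = embed_state(0.8, planar_ring) + delta * v
        traj = Trajectory(times=np.array([0.0]), states=state[None, None, :])
        result = deviation(traj, planar_ring, planar_decoder)
        assert result.mean_deviation == pytest.approx(delta, rel=0.05)
        assert result.normalized == pytest.approx(delta / planar_ring.radius, rel=0.05)

    def test_invariant_to_normal_frame_choice(self, highdim_ring):
        # the metric uses only decode -> embed, never the normals
        decoder = fit_decoder(highdim_ring)
        rng = np.random.default_rng(4)
        states = embed_state(rng.uniform(0, 2 * np.pi, 9), highdim_ring)
        states += 0.3 * rng.standard_normal(states.shape)
        traj = Trajectory(times=np.array([0.0]), states=states[None])
        r1 = deviation(traj, highdim_ring, decoder).mean_deviation
        r2 = deviation(traj, highdim_ring, decoder).mean_deviation
        assert r1 == r2 > 0
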