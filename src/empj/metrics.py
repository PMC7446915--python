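"""Decoding and error metrics for ring networks.

A linear decoder maps tanh(x) to (cos, sin) of the represented angle;
angles are recovered with atan2.  End-state statistics follow the
bias/variance decomposition on the circle: for each initial condition
the desired end state is the initial angle itself (a veridical memory),
``bias_i`` is the wrapped difference between the circular mean of the
end angles and that target, and ``var_i`` is the circular variance
estimated from the mean resultant length.  BIAS is the RMS of the
bias_i, VAR the mean of the var_i, and RMSE their quadrature sum, so
RMSE^2 = BIAS^2 + VAR holds exactly.

The "deviation" stability metric compares each visited network state
with the on-manifold state implied by its decoded angle, averaged over
time and initial conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .manifolds import RingSpec, embed_state
from .simulate import SimConfig, Trajectory, simulate_rnn
from .synthesis import RNN

__all__ = [
    "Decoder",
    "EndStateStats",
    "DeviationResult",
    "wrap_angle",
    "circ_diff",
    "circular_mean",
    "circular_variance",
    "fit_decoder",
    "decode_angle",
    "measure_drift",
    "endstate_stats",
    "deviation",
]


def wrap_angle(theta):
    """Wrap to [0, 2*pi)."""
    return np.asarray(theta, dtype=float) % (2.0 * np.pi)


def circ_diff(a, b):
    """Signed circular difference a - b wrapped to (-pi, pi]."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return -((-d + np.pi) % (2.0 * np.pi) - np.pi)


def circular_mean(angles, axis=None):
    """Mean direction of a sample of angles, in [0, 2*pi)."""
    angles = np.asarray(angles, dtype=float)
    return wrap_angle(
        np.arctan2(np.sin(angles).mean(axis=axis), np.cos(angles).mean(axis=axis))
    )


def circular_variance(angles, axis=None, method: str = "log"):
    """Circular variance (rad^2) from the mean resultant length R.

    ``method="log"`` returns -2 ln R, which is exactly sigma^2 for a
    wrapped normal sample and is the default; ``method="one_minus_r"``
    returns 2 (1 - R), the small-angle expansion of the same quantity.
    """
    angles = np.asarray(angles, dtype=float)
    r = np.hypot(np.sin(angles).mean(axis=axis), np.cos(angles).mean(axis=axis))
    r = np.clip(r, 1e-12, 1.0)
    if method == "log":
        return -2.0 * np.log(r)
    if method == "one_minus_r":
        return 2.0 * (1.0 - r)
    raise ValueError(f"unknown circular variance method {method!r}")


@dataclass(frozen=True)
class Decoder:
    """Linear readout of the represented angle from tanh(x)."""

    weights: np.ndarray  # 2 x N, rows decode (cos, sin)
    training_thetas: np.ndarray


class UndefinedAngleError(ValueError):
    """Raised when the decoded (cos, sin) vector has near-zero norm."""


def fit_decoder(
    ring: RingSpec, n_train: int = 360, offset: np.ndarray | None = None
) -> Decoder:
    """Least-squares fit of (cos, sin) from tanh of on-ring states.

    ``offset`` optionally shifts the training states by a constant
    vector (used for rings displaced along an input direction).
    """
    if n_train < 8 * ring.n_dim:
        raise ValueError(f"n_train = {n_train} too small for n_dim = {ring.n_dim}")
    thetas = 2.0 * np.pi * np.arange(n_train) / n_train
    states = embed_state(thetas, ring)
    if offset is not None:
        states = states + offset[np.newaxis, :]
    X = np.tanh(states)
    Y = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    sol, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    decoder = Decoder(weights=sol.T, training_thetas=thetas)
    round_trip = np.max(np.abs(circ_diff(decode_angle(decoder, states), thetas)))
    if round_trip > 1e-3:
        warnings.warn(
            f"poorly fit decoder: worst training round-trip error {round_trip:.2g} rad"
        )
    return decoder


def decode_angle(decoder: Decoder, state: np.ndarray) -> np.ndarray:
    """Decoded angle(s) in [0, 2*pi); batched over leading axes."""
    state = np.asarray(state, dtype=float)
    cs = np.tanh(state) @ decoder.weights.T
    norm = np.linalg.norm(cs, axis=-1)
    if np.any(norm < 1e-6):
        raise UndefinedAngleError("decoded direction vector has near-zero norm")
    out = wrap_angle(np.arctan2(cs[..., 1], cs[..., 0]))
    return out if out.ndim else float(out)


def measure_drift(
    rnn: RNN,
    decoder: Decoder,
    ring: RingSpec,
    theta_grid: np.ndarray,
    window: float = 0.5,
    dt: float | None = None,
    tonic_input: np.ndarray | None = None,
    offset: np.ndarray | None = None,
) -> np.ndarray:
    """Realized drift (rad/s) at each grid angle, from short noiseless runs.

    Initializes on the ring at each grid angle (optionally shifted by
    ``offset``), integrates for ``window`` seconds, and reports the
    wrapped decoded-angle change per unit time.  Decoding both
    endpoints cancels any static decoder bias to first order.
    """
    dt = dt if dt is not None else min(0.01, rnn.tau / 5.0)
    if window < dt:
        raise ValueError("window must be at least one timestep")
    theta_grid = np.asarray(theta_grid, dtype=float)
    x0 = embed_state(theta_grid, ring)
    if offset is not None:
        x0 = x0 + offset[np.newaxis, :]
    traj = simulate_rnn(
        rnn,
        x0,
        SimConfig(dt=dt, duration=window, record_every=max(1, int(round(window / dt)))),
        tonic_input=tonic_input,
    )
    start = decode_angle(decoder, traj.states[0])
    end = decode_angle(decoder, traj.states[-1])
    return circ_diff(end, start) / window


@dataclass(frozen=True)
class EndStateStats:
    """Bias/variance decomposition of end-state errors on the circle."""

    bias_per_init: np.ndarray
    var_per_init: np.ndarray
    bias: float
    sqrt_var: float
    rmse: float


def endstate_stats(
    end_angles_by_init: np.ndarray,
    init_angles: np.ndarray,
    target_angles: np.ndarray | None = None,
    var_method: str = "log",
) -> EndStateStats:
    """Summarize end-state distributions per initial condition.

    ``end_angles_by_init`` has shape (n_init, n_trials).  The desired
    end state defaults to the initial angle (``target_angles`` may
    override it).  RMSE^2 = BIAS^2 + VAR by construction.
    """
    end = np.asarray(end_angles_by_init, dtype=float)
    if end.ndim != 2 or end.shape[1] < 2:
        raise ValueError("need a (n_init, n_trials >= 2) array of end angles")
    init = np.asarray(init_angles, dtype=float)
    if init.shape[0] != end.shape[0]:
        raise ValueError("one initial angle per row of end angles required")
    target = init if target_angles is None else np.asarray(target_angles, dtype=float)

    mean_end = circular_mean(end, axis=1)
    bias_i = circ_diff(mean_end, target)
    var_i = circular_variance(end, axis=1, method=var_method)
    bias = float(np.sqrt(np.mean(bias_i**2)))
    var = float(np.mean(var_i))
    return EndStateStats(
        bias_per_init=bias_i,
        var_per_init=var_i,
        bias=bias,
        sqrt_var=float(np.sqrt(var)),
        rmse=float(np.sqrt(bias**2 + var)),
    )


@dataclass(frozen=True)
class DeviationResult:
    """Distance between visited states and their decoded on-ring images."""

    per_timepoint: np.ndarray  # (T, B) state-space distances
    mean_deviation: float
    normalized: float  # mean deviation / ring radius


def deviation(
    trajectory: Trajectory,
    ring: RingSpec,
    decoder: Decoder,
    sample_every: int = 1,
) -> DeviationResult:
    """Mean Euclidean distance to the decoded-angle state on the ring.

    At each sampled timepoint the decoded angle is mapped back through
    the latent tuning functions to the expected on-ring state x_hat,
    and the Euclidean distance |x - x_hat| is averaged over timepoints
    and trajectories.
    """
    states = trajectory.states
    if states.ndim == 2:
        states = states[:, np.newaxis, :]
    states = states[::sample_every]
    theta_hat = decode_angle(decoder, states)
    x_hat = embed_state(theta_hat, ring)
    dist = np.linalg.norm(states - x_hat, axis=-1)
    return DeviationResult(
        per_timepoint=dist,
        mean_deviation=float(dist.mean()),
        normalized=float(dist.mean() / ring.radius),
    )
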