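"""Forward integration of the network and of the reference drift-diffusion model.

The network is integrated by forward Euler,

    x <- x + (dt/tau) * (-x + W^T tanh(x) + I + noise)

with the noise term sampled per step like an input: "external" noise is
a random combination of the ring's projection vectors (confined to the
embedding subspace), "internal" noise is i.i.d. per unit.  The
reference model on the circle, d(theta) = G(theta) dt + sigma dW, is
integrated by Euler-Maruyama with the sqrt(dt) diffusion scaling.

With external noise of per-direction standard deviation
sigma_RNN = sigma_DDM * r * tau / sqrt(dt), the decoded angle of a
drift-free ring diffuses with variance sigma_DDM^2 * t, matching the
reference model: each Euler step adds (dt/tau) * sigma_RNN =
sigma_DDM * r * sqrt(dt) of in-plane displacement, i.e.
sigma_DDM * sqrt(dt) radians of angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import DriftSpec, drift
from .synthesis import RNN

__all__ = [
    "SimConfig",
    "Trajectory",
    "simulate_rnn",
    "simulate_ddm",
    "external_noise_sigma",
]


class DivergenceError(RuntimeError):
    """Raised when the integrated state becomes non-finite."""


@dataclass(frozen=True)
class SimConfig:
    """Integration parameters.

    ``noise_mode`` is one of "none", "internal", "external"; ``sigma``
    is the noise standard deviation in the units of that mode
    (per-unit for internal, per-projection-direction for external).
    ``record_every`` thins the stored trajectory (the final state is
    always recorded).
    """

    dt: float = 0.01
    duration: float = 1.0
    seed: int = 0
    noise_mode: str = "none"
    sigma: float = 0.0
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one timestep")
        if self.noise_mode not in ("none", "internal", "external"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class Trajectory:
    """Recorded states at uniformly spaced times.

    ``states`` has shape (T, N) for a single initial condition or
    (T, B, N) for a batch; for the circular reference model the last
    axis is absent ((T,) or (T, B) angles in [0, 2*pi)).
    """

    times: np.ndarray
    states: np.ndarray
    inputs: np.ndarray | None = None

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def external_noise_sigma(sigma_ddm: float, radius: float, tau: float, dt: float) -> float:
    """Network noise level equivalent to a given circular diffusion level.

    sigma_RNN = sigma_DDM * r * tau / sqrt(dt): the radius converts
    radians to state-space distance, and tau/sqrt(dt) undoes the Euler
    step's dt/tau attenuation while keeping the variance growing
    linearly in time.
    """
    if min(sigma_ddm, radius, tau, dt) <= 0:
        raise ValueError("all arguments must be positive")
    return sigma_ddm * radius * tau / np.sqrt(dt)


def simulate_rnn(
    rnn: RNN,
    x0: np.ndarray,
    config: SimConfig,
    tonic_input: np.ndarray | None = None,
    noise_basis: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the rate equation from ``x0`` (shape (N,) or (B, N)).

    ``tonic_input`` is a constant N-vector added inside the rate
    equation.  External noise requires ``noise_basis`` (N x K, the
    ring's projection vectors); a fresh Gaussian sample per column and
    per step is mixed through the basis, so the noise lies exactly in
    the embedding subspace.
    """
    if config.dt > rnn.tau / 5.0 + 1e-12:
        raise ValueError(
            f"dt = {config.dt:g} too coarse for tau = {rnn.tau:g}; need dt <= tau/5"
        )
    if config.noise_mode == "external" and noise_basis is None:
        raise ValueError("external noise requires noise_basis (projection vectors)")

    x0 = np.asarray(x0, dtype=float)
    single = x0.ndim == 1
    x = x0[np.newaxis, :].copy() if single else x0.copy()
    n_batch, n_units = x.shape
    if n_units != rnn.n_units:
        raise ValueError("x0 length does not match the network size")

    n_steps = int(round(config.duration / config.dt))
    rec_idx = list(range(0, n_steps + 1, config.record_every))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    rec_set = set(rec_idx)

    rng = np.random.default_rng(config.seed)
    inp = 0.0 if tonic_input is None else np.asarray(tonic_input, dtype=float)
    W = rnn.weights
    dt_over_tau = config.dt / rnn.tau

    recorded = [x.copy()]
    for step in range(1, n_steps + 1):
        drive = -x + np.tanh(x) @ W + inp
        if config.noise_mode == "external":
            eta = rng.standard_normal((n_batch, noise_basis.shape[1])) * config.sigma
            drive += eta @ noise_basis.T
        elif config.noise_mode == "internal":
            drive += rng.standard_normal((n_batch, n_units)) * config.sigma
        x = x + dt_over_tau * drive
        if step % 200 == 0 and not np.all(np.isfinite(x)):
            raise DivergenceError(f"state diverged at step {step}")
        if step in rec_set:
            recorded.append(x.copy())
    if not np.all(np.isfinite(x)):
        raise DivergenceError(f"state diverged by step {n_steps}")

    states = np.stack(recorded, axis=0)
    times = np.asarray(rec_idx, dtype=float) * config.dt
    if single:
        states = states[:, 0, :]
    return Trajectory(times=times, states=states)


def simulate_ddm(
    drift_spec: DriftSpec,
    theta0: np.ndarray | float,
    sigma_ddm: float,
    config: SimConfig,
) -> Trajectory:
    """Euler-Maruyama integration of the circular drift-diffusion model.

    theta <- theta + G(theta) dt + sigma * sqrt(dt) * N(0, 1),
    wrapped to [0, 2*pi).  ``theta0`` may be a scalar or a batch.
    """
    if sigma_ddm < 0:
        raise ValueError("sigma_ddm must be non-negative")
    theta0 = np.asarray(theta0, dtype=float)
    single = theta0.ndim == 0
    theta = np.atleast_1d(theta0).astype(float).copy()

    n_steps = int(round(config.duration / config.dt))
    rec_idx = list(range(0, n_steps + 1, config.record_every))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    rec_set = set(rec_idx)

    rng = np.random.default_rng(config.seed)
    sqrt_dt = np.sqrt(config.dt)
    recorded = [theta.copy()]
    for step in range(1, n_steps + 1):
        theta = theta + drift(theta, drift_spec) * config.dt
        if sigma_ddm > 0:
            theta = theta + sigma_ddm * sqrt_dt * rng.standard_normal(theta.shape)
        theta %= 2.0 * np.pi
        if step in rec_set:
            recorded.append(theta.copy())

    states = np.stack(recorded, axis=0)
    times = np.asarray(rec_idx, dtype=float) * config.dt
    if single:
        states = states[:, 0]
    return Trajectory(times=times, states=states)
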