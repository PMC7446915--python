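"""Target dynamics over the ring: drift functions and Jacobian eigenstructure.

The latent dynamics to be embodied by the network are specified by a
sinusoidal drift function over the ring angle,

    G(theta) = b - a * cos(omega * theta)   [rad/s]

whose zero crossings are the fixed points of the dynamics (stable where
G' < 0).  The frequency ``omega`` equals the number of *stable* fixed
points; ``omega = 0`` with zero amplitude gives a continuous attractor.
At each setpoint, the target Jacobian is expressed through its
eigendecomposition: the eigenvalue along the ring tangent is set to the
drift derivative G'(theta), and eigenvalues along the remaining frame
directions (and an optional input direction) are set to negative
constants so that off-ring activity decays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .manifolds import Setpoint

__all__ = [
    "DriftSpec",
    "EigenSpec",
    "FixedPoint",
    "drift",
    "drift_derivative",
    "drift_fixed_points",
    "eigenspec_at_setpoint",
]


@dataclass(frozen=True)
class DriftSpec:
    """Sinusoidal drift function G(theta) = baseline - amplitude*cos(frequency*theta).

    ``amplitude`` and ``baseline`` are in rad/s; ``frequency`` is an
    integer number of cycles per revolution and equals the number of
    stable fixed points when baseline is zero.
    """

    amplitude: float
    frequency: int
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.frequency < 0 or int(self.frequency) != self.frequency:
            raise ValueError("frequency must be a non-negative integer")

    def to_dict(self) -> dict:
        return {
            "amplitude": float(self.amplitude),
            "n_fp": int(self.frequency),
            "baseline": float(self.baseline),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriftSpec":
        return cls(
            amplitude=d["amplitude"],
            frequency=d.get("n_fp", d.get("frequency", 0)),
            baseline=d.get("baseline", 0.0),
        )


@dataclass(frozen=True)
class FixedPoint:
    """A zero crossing of the drift function."""

    theta: float
    stability: str  # "stable" | "unstable" | "marginal"


@dataclass(frozen=True)
class EigenSpec:
    """Per-setpoint target eigenvectors and eigenvalues of the Jacobian.

    ``eigvecs`` is N x d with orthonormal columns ordered
    [tangent | normals... | input direction (optional)]; ``eigvals``
    holds the matching eigenvalues in 1/s.
    """

    eigvecs: np.ndarray
    eigvals: np.ndarray
    setpoint_theta: float


def drift(theta, spec: DriftSpec):
    """G(theta) in rad/s; vectorized over theta."""
    theta = np.asarray(theta, dtype=float)
    out = spec.baseline - spec.amplitude * np.cos(spec.frequency * theta)
    return out if out.ndim else float(out)


def drift_derivative(theta, spec: DriftSpec):
    """G'(theta) in 1/s; vectorized over theta."""
    theta = np.asarray(theta, dtype=float)
    out = spec.amplitude * spec.frequency * np.sin(spec.frequency * theta)
    return out if out.ndim else float(out)


def drift_fixed_points(spec: DriftSpec, tol: float = 1e-10) -> list[FixedPoint]:
    """All zero crossings of G on [0, 2*pi), classified by the sign of G'.

    Returns an empty list when G never vanishes (|baseline| > amplitude:
    pure rotation) and for the everywhere-zero continuous attractor
    (amplitude = baseline = 0), which has no isolated fixed points.
    Tangent zeros (G = G' = 0) are flagged ``"marginal"``.
    """
    a, b, w = spec.amplitude, spec.baseline, spec.frequency
    if a == 0 or w == 0:
        # constant drift: either pure rotation or (b == a*cos(0)) degenerate;
        # neither has isolated fixed points
        return []
    if abs(b) > a:
        return []
    phi = float(np.arccos(np.clip(b / a, -1.0, 1.0)))
    # roots of cos(w*theta) = b/a within one period of w*theta; the two
    # branches +-phi coincide when phi is 0 or pi
    branch = {round(phi, 12), round((2.0 * np.pi - phi) % (2.0 * np.pi), 12)}
    thetas = sorted(
        (root + 2.0 * np.pi * k) / w for k in range(w) for root in branch
    )
    fixed_points: list[FixedPoint] = []
    for th in thetas:
        slope = drift_derivative(th, spec)
        if abs(slope) < tol:
            stability = "marginal"
        elif slope < 0:
            stability = "stable"
        else:
            stability = "unstable"
        fixed_points.append(FixedPoint(theta=float(th % (2.0 * np.pi)), stability=stability))
    return fixed_points


def eigenspec_at_setpoint(
    setpoint: Setpoint,
    drift_spec: DriftSpec,
    lambda_normal: float,
    input_dir: np.ndarray | None = None,
    lambda_input: float | None = None,
    drift_scale: float = 1.0,
) -> EigenSpec:
    """Target eigenstructure of the Jacobian at one setpoint.

    The tangential eigenvalue is ``drift_scale * G'(theta)``; every
    normal direction within the embedding subspace gets
    ``lambda_normal`` (< 0), and the optional input direction gets
    ``lambda_input`` (< 0).  The input direction must be orthogonal to
    the local frame.
    """
    if lambda_normal >= 0:
        raise ValueError("lambda_normal must be strictly negative")
    frame = setpoint.frame
    cols = [frame.tangent[:, np.newaxis], frame.normals]
    vals = [drift_scale * drift_derivative(setpoint.theta, drift_spec)]
    vals.extend([lambda_normal] * frame.normals.shape[1])
    if input_dir is not None:
        if lambda_input is None or lambda_input >= 0:
            raise ValueError("lambda_input must be provided and strictly negative")
        u = np.asarray(input_dir, dtype=float)
        frame_mat = np.concatenate([frame.tangent[:, np.newaxis], frame.normals], axis=1)
        overlap = np.max(np.abs(frame_mat.T @ u))
        if overlap > 1e-6:
            raise ValueError(
                f"input direction is not orthogonal to the local frame (overlap {overlap:g})"
            )
        cols.append(u[:, np.newaxis])
        vals.append(lambda_input)
    return EigenSpec(
        eigvecs=np.concatenate(cols, axis=1),
        eigvals=np.asarray(vals, dtype=float),
        setpoint_theta=setpoint.theta,
    )
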