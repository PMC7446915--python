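"""Ring manifolds embedded in neural state space.

A ring manifold is a closed parametric curve x(theta) living in an
``n_dim``-dimensional linear subspace of the N-dimensional neural state
space.  The latent coordinates of the curve are built from a sine/cosine
pair (the planar part) plus ``n_dim - 2`` evenly spaced von Mises bumps
(the out-of-plane excursions).  The sine/cosine amplitude is rescaled
pointwise so that the curve lies exactly on a hypersphere of radius
``r``; a planar ring (``n_dim = 2``) is then simply a circle of radius
``r``.

The subspace itself is spanned by an arbitrary but reproducible
orthonormal basis (``EmbeddingBasis``).  All geometry (tangents, normal
frames, arc length) is computed analytically in latent coordinates and
mapped through the basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EmbeddingBasis",
    "RingSpec",
    "Setpoint",
    "Frame",
    "make_embedding_basis",
    "latent_tuning",
    "latent_tuning_derivative",
    "embed_state",
    "tangent_normal_frame",
    "make_setpoints",
    "ring_length",
]


class GeometryError(ValueError):
    """Raised when a ring specification is geometrically inconsistent."""


@dataclass(frozen=True)
class EmbeddingBasis:
    """Orthonormal basis of the manifold's embedding subspace.

    Attributes
    ----------
    basis_vectors : (N, n_dim) ndarray
        Mutually orthonormal unit columns spanning the subspace.
    seed : int
        Seed used to draw the basis; the basis is deterministic given
        ``(N, n_dim, seed)``.
    """

    basis_vectors: np.ndarray
    seed: int

    @property
    def n_units(self) -> int:
        return self.basis_vectors.shape[0]

    @property
    def n_dim(self) -> int:
        return self.basis_vectors.shape[1]


def make_embedding_basis(n_units: int, n_dim: int, seed: int) -> EmbeddingBasis:
    """Draw a reproducible random orthonormal basis.

    An i.i.d. standard-normal matrix is orthonormalized by QR; the sign
    of each column is fixed from the R diagonal so that the result is
    deterministic across LAPACK implementations.  The raw columns are
    drawn one at a time, so bases with the same ``(n_units, seed)`` are
    nested: the basis for ``n_dim`` is the first ``n_dim`` columns of
    the basis for any larger dimension.  This lets an input direction
    be appended to an existing ring basis without redrawing it.
    """
    if n_dim > n_units:
        raise ValueError(
            f"embedding dimension {n_dim} exceeds number of units {n_units}"
        )
    if n_dim < 1:
        raise ValueError("n_dim must be positive")
    rng = np.random.default_rng(seed)
    mat = rng.standard_normal((n_dim, n_units)).T
    q, r = np.linalg.qr(mat)
    q = q * np.sign(np.diag(r))[np.newaxis, :]
    return EmbeddingBasis(basis_vectors=q, seed=seed)


@dataclass(frozen=True)
class RingSpec:
    """Full geometric description of a ring manifold.

    Attributes
    ----------
    basis : EmbeddingBasis
        Subspace the ring lives in; ``basis.n_dim`` is the embedding
        dimension of the ring.
    radius : float
        Hypersphere radius r, in state-space units.
    kappa : float
        von Mises width parameter (dimensionless, >= 0).  Larger kappa
        means narrower bumps; kappa = 0 flattens every bump to a
        constant and the ring degenerates to a planar circle.
    vm_amplitude : float
        Peak amplitude of each von Mises bump (default 0.5).
    vm_center_offset : float
        Angular offset of the first von Mises center (radians).
    """

    basis: EmbeddingBasis
    radius: float
    kappa: float = 0.0
    vm_amplitude: float = 0.5
    vm_center_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("radius must be positive")
        if self.kappa < 0:
            raise GeometryError("kappa must be non-negative")
        if self.n_dim < 2:
            raise GeometryError("a ring needs an embedding dimension >= 2")
        # hypersphere scaling must stay real everywhere on the ring
        if self.n_vm > 0:
            theta = np.linspace(0.0, 2.0 * np.pi, 721)
            c = _von_mises_values(theta, self)
            max_sq = float(np.max(np.sum(c**2, axis=-1)))
            if self.radius**2 <= max_sq:
                raise GeometryError(
                    "radius too small for the requested von Mises excursions: "
                    f"r^2 = {self.radius ** 2:.4g} <= max sum c_j^2 = {max_sq:.4g}"
                )

    @property
    def n_dim(self) -> int:
        return self.basis.n_dim

    @property
    def n_units(self) -> int:
        return self.basis.n_units

    @property
    def n_vm(self) -> int:
        """Number of von Mises latent tuning functions (n_dim - 2)."""
        return self.n_dim - 2

    @property
    def vm_centers(self) -> np.ndarray:
        """Centers of the von Mises bumps, evenly spaced on the circle."""
        if self.n_vm == 0:
            return np.empty(0)
        j = np.arange(self.n_vm)
        return self.vm_center_offset + 2.0 * np.pi * j / self.n_vm

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "n_dim": self.n_dim,
            "radius": float(self.radius),
            "kappa": float(self.kappa),
            "vm_amplitude": float(self.vm_amplitude),
            "vm_center_offset": float(self.vm_center_offset),
            "basis_seed": int(self.basis.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RingSpec":
        basis = make_embedding_basis(d["n_units"], d["n_dim"], d["basis_seed"])
        return cls(
            basis=basis,
            radius=d["radius"],
            kappa=d.get("kappa", 0.0),
            vm_amplitude=d.get("vm_amplitude", 0.5),
            vm_center_offset=d.get("vm_center_offset", 0.0),
        )


@dataclass(frozen=True)
class Frame:
    """Local orthonormal frame of the ring at one angle.

    ``tangent`` is the unit vector in the direction of increasing theta
    (counterclockwise); ``normals`` are the remaining ``n_dim - 1``
    orthonormal directions completing the frame within the embedding
    subspace.
    """

    tangent: np.ndarray
    normals: np.ndarray  # (N, n_dim - 1)


@dataclass(frozen=True)
class Setpoint:
    """A state on the target manifold at which constraints are imposed."""

    theta: float
    latent: np.ndarray
    state: np.ndarray
    frame: Frame


def _von_mises_values(theta: np.ndarray, ring: RingSpec) -> np.ndarray:
    """von Mises latent tuning values, shape (..., n_vm)."""
    theta = np.asarray(theta, dtype=float)
    if ring.n_vm == 0:
        return np.zeros(theta.shape + (0,))
    mu = ring.vm_centers
    return ring.vm_amplitude * np.exp(
        ring.kappa * (np.cos(theta[..., np.newaxis] - mu) - 1.0)
    )


def _von_mises_derivative(theta: np.ndarray, ring: RingSpec) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if ring.n_vm == 0:
        return np.zeros(theta.shape + (0,))
    mu = ring.vm_centers
    c = _von_mises_values(theta, ring)
    return -ring.kappa * np.sin(theta[..., np.newaxis] - mu) * c


def latent_tuning(theta, ring: RingSpec) -> np.ndarray:
    """Latent coordinates of the ring at angle(s) ``theta``.

    The first two components are ``s(theta) cos(theta)`` and
    ``s(theta) sin(theta)`` with the hypersphere scaling
    ``s = sqrt(r^2 - sum_j c_j^2)``; the remaining components are the
    von Mises values ``c_j``.  The output always has Euclidean norm r.
    """
    theta = np.asarray(theta, dtype=float)
    c = _von_mises_values(theta, ring)
    s_sq = ring.radius**2 - np.sum(c**2, axis=-1)
    if np.any(s_sq <= 0):
        raise GeometryError("radius too small for von Mises excursions")
    s = np.sqrt(s_sq)
    out = np.empty(theta.shape + (ring.n_dim,))
    out[..., 0] = s * np.cos(theta)
    out[..., 1] = s * np.sin(theta)
    out[..., 2:] = c
    return out


def latent_tuning_derivative(theta, ring: RingSpec) -> np.ndarray:
    """Analytic d/d(theta) of :func:`latent_tuning`."""
    theta = np.asarray(theta, dtype=float)
    c = _von_mises_values(theta, ring)
    dc = _von_mises_derivative(theta, ring)
    s = np.sqrt(ring.radius**2 - np.sum(c**2, axis=-1))
    ds = -np.sum(c * dc, axis=-1) / s
    out = np.empty(theta.shape + (ring.n_dim,))
    out[..., 0] = ds * np.cos(theta) - s * np.sin(theta)
    out[..., 1] = ds * np.sin(theta) + s * np.cos(theta)
    out[..., 2:] = dc
    return out


def embed_state(theta, ring: RingSpec) -> np.ndarray:
    """Map angle(s) to N-dimensional neural states on the ring."""
    return latent_tuning(theta, ring) @ ring.basis.basis_vectors.T


def tangent_normal_frame(theta: float, ring: RingSpec) -> Frame:
    """Local frame at ``theta``: unit tangent plus orthonormal normals.

    The normals are the deterministic Gram-Schmidt completion of the
    tangent within the embedding subspace, built from the basis columns
    in fixed order.
    """
    dx_latent = latent_tuning_derivative(theta, ring)
    norm = np.linalg.norm(dx_latent)
    if norm < 1e-12:
        raise GeometryError(f"degenerate curve: |dx/dtheta| = {norm:g} at theta={theta}")
    basis = ring.basis.basis_vectors
    tangent = basis @ (dx_latent / norm)
    frame_vecs = [tangent]
    for col in basis.T:
        v = col.copy()
        for u in frame_vecs:
            v -= (u @ v) * u
        nv = np.linalg.norm(v)
        if nv > 1e-10:
            frame_vecs.append(v / nv)
        if len(frame_vecs) == ring.n_dim:
            break
    normals = np.stack(frame_vecs[1:], axis=1)
    return Frame(tangent=tangent, normals=normals)


def make_setpoints(m: int, ring: RingSpec) -> list[Setpoint]:
    """``m`` evenly spaced setpoints theta_i = 2*pi*i/m with frames."""
    if m < 3:
        raise ValueError(f"need at least 3 setpoints to sample a ring, got {m}")
    thetas = 2.0 * np.pi * np.arange(m) / m
    setpoints = []
    for th in thetas:
        latent = latent_tuning(th, ring)
        setpoints.append(
            Setpoint(
                theta=float(th),
                latent=latent,
                state=ring.basis.basis_vectors @ latent,
                frame=tangent_normal_frame(th, ring),
            )
        )
    return setpoints


def ring_length(ring: RingSpec, n_quad: int = 1000) -> float:
    """Total arc length of the ring by trapezoidal quadrature.

    Because the basis is orthonormal, the speed ``|dx/dtheta|`` equals
    the latent-coordinate speed, so the quadrature runs entirely in
    latent space.
    """
    if n_quad < 100:
        raise ValueError("n_quad must be at least 100 for a meaningful quadrature")
    theta = np.linspace(0.0, 2.0 * np.pi, n_quad + 1)
    speed = np.linalg.norm(latent_tuning_derivative(theta, ring), axis=-1)
    return float(np.trapezoid(speed, theta))
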