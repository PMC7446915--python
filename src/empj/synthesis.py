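"""Assemble and solve the linear system that wires the network.

The network obeys

    dx/dt = (1/tau) * (-x + W^T tanh(x) + I)

so its Jacobian at a state x is J = (1/tau) * (-I_N + W^T Phi) with
Phi = diag(1 - tanh(x)^2).  Requiring J to share the eigenpairs
(u_k, lambda_k) of a target Jacobian at a setpoint x_j yields, for the
d constrained modes collected in U (N x d, orthonormal columns) and
Sigma (diagonal),

    U^T Phi(x_j) W = tau * (Sigma + I_d / tau) * U^T

which is linear in W.  Stacking these d-row blocks over many setpoints
(plus, optionally, fixed-point rows tanh(x_f)^T W = x_f^T that pin
dx/dt = 0 at chosen states) gives A W = B, solved in the least-squares
sense after adding a small Gaussian regularization perturbation to A.
The minimum-norm solution confines the row and column spaces of W to
the span of the constraints, so unconstrained off-manifold directions
decay with the leak rate 1/tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    DriftSpec,
    EigenSpec,
    drift_fixed_points,
    eigenspec_at_setpoint,
)
from .manifolds import RingSpec, Setpoint, embed_state, make_setpoints

__all__ = [
    "RNN",
    "ConstraintSystem",
    "SynthesisReport",
    "SynthesisConfig",
    "phi_prime_diag",
    "constraint_rows",
    "fixed_point_rows",
    "assemble",
    "solve_weights",
    "synthesize_ring_rnn",
    "synthesize_input_controlled_rnn",
    "tonic_input_for_offset",
    "verify_jacobian",
]


class SynthesisError(RuntimeError):
    """Raised when the linear solve produces a non-finite weight matrix."""


@dataclass
class RNN:
    """A synthesized recurrent network.

    ``weights`` is the N x N coupling matrix W of the rate equation
    dx/dt = (1/tau)(-x + W^T tanh(x) + I); ``input_vector`` (optional)
    is the unit vector along which tonic input is applied.
    """

    weights: np.ndarray
    tau: float
    input_vector: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weight matrix contains non-finite entries")

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    def dxdt(self, x: np.ndarray, tonic_input: np.ndarray | float = 0.0) -> np.ndarray:
        """Right-hand side of the rate equation; batched over leading axes."""
        return (-x + np.tanh(x) @ self.weights + tonic_input) / self.tau


@dataclass
class ConstraintSystem:
    """Stacked linear constraints A W = B with per-row provenance tags."""

    A: np.ndarray
    B: np.ndarray
    row_tags: list[str]

    def __post_init__(self) -> None:
        if self.A.shape != self.B.shape:
            raise ValueError("A and B must have identical shapes")
        if len(self.row_tags) != self.A.shape[0]:
            raise ValueError("one tag per row required")


@dataclass
class SynthesisReport:
    """Diagnostics of one linear solve."""

    residual_norm: float
    weight_rank: int
    jacobian_errors: dict[float, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SynthesisConfig:
    """Tunable parameters of ring-network synthesis.

    ``lambda_normal`` defaults to -1/tau (the leak rate) when None.
    ``fixed_point_rows`` is "auto" (add rows at the drift's zero
    crossings whenever the baseline is non-zero), "always" or "never".

    ``offmanifold`` selects how the N - d unconstrained directions are
    handled: "minimum_norm" (default) relies on the minimum-norm
    least-squares solution to confine W to the constraint span, which
    reproduces the target dynamics to high precision;  "explicit"
    additionally imposes zero-target rows for the full orthogonal
    complement at every setpoint, which over-determines the system and
    trades some drift accuracy for a near-symmetric weight matrix (used
    for connectivity-structure analyses).  ``n_offmanifold_rows`` adds
    a sampled subset of such rows to the minimum-norm system (ablation).
    """

    n_setpoints: int = 64
    tau: float = 0.1
    lambda_normal: float | None = None
    sigma_reg: float = 1e-6
    seed: int = 0
    fixed_point_rows: str = "auto"
    fp_row_weight: float = 1.0
    offmanifold: str = "minimum_norm"
    n_offmanifold_rows: int = 0
    half_setpoints: bool = False
    verify: bool = True

    def __post_init__(self) -> None:
        if self.offmanifold not in ("minimum_norm", "explicit"):
            raise ValueError(f"unknown offmanifold mode {self.offmanifold!r}")
        if self.fixed_point_rows not in ("auto", "always", "never"):
            raise ValueError(f"unknown fixed_point_rows mode {self.fixed_point_rows!r}")


def phi_prime_diag(state: np.ndarray) -> np.ndarray:
    """Diagonal of Phi: elementwise tanh'(x) = 1 - tanh(x)^2."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite entries")
    return 1.0 - np.tanh(state) ** 2


def constraint_rows(
    setpoint: Setpoint, eigenspec: EigenSpec, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """One d-row constraint block (A, B) at a setpoint.

    A = U^T Phi(x_j);  B = tau * (Sigma + I_d/tau) U^T.  A target
    eigenvalue of exactly -1/tau makes the corresponding B row zero,
    which is how unconstrained directions are dropped from the system.
    """
    u = eigenspec.eigvecs
    a_block = u.T * phi_prime_diag(setpoint.state)[np.newaxis, :]
    scale = tau * eigenspec.eigvals + 1.0
    b_block = scale[:, np.newaxis] * u.T
    return a_block, b_block


def fixed_point_rows(x_f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row pair enforcing W^T tanh(x_f) = x_f, i.e. dx/dt = 0 at x_f."""
    x_f = np.asarray(x_f, dtype=float)
    if np.allclose(x_f, 0.0):
        warnings.warn("fixed-point row at the origin is trivially satisfied")
    return np.tanh(x_f)[np.newaxis, :], x_f[np.newaxis, :]


def assemble(
    blocks: list[tuple[np.ndarray, np.ndarray]], tags: list[str] | None = None
) -> ConstraintSystem:
    """Vertically stack (A, B) blocks into one constraint system."""
    if not blocks:
        raise ValueError("cannot assemble an empty constraint system")
    n_cols = blocks[0][0].shape[1]
    for a, b in blocks:
        if a.shape[1] != n_cols or b.shape[1] != n_cols:
            raise ValueError("inconsistent column count across blocks")
    A = np.concatenate([a for a, _ in blocks], axis=0)
    B = np.concatenate([b for _, b in blocks], axis=0)
    if tags is None:
        tags = []
        for i, (a, _) in enumerate(blocks):
            tags.extend([f"block{i}"] * a.shape[0])
    return ConstraintSystem(A=A, B=B, row_tags=tags)


def solve_weights(
    system: ConstraintSystem, sigma_reg: float = 1e-6, seed: int = 0
) -> tuple[np.ndarray, SynthesisReport]:
    """Minimum-norm least-squares solve of (A + xi) W = B.

    ``xi`` is i.i.d. Gaussian noise with standard deviation
    ``sigma_reg``, a regularizer that decouples the solution from the
    specific choice of setpoints.  Rank deficiency is resolved by the
    minimum-norm solution, which keeps the rank of W equal to the rank
    of B (the embedding dimension of the manifold).
    """
    if sigma_reg < 0:
        raise ValueError("sigma_reg must be non-negative")
    A = system.A
    if sigma_reg > 0:
        rng = np.random.default_rng(seed)
        A = A + rng.normal(0.0, sigma_reg, size=A.shape)
    W, _, _, _ = np.linalg.lstsq(A, system.B, rcond=None)
    if not np.all(np.isfinite(W)):
        raise SynthesisError(
            f"non-finite solution (system {A.shape[0]}x{A.shape[1]}, "
            f"sigma_reg={sigma_reg:g})"
        )
    residual = float(np.linalg.norm(A @ W - system.B))
    sv = np.linalg.svd(W, compute_uv=False)
    rank = int(np.sum(sv > 1e-6 * sv[0])) if sv[0] > 0 else 0
    return W, SynthesisReport(residual_norm=residual, weight_rank=rank)


def _ring_blocks(
    setpoints: list[Setpoint],
    drift_spec: DriftSpec,
    tau: float,
    lambda_normal: float,
    input_dir: np.ndarray | None = None,
    lambda_input: float | None = None,
    drift_scale: float = 1.0,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[str]]:
    blocks, tags = [], []
    for sp in setpoints:
        es = eigenspec_at_setpoint(
            sp,
            drift_spec,
            lambda_normal,
            input_dir=input_dir,
            lambda_input=lambda_input,
            drift_scale=drift_scale,
        )
        blocks.append(constraint_rows(sp, es, tau))
        d = es.eigvals.size
        tags.extend(f"jac:theta={sp.theta:.4f}:mode{k}" for k in range(d))
    return blocks, tags


def synthesize_ring_rnn(
    ring: RingSpec, drift_spec: DriftSpec, config: SynthesisConfig | None = None
) -> tuple[RNN, SynthesisReport]:
    """End-to-end synthesis of a ring network.

    Builds evenly spaced setpoints, the per-setpoint Jacobian constraint
    blocks (tangential eigenvalue = G'(theta), normal eigenvalues =
    lambda_normal), optional fixed-point rows at the baseline-shifted
    zero crossings, and solves for W.
    """
    config = config or SynthesisConfig()
    tau = config.tau
    lambda_normal = config.lambda_normal if config.lambda_normal is not None else -1.0 / tau
    if config.offmanifold == "explicit":
        return _synthesize_ring_explicit(ring, drift_spec, config, lambda_normal)
    setpoints = make_setpoints(config.n_setpoints, ring)
    if config.half_setpoints:
        # tanh is odd, so for origin-centered rings the blocks at theta and
        # theta + pi coincide up to sign; half the ring suffices
        setpoints = setpoints[: (len(setpoints) + 1) // 2]
    blocks, tags = _ring_blocks(setpoints, drift_spec, tau, lambda_normal)

    add_fp = config.fixed_point_rows == "always" or (
        config.fixed_point_rows == "auto" and drift_spec.baseline != 0.0
    )
    if add_fp:
        for fp in drift_fixed_points(drift_spec):
            a_row, b_row = fixed_point_rows(embed_state(fp.theta, ring))
            w = config.fp_row_weight
            blocks.append((w * a_row, w * b_row))
            tags.append(f"fp:theta={fp.theta:.4f}:{fp.stability}")

    if config.n_offmanifold_rows > 0:
        rng = np.random.default_rng(config.seed + 1)
        basis = ring.basis.basis_vectors
        for i in range(config.n_offmanifold_rows):
            v = rng.standard_normal(ring.n_units)
            v -= basis @ (basis.T @ v)
            v /= np.linalg.norm(v)
            sp = setpoints[i % len(setpoints)]
            a_row = (v * phi_prime_diag(sp.state))[np.newaxis, :]
            blocks.append((a_row, np.zeros((1, ring.n_units))))
            tags.append(f"offmanifold:{i}")

    system = assemble(blocks, tags)
    W, report = solve_weights(system, sigma_reg=config.sigma_reg, seed=config.seed)
    rnn = RNN(
        weights=W,
        tau=tau,
        metadata={
            "ring_spec": ring.to_dict(),
            "drift_spec": drift_spec.to_dict(),
            "config": {
                "n_setpoints": config.n_setpoints,
                "lambda_normal": lambda_normal,
                "sigma_reg": config.sigma_reg,
                "seed": config.seed,
            },
        },
    )
    if config.verify:
        errors = {}
        for sp in setpoints:
            es = eigenspec_at_setpoint(sp, drift_spec, lambda_normal)
            err = verify_jacobian(rnn, sp, es)
            errors[sp.theta] = float(np.max(np.abs(err)))
        report.jacobian_errors = errors
    return rnn, report


def _synthesize_ring_explicit(
    ring: RingSpec, drift_spec: DriftSpec, config: SynthesisConfig, lambda_normal: float
) -> tuple[RNN, SynthesisReport]:
    """Closed-form solve with explicit off-manifold zero rows.

    Constraining the full orthonormal frame at each setpoint (the d
    target modes plus the orthogonal complement at eigenvalue -1/tau)
    turns the per-setpoint block into the matrix equation
    Phi(x_j) W = S_j with S_j = sum_k (tau lambda_k + 1) u_k u_k^T
    (rank d, symmetric).  Because Phi is diagonal, the stacked
    least-squares problem decouples by row of W:

        W[i, :] = sum_j phi'_i(x_j) S_j[i, :] / sum_j phi'_i(x_j)^2

    The system is over-determined and inconsistent across setpoints, so
    the realized drift is less precise than the minimum-norm solve, but
    the blend of symmetric targets yields a near-symmetric W whose
    coupling structure mirrors classical ring-attractor connectivity.
    """
    setpoints = make_setpoints(config.n_setpoints, ring)
    n = ring.n_units
    num = np.zeros((n, n))
    den = np.zeros(n)
    for sp in setpoints:
        es = eigenspec_at_setpoint(sp, drift_spec, lambda_normal)
        phip = phi_prime_diag(sp.state)
        s_j = (es.eigvecs * (config.tau * es.eigvals + 1.0)[np.newaxis, :]) @ es.eigvecs.T
        num += phip[:, np.newaxis] * s_j
        den += phip**2
    W = num / den[:, np.newaxis]
    sv = np.linalg.svd(W, compute_uv=False)
    rank = int(np.sum(sv > 1e-6 * sv[0])) if sv[0] > 0 else 0
    rnn = RNN(
        weights=W,
        tau=config.tau,
        metadata={
            "ring_spec": ring.to_dict(),
            "drift_spec": drift_spec.to_dict(),
            "config": {
                "n_setpoints": config.n_setpoints,
                "lambda_normal": lambda_normal,
                "offmanifold": "explicit",
            },
        },
    )
    residual = 0.0
    for sp in setpoints:
        es = eigenspec_at_setpoint(sp, drift_spec, lambda_normal)
        a_block, b_block = constraint_rows(sp, es, config.tau)
        residual += float(np.linalg.norm(a_block @ W - b_block) ** 2)
    return rnn, SynthesisReport(residual_norm=float(np.sqrt(residual)), weight_rank=rank)


def tonic_input_for_offset(offset: float, lambda_input: float, tau: float) -> float:
    """Tonic input magnitude that parks the input-direction state at ``offset``.

    Linearizing the rate equation along the input direction gives
    dy/dt = lambda_input * y + I/tau, whose equilibrium is
    y* = I / (tau * |lambda_input|); inverting yields
    I = tau * |lambda_input| * offset.
    """
    return tau * abs(lambda_input) * offset


def synthesize_input_controlled_rnn(
    ring: RingSpec,
    base_drift: DriftSpec,
    input_levels: list[float],
    level_spacing: float = 6.0,
    lambda_input: float | None = None,
    config: SynthesisConfig | None = None,
) -> tuple[RNN, SynthesisReport]:
    """Synthesize a network whose drift speed is selected by a tonic input.

    The ring plane is spanned by the first ``ring.n_dim`` basis columns;
    one extra orthonormal direction (drawn from the same seeded basis)
    serves as the input direction.  Level k (k = 0..M-1) places a copy
    of the ring at offset ``k * level_spacing`` along the input
    direction, with tangential eigenvalues scaled by the level *label*
    ``input_levels[k]`` (drift speed proportional to input level) and
    eigenvalue ``lambda_input`` along the input direction everywhere.
    The tonic input that selects level k is
    ``tonic_input_for_offset(k * level_spacing, lambda_input, tau)``
    times the input unit vector.
    """
    if level_spacing <= 0:
        raise ValueError("level_spacing must be positive")
    config = config or SynthesisConfig()
    tau = config.tau
    if lambda_input is None:
        # the leak rate: makes the input-direction B rows vanish, so the
        # direction decays through the leak term alone and the tonic-input
        # equilibrium is exactly I in state units
        lambda_input = -1.0 / tau
    if lambda_input >= 0:
        raise ValueError("lambda_input must be strictly negative")
    lambda_normal = config.lambda_normal if config.lambda_normal is not None else -1.0 / tau

    from .manifolds import make_embedding_basis

    # bases are nested in n_dim, so extending the ring's own basis by one
    # column yields an input direction orthogonal to the ring subspace
    ext = make_embedding_basis(ring.n_units, ring.n_dim + 1, ring.basis.seed)
    if not np.allclose(ext.basis_vectors[:, : ring.n_dim], ring.basis.basis_vectors):
        raise ValueError(
            "ring basis is not the seeded nested basis; cannot extend it "
            "with an input direction"
        )
    input_dir = ext.basis_vectors[:, ring.n_dim]

    blocks: list[tuple[np.ndarray, np.ndarray]] = []
    tags: list[str] = []
    base_setpoints = make_setpoints(config.n_setpoints, ring)
    for k, level in enumerate(input_levels):
        offset = k * level_spacing
        for sp in base_setpoints:
            shifted = Setpoint(
                theta=sp.theta,
                latent=sp.latent,
                state=sp.state + offset * input_dir,
                frame=sp.frame,
            )
            es = eigenspec_at_setpoint(
                shifted,
                base_drift,
                lambda_normal,
                input_dir=input_dir,
                lambda_input=lambda_input,
                drift_scale=level,
            )
            blocks.append(constraint_rows(shifted, es, tau))
            tags.extend(
                f"jac:level={level}:theta={sp.theta:.4f}:mode{m}"
                for m in range(es.eigvals.size)
            )
            if level == 0.0 and offset == 0.0:
                # the zero-input, zero-drift ring consists of true fixed
                # points; pinning them anchors the whole ring family along
                # the input axis (Jacobian rows alone leave the baseline of
                # the input-direction dynamics free)
                blocks.append(fixed_point_rows(shifted.state))
                tags.append(f"fp:level=0:theta={sp.theta:.4f}")
    system = assemble(blocks, tags)
    W, report = solve_weights(system, sigma_reg=config.sigma_reg, seed=config.seed)
    rnn = RNN(
        weights=W,
        tau=tau,
        input_vector=input_dir,
        metadata={
            "ring_spec": ring.to_dict(),
            "drift_spec": base_drift.to_dict(),
            "input_levels": list(map(float, input_levels)),
            "level_spacing": float(level_spacing),
            "lambda_input": float(lambda_input),
        },
    )
    return rnn, report


def verify_jacobian(
    rnn: RNN, setpoint: Setpoint, eigenspec: EigenSpec, step: float = 1e-5
) -> np.ndarray:
    """Numeric check that the network Jacobian realizes the target eigenpairs.

    Differentiates the rate equation by central differences along each
    target eigenvector and compares the Rayleigh quotient u^T J u with
    the target eigenvalue.  Returns the per-mode signed errors (1/s).
    """
    x = setpoint.state
    errors = np.empty(eigenspec.eigvals.size)
    for k in range(eigenspec.eigvals.size):
        u = eigenspec.eigvecs[:, k]
        ju = (rnn.dxdt(x + step * u) - rnn.dxdt(x - step * u)) / (2.0 * step)
        errors[k] = float(u @ ju) - eigenspec.eigvals[k]
    return errors
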