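"""Reverse-engineering synthesized networks.

Three N x N similarity matrices summarize how a ring network is wired:
the *tuning similarity* (covariance of unit tuning curves over the ring
angle), the *input coupling* (inner products of the input weight
vectors of unit pairs), and the *output coupling* (inner products of
their output weight vectors).  Under the rate equation
dx/dt = (1/tau)(-x + W^T tanh(x)), the input weights into unit i are
the i-th column of W, so the input coupling is W^T W and the output
coupling is W W^T.  Classical ring attractor models predict all three
to share the same circulant structure; element-wise Pearson
correlations, partial correlations, and a label-shuffle null quantify
how much of that structure survives for rings embedded in higher
dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .manifolds import RingSpec, embed_state
from .synthesis import RNN

__all__ = [
    "SimilaritySet",
    "CorrelationReport",
    "weight_rank",
    "unit_tuning_curves",
    "similarity_set",
    "matrix_correlation",
    "correlation_report",
    "shuffle_null",
    "shuffle_null_from_matrices",
]


def weight_rank(W: np.ndarray, rel_tol: float = 1e-6) -> int:
    """Numerical rank: singular values above ``rel_tol`` times the largest."""
    if not 0 < rel_tol < 1:
        raise ValueError("rel_tol must be in (0, 1)")
    sv = np.linalg.svd(np.asarray(W, dtype=float), compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > rel_tol * sv[0]))


def unit_tuning_curves(
    ring: RingSpec, theta_grid: np.ndarray, pre_nonlinearity: bool = True
) -> np.ndarray:
    """Tuning curve of every unit over the ring, shape (N, len(grid)).

    By default row i is the raw state x_i(theta) — the unit's tuning
    function as a weighted sum of the latent tuning functions; with
    ``pre_nonlinearity=False`` the saturated output tanh(x_i(theta)) is
    returned instead.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size < 64:
        raise ValueError("need at least 64 grid points for stable tuning curves")
    states = embed_state(theta_grid, ring)  # (G, N)
    curves = states.T if pre_nonlinearity else np.tanh(states.T)
    return curves


@dataclass(frozen=True)
class SimilaritySet:
    """The three pairwise-similarity matrices of one network."""

    tuning_sim: np.ndarray
    input_coupling: np.ndarray
    output_coupling: np.ndarray
    unit_order: np.ndarray  # units sorted by preferred angle


def similarity_set(
    rnn: RNN,
    ring: RingSpec,
    n_grid: int = 256,
    pre_nonlinearity: bool = True,
) -> SimilaritySet:
    """Tuning covariance plus the input (W^T W) and output (W W^T) couplings."""
    grid = 2.0 * np.pi * np.arange(n_grid) / n_grid
    curves = unit_tuning_curves(ring, grid, pre_nonlinearity=pre_nonlinearity)
    tuning_sim = np.cov(curves)
    preferred = grid[np.argmax(curves, axis=1)]
    W = rnn.weights
    return SimilaritySet(
        tuning_sim=tuning_sim,
        input_coupling=W.T @ W,
        output_coupling=W @ W.T,
        unit_order=np.argsort(preferred, kind="stable"),
    )


def _offdiag(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def matrix_correlation(
    M1: np.ndarray,
    M2: np.ndarray,
    control: np.ndarray | None = None,
    include_diagonal: bool = False,
) -> float:
    """Pearson correlation of matrix elements (upper off-diagonal triangle).

    With ``control`` given, returns the partial correlation
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    M1, M2 = np.asarray(M1, dtype=float), np.asarray(M2, dtype=float)
    if M1.shape != M2.shape:
        raise ValueError("matrices must have identical shapes")
    take = (lambda m: m.ravel()) if include_diagonal else _offdiag
    x, y = take(M1), take(M2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant matrix")
    r_xy = float(stats.pearsonr(x, y).statistic)
    if control is None:
        return r_xy
    z = take(np.asarray(control, dtype=float))
    if np.ptp(z) == 0:
        raise ValueError("correlation undefined for a constant control matrix")
    r_xz = float(stats.pearsonr(x, z).statistic)
    r_yz = float(stats.pearsonr(y, z).statistic)
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0:
        raise ValueError("partial correlation undefined: control fully explains a matrix")
    return (r_xy - r_xz * r_yz) / denom


@dataclass(frozen=True)
class CorrelationReport:
    """Raw, partial and null correlations between the similarity matrices."""

    r_tuning_input: float
    r_tuning_output: float
    r_input_output: float
    partial_tuning_input: float  # controlling for output coupling
    partial_tuning_output: float  # controlling for input coupling
    partial_input_output: float  # controlling for tuning similarity
    null_tuning_input: np.ndarray
    null_tuning_output: np.ndarray
    null_input_output: np.ndarray


def correlation_report(
    sims: SimilaritySet, n_shuffles: int = 500, seed: int = 0
) -> CorrelationReport:
    """All pairwise (partial) correlations plus label-shuffle nulls."""
    t, i, o = sims.tuning_sim, sims.input_coupling, sims.output_coupling
    nulls = shuffle_null_from_matrices(t, i, o, n_shuffles=n_shuffles, seed=seed)
    return CorrelationReport(
        r_tuning_input=matrix_correlation(t, i),
        r_tuning_output=matrix_correlation(t, o),
        r_input_output=matrix_correlation(i, o),
        partial_tuning_input=matrix_correlation(t, i, control=o),
        partial_tuning_output=matrix_correlation(t, o, control=i),
        partial_input_output=matrix_correlation(i, o, control=t),
        **{f"null_{k}": v for k, v in nulls.items()},
    )


def shuffle_null_from_matrices(
    tuning: np.ndarray,
    input_coupling: np.ndarray,
    output_coupling: np.ndarray,
    n_shuffles: int = 500,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Label-shuffle null for each matrix pair.

    For each draw, the unit labels of the first matrix of the pair are
    permuted (rows and columns jointly, preserving symmetry) and the
    element-wise correlation recomputed.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a usable null")
    rng = np.random.default_rng(seed)
    n = tuning.shape[0]
    out = {"tuning_input": [], "tuning_output": [], "input_output": []}
    for _ in range(n_shuffles):
        p = rng.permutation(n)
        t_p = tuning[np.ix_(p, p)]
        i_p = input_coupling[np.ix_(p, p)]
        out["tuning_input"].append(matrix_correlation(t_p, input_coupling))
        out["tuning_output"].append(matrix_correlation(t_p, output_coupling))
        out["input_output"].append(matrix_correlation(i_p, output_coupling))
    return {k: np.asarray(v) for k, v in out.items()}


def shuffle_null(
    rnn: RNN, ring: RingSpec, n_shuffles: int = 500, seed: int = 0
) -> dict[str, np.ndarray]:
    """Convenience wrapper: build the similarity set, then its shuffle null."""
    sims = similarity_set(rnn, ring)
    return shuffle_null_from_matrices(
        sims.tuning_sim,
        sims.input_coupling,
        sims.output_coupling,
        n_shuffles=n_shuffles,
        seed=seed,
    )
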