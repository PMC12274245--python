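"""Recover a D-optimal design from the optimal variogram.

The dual optimum ``Gamma*`` determines the optimal information matrix (and
hence the edge weights ``Q*``) uniquely, but typically many designs share
that information matrix.  This module recovers one: a nonnegative-least-
squares fit of ``xi`` to ``Q* = L S^T R^{-1} xi`` on the simplex for the
general problem, the closed form ``w_uv = Q*_uv / lambda_uv`` for paired
comparisons, and the decomposable (chordal-support) rational recovery.

The reconstruction of ``Q*`` from ``Gamma*`` follows one fixed path --
inverse Farris transform, matrix inverse, Laplacian completion, negated
off-diagonal -- so sign conventions are single-sourced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.optimize import nnls

from .choice_model import Design, Utilities, _as_pi, complete_matrix, enumerate_pairs
from .dual_solver import DualProblem, build_dual
from .farris_geometry import gamma_to_vec, inverse_farris

__all__ = [
    "RecoveryResult",
    "q_from_gamma",
    "recover_design",
    "recover_bt_design",
    "is_chordal",
    "decomposable_recovery",
    "support_is_decomposable",
]

#: weights below this threshold are treated as zero for support reporting
SUPPORT_THRESHOLD = 1e-4


@dataclass
class RecoveryResult:
    """A recovered design plus the Euclidean norm of the Q-mismatch."""

    design: Design
    residual: float
    method: str  # "qp" | "bt_closed_form" | "decomposable"


def q_from_gamma(G: np.ndarray) -> np.ndarray:
    """Edge weights implied by a variogram.

    Fixed reconstruction path: ``Gamma -> A`` (inverse Farris), ``A ->
    Theta_red`` (inverse), ``Theta_red -> Theta`` (Laplacian completion),
    then ``Q = -offdiag(Theta)`` vectorized in lexicographic pair order.
    """
    A = inverse_farris(np.asarray(G, dtype=float))
    Theta = complete_matrix(np.linalg.inv(A))
    Q = -Theta
    np.fill_diagonal(Q, 0.0)
    return gamma_to_vec(Q)


def recover_design(gamma_star: np.ndarray, dp: DualProblem) -> RecoveryResult:
    """Least-squares design recovery on the simplex.

    Minimizes ``||Q* - L S^T R^{-1} xi||_2`` over ``xi >= 0`` with
    ``1^T xi = 1`` (the sum constraint enters as a strongly weighted
    augmented row, followed by exact renormalization).  A tiny ridge term
    makes the minimizer unique, approximating the minimum-norm solution
    among least-squares minimizers when the fit is degenerate.

    Raises
    ------
    RuntimeError
        If the residual exceeds 1e-6, indicating the dual solve that
        produced ``gamma_star`` did not converge.
    """
    q = q_from_gamma(gamma_star)
    At = dp.A.T  # columns indexed by choice sets
    n = At.shape[1]
    qscale = max(1.0, float(np.abs(q).max()))
    c = qscale  # weight of the sum-to-one row
    delta = 1e-8 * qscale  # ridge for uniqueness / minimum-norm tie-break
    M = np.vstack([At, c * np.ones((1, n)), delta * np.eye(n)])
    rhs = np.concatenate([q, [c], np.zeros(n)])
    w, _ = nnls(M, rhs)
    if w.sum() <= 0:
        raise RuntimeError("design recovery produced the zero vector")
    w = w / w.sum()
    residual = float(np.linalg.norm(At @ w - q))
    if residual > 1e-6 * qscale:
        raise RuntimeError(
            f"design recovery residual {residual:.3g} is too large; dual not converged"
        )
    design = Design(np.clip(w, 0.0, None) / np.clip(w, 0.0, None).sum(), dp.problem.m, dp.problem.k)
    return RecoveryResult(design, residual, "qp")


def recover_bt_design(gamma_star: np.ndarray, pi) -> RecoveryResult:
    """Closed-form recovery for paired comparisons: ``w_uv = Q*_uv / lambda_uv``.

    The weights of a converged dual solution sum to one up to roundoff
    (a trace identity); they are renormalized exactly.

    Raises
    ------
    ValueError
        If ``Q*`` has a significantly negative entry, meaning
        ``gamma_star`` is not the variogram of a valid design.
    """
    p = _as_pi(pi)
    m = p.size
    q = q_from_gamma(gamma_star)
    lam = np.array([p[u - 1] * p[v - 1] / (p[u - 1] + p[v - 1]) ** 2 for u, v in enumerate_pairs(m)])
    w = q / lam
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError(f"negative edge weight {w.min():.3g}: inconsistent gamma_star")
    w = np.clip(w, 0.0, None)
    residual = float(abs(w.sum() - 1.0))
    w = w / w.sum()
    return RecoveryResult(Design(w, m, 2), residual, "bt_closed_form")


def is_chordal(edges: Iterable[tuple[int, int]], m: int) -> bool:
    """Chordality of the graph on ``{1..m}`` with the given edges
    (maximum-cardinality-search test via networkx)."""
    G = nx.Graph()
    G.add_nodes_from(range(1, m + 1))
    G.add_edges_from(edges)
    return nx.is_chordal(G)


def decomposable_recovery(
    gamma_star: np.ndarray, pi, support: Iterable[tuple[int, int]]
) -> RecoveryResult:
    """Rational recovery for paired comparisons with chordal support.

    When the support graph of the optimal design is decomposable
    (equivalently chordal), the design is the unique rational function of
    ``pi`` given by ``xi_uv = -M_uv(xi*, pi) / lambda_uv``, with ``M``
    rebuilt from ``Gamma*`` through the fixed reconstruction path.  The
    entries of ``M`` outside the support must vanish; a violation means
    the support guess is wrong.
    """
    p = _as_pi(pi)
    m = p.size
    support = {tuple(sorted(e)) for e in support}
    if not is_chordal(support, m):
        raise ValueError("support graph is not chordal (decomposable)")
    G = nx.Graph()
    G.add_nodes_from(range(1, m + 1))
    G.add_edges_from(support)
    if not nx.is_connected(G):
        raise ValueError("support graph does not connect all alternatives")
    q = q_from_gamma(gamma_star)
    pairs = enumerate_pairs(m)
    qscale = max(1.0, float(np.abs(q).max()))
    off = [abs(qv) for pr, qv in zip(pairs, q) if pr not in support]
    if off and max(off) > 1e-8 * qscale:
        raise ValueError(
            f"off-support entry of M is {max(off):.3g}, not zero: support guess is wrong"
        )
    lam = np.array([p[u - 1] * p[v - 1] / (p[u - 1] + p[v - 1]) ** 2 for u, v in pairs])
    w = np.where([pr in support for pr in pairs], np.clip(q, 0.0, None) / lam, 0.0)
    residual = float(abs(w.sum() - 1.0))
    w = w / w.sum()
    return RecoveryResult(Design(w, m, 2), residual, "decomposable")


def support_is_decomposable(xi: Design, threshold: float = SUPPORT_THRESHOLD) -> bool:
    """Chordality of a paired-comparison design's support graph.

    Generic D-optimal paired-comparison designs are expected to have
    decomposable supports; this is an empirical monitor, not a theorem
    for all instances, so callers should warn rather than assert.
    """
    if xi.k != 2:
        raise ValueError("support_is_decomposable applies to k=2 designs")
    pairs = enumerate_pairs(xi.m)
    edges = [pairs[j] for j in xi.support(threshold)]
    return is_chordal(edges, xi.m)
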