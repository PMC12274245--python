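"""Farris transform, Cayley--Menger determinant and Kirchhoff identities.

The reduced covariance ``Sigma = inv(M^(m))`` of a design is mapped by the
Farris transform to a variogram ``Gamma`` (symmetric, zero diagonal,
conditionally negative definite).  The D-criterion's dual objective is the
log of the Cayley--Menger bordered determinant of ``Gamma``, which equals
``log det Sigma``.  Kirchhoff's matrix tree theorem expresses
``det M^(m)`` as the spanning-tree polynomial in the edge weights ``Q``.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from .choice_model import (
    Design,
    complete_matrix,
    enumerate_pairs,
    information_matrix,
    reduce_matrix,
)

__all__ = [
    "CNDDomainError",
    "SingularDesignError",
    "farris_transform",
    "inverse_farris",
    "bordered_matrix",
    "bordered_logdet",
    "is_cnd",
    "gamma_of_design",
    "kirchhoff_determinant",
    "inner_product_identity_check",
    "vec_to_gamma",
    "gamma_to_vec",
]


class CNDDomainError(ValueError):
    """The bordered determinant is not positive: Gamma lies outside the CND cone."""


class SingularDesignError(np.linalg.LinAlgError):
    """The design's information matrix is singular (support does not connect all alternatives)."""


def farris_transform(A: np.ndarray) -> np.ndarray:
    """Map a symmetric ``(m-1) x (m-1)`` matrix to an ``m x m`` variogram.

    ``Gamma_uv = A_uu + A_vv - 2 A_uv`` for ``u, v < m``, ``Gamma_um =
    A_uu`` and ``Gamma_mm = 0``.  ``A`` is positive definite iff the image
    is conditionally negative definite.
    """
    A = np.asarray(A, dtype=float)
    d = A.shape[0]
    G = np.zeros((d + 1, d + 1))
    diag = np.diag(A)
    G[:d, :d] = diag[:, None] + diag[None, :] - 2.0 * A
    G[:d, d] = diag
    G[d, :d] = diag
    np.fill_diagonal(G, 0.0)
    return G


def inverse_farris(G: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`farris_transform`:
    ``A_uv = (Gamma_um + Gamma_vm - Gamma_uv) / 2``.
    """
    G = np.asarray(G, dtype=float)
    d = G.shape[0] - 1
    last = G[:d, d]
    return 0.5 * (last[:, None] + last[None, :] - G[:d, :d])


def bordered_matrix(G: np.ndarray) -> np.ndarray:
    """The Cayley--Menger bordered matrix ``[[0, -1^T], [1, -Gamma/2]]``.

    The layout is asymmetric exactly as written (top row ``-1``, left
    column ``+1``) so that the determinant's sign is unambiguous.
    """
    G = np.asarray(G, dtype=float)
    m = G.shape[0]
    B = np.empty((m + 1, m + 1))
    B[0, 0] = 0.0
    B[0, 1:] = -1.0
    B[1:, 0] = 1.0
    B[1:, 1:] = -G / 2.0
    return B


def _bordered_slogdet(G: np.ndarray) -> tuple[float, float]:
    """(sign, log|det|) of the bordered matrix; no domain check."""
    sign, logabs = np.linalg.slogdet(bordered_matrix(G))
    return float(sign), float(logabs)


def bordered_logdet(G: np.ndarray) -> float:
    """Log of the Cayley--Menger determinant of the variogram ``G``.

    Raises
    ------
    CNDDomainError
        If the determinant is not strictly positive, i.e. ``G`` lies
        outside the cone on which the dual objective is defined.
    """
    sign, logabs = _bordered_slogdet(G)
    if sign <= 0 or not np.isfinite(logabs):
        raise CNDDomainError("bordered determinant is not positive: outside CND domain")
    return logabs


def is_cnd(G: np.ndarray, tol: float = 1e-12) -> bool:
    """Membership in the CND cone, tested via positive definiteness of the
    inverse Farris transform (Cholesky with a relative shift tolerance)."""
    A = inverse_farris(G)
    scale = max(1.0, float(np.abs(A).max()))
    try:
        np.linalg.cholesky(A + tol * scale * np.eye(A.shape[0]))
        return True
    except np.linalg.LinAlgError:
        return False


def gamma_of_design(xi: Design, pi) -> np.ndarray:
    """Variogram ``Gamma(xi)``: Farris transform of ``inv(M^(m)(xi))``.

    Raises
    ------
    SingularDesignError
        If the support of ``xi`` does not connect all ``m`` alternatives,
        so that the reduced information matrix is singular.
    """
    Mred = reduce_matrix(information_matrix(xi, pi))
    sign, logabs = np.linalg.slogdet(Mred)
    if sign <= 0 or not np.isfinite(logabs):
        raise SingularDesignError(
            "singular information matrix: design support does not connect all alternatives"
        )
    return farris_transform(np.linalg.inv(Mred))


def kirchhoff_determinant(q: np.ndarray, m: int) -> float:
    """Spanning-tree polynomial ``sum_T prod_{uv in T} q_uv``.

    Testing oracle for the matrix tree theorem: equals ``det`` of the
    reduced Laplacian built from the edge weights ``q`` (lexicographic
    pair order).  Enumerates spanning trees explicitly and is capped at
    ``m <= 9``; it is not a production path.
    """
    if m > 9:
        raise ValueError("spanning-tree enumeration capped at m <= 9; use the determinant")
    q = np.asarray(q, dtype=float)
    G = nx.Graph()
    G.add_nodes_from(range(1, m + 1))
    for (u, v), w in zip(enumerate_pairs(m), q):
        if w != 0.0:
            G.add_edge(u, v, weight=w)
    if G.number_of_nodes() > G.number_of_edges() + 1:
        return 0.0
    total = 0.0
    for T in nx.SpanningTreeIterator(G):
        total += float(np.prod([d["weight"] for _, _, d in T.edges(data=True)]))
    return total


def gamma_to_vec(G: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a zero-diagonal symmetric
    matrix in lexicographic pair order."""
    m = G.shape[0]
    iu = np.triu_indices(m, k=1)
    return np.asarray(G, dtype=float)[iu]


def vec_to_gamma(v: np.ndarray, m: int) -> np.ndarray:
    """Inverse of :func:`gamma_to_vec`."""
    G = np.zeros((m, m))
    iu = np.triu_indices(m, k=1)
    G[iu] = v
    return G + G.T


def inner_product_identity_check(A: np.ndarray, Theta: np.ndarray, tol: float = 1e-10) -> bool:
    """Verify ``<A, Theta^(m)> = <<Gamma, Q>>`` for the Farris pair.

    ``A`` is symmetric of size ``m-1``, ``Theta`` an ``m x m`` zero-row-sum
    matrix; the trace inner product of ``A`` with the reduced ``Theta``
    must equal ``sum_{s<t} Gamma_st Q_st`` with ``Gamma`` the Farris
    transform of ``A`` and ``Q`` the negated off-diagonal of ``Theta``.
    """
    A = np.asarray(A, dtype=float)
    Theta = np.asarray(Theta, dtype=float)
    lhs = float(np.trace(A @ reduce_matrix(Theta)))
    G = farris_transform(A)
    Q = -Theta.copy()
    np.fill_diagonal(Q, 0.0)
    rhs = 0.0
    m = Theta.shape[0]
    for s, t in itertools.combinations(range(m), 2):
        rhs += G[s, t] * Q[s, t]
    scale = max(1.0, abs(lhs), abs(rhs))
    return abs(lhs - rhs) <= tol * scale
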