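"""Combinatorics and information matrices of the multinomial choice model.

A discrete choice experiment presents respondents with choice sets of ``k``
out of ``m`` unstructured alternatives.  Alternative ``i`` has latent
attractiveness ``pi_i > 0`` and is chosen from set ``C`` with probability
``pi_i / sum(pi_s, s in C)`` (the Bradley--Terry model when ``k == 2``).
The Fisher information of a design -- a probability vector over all
``C(m, k)`` choice sets -- is a weighted graph Laplacian whose edge weights
depend on ``pi``.  This module builds those objects.

Conventions
-----------
Alternatives are 1-based.  Choice sets and alternative pairs are ordered
lexicographically, ``(12, 13, ..., (m-1)m)`` for pairs, and every
vectorization in the package uses this order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChoiceProblem",
    "Utilities",
    "Design",
    "enumerate_choice_sets",
    "enumerate_pairs",
    "incidence_matrix",
    "choice_probabilities",
    "set_information_matrix",
    "information_matrix",
    "laplacian_from_edge_weights",
    "reduce_matrix",
    "complete_matrix",
    "scaling_matrices",
    "q_vector",
    "is_laplacian",
    "read_design_csv",
    "write_design_csv",
    "read_utilities_json",
    "write_utilities_json",
]

#: relative tolerance for Laplacian row-sum / PSD checks
LAPLACIAN_TOL = 1e-10


def enumerate_choice_sets(m: int, k: int) -> list[tuple[int, ...]]:
    """All k-subsets of ``{1, ..., m}`` in lexicographic order.

    Parameters
    ----------
    m : int
        Number of alternatives.
    k : int
        Choice-set size, ``2 <= k <= m``.
    """
    if not (isinstance(m, (int, np.integer)) and isinstance(k, (int, np.integer))):
        raise TypeError("m and k must be integers")
    if k < 2 or k > m:
        raise ValueError(f"need 2 <= k <= m, got k={k}, m={m}")
    return list(itertools.combinations(range(1, m + 1), k))


def enumerate_pairs(m: int) -> list[tuple[int, int]]:
    """All unordered pairs of ``{1, ..., m}``, lexicographically."""
    return list(itertools.combinations(range(1, m + 1), 2))


@lru_cache(maxsize=None)
def _pair_index(m: int) -> dict[tuple[int, int], int]:
    return {p: i for i, p in enumerate(enumerate_pairs(m))}


@lru_cache(maxsize=None)
def incidence_matrix(m: int, k: int) -> np.ndarray:
    """Edge--hyperedge incidence matrix ``S``.

    Row ``j`` is the indicator vector of the pairs contained in choice set
    ``C_j``; shape ``(C(m,k), C(m,2))``.  Each row has ``C(k,2)`` ones and
    each column ``C(m-2, k-2)``.  For ``k == 2`` this is the identity.
    """
    sets_ = enumerate_choice_sets(m, k)
    pidx = _pair_index(m)
    S = np.zeros((len(sets_), comb(m, 2)))
    for j, C in enumerate(sets_):
        for p in itertools.combinations(C, 2):
            S[j, pidx[p]] = 1.0
    S.setflags(write=False)
    return S


class ChoiceProblem:
    """The combinatorial frame of an experiment: ``m`` alternatives, sets of size ``k``.

    Attributes
    ----------
    m, k : int
    choice_sets : list of tuple
        The ``C(m,k)`` k-subsets in lexicographic order.
    pairs : list of tuple
        The ``C(m,2)`` pairs in lexicographic order.
    S : ndarray
        Edge--hyperedge incidence matrix (read-only view).
    """

    def __init__(self, m: int, k: int):
        self.choice_sets = enumerate_choice_sets(m, k)
        self.m = int(m)
        self.k = int(k)
        self.pairs = enumerate_pairs(m)
        self.S = incidence_matrix(m, k)

    @property
    def n_sets(self) -> int:
        return len(self.choice_sets)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def set_index(self, C: Iterable[int]) -> int:
        """Lexicographic index (0-based) of the choice set ``C``."""
        return self.choice_sets.index(tuple(sorted(C)))

    def __eq__(self, other):
        return isinstance(other, ChoiceProblem) and (self.m, self.k) == (other.m, other.k)

    def __hash__(self):
        return hash((self.m, self.k))

    def __repr__(self):
        return f"ChoiceProblem(m={self.m}, k={self.k})"


@dataclass(frozen=True)
class Utilities:
    """Attractiveness parameters ``pi`` (positive) with ``beta = log(pi)``.

    All model quantities are invariant under rescaling ``pi -> c * pi``;
    :meth:`normalized` recentres ``beta`` so the geometric mean of ``pi``
    is one, which tames the dynamic range before numerics.
    """

    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or pi.size < 2:
            raise ValueError("pi must be a vector of length >= 2")
        if not np.all(pi > 0):
            raise ValueError("all entries of pi must be strictly positive")
        object.__setattr__(self, "pi", pi)

    @classmethod
    def from_beta(cls, beta: Sequence[float]) -> "Utilities":
        return cls(np.exp(np.asarray(beta, dtype=float)))

    @property
    def m(self) -> int:
        return self.pi.size

    @property
    def beta(self) -> np.ndarray:
        return np.log(self.pi)

    def normalized(self) -> "Utilities":
        """Rescale to geometric mean one (``beta`` centred)."""
        b = self.beta
        return Utilities.from_beta(b - b.mean())

    def reduced(self) -> np.ndarray:
        """Identifiable parameter ``pi_0 = (pi_1/pi_m, ..., pi_{m-1}/pi_m)``."""
        return self.pi[:-1] / self.pi[-1]


def _as_pi(pi) -> np.ndarray:
    """Validate and return the utility vector as given.

    No rescaling happens here: every downstream quantity is invariant
    under ``pi -> c pi``, and the solver normalizes explicitly (geometric
    mean one) where the dynamic range matters.
    """
    if isinstance(pi, Utilities):
        return pi.pi
    return Utilities(np.asarray(pi, dtype=float)).pi


@dataclass(frozen=True)
class Design:
    """An approximate design: nonnegative weights over the choice sets, summing to one.

    ``weights[j]`` is the proportion of observations assigned to the j-th
    lexicographic choice set of :class:`ChoiceProblem` ``(m, k)``.
    """

    weights: np.ndarray
    m: int
    k: int

    #: admissible deviation of sum(weights) from one on input
    SUM_TOL = 1e-12

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        n = comb(self.m, self.k)
        if w.shape != (n,):
            raise ValueError(f"expected {n} weights for (m,k)=({self.m},{self.k}), got {w.shape}")
        if np.any(w < -self.SUM_TOL):
            raise ValueError("design weights must be nonnegative")
        if abs(w.sum() - 1.0) > max(self.SUM_TOL, 1e-9 * n):
            raise ValueError(f"design weights must sum to 1 (got {w.sum():.15g})")
        w = np.clip(w, 0.0, None)
        w = w / w.sum()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @classmethod
    def uniform(cls, m: int, k: int) -> "Design":
        n = comb(m, k)
        return cls(np.full(n, 1.0 / n), m, k)

    @classmethod
    def vertex(cls, m: int, k: int, C: Iterable[int]) -> "Design":
        """The design putting all weight on a single choice set."""
        prob = ChoiceProblem(m, k)
        w = np.zeros(prob.n_sets)
        w[prob.set_index(C)] = 1.0
        return cls(w, m, k)

    @property
    def problem(self) -> ChoiceProblem:
        return ChoiceProblem(self.m, self.k)

    def support(self, threshold: float = 1e-4) -> list[int]:
        """Indices (0-based) of choice sets with weight above ``threshold``."""
        return [int(j) for j in np.nonzero(self.weights > threshold)[0]]

    def support_sets(self, threshold: float = 1e-4) -> list[tuple[int, ...]]:
        cs = self.problem.choice_sets
        return [cs[j] for j in self.support(threshold)]


def choice_probabilities(C: Iterable[int], pi) -> np.ndarray:
    """Choice probabilities ``pi_i / sum_{s in C} pi_s`` over the set ``C``.

    The returned vector is ordered like ``sorted(C)`` and sums to one.
    """
    C = tuple(sorted(C))
    if len(C) == 0:
        raise ValueError("empty choice set")
    pi = _as_pi(pi)
    vals = pi[np.asarray(C) - 1]
    return vals / vals.sum()


def set_information_matrix(C: Iterable[int], pi, m: int | None = None) -> np.ndarray:
    """Information matrix ``M(C, pi)`` of one observation of choice set ``C``.

    This is the Laplacian of the complete graph on ``C`` embedded in the
    full ``m x m`` frame: off-diagonal entries ``-pi_s pi_t / (sum_{i in C}
    pi_i)^2`` for ``s, t in C`` and zero elsewhere; row sums vanish.
    """
    pi = _as_pi(pi)
    if m is None:
        m = pi.size
    C = tuple(sorted(C))
    M = np.zeros((m, m))
    P = pi[np.asarray(C) - 1].sum()
    for s, t in itertools.combinations(C, 2):
        q = pi[s - 1] * pi[t - 1] / P**2
        M[s - 1, t - 1] -= q
        M[t - 1, s - 1] -= q
        M[s - 1, s - 1] += q
        M[t - 1, t - 1] += q
    return M


def laplacian_from_edge_weights(q: np.ndarray, m: int) -> np.ndarray:
    """Graph Laplacian with edge weights ``q`` (lexicographic pair order)."""
    M = np.zeros((m, m))
    for (u, v), w in zip(enumerate_pairs(m), q):
        M[u - 1, v - 1] -= w
        M[v - 1, u - 1] -= w
        M[u - 1, u - 1] += w
        M[v - 1, v - 1] += w
    return M


def information_matrix(xi: Design, pi) -> np.ndarray:
    """Information matrix ``M(xi, pi)`` of a design: the weighted-Laplacian mixture.

    Equal to ``sum_j w_j M(C_j, pi)``; computed through the edge-weight
    vector ``Q(xi)`` which collects the same sums per pair.
    """
    return laplacian_from_edge_weights(q_vector(xi, pi), xi.m)


def reduce_matrix(M: np.ndarray, drop: int | None = None) -> np.ndarray:
    """Delete row and column ``drop`` (1-based; default the last) from ``M``.

    Applied to an information matrix this yields the reduced, nonsingular
    ``(m-1) x (m-1)`` information matrix of the identifiable model.
    """
    M = np.asarray(M, dtype=float)
    m = M.shape[0]
    if drop is None:
        drop = m
    keep = [i for i in range(m) if i != drop - 1]
    return M[np.ix_(keep, keep)]


def complete_matrix(Mred: np.ndarray, drop: int | None = None) -> np.ndarray:
    """Rebuild the ``m x m`` zero-row-sum matrix from its reduced form.

    Exact inverse of :func:`reduce_matrix`: the deleted row/column is
    restored so that all row sums vanish.  ``drop`` is the 1-based position
    at which the row/column is reinserted (default: appended last).
    """
    A = np.asarray(Mred, dtype=float)
    d = A.shape[0] + 1
    if drop is None:
        drop = d
    M = np.zeros((d, d))
    keep = [i for i in range(d) if i != drop - 1]
    M[np.ix_(keep, keep)] = A
    r = -A.sum(axis=1)
    M[keep, drop - 1] = r
    M[drop - 1, keep] = r
    M[drop - 1, drop - 1] = A.sum()
    return M


def scaling_matrices(problem: ChoiceProblem, pi) -> tuple[np.ndarray, np.ndarray]:
    """Diagonals of the scaling matrices ``R`` and ``L``.

    ``R_jj = (sum_{i in C_j} pi_i)^2`` over choice sets and
    ``L_uv = pi_u pi_v`` over lexicographic pairs.  Returned as 1-d arrays
    of the diagonal entries.
    """
    pi = _as_pi(pi)
    R = np.array([pi[np.asarray(C) - 1].sum() ** 2 for C in problem.choice_sets])
    L = np.array([pi[u - 1] * pi[v - 1] for u, v in problem.pairs])
    return R, L


def q_vector(xi: Design, pi) -> np.ndarray:
    """Edge-weight vector ``Q(xi) = L S^T R^{-1} xi`` of the information matrix.

    Entry ``uv`` equals ``pi_u pi_v sum_{j: u,v in C_j} w_j / (sum_{i in
    C_j} pi_i)^2``.  For ``k == 2`` it reduces to ``lambda_uv * w_uv``.
    """
    prob = xi.problem
    R, L = scaling_matrices(prob, pi)
    return L * (prob.S.T @ (xi.weights / R))


def is_laplacian(M: np.ndarray, tol: float = LAPLACIAN_TOL) -> bool:
    """Check symmetry, zero row sums, nonpositive off-diagonal and PSD-ness."""
    M = np.asarray(M, dtype=float)
    scale = max(1.0, float(np.abs(M).max()))
    if not np.allclose(M, M.T, atol=tol * scale):
        return False
    if np.abs(M.sum(axis=1)).max() > tol * scale:
        return False
    off = M - np.diag(np.diag(M))
    if off.max() > tol * scale:
        return False
    w = np.linalg.eigvalsh(M)
    return bool(w.min() > -tol * scale)


# ---------------------------------------------------------------------------
# file formats: designs as CSV, utilities as JSON


def write_design_csv(xi: Design, path) -> None:
    """Write a design as CSV with columns ``choice_set`` ("1,2,5") and ``weight``."""
    cs = xi.problem.choice_sets
    df = pd.DataFrame(
        {
            "choice_set": [",".join(map(str, C)) for C in cs],
            "weight": xi.weights,
        }
    )
    df.to_csv(path, index=False)


def read_design_csv(path, m: int, k: int) -> Design:
    """Read a design written by :func:`write_design_csv`.

    Unlisted choice sets get weight zero; listing a set twice is an error.
    """
    df = pd.read_csv(path)
    for col in ("choice_set", "weight"):
        if col not in df.columns:
            raise ValueError(f"design file {path} lacks required column '{col}'")
    prob = ChoiceProblem(m, k)
    w = np.zeros(prob.n_sets)
    seen = set()
    for ln, (cell, weight) in enumerate(zip(df["choice_set"], df["weight"]), start=2):
        try:
            C = tuple(sorted(int(x) for x in str(cell).split(",")))
            j = prob.set_index(C)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{ln}: cannot parse choice set {cell!r}") from exc
        if j in seen:
            raise ValueError(f"{path}:{ln}: duplicate choice set {cell!r}")
        seen.add(j)
        w[j] = float(weight)
    return Design(w, m, k)


def write_utilities_json(pi: Utilities, path, labels: Sequence[str] | None = None) -> None:
    payload: dict = {"pi": [float(x) for x in pi.pi]}
    if labels is not None:
        payload["labels"] = list(labels)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_utilities_json(path) -> tuple[Utilities, list[str] | None]:
    with open(path) as fh:
        payload = json.load(fh)
    if "pi" not in payload:
        raise ValueError(f"{path}: expected a JSON object with a 'pi' list")
    return Utilities(np.asarray(payload["pi"], dtype=float)), payload.get("labels")
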