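"""Shared fixtures and independent oracles.

The primal oracle maximizes ``log det M^(m)(xi)`` directly over the
simplex with a generic constrained optimizer, building the information
matrix from first principles (its own loop over choice sets); it shares
no code path with the package's dual solver.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def oracle_reduced_information(weights, pi, m, k):
    """Reduced information matrix built independently of the package."""
    M = np.zeros((m, m))
    for w, C in zip(weights, itertools.combinations(range(m), k)):
        P = sum(pi[i] for i in C)
        for s, t in itertools.combinations(C, 2):
            q = w * pi[s] * pi[t] / P**2
            M[s, t] -= q
            M[t, s] -= q
            M[s, s] += q
            M[t, t] += q
    return M[: m - 1, : m - 1]


def oracle_primal_opt(pi, k, return_design=False):
    """Maximize log det of the reduced information over the simplex (SLSQP).

    The iterate is renormalized onto the simplex before the final
    evaluation, since SLSQP satisfies the equality constraint only to a
    tolerance.
    """
    pi = np.asarray(pi, dtype=float)
    m = pi.size
    n = len(list(itertools.combinations(range(m), k)))

    def negld(x):
        sign, ld = np.linalg.slogdet(oracle_reduced_information(x, pi, m, k))
        return -ld if sign > 0 else 1e10

    res = minimize(
        negld,
        np.full(n, 1.0 / n),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
        options={"maxiter": 3000, "ftol": 1e-16},
    )
    x = np.clip(res.x, 0.0, None)
    x = x / x.sum()
    ld = float(np.linalg.slogdet(oracle_reduced_information(x, pi, m, k))[1])
    if return_design:
        return ld, x
    return ld


def random_connected_design(rng, m, k, sparsity=0.0):
    """A random design (optionally sparse) whose support connects all
    alternatives; falls back to mixing in the uniform design."""
    import choicedesign as cd

    n = len(cd.enumerate_choice_sets(m, k))
    w = rng.dirichlet(np.ones(n))
    if sparsity > 0:
        mask = rng.random(n) > sparsity
        if not mask.any():
            mask[rng.integers(n)] = True
        w = w * mask
    if w.sum() == 0 or _disconnected(w, m, k):
        w = 0.9 * w / max(w.sum(), 1e-300) + 0.1 / n
    return cd.Design(w / w.sum(), m, k)


def _disconnected(w, m, k):
    import networkx as nx
    import choicedesign as cd

    G = nx.Graph()
    G.add_nodes_from(range(1, m + 1))
    for wj, C in zip(w, cd.enumerate_choice_sets(m, k)):
        if wj > 0:
            for u, v in itertools.combinations(C, 2):
                G.add_edge(u, v)
    return not nx.is_connected(G)
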