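"""KKT optimality certificates, duality gaps and D-efficiencies.

A design is D-optimal iff it lies in the simplex, every directional
derivative ``tr(M^(m)(xi)^{-1} M^(m)(C_j)) - (m-1)`` is nonpositive, and
complementary slackness holds (equivalence theorem).  The directional
derivatives are evaluated through the variogram: derivative ``j`` equals
the j-th dual constraint value at ``Gamma(xi)`` minus ``m-1``, which is
the same number by the Farris inner-product identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .choice_model import ChoiceProblem, Design, Utilities, _as_pi, information_matrix, reduce_matrix
from .dual_solver import DualProblem, build_dual, solve_dual
from .farris_geometry import SingularDesignError, bordered_logdet, gamma_of_design, gamma_to_vec

__all__ = [
    "CertificationReport",
    "directional_derivatives",
    "check_optimality",
    "duality_gap",
    "d_efficiency",
]

#: default tolerance on directional derivatives for declaring optimality
CERT_TOL = 1e-6

#: duality gaps below this are reported as exactly zero
GAP_ZERO = 1e-16


@dataclass
class CertificationReport:
    """Outcome of the KKT certificate for one design.

    ``kkt_pass`` is true iff the design is in the simplex, the largest
    directional derivative is at most ``tol`` and the weighted slack
    (complementary slackness) vanishes within ``tol``.
    """

    directional_derivatives: np.ndarray
    max_directional_derivative: float
    complementary_slackness: float
    simplex_ok: bool
    kkt_pass: bool
    tol: float
    duality_gap: float | None = None
    d_efficiency: float | None = None


def _dp_for(xi: Design, pi) -> DualProblem:
    return build_dual(ChoiceProblem(xi.m, xi.k), pi)


def directional_derivatives(xi: Design, pi) -> np.ndarray:
    """Per-choice-set derivatives ``tr(M^(m)(xi)^{-1} M^(m)(C_j)) - (m-1)``.

    Computed through the variogram as ``A vec(Gamma(xi)) - (m-1)``.  All
    entries are nonpositive (within tolerance) iff ``xi`` is D-optimal;
    the weights of ``xi`` always average them to zero.
    """
    dp = _dp_for(xi, pi)
    gvec = gamma_to_vec(gamma_of_design(xi, pi))
    return dp.A @ gvec - dp.bound


def check_optimality(xi: Design, pi, tol: float = CERT_TOL) -> CertificationReport:
    """Run the full KKT certificate for ``xi`` at parameter ``pi``.

    For paired comparisons this is the coordinatewise form (slack of
    ``Gamma(xi)`` against the box bound per supported pair); the general
    form is used uniformly here since the two coincide row by row.
    """
    dd = directional_derivatives(xi, pi)
    max_dd = float(dd.max())
    cs = float(abs(np.dot(dd, xi.weights)))
    simplex_ok = bool(np.all(xi.weights >= 0) and abs(xi.weights.sum() - 1.0) < 1e-9)
    kkt = simplex_ok and max_dd <= tol and cs <= tol
    return CertificationReport(dd, max_dd, cs, simplex_ok, kkt, tol)


def _logdet_reduced(xi: Design, pi) -> float:
    Mred = reduce_matrix(information_matrix(xi, pi))
    sign, logabs = np.linalg.slogdet(Mred)
    if sign <= 0:
        raise SingularDesignError("singular information matrix")
    return float(logabs)


def duality_gap(xi: Design, G: np.ndarray, dp: DualProblem | np.ndarray | None = None) -> float:
    """Absolute gap between primal and dual objectives.

    The primal value is ``-log det M^(m)(xi)`` and the dual value the
    bordered log-determinant of ``G``; the equality-constraint terms of
    the augmented primal cancel, so the gap is ``|-log det M^(m)(xi) -
    logdet_CM(G)|``.  It vanishes identically for matched pairs ``G =
    Gamma(xi)`` and at an optimal pair; values below 1e-16 are reported
    as exactly zero.

    ``dp`` supplies the parameter ``pi`` (a :class:`DualProblem` or a raw
    positive vector).
    """
    if dp is None:
        raise ValueError("duality_gap needs the parameter pi (a DualProblem or vector)")
    pi = dp.pi if isinstance(dp, DualProblem) else dp
    gap = abs(-_logdet_reduced(xi, pi) - bordered_logdet(G))
    return 0.0 if gap < GAP_ZERO else gap


def d_efficiency(xi: Design, pi, xi_star: Design | str = "solve", drop: int | None = None) -> float:
    """D-efficiency of ``xi`` relative to the locally D-optimal design.

    ``(det M^(m)(xi) / det M^(m)(xi*))^(1/(m-1))``, a value in ``(0, 1]``;
    an efficiency of 1/2 means twice the sample size is needed to match
    the optimal design's information.  With ``xi_star="solve"`` the
    optimal determinant is taken from the dual optimum (by strong duality
    ``log det M^(m)(xi*) = -logdet_CM(Gamma*)``), avoiding any recovery
    error.  The value is invariant to rescaling ``pi`` and to the choice
    of dropped identifiability index.

    A singular input design has efficiency zero (returned with a warning).
    """
    pi_u = Utilities(_as_pi(pi))
    try:
        Mred = reduce_matrix(information_matrix(xi, pi_u), drop=drop)
        sign, ld_xi = np.linalg.slogdet(Mred)
        if sign <= 0:
            raise SingularDesignError
    except SingularDesignError:
        warnings.warn("singular input design: D-efficiency reported as 0")
        return 0.0
    if isinstance(xi_star, str):
        if xi_star != "solve":
            raise ValueError(f"xi_star must be a Design or 'solve', got {xi_star!r}")
        dp = build_dual(ChoiceProblem(xi.m, xi.k), pi_u)
        sol = solve_dual(dp)
        ld_opt = -sol.objective
    else:
        ld_opt = float(
            np.linalg.slogdet(reduce_matrix(information_matrix(xi_star, pi_u), drop=drop))[1]
        )
    return float(np.exp((ld_xi - ld_opt) / (xi.m - 1)))
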