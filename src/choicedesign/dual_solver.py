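"""Dual solver: maximize the Cayley--Menger log-determinant under sparse
linear constraints.

The D-criterion's dual asks for the variogram ``Gamma`` maximizing
``log det [[0, -1^T], [1, -Gamma/2]]`` subject to ``R^{-1} S L vec(Gamma)
<= (m-1) 1`` (and implicit membership in the CND cone, which the
objective's domain enforces).  The optimum ``Gamma*`` is unique; a
D-optimal design is any simplex vector reproducing its edge weights (see
:mod:`choicedesign.design_recovery`).

The solver runs SLSQP on scaled variables and then polishes the solution
with an equality-constrained Newton method on the detected active set,
which brings the KKT residual to near machine precision.  The constraint
multipliers of the polished solution are exactly the design weights of a
D-optimal design supported on the active choice sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .choice_model import ChoiceProblem, Design, Utilities, _as_pi, scaling_matrices
from .farris_geometry import (
    bordered_matrix,
    gamma_of_design,
    gamma_to_vec,
    vec_to_gamma,
)

__all__ = [
    "DualProblem",
    "DualSolution",
    "ConvergenceError",
    "build_dual",
    "bt_upper_bound",
    "feasible_start",
    "solve_dual",
    "solve_bt_dual",
    "objective_gradient",
]

log = logging.getLogger(__name__)

#: a constraint is considered tight within this fraction of the bound m-1
ACTIVE_TOL = 1e-7


class ConvergenceError(RuntimeError):
    """The dual solve did not reach the requested KKT residual."""


@dataclass(frozen=True)
class DualProblem:
    """The dual optimization problem for one ``(m, k, pi)`` instance.

    Attributes
    ----------
    problem : ChoiceProblem
    pi : Utilities
        Normalized to geometric mean one.
    A : ndarray
        Constraint matrix ``R^{-1} S L`` of shape ``(C(m,k), C(m,2))``;
        row ``j`` evaluated at ``Gamma`` is ``sum_{u<v in C_j} pi_u pi_v
        Gamma_uv / (sum_{i in C_j} pi_i)^2``.
    bound : float
        Right-hand side ``m - 1`` of every constraint.
    lam : ndarray
        Pair weights ``lambda_uv = pi_u pi_v / (pi_u + pi_v)^2``.
    scale : ndarray
        Per-pair variable scaling ``(m-1)/lambda_uv`` used by the solver.
    """

    problem: ChoiceProblem
    pi: Utilities
    A: np.ndarray
    bound: float
    lam: np.ndarray
    scale: np.ndarray


@dataclass
class DualSolution:
    """Converged (or best-effort) solution of the dual problem."""

    gamma_star: np.ndarray
    objective: float
    constraint_values: np.ndarray
    active_set: list[int]
    multipliers: np.ndarray  # per active constraint; the design weights
    kkt_residual: float
    n_iter: int
    converged: bool


def build_dual(problem: ChoiceProblem, pi) -> DualProblem:
    """Assemble constraint matrix and scalings for the dual problem."""
    pi = Utilities(_as_pi(pi)).normalized()
    if pi.m != problem.m:
        raise ValueError(f"pi has length {pi.m}, problem has m={problem.m}")
    R, L = scaling_matrices(problem, pi)
    A = (problem.S * L[None, :]) / R[:, None]
    p = pi.pi
    lam = np.array([p[u - 1] * p[v - 1] / (p[u - 1] + p[v - 1]) ** 2 for u, v in problem.pairs])
    bound = float(problem.m - 1)
    return DualProblem(problem, pi, A, bound, lam, bound / lam)


def bt_upper_bound(pi) -> np.ndarray:
    """Coordinatewise dual bound for paired comparisons (``k = 2``).

    ``Gammabar_uv = (m-1)/lambda_uv`` with ``lambda_uv = pi_u pi_v /
    (pi_u + pi_v)^2``; the dual constraints for ``k = 2`` decouple into
    ``Gamma <= Gammabar``.
    """
    p = _as_pi(pi)
    m = p.size
    lam = p[:, None] * p[None, :] / (p[:, None] + p[None, :]) ** 2
    G = (m - 1) / lam
    np.fill_diagonal(G, 0.0)
    return G


def feasible_start(dp: DualProblem) -> np.ndarray:
    """A dually feasible interior variogram: ``t * Gamma(uniform design)``.

    The uniform complete design connects all alternatives, so its
    variogram is in the CND cone; scaling by ``t = min(1, (m-1) /
    max_j constraint_j)`` enforces every linear constraint (the cone is
    closed under positive scaling).  At ``pi = 1`` all constraints are
    tight by symmetry and the start is already optimal.
    """
    G0 = gamma_of_design(Design.uniform(dp.problem.m, dp.problem.k), dp.pi)
    cons = dp.A @ gamma_to_vec(G0)
    t = min(1.0, dp.bound / float(cons.max()))
    return t * G0


# ---------------------------------------------------------------------------
# objective derivatives


def _pair_border_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    iu, iv = np.triu_indices(m, k=1)
    return iu + 1, iv + 1  # offset for the border row/column


def _value_grad(G: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(logdet, gradient over pair vector, B^{-1}); raises outside domain.

    Domain membership is the full CND-cone test (Cholesky of the inverse
    Farris transform): positivity of the bordered determinant alone does
    not prevent a line search from jumping across the cone boundary into
    a spurious region where the determinant is positive again.
    """
    from .farris_geometry import inverse_farris  # local to avoid cycle at import

    try:
        np.linalg.cholesky(inverse_farris(G))
    except np.linalg.LinAlgError:
        raise FloatingPointError("outside CND domain") from None
    B = bordered_matrix(G)
    sign, logabs = np.linalg.slogdet(B)
    if sign <= 0 or not np.isfinite(logabs):
        raise FloatingPointError("outside CND domain")
    Binv = np.linalg.inv(B)
    I, J = _pair_border_indices(G.shape[0])
    grad = -0.5 * (Binv[J, I] + Binv[I, J])
    return logabs, grad, Binv


def objective_gradient(G: np.ndarray) -> np.ndarray:
    """Gradient of :func:`~choicedesign.farris_geometry.bordered_logdet`
    with respect to the off-diagonal entries of ``Gamma``.

    Each unordered pair is varied symmetrically; the result is returned as
    a symmetric zero-diagonal matrix.  At ``Gamma = Gamma(xi)`` this equals
    the edge-weight matrix ``Q(xi)`` of the design's information matrix,
    which is the geometric heart of the design-recovery step.
    """
    G = np.asarray(G, dtype=float)
    _, grad, _ = _value_grad(G)
    return vec_to_gamma(grad, G.shape[0])


def _hessian(G: np.ndarray, Binv: np.ndarray) -> np.ndarray:
    """Hessian of the bordered log-determinant over the pair vector."""
    I, J = _pair_border_indices(G.shape[0])
    P_JI = Binv[np.ix_(J, I)]
    P_JJ = Binv[np.ix_(J, J)]
    P_II = Binv[np.ix_(I, I)]
    P_IJ = Binv[np.ix_(I, J)]
    return -0.25 * (P_JI * P_JI.T + P_JJ * P_II.T + P_II * P_JJ.T + P_IJ * P_IJ.T)


# ---------------------------------------------------------------------------
# solver


def _slsqp_stage(dp: DualProblem, x0: np.ndarray, max_iter: int) -> np.ndarray:
    """First stage: SLSQP on scaled variables with a domain guard."""
    g = dp.scale
    Ag = dp.A * g[None, :]
    m = dp.problem.m

    def fun(x):
        try:
            val, _, _ = _value_grad(vec_to_gamma(g * x, m))
            return -val
        except FloatingPointError:
            return 1e12

    def jac(x):
        try:
            _, grad, _ = _value_grad(vec_to_gamma(g * x, m))
            return -g * grad
        except FloatingPointError:
            return np.zeros_like(x)

    cons = [{"type": "ineq", "fun": lambda x: dp.bound - Ag @ x, "jac": lambda x: -Ag}]
    res = minimize(
        fun,
        x0,
        jac=jac,
        method="SLSQP",
        constraints=cons,
        options={"maxiter": max_iter, "ftol": 1e-12},
    )
    log.debug("SLSQP stage: status=%s nit=%d f=%.12g", res.status, res.nit, res.fun)
    x = res.x
    # make sure we hand a domain point to the polish stage
    lo = 0.0
    while True:
        try:
            _value_grad(vec_to_gamma(g * x, m))
            return x
        except FloatingPointError:
            lo += 1.0
            if lo > 60:
                return x0
            x = 0.5 * (x + x0)


def _polish(
    dp: DualProblem, x: np.ndarray, tol: float, max_outer: int = 25, max_newton: int = 60
) -> tuple[np.ndarray, list[int], np.ndarray, float, int]:
    """Active-set Newton refinement in the scaled coordinates.

    Maximizes the (strictly concave) objective on the affine hull of the
    detected tight constraints; drops constraints with negative
    multipliers and adds violated ones until the KKT conditions hold.
    Returns ``(x, active, multipliers, kkt_residual, n_iter)``.
    """
    g = dp.scale
    Ag = dp.A * g[None, :]
    m = dp.problem.m
    b = dp.bound
    n_iter = 0

    slack = b - Ag @ x
    active = list(np.nonzero(slack <= ACTIVE_TOL * b)[0])
    if not active:
        active = [int(np.argmin(slack))]

    mu = np.zeros(0)
    for _outer in range(max_outer):
        AJ = Ag[active]
        for _it in range(max_newton):
            n_iter += 1
            G = vec_to_gamma(g * x, m)
            val, grad_v, Binv = _value_grad(G)
            gx = g * grad_v  # gradient of logdet in scaled coords
            H = (g[:, None] * _hessian(G, Binv) * g[None, :])  # negative definite
            nJ = len(active)
            K = np.block([[-H, AJ.T], [AJ, np.zeros((nJ, nJ))]])
            rhs = np.concatenate([gx, b - AJ @ x])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            dx, mu = sol[: x.size], sol[x.size :]
            resid = np.linalg.norm(gx - AJ.T @ mu, np.inf) / max(1.0, np.linalg.norm(gx, np.inf))
            feas = np.linalg.norm(AJ @ x - b, np.inf) / b
            if resid <= tol and feas <= tol:
                break
            # backtrack into the domain and the feasible side of inactive rows
            alpha = 1.0
            inact = [j for j in range(Ag.shape[0]) if j not in active]
            for _bt in range(60):
                xn = x + alpha * dx
                try:
                    _value_grad(vec_to_gamma(g * xn, m))
                except FloatingPointError:
                    alpha *= 0.5
                    continue
                if inact and (b - Ag[inact] @ xn).min() < -1e-9 * b:
                    alpha *= 0.5
                    continue
                break
            else:
                break
            if np.linalg.norm(alpha * dx) <= 1e-16 * max(1.0, np.linalg.norm(x)):
                x = xn
                break
            x = xn
        # optimality check first: under degeneracy (more tight constraints
        # than variables) the KKT-system multipliers are non-unique and may
        # be negative even though valid nonnegative multipliers exist, so
        # test stationarity with nonnegative least squares before dropping.
        from scipy.optimize import nnls

        G = vec_to_gamma(g * x, m)
        _, grad_v, _ = _value_grad(G)
        gx = g * grad_v
        slack_now = b - Ag @ x
        tight = list(np.nonzero(slack_now <= ACTIVE_TOL * b)[0])
        if tight:
            mu_n, _ = nnls(Ag[tight].T, gx)
            resid_n = np.linalg.norm(gx - Ag[tight].T @ mu_n, np.inf) / max(
                1.0, np.linalg.norm(gx, np.inf)
            )
            if resid_n <= max(tol, 1e-11) and slack_now.min() >= -1e-9 * b:
                active = tight
                mu = mu_n
                break
        # working-set update
        if mu.size and mu.min() < -1e-9 * max(1.0, abs(mu).max()):
            drop = active[int(np.argmin(mu))]
            active.remove(drop)
            log.debug("polish: dropping constraint %d (negative multiplier)", drop)
            continue
        slack = b - Ag @ x
        viol = [j for j in range(Ag.shape[0]) if j not in active and slack[j] < -1e-11 * b]
        if viol:
            add = min(viol, key=lambda j: slack[j])
            active.append(add)
            active.sort()
            log.debug("polish: adding violated constraint %d", add)
            continue
        break

    # final multipliers by nonnegative least squares against stationarity
    from scipy.optimize import nnls

    G = vec_to_gamma(g * x, m)
    _, grad_v, _ = _value_grad(G)
    gx = g * grad_v
    AJ = Ag[active]
    mu, _ = nnls(AJ.T, gx)
    resid = np.linalg.norm(gx - AJ.T @ mu, np.inf) / max(1.0, np.linalg.norm(gx, np.inf))
    return x, active, mu, float(resid), n_iter


def solve_dual(
    dp: DualProblem,
    tol: float = 1e-10,
    max_iter: int = 500,
    start: str = "scaled_uniform",
) -> DualSolution:
    """Solve the dual problem to the requested KKT residual.

    Parameters
    ----------
    dp : DualProblem
    tol : float
        Target relative KKT stationarity residual.
    max_iter : int
        Iteration cap for the SLSQP stage.
    start : {"scaled_uniform", "bt_bound"}
        Initial point: the scaled uniform-design variogram (always
        feasible), or the coordinatewise bound (dually feasible for
        ``k = 2`` only).

    Raises
    ------
    ConvergenceError
        If the final KKT residual exceeds ``1e-6`` (the certification
        default), which indicates the solve cannot be trusted.
    """
    g = dp.scale
    if start == "scaled_uniform":
        x0 = gamma_to_vec(feasible_start(dp)) / g
    elif start == "bt_bound":
        if dp.problem.k != 2:
            raise ValueError("start='bt_bound' requires k=2")
        x0 = gamma_to_vec(bt_upper_bound(dp.pi)) / g
    else:
        raise ValueError(f"unknown start {start!r}")

    x = _slsqp_stage(dp, x0, max_iter)
    x, active, mu, resid, n_iter = _polish(dp, x, tol)
    gamma = vec_to_gamma(g * x, dp.problem.m)
    val, _, _ = _value_grad(gamma)
    cons = dp.A @ gamma_to_vec(gamma)
    converged = resid <= max(100 * tol, 1e-8)
    if resid > 1e-6:
        raise ConvergenceError(f"dual solve stalled with KKT residual {resid:.3g}")
    log.debug(
        "solve_dual: m=%d k=%d objective=%.12g active=%s residual=%.3g",
        dp.problem.m,
        dp.problem.k,
        val,
        active,
        resid,
    )
    return DualSolution(gamma, float(val), cons, list(active), mu, resid, n_iter, converged)


def solve_bt_dual(pi, tol: float = 1e-10, max_iter: int = 2000) -> DualSolution:
    """Coordinatewise-bound route for paired comparisons (``k = 2``).

    For the Bradley--Terry model the constraints decouple into the box
    ``Gamma <= Gammabar``, so the dual is a bound-constrained concave
    maximization; this route solves it with L-BFGS-B and serves as an
    independent cross-check of the general solver.
    """
    pi = Utilities(_as_pi(pi))
    m = pi.m
    dp = build_dual(ChoiceProblem(m, 2), pi)
    g = dp.scale  # equals vec(Gammabar)

    def fun_jac(x):
        try:
            val, grad, _ = _value_grad(vec_to_gamma(g * x, m))
            return -val, -g * grad
        except FloatingPointError:
            return 1e12, np.zeros_like(x)

    x0 = gamma_to_vec(feasible_start(dp)) / g
    res = minimize(
        fun_jac,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, 1.0)] * x0.size,
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12},
    )
    gamma = vec_to_gamma(g * res.x, m)
    val, grad, _ = _value_grad(gamma)
    cons = dp.A @ gamma_to_vec(gamma)
    slack = dp.bound - cons
    active = list(np.nonzero(slack <= ACTIVE_TOL * dp.bound)[0])
    # box multipliers are the gradient entries at the bound (k=2: A is diagonal)
    mu = np.clip(grad[active] / dp.A[active, active], 0.0, None)
    # stationarity: gradient must vanish off the active box facets
    resid = float(
        np.linalg.norm(np.where(slack > ACTIVE_TOL * dp.bound, grad, 0.0), np.inf)
        / max(1.0, np.linalg.norm(grad, np.inf))
    )
    return DualSolution(gamma, float(val), cons, active, mu, resid, res.nit, res.success)
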