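# Methods

## Model and criterion

For `m` unstructured alternatives with attractiveness `π ∈ R_{>0}^m`, one
observation of a choice set `C_j` of size `k` is multinomial with
probabilities `π_i / Σ_{s∈C_j} π_s`.  Its Fisher information `M(C_j, π)` is
the Laplacian of the complete graph on `C_j` with edge weights
`π_s π_t / (Σ_{i∈C_j} π_i)²`, embedded in the `m×m` frame.  A design
`ξ ∈ Δ_{C(m,k)}` has information `M(ξ, π) = Σ_j w_j M(C_j, π)`, again a
Laplacian with edge weights `Q_uv(ξ) = π_u π_v Σ_{j: u,v∈C_j} w_j / (Σ_{i∈C_j} π_i)²`,
or in matrix form `vec(Q) = L Sᵀ R⁻¹ ξ` with `S` the edge–hyperedge
incidence matrix, `R_jj = (Σ_{i∈C_j} π_i)²` and `L_uv = π_u π_v`.  The model
is invariant under `π → cπ`; identifiability is restored by deleting the
m-th row/column of `M` (any other index gives identical criteria values —
a test asserts this).  The D-criterion maximizes `log det M⁽ᵐ⁾(ξ, π)` over
the simplex; by Kirchhoff's matrix tree theorem this determinant is the
spanning-tree polynomial in the `Q_uv`, which is the combinatorial heart
of the dual below.

## The dual and its solver

Let `Σ⁽ᵐ⁾(ξ) = M⁽ᵐ⁾(ξ)⁻¹` and let `Γ(ξ)` be its Farris transform
(`Γ_uv = Σ_uu + Σ_vv − 2Σ_uv`, bordered by `Γ_um = Σ_uu`), a symmetric
zero-diagonal conditionally-negative-definite (CND) matrix.  The dual
problem maximizes the Cayley–Menger bordered log-determinant
`log det [[0, −1ᵀ],[1, −Γ/2]]` — which equals `log det` of the inverse
Farris transform, hence `−log det M⁽ᵐ⁾` at matched pairs — subject to
`R⁻¹ S L vec(Γ) ≤ (m−1)1` and `Γ` in the CND cone.  The objective is
strictly concave on its domain, so Γ* is unique even when the optimal
design is not.

The solver works in scaled variables `x_uv = Γ_uv λ_uv/(m−1)` with
`λ_uv = π_u π_v/(π_u+π_v)²`, which makes all variables O(1) even for the
extreme utility ratios of the line study (up to `e^{17.5}`); utilities are
rescaled to geometric mean one beforehand (every output is
scale-invariant, so this only tames intermediate magnitudes).  Two stages:

1. **SLSQP** (scipy) from a feasible interior start with analytic
   gradients.  The gradient of the bordered log-determinant with respect
   to `Γ_uv` is read off the inverse bordered matrix; at `Γ(ξ)` it equals
   `Q_uv(ξ)`, which is what ties stationarity to design recovery.
2. **Active-set Newton polish.**  The constraints tight at the SLSQP
   point (slack ≤ 1e-7·(m−1)) are treated as equalities and the
   equality-constrained maximum is found by damped Newton steps using the
   analytic Hessian, backtracking to stay inside the CND cone and on the
   feasible side of the remaining constraints.  Working-set changes:
   before dropping anything, stationarity is tested with *nonnegative*
   least-squares multipliers — under degeneracy (more tight constraints
   than the `C(m,2)` variables, typical near symmetric π) the KKT-system
   multipliers are non-unique and their signs are meaningless, and an
   earlier sign-based rule cycled; constraints are dropped on negative
   multipliers and violated ones added only when the NNLS test fails.
   The polish reaches KKT residuals near machine precision (~1e-14).

The domain test is a Cholesky factorization of the inverse Farris
transform, not positivity of the bordered determinant alone: a line
search can jump across the CND boundary into a region where the
determinant is positive again but the matrix is not CND, and the weaker
test accepts such points (observed in development, guarded by tests).

Defaults: `tol = 1e-10` (relative KKT residual), `max_iter = 500` for the
SLSQP stage; `solve_dual` raises if the final residual exceeds 1e-6.  For
`k = 2` the constraints decouple into the box `Γ ≤ Γ̄`,
`Γ̄_uv = (m−1)/λ_uv`; `solve_bt_dual` solves this box form with L-BFGS-B
and serves as an independent cross-check of the general path.

## Design recovery

Γ* determines the optimal edge weights `Q*` through one fixed path —
inverse Farris transform, matrix inverse, Laplacian completion, negated
off-diagonal — so sign conventions are single-sourced.  The recovery QP
minimizes `‖L Sᵀ R⁻¹ ξ − vec(Q*)‖₂` over the simplex, implemented as NNLS
on an augmented system (a strongly weighted sum-to-one row, then exact
renormalization) with a tiny ridge (1e-8 relative) that selects a unique,
approximately minimum-norm solution when the optimal design is not unique
(the optimal information matrix typically has many representations as a
convex combination of vertices).  Residuals at converged duals are
~1e-14; a residual above 1e-6 raises, since it means the dual solve
cannot be trusted.  For `k = 2` the closed form `w_uv = Q*_uv/λ_uv`
applies, and when the support graph is chordal the decomposable route
recovers the same weights from the completed `M(ξ*, π)` directly
(checking that off-support entries vanish).  Chordality of optimal
supports is monitored, never asserted: it is a conjecture, not a theorem.

## Certification and efficiency

Directional derivatives are evaluated through the variogram
(`A vec(Γ(ξ)) − (m−1)`, identical to the trace form by the Farris
inner-product identity; a test compares both).  The certificate requires
simplex membership, max directional derivative ≤ tol (default 1e-6, the
converged values are 1e-8 and below) and complementary slackness.  The
duality gap is reported as `|−log det M⁽ᵐ⁾(ξ) − logdet_CM(Γ)|`, with
values below 1e-16 reported as exactly zero.  D-efficiency
`(det M⁽ᵐ⁾(ξ)/det M⁽ᵐ⁾(ξ*))^{1/(m−1)}` uses the dual objective for the
denominator (`log det M⁽ᵐ⁾(ξ*) = −objective*` by strong duality), so no
recovery error enters reported efficiencies.

## Study fixtures and the simulation generator

The icons fixture carries the published 9-row response table (133
respondents, choice sets of 4 of 6 climate icons) and the published MLE;
the table transcription is frozen with a SHA-256 checksum.  The layout
(which 4 icons each row's counts belong to) was restored from the
published marginals: among all assignments of the 9 count quadruples to
column subsets, exactly one makes the table's maximum-likelihood estimate
reproduce the published π̂ to all four printed decimals, and that unique
alignment — a structured design pairing 2 of {NB, L, PB} with 2 of
{THC, OA, WAIS} in every set — is the fixture.  The T20 fixture carries
the published 13-team strength estimate only; the match schedule is not
public, so no study design is attached.

The log-normal simulation draws `β_u` iid `N(0, σ²)` (so `π = exp(β)` is
log-normal) with a single seeded `numpy` generator; the seed is recorded
in every report.  `sigma` is the actual standard deviation of β.  The
benchmark table this study reproduces labels its four cells 0.5, 1, 1.5,
2, but its printed efficiencies match simulation only when β is drawn
with standard deviation equal to the *square* of the label — all four
cells then agree within Monte-Carlo error, and none but the second does
otherwise — so the package's reproduction grid is
`TABLE_SIGMA_GRID = (0.25, 1.0, 2.25, 4.0)`.  Support sizes are counted
above a 1e-4 weight threshold (no published threshold exists; reported
mean support sizes are threshold- and solver-precision-dependent, and a
looser solver leaves small spurious weights that inflate them).

What the generator emulates: independent respondents, a correctly
specified multinomial choice model, and parameter uncertainty around the
origin of log-utility space.  What it does not: estimation error in π̂
(parameters are drawn, not estimated), respondent heterogeneity,
position or context effects, and exact integer allocation (designs are
approximate).  Passing tests therefore show the optimizer and the theory
are correct at known parameters, not that a practical experiment with
estimated parameters achieves the nominal efficiency.

The line study evaluates `π = (p, p^{1/2}, p^{5/4}, p^{7/4}, p^{3/4}, 1)`
with `p = exp(ℓ/10)` at `ℓ = 0, …, 99`, plus the extrapolated endpoint
`ℓ = 100` at which the optimal design is computed (the definition of the
endpoint follows the benchmark's own usage, outside its stated grid).
The two complementary BIBDs put weight 1/10 on complementary halves of
the 20 triples, covering every pair exactly twice; their equal mixture is
the uniform complete design, which by concavity of log det can never be
worse than the worse BIBD — the tests assert that exact bound, and the
empirical observation that it is also no better than the better BIBD
holds only up to ~1e-3 (it fails slightly near both ends of the line).

## Problem sizes and numerical choices

Test and reproduction runs use m ≤ 8 (m = 13 for the paired-comparison
study), n = 1000 Monte-Carlo replicates for the outer simulation cells
and 250 for the inner ones — sizes at which every identity is checked to
tight tolerances while the whole suite stays fast.  Spanning-tree
enumeration (the Kirchhoff test oracle) is capped at m ≤ 9 and is not a
production path.  Laplacian checks use 1e-10 relative tolerances;
Farris round trips are exact to machine precision; the simplex sum
tolerance on design input is 1e-12, then weights are renormalized
exactly.  Degenerate inputs: designs whose support does not connect all
alternatives have singular information, which raises a dedicated error
(efficiency reports 0 with a warning instead when asked for a number).

## Known limitations

- Local optimality only: everything is at a fixed parameter guess π.
- The recovered design is one representative of a possibly large optimal
  face; only Γ*, the optimal determinant and efficiencies are unique.
- No exact (integer) design rounding beyond naive rounding, and no
  symbolic/rational recovery for decomposable supports — the decomposable
  path validates the rational structure numerically.
- The interior-point-free solver targets the moderate dimensions of
  choice experiments (tested to m = 13 for pairs, m = 10 for k up to 6);
  it is not engineered for hundreds of alternatives.
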