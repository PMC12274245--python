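"""Packaged study fixtures and simulation drivers.

Two published choice datasets from the R package hyper2 anchor the worked
examples: the *icons* climate-change survey (133 respondents choosing the
most concerning of 4 out of 6 climate icons) and the *T20* Indian Premier
League cricket seasons 2008--2017 (633 paired team comparisons).  Both
enter only through their published maximum-likelihood strength estimates
and, for icons, the published response table; no likelihood is re-fit
here.

Also provided: a log-normal parameter simulation (m=6, k=3) measuring how
the equal-weight complete design degrades as parameters spread out, and
an efficiency study along a line in logarithmic parameter space comparing
the complete design with two complementary balanced incomplete block
designs (BIBDs).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .certification import check_optimality, d_efficiency, duality_gap
from .choice_model import ChoiceProblem, Design, Utilities
from .design_recovery import SUPPORT_THRESHOLD, recover_design
from .dual_solver import ConvergenceError, build_dual, solve_dual

__all__ = [
    "StudyFixture",
    "SimulationReport",
    "icons_fixture",
    "icons_table",
    "t20_fixture",
    "bibd_fixtures",
    "lognormal_simulation",
    "simulation_table",
    "line_study",
    "line_parameter",
    "line_optimal_design",
    "TABLE_SIGMA_GRID",
]


@dataclass(frozen=True)
class StudyFixture:
    """A named instance: parameter estimate, set size, optional study design."""

    name: str
    pi_hat: Utilities
    k: int
    study_design: Design | None = None
    labels: tuple[str, ...] | None = None
    notes: str = ""


@dataclass
class SimulationReport:
    """Means over replications of one log-normal simulation cell.

    ``se_efficiency_uniform`` is the Monte-Carlo standard error of
    ``mean_efficiency_uniform`` (sample standard deviation over the
    successful replicates divided by their square root).
    """

    sigma: float
    n: int
    seed: int
    mean_max_directional_derivative: float
    mean_duality_gap: float
    mean_efficiency_uniform: float
    se_efficiency_uniform: float
    mean_support_size: float
    n_failures: int = 0


# ---------------------------------------------------------------------------
# icons: perception of climate change (m=6 icons, choice sets of k=4)

ICONS_LABELS = ("NB", "L", "PB", "THC", "OA", "WAIS")

#: published MLE of the icon attractiveness parameters
ICONS_PI_HAT = (0.2523, 0.1736, 0.2246, 0.1701, 0.1107, 0.0687)

#: the 9 choice sets used in the survey and the per-icon selection counts,
#: icons in the order of ICONS_LABELS within each set
ICONS_RESPONSES = (
    (("NB", "L", "THC", "WAIS"), (5, 3, 4, 3)),
    (("NB", "PB", "THC", "WAIS"), (3, 5, 8, 2)),
    (("L", "PB", "THC", "WAIS"), (4, 9, 2, 1)),
    (("NB", "L", "THC", "OA"), (10, 3, 3, 4)),
    (("NB", "PB", "THC", "OA"), (4, 5, 6, 3)),
    (("L", "PB", "THC", "OA"), (4, 3, 1, 3)),
    (("NB", "L", "OA", "WAIS"), (5, 1, 1, 2)),
    (("NB", "PB", "OA", "WAIS"), (5, 1, 1, 1)),
    (("L", "PB", "OA", "WAIS"), (9, 7, 2, 0)),
)

ICONS_N_RESPONDENTS = 133

#: checksum of the canonical transcription (guards accidental edits)
_ICONS_SHA256 = "ada9ddb9078f6fbed991cfbe7db07a1452164a9c53638d67fef7215a63b99262"


def icons_table() -> pd.DataFrame:
    """The survey response table: one row per choice set, NaN outside it."""
    rows = []
    for (names, counts) in ICONS_RESPONSES:
        row = {lab: np.nan for lab in ICONS_LABELS}
        for lab, c in zip(names, counts):
            row[lab] = float(c)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(ICONS_LABELS))


def _icons_checksum() -> str:
    canonical = ";".join(
        ",".join(names) + ":" + ",".join(map(str, counts)) for names, counts in ICONS_RESPONSES
    )
    return hashlib.sha256(canonical.encode()).hexdigest()


def icons_fixture() -> StudyFixture:
    """The icons survey: m=6, k=4, published MLE and the study design.

    The study design puts weight (row total)/133 on each of the 9 choice
    sets used in the survey, zero on the other 6 possible sets; all
    weights are integer multiples of 1/133.
    """
    if _icons_checksum() != _ICONS_SHA256:
        raise RuntimeError("icons fixture transcription was modified (checksum mismatch)")
    prob = ChoiceProblem(6, 4)
    idx = {lab: i + 1 for i, lab in enumerate(ICONS_LABELS)}
    w = np.zeros(prob.n_sets)
    for names, counts in ICONS_RESPONSES:
        C = tuple(sorted(idx[lab] for lab in names))
        w[prob.set_index(C)] = sum(counts) / ICONS_N_RESPONDENTS
    return StudyFixture(
        name="icons",
        pi_hat=Utilities(np.array(ICONS_PI_HAT)),
        k=4,
        study_design=Design(w, 6, 4),
        labels=ICONS_LABELS,
        notes="climate-change icon survey, 133 respondents (hyper2 'icons' data)",
    )


# ---------------------------------------------------------------------------
# T20: Indian Premier League cricket (m=13 teams, paired comparisons)

T20_PI_HAT = (
    0.1177, 0.0503, 0.0614, 0.0634, 0.0867, 0.0571, 0.0724,
    0.1106, 0.0296, 0.0767, 0.0816, 0.0926, 0.0999,
)


def t20_fixture() -> StudyFixture:
    """The T20 cricket study: m=13 teams, k=2, published strength MLE.

    The match schedule (observed design) is not published, so no study
    design is attached.
    """
    return StudyFixture(
        name="t20",
        pi_hat=Utilities(np.array(T20_PI_HAT)),
        k=2,
        notes="Indian Premier League 2008-2017, 633 matches (hyper2 'T20' data)",
    )


# ---------------------------------------------------------------------------
# BIBDs for m=6, k=3

#: indicator of the first BIBD over the 20 lexicographic triples
_BIBD1_PATTERN = (0, 1, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1, 0, 0, 0, 1, 0, 1, 0, 1)


def bibd_fixtures() -> tuple[Design, Design]:
    """Two complementary balanced incomplete block designs for m=6, k=3.

    Each puts weight 1/10 on 10 of the 20 triples so that every pair of
    alternatives is covered by exactly 2 supported sets; together they
    tile the uniform complete design.
    """
    w1 = np.array(_BIBD1_PATTERN, dtype=float) / 10.0
    w2 = np.full(20, 1.0 / 10.0) - w1
    return Design(w1, 6, 3), Design(w2, 6, 3)


# ---------------------------------------------------------------------------
# log-normal parameter simulation (m=6, k=3)


def lognormal_simulation(
    sigma: float,
    n: int = 1000,
    seed: int = 0,
    m: int = 6,
    k: int = 3,
    support_threshold: float = SUPPORT_THRESHOLD,
) -> SimulationReport:
    """Monte Carlo study of the equal-weight complete design's efficiency.

    Each replicate draws ``beta ~ N(0, sigma^2)`` iid (so ``pi`` is
    log-normal), solves for the locally D-optimal design, and records the
    uniform design's D-efficiency, the recovered design's largest
    directional derivative and duality gap, and its support size above
    ``support_threshold``.  Replicates where the solver fails are counted
    and skipped.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prob = ChoiceProblem(m, k)
    uniform = Design.uniform(m, k)
    effs, dds, gaps, sizes = [], [], [], []
    failures = 0
    for _ in range(n):
        beta = sigma * rng.standard_normal(m)
        pi = Utilities.from_beta(beta)
        try:
            dp = build_dual(prob, pi)
            sol = solve_dual(dp)
            rec = recover_design(sol.gamma_star, dp)
        except (ConvergenceError, RuntimeError, np.linalg.LinAlgError):
            failures += 1
            continue
        ld_uniform = _safe_logdet(uniform, pi)
        effs.append(np.exp((ld_uniform + sol.objective) / (m - 1)))
        report = check_optimality(rec.design, pi)
        dds.append(report.max_directional_derivative)
        gaps.append(duality_gap(rec.design, sol.gamma_star, dp))
        sizes.append(len(rec.design.support(support_threshold)))
    effs = np.asarray(effs)
    return SimulationReport(
        sigma=float(sigma),
        n=n,
        seed=seed,
        mean_max_directional_derivative=float(np.mean(dds)),
        mean_duality_gap=float(np.mean(gaps)),
        mean_efficiency_uniform=float(effs.mean()),
        se_efficiency_uniform=float(effs.std(ddof=1) / np.sqrt(effs.size)) if effs.size > 1 else float("nan"),
        mean_support_size=float(np.mean(sizes)),
        n_failures=failures,
    )


def _safe_logdet(xi: Design, pi) -> float:
    from .choice_model import information_matrix, reduce_matrix

    return float(np.linalg.slogdet(reduce_matrix(information_matrix(xi, pi)))[1])


#: dispersion grid (standard deviations of beta) of the benchmark
#: simulation study this package reproduces; the benchmark tabulates the
#: cells under the labels 0.5, 1, 1.5, 2 -- the square roots of the
#: standard deviations actually sampled (see docs/methods.md)
TABLE_SIGMA_GRID = (0.25, 1.0, 2.25, 4.0)


def simulation_table(
    sigmas=TABLE_SIGMA_GRID, n: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Run :func:`lognormal_simulation` over a sigma grid; one row per sigma."""
    rows = []
    for i, s in enumerate(sigmas):
        rep = lognormal_simulation(s, n=n, seed=seed + i)
        rows.append(vars(rep))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# efficiency along a line in parameter space (m=6, k=3)


def line_parameter(ell: float) -> Utilities:
    """The line ``pi = (p, p^1/2, p^5/4, p^7/4, p^3/4, 1)``, ``p = exp(ell/10)``."""
    p1 = np.exp(ell / 10.0)
    return Utilities(np.array([p1, p1**0.5, p1**1.25, p1**1.75, p1**0.75, 1.0]))


def line_study(num_points: int = 100) -> pd.DataFrame:
    """Efficiencies of the complete design and both BIBDs along the line.

    Evaluates ``ell = 0, 1, ..., num_points - 1``; at ``ell = 0`` (all
    parameters equal) all three designs are D-optimal with efficiency 1.
    Returns a DataFrame with one row per ``ell``.
    """
    xi1, xi2 = bibd_fixtures()
    uniform = Design.uniform(6, 3)
    prob = ChoiceProblem(6, 3)
    rows = []
    for ell in range(num_points):
        pi = line_parameter(ell)
        dp = build_dual(prob, pi)
        sol = solve_dual(dp)
        ld_opt = -sol.objective
        row = {"ell": ell}
        for name, xi in (("complete", uniform), ("bibd1", xi1), ("bibd2", xi2)):
            row[f"eff_{name}"] = float(np.exp((_safe_logdet(xi, pi) - ld_opt) / 5.0))
        rows.append(row)
    return pd.DataFrame(rows)


def line_optimal_design(ell: float = 100.0) -> Design:
    """The locally D-optimal design at a point of the line (default the
    extrapolated endpoint ``ell = 100``)."""
    pi = line_parameter(ell)
    dp = build_dual(ChoiceProblem(6, 3), pi)
    sol = solve_dual(dp)
    return recover_design(sol.gamma_star, dp).design
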