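"""Randomized rounding of the fractional LP solution.

The LP relaxation yields per-locus selection probabilities
``p_i = ell_i^LP``.  Each rounding iteration draws an independent
Bernoulli(p_i) decision per locus; over ``N`` iterations plus one
guaranteed-feasible floor-rounded candidate, the procedure keeps the
feasible candidate (budget respected) with the lowest objective.  Because
the randomized objective has expectation OPT with the budget satisfied in
expectation, a Markov/Hoeffding argument bounds from below the probability
that the candidate set contains a solution that is both near-budget
(``<= n*b*(1+a)`` selected) and near-optimal, by

    1 - (1/c + exp(-2*n*(a*b)^2))**N

for any a > 0, c > 1 with 1/c + exp(-2n(ab)^2) < 1; the bound approaches 1
rapidly in N at genomic n.  ``rounding_success_bound`` evaluates it.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np

from .optimize import OptimizeParams, RelaxedSolution, budget_cap, objective_cp

logger = logging.getLogger(__name__)

__all__ = [
    "IntegralSolution",
    "RRParams",
    "draw_random_solution",
    "floor_solution",
    "run_rr",
    "rounding_success_bound",
    "chromosome_rng",
]


@dataclass
class IntegralSolution:
    """A binary selection vector with its exactly re-evaluated objective,
    selection count, and budget feasibility."""

    ell: np.ndarray
    objective: float
    n_selected: int
    feasible: bool


@dataclass(frozen=True)
class RRParams:
    """Number of rounding iterations N (default 50) and the RNG seed."""

    N: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be >= 0")


def _finalize(ell: np.ndarray, S, gamma: float, cap: int) -> IntegralSolution:
    n_sel = int(ell.sum())
    return IntegralSolution(
        ell=ell,
        objective=objective_cp(ell, S, gamma),
        n_selected=n_sel,
        feasible=n_sel <= cap,
    )


def draw_random_solution(
    ell_lp: np.ndarray, S, gamma: float, cap: int, rng: np.random.Generator
) -> IntegralSolution:
    """One rounding iteration: independent Bernoulli(ell_lp_i) draws."""
    p = np.clip(np.asarray(ell_lp, dtype=np.float64), 0.0, 1.0)
    ell = (rng.random(p.shape[0]) < p).astype(np.float64)
    return _finalize(ell, S, gamma, cap)


def floor_solution(
    ell_lp: np.ndarray, S, gamma: float, cap: int, eps: float = 1e-9
) -> IntegralSolution:
    """Floor-round the fractional solution (values within ``eps`` of 1 are
    snapped up first).  Always feasible: sum(floor(ell)) <= sum(ell) <= cap."""
    x = np.clip(np.asarray(ell_lp, dtype=np.float64), 0.0, 1.0)
    x = np.where(x >= 1.0 - eps, 1.0, x)
    ell = np.floor(x)
    return _finalize(ell, S, gamma, cap)


def run_rr(
    relaxed: RelaxedSolution,
    S,
    opt_params: OptimizeParams = OptimizeParams(),
    rr_params: RRParams = RRParams(),
    rng: np.random.Generator | None = None,
) -> IntegralSolution:
    """Pick the best feasible candidate among N Bernoulli draws plus the
    floor-rounded fallback.

    Infeasible draws (budget violated) are discarded, not repaired; the
    floor candidate guarantees the feasible set is nonempty.  Ties on
    objective break toward fewer selected loci, then the earliest-generated
    candidate (floor first, then draws in order), so results are
    deterministic under a fixed seed.
    """
    n = relaxed.ell_lp.shape[0]
    cap = budget_cap(n, opt_params.b)
    if rng is None:
        rng = np.random.default_rng(rr_params.seed)
    best = floor_solution(
        relaxed.ell_lp, S, opt_params.gamma, cap, eps=opt_params.integrality_eps
    )
    for _ in range(rr_params.N):
        cand = draw_random_solution(relaxed.ell_lp, S, opt_params.gamma, cap, rng)
        if not cand.feasible:
            continue
        if cand.objective < best.objective or (
            cand.objective == best.objective and cand.n_selected < best.n_selected
        ):
            best = cand
    return best


def rounding_success_bound(n: int, b: float, a: float, c: float, N: int) -> float:
    """Lower bound on the probability that N rounding iterations contain a
    near-budget, near-optimal solution: ``1 - (1/c + exp(-2n(ab)^2))^N``.

    Requires a > 0 and c > 1.  If the hypothesis 1/c + exp(-2n(ab)^2) < 1
    fails, the bound is vacuous: returns 0.0 with a logged warning.
    """
    if a <= 0:
        raise ValueError("a must be > 0")
    if c <= 1:
        raise ValueError("c must be > 1")
    if n < 1 or not 0.0 < b < 1.0:
        raise ValueError("need n >= 1 and b in (0,1)")
    base = 1.0 / c + math.exp(-2.0 * n * (a * b) ** 2)
    if base >= 1.0:
        logger.warning(
            "bound hypothesis 1/c + exp(-2n(ab)^2) < 1 fails (base=%.6f); "
            "returning vacuous bound 0",
            base,
        )
        return 0.0
    return 1.0 - base**N


def chromosome_rng(seed: int, chrom: str) -> np.random.Generator:
    """Per-chromosome RNG stream: seeded from the run seed plus a stable
    hash of the chromosome name, so each chromosome's result is independent
    of processing order."""
    return np.random.default_rng([seed, zlib.crc32(chrom.encode())])
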