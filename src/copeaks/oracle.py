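"""Exhaustive small-instance solver of the integer selection program.

Test oracle only: enumerates all 2^n binary decision vectors (hard cap
n <= 20), filters by the budget, and evaluates the exact objective.  Tie
handling matches the rounding stage — fewest selected loci first, then
lexicographically smallest vector (first coordinate most significant).
Never used in the pipeline; exact integer solving is impractical at
genomic scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimize import budget_cap

__all__ = ["OracleResult", "brute_force_ip", "MAX_ORACLE_N"]

MAX_ORACLE_N = 20


@dataclass
class OracleResult:
    best_ell: np.ndarray
    best_objective: float
    num_feasible: int


def brute_force_ip(S, b: float, gamma: float) -> OracleResult:
    """Exact minimizer of the budgeted selection IP by full enumeration."""
    s = np.asarray(getattr(S, "S", S), dtype=np.float64)
    n = s.shape[0]
    if n > MAX_ORACLE_N:
        raise ValueError(
            f"brute-force oracle refuses n={n} > {MAX_ORACLE_N} (2^n enumeration)"
        )
    cap = budget_cap(n, b)

    best_obj = np.inf
    best_count = n + 1
    best_code = -1
    best_ell: np.ndarray | None = None
    num_feasible = 0

    # chunked enumeration keeps memory bounded at n=20
    total = 1 << n
    chunk = min(total, 1 << 16)
    # bit j of the code holds ell_{j+1}; lexicographic order of vectors is
    # ascending order of the code with ell_1 as the most significant bit
    weights = 1 << np.arange(n - 1, -1, -1, dtype=np.int64)
    for lo in range(0, total, chunk):
        codes = np.arange(lo, min(lo + chunk, total), dtype=np.int64)
        M = ((codes[:, None] & weights[None, :]) > 0).astype(np.float64)
        counts = M.sum(axis=1)
        feas = counts <= cap
        num_feasible += int(feas.sum())
        if not feas.any():
            continue
        Mf, cf, codef = M[feas], counts[feas], codes[feas]
        obj = -(Mf @ s)
        if n > 1 and gamma != 0:
            obj = obj + gamma * np.abs(np.diff(Mf, axis=1)).sum(axis=1)
        # ties: fewest selected, then lexicographically smallest vector
        order = np.lexsort((codef, cf, obj))
        j = order[0]
        key = (float(obj[j]), int(cf[j]), int(codef[j]))
        if key < (best_obj, best_count, best_code) or best_ell is None:
            best_obj, best_count, best_code = key
            best_ell = Mf[j].copy()

    assert best_ell is not None  # ell = 0 is always feasible
    return OracleResult(
        best_ell=best_ell, best_objective=best_obj, num_feasible=num_feasible
    )
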