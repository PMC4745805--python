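"""Independent brute-force oracles used to verify the implementation.

These deliberately use the most direct definition of each quantity —
exhaustive enumeration, closed-form formulas, pairwise counting — and share
no code with the package paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_force_digest(sequence: str, max_missed: int,
                       proline_restriction: bool) -> list[str]:
    """All peptides bounded by cleavage sites with <= max_missed internal
    sites, enumerated directly from the cleavage-site list."""
    sites = [
        i for i in range(1, len(sequence))
        if sequence[i - 1] in "KR"
        and not (proline_restriction and sequence[i] == "P")
    ]
    bounds = [0] + sites + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            peptides.append(sequence[bounds[i]:bounds[j]])
    return peptides


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose
    probability does not exceed the observed table's (with the standard
    1 + 1e-7 relative guard against floating-point ties).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def welch_closed_form(x, y) -> tuple[float, float, float]:
    """(t, df, p) from the textbook Welch formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pairwise_auc(control, patient) -> float:
    """Mann-Whitney AUC by direct pairwise comparison (ties count half)."""
    control = np.asarray(control, dtype=float)
    patient = np.asarray(patient, dtype=float)
    wins = (patient[:, None] > control[None, :]).sum()
    ties = (patient[:, None] == control[None, :]).sum()
    return float((wins + 0.5 * ties) / (control.size * patient.size))


def exhaustive_youden(control, patient) -> float:
    """Maximum J over every possible threshold (all midpoints and beyond)."""
    control = np.asarray(control, dtype=float)
    patient = np.asarray(patient, dtype=float)
    pooled = np.unique(np.concatenate([control, patient]))
    candidates = np.concatenate(
        [[-np.inf], (pooled[:-1] + pooled[1:]) / 2, pooled, [np.inf]])
    best = -np.inf
    for t in candidates:
        j = (patient > t).mean() + (control <= t).mean() - 1.0
        best = max(best, j)
    return float(best)
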