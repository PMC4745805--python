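"""Differential abundance between patient and control urinary-exosome proteomes.

Two complementary routes flag a protein as altered:

* **Presence/absence** — detection counts per group compared with a
  two-sided Fisher exact test (detection itself is informative because low
  abundances are censored at the instrument's detection limit).
* **Label-free quantification (LFQ)** — Welch's heteroscedastic two-sided
  t-test on per-sample abundances, run independently on the spectral-count
  (PSM) and Top3TIC channels; a protein is LFQ-significant only when both
  channels give p < alpha.

An orthogonal pooled-set iBAQ analysis validates candidates: each group's
samples are pooled into three sets, control pools are normalised to the
patient-pool total, and a protein's patient:control iBAQ ratio is tested
with a two-sided t-test across pools.  A protein present in at most one of
a group's three pools is marked invalid (single-pool observations are not
trustworthy for a ratio).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .quantify import CONTROL, PATIENT, ProteinQuantMatrix

UP = "up"
DOWN = "down"
NONE = "none"


@lru_cache(maxsize=100_000)
def presence_fisher_test(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Rows are groups, columns detected/absent.  Two-sided extremeness is by
    probability ordering: the p-value sums hypergeometric probabilities of
    all tables (at fixed margins) no more probable than the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("Fisher table entries must be non-negative integers")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sided t-test (unequal variances).

    Returns ``(t, p)`` with Welch-Satterthwaite degrees of freedom.  When
    both groups are exactly constant the test is undefined; by convention
    p = 1 for equal means (no evidence of change) and p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def dual_channel_significance(p_psm: float, p_top3: float,
                              alpha: float = 0.05) -> bool:
    """True iff both channel p-values are strictly below ``alpha``."""
    for p in (p_psm, p_top3):
        if not 0 <= p <= 1:
            raise ValueError("p-values must lie in [0, 1]")
    return bool(p_psm < alpha and p_top3 < alpha)


def fold_change_ratio(control_values: Sequence[float],
                      patient_values: Sequence[float]) -> float:
    """Patient:control ratio of group means.

    Returns ``inf`` for patient-unique proteins (control mean 0, patient
    mean > 0) and 1.0 when both means are 0.
    """
    c = float(np.mean(np.asarray(control_values, dtype=float)))
    p = float(np.mean(np.asarray(patient_values, dtype=float)))
    if c < 0 or p < 0:
        raise ValueError("abundances must be >= 0")
    if c == 0:
        return np.inf if p > 0 else 1.0
    return p / c


def _pool_validity(n_control_present: int, n_patient_present: int) -> bool:
    """Single-pool observations are untrustworthy; group absence is not.

    A protein seen in exactly 1 of a group's 3 pools is invalid (one
    observation cannot support a ratio for that group).  Presence in 0 of 3
    pools is a different statement — the protein is absent from that group
    (the patient- or control-unique case, ratio +/-infinity) — and remains
    valid provided the other group shows it in at least 2 pools.
    """
    counts = (n_control_present, n_patient_present)
    if 1 in counts:
        return False
    return max(counts) >= 2


def ibaq_pool_validation(
    control_pools: Sequence[float],
    patient_pools: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Ratio, p-value and validity flag from pooled-set iBAQ triplicates.

    Pools are assumed already normalised to the reference (patient-pool)
    total.  The ratio is mean(patient)/mean(control), +infinity for
    patient-unique proteins; the p-value is a two-sided t-test across the
    pool triplicates; validity follows the single-pool rule above.
    """
    c = np.asarray(control_pools, dtype=float)
    p = np.asarray(patient_pools, dtype=float)
    if c.size != 3 or p.size != 3:
        raise ValueError("expected exactly 3 pooled sets per group")
    ratio = fold_change_ratio(c, p)
    _, pval = welch_t_test(p, c)
    valid = _pool_validity(int((c > 0).sum()), int((p > 0).sum()))
    return ratio, pval, valid


def anchored_log_transform(values: pd.DataFrame | np.ndarray,
                           floor: float | None = None) -> np.ndarray:
    """log10 transform anchored so non-detected zeros stay at zero.

    Detected values are mapped to ``log10(v / floor)`` with the floor set to
    half the smallest positive value in the table, so every detected value
    is strictly positive after transformation and censored zeros remain 0.
    This keeps presence/absence informative inside the t-tests while taming
    the orders-of-magnitude skew of raw intensities.
    """
    arr = np.asarray(values, dtype=float)
    pos = arr[arr > 0]
    if pos.size == 0:
        return np.zeros_like(arr)
    if floor is None:
        floor = float(pos.min()) / 2.0
    out = np.zeros_like(arr)
    mask = arr > 0
    out[mask] = np.log10(arr[mask] / floor)
    return out


def _vector_welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch test on 2-D arrays; degenerate rows get the convention."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    va = a.std(axis=1, ddof=1)
    vb = b.std(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    same = degenerate & (a.mean(axis=1) == b.mean(axis=1))
    diff = degenerate & ~same
    p[same] = 1.0
    t[same] = 0.0
    p[diff] = 0.0
    t[diff] = np.where(a.mean(axis=1)[diff] > b.mean(axis=1)[diff], np.inf, -np.inf)
    return t, p


class DifferentialAnalyzer(BaseEstimator):
    """Per-protein differential testing across a labelled cohort.

    Parameters
    ----------
    alpha : significance level for every test (strict ``p < alpha``).
    log_transform : apply the anchored log10 transform to PSM/Top3 values
        before the Welch tests (recommended for intensity-scale data).
    zero_policy : ``"zero"`` keeps non-detected samples as 0 in the tests
        (presence differences contribute to the statistic); ``"exclude"``
        drops them (requires >= 2 detected per group, else p = NaN).

    Attributes (after :meth:`fit`)
    ------------------------------
    results_ : DataFrame indexed by accession with detection counts, Fisher
        and Welch p-values (plus Benjamini-Hochberg q-values for modern
        use; they gate nothing), fold changes, iBAQ ratio/p/validity, the
        dual-channel ``lfq_significant`` flag, the joint
        ``lfq_and_ibaq_significant`` flag (focus-list criterion), the union
        ``significantly_altered`` flag, and the change ``direction``.
    """

    def __init__(self, alpha: float = 0.05, log_transform: bool = True,
                 zero_policy: str = "zero"):
        self.alpha = alpha
        self.log_transform = log_transform
        self.zero_policy = zero_policy

    # -- internals ---------------------------------------------------------

    def _channel_pvalues(self, matrix: ProteinQuantMatrix) -> np.ndarray:
        ctr = matrix.group_columns(CONTROL).to_numpy()
        pat = matrix.group_columns(PATIENT).to_numpy()
        if self.log_transform:
            floor = None
            joint = np.concatenate([ctr, pat], axis=1)
            pos = joint[joint > 0]
            if pos.size:
                floor = float(pos.min()) / 2.0
            ctr = anchored_log_transform(ctr, floor)
            pat = anchored_log_transform(pat, floor)
        if self.zero_policy == "zero":
            _, p = _vector_welch(pat, ctr)
            return p
        if self.zero_policy != "exclude":
            raise ValueError(f"unknown zero_policy {self.zero_policy!r}")
        out = np.full(ctr.shape[0], np.nan)
        for i in range(ctr.shape[0]):
            c = ctr[i][ctr[i] > 0]
            q = pat[i][pat[i] > 0]
            if c.size >= 2 and q.size >= 2:
                out[i] = welch_t_test(q, c)[1]
        return out

    def fit(self, psm: ProteinQuantMatrix, top3: ProteinQuantMatrix,
            ibaq_pools: ProteinQuantMatrix | None = None,
            y=None) -> "DifferentialAnalyzer":
        """Run all tests.  ``psm``/``top3`` are sample-level matrices with
        identical protein and sample axes; ``ibaq_pools`` holds the raw 3+3
        pooled-set iBAQ values (normalised internally to the patient total).
        """
        if not psm.proteins.equals(top3.proteins):
            raise ValueError("PSM and Top3 matrices must share the protein axis")
        if list(psm.samples) != list(top3.samples):
            raise ValueError("PSM and Top3 matrices must share the sample axis")
        proteins = psm.proteins
        n_ctr = int((psm.groups == CONTROL).sum())
        n_pat = int((psm.groups == PATIENT).sum())

        detected = (psm.detected | top3.detected)
        det_ctr = detected.loc[:, psm.groups == CONTROL].sum(axis=1).to_numpy()
        det_pat = detected.loc[:, psm.groups == PATIENT].sum(axis=1).to_numpy()

        fisher_p = np.array([
            presence_fisher_test(int(a), n_ctr - int(a), int(c), n_pat - int(c))
            for a, c in zip(det_ctr, det_pat)
        ])

        p_psm = self._channel_pvalues(psm)
        p_top3 = self._channel_pvalues(top3)
        lfq_sig = (p_psm < self.alpha) & (p_top3 < self.alpha)

        def _fc(matrix: ProteinQuantMatrix) -> np.ndarray:
            cmean = matrix.group_columns(CONTROL).mean(axis=1).to_numpy()
            pmean = matrix.group_columns(PATIENT).mean(axis=1).to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(cmean > 0, pmean / cmean,
                                np.where(pmean > 0, np.inf, 1.0))

        fc_psm = _fc(psm)
        fc_top3 = _fc(top3)

        ibaq_ratio = np.full(len(proteins), np.nan)
        ibaq_p = np.full(len(proteins), np.nan)
        ibaq_valid = np.zeros(len(proteins), dtype=bool)
        if ibaq_pools is not None:
            from .quantify import normalize_to_reference_total

            pat_totals = ibaq_pools.group_columns(PATIENT).sum(axis=0)
            reference = float(pat_totals.mean())
            pools = normalize_to_reference_total(ibaq_pools, reference)
            pools_aligned = pools.values.reindex(proteins).fillna(0.0)
            cpool = pools_aligned.loc[:, pools.groups == CONTROL].to_numpy()
            ppool = pools_aligned.loc[:, pools.groups == PATIENT].to_numpy()
            _, ibaq_p = _vector_welch(ppool, cpool)
            cmean = cpool.mean(axis=1)
            pmean = ppool.mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ibaq_ratio = np.where(
                    cmean > 0, pmean / cmean,
                    np.where(pmean > 0, np.inf, 1.0),
                )
            c_present = (cpool > 0).sum(axis=1)
            p_present = (ppool > 0).sum(axis=1)
            ibaq_valid = np.array([
                _pool_validity(int(a), int(b))
                for a, b in zip(c_present, p_present)
            ])

        ratio_for_dir = np.where(np.isfinite(ibaq_ratio) | np.isinf(ibaq_ratio),
                                 ibaq_ratio, fc_top3)
        direction = np.where(ratio_for_dir > 1, UP,
                             np.where(ratio_for_dir < 1, DOWN, NONE))

        lfq_and_ibaq = lfq_sig & ibaq_valid & (ibaq_p < self.alpha)
        altered = lfq_sig | (fisher_p < self.alpha)

        res = pd.DataFrame({
            "control_detected": det_ctr,
            "patient_detected": det_pat,
            "n_control": n_ctr,
            "n_patient": n_pat,
            "fisher_p": fisher_p,
            "welch_p_psm": p_psm,
            "welch_p_top3": p_top3,
            "fold_change_psm": fc_psm,
            "fold_change_top3": fc_top3,
            "lfq_significant": lfq_sig,
            "ibaq_ratio": ibaq_ratio,
            "ibaq_p": ibaq_p,
            "ibaq_valid": ibaq_valid,
            "lfq_and_ibaq_significant": lfq_and_ibaq,
            "significantly_altered": altered,
            "direction": direction,
        }, index=proteins)
        for col in ("fisher_p", "welch_p_psm", "welch_p_top3"):
            pvals = res[col].to_numpy(dtype=float)
            ok = np.isfinite(pvals)
            q = np.full_like(pvals, np.nan)
            if ok.sum():
                q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
            res[col.replace("_p", "_q")] = q
        self.results_ = res
        self.n_control_ = n_ctr
        self.n_patient_ = n_pat
        return self
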