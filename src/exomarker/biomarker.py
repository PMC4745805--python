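"""Diagnostic evaluation of candidate protein markers.

Each protein is treated as a single-analyte diagnostic test: a sample is
called positive when its abundance is *strictly above* a threshold.  Two
operating points are computed per marker:

* the **full-specificity threshold** — the maximum observed control value,
  so every control in the discovery cohort scores negative (specificity is
  exactly 1 by construction).  When a protein is undetected in all controls
  the threshold is 0 and positivity reduces to detection itself.
* the **Youden threshold** — the cut-off maximising Youden's
  J = sensitivity + specificity - 1 over all candidate thresholds.

The full ROC staircase and its trapezoidal AUC (equal to the Mann-Whitney
probability that a random patient outscores a random control, ties counting
half) are produced per marker, along with panel combinations: the OR rule
(positive on any marker at its full-specificity threshold) and a pooled
rank score (mean of within-cohort empirical quantiles) whose AUC measures
multi-marker discrimination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted


# --------------------------------------------------------------------------
# scalar operations
# --------------------------------------------------------------------------

def full_specificity_threshold(control_values: Sequence[float]) -> float:
    """Detection threshold at which every control sample is negative.

    Positivity is value > threshold, so the threshold is the control
    maximum.  All-undetected controls give threshold 0: the marker's mere
    detection is then the positive call.
    """
    arr = np.asarray(list(control_values), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one control value is required")
    return float(arr.max())


def round_percent(fraction: float) -> int:
    """Percent rounded half away from zero (62.5 -> 63, 68.75 -> 69)."""
    return int(math.floor(abs(fraction) * 100 + 0.5)) * (1 if fraction >= 0 else -1)


def sensitivity_at_full_specificity(
    patient_values: Sequence[float], threshold: float, n_patient: int | None = None
) -> tuple[float, int, int]:
    """(fraction, positive count, rounded percent) of patients above threshold."""
    arr = np.asarray(list(patient_values), dtype=float)
    if n_patient is None:
        n_patient = arr.size
    if n_patient < 1:
        raise ValueError("n_patient must be >= 1")
    count = int((arr > threshold).sum())
    fraction = count / n_patient
    return fraction, count, round_percent(fraction)


def _candidate_thresholds(pooled: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct pooled values, plus +/-inf."""
    distinct = np.unique(pooled)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def youden_threshold(control_values: Sequence[float],
                     patient_values: Sequence[float]) -> tuple[float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct pooled values plus
    infinite sentinels; ties in J break toward the higher threshold (the
    more specific operating point).
    """
    ctr = np.asarray(list(control_values), dtype=float)
    pat = np.asarray(list(patient_values), dtype=float)
    if ctr.size == 0 or pat.size == 0:
        raise ValueError("both groups must be non-empty")
    best_t, best_j = -np.inf, -np.inf
    for t in _candidate_thresholds(np.concatenate([ctr, pat])):
        sens = float((pat > t).mean())
        spec = float((ctr <= t).mean())
        j = sens + spec - 1.0
        if j >= best_j:  # >= so ties move toward higher thresholds
            best_t, best_j = t, j
    return float(best_t), float(best_j)


def roc_points(control_values: Sequence[float],
               patient_values: Sequence[float]) -> list[tuple[float, float]]:
    """ROC staircase: (1 - specificity, sensitivity) per distinct threshold.

    Thresholds are the distinct observed values plus infinite sentinels;
    positivity is value > threshold.  Points are sorted from (0, 0) to
    (1, 1).
    """
    ctr = np.asarray(list(control_values), dtype=float)
    pat = np.asarray(list(patient_values), dtype=float)
    if ctr.size == 0 or pat.size == 0:
        raise ValueError("both groups must be non-empty")
    thresholds = np.concatenate(
        ([-np.inf], np.unique(np.concatenate([ctr, pat])), [np.inf]))
    pts = {(float((ctr > t).mean()), float((pat > t).mean()))
           for t in thresholds}
    return sorted(pts)


def auc(control_values: Sequence[float],
        patient_values: Sequence[float]) -> float:
    """Trapezoidal area under the ROC staircase.

    Equals the Mann-Whitney statistic over n_control * n_patient: the
    probability a random patient value exceeds a random control value, with
    ties contributing one half.
    """
    pts = roc_points(control_values, patient_values)
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


def combine_markers_or_rule(
    thresholds: Mapping[str, float],
    patient_values: Mapping[str, Sequence[float]],
    control_values: Mapping[str, Sequence[float]],
) -> tuple[float, float]:
    """Panel sensitivity/specificity under the any-marker-positive rule.

    A sample is positive when positive on *any* marker at that marker's
    full-specificity threshold.  On the thresholds' defining controls the
    panel specificity remains exactly 1.
    """
    markers = list(thresholds)
    if len(markers) < 2:
        raise ValueError("a panel needs at least 2 markers")
    n_pat = {len(patient_values[m]) for m in markers}
    n_ctr = {len(control_values[m]) for m in markers}
    if len(n_pat) != 1 or len(n_ctr) != 1:
        raise ValueError("markers must be measured on the same samples")
    pat = np.vstack([np.asarray(patient_values[m], dtype=float) for m in markers])
    ctr = np.vstack([np.asarray(control_values[m], dtype=float) for m in markers])
    th = np.array([thresholds[m] for m in markers])[:, None]
    pat_pos = (pat > th).any(axis=0)
    ctr_pos = (ctr > th).any(axis=0)
    return float(pat_pos.mean()), float(1.0 - ctr_pos.mean())


def combined_rank_score_auc(
    marker_values: Mapping[str, Sequence[float]],
    labels: Sequence[int],
) -> float:
    """AUC of the mean-of-quantiles panel score.

    Each marker's values are converted to empirical quantiles within the
    whole cohort (average ranks over n, so ties share a quantile); the
    panel score is the mean quantile across markers, and its AUC is
    computed with the usual tie-half convention.
    """
    labels = np.asarray(labels)
    if len(marker_values) < 2:
        raise ValueError("a panel needs at least 2 markers")
    quantiles = []
    for m, vals in marker_values.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size != labels.size:
            raise ValueError(f"marker {m!r} has {vals.size} values for "
                             f"{labels.size} labels")
        quantiles.append(stats.rankdata(vals) / vals.size)
    score = np.mean(quantiles, axis=0)
    return auc(score[labels == 0], score[labels == 1])


# --------------------------------------------------------------------------
# focus list
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FocusCriteria:
    """The three-way filter selecting focus-list biomarker candidates.

    alpha : significance level already applied upstream (documentation
        value; the significance flags are consumed as booleans).
    min_sensitivity : minimum sensitivity at the full-specificity
        threshold (fraction, inclusive).
    min_fold_change : minimum effect size, measured symmetrically as
        max(ratio, 1/ratio) (inclusive, so a printed 1.75 or its downward
        mirror 0.57 qualifies).
    """

    alpha: float = 0.05
    min_sensitivity: float = 0.50
    min_fold_change: float = 1.75

    def __post_init__(self) -> None:
        if not (0 < self.alpha and 0 < self.min_sensitivity <= 1
                and self.min_fold_change > 0):
            raise ValueError("criteria must be strictly positive "
                             "(min_sensitivity <= 1)")


def symmetric_effect(ratio: float) -> float:
    """Fold change regardless of direction: max(ratio, 1/ratio)."""
    if ratio <= 0:
        return np.inf if ratio == 0 else np.nan
    if np.isinf(ratio):
        return np.inf
    return max(ratio, 1.0 / ratio)


def focus_list_filter(results: pd.DataFrame,
                      criteria: FocusCriteria | None = None) -> pd.DataFrame:
    """Apply the three focus-list criteria and order the survivors.

    ``results`` joins differential and marker evaluations per accession and
    must contain ``lfq_and_ibaq_significant``, ``sensitivity_full_spec``
    and ``ibaq_ratio``.  Keeps proteins that are (i) significant in both
    the LFQ and iBAQ analyses, (ii) at least ``min_sensitivity`` sensitive
    at the full-specificity threshold, and (iii) changed at least
    ``min_fold_change``-fold in either direction; sorts by sensitivity then
    effect, both descending.
    """
    criteria = criteria or FocusCriteria()
    required = ["lfq_and_ibaq_significant", "sensitivity_full_spec", "ibaq_ratio"]
    missing = [c for c in required if c not in results.columns]
    if missing:
        raise KeyError(f"results table lacks columns: {missing}")
    effect = results["ibaq_ratio"].map(symmetric_effect)
    keep = (
        results["lfq_and_ibaq_significant"].astype(bool)
        & (results["sensitivity_full_spec"] >= criteria.min_sensitivity)
        & (effect >= criteria.min_fold_change)
    )
    out = results.loc[keep].copy()
    out["effect"] = effect[keep]
    return out.sort_values(["sensitivity_full_spec", "effect"],
                           ascending=[False, False])


def exclusion_filter(candidates: pd.DataFrame,
                     confounder_set: set[str]) -> tuple[pd.DataFrame, list[str]]:
    """Drop candidates whose accession is in a confounder set.

    Used to remove proteins whose levels vary for reasons unrelated to
    disease (e.g. proteins differing between first and second morning urine
    voids).  Returns the filtered table and the list of removed accessions.
    """
    removed = [acc for acc in candidates.index if acc in confounder_set]
    return candidates.drop(index=removed), removed


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

class MarkerEvaluator(BaseEstimator, TransformerMixin):
    """Evaluate every protein column as a single-analyte diagnostic test.

    Parameters
    ----------
    threshold : ``"full_specificity"`` (control maximum) or ``"youden"``
        (J-maximising cut-off) — the operating point used by
        :meth:`transform` for positivity calls.

    Attributes (after ``fit(X, y)`` with X samples x proteins, y in {0, 1};
    1 = patient)
    -----------------------------------------------------------------------
    results_ : per-marker DataFrame with ``threshold_full_spec``,
        ``sensitivity_full_spec``, ``n_patients_positive``,
        ``percent_sensitivity``, ``threshold_youden``, ``youden_j``, ``auc``.
    roc_ : accession -> list of (1 - specificity, sensitivity) points.
    """

    def __init__(self, threshold: str = "full_specificity"):
        self.threshold = threshold

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary with 1 = patient")
        if X.shape[0] != y.size:
            raise ValueError("X rows and y length differ")
        ctr = X.loc[y == 0]
        pat = X.loc[y == 1]
        if ctr.empty or pat.empty:
            raise ValueError("both groups must be represented in y")
        rows = []
        self.roc_ = {}
        for acc in X.columns:
            c = ctr[acc].to_numpy(dtype=float)
            p = pat[acc].to_numpy(dtype=float)
            th = full_specificity_threshold(c)
            frac, count, pct = sensitivity_at_full_specificity(p, th)
            yt, j = youden_threshold(c, p)
            self.roc_[acc] = roc_points(c, p)
            rows.append({
                "protein_accession": acc,
                "threshold_full_spec": th,
                "sensitivity_full_spec": frac,
                "n_patients_positive": count,
                "percent_sensitivity": pct,
                "threshold_youden": yt,
                "youden_j": j,
                "auc": auc(c, p),
            })
        self.results_ = pd.DataFrame(rows).set_index("protein_accession")
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def _thresholds(self) -> pd.Series:
        if self.threshold == "full_specificity":
            return self.results_["threshold_full_spec"]
        if self.threshold == "youden":
            return self.results_["threshold_youden"]
        raise ValueError(f"unknown threshold strategy {self.threshold!r}")

    def transform(self, X) -> pd.DataFrame:
        """Binary positivity calls (samples x markers) at the chosen
        threshold — the biomarker heat-map matrix."""
        check_is_fitted(self, "results_")
        X = pd.DataFrame(X)
        th = self._thresholds().reindex(X.columns)
        if th.isna().any():
            raise ValueError("X contains markers not seen during fit")
        return X.gt(th, axis=1)


def biomarker_heatmap_matrix(evaluator: MarkerEvaluator,
                             X) -> pd.DataFrame:
    """Sample x marker positivity table at the evaluator's threshold."""
    return evaluator.transform(X)


class OrRulePanel(BaseEstimator, ClassifierMixin):
    """Multi-marker panel classifier: positive on any marker.

    ``fit(X, y)`` learns each marker's full-specificity threshold from the
    controls in ``X`` (y = 0); ``predict`` calls a sample positive when any
    marker exceeds its threshold.  By construction the panel keeps
    specificity 1 on the defining controls while sensitivity is at least
    that of every member marker.
    """

    def __init__(self, markers: Sequence[str] | None = None):
        self.markers = markers

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        cols = list(self.markers) if self.markers is not None else list(X.columns)
        missing = [m for m in cols if m not in X.columns]
        if missing:
            raise ValueError(f"markers absent from X: {missing}")
        ctr = X.loc[y == 0, cols]
        if ctr.empty:
            raise ValueError("no control samples (y == 0) to set thresholds")
        self.thresholds_ = ctr.max(axis=0)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        pat = X.loc[y == 1, cols]
        self.sensitivity_ = (
            float(pat.gt(self.thresholds_, axis=1).any(axis=1).mean())
            if not pat.empty else np.nan
        )
        self.specificity_ = float(
            1.0 - ctr.gt(self.thresholds_, axis=1).any(axis=1).mean())
        return self

    def predict(self, X):
        check_is_fitted(self, "thresholds_")
        X = pd.DataFrame(X)
        cols = list(self.thresholds_.index)
        return X[cols].gt(self.thresholds_, axis=1).any(axis=1).to_numpy().astype(int)
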