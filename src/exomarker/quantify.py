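"""Protein-level quantification from identified-peptide evidence.

Three label-free channels are produced per run, then aggregated per sample:

* **PSM** — spectral counts: number of peptide-spectrum matches assigned to
  a protein's peptides; a semi-quantitative abundance proxy.
* **Top3TIC** — mean precursor intensity of the protein's three most intense
  peptides (total-ion-chromatogram scale).
* **iBAQ** — summed peptide precursor intensity divided by the number of
  theoretically observable tryptic peptides (see :mod:`exomarker.digest`),
  giving an absolute-abundance scale comparable across proteins.

Column normalisation (all channels) rescales each sample to a common total
so that per-sample composition, not injected amount, is compared; the ppm
view expresses every protein as parts-per-million of its sample's total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

CHANNELS = ("psm", "top3tic", "ibaq")

EVIDENCE_COLUMNS = [
    "peptide_sequence",
    "protein_accession",
    "sample_id",
    "run_id",
    "precursor_intensity",
    "spectrum_count",
]

CONTROL = "control"
PATIENT = "patient"


@dataclass
class CohortDesign:
    """Sample -> group assignment plus the run (technical replicate) map.

    ``samples``: DataFrame with columns ``sample_id``, ``group``
    (control|patient).  ``runs``: DataFrame with columns ``run_id``,
    ``sample_id``; every run belongs to exactly one sample.
    """

    samples: pd.DataFrame
    runs: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        bad = set(self.samples["group"]) - {CONTROL, PATIENT}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.runs is None:
            self.runs = pd.DataFrame(
                {"run_id": self.samples["sample_id"],
                 "sample_id": self.samples["sample_id"]}
            )
        if self.runs["run_id"].duplicated().any():
            raise ValueError("duplicate run_id in design")
        unknown = set(self.runs["sample_id"]) - set(self.samples["sample_id"])
        if unknown:
            raise ValueError(f"runs reference unknown samples: {sorted(unknown)}")

    @property
    def group_of(self) -> pd.Series:
        return self.samples.set_index("sample_id")["group"]

    @property
    def sample_of_run(self) -> pd.Series:
        return self.runs.set_index("run_id")["sample_id"]

    def sample_ids(self, group: str | None = None) -> list[str]:
        tbl = self.samples
        if group is not None:
            tbl = tbl[tbl["group"] == group]
        return list(tbl["sample_id"])


@dataclass
class ProteinQuantMatrix:
    """Proteins x samples (or runs/pools) table for one quantification channel.

    ``values`` is non-negative; a value of 0 means not detected.  ``groups``
    maps each column to control/patient.
    """

    values: pd.DataFrame
    channel: str
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.values = self.values.rename_axis(index="protein_accession",
                                              columns=None)
        if self.values.index.duplicated().any():
            raise ValueError("duplicate protein accessions")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample columns")
        vals = self.values.to_numpy()
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("matrix values must be finite and >= 0")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"columns without group label: {missing}")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean detection flags; detected iff the stored value is nonzero."""
        return self.values > 0

    def group_columns(self, group: str) -> pd.DataFrame:
        return self.values.loc[:, self.groups == group]

    def copy_with(self, values: pd.DataFrame) -> "ProteinQuantMatrix":
        return ProteinQuantMatrix(values=values, channel=self.channel,
                                  groups=self.groups.copy())


def top3_tic(intensities: Iterable[float], k: int = 3,
             aggregator: str = "mean") -> float:
    """Protein abundance from its ``k`` most intense peptides.

    Mean of the top-``k`` peptide precursor intensities; with fewer than
    ``k`` peptides, the mean of those present; 0 with no evidence.  The
    aggregator is configurable (``"mean"`` or ``"sum"``) because the field
    uses both dialects; the pipeline default is the mean.
    """
    arr = np.sort(np.asarray(list(intensities), dtype=float))[::-1][:k]
    if arr.size == 0:
        return 0.0
    if np.any(arr < 0):
        raise ValueError("peptide intensities must be >= 0")
    if aggregator == "mean":
        return float(arr.mean())
    if aggregator == "sum":
        return float(arr.sum())
    raise ValueError(f"unknown aggregator {aggregator!r}")


def ibaq_intensity(total_protein_intensity: float,
                   observable_count: int) -> float:
    """iBAQ: summed peptide intensity over the observable-peptide count."""
    if total_protein_intensity < 0:
        raise ValueError("total intensity must be >= 0")
    if observable_count == 0:
        raise ZeroDivisionError(
            "protein has no observable tryptic peptides; iBAQ undefined"
        )
    return total_protein_intensity / observable_count


def _dedupe_peptides(evidence: pd.DataFrame) -> pd.DataFrame:
    """One intensity per peptide sequence: max over duplicate observations.

    Multiple rows of the same sequence in one run (charge states, repeated
    identifications) collapse to their maximum precursor intensity; spectral
    counts, in contrast, accumulate over all rows.
    """
    return (
        evidence.groupby("peptide_sequence", sort=False)["precursor_intensity"]
        .max()
        .reset_index()
    )


def quantify_evidence(
    evidence: pd.DataFrame,
    design: CohortDesign,
    observable_counts: Mapping[str, int] | None = None,
    top3_aggregator: str = "mean",
) -> dict[str, ProteinQuantMatrix]:
    """Run-level quantification matrices from a peptide-evidence table.

    Returns ``{"psm": ..., "top3tic": ...}`` and, when ``observable_counts``
    (accession -> observable-peptide count) is given, ``"ibaq"`` as well.
    Columns are run ids; aggregate with :func:`aggregate_replicates` to get
    per-sample matrices.
    """
    missing = [c for c in EVIDENCE_COLUMNS if c not in evidence.columns]
    if missing:
        raise ValueError(f"evidence table lacks columns: {missing}")
    if (evidence["precursor_intensity"] < 0).any():
        raise ValueError("negative precursor intensity in evidence")
    if (evidence["spectrum_count"] < 0).any():
        raise ValueError("negative spectrum count in evidence")
    sample_of_run = design.sample_of_run
    unknown_runs = set(evidence["run_id"]) - set(sample_of_run.index)
    if unknown_runs:
        raise ValueError(f"evidence references unknown runs: {sorted(unknown_runs)}")

    run_ids = list(design.runs["run_id"])
    proteins = pd.Index(sorted(evidence["protein_accession"].unique()))
    psm = pd.DataFrame(0.0, index=proteins, columns=run_ids)
    top3 = pd.DataFrame(0.0, index=proteins, columns=run_ids)
    total = pd.DataFrame(0.0, index=proteins, columns=run_ids)

    for (acc, run), chunk in evidence.groupby(
            ["protein_accession", "run_id"], sort=False):
        peps = _dedupe_peptides(chunk)
        psm.loc[acc, run] = float(chunk["spectrum_count"].sum())
        top3.loc[acc, run] = top3_tic(peps["precursor_intensity"],
                                      aggregator=top3_aggregator)
        total.loc[acc, run] = float(peps["precursor_intensity"].sum())

    run_groups = sample_of_run.map(design.group_of).reindex(run_ids)
    out = {
        "psm": ProteinQuantMatrix(psm, "psm", run_groups),
        "top3tic": ProteinQuantMatrix(top3, "top3tic", run_groups),
    }
    if observable_counts is not None:
        counts = pd.Series(observable_counts).reindex(proteins)
        if counts.isna().any():
            missing_accs = list(counts.index[counts.isna()])
            raise ValueError(
                f"no observable-peptide count for: {missing_accs[:5]}"
                + ("..." if len(missing_accs) > 5 else "")
            )
        if (counts == 0).any():
            zero = list(counts.index[counts == 0])
            raise ZeroDivisionError(
                f"proteins with zero observable peptides: {zero[:5]}"
            )
        ibaq = total.div(counts.astype(float), axis=0)
        out["ibaq"] = ProteinQuantMatrix(ibaq, "ibaq", run_groups)
    return out


def aggregate_replicates(matrix: ProteinQuantMatrix,
                         design: CohortDesign) -> ProteinQuantMatrix:
    """Collapse run-level columns to per-sample means.

    A protein counts as detected in a sample when detected in at least one
    of its runs — which the mean preserves, since values are non-negative.
    """
    sample_of_run = design.sample_of_run
    unknown = set(matrix.samples) - set(sample_of_run.index)
    if unknown:
        raise ValueError(f"matrix has runs absent from design: {sorted(unknown)}")
    mapped = matrix.values.T.groupby(sample_of_run.reindex(matrix.samples)).mean().T
    order = [s for s in design.sample_ids() if s in mapped.columns]
    mapped = mapped[order]
    groups = design.group_of.reindex(mapped.columns)
    return ProteinQuantMatrix(mapped, matrix.channel, groups)


def normalize_to_reference_total(
    matrix: ProteinQuantMatrix, reference_total: float
) -> ProteinQuantMatrix:
    """Rescale every sample column so its total equals ``reference_total``.

    Within-column ratios are preserved; this is the total-abundance
    normalisation used before comparing compositions across samples (e.g.
    pooled-set iBAQ values normalised to the patient-pool total).
    """
    if reference_total <= 0:
        raise ValueError("reference_total must be > 0")
    totals = matrix.values.sum(axis=0)
    zero_cols = list(totals.index[totals == 0])
    if zero_cols:
        raise ValueError(f"all-zero sample columns cannot be normalised: {zero_cols}")
    return matrix.copy_with(matrix.values * (reference_total / totals))


def ppm_abundance(matrix: ProteinQuantMatrix) -> pd.DataFrame:
    """Each value as parts-per-million of its sample-column total."""
    totals = matrix.values.sum(axis=0)
    zero_cols = list(totals.index[totals == 0])
    if zero_cols:
        raise ValueError(f"all-zero sample columns: {zero_cols}")
    return matrix.values * (1e6 / totals)


class TotalAbundanceNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: rescale each sample row to a common total.

    Operates on the samples x proteins orientation used by the estimator
    layer.  ``reference_total=None`` uses the median row total of the
    fitted data, mirroring normalisation to a designated reference sample.
    """

    def __init__(self, reference_total: float | None = None):
        self.reference_total = reference_total

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x proteins array")
        totals = X.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("samples with non-positive totals cannot be normalised")
        self.reference_total_ = (
            float(np.median(totals))
            if self.reference_total is None
            else float(self.reference_total)
        )
        if self.reference_total_ <= 0:
            raise ValueError("reference_total must be > 0")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "reference_total_")
        df = isinstance(X, pd.DataFrame)
        index = columns = None
        if df:
            index, columns = X.index, X.columns
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("samples with non-positive totals cannot be normalised")
        out = X * (self.reference_total_ / totals)
        if df:
            return pd.DataFrame(out, index=index, columns=columns)
        return out
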