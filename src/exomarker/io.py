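"""File formats, dataset-overlap analyses, abundance summaries and the
end-to-end pipeline driver.

All tabular formats are UTF-8 TSV with mandatory headers; missing values
are empty fields; accessions are opaque strings.  Rounding for display
happens only here, at the reporting layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .biomarker import (
    FocusCriteria,
    MarkerEvaluator,
    OrRulePanel,
    exclusion_filter,
    focus_list_filter,
)
from .differential import DifferentialAnalyzer
from .quantify import (
    CONTROL,
    PATIENT,
    CohortDesign,
    ProteinQuantMatrix,
    aggregate_replicates,
    quantify_evidence,
)

logger = logging.getLogger("exomarker")


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Accession -> sequence; the accession is the first whitespace-delimited
    token of the FASTA header."""
    out = {}
    for record in SeqIO.parse(str(path), "fasta"):
        out[record.id.split()[0]] = str(record.seq).upper()
    return out


def write_fasta_sequences(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_evidence_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={
        "peptide_sequence": str, "protein_accession": str,
        "sample_id": str, "run_id": str,
    })
    from .quantify import EVIDENCE_COLUMNS

    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: evidence TSV lacks columns {missing}")
    return df


def write_evidence_tsv(evidence: pd.DataFrame, path: str | Path) -> None:
    evidence.to_csv(path, sep="\t", index=False)


def write_design_tsv(design: CohortDesign, path: str | Path) -> None:
    runs_of = design.runs.groupby("sample_id")["run_id"].apply(
        lambda r: ",".join(r))
    tbl = design.samples.copy()
    tbl["runs"] = tbl["sample_id"].map(runs_of)
    tbl.to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> CohortDesign:
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    run_rows = []
    for _, row in tbl.iterrows():
        runs = row.get("runs")
        run_ids = (str(runs).split(",") if isinstance(runs, str) and runs
                   else [row["sample_id"]])
        for rid in run_ids:
            run_rows.append({"run_id": rid, "sample_id": row["sample_id"]})
    return CohortDesign(samples=tbl[["sample_id", "group"]],
                        runs=pd.DataFrame(run_rows))


def write_matrix_tsv(matrix: ProteinQuantMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_accession"
    out.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path, channel: str,
                    groups: pd.Series) -> ProteinQuantMatrix:
    values = pd.read_csv(path, sep="\t", index_col="protein_accession")
    return ProteinQuantMatrix(values, channel, groups)


# --------------------------------------------------------------------------
# protein-set overlap
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinSet:
    """A named set of protein accessions (e.g. one study's identifications)."""

    name: str
    accessions: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, accessions: Iterable[str]) -> "ProteinSet":
        return cls(name=name, accessions=frozenset(accessions))


def pairwise_overlap(a: ProteinSet, b: ProteinSet) -> tuple[int, int, int]:
    """(shared, union, percent) qualitative overlap of two protein sets.

    Percent is shared/union x 100 rounded to the nearest integer for
    display; the operation is symmetric.
    """
    shared = len(a.accessions & b.accessions)
    union = len(a.accessions | b.accessions)
    percent = int(round(100.0 * shared / union)) if union else 0
    return shared, union, percent


def multiset_intersection_counts(
    sets: Sequence[ProteinSet],
) -> dict[tuple[bool, ...], int]:
    """Venn-region counts for 2-4 protein sets.

    Keys are membership patterns (one boolean per input set, at least one
    True); values are the number of accessions with exactly that pattern.
    Counts sum to the size of the union.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("between 2 and 4 sets are supported")
    union = frozenset().union(*(s.accessions for s in sets))
    counts: dict[tuple[bool, ...], int] = {
        pattern: 0
        for pattern in itertools.product([False, True], repeat=len(sets))
        if any(pattern)
    }
    for acc in union:
        pattern = tuple(acc in s.accessions for s in sets)
        counts[pattern] += 1
    return counts


# --------------------------------------------------------------------------
# abundance summaries
# --------------------------------------------------------------------------

def top_n_abundance_share(matrix: ProteinQuantMatrix, n: int = 25,
                          group: str = PATIENT) -> float:
    """Percent of a group's total abundance held by its n most abundant
    proteins (group means)."""
    cols = matrix.group_columns(group)
    if cols.shape[1] == 0:
        raise ValueError(f"no columns for group {group!r}")
    means = cols.mean(axis=1)
    total = means.sum()
    if total <= 0:
        raise ValueError("group has zero total abundance")
    if n > means.size:
        logger.warning("top_n_abundance_share: n=%d exceeds %d proteins; "
                       "clamping", n, means.size)
        n = means.size
    return float(means.nlargest(n).sum() / total * 100.0)


def ratio_distribution_summary(ratios: Sequence[float],
                               low: float = 0.5,
                               high: float = 2.0) -> dict[str, int]:
    """Counts of patient:control ratios inside and outside [low, high].

    Bounds are inclusive; infinite ratios (group-unique proteins) count as
    outside.  Totals are preserved.
    """
    arr = np.asarray(ratios, dtype=float)
    arr = arr[~np.isnan(arr)]
    within = int(((arr >= low) & (arr <= high)).sum())
    return {"within": within, "outside": int(arr.size - within),
            "total": int(arr.size)}


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    output_dir: str | Path,
    synthetic_config=None,
    evidence_path: str | Path | None = None,
    design_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
    ibaq_pools_path: str | Path | None = None,
    criteria: FocusCriteria | None = None,
    confounders: Iterable[str] = (),
    evaluate_all: bool = False,
) -> dict:
    """Quantify -> differential -> biomarker -> reports, with a manifest.

    Inputs are either a :class:`~exomarker.synthetic.SyntheticConfig` (the
    cohort is simulated) or file paths: a peptide-evidence TSV plus design
    TSV (and a FASTA for the iBAQ denominators; a pooled-iBAQ matrix TSV is
    optional).  Marker evaluation covers the significantly altered proteins
    unless ``evaluate_all`` is set.  Returns a summary dict; all tables and
    a reproducibility manifest are written under ``output_dir``.
    """
    from .digest import DigestConfig, count_observable_peptides

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    criteria = criteria or FocusCriteria()
    manifest: dict = {
        "exomarker_version": __version__,
        "criteria": dataclasses.asdict(criteria),
        "inputs": {},
    }

    if synthetic_config is not None:
        from .synthetic import generate_cohort

        logger.info("simulating cohort (seed=%d)", synthetic_config.seed)
        cohort = generate_cohort(synthetic_config)
        psm, top3, pools = cohort.psm, cohort.top3tic, cohort.ibaq_pools
        design = cohort.design
        manifest["inputs"]["synthetic_config"] = dataclasses.asdict(
            synthetic_config)
        cohort.truth.to_csv(output_dir / "truth.tsv", sep="\t")
    else:
        if evidence_path is None or design_path is None:
            raise ValueError("provide either synthetic_config or "
                             "evidence_path + design_path")
        design = read_design_tsv(design_path)
        evidence = read_evidence_tsv(evidence_path)
        manifest["inputs"]["evidence"] = _sha256(Path(evidence_path))
        manifest["inputs"]["design"] = _sha256(Path(design_path))
        observable = None
        if fasta_path is not None:
            sequences = read_fasta_sequences(fasta_path)
            cfg = DigestConfig()
            observable = {acc: count_observable_peptides(seq, cfg)
                          for acc, seq in sequences.items()}
            manifest["inputs"]["fasta"] = _sha256(Path(fasta_path))
        logger.info("quantifying %d evidence rows", len(evidence))
        run_matrices = quantify_evidence(evidence, design,
                                         observable_counts=observable)
        psm = aggregate_replicates(run_matrices["psm"], design)
        top3 = aggregate_replicates(run_matrices["top3tic"], design)
        pools = None
        if ibaq_pools_path is not None:
            tbl = pd.read_csv(ibaq_pools_path, sep="\t",
                              index_col="protein_accession")
            groups = pd.Series(
                [CONTROL if c.startswith("ctr") else PATIENT
                 for c in tbl.columns], index=tbl.columns)
            pools = ProteinQuantMatrix(tbl, "ibaq", groups)
            manifest["inputs"]["ibaq_pools"] = _sha256(Path(ibaq_pools_path))

    write_matrix_tsv(psm, output_dir / "psm_matrix.tsv")
    write_matrix_tsv(top3, output_dir / "top3tic_matrix.tsv")
    if pools is not None:
        write_matrix_tsv(pools, output_dir / "ibaq_pools.tsv")
    write_design_tsv(design, output_dir / "design.tsv")

    logger.info("differential testing over %d proteins", len(psm.proteins))
    analyzer = DifferentialAnalyzer()
    analyzer.fit(psm, top3, ibaq_pools=pools)
    results = analyzer.results_
    results.to_csv(output_dir / "differential.tsv", sep="\t")

    candidates = (results.index if evaluate_all
                  else results.index[results["significantly_altered"]])
    logger.info("marker evaluation of %d candidates", len(candidates))
    X = top3.values.loc[candidates].T  # samples x markers
    y = (top3.groups == PATIENT).astype(int).to_numpy()
    evaluator = MarkerEvaluator().fit(X, y)
    marker_tbl = evaluator.results_
    marker_tbl.to_csv(output_dir / "marker_evaluation.tsv", sep="\t")

    roc_rows = []
    for acc, pts in evaluator.roc_.items():
        for fpr, tpr in pts:
            roc_rows.append({"protein_accession": acc,
                             "fpr": fpr, "tpr": tpr})
    pd.DataFrame(roc_rows).to_csv(output_dir / "roc_points.tsv", sep="\t",
                                  index=False)

    heatmap = evaluator.transform(X)
    heatmap.astype(int).to_csv(output_dir / "heatmap.tsv", sep="\t")

    joined = results.join(marker_tbl, how="inner")
    focus = focus_list_filter(joined, criteria)
    focus, removed = exclusion_filter(focus, set(confounders))
    if removed:
        logger.info("confounder exclusion removed: %s", ", ".join(removed))
    focus.to_csv(output_dir / "focus_list.tsv", sep="\t")

    panel = {"sensitivity": None, "specificity": None, "markers": []}
    if len(focus) >= 2:
        best = list(focus.index[:2])
        clf = OrRulePanel(markers=best).fit(X, y)
        panel = {"sensitivity": clf.sensitivity_,
                 "specificity": clf.specificity_, "markers": best}

    summary = {
        "n_proteins": int(len(psm.proteins)),
        "n_significantly_altered": int(results["significantly_altered"].sum()),
        "n_lfq_significant": int(results["lfq_significant"].sum()),
        "n_focus": int(len(focus)),
        "confounders_removed": removed,
        "or_panel": panel,
    }
    manifest["summary"] = summary
    (output_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    logger.info("pipeline complete: %d altered, %d focus candidates",
                summary["n_significantly_altered"], summary["n_focus"])
    return summary
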