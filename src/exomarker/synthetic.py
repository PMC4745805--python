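"""Synthetic urinary-exosome proteomics cohorts with known planted truth.

The generator emulates the statistical structure of a discovery cohort of
15 healthy controls and 16 prostate-cancer patients:

* protein base abundances are log-normal, spanning more than four orders of
  magnitude, with the most abundant protein around 5% of the summed total;
* each sample adds multiplicative biological (inter-subject) noise and each
  technical run adds replicate noise calibrated so that technical-triplicate
  log-intensity correlation is about 0.87;
* measurements below a hard detection limit are recorded as 0, so that
  presence/absence group differences arise naturally from censoring plus
  regulation (an up-regulated low-abundance protein can be detectable in
  patients only);
* a chosen number of proteins is planted up- or down-regulated in patients
  with log-uniform fold changes; planted proteins are drawn from the lower
  half of the abundance distribution, as disease-specific exosomal cargo is
  typically far below the bulk proteome and this keeps total protein mass
  (the normalisation reference) approximately comparable between groups;
* pooled-set iBAQ triplicates per group mirror the validation design, and
  a peptide-level evidence table (optional) feeds the quantification stage.

Simulation starts at the identified-peptide/protein level; retention time,
m/z and spectra are out of scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .digest import DigestConfig, in_silico_tryptic_digest
from .quantify import (
    CONTROL,
    PATIENT,
    CohortDesign,
    ProteinQuantMatrix,
    aggregate_replicates,
)

# residue frequencies: roughly vertebrate-like, ~11% K+R so the mean tryptic
# peptide is ~9 residues
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_P = np.array([
    0.074, 0.025, 0.054, 0.058, 0.047, 0.074, 0.029, 0.038, 0.058, 0.099,
    0.025, 0.045, 0.039, 0.034, 0.052, 0.072, 0.051, 0.063, 0.013, 0.033,
])
_AA_P = _AA_P / _AA_P.sum()


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and noise parameters of the simulated cohort.

    Abundances are in arbitrary intensity units with a median base
    abundance of ``10**base_mean_log10``; all noise standard deviations are
    on the log10 scale.
    """

    n_control: int = 15
    n_patient: int = 16
    n_proteins: int = 1600
    n_up: int = 221
    n_down: int = 25
    fold_change_range: tuple[float, float] = (1.75, 20.0)
    base_mean_log10: float = 6.0
    base_sigma_log10: float = 0.78
    biological_sd: float = 0.20
    replicate_noise_sd: float = 0.20
    detection_limit: float = 4.0e5
    marker_detectability_margin: float = 0.25
    triplicated_samples: int = 6
    n_pools: int = 3
    pool_noise_sd: float = 0.08
    top3_channel_sd: float = 0.05
    psm_rate: float = 3.0
    psm_yield_sd: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_proteins:
            raise ValueError("n_up + n_down exceeds n_proteins")
        if min(self.n_control, self.n_patient) < 2:
            raise ValueError("group sizes must be >= 2")
        lo, hi = self.fold_change_range
        if not (0 < lo <= hi):
            raise ValueError("fold_change_range must be positive and ordered")
        if self.triplicated_samples > min(self.n_control, self.n_patient):
            raise ValueError("more triplicated samples than samples per group")


@dataclass
class SyntheticCohort:
    """Everything one generated cohort produces, including the truth."""

    psm: ProteinQuantMatrix
    top3tic: ProteinQuantMatrix
    ibaq_pools: ProteinQuantMatrix
    design: CohortDesign
    truth: pd.DataFrame
    config: SyntheticConfig
    psm_runs: ProteinQuantMatrix | None = None
    top3tic_runs: ProteinQuantMatrix | None = None
    evidence: pd.DataFrame | None = None
    sequences: Mapping[str, str] = field(default_factory=dict)


def _make_design(config: SyntheticConfig) -> CohortDesign:
    ctr = [f"CTR{i + 1:02d}" for i in range(config.n_control)]
    pat = [f"PAT{i + 1:02d}" for i in range(config.n_patient)]
    samples = pd.DataFrame({
        "sample_id": ctr + pat,
        "group": [CONTROL] * len(ctr) + [PATIENT] * len(pat),
    })
    rows = []
    for group_samples in (ctr, pat):
        for j, sid in enumerate(group_samples):
            n_runs = 3 if j < config.triplicated_samples else 1
            for r in range(n_runs):
                rows.append({"run_id": f"{sid}_r{r + 1}", "sample_id": sid})
    return CohortDesign(samples=samples, runs=pd.DataFrame(rows))


def _pool_assignment(sample_ids: list[str], n_pools: int) -> list[list[str]]:
    """Round-robin partition of a group's samples into pools."""
    pools: list[list[str]] = [[] for _ in range(n_pools)]
    for i, sid in enumerate(sample_ids):
        pools[i % n_pools].append(sid)
    return pools


def _random_protein_sequence(rng: np.random.Generator,
                             digest_config: DigestConfig) -> str:
    """Random sequence guaranteed to have >= 1 observable tryptic peptide."""
    lo, hi = digest_config.observable_min_len, digest_config.observable_max_len
    for _ in range(50):
        length = int(rng.integers(120, 600))
        seq = "".join(rng.choice(_AA, size=length, p=_AA_P))
        peptides = in_silico_tryptic_digest(
            seq, dataclasses.replace(digest_config, max_missed_cleavages=0))
        if any(lo <= len(p) <= hi for p in peptides):
            return seq
    raise RuntimeError("failed to draw a sequence with observable peptides")


def generate_cohort(config: SyntheticConfig | None = None,
                    include_evidence: bool = False) -> SyntheticCohort:
    """Simulate one cohort; deterministic given ``config.seed``.

    Returns sample-level PSM and Top3TIC matrices (aggregated from
    simulated technical runs), raw pooled-set iBAQ triplicates, the cohort
    design, the planted-truth table and, when ``include_evidence`` is set,
    a peptide-evidence table plus the protein sequences behind it.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    proteins = pd.Index([f"SYN{i + 1:04d}" for i in range(config.n_proteins)],
                        name="protein_accession")

    base = rng.normal(config.base_mean_log10, config.base_sigma_log10,
                      config.n_proteins)

    # Planted effects are drawn from the lower half of the abundance range
    # (disease markers are low-ppm proteins) but must be detectable in the
    # group where they are elevated: an altered protein censored in every
    # sample could never have entered the identified proteome, so it is not
    # a marker the emulated study could report.
    effect = np.zeros(config.n_proteins)
    direction = np.array(["null"] * config.n_proteins, dtype=object)
    fold = np.ones(config.n_proteins)
    n_planted = config.n_up + config.n_down
    lo, hi = config.fold_change_range
    planted_fold = np.exp(rng.uniform(np.log(lo), np.log(hi), n_planted))
    floor_log = np.log10(config.detection_limit) + config.marker_detectability_margin
    low_half = rng.permutation(np.flatnonzero(base < np.median(base)))
    used = np.zeros(config.n_proteins, dtype=bool)
    planted = np.empty(n_planted, dtype=int)
    for slot in range(n_planted):
        is_up = slot < config.n_up
        need = floor_log - (np.log10(planted_fold[slot]) if is_up else 0.0)
        chosen = -1
        for idx in low_half:
            if not used[idx] and base[idx] >= need:
                chosen = idx
                break
        if chosen < 0:
            raise ValueError(
                "not enough detectable low-abundance proteins to plant "
                "effects in; lower the detection limit or n_up/n_down")
        used[chosen] = True
        planted[slot] = chosen
    up_idx = planted[: config.n_up]
    down_idx = planted[config.n_up:]
    fold[planted] = planted_fold
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    effect[up_idx] = np.log10(fold[up_idx])
    effect[down_idx] = -np.log10(fold[down_idx])

    ctr_ids = design.sample_ids(CONTROL)
    pat_ids = design.sample_ids(PATIENT)
    sample_ids = ctr_ids + pat_ids
    is_patient = np.array([0] * len(ctr_ids) + [1] * len(pat_ids))

    bio = rng.normal(0.0, config.biological_sd,
                     (config.n_proteins, len(sample_ids)))
    sample_log = base[:, None] + effect[:, None] * is_patient[None, :] + bio

    run_ids = list(design.runs["run_id"])
    run_sample_pos = [sample_ids.index(s) for s in design.sample_of_run[run_ids]]
    run_log = (sample_log[:, run_sample_pos]
               + rng.normal(0.0, config.replicate_noise_sd,
                            (config.n_proteins, len(run_ids))))
    run_value = np.power(10.0, run_log)
    detected = run_value >= config.detection_limit
    if detected.mean() < 0.01:
        raise ValueError(
            "infeasible configuration: detection limit censors essentially "
            "all simulated measurements")
    run_value = np.where(detected, run_value, 0.0)

    top3_run = run_value * np.power(
        10.0, rng.normal(0.0, config.top3_channel_sd, run_value.shape))
    top3_run = np.where(detected, top3_run, 0.0)

    psm_yield = np.power(10.0, rng.normal(0.0, config.psm_yield_sd,
                                          config.n_proteins))
    lam = config.psm_rate * (run_value / 10.0 ** config.base_mean_log10) \
        * psm_yield[:, None]
    psm_run = np.where(detected, 1.0 + rng.poisson(lam), 0.0)

    run_groups = design.sample_of_run.map(design.group_of).reindex(run_ids)
    psm_runs = ProteinQuantMatrix(
        pd.DataFrame(psm_run, index=proteins, columns=run_ids), "psm", run_groups)
    top3_runs = ProteinQuantMatrix(
        pd.DataFrame(top3_run, index=proteins, columns=run_ids), "top3tic",
        run_groups)
    psm_samples = aggregate_replicates(psm_runs, design)
    top3_samples = aggregate_replicates(top3_runs, design)

    # pooled-set iBAQ triplicates: pools of samples measured in one run each
    pool_cols, pool_groups, pool_vals = [], [], []
    sample_value = np.power(10.0, sample_log)
    for group, ids in ((CONTROL, ctr_ids), (PATIENT, pat_ids)):
        for k, members in enumerate(_pool_assignment(ids, config.n_pools)):
            pos = [sample_ids.index(s) for s in members]
            pooled = sample_value[:, pos].mean(axis=1)
            noisy = pooled * np.power(
                10.0, rng.normal(0.0, config.pool_noise_sd,
                                 config.n_proteins))
            noisy = np.where(noisy >= config.detection_limit, noisy, 0.0)
            pool_cols.append(f"{'ctr' if group == CONTROL else 'pat'}_pool{k + 1}")
            pool_groups.append(group)
            pool_vals.append(noisy)
    ibaq_pools = ProteinQuantMatrix(
        pd.DataFrame(np.column_stack(pool_vals), index=proteins,
                     columns=pool_cols),
        "ibaq",
        pd.Series(pool_groups, index=pool_cols),
    )

    pools_complete = (ibaq_pools.values > 0).all(axis=1)
    detected_everywhere = (
        (psm_samples.detected | top3_samples.detected).all(axis=1)
        & pools_complete
    )
    truth = pd.DataFrame({
        "direction": direction,
        "fold_change": fold,
        "base_abundance": np.power(10.0, base),
        "effect_log10": effect,
        "fully_detected": detected_everywhere.to_numpy(),
        "pools_complete": pools_complete.to_numpy(),
    }, index=proteins)

    evidence = None
    sequences: dict[str, str] = {}
    if include_evidence:
        evidence, sequences = _generate_evidence(
            rng, config, proteins, run_ids, run_value, design)

    return SyntheticCohort(
        psm=psm_samples, top3tic=top3_samples, ibaq_pools=ibaq_pools,
        design=design, truth=truth, config=config,
        psm_runs=psm_runs, top3tic_runs=top3_runs,
        evidence=evidence, sequences=sequences,
    )


def _generate_evidence(rng, config, proteins, run_ids, run_value, design):
    """Peptide-level evidence consistent with the protein-level abundances.

    Each protein gets a random sequence; its fully-cleaved observable
    peptides carry fixed per-peptide ionisation factors, so summed peptide
    intensity (hence iBAQ) is proportional to protein abundance.
    """
    digest_config = DigestConfig()
    lo, hi = digest_config.observable_min_len, digest_config.observable_max_len
    sequences = {}
    peptide_sets = {}
    ionisation = {}
    for acc in proteins:
        seq = _random_protein_sequence(rng, digest_config)
        sequences[acc] = seq
        peps = [p for p in in_silico_tryptic_digest(
            seq, dataclasses.replace(digest_config, max_missed_cleavages=0))
            if lo <= len(p) <= hi]
        peptide_sets[acc] = peps
        factors = np.power(10.0, rng.normal(-0.5, 0.5, len(peps)))
        ionisation[acc] = factors / factors.sum()  # intensities sum to abundance

    sample_of_run = design.sample_of_run
    peptide_floor = config.detection_limit / 50.0
    records = []
    for j, run in enumerate(run_ids):
        col = run_value[:, j]
        detected_idx = np.flatnonzero(col > 0)
        sid = sample_of_run[run]
        for i in detected_idx:
            acc = proteins[i]
            intens = col[i] * ionisation[acc]
            keep = intens >= peptide_floor
            if not keep.any():
                # keep the strongest peptide so the identification exists
                keep = intens == intens.max()
            peps = np.asarray(peptide_sets[acc], dtype=object)[keep]
            vals = intens[keep]
            counts = 1 + rng.poisson(
                config.psm_rate * vals / 10.0 ** config.base_mean_log10)
            for pep, v, c in zip(peps, vals, counts):
                records.append((pep, acc, sid, run, float(v), int(c)))
    evidence = pd.DataFrame(records, columns=[
        "peptide_sequence", "protein_accession", "sample_id", "run_id",
        "precursor_intensity", "spectrum_count"])
    return evidence, sequences


def generate_null_cohort(config: SyntheticConfig | None = None,
                         include_evidence: bool = False) -> SyntheticCohort:
    """Same generator with no planted effects (n_up = n_down = 0)."""
    config = config or SyntheticConfig()
    return generate_cohort(
        dataclasses.replace(config, n_up=0, n_down=0),
        include_evidence=include_evidence,
    )


def generate_worked_example_fixture() -> tuple[ProteinQuantMatrix, CohortDesign]:
    """Small deterministic cohort reproducing the canonical count patterns.

    Eight markers on 15 controls / 16 patients, built so that exactly 15,
    13, 12, 11, 10, 9 and 8 patients lie strictly above the control maximum.
    ``vatl-like`` is the all-absent-in-controls case: threshold 0, so
    positivity is detection itself.  ``s100a6-like`` is a down-regulated
    marker (patients below controls).
    """
    n_ctr, n_pat = 15, 16
    positives = {
        "tm256-like": 15,
        "lamtor1-like": 13,
        "steap4-like": 11,
        "arl8b-like": 10,
        "cldn10-like": 9,
        "bdh2-like": 8,
    }
    columns = {}
    ctr_base = np.linspace(1.0, 10.0, n_ctr)  # control max = 10
    for name, k in positives.items():
        pat = np.concatenate([
            20.0 + np.arange(k),          # strictly above the control max
            np.linspace(2.0, 8.0, n_pat - k),  # inside the control range
        ])
        columns[name] = np.concatenate([ctr_base, pat])
    # detected in no control, 12 of 16 patients: positivity == detection
    vatl = np.concatenate([
        np.zeros(n_ctr), 8.0 + np.arange(12.0), np.zeros(4)])
    columns["vatl-like"] = vatl
    # down-regulated marker: every patient below every control
    columns["s100a6-like"] = np.concatenate([
        30.0 + np.arange(n_ctr, dtype=float), np.linspace(1.0, 12.0, n_pat)])
    sample_ids = [f"CTR{i + 1:02d}" for i in range(n_ctr)] + \
                 [f"PAT{i + 1:02d}" for i in range(n_pat)]
    design = CohortDesign(samples=pd.DataFrame({
        "sample_id": sample_ids,
        "group": [CONTROL] * n_ctr + [PATIENT] * n_pat,
    }))
    values = pd.DataFrame(columns, index=sample_ids).T
    values.index.name = "protein_accession"
    matrix = ProteinQuantMatrix(values, "top3tic", design.group_of)
    return matrix, design
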