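# exomarker

Label-free proteomics biomarker discovery for case/control exosome cohorts.

`exomarker` re-implements, as a tested and reusable pipeline, the analysis
used to mine urinary-exosome proteomes for prostate-cancer biomarkers: a
discovery cohort of 15 healthy controls and 16 patients is quantified
label-free on several channels, proteins altered between the groups are
identified with simple exact and t-tests, and each candidate is evaluated
as a single-analyte diagnostic test and assembled into a focus list and
multi-marker panels.  A synthetic-cohort generator with known planted truth
makes every stage testable without access to the original raw data.

## The method

**Quantification** (`exomarker.quantify`, `exomarker.digest`). From a
peptide-evidence table (sequence, protein, run, precursor intensity,
spectrum count), three protein x sample channels are built:

- **PSM** — spectral counts (peptide-spectrum matches per protein);
- **Top3TIC** — mean precursor intensity of the protein's three most
  intense peptides;
- **iBAQ** — summed peptide intensity divided by the number of observable
  tryptic peptides (7–30 residues, fully cleaved).  Digestion is tryptic
  (C-terminal of K/R, no proline restriction, up to two missed cleavages).

Sample columns are normalised to a common total; abundances are reported
as ppm of the per-sample proteome.

**Differential abundance** (`exomarker.differential`). Per protein:

- a two-sided Fisher exact test on detection counts (presence/absence is
  informative because low abundances are censored at the detection limit);
- Welch's heteroscedastic two-sided t-test on each LFQ channel; a protein
  is *LFQ-significant* only when p < 0.05 on **both** PSM and Top3TIC;
- a pooled-set iBAQ validation: each group's samples pooled into three
  sets, control pools normalised to the patient-pool total, the
  patient:control ratio tested across pools (a protein present in exactly
  one of a group's three pools is invalid).

**Marker evaluation** (`exomarker.biomarker`). Each protein is scored as a
diagnostic test with positivity *strictly above* a threshold:

- the **full-specificity threshold** is the control maximum, so every
  control is negative by construction and sensitivity is the fraction of
  patients above it (percent rounded half away from zero);
- the **Youden threshold** maximises J = sensitivity + specificity − 1;
- ROC staircases and trapezoidal AUC (equal to the Mann–Whitney
  probability, ties counting ½);
- panels: the OR rule (positive on any marker; specificity stays 1 on the
  defining controls) and a mean-of-quantiles rank score for combined ROC.

The **focus list** keeps proteins that are (i) significant in both the LFQ
and iBAQ analyses, (ii) ≥ 50% sensitive at full specificity, and (iii)
changed ≥ 1.75-fold in either direction, then removes known confounders
(e.g. proteins that differ between first and second morning urine voids).

## Worked example

The bundled worked-example cohort has eight markers constructed so that a
known number of the 16 patients exceed the control maximum:

```python
import exomarker as em

matrix, design = em.generate_worked_example_fixture()
X = matrix.values.T                                   # samples x markers
y = (matrix.groups == "patient").astype(int).to_numpy()
ev = em.MarkerEvaluator().fit(X, y)
print(ev.results_[["threshold_full_spec", "n_patients_positive",
                   "percent_sensitivity", "youden_j", "auc"]].round(3))
```

```
                   threshold_full_spec  n_patients_positive  percent_sensitivity  youden_j    auc
protein_accession
tm256-like                        10.0                   15                   94     0.938  0.946
lamtor1-like                      10.0                   13                   81     0.812  0.896
steap4-like                       10.0                   11                   69     0.688  0.825
arl8b-like                        10.0                   10                   63     0.625  0.796
cldn10-like                       10.0                    9                   56     0.562  0.758
bdh2-like                         10.0                    8                   50     0.500  0.721
vatl-like                          0.0                   12                   75     0.750  0.875
s100a6-like                       44.0                    0                    0     0.000  0.000
```

15 of 16 patients positive is 94% sensitivity at 100% specificity; 10 of
16 is 62.5%, displayed as 63% (half-away-from-zero rounding); the
`vatl-like` marker is undetected in every control, so its threshold is 0
and mere detection is the positive call (12/16 = 75%).  `s100a6-like` is
down-regulated, hence useless as an *elevated* marker (sensitivity 0).

Running the whole pipeline on the default synthetic cohort:

```python
summary = em.run_pipeline("out/", synthetic_config=em.SyntheticConfig(seed=1))
print(summary)
# {'n_proteins': 1600, 'n_significantly_altered': 270,
#  'n_lfq_significant': 265, 'n_focus': 133, 'confounders_removed': [],
#  'or_panel': {'sensitivity': 1.0, 'specificity': 1.0,
#               'markers': ['SYN0136', 'SYN0226']}}
```

Of the 1,600 simulated proteins (221 planted up-regulated, 25 down), 270
come out significantly altered, 133 survive the focus criteria, and the
OR-combination of the two best markers reaches 100% sensitivity at 100%
specificity on the discovery cohort.  `out/` receives every table
(matrices, differential results, marker evaluations, ROC points, heat map,
focus list, planted truth) plus a reproducibility manifest.

The same stages are available from the shell:

```bash
exomarker simulate --seed 1 --out cohort/
exomarker diff --psm cohort/psm_matrix.tsv --top3 cohort/top3tic_matrix.tsv \
    --pools cohort/ibaq_pools.tsv --design cohort/design.tsv --out diff.tsv
exomarker report --seed 1 --out out/
```

## Output data dictionary

`marker_evaluation.tsv` — per protein: `threshold_full_spec`,
`sensitivity_full_spec` (fraction), `n_patients_positive`,
`percent_sensitivity` (rounded), `threshold_youden`, `youden_j`, `auc`.
`differential.tsv` — detection counts per group, `fisher_p`,
`welch_p_psm`, `welch_p_top3` (with Benjamini–Hochberg `*_q` columns,
informational only), fold changes, `ibaq_ratio`/`ibaq_p`/`ibaq_valid`,
`lfq_significant`, `lfq_and_ibaq_significant`, `significantly_altered`,
`direction`.  `focus_list.tsv` — the filtered candidates with their
symmetric `effect`.  `heatmap.tsv` — sample x marker positivity calls.
`roc_points.tsv` — (1−specificity, sensitivity) staircase per marker.

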