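# Methods

This note documents the models, conventions and numerical choices behind
`exomarker`, and what the synthetic cohorts do and do not establish.

## Quantification model

**Digestion.** Trypsin cleaves C-terminal of K and R; by default no
proline restriction is applied (a K/R–P bond is still a site), with up to
two missed cleavages for peptide enumeration.  The iBAQ denominator counts
*observable* peptides: fully cleaved fragments of 7–30 residues.  The
length window is a common community dialect rather than a universal
constant, and is configurable in `DigestConfig`.

**Top3TIC.** The protein-level value is the *mean* of the three largest
peptide precursor intensities (with fewer than three peptides, the mean of
those present; zero with none).  Sum and mean differ only by a constant
factor for fully observed proteins but diverge for one- and two-peptide
proteins; the mean degrades more gracefully and is the default, with the
aggregator exposed as a parameter.  Duplicate observations of one peptide
sequence within a run (charge states, repeated identifications) collapse
to their maximum intensity; spectral counts, by contrast, accumulate over
all rows.

**Replicates and detection.** A protein is detected in a sample when at
least one of its runs shows nonzero signal; per-sample values are the mean
over that sample's runs.  Because values are non-negative, the mean is
consistent with any-run detection (nonzero mean iff nonzero somewhere).

**Normalisation.** Sample columns are rescaled to a common total (for the
pooled-iBAQ analysis, to the patient-pool total), preserving within-sample
ratios; the ppm view divides by the column total and multiplies by 1e6.
Both are invariant to the unit of raw intensity.  This total-abundance
normalisation assumes the bulk proteome is comparable between groups; if a
large abundance fraction is truly regulated, all ratios inherit a
compositional bias (see *Limitations*).

## Differential testing

Presence/absence differences are tested with the two-sided Fisher exact
test under probability ordering (the p-value sums hypergeometric
probabilities of margin-fixed tables no more probable than the observed
one).  Other two-sided conventions exist (doubling the one-sided p);
probability ordering is the commonest and is what the implementation and
its enumeration oracle both use.

Abundance differences use Welch's heteroscedastic two-sided t-test per
channel, with the dual-channel rule: LFQ-significant means p < 0.05
(strict) on *both* spectral counts and Top3TIC.  No multiple-testing
correction gates any decision — the procedure is deliberately the raw
p < 0.05 workflow — but Benjamini–Hochberg q-value columns are emitted for
modern re-analysis.

Two analysis choices the data format forces:

- **Censored zeros.** Non-detected values enter the t-tests as zeros
  (switchable to exclusion via `zero_policy`).  Presence differences then
  contribute to the abundance statistic, which is intended: in this design
  absence is informative, not missing-at-random.
- **Anchored log transform.** Intensities span four-plus orders of
  magnitude, so raw-scale t-tests are dominated by a handful of samples.
  By default detected values are transformed to `log10(v / floor)` with
  the floor at half the smallest positive value in the table, leaving
  censored zeros at 0 and every detected value strictly positive.  The
  transform is monotone, keeps the zero convention meaningful, and makes
  the Welch test operate on the scale on which the noise is approximately
  additive.  Under the null the groups remain exchangeable, so calibration
  is preserved (verified on null cohorts).

The per-protein "significantly altered" flag is the union of the two
routes — LFQ-significant or Fisher-significant — because presence shifts
and abundance shifts are complementary discoveries (a marker detectable
only in patients may have too few quantified controls for a t-test).
The focus-list criterion (i) is stricter: LFQ-significant *and* a valid,
significant pooled-iBAQ change.

**Pooled-iBAQ validity.** A protein present in exactly one of a group's
three pools is invalid: a single observation cannot support a group ratio.
Complete absence from one group is a different, meaningful statement — the
protein is group-unique and its ratio is ±infinity — and remains valid
when the other group shows it in at least two pools.

## Marker evaluation

Positivity is *strictly above* the threshold.  The full-specificity
threshold is the maximum control value, which makes "negative for every
control" literally true, including the all-absent case where the threshold
is 0 and detection itself is the test.  Percent sensitivities are rounded
half away from zero (62.5 → 63, 68.75 → 69); this is the only rounding
rule consistent with the reference panel's printed percentages.

Youden's J is maximised over midpoints between adjacent distinct pooled
values plus ±∞ sentinels; ties break toward the higher (more specific)
threshold.  ROC staircases use the distinct observed values as the
threshold grid with no interpolation beyond trapezoids; the trapezoidal
AUC therefore equals the Mann–Whitney statistic with ties counting half.

Focus criterion (iii) is inclusive (≥ 1.75-fold), measured symmetrically
as max(ratio, 1/ratio), so a 0.57-fold down-regulation qualifies exactly
as a 1.75-fold up-regulation does.

**Panel combination.** No canonical combination rule exists for
threshold-based multi-marker tests, so two labelled conventions are
emitted: the OR rule for threshold tests (a sample is positive on any
member marker; specificity on the defining controls remains exactly 1, and
sensitivity can only grow), and, for ROC purposes, a pooled rank score —
the mean of each marker's within-cohort empirical quantiles — whose AUC is
computed with the same tie convention.  Identical markers leave both
combinations unchanged; complementary markers (each flagging a different
patient subset) raise the combined AUC above either alone.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the identified-peptide/protein level (no retention times, m/z or spectra).

| parameter | default | meaning |
|---|---|---|
| `n_control` / `n_patient` | 15 / 16 | cohort design |
| `n_proteins` | 1600 | detected-proteome scale |
| `n_up` / `n_down` | 221 / 25 | planted regulated proteins |
| `fold_change_range` | 1.75–20, log-uniform | planted effect sizes |
| `base_mean_log10`, `base_sigma_log10` | 6.0, 0.78 | log-normal base abundance (arbitrary intensity units) |
| `biological_sd` | 0.20 log10 | inter-subject noise |
| `replicate_noise_sd` | 0.20 log10 | technical run noise |
| `detection_limit` | 4e5 | hard censoring threshold |
| `pool_noise_sd` | 0.08 log10 | pooled-iBAQ run noise |
| `triplicated_samples` | 6 per group | samples measured in technical triplicate |

Calibration: `base_sigma_log10 = 0.78` gives a detected dynamic range
above four orders of magnitude with the most abundant protein typically
around 5% of the summed total (median over seeds; the statistic is
heavy-tailed).  `replicate_noise_sd = 0.20` was calibrated so that
technical-triplicate log-intensity correlation, computed on pairs detected
in both runs, is ≈ 0.87 (the detection cut restricts the range, so the
naive variance-ratio value would overshoot).  The detection limit puts
mean detected proteins per sample near 1,090 in controls and 1,220 in
patients.  `pool_noise_sd` is deliberately smaller than the discovery-run
noise: the pooled-set quantification models a dedicated quantitative
instrument with internal standard, and pooling itself averages five to six
subjects per set.

Planted markers are drawn from the lower half of the base-abundance
distribution — disease-specific exosomal cargo sits well below the bulk
proteome, and keeping planted mass small preserves the total-abundance
normalisation — with the added constraint that a marker must be detectable
in its elevated group (base plus up-effect, or base for down-regulated
proteins, at least 0.25 log10 above the detection limit).  An altered
protein censored in every sample could never have entered the identified
proteome, so it is not a marker the emulated study could report; without
the constraint, the planted-truth table would contain unrecoverable
"markers" that no analysis, including the original one, could see.

PSM counts are generated as 1 + Poisson with rate proportional to run
abundance and a per-protein yield factor; Top3TIC adds small lognormal
channel noise; the optional peptide-evidence layer distributes each
protein's abundance over its observable peptides with fixed lognormal
ionisation factors (so iBAQ recovers abundance up to a per-protein
constant), censoring weak peptides.

**What passing tests show — and what they do not.** The synthetic cohorts
establish that the implementation recovers planted structure under the
stated noise model and stays calibrated under its null.  They do not
establish performance on real urinary-exosome data: real intensity noise
is not lognormal-homoscedastic, censoring is soft rather than hard,
peptide ionisation varies with sequence and matrix, protein inference and
shared peptides are not simulated, and the real cohort's biological
covariates (age, urine collection protocol) have no synthetic counterpart.
The generator's noise values are conventions chosen for realism, not
inferences from the original raw data.

## Degenerate inputs and numerical conventions

- Welch test with two exactly constant groups: p = 1 if the means agree,
  else p = 0 (t = ±∞); groups of fewer than two observations are errors.
- Fold-change ratio: ∞ for patient-unique proteins, 1.0 when both groups
  are all-zero.
- All-zero sample columns cannot be normalised and raise, naming the
  sample.
- iBAQ is undefined for a protein with zero observable peptides (error).
- Ratio-interval summaries use inclusive bounds; infinities count as
  outside [0.5, 2].
- All tabular outputs keep full precision; rounding (percent columns,
  overlap percentages) happens only in reporting fields.

## Problem sizes used by the test suite

Oracle-equivalence tests enumerate every 2×2 table with both margins ≤ 20
(Fisher vs hypergeometric enumeration, 1e-12), 300 random instances each
for Welch (1e-10 vs closed form), AUC (exact vs pairwise counting, n ≤ 12)
and Youden (vs exhaustive search).  Recovery tests run one full-scale
default cohort (1,600 proteins, 15/16 samples, seed fixed); null
calibration uses twenty 200-protein null cohorts, matching the rate bound
α + 3·SE computed over 4,000 protein-tests.  These sizes give stable
verdicts while keeping the default suite fast.

## Limitations

- The real study's headline counts (1,644 identified proteins, 246
  significant, AUC 0.87 for the top marker) depend on per-sample
  quantifications that were never released; nothing here asserts them.
- Compositional bias: normalising to total abundance transfers any
  aggregate group difference into every ratio (kept ≈ 6% in the synthetic
  defaults by planting effects low in the abundance distribution).
- With three pools per group, individual iBAQ ratio estimates carry
  sampling error that no convention can push below ~15–20% for a tail of
  proteins; accuracy statements are therefore about the median protein.
- No cross-validation or held-out cohorts: all sensitivities and
  specificities are in-sample discovery-cohort quantities, and the
  full-specificity threshold is optimistically biased by construction.
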