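# Methods

## Solubility-shift indexing

A fractionated co-IP quantifies each interactor of a bait protein in the
soluble (supernatant) and insoluble (pellet) fractions of an
ultracentrifuged lysate, in two conditions (control and a destabilizing
treatment), with one spectral-index value per replicate. The solubility
ratio is SR = soluble / (soluble + insoluble) on replicate-averaged
spectral indices, and the destabilization index DI = SR(control) −
SR(treatment). DI = 1 means a complete soluble→insoluble shift; −1 the
reverse.

Conventions and edge cases:

* **Replicate aggregation** defaults to mean-then-ratio (average spectral
  indices per (protein, condition, fraction), then ratio), mirroring how
  mean-of-replicates quantities are formed in the binding analysis; a
  ratio-per-replicate-then-mean variant is exposed via the `aggregate`
  switch. The two agree exactly when replicates are equal and differ only
  through noise (ratio of means vs mean of ratios).
* **Missing values.** A protein absent from a condition has NA SR there
  and NA DI, and is excluded from ranking; the "top 10%" denominator is
  the set of proteins with defined DI, not the full detected proteome
  (an undefined DI cannot be ordered). A protein detected in a condition
  but lacking a record for one fraction is treated as 0 in that fraction
  (below detection). 0/0 yields NA, never a pseudo-count: no pseudo-count
  is added anywhere.
* **Ranking** is descending by DI with protein-identifier lexicographic
  order as the tie-break, so the top-decile selection
  (ceil(0.10 · k) proteins) is deterministic under ties.
* Bait normalization is *not* applied before solubility ratioing by
  default (it is defined for the whole-lysate binding analysis); SR is
  scale-free within a condition, so a global per-condition factor cancels
  regardless.

## Bait-normalized relative binding

For whole-lysate co-IPs, treatment spectral indices are multiplied by
(mean bait SI in control / mean bait SI in treatment); control records
are untouched so control-relative quantities keep their raw scale. The
bait must have a positive mean spectral index in both conditions.
Relative binding RB = adjusted treatment mean / control mean. RB is NA
with a `treatment_only` flag when the control mean is 0 — reporting an
infinite ratio would fabricate a magnitude. The detection-confidence
filter uses the maximum PSM count over all of a protein's runs
(the most permissive reading of a per-protein PSM ≥ 2 rule); failing
proteins are flagged, not dropped. RB inherits two exact symmetries that
the tests assert: bait RB ≡ 1, and swapping condition labels maps
RB → 1/RB.

## Over-representation analysis

The p-value is the exact upper-tail hypergeometric probability
P(X ≥ x) computed by summation of integer-binomial PMF terms; no
approximation. The universe is explicit and caller-supplied — all
proteins with a defined DI for solubility selections, all detected
interactors for binding — because the background choice dominates ORA
results; every annotation set is intersected with the universe before
counting, and sets with fewer than 2 members after intersection are
dropped as uninformative. Multiple testing is controlled by
Benjamini–Hochberg step-up FDR across the reported sets. No annotation
database is bundled; GMT files are user-supplied and tests use synthetic
annotations.

## Cross-dataset DE classification

Significance is |log2FC| strictly greater than 0.5 and p strictly less
than 0.05 (so a gene at exactly the cutoff is not called). Genes
significant in dataset A are classified against dataset B as unchanged
(measured, not significant in B), inverse (significant with opposite
sign), concordant (significant with the same sign) or absent_in_B; the
four classes partition sig A exactly. "Inverse" requires significance in
B, not merely an opposite sign, so it contrasts cleanly with
"not significantly changed". By default B uses the same two thresholds
as A; a `b_p_only` switch reproduces the looser p-value-only reading.
Summaries are rounded to whole percent — the granularity at which such
compositions are quoted (25 and 7 of 37 → 68% and 19%). Raw p-values are
used throughout; FDR-adjusted inputs can be supplied in the p_value
column by the caller if preferred.

## Reporter, cytometry, staining and qPCR rules

* **Nuclear scoring:** a cell is positive when nucleus/cytosol intensity
  ≥ 2-fold ("at least" read as ≥). The denominator is fixed at 20
  intestinal cells per animal, so percentages are multiples of 5. Cells
  with zero cytosolic intensity are unscorable: excluded from the
  numerator, denominator unchanged.
* **Flow cytometry:** normalized fluorescence is the per-event ratio
  fluorescence/TOF, averaged per group, then standardized to control.
  The wording of TOF normalization would also admit a population-level
  regression; the per-event ratio is the simplest reading and is recorded
  in the output as the method used.
* **oil red O:** relative density is (1/brightness) divided by the mean
  control inverse brightness (brighter = less dye). Whether the control
  reference is the mean of inverses or the inverse of the mean is
  ambiguous; the former is the default, the latter available via
  `inverse_of_mean=True`.
* **TEM lipid density:** images are inverted (v → 255 − v) and binarized
  at a global threshold (default 128; the original "maximum black
  saturation" is an interactive Photoshop setting with no algorithmic
  definition, so a configurable plain threshold stands in for it); the
  readout is the black-pixel fraction, normalized to the mean control
  fraction.
* **ΔΔCt:** technical replicates are averaged first; ΔCt subtracts the
  arithmetic mean of housekeeping Cts (exactly equivalent to
  geometric-mean normalization on the linear scale, since Ct is already
  log2); ΔΔCt subtracts the control sample's ΔCt; relative abundance is
  2^(−ΔΔCt). A batch shift applied to *all* genes of a sample cancels in
  ΔCt; applied to the target alone it does not — the tests assert exactly
  that form.
* **Absorption:** an animal is impaired when its absorbed fraction is
  strictly below 0.5 ("less than 50%" read literally).

## Synthetic data

Generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`; the same seed reproduces the same table
bit for bit. Observation models:

* spectral indices: negative binomial (gamma–Poisson) around a
  log-normal per-protein abundance — the standard overdispersed model
  for spectral counting. Defaults: mean depth 50 counts, dispersion 0.25
  (variance = μ + 0.25 μ²), log-normal abundance sigma 0.5 — moderate
  inter-protein spread and replicate noise typical of co-IP spectral
  counts;
* PSM counts: Poisson with mean proportional to abundance (rate 0.05),
  which makes the PSM ≥ 2 filter bite on low-abundance proteins;
* fluorescence and intensities: multiplicative log-normal noise with
  unit mean;
* the co-IP bait is simulated 2× more abundant in control than
  treatment so bait normalization is genuinely exercised.

The pinned recovery-study conditions are 200 proteins, 20 planted,
solubility ratio 0.9 shifting to 0.1, 2 biological replicates. The DE
pair generator plants exact class counts (rounded from the requested
fractions) and keeps noise inside class boundaries: non-significant
genes get p ≥ 0.06, significant ones |log2FC| ≥ 0.55 and p ≤ 0.032, so
the planted composition is recovered by construction while values still
vary.

What the generators do **not** emulate: correlated protein abundances,
shared-peptide ambiguity, batch effects, realistic GO DAG structure,
instrument drift, or image texture beyond flat discs plus Gaussian
noise. Passing recovery tests therefore shows the statistics are
computed correctly and are sensitive under the stated noise model — not
that real co-IP data will separate this cleanly.

### Pinned Monte-Carlo bounds

`scripts/pin_bounds.py` ran the 100-seed oracle once, before the
recovery tests were written, and its printed suggestions were
transcribed into `solshift.synthetic_data`:

* `RECOVERY_RECALL_BOUND = 1.0` — observed top-decile recall was 1.0 on
  every seed (the 0.9 → 0.1 shift is far larger than the counting
  noise at depth 50);
* `SPEARMAN_DI_BOUND = 0.5` — the per-seed minimum Spearman correlation
  between planted shift magnitude and estimated DI was 0.519; a binary
  truth vector against a continuous index caps the achievable rank
  correlation near 0.52 even at perfect separation, which is why this
  bound is far from 1;
* `ENRICH_TOP_HIT_BOUND = 1.0` — the planted annotation set was the top
  enrichment hit on every seed.

## Problem sizes

The default test suite uses tables of 4–200 proteins, DE tables of
100–500 genes, 100-seed recovery runs, full hypergeometric enumeration
for universes up to 12 (3,184 instances) plus a 10,829-instance exact
cross-check up to N = 17, and 10³-table fuzzing of the solubility
invariants — sizes at which every oracle is exact and the whole suite
runs in about a minute.

## Known limitations

* Spectral indices are taken as given; whether upstream search software
  length- or run-normalized them is outside the model.
* No statistical test is attached to DI (none is defined for it) or to
  RB (with two replicates, a t-test on RB is possible but its exact form
  on ratios vs means is ambiguous; testing is left to the user).
* Identifier harmonization is exact and case-sensitive; no aliasing.
* The TEM threshold stands in for an interactive thresholding step and
  will not match any particular manual segmentation.
* ORA here is plain hypergeometric + BH; it does not reproduce
  EASE-style modified scores or any specific annotation database.
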