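# solshift

Quantification pipeline for solubility-shift interactomics and the
companion assays used to study proteostasis–lipid crosstalk in
*C. elegans* — for proteomics and worm labs that quantify
co-immunoprecipitation (co-IP) LC-MS/MS experiments with spectral
counting and score their reporter, cytometry, staining and qPCR readouts
with explicit, reproducible rules.

## What it computes

**Solubility shift.** For each interactor of a bait protein (e.g. the
enteric actin ACT-5) quantified in soluble and insoluble lysate fractions
under two conditions, the solubility ratio per condition is

    SR = SI_soluble / (SI_soluble + SI_insoluble)        SR ∈ [0, 1]

with SI the replicate-averaged spectral index. The destabilization index

    DI = SR(control) − SR(treatment)                     DI ∈ [−1, 1]

is 1 for a complete soluble→insoluble shift upon treatment. Proteins are
ranked by DI and the top decile (ceil(0.10·k) of the k proteins with
defined DI) is selected for enrichment analysis.

**Relative binding.** For whole-lysate co-IPs (e.g. GFP::RAB-11.1), the
treatment condition is rescaled so the bait's mean spectral index matches
control, then per interactor

    RB = mean SI(treatment, bait-adjusted) / mean SI(control)

with a PSM ≥ 2 detection-confidence flag and category subsetting (e.g. a
KEGG endocytosis list).

**Over-representation.** Exact upper-tail hypergeometric p-values over an
explicit, caller-chosen universe, with Benjamini–Hochberg FDR across the
tested annotation sets.

**Cross-dataset DE classification.** Genes significant in dataset A
(|log2FC| > 0.5, p < 0.05, both strict) are classified against dataset B
as unchanged / inverse / concordant / absent, with whole-percent
summaries.

**Reporter rules.** Nuclear reporter scoring (≥ 2-fold
nucleus-over-cytosol, percent of the 20 intestinal cells), time-of-flight
normalized large-particle flow cytometry, inverse-brightness oil red O
density, inverted-threshold TEM black-pixel lipid density, ΔΔCt qPCR with
geometric-mean housekeeping normalization, and strict <50% absorption
impairment scoring.

**Synthetic data.** Seeded generators for every input type with planted
ground truth (negative-binomial spectral counts with planted solubility
shifts, paired DE tables with a planted inverse/unchanged composition,
size-correlated flow events, bimodal cell intensities, disc images with
exactly known dark area, Ct tables), so the whole pipeline is testable
end to end with no external data.

## Worked example

```python
import solshift as ss

table, truth = ss.gen_coip(n_proteins=200, n_planted=20, seed=42)
res = ss.index_table(table)
print(res.sort_values("rank").head(3).to_string(index=False))
top = ss.top_fraction(res, 0.10)
planted = truth.planted_sets["destabilized"]
print("recovered", len(top & planted), "of", len(planted), "planted proteins")
```

prints

```
protein_id  sr_control  sr_treatment  destab_index  rank  in_top_fraction
     P0039    0.984496      0.052083      0.932413     1             True
     P0187    0.953125      0.028571      0.924554     2             True
     P0120    0.953390      0.062044      0.891346     3             True
recovered 20 of 20 planted proteins
```

Protein P0039 was almost fully soluble in control (SR 0.98) and almost
fully insoluble under treatment (SR 0.05), so its destabilization index
is 0.93 — near the complete-shift endpoint of 1 — and it ranks first.
All 20 proteins planted with a 0.9 → 0.1 solubility-ratio shift are
recovered in the top decile. Feeding that selection to `ss.enrich`
against a gene-set collection containing the planted set plus decoys
ranks the planted set first (p ≈ 1.2 × 10⁻²⁶ for a 20-of-21 overlap in a
201-protein universe).

The same operations are available from the shell:

```sh
solshift simulate coip --seed 42 --out-prefix run
solshift solubility --quant run_coip.tsv --bait BAIT --fraction 0.10 --out sol.tsv
solshift degcompare --a deA.tsv --b deB.tsv --lfc 0.5 --p 0.05 --out cross.tsv
```

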