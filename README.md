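# melmeth

Melanoma methylome progression analysis: a tested, reusable pipeline for
Infinium 450K-style beta-value studies that span the full disease course —
benign nevi, primary melanomas, and metastases — with survival follow-up.

It is written for epigenomics analysts who have a normalized beta-value
matrix (probes × samples), an Illumina-manifest-style probe annotation, a
clinical sample sheet, and optionally pre-computed differential-expression
tables, and who want the stage-wise differential-methylation screen, genomic
compartment profiling, methylation–expression concordance, and prognostic
biomarker evaluation as importable, unit-tested operations rather than a
one-off script.

## The method

For a probe with beta values (methylation fractions in [0, 1]) across three
ordered stage groups (nevus < primary < metastasis):

1. **Probe QC** — genotyping probes and probes overlapping known SNPs are
   removed; data points with detection p > 0.01 are masked as missing.
2. **ANOVA pre-screen** — probes with a one-way ANOVA p < 0.01 across the
   three groups and at least one pair of group medians differing by ≥ 0.33
   feed Ward hierarchical clustering of the samples.
3. **DGMB screen** — for each stage contrast, the difference of group
   methylation medians DGMB = median(later) − median(earlier) is the effect
   statistic. Probes with |DGMB| ≥ 0.25 are kept *first*; a probe-wise
   Mann–Whitney test is then applied and Benjamini–Hochberg adjusted within
   the gated family, calling probes significant at q < 0.05. The sign of
   DGMB gives the direction (hyper = gain toward the later stage).
4. **Hit-list crossing** — probes significant with consistent direction in
   both nevi-vs-primary and nevi-vs-metastasis are *development* changes;
   primary-vs-metastasis hits are *progression* changes. Gene-level sets
   come from exploded Illumina gene annotations; promoter means
   TSS1500/TSS200/5'UTR/1stExon.
5. **Compartment profile** — hits are classified island / shore (≤ 2 kb) /
   shelf (2–4 kb) / open sea, and a two-tailed Fisher exact test checks the
   hyper/hypo × island/non-island association. A probe is promoter-island
   if it lies inside a CpG island and < 2000 bp from a TSS.
6. **Expression integration** — a DM gene is concordant-negative if at least
   one differential-expression table calls it significantly changed
   (|log2FC| ≥ 1, q < 0.05) with sign opposite to its methylation direction.
   Gene-set over-representation uses the hypergeometric upper tail.
7. **Survivor signature** — among primary tumors, patients dying of disease
   before 48 months vs patients surviving past it; probes with
   |mean difference| ≥ 0.2 and Mann–Whitney BH q < 0.01 form the signature.
8. **Biomarker evaluation** — markers (methylation or IHC H-score,
   H = 1·pct₁ + 2·pct₂ + 3·pct₃) are dichotomized at a cohort cutoff
   (median/quartile/fixed) and evaluated by Kaplan–Meier, log-rank, and
   multivariate Cox regression (Breslow tie handling) against Breslow
   thickness and ulceration.

A seeded synthetic-data module generates every input with planted ground
truth — stage-specific probes on a Beta(mean, precision) noise model, a toy
genome with CpG islands and TSSs, sign-concordant expression tables, and
survival times tied to a planted prognostic marker — so every stage has an
end-to-end recovery test.

## Worked example

`examples/03_prognosis.py` plants 50 prognostic probes (mean shift 0.3) in
the primary tumors of short survivors among a 40-patient cohort, derives
the survivor signature, and evaluates the top probe as a dichotomized
marker:

```
survivor groups: 20 short / 20 long
signature probes: 50 (sensitivity vs planted: 1.00)

KM survival at last event: high-methylation 0.05, low 0.14
log-rank: chi2 = 38.3, p = 6.21e-10

multivariate Cox (HR [95% CI], Wald p):
  marker       HR  45.34 [9.86, 208.54]  p = 9.61e-07
  breslow_mm   HR   0.78 [0.57, 1.06]  p = 0.113
  ulceration   HR   0.66 [0.27, 1.57]  p = 0.345
```

The signature recovers all 50 planted probes; the dichotomized marker
separates survival strongly (log-rank p ≈ 6e-10) and keeps a large hazard
ratio in the multivariate Cox fit while the clinical covariates — drawn
independently of the marker in this simulation — stay near HR 1. The other
examples cover the stage screen with compartment profiling (`01`),
expression integration and gene-set overlap (`02`), and H-score computation
with quartile splits (`04`).

The same pipeline runs end to end from the shell:

```sh
melmeth run-all --seed 7 --outdir out/        # simulated cohort
melmeth dgmb --beta beta.tsv --sample-sheet samples.csv \
        --group-a nevus --group-b metastasis --out hits.tsv
```

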