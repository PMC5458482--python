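# Methods

This note records the statistical model behind each stage of the pipeline,
the defaults and why they were chosen, what the synthetic cohort does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Data model

A study is a beta-value matrix **B** (probes × samples, values in [0, 1],
`NaN` = missing), an Illumina-manifest-style probe annotation (1-based
coordinates, `;`-separated multi-gene assignments, nearest CpG island,
SNP-overlap and genotyping flags), a TSS table, and a sample sheet with
stage labels (`nevus`, `primary`, `metastasis`), survival time in months,
an event flag, Breslow thickness and ulceration. Detection-p masking
(p > 0.01 → missing) is applied at read time so every downstream statistic
shares one mask. QC removes genotyping and SNP-overlapping probes as
flagged in the manifest; the SNP catalogue that defines the flags is taken
as input, not recomputed.

## Differential methylation

**ANOVA pre-screen.** A probe passes when one-way ANOVA across the three
stage groups gives p < 1 − conf (conf = 0.99) *and* at least one pair of
group medians differs by ≥ 0.33. "A difference in at least two groups" is
read as "at least one pair of groups", the only reading consistent with
three groups and a single confidence level. Probes with fewer than two
groups of ≥ 2 non-missing values are skipped.

**DGMB screen.** Per probe and contrast, medians are taken over non-missing
values; a probe is excluded (and logged) when either group has fewer than
`min_group_n = 3` non-missing values. The effect gate |DGMB| ≥ 0.25 is
applied *before* testing, and the BH family consists of the gated probes
only — this follows the stated ordering of the original procedure
(effect filter first, then rank test). The alternative test-then-gate
ordering is available as `gate_order="test_first"`; it never changes which
probes pass the effect gate, only the multiplicity burden.

**Mann–Whitney.** Exact enumeration when the pooled sample size is ≤ 12
with no ties, otherwise the normal approximation with tie and continuity
corrections. With landmark groups of ~7–8 patients the asymptotic p-value
floors near 1.5e-3, which after BH adjustment across thousands of probes
cannot reach q < 0.01 — the survivor signature therefore needs roughly 15+
patients per group to be non-trivially powered, which the default cohort
sizes provide.

**Ward clustering.** Samples are clustered on Euclidean distance after
per-probe mean imputation of missing values (probes that are entirely
missing impute to 0.5, the uninformative center). Merge-height ties are
resolved by scipy's deterministic lowest-index rule, so output is a pure
function of input order.

**Crossing.** Development changes require significance with consistent
direction in *both* nevi contrasts; direction conflicts are excluded from
the development set but reported (`dev_conflict`), as are probes
significant in only one nevi contrast (`dev_single`). Gene-level sets use
exploded (probe, gene, feature) triples with case-folded symbols; a gene is
promoter-hypermethylated when at least one of its significant probes
carries a promoter feature (TSS1500, TSS200, 5'UTR, 1stExon).

**Compartments.** Island if inside the nearest island (edges inclusive),
shore within 2 kb of an edge, shelf within 2–4 kb, open sea beyond — the
universal Illumina convention; the four labels partition every probe.
Promoter-island = inside an island *and* strictly less than 2000 bp from a
TSS. Strand is ignored for all distances. The island-association test is
the two-tailed Fisher exact test on {hyper, hypo} × {island, non-island}.

## Expression integration

"Negative correlation" is operationalized as direction-concordant
significance — hypermethylated & downregulated or hypomethylated &
upregulated (|log2FC| ≥ 1, q < 0.05) in at least one table — because
methylation and expression come from different cohorts; no per-sample
correlation exists to compute. Symbols match exactly after uppercasing;
no alias resolution. Reported percentages always recompute from their own
counts as `round(100·part/whole, 1)`. The gene-set step is hypergeometric
over-representation (upper tail P(X ≥ k), BH across sets); a ranked-list
enrichment statistic is deliberately out of scope.

## Survival

**Survivor signature.** Short = died of disease before the 48-month
landmark; long = survived past it (including later deaths). Patients
exactly at the landmark, or alive with follow-up shorter than it, are
excluded by default (`include_censored_as_long=True` reassigns the
latter). Group *means* are used here — the stage screen uses medians —
with Mann–Whitney p, BH adjustment, and selection at |Δmean| ≥ 0.2,
q < 0.01.

**Kaplan–Meier / log-rank.** Standard product-limit estimator and
two-group log-rank (both via lifelines), each verified in the test suite
against hand-computed oracles.

**Cox regression.** The Breslow-tie partial likelihood is maximized by
Newton's method with step-halving, covariates centered, convergence at
gradient norm < 1e-8. Breslow was chosen as the default tie handling
because its likelihood is simple enough to brute-force against in tests;
Efron is available via `ties="efron"` (delegated to lifelines).
Constant covariates are flagged `non-identifiable`; a monotone likelihood
(perfect separation, detected by coefficient escape past ±20 or
non-convergence) yields `non-converged` with no coefficient reported,
never a spurious number. Confidence intervals come from the observed
information.

**Dichotomization.** `high` means strictly above the cutoff (ties go low);
quartiles use linear interpolation (type-7), stated explicitly because
quartile conventions differ. Breslow thickness enters Cox as a continuous
covariate by default; median-dichotomized modes mirror validation-cohort
style groupings.

**H-score.** H = 1·pct₁ + 2·pct₂ + 3·pct₃ on the per-sample intensity
histogram — the canonical formula, adopted because the original
image-analysis software does not publish its exact scoring rule. Linear in
each percentage, bounded in [0, 300], invariant to cell-count scaling.

## Synthetic cohort

The generator emulates the statistical structure the screen assumes, not
array chemistry:

- **Noise**: Beta(mean·φ, (1−mean)·φ) with precision φ = 50 — the standard
  bounded model for methylation fractions; per-probe baselines from a
  bimodal mixture (modes ≈ 0.15 / 0.85) mimicking real 450K marginals.
  Planted probes draw their baseline from the mode that leaves room for
  the shift, then are clipped so every shifted mean stays inside (0, 1);
  infeasible effect sizes raise an error.
- **Planted classes**: `dev_hyper`/`dev_hypo` shift primary *and*
  metastasis means by ±0.4 relative to nevi; `prog_hyper`/`prog_hypo`
  shift metastases only; `prognostic` probes shift by 0.3 in the high-risk
  half of primaries. Defaults plant 5% of probes with stage effects —
  effect sizes chosen to straddle the 0.25 (DGMB) and 0.2 (signature)
  gates, and group sizes default to the 14/33/28 discovery-cohort design.
- **Genome**: a single toy chromosome with probes on a 100-bp grid,
  islands of 1 kb at a regular spacing, and one gene per TSS with
  Illumina-style features by distance — compartment fractions are
  therefore computable in closed form, which the tests exploit.
- **Expression**: a seeded fraction of planted genes gets, in one randomly
  chosen table, a logFC of opposite sign with |logFC| ≥ 1 and q < 0.05;
  all other rows are null. Gene direction is the majority vote of a
  gene's planted probes; tied genes are ambiguous and excluded from the
  planted set.
- **Survival**: two regimes. `simulate_survival` is exponential with a
  multiplicative hazard for high-marker samples and independent uniform
  censoring tuned numerically to the target censoring fraction — the
  right model for Cox/log-rank parameter recovery. For survivor-signature
  work, `simulate_survival_from_risk` places risk groups on opposite sides
  of the landmark with a fixed 5% misalignment: with a realistic hazard
  ratio the landmark groups are otherwise so mixed that no planted mean
  shift survives group averaging, while zero misalignment would make any
  marker perfectly separate survival and render Cox non-identifiable.
- **Missingness** is completely at random; the detection-p mechanism is
  not modeled mechanistically. No batch or slide effects, no tumor-purity
  mixtures, no IDAT-level simulation.

Passing recovery tests on this cohort shows the pipeline's selection logic
and statistics are correct under the assumed noise model; it does not show
robustness to batch structure, purity variation, or probe cross-reactivity,
which real arrays have and the generator does not.

## Problem sizes and tolerances

Recovery experiments run at 5000 probes with 15 samples per stage (stage
screen) and 3000 probes with 20 patients per survivor group (signature);
calibration uses 10⁴ Mann–Whitney and 10³ log-rank null replicates, judged
against binomial 99% bands around the nominal 0.05. Oracle equivalences are
exact to numerical precision: Mann–Whitney vs full enumeration for all
pooled sizes ≤ 10, BH vs the brute-force step-up definition, Fisher vs
hypergeometric enumeration for all 2×2 tables with total ≤ 40, Cox vs
brute-force likelihood maximization (|Δ| < 1e-4), Kaplan–Meier vs the hand
product-limit. The Cox log-HR recovery bound of 0.25 at n = 200 is roughly
1.5 standard errors, so it is seed-sensitive by construction; the shipped
seed satisfies it and the acceptance script reports the measured error.

## Known limitations

- Counts depend on the input cohort; published probe counts from the
  original study are not reproducible without its raw data and
  era-specific SNP blacklists, and are not targets of this package.
- Gene-symbol matching is exact; aliases and retired symbols will not
  join across methylation and expression tables.
- The Cox implementation handles a handful of covariates; it is not a
  general-purpose survival package.
- `anova_screen` loops probes in Python; fine for array-scale inputs
  (~10⁵ probes in minutes) but not optimized beyond that.
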