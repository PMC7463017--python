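# Methods

## The pathway-activity model

`erpathway` infers the transcriptional activity of the oestrogen-receptor
(ER) transcription complex from the mRNA levels of its target genes. The
model is a two-layer Bayesian network with three node types:

1. a single binary **activation node** TF ∈ {active, inactive} with prior
   P(TF = active) = `prior_active`;
2. per target gene a binary **regulation node** R ∈ {down, up} with
   P(R = up | TF) given by the gene's regulation CPT;
3. per target gene a binary **intensity node** I ∈ {low, high} with
   P(I = high | R) given by the gene's intensity CPT.

Continuous expression enters as *soft (virtual) evidence* on the intensity
node: a weight e ∈ [0, 1] on the state "high". Conditioned on TF the genes
are independent, so the posterior odds factorise,

    odds(active | e₁..e_G) = prior_odds · ∏_g LR_g(e_g),
    LR_g(e) = Σ_r P(r|active)·(e·P(high|r) + (1−e)·P(low|r))
            / Σ_r P(r|inactive)·(e·P(high|r) + (1−e)·P(low|r)).

The log2 of the posterior odds is mapped affinely onto [0, 100] using the
model's attainable range: because each LR is a monotone Möbius function of
e, the per-gene extremes sit at e ∈ {0, 1}, and the range endpoints are the
totals with every gene at its minimising/maximising endpoint (prior term
included). A score of 0 is therefore the lowest odds the model can express
and 100 the highest — by construction, not by data-dependent rescaling.

Exactness of the factored inference is guarded by an independent oracle,
`brute_force_posterior`, which enumerates every joint (TF, R_g, I_g)
assignment (≤ 12 genes) and must agree with the factored posterior to
1e−10; the test suite checks 500 random models.

**Assumptions.** Genes are conditionally independent given TF; evidence
weights follow virtual-evidence semantics; genes without evidence are
marginalised out (LR = 1) rather than imputed, with `n_genes_used`
reported. The default prior is 0.5 (odds 1:1) so the score is purely
evidence-driven.

## Evidence mapping

Expression (log2 scale) is converted to evidence by the posterior
responsibility of the "high" component under a two-component normal model
with equal class priors: the "high" component is fitted on ground-truth
*active* samples, the "low" component on *inactive* samples. For repressed
targets the active-class mean lies below the inactive-class mean; evidence
is therefore automatically oriented towards the activity-associated state
and no explicit sign flipping is needed (a `direction` flag records the
orientation). With equal class SDs the map reduces to a logistic function
of expression, which the tests verify in closed form.

Class SDs are floored at **0.05 log2 units** to keep a zero-variance
calibration class from generating degenerate 0/1 evidence.

## Calibration

Ground-truth samples of known pathway state (emulating oestradiol-
stimulated vs deprived MCF7 profiles) drive four steps:

1. **intensity maps** — per-gene class means/SDs as above;
2. **gene selection** — Mann–Whitney AUC per gene (computed from midranks,
   identical to exhaustive pair counting with tie halving); genes pass at
   directional AUC = max(AUC, 1−AUC) ≥ **0.8**, the top **20** are kept,
   ties broken lexicographically by gene id for determinism;
3. **CPT estimation** — P(I=high | R=up) and P(I=high | R=down) are the
   Laplace-smoothed (pseudocount **1**) mean evidence in the active and
   inactive classes; the regulation layer is a fixed near-deterministic
   link P(R=up | TF=active) = **0.95** (the regulation structure of the
   published test is knowledge-based; a fixed high-fidelity link is the
   minimal faithful stand-in);
4. **score range** — per-gene log2 LR extremes accumulated with the prior.

Calibration fails loudly (with the selection report attached) if no gene
passes, if the model range collapses, or if the calibrated model does not
rank active above inactive calibration samples.

## qPCR ingestion

FFPE cohorts are measured by qPCR rather than microarray. Cq tables are
normalised by the standard ΔCq convention: technical replicates are
averaged on the Cq scale, ΔCq = Cq_target − mean(Cq over reference genes)
per sample, and log2 relative expression = −ΔCq. The arithmetic mean of
reference Cq values is equivalent to the geometric mean of reference
expression. Samples lacking all reference genes are dropped and reported.

## Synthetic-data generator

The generator emulates the study's inputs with a **shared latent design**:
one latent activity a ∈ [0, 100] per sample drives expression, IHC and
outcome, so that the cohort-level association claims are true by
construction and recoverable by the pipeline.

* **Tissue groups** — a ~ truncated normal with the published group
  parameters: proliferative 41 (SD 8), hyperplasia 43 (SD 4), EEC stage I
  36 (SD 11), EEC stage II–IV 31 (SD 9), USC 28 (SD 13); default group
  sizes 4/20/57/12/14.
* **Expression** — 100 genes, 25 % informative; informative gene g has
  x_g = baseline_g + s_g·δ·(a−50)/100 + N(0, 1), with per-gene sign s_g
  and effect size δ = 2 log2 units. Calibration classes sit at the latent
  extremes (a = 100/0), i.e. classes differ by ±δ/2 per informative gene.
  δ = 2 with unit noise gives a per-gene ground-truth AUC of
  Φ(2/√2) ≈ 0.92 — strong but imperfect markers, matching a realistic
  targeted panel.
* **IHC** — ER % = clamp(1.6·a − 20 + N(0, 15), 0, 100) (PR with intercept
  −10, noise SD 18). The noise keeps the IHC↔activity relation imperfect;
  no published correlation coefficient exists to match, so the link is
  tunable and not claimed to reproduce unpublished values.
* **Outcomes** — recurrence times are exponential with rate
  λ(a) = 0.0006 · exp(0.9·(50−a)/10) per month; disease-specific death at
  0.5·λ(a); administrative censoring uniform on 36–120 months (the study
  required ≥ 36 months follow-up; median follow-up 57/45/28 months per
  group). With these defaults the EEC-I group mean activity yields ≈ 15 %
  recurrence over a median follow-up, matching the published 14 %.
  Residual-disease flags are assigned per group to the published exclusion
  counts (USC 4, EEC II–IV 1). Grade is tied to the lowest-activity
  fraction of each EEC group (published grade-3 rates); FIGO, LVSI and
  myometrial invasion are drawn at the published per-group rates,
  independent of a.

All randomness flows from a single seed through named substreams
(metadata / calibration / validation / cohort / qPCR), making outputs
byte-reproducible and hold-out sets independent.

### What the generator does not emulate

Probe-level microarray artifacts, batch/platform shifts in intensity
scale, menstrual-cycle dynamics beyond group means, competing risks, and
correlation between stage covariates and activity beyond the grade link.
Passing tests therefore demonstrate the pipeline's correctness and
statistical calibration on data satisfying the generative assumptions, not
performance on clinical material.

### Score read-out is compressed, by design of the scorer

The score is a saturating transform of summed per-gene log2 likelihood
ratios. Scoring a cohort with a model calibrated at the activity extremes
yields an approximately affine read-out with gain ≈ 0.6 toward the
midpoint (latent 28 scores ≈ 37) plus ≈ 7 points of per-sample measurement
noise from the 20-gene evidence sum. Group-mean *ordering* is preserved
exactly and scores correlate strongly with the latent state, which is what
the loop-closure property test asserts; the configured group parameters
are matched on the latent scale, not the scored scale. An unbiased scored
read-out would require calibrating the generator against its own consumer,
which would make the recovery tests circular.

## Statistical stages

* Multi-group comparisons: one-way ANOVA with Tukey HSD post-hoc adjusted
  p-values (singleton groups excluded with a warning); Mann–Whitney U for
  two-group continuous calls; χ² for categorical tables. All two-sided at
  α = 0.05.
* IHC groups 0–10 / 11–50 / 51–100 % with inclusive upper bounds; ER-low
  at ≤ 10 %.
* Activity quartiles by sample-quantile cuts; ties fall into the lower
  quartile (deterministic; eight equal scores are all quartile 1).
  Combined high-risk = ER-low AND first quartile.
* Survival: Kaplan–Meier product-limit curves, two-sided log-rank tests;
  DFS excludes residual-disease patients; DFS/DSS clocks start at surgery.
  Cox regression uses Efron tie handling (lifelines default); multivariate
  models include only covariates with univariate p ≤ 0.05; constant or
  non-converging covariates are reported as non-estimable, never silently
  dropped.

## Numerical choices

* Scores are clamped to [0, 100]; drift beyond 1e−9 in log2-odds units
  triggers a warning (anything smaller is float noise).
* The scoring normalisation computes the ratio before scaling by 100 so
  extreme evidence lands exactly on 0/100.
* Model documents (YAML) round-trip losslessly (Python float repr).
* CPT probabilities are constrained to the open interval (0, 1);
  pseudocount smoothing guarantees this for estimated tables.
* The brute-force oracle enumerates ≤ 8 genes as a dense state grid and
  chunks larger models (≤ 12) to bound memory.

## Problem sizes used in the test suite

Simulation-backed tests are sized to keep the default suite fast while
leaving comfortable statistical margins: oracle equivalence over 500
random models; CPT recovery at n = 500/class (binomial SE ≈ 0.013 against
a ±0.05 band); hazard-coefficient recovery on a 2 000-patient cohort
(≈ 400 events, SE(β) ≈ 0.05 against a ±25 % band); type-I error of the
omnibus comparison from 1 000 null replicates (SE ≈ 0.007 against a ±0.02
band); pattern-reproduction checks at 500 samples per tissue group; the
loop-closure property at 1 000 per group.

## Known limitations

* The published gene panel and CPT values are proprietary; the package is
  panel-agnostic and calibrates its own CPTs from ground truth.
* The published discretisation of continuous expression is likewise
  unpublished; the two-component responsibility map is a transparent,
  monotone replacement calibrated from the same ground-truth design.
* Cross-platform (array ↔ qPCR) agreement is demonstrated only on
  synthetic paired data.
* How the published model handles between-cohort batch shifts is not
  described; the package does not re-normalise per cohort.
* DSS event times are generated independently of recurrence times, so a
  sample can die of disease without a recorded earlier recurrence.
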