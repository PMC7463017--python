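# erpathway

Quantifying **oestrogen-receptor (ER) pathway activity** from target-gene
mRNA, and relating it to outcome in endometrial tissue.

ER and PR immunohistochemistry (IHC) are established prognostic markers in
endometrial cancer, but receptor *expression* does not reveal whether the
receptor is transcriptionally *active*. This package implements a
Bayesian-network pathway test that infers the odds of an active ER
transcription complex from the expression of its target genes, normalises
those odds to a 0–100 activity score, and provides the full surrounding
pipeline: ground-truth calibration, microarray/qPCR ingestion with ΔCq
reference-gene normalisation, a synthetic-cohort generator, and the cohort
statistics (ANOVA/Tukey, Mann–Whitney, χ², Kaplan–Meier/log-rank, Cox
regression) used to evaluate the score's prognostic value. It is aimed at
computational biologists who want a transparent, testable re-implementation
of transcription-factor activity scoring for method development on
synthetic or in-house data.

## The model

For each target gene g, a two-layer network links the ER transcription
complex TF ∈ {active, inactive} to a regulation node R_g ∈ {down, up} and
an intensity node I_g ∈ {low, high}. Expression enters as soft evidence
e_g ∈ [0, 1] on I_g = high, and the posterior odds factorise:

    odds(TF = active | e) = P(active)/P(inactive) · ∏_g LR_g(e_g)

    LR_g(e) = Σ_r P(r|active) [e·P(high|r) + (1−e)·P(low|r)]
            / Σ_r P(r|inactive) [e·P(high|r) + (1−e)·P(low|r)]

The activity score maps log2 odds affinely onto [0, 100], anchored at the
model's attainable extremes: 0 = lowest odds the model can infer, 100 =
highest. Factored inference is verified against full joint enumeration to
1e−10 in the test suite.

Models are calibrated on samples of known pathway state (e.g. oestradiol-
stimulated vs hormone-deprived cell-line profiles): genes are selected by
Mann–Whitney AUC, intensity distributions and CPTs estimated per class,
and the score range computed. See `docs/methods.md` for the full account.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1). `python analysis/01_simulate.py` writes a ground-truth
calibration set and a 107-sample cohort with the published tissue
composition; `python analysis/02_calibrate.py` then prints:

```
selected 20 of 100 genes; log2-odds range [-33.26, 33.36]
held-out validation: mean active score 78.3, mean inactive score 22.4, AUC 1.000
```

i.e. 20 target genes passed the AUC ≥ 0.8 screen, and on held-out samples
of known state the score separates active from inactive perfectly.
`python analysis/03_score_and_compare.py` scores the cohort blind to the
clinical table and compares tissue groups:

```
pathway activity by tissue group (mean, SD):
  eec_stage_i       43.1 (SD 11.2), n=57
  eec_stage_ii_iv   38.2 (SD 9.8), n=12
  hyperplasia       48.4 (SD 8.5), n=20
  proliferative     48.6 (SD 6.4), n=4
  usc               39.9 (SD 11.9), n=14
one-way ANOVA: F = 2.47, p = 0.049
recurrent vs non-recurrent mean score: 38 (SD 10) vs 44 (SD 12), Mann-Whitney p = 0.0426
```

Benign/early tissue scores highest, advanced-stage and serous cancers
lowest, and patients who later recur score significantly lower — the
qualitative pattern the score is designed to expose. (Scores read out the
latent activity with a gain below 1, so group means sit closer to 50 than
the generator's latent parameters; `docs/methods.md` discusses this.)
`python analysis/04_survival.py` adds Kaplan–Meier/log-rank and Cox
analyses, e.g. DFS by combined risk group (ER IHC ≤ 10 % *and* lowest
activity quartile): survival at 60 months 0.47 vs 0.81, log-rank p = 0.026.

The same pipeline is available as a CLI for external data:

```
erpathway simulate --seed 1 --out-dir run/
erpathway calibrate --matrix run/calibration_matrix.tsv \
    --labels run/calibration_labels.csv --model-out run/model.yaml
erpathway score --model run/model.yaml --matrix run/cohort_expression.tsv \
    --out run/scores.tsv
erpathway analyze --scores run/scores.tsv --clinical run/clinical.csv \
    --out-dir run/reports/
```

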