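# pairrank

Rank-based gene-pair prognostic signatures for survival analysis of
transcriptomic cohorts.

## The problem

Gene-expression prognostic models rarely transfer between cohorts because
every platform (RNA-seq counts, microarray intensities) puts expression on
a different scale, and cross-platform normalization is fragile. The
relative-expression-ordering idea sidesteps normalization entirely: for a
pair of genes *(a, b)* define, within each sample *s*,

    I(a, b, s) = 1  if  expr(a, s) > expr(b, s),   else 0.

The indicator depends only on the within-sample ranking, so it is
invariant under any strictly increasing per-sample transform of the
measurements — a signature built from such indicators can be trained on
one platform and applied to another with no rescaling. A sample's risk
score is a weighted sum over the signature's pairs,

    score(s) = Σ_k  β_k · I(a_k, b_k, s),

with coefficients β from L1-penalized (LASSO) Cox regression.

`pairrank` implements the complete pipeline around this idea for
immune-related gene-pair (IRGP) signatures:

- **data_io** — expression / clinical / gene-list / signature readers and
  writers, duplicate-probe collapsing by mean, stratified cohort summary
  tables. A published 22-pair head-and-neck squamous cell carcinoma
  signature (28 unique immune genes) ships as a bundled fixture, along
  with its cohort's clinical count table.
- **pair_engine** — MAD gene filter (raw median absolute deviation > 0.5),
  exhaustive within-sample pair binarization, 20% prevalence filter,
  risk scoring, cutoff-based group assignment.
- **signature_selection** — stability-style selection: repeated 80%
  subsample refits of LASSO-Cox over the pair indicators (penalty per
  refit by cross-validated partial likelihood), frequency ranking, and a
  final penalized fit for the coefficients.
- **survival_eval** — cumulative/dynamic time-dependent ROC with
  Kaplan–Meier censoring weights (cutoff = Youden optimum at 3 years),
  Kaplan–Meier curves, log-rank tests, univariate/multivariate Cox
  reports with Wald CIs.
- **immune_assoc** — immune-cell fraction estimation by non-negative
  least squares against a user-supplied signature (basis) matrix, rank-sum
  group differences and Pearson score–fraction correlations.
- **synthetic** — cohort generator with planted pair effects
  (Cox–Weibull survival, calibrated censoring), per-sample monotone
  "platform" distortions, and score-linked immune mixtures, so the whole
  pipeline is testable without any download.

## Worked example

The `analysis/` directory holds the end-to-end study on synthetic data;
run the scripts in order. `01_simulate_cohorts.py` splits one latent
300-tumor cohort into two differently distorted "platforms" with 5
informative pairs (log-hazard effects ±1, ~30% censoring).
`02_build_pair_matrix.py` applies the filter cascade:

```
genes on training platform:            25
after cross-platform intersection:     15
after MAD > 0.5 (log2 scale):          15
candidate pairs (all combinations):    105
after 20% prevalence filter:           72
```

`03_select_signature.py` runs 200 resampled LASSO-Cox refits; all 5
planted pairs rank in the top 10 by selection frequency and 9 pairs pass
the 0.5 frequency threshold. `04_evaluate_survival.py` picks the cutoff
on the training half (3-year time-dependent ROC) and evaluates both
halves:

```
training 3-year AUC 0.944; cutoff 1.6174 (sens 0.855, spec 0.894)
[train] n=150 (68 high risk): log-rank chi2=123.3 p=1.23e-28; 5-year AUC 0.942
  univariate   HR(risk_group_high) = 12.345 [7.339, 20.765] p=2.75e-21
  multivariate HR(risk_group_high) = 13.745 [7.776, 24.295] p=1.92e-19
[valid] n=150 (69 high risk): log-rank chi2=57.1 p=4.20e-14; 5-year AUC 0.899
  univariate   HR(risk_group_high) = 4.891 [3.135, 7.633] p=2.72e-12
  multivariate HR(risk_group_high) = 5.389 [3.335, 8.707] p=5.97e-12
```

The validation half was observed through a different monotone distortion
family and is scored with no renormalization — the separation
(log-rank p = 4.2e-14, HR ≈ 4.9 for high- vs low-score patients) carries
over because only within-sample orderings enter the score.
`05_immune_association.py` ties immune fractions to the score (planted
Pearson correlations −0.35/+0.35 for two of five synthetic cell types)
and recovers them from NNLS-deconvolved mixtures (r = −0.413 / +0.364).

The same pipeline is available as a CLI (`pairrank simulate | binarize |
train | score | evaluate | deconvolve | immune-assoc`), or in one shot
from a YAML config with a reproducible run manifest:

```sh
pairrank run --config config.yaml
```

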