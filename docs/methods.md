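# Methods

## The pair indicator and its invariance

The primitive is the within-sample comparison: for an ordered gene pair
*(a, b)* and sample *s*, the indicator is 1 exactly when
expr(a, s) > expr(b, s); ties score 0. Ties are worth spelling out
because RNA-seq zero counts make them common: the "otherwise 0" rule
means a pair of jointly unexpressed genes contributes nothing to the
score rather than a coin flip. Each unordered pair appears once, in the
canonical direction given by input row order; the reverse direction is
the complement on tie-free data and would be perfectly collinear with
the forward direction in any penalized regression, so it is never
emitted.

Because the indicator depends only on the within-sample ordering, it is
invariant under any strictly increasing per-sample transform of the
expression values. This is the property that licenses cross-platform
application of a trained signature with no normalization, and it is
tested bit-for-bit (affine, cubic and log transforms applied to
different samples of the same matrix).

## Filters

**MAD filter.** Genes are kept when their raw median absolute deviation
across samples — median of |x − median(x)|, with *no* 1.4826 consistency
constant — strictly exceeds 0.5. The scale on which the MAD is computed
is configurable (`log2_transform`): log2(x+1) is the sensible scale for
counts, native scale for microarray intensities. The boundary is strict:
a gene with MAD exactly 0.5 is dropped.

**Prevalence filter.** A pair whose indicator is 1 (or 0) in less than
20% of samples is nearly constant and carries no ranking information;
"less than" is read literally, so a pair at exactly 20% is kept. After
the filter every retained pair has minority fraction ≥ the threshold by
construction.

**Gene-list restriction.** The immune-gene intersection (and, for
multi-cohort work, the cross-platform gene intersection) runs before the
MAD filter. Intersection sizes are logged, not asserted — they are
cohort- and platform-specific.

## Signature selection

Selection is stability-style: `n_iterations` (default 1000; the
simulation studies in the tests use 200, scaled to their smaller
problems) repetitions of: draw 80% of samples without replacement; fit
the L1-penalized Cox path (scikit-survival's Coxnet, Breslow ties); pick
the penalty maximizing k-fold cross-validated partial log-likelihood
(Breslow, implemented here; k = 3 inside the loop, 5 in the final fit);
record which pairs have nonzero coefficients at that penalty. A pair's
selection frequency is the fraction of repetitions in which it was
nonzero. Default selection rule: frequency ≥ 0.5, ties broken
lexicographically by pair id so results are reproducible. Final
coefficients come from a single penalized fit on the full training data
restricted to the selected pairs, at the CV-optimal penalty; pairs shrunk
exactly to zero are dropped with a log entry. Coefficients are therefore
LASSO-scale (shrunken), which is the convention the bundled published
signature also follows.

Randomness: one master seed; per-iteration generators are spawned from
deterministic child seeds, so identical seed + inputs give bit-identical
results. Subsamples with fewer than 2 events are redrawn (bounded
retries).

## Cutoff and survival evaluation

**Time-dependent ROC.** Cumulative cases / dynamic controls at a fixed
horizon (36 months for cutoff selection, 60 months for validation AUC):
cases are subjects with an observed event by the horizon, controls are
subjects still event-free past it, and subjects censored before the
horizon are removed with the case side reweighted by the inverse
Kaplan–Meier censoring survival just before each event time (IPCW). This
estimator is deterministic (no smoothing bandwidth), reduces exactly to
the empirical binary ROC when no censoring precedes the horizon, and
yields monotone sensitivity/specificity in the threshold by
construction. AUC is the trapezoid over (1 − specificity, sensitivity)
with the (0,0) and (1,1) endpoints appended. The cutoff maximizes the
Youden index (sens + spec − 1); ties resolve toward the *lower* cutoff,
which makes the high-risk group larger. Group assignment is strict:
score > cutoff → high.

**Kaplan–Meier, log-rank, Cox.** The product-limit estimator and the
log-rank test come from lifelines; a helper exposes the per-group
observed-minus-expected tally so the *direction* of a separation (which
group fares worse) can be reported alongside the p-value. Cox reports
give hazard ratios with Wald 95% CIs and p-values, each covariate alone
(univariate) and all jointly (multivariate); categorical covariates are
dummy-coded with the first level as reference, except risk groups, which
are always reported as high-vs-low. Rows missing a covariate are dropped
per model; a warning is emitted below 10 events; non-convergence or
separation is reported per covariate (NaN estimates and a note) rather
than aborting the report. lifelines handles ties by Efron's method; the
penalized selection path uses Breslow. The two coincide on continuous
(tie-free) survival times, which is what the generator produces. No
multiple-testing correction is applied anywhere; all p-values are raw.

## Immune-fraction association

Cell composition is estimated by non-negative least squares of each bulk
profile against a user-supplied genes × cell-types basis matrix on their
shared genes, with the fitted weights normalized to fractions summing
to 1. This is a linear stand-in for dedicated deconvolution machinery
(ν-SVR with quantile normalization and permutation p-values); the
association functions equally accept externally computed fraction tables.
NNLS is scale-equivariant up to the normalization, so mixtures on
arbitrary scales are handled. Group differences use two-sided
Mann–Whitney rank-sum tests (medians reported; constant cell types are
flagged with p = 1); score associations use Pearson correlation with
two-sided p-values.

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes,
at sizes chosen to resemble a mid-sized tumor cohort:

- latent per-gene log-expression, Gaussian with gene-specific means
  (N(5, 1.5)) and spreads (U(0.8, 1.5));
- a designated set of informative pairs (chosen among pairs with
  balanced indicator prevalence so the filters cannot remove them),
  whose indicators drive the hazard linearly with user-set log-hazard
  coefficients (default ±1);
- survival from a Weibull baseline (shape 1.2, scale 60 months — median
  latent survival near 4 years), so the proportional-hazards fit is
  non-trivial but correct;
- independent exponential censoring whose rate is solved numerically
  (bisection on the expected censored fraction given the drawn event
  times) to hit the target rate, default 30%;
- prognosis-neutral clinical covariates (age, gender, T/N/M stage,
  grade) with ~2% missingness in the stage variables;
- observed expression = per-sample strictly increasing distortion of the
  latent values. Families: `exp-affine` (x ↦ exp(bx + c)), `power`
  (x ↦ a(x − xmin + 1)^p), `none`; a deliberately non-monotone `broken`
  family exists solely to demonstrate when rank-based scoring fails.
  The two-platform generator splits one latent cohort, applies a
  different family to each half, and appends disjoint platform-specific
  extra genes.

The immune generator builds a marker-block basis (5 cell types × 20
markers by default), Dirichlet fractions, and tilts chosen cell types so
their fraction correlates with a supplied score: an auxiliary Gaussian
latent is constructed with *exactly* the target in-sample correlation to
the score (orthogonalized noise), and the Dirichlet draws for that cell
type are reordered to follow its ranks before renormalization. The
realized Pearson correlation on the fraction scale is then attenuated
only by the skewed Dirichlet margins and measurement noise (observed
deviations ≲ 0.08 at n = 472 for targets of ±0.35). Planted |ρ| above
0.9 is refused.

What the generator does **not** emulate: negative-binomial count noise
and library-size effects (only the rank structure matters downstream),
gene–gene correlation beyond the planted pairs, informative censoring,
prognostic clinical covariates, and real immune-cell co-variation.
Passing tests therefore demonstrate correctness of the machinery under
the model's own assumptions — rank-preserving platform effects,
proportional hazards, independent censoring — not performance on any
real cohort, where those assumptions hold only approximately.

## Null controls and problem sizes

The recovery studies use n = 300 samples, 15 genes (105 candidate
pairs), 5 planted pairs with |coefficient| = 1, 30% censoring, and 200
selection iterations; held-out transfer uses a 150/150 two-platform
split with selection at 50 iterations per seed over 10 seeds.
"Separation" on a held-out cohort is directional: log-rank p < 0.05
*and* excess observed deaths in the high-score group — the claim a risk
signature actually makes. The shuffled-survival null rate is estimated
from 20 permutations per seed (the permutation stream is seeded
distinctly from the simulation stream); its expected value for a
calibrated directional test is 2.5%. Calibration checks use n = 1000 for
the null AUC (expected 0.5) and 200 replicates of n = 200 for the
uniformity of null log-rank p-values (Kolmogorov–Smirnov).

## Degenerate inputs and numerical conventions

Distinct parse errors name the offending row/column (non-numeric cells,
duplicate sample ids, missing required columns). Times are canonical in
months (12 months/year, 30.44 days/month). Signature files round-trip
with coefficients serialized to 6 decimals (one more than the bundled
signature's printed precision). Scores exactly at the cutoff go to the
low-risk group. Zero-variance inputs to correlation raise; constant cell
types in group comparison are flagged rather than raised. The cohort
summary table reports explicit "Missing" rows and within-group
percentages to one decimal, which sum to 100% up to rounding.

## Known limitations

The prevalence and MAD thresholds interact with cohort composition;
heavily imbalanced cohorts can silently thin the candidate set (counts
are logged at every filter for this reason). Stability-selection
frequencies are not selection probabilities and have no finite-sample
error control; the 0.5 default is a convention. The NNLS deconvolution
inherits the usual linear-mixing assumptions and a user-supplied basis;
it is not a substitute for basis construction. The time-dependent ROC's
IPCW weights assume censoring independent of the score.
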