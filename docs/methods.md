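# Methods

## The model

This package builds and evaluates **pathway-pair survival signatures** for
bulk transcriptomics. The motivating problem is portability: prognostic
models built on absolute gene expression rarely transfer between cohorts
sequenced on different platforms, because platform effects shift and rescale
expression values per sample. The method sidesteps this by working entirely
with **within-sample rank order**:

1. **ssGSEA scoring.** Each pathway *P* (a named gene set) is scored per
   sample by a rank-weighted running sum. Genes are ranked by expression
   within the sample (largest value = largest rank *N*); walking the genes
   in descending rank order, the score is

   S(P) = Σ_k [ P_in(k) − P_out(k) ],

   where P_in(k) is the cumulative rank^α-weighted fraction of in-set genes
   among the first *k* positions and P_out(k) the uniform cumulative
   fraction of out-of-set genes. The statistic is the *sum* of the running
   difference over all positions (the single-sample variant), not the
   maximum deviation used by two-group GSEA.

2. **Pair features.** For every unordered pathway pair (A, B), taken in
   catalog order, a sample contributes one bit: 1 if S(A) > S(B), else 0
   (ties give 0). Pairs that are almost constant in the training cohort —
   fraction of ones outside [0.2, 0.8], both boundaries inclusive — are
   discarded.

3. **Selection chain.** Surviving pairs pass through (i) a per-pair
   univariable Cox screen (Wald p < 0.05), (ii) LASSO-penalized Cox
   regression with the penalty chosen by 10-fold cross-validated partial-
   likelihood deviance ("min" rule), and (iii) backward stepwise elimination
   under AIC in a multivariable Cox model. The retained pairs and their
   multivariable log hazard ratios form the signature.

4. **Risk score (MPPS).** score(s) = Σ_i coef_i · value_i(s). Each cohort is
   split at its own maximally selected log-rank cutpoint (minimum group
   proportion 0.1; "high" = score strictly above the cutpoint); cutpoints
   are never transferred between cohorts.

5. **Evaluation.** Kaplan–Meier curves, the log-rank test,
   cumulative/dynamic time-dependent ROC with inverse-probability-of-
   censoring weights, Harrell's C-index, a multivariable clinical Cox model
   (whose linear predictor plus baseline survival is the numeric core of a
   nomogram) with quantile-binned calibration, and Wilcoxon/Kruskal–Wallis
   group comparisons with Benjamini–Hochberg adjustment.

Because steps 1–2 depend only on per-sample rank order, any strictly
increasing per-sample transform of expression — the idealized form of a
platform effect — leaves the pair matrix, the risk scores and every
downstream metric bit-identical. This is the package's headline invariant
and is asserted end-to-end in the test suite.

## Key parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `alpha` | 0.25 | ssGSEA rank-weight exponent; the value used by the common single-sample implementation. Rank-based weighting keeps the score monotone-invariant. |
| `min_size` | 5 | Minimum genes of a set present in a cohort; smaller sets are dropped with a warning, so platform gene dropout cannot silently change the catalog. |
| `normalize` | True | Global min–max rescaling of the whole score matrix. A single affine map preserves within-sample ordering, so it provably never changes the pair matrix. |
| filter `low`, `high` | 0.2, 0.8 | Prevalence window for informative pairs; boundaries inclusive (the removal rule is *strictly* more than 80% or less than 20%). |
| screen `p_threshold` | 0.05 | Univariable Wald threshold; convention, exposed in config. |
| `folds`, `lambda_rule` | 10, "min" | CV-LASSO settings. Binary pair features share a scale and are not standardized. The CV seed is recorded in the model. |
| stepwise `direction` | "backward" | AIC refinement starting from the LASSO set; "both" also re-admits dropped terms. |
| `minprop` | 0.1 | Minimum group proportion for the maximally selected cutpoint (the common default of maximally-selected-rank-statistic implementations); tie among maxima → smallest cutpoint. |
| ties | Efron | Event-time ties in every partial likelihood. Newton iterations with step-halving, tolerance 1e-7 on the log partial likelihood, max 100 iterations. |

Expression ranking ties are broken by gene ID (lexicographically smaller ID
gets the higher rank) — an arbitrary but documented and deterministic rule,
so identical inputs reproduce identical outputs on any platform.

## The synthetic world

No real cohorts ship with the package; every test runs on the bundled
generator, which emulates the *structure* the analysis assumes:

- a catalog of 20 pathways × 60 genes over 2000 genes, 10% of each set
  drawn from a shared pool (overlapping sets);
- per-sample latent pathway activities: Gaussian with pathway-specific means
  (spread 1.0) and unit per-sample jitter; three causal pairs get a fixed
  mean separation of 0.4, which places their pair prevalence near 0.6 —
  safely inside the filter window;
- expression = gene baseline N(5, 0.8²) + mean activity of the gene's
  pathway(s) + N(0, 0.7²) noise, on a log-like scale;
- event times from a proportional-hazards model on the TRUE pair indicators
  1[activity_a > activity_b] with log hazard ratios +1.0, +0.8, −0.9 and an
  exponential baseline hazard 0.1 per year (Weibull optional, to stress the
  proportional-hazards assumption);
- independent censoring calibrated to 30%, implemented as early dropout:
  a calibrated fraction of subjects can drop out uniformly within the first
  5% of the baseline mean lifetime. Dropping out this early is nearly
  uninformative about risk, so the censoring indicator stays essentially
  uncorrelated with the linear predictor (|r| < 0.1) — a property a
  late-censoring mechanism cannot deliver when effects are strong;
- per-cohort platform distortion: per-gene batch offsets, then random gene
  dropout (5%), then an independent strictly increasing affine-power map per
  sample (the map is applied last, so it sets the final within-sample
  ranks).

The noise scales were calibrated once, at design time, so that the world
satisfies its own contracts — pathway scores track latent activities with
r > 0.85 and the pipeline's pair bits agree with the true indicators for
better than 90% of samples — and were then frozen.

What the generator does **not** emulate: negative-binomial count noise,
library-size effects, tumor purity, correlated censoring, non-proportional
hazards beyond the Weibull option. A green test therefore establishes that
the pipeline recovers the structure it assumes, not that it is robust to
every failure mode of real RNA-seq.

## Numerical and design choices

- **Cox core.** A compact Efron-tie Newton solver backs the univariable
  screen and stepwise AIC (≈10³ fits per training run); it is cross-checked
  against `lifelines` to 1e-5 in the tests. Standard single-fit steps
  (Kaplan–Meier, log-rank, Harrell's C, the clinical model with baseline
  survival) go through `lifelines`; the LASSO path goes through
  scikit-survival's pathwise coordinate descent, with the fold deviance
  computed as −2·[pl_all(β) − pl_train(β)] (the glmnet convention).
- **Time-dependent ROC.** Cumulative/dynamic with marginal Kaplan–Meier
  IPCW; cases weighted 1/G(T⁻), controls 1/G(t); score ties count ½. An
  additive-hazards (conditional) censoring model is deliberately out of
  scope; the estimator is cross-checked against scikit-survival's
  implementation.
- **Cutpoint search.** Exhaustive over observed score values with the
  minimum-group constraint — the estimator *is* the brute force, so the
  test oracle re-derives it through an independent log-rank routine.
- **Degenerate inputs.** Zero-variance pairs are skipped (not fitted) in
  the screen; non-convergent stepwise candidates count as AIC = +∞; empty
  prevalence filters, empty LASSO selections and missing pathways in
  validation cohorts raise stage-labelled errors.
- **Determinism.** All generator randomness flows from one root seed via
  named substreams; the LASSO CV seed is stored in the model; metrics JSON
  is written with sorted keys and no timestamps, making reruns
  byte-identical.

## Known limitations

- The single-sample score depends mildly on the gene universe (ranks and
  the out-of-set denominator), so gene dropout changes scores slightly even
  for intact pathways; exact platform invariance holds for monotone
  distortions, near-invariance for small dropout.
- Stepwise AIC after LASSO inherits the usual post-selection caveats; the
  reported multivariable coefficients are not debiased.
- The maximally selected cutpoint is returned with its log-rank statistic
  uncorrected for the selection (the usual practice it mirrors); p-values
  for the induced grouping are therefore optimistic and are used for
  stratification, not inference.
- With ≤ ~40 candidate pairs after screening, the stepwise stage is exact
  enough; very large candidate sets would make the O(k²) elimination loop
  slow.
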