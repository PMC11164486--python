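# mpps — pathway-pair survival signatures

Prognostic models built on absolute gene expression usually break when moved
to a cohort sequenced on a different platform: values shift, scales change,
genes go missing. `mpps` implements a platform-robust alternative for
survival modelling in bulk transcriptomics (built for multi-cohort lung
adenocarcinoma-style studies, but generic): score pathway activity per
sample with ssGSEA, reduce every **pair** of pathways to a single
within-sample bit — 1 if the first pathway out-scores the second — and build
a weighted Cox risk score on those bits. Because each bit depends only on
within-sample rank order, the trained signature transfers unchanged across
any strictly increasing per-sample distortion of expression.

The pipeline:

1. **ssGSEA** per pathway per sample (rank-weighted running sum, exponent α = 0.25);
2. **pair matrix**: value(A|B, s) = 1 iff score(A, s) > score(B, s), pairs with
   fraction-of-ones outside [0.2, 0.8] in the training cohort removed;
3. **selection chain**: univariable Cox screen (p < 0.05) → cross-validated
   LASSO-Cox → backward stepwise AIC;
4. **risk score**: MPPS(s) = Σᵢ coefᵢ · valueᵢ(s), with per-cohort maximally
   selected log-rank cutpoints splitting high- vs low-risk groups;
5. **evaluation**: Kaplan–Meier + log-rank, time-dependent ROC/AUC (IPCW),
   Harrell's C-index, multivariable clinical Cox with calibration, and
   FDR-adjusted rank-sum comparisons.

A bundled synthetic-cohort generator (`mpps.synthetic_data`) provides
multi-platform benchmark suites with known causal structure, so the whole
pipeline is testable without any data downloads. See `docs/methods.md` for
the model, assumptions and numerical choices.

## Worked example

```python
import mpps

# a synthetic study: 1 training cohort + 1 platform-shifted validation cohort
cfg = mpps.SimulationConfig(seed=1)          # n=600, 3 causal pairs, 30% censoring
suite = mpps.make_benchmark_suite(cfg, k_validation=1)

pc = mpps.PipelineConfig()
train = suite["train"]
result = mpps.train_pipeline(train.expression, train.gene_sets, train.survival, pc)
print(result.metrics["funnel"])
print(result.model.pair_ids)

val = suite["validation"][0]
_, strat, metrics = mpps.evaluate_cohort(result.model, val.expression,
                                         val.gene_sets, val.survival, pc)
print(round(metrics["c_index"], 3), metrics["logrank_p"])
```

prints

```
{'pairs_total': 190, 'pairs_after_prevalence_filter': 116, 'pairs_pass_screen': 29,
 'pairs_lasso': 18, 'pairs_final': 9}
['PW01|PW04', 'PW02|PW09', 'PW03|PW04', 'PW03|PW09', 'PW06|PW16',
 'PW07|PW08', 'PW11|PW12', 'PW11|PW19', 'PW12|PW14']
0.657 3.578820755150689e-23
```

Reading: of 190 possible pathway pairs, 116 survive the prevalence filter,
29 the univariable screen, 18 the LASSO, and 9 the AIC stage — including all
three planted causal pairs (`PW03|PW04`, `PW07|PW08`, `PW11|PW12`) with
correctly signed coefficients. On the held-out, platform-distorted cohort the
signature reaches C-index 0.657 and separates high- from low-risk groups at
log-rank p ≈ 4·10⁻²³.

The same flow is available from the shell:

```bash
mpps simulate --seed 1 --out-dir bench
mpps train --expression bench/cohort1/expression.tsv \
           --clinical bench/cohort1/clinical.tsv \
           --gmt bench/pathways.gmt --out-dir run
mpps validate --model run/model.json \
              --expression bench/validation1/expression.tsv \
              --clinical bench/validation1/clinical.tsv \
              --gmt bench/pathways.gmt --out-dir run
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the benchmark end-to-end from scratch: it simulates the default
synthetic study from the given seed, trains the signature through the full
selection chain, evaluates it on the held-out platform-shifted cohort, logs
the selection funnel and held-out metrics, and writes the collected values
as JSON.
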