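# icbtpred

Does the written exchange between patients and therapists predict symptom
outcome in guided internet-delivered cognitive behavioural therapy (ICBT)?
`icbtpred` implements, end to end, a comparison of text-based, symptom-based
and fused prediction models for post-treatment symptom severity, together
with the evaluation harness such a comparison needs when the symptom data
contain missing assessments: multiple imputation **before** cross-validation,
nested cross-validation for tuning, and Rubin's-rules pooling of performance
metrics across the imputed datasets.

Because routine-care clinical data of this kind cannot be shared, the package
ships a synthetic-cohort generator that reproduces the statistical structure
the analysis assumes — three treatment arms (depression / panic / social
anxiety) each scored on its own questionnaire (MADRS-S max 54, PDSS-SR max
28, LSAS-SR max 144), pre-treatment severity near 44 % of the scale maximum
falling to roughly 27 % after treatment, per-timepoint missingness between
3 % and 40 %, heavy-tailed early word counts, and message text whose token
frequencies carry a *tunable* amount of signal about each patient's latent
improvement. Every stage of the pipeline is therefore testable offline.

## Models compared

All outcomes are min-max scaled, `y = raw / scale_max`, so RMSE reads as the
mean fraction of the scale by which a prediction misses. Continuous
predictions are dichotomized in retrospect into treatment success (raw
prediction below the questionnaire's remission cutoff, or ≤ 50 % of the
pre-treatment score) for balanced accuracy (BACC) and F1.

| family         | input                                    |
|----------------|------------------------------------------|
| `dummy`        | nothing (predicts the outcome mean)      |
| `linear`       | 9 features: scaled scores at screening, pre, weeks 1–4 + treatment one-hot |
| `tfidf[_sym]`  | TF-IDF bag of words over the aggregated first-four-week messages, elastic net (optionally + the 9 features) |
| `encoder[_sym]`| transformer encoder over one 510-token head+tail window (first 128 + last 382 tokens), regression head (optionally fusing the 9 features: 768 + 9 = 777-wide head input at full scale) |
| `windowed[_sym]`| five independent encoders over rolling 510-token windows (two front, three tiling the last 1530 tokens), predictions mean-pooled |

Evaluation protocol: `m` imputed datasets (chained equations with predictive
mean matching) × 10 outer folds (stratified by treatment, shared across
models so comparisons are paired) × 5 inner folds for hyperparameter
selection by RMSE. Per model and metric the fold values pool via Rubin's
rules with Barnard–Rubin degrees of freedom; models are compared with
Welch's *t*-test on the pooled means.

The transformer stack is a compact numpy implementation (reverse-mode
autodiff, pre-norm blocks, masked attention, Adam with warmup/decay) sized
for desk-scale experiments; full-scale dimensions can be constructed for
architecture checks.

## Worked example

```python
from icbtpred import GeneratorConfig, OutcomeStudy, default_missing_rates, \
    generate_cohort, inject_missingness

cfg = GeneratorConfig(n_patients=150, seed=7, text_signal_strength=2.0,
                      wordcount_log_mean=5.0, wordcount_log_sd=0.5)
cohort, messages = generate_cohort(cfg)
cohort = inject_missingness(cohort, default_missing_rates(cfg), seed=8)

study = OutcomeStudy(cohort, messages, families=("dummy", "linear"),
                     m=2, imputation_iterations=5, seed=9)
print(study.run().summary())
```

prints (abridged):

```
Pooled model performance (Rubin's rules across imputations)
==============================================================
model         metric     mean      se   ci_low  ci_high     df
--------------------------------------------------------------
dummy         RMSE     0.1526  0.0078   0.1336   0.1716   6.16
dummy         BACC     0.3559  0.0506   0.0922   0.6197   1.67
linear        RMSE     0.0789  0.0056   0.0657   0.0920   7.43
linear        BACC     0.7852  0.0468   0.6087   0.9617   2.32
...
Pairwise Welch comparisons (two-sided):
  dummy vs linear [RMSE]: t(11.61) = 7.65, p = 0.0000
```

The symptom-only linear benchmark halves the null model's error because the
generator's weekly trajectories genuinely carry the latent improvement — the
qualitative pattern the method is designed to detect. The wide intervals and
small degrees of freedom are the honest price of pooling over only a few
imputed datasets.

The same pipeline runs from a shell via a YAML config:

```sh
icbtpred generate config.yaml   # write cohort.csv + messages.jsonl
icbtpred run config.yaml        # full pipeline -> pooled.csv, comparisons.csv, ...
icbtpred report config.yaml     # print the stored summary
```

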