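# Methods

`icbtpred` evaluates whether the written patient–therapist exchange during
the first four weeks of a 12-week guided ICBT treatment predicts the
post-treatment symptom score, and whether text adds anything beyond the
symptom course itself. This note documents the models, the synthetic data
they are exercised on, the evaluation protocol, the numerical choices, and
what the shipped tests do and do not establish.

## Outcomes and features

Three treatment arms use three questionnaires — MADRS-S (depression, max
54), PDSS-SR (panic, max 28), LSAS-SR (social anxiety, max 144), all with
minimum 0. Arms are pooled after min-max scaling, `y = raw / scale_max`, so
every outcome lives on [0, 1] and an RMSE of 0.10 means "off by ten
percentage points of the scale". The symptom feature vector has exactly 9
entries: scaled scores at screening, pre-treatment and weeks 1–4 (six
values, everything available by day 28), plus a three-way treatment
one-hot. A continuous predicted post score is dichotomized in retrospect:
success when the raw prediction falls below the questionnaire's remission
cutoff **or** is at most half the raw pre-treatment score. Cutoff defaults
(MADRS-S 10, PDSS-SR 7, LSAS-SR 30) are conventional remission thresholds
and are configurable; comparisons happen in raw units because cutoffs are
defined there. The rule is monotone: lowering a prediction can only turn
failure into success.

## Model families

* **dummy** — predicts the training-outcome mean; the null reference.
* **linear** — least squares on the 9 features. The intercept plus the full
  one-hot is collinear; `lstsq`'s minimum-norm solution resolves this (the
  predictions, which are all that matter, are unique).
* **tfidf / tfidf_sym** — TF-IDF over the patient's aggregated, cleaned,
  lowercased, punctuation- and stopword-stripped, (pluggably) lemmatized
  first-four-week messages. Terms in more than 80 % of training documents
  are discarded; the vocabulary is capped by corpus frequency; weighting is
  `tf × (ln((1+n)/(1+df)) + 1)` with L2 row normalisation. An elastic net
  minimising `1/(2n)·‖y−Xw‖² + α(l1·‖w‖₁ + (1−l1)/2·‖w‖²)` (so the α grid
  is interpretable under the 1/(2n) convention) regresses the outcome; the
  `_sym` variant appends the 9 features as columns.
* **encoder / encoder_sym** — transformer encoder over one window of at most
  510 content tokens: the whole text when it fits, else the first 128 plus
  the last 382 tokens. The regression head reads a learned sequence-summary
  position (a [CLS] token the model prepends), passes one dense layer with
  tanh, dropout (0.1), and a linear scalar output. The `_sym` variant
  concatenates the 9 features before the dense layer — at full-scale
  dimension 768 the head input is 777-wide.
* **windowed / windowed_sym** — five *independent* encoders (no weight
  tying), one per rolling window: windows 1–2 cover tokens [0, 510) and
  [510, 1020), windows 3–5 tile the final 1530 tokens. For texts shorter
  than 2550 tokens the rear windows overlap the front coverage rather than
  waste capacity on padding; shortfall is right-padded and masked. The
  prediction is the arithmetic mean of the five sub-model outputs
  (prediction-level pooling; pooling the five embeddings into one head
  would be the main alternative, but separate per-window analyses with
  averaged outputs keeps the sub-models independent). The `_sym` variant
  fuses the 9 features inside every sub-model's head.

Text featurization (TF-IDF vocabulary, encoder word tokenizer) is always
fitted inside `fit` on training patients, never on held-out patients; a
leakage canary test plants a token only in test documents and asserts it
never enters the vocabulary.

### The numpy transformer

The encoder stack is implemented in this package on a small reverse-mode
autodiff engine (float32 training; fused masked softmax; dropout on
embeddings, residual branches and the head, not on attention weights;
pre-norm blocks for stable training from random initialisation). Training
is mini-batch Adam on squared error with global-norm gradient clipping
(1.0), linear warmup over the first 10 % of steps then linear decay — the
schedule conventional for this architecture family, and the single biggest
stabiliser of fold-to-fold variance in our experiments. The output bias is
initialised at the training-outcome mean. Mini-batches are length-bucketed
(random ties) so padding work stays proportional to true text length; fits
are deterministic given a seed. Gradients are verified against central
finite differences through the full architecture.

Desk-scale defaults (embedding 32, 1 layer, 2 heads, feed-forward 64,
learning rate 1e-3, batch 8, 8 epochs) are sized so that a complete
nested-CV arm trains in minutes on one CPU; the published full-scale grid
(learning rates 5e-5/2e-5, batches 32/8, 4/5 epochs, dropout 0.1, TF-IDF
500/5000 features, uni/bigrams, α ∈ {3, 1, 0.5, 0.2}, l1 ∈ {0.2, 0.5,
0.8}) is available as `HyperparameterGrid.full_grid()` and is what the
grid type stores by default. The tiny learning rates of that grid presume a
pretrained checkpoint; a randomly initialised 1-layer model needs the
desk-scale rate, which is why the grid accepts values outside the published
sets.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which everything else is validated.

* **Trajectories.** Each patient draws a latent pre-treatment severity
  `pre ~ N(0.44, 0.15)` (fraction of scale max) and an improvement
  `δ ~ N(0.17, 0.10)`; weekly scores interpolate linearly from `pre` to
  `post = pre − δ` with independent `N(0, 0.04)` weekly noise, clipped to
  the scale. The defaults reproduce cohort descriptives of large
  routine-care ICBT samples (pre 44 % (15 %), post 27 % with SD
  `√(0.15² + 0.10²) ≈ 0.18`); arm proportions default to 3038/1740/1835
  out of 6613. Because the weekly course carries `δ`, early symptoms
  genuinely predict the post score — the property a symptom-only benchmark
  needs.
* **Text.** Per-patient first-four-week word counts are log-normal with
  `μ = 7.93668, σ = 0.76152`, solved analytically so that the top-5 %-
  trimmed mean/SD equal 3194/2053 words (the trimmed descriptives such
  cohorts report). Words are multinomial draws from a fixed vocabulary in
  which the designated signal-token subset (10 % of the vocabulary) has its
  log-odds shifted by `β·z`, `z` the standardised improvement; therapist
  messages get half the shift, mirroring an attenuated signal in the mixed
  stream. `β = 0` yields pure noise; the frequency–improvement R² rises
  monotonically with `β` over the operating range (roughly β ≤ 1) and
  saturates beyond it as the logit link flattens — at β = 3 the sample
  correlation between signal-token frequency and outcome is ≈ −0.55.
* **Missingness.** `inject_missingness` deletes scores per timepoint at
  requested rates (defaults ramp 3 % → 40 % from screening to post) under a
  MAR law: the deletion probability is logistic in the patient's observed
  scaled pre score (screening when deleting pre itself), slope 1.0 per SD,
  intercept solved by bisection to hit the marginal rate. Missingness never
  depends on the value deleted.

What the generator does **not** emulate: real language (tokens are
synthetic symbols, so nothing about Swedish or clinical vocabulary is
tested), therapist behaviour beyond the sender tag and halved signal,
non-linear symptom courses, MNAR dropout, and demographics. Passing tests
therefore show that the *pipeline* recovers signal it is pointed at and
refuses signal that is absent — not that clinical text carries any
particular signal.

## Imputation

Missing scores are imputed **before** cross-validation (the completed
datasets are fixed inputs to every model), by chained equations with
predictive mean matching on the scaled scores: sweeping timepoints
chronologically, each variable is regressed (OLS) on all other timepoints,
drop-one treatment indicators, and a patient-level cluster covariate; each
missing cell copies the observed value of a random donor among the 5
closest predicted means. Imputation in the pooled scaled space means donors
can come from any arm; the donor property (every imputed value is an
observed scaled value of its variable) and the range restriction hold by
construction. `m` defaults to 3 with 10 sweeps; chains are independent with
spawned sub-seeds, and a per-variable mean trace is kept as a convergence
diagnostic (a warning fires if the last two sweeps move a mean by more than
half an observed SD).

The cluster covariate is the leave-one-column-out mean of the *current
completed* matrix, recomputed each sweep. Both obvious alternatives are
biased, and measurably so on synthetic MAR data: a mean over observed cells
only over-weights early (more severe) visits for exactly the patients whose
late visits are missing (pulling imputations up), while a full-row mean of
the completed matrix leaks the target column into its own predictor and
freezes the chain near its initial draws (pulling them down). With the
leave-one-out covariate the pooled post-treatment mean lands within ~0.002
of the pre-deletion mean at n = 1000 under the default 3–40 % MAR
missingness. This two-level shortcut stands in for a full linear
mixed-model imputation; it captures within-patient clustering at a fraction
of the complexity and is exact only as an approximation.

## Evaluation protocol

Ten outer folds, stratified by treatment arm and **shared** across model
families and imputed datasets (comparisons are paired); five inner folds on
each outer-training split select hyperparameters by minimal mean RMSE, ties
resolving to the first-listed configuration, single-point grids skipping
the inner loop. The refit model predicts the held-out fold; predictions and
(imputed) truths are dichotomized with the same rule for BACC and F1. RMSE
is the optimisation target throughout; BACC and F1 are reporting-only. A
fold whose dichotomized truth is single-class records BACC as missing with
a warning and is dropped from pooling.

Pooling: per imputed dataset, a model's estimate is the mean of its 10 fold
values with within-variance `var(folds)/10` — the usual CV-mean standard
error, approximate because folds share training data. Rubin's rules combine
the m estimates (`T = W + (1 + 1/m)B`) with Barnard–Rubin degrees of
freedom at component df = folds − 1 (the B → 0 limit is taken continuously,
giving `ν_com(ν_com+1)/(ν_com+3)`); the CI is `mean ± t(df)·√T`. Model
pairs are compared with Welch's t on the pooled means, Welch–Satterthwaite
df capped at the sum of the two component dfs, two-sided p. With m = 2 or 3
the between-imputation term is estimated on 1–2 degrees of freedom, so
intervals can be very wide and dfs very small; that is the honest cost of
few imputations, and the package leaves it visible rather than smoothing it
over.

Predictions are clipped to [0, 1] for dichotomization only (raw cutoffs are
undefined outside the scale); RMSE uses the unclipped values.

## Problem sizes and calibration checks

The shipped acceptance study runs n = 300 patients, m = 2, 10 × 5 nested
CV, families dummy/linear/encoder, `β = 3.0` (moderate text signal,
frequency–outcome R² ≈ 0.3), word counts scaled to ≈ 150 mean words, the
desk-scale encoder, and the default 3–40 % MAR missingness. Under these
conditions the pooled RMSE ordering is linear ≤ encoder < dummy with
non-overlapping dummy/linear intervals; with `β = 0` neither text family
beats the dummy beyond its own interval width. A separate calibration check
uses a genuinely null cohort — identical pre severities, improvement spread
drowned by weekly noise, cutoffs at the outcome's centre so the dichotomized
truth is a fair coin — and asserts every model's pooled BACC interval covers
0.5. The null construction matters: on the default cohort the outcome is
predictable from the symptom course *by design*, so BACC above chance is
correct there, and a constant-valued continuous prediction does not
dichotomize to a constant class (the 50 %-reduction clause depends on each
patient's pre score), which is why even the dummy's BACC sits away from
50 % on structured cohorts.

`scripts/acceptance.py` re-runs this study plus the data-free checks
(inverse scaling cutpoints, 777-wide fusion head, window arithmetic) and
the trimmed word-count descriptives on a 600-patient cohort at the
full-scale word-count parameters, writing every quantity it computes to
JSON. End-to-end determinism (identical tables across two seeded runs,
including a transformer family) is asserted at a reduced size (n = 100,
5 outer folds, 2 epochs).

## Known limitations

* The imputation model is linear and single-level-plus-covariate; strongly
  non-linear trajectories or cluster-specific variances would call for a
  real mixed-model imputation.
* The within-imputation variance of a CV mean ignores fold overlap; the
  resulting CIs are approximate (a known property of CV-based error bars).
* The desk-scale encoder is randomly initialised; nothing here speaks to
  what a pretrained checkpoint would add. The windowed family at desk scale
  inherits the high variance that small batches and few epochs bring.
* Synthetic text has no syntax or semantics; models that exploit word order
  cannot demonstrate an advantage on it beyond frequency signal.
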