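"""Multiple-imputation x nested cross-validation evaluation harness.

For every model family and every imputed dataset, the outer 10-fold loop
(stratified by treatment arm, fold assignment shared across families and
imputations so all comparisons are paired) estimates out-of-sample
performance; the inner 5-fold loop, run on each outer-training split,
selects hyperparameters by mean RMSE. Continuous predictions are scored
with RMSE, then dichotomized (together with the observed outcomes) into
treatment success for balanced accuracy and F1.

Per model and metric, the 10 fold values of each imputed dataset collapse
to one estimate (their mean) with a within-imputation variance (fold
variance / folds); Rubin's rules pool the m estimates, the Barnard-Rubin
formula supplies the degrees of freedom (component df = folds - 1), and a
t interval gives the CI. Models are compared with Welch's t-test on the
pooled means, with Welch-Satterthwaite df capped at the sum of the two
component dfs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ConfigError
from .impute import pool_scalar
from .metrics import balanced_accuracy, f1, rmse
from .models import HyperparameterGrid, ModelInputs, make_model
from .nn.transformer import EncoderSpec
from .preprocess import DichotomizationRule, dichotomize

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationConfig", "EvaluationData", "FoldMetric", "PooledEstimate",
    "ComparisonResult", "make_outer_folds", "inner_select", "nested_cv",
    "pool_metric", "compare",
]

METRICS = ("RMSE", "BACC", "F1")


@dataclass(frozen=True)
class EvaluationConfig:
    """Protocol constants: 10 outer folds, 5 inner folds, 95 % CIs."""

    outer_folds: int = 10
    inner_folds: int = 5
    confidence_level: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.outer_folds < 2:
            raise ConfigError("outer_folds", "must be >= 2")
        if self.inner_folds < 2:
            raise ConfigError("inner_folds", "must be >= 2")
        if not (0 < self.confidence_level < 1):
            raise ConfigError("confidence_level", "must lie in (0, 1)")


@dataclass
class EvaluationData:
    """Everything the harness needs for one (imputed) complete cohort."""

    inputs: ModelInputs
    outcomes: np.ndarray          # scaled post scores, the regression target
    pre_scaled: np.ndarray        # scaled pre scores, for the 50 %-reduction clause
    scale_ids: np.ndarray
    scale_maxima: np.ndarray
    treatments: np.ndarray

    def __len__(self) -> int:
        return len(self.outcomes)


@dataclass(frozen=True)
class FoldMetric:
    """One (model, imputation, outer fold, metric) performance value."""

    model_id: str
    imputation: int
    outer_fold: int
    metric: str
    value: float
    hyperparameters: tuple = ()


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules pooled metric for one model."""

    model_id: str
    metric: str
    mean: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


@dataclass(frozen=True)
class ComparisonResult:
    """Welch's t comparison of two pooled estimates on the same metric."""

    model_a: str
    model_b: str
    metric: str
    t_statistic: float
    df: float
    p_value: float


# ---------------------------------------------------------------------------
# folds and selection
# ---------------------------------------------------------------------------

def make_outer_folds(treatments: np.ndarray, n_folds: int, seed: int
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Treatment-stratified outer folds, shared across models and imputations."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(treatments)), treatments)]


def inner_select(family: str, configs: list[dict], data: EvaluationData,
                 train_idx: np.ndarray, config: EvaluationConfig,
                 encoder_spec: EncoderSpec | None, seed: int) -> dict:
    """Exhaustive grid evaluation by inner-fold CV on the outer-training split.

    Returns the configuration with minimal mean inner RMSE; ties (and a
    single-configuration grid, which skips the inner loop entirely) resolve
    to the first-listed configuration. A configuration that fails to fit is
    skipped with a warning; if all fail, an error is raised.
    """
    if not configs:
        raise ValueError("empty hyperparameter grid")
    if len(configs) == 1:
        return configs[0]
    kf = KFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(train_idx))
    best_score, best_cfg = np.inf, None
    for cfg in configs:
        scores = []
        try:
            for in_tr, in_va in splits:
                tr, va = train_idx[in_tr], train_idx[in_va]
                model = make_model(family, cfg, encoder_spec=encoder_spec, seed=seed)
                model.fit(data.inputs.subset(tr), data.outcomes[tr])
                scores.append(rmse(model.predict(data.inputs.subset(va)),
                                   data.outcomes[va]))
        except Exception as exc:  # noqa: BLE001 - configuration-level isolation
            warnings.warn(f"configuration {cfg} failed during inner CV: {exc}",
                          RuntimeWarning)
            continue
        score = float(np.mean(scores))
        if score < best_score - 1e-15:
            best_score, best_cfg = score, cfg
    if best_cfg is None:
        raise RuntimeError(f"all hyperparameter configurations failed for {family}")
    return best_cfg


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

def nested_cv(family: str, grid: HyperparameterGrid, data: EvaluationData,
              config: EvaluationConfig, rule: DichotomizationRule,
              outer_folds: list[tuple[np.ndarray, np.ndarray]],
              imputation: int = 0, encoder_spec: EncoderSpec | None = None,
              ) -> list[FoldMetric]:
    """Run the outer loop for one model family on one completed cohort.

    Per outer fold: select hyperparameters on the training part, refit on
    the full training part, predict the held-out fold; RMSE on the scaled
    predictions, then BACC and F1 on the dichotomized predictions and
    truths. A fold whose dichotomized truth is single-class records BACC as
    NaN with a warning.
    """
    config.validate()
    configs = grid.configs(family)
    out: list[FoldMetric] = []
    for k, (train_idx, test_idx) in enumerate(outer_folds):
        sel_seed = (config.seed * 1009 + k * 101 + imputation) % (2**31 - 1)
        chosen = inner_select(family, configs, data, train_idx, config,
                              encoder_spec, sel_seed)
        model = make_model(family, chosen, encoder_spec=encoder_spec, seed=sel_seed)
        model.fit(data.inputs.subset(train_idx), data.outcomes[train_idx])
        pred = np.asarray(model.predict(data.inputs.subset(test_idx)), float)
        if not np.isfinite(pred).all():
            raise RuntimeError(f"{family}: non-finite predictions in outer fold {k}")
        truth = data.outcomes[test_idx]
        hp = tuple(sorted(chosen.items()))
        out.append(FoldMetric(family, imputation, k, "RMSE",
                              rmse(pred, truth), hp))

        pred_bin = dichotomize(np.clip(pred, 0.0, 1.0), data.pre_scaled[test_idx],
                               data.scale_ids[test_idx], data.scale_maxima[test_idx],
                               rule)
        truth_bin = dichotomize(truth, data.pre_scaled[test_idx],
                                data.scale_ids[test_idx], data.scale_maxima[test_idx],
                                rule)
        if len(np.unique(truth_bin)) < 2:
            warnings.warn(f"outer fold {k}: single-class truth, BACC undefined",
                          RuntimeWarning)
            bacc_val = np.nan
        else:
            bacc_val = balanced_accuracy(pred_bin, truth_bin)
        out.append(FoldMetric(family, imputation, k, "BACC", bacc_val, hp))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out.append(FoldMetric(family, imputation, k, "F1",
                                  f1(pred_bin, truth_bin), hp))
    return out


# ---------------------------------------------------------------------------
# pooling and comparison
# ---------------------------------------------------------------------------

def pool_metric(fold_metrics: list[FoldMetric], config: EvaluationConfig,
                ) -> PooledEstimate:
    """Pool one model's fold values for one metric across imputations.

    Per imputation: estimate = mean of its fold values, within-variance =
    fold variance / number of folds (the standard CV-mean standard error,
    approximate because folds share training data). NaN fold values (e.g.
    single-class BACC folds) are dropped within their imputation.
    """
    model_ids = {fm.model_id for fm in fold_metrics}
    metrics = {fm.metric for fm in fold_metrics}
    if len(model_ids) != 1 or len(metrics) != 1:
        raise ValueError("pool_metric expects folds from one model and one metric")
    by_imp: dict[int, list[float]] = {}
    for fm in fold_metrics:
        by_imp.setdefault(fm.imputation, []).append(fm.value)
    if len(by_imp) < 2:
        raise ValueError("pooling requires fold metrics from >= 2 imputations")
    estimates, withins, n_folds = [], [], []
    for imp in sorted(by_imp):
        vals = np.asarray(by_imp[imp], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError(f"imputation {imp} has fewer than 2 usable fold values")
        estimates.append(vals.mean())
        withins.append(vals.var(ddof=1) / len(vals))
        n_folds.append(len(vals))
    pooled = pool_scalar(estimates, withins, component_df=min(n_folds) - 1)
    alpha = 1.0 - config.confidence_level
    half = (stats.t.ppf(1 - alpha / 2, pooled.df) * pooled.se
            if pooled.total_variance > 0 else 0.0)
    return PooledEstimate(
        model_id=model_ids.pop(), metric=metrics.pop(), mean=pooled.mean,
        within_variance=pooled.within_variance,
        between_variance=pooled.between_variance,
        total_variance=pooled.total_variance, df=pooled.df,
        ci_low=pooled.mean - half, ci_high=pooled.mean + half)


def compare(a: PooledEstimate, b: PooledEstimate) -> ComparisonResult:
    """Welch's t-test on two pooled means using their total variances.

    ``t = (mean_a - mean_b) / sqrt(T_a + T_b)``; Welch-Satterthwaite df from
    the two (T, df) pairs, capped at ``df_a + df_b``; two-sided p.
    """
    if a.metric != b.metric:
        raise ValueError("cannot compare estimates of different metrics")
    ta, tb = a.total_variance, b.total_variance
    denom = np.sqrt(ta + tb)
    if denom == 0.0:
        if a.mean == b.mean:
            return ComparisonResult(a.model_id, b.model_id, a.metric, 0.0,
                                    a.df + b.df, 1.0)
        raise ValueError("zero combined standard error with unequal means")
    t_stat = (a.mean - b.mean) / denom
    df = (ta + tb) ** 2 / (ta**2 / a.df + tb**2 / b.df)
    df = min(df, a.df + b.df)
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return ComparisonResult(a.model_id, b.model_id, a.metric, float(t_stat),
                            float(df), p)
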