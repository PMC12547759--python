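"""End-to-end study object: data in, pooled model comparison out.

:class:`OutcomeStudy` is built from a cohort (possibly with missing
assessments) and its message stream, plus the protocol configuration; its
:meth:`~OutcomeStudy.run` executes text preparation, multiple imputation,
the nested-CV loop for every requested model family, Rubin's-rules pooling
and pairwise Welch comparisons, and returns a :class:`StudyResults` whose
``summary()`` prints the pooled table.

Example
-------
>>> from icbtpred import GeneratorConfig, generate_cohort, OutcomeStudy
>>> cohort, messages = generate_cohort(GeneratorConfig(n_patients=120, seed=1))
>>> study = OutcomeStudy(cohort, messages, families=("dummy", "linear"),
...                      m=2, seed=1)
>>> results = study.run()
>>> print(results.summary())                       # doctest: +SKIP
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, MessageStream
from .evaluate import (METRICS, ComparisonResult, EvaluationConfig,
                       EvaluationData, FoldMetric, PooledEstimate, compare,
                       make_outer_folds, nested_cv, pool_metric)
from .impute import ImputationConfig, ImputedCohortSet, impute
from .models import HyperparameterGrid, MODEL_FAMILIES, ModelInputs
from .nn.transformer import EncoderSpec
from .preprocess import (DichotomizationRule, aggregate_messages,
                         build_feature_matrix, clean_text, normalize_for_bow)
from .scales import TIMEPOINTS

logger = logging.getLogger(__name__)

__all__ = ["OutcomeStudy", "StudyResults"]


def prepare_evaluation_data(completed: CohortTable, texts: pd.Series,
                            ) -> EvaluationData:
    """Model-ready bundle for one fully observed cohort."""
    features = build_feature_matrix(completed)
    scaled = completed.scaled_scores()
    post = scaled[:, TIMEPOINTS.index("post")]
    pre = scaled[:, TIMEPOINTS.index("pre")]
    text_list = [texts.get(pid, "") for pid in completed.patient_ids]
    bow = [normalize_for_bow(t) for t in text_list]
    return EvaluationData(
        inputs=ModelInputs(texts=text_list, bow_tokens=bow, features=features),
        outcomes=post, pre_scaled=pre,
        scale_ids=completed.frame["scale_id"].to_numpy(),
        scale_maxima=completed.scale_maxima,
        treatments=completed.treatments)


@dataclass
class StudyResults:
    """Fold metrics, pooled estimates, comparisons and provenance."""

    fold_metrics: list[FoldMetric]
    pooled: list[PooledEstimate]
    comparisons: list[ComparisonResult]
    seeds: dict[str, int]
    families: tuple[str, ...]

    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model": fm.model_id, "imputation": fm.imputation,
            "outer_fold": fm.outer_fold, "metric": fm.metric, "value": fm.value,
            "hyperparameters": dict(fm.hyperparameters),
        } for fm in self.fold_metrics])

    def pooled_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model": pe.model_id, "metric": pe.metric, "mean": pe.mean,
            "se": pe.se, "ci_low": pe.ci_low, "ci_high": pe.ci_high,
            "df": pe.df, "within_variance": pe.within_variance,
            "between_variance": pe.between_variance,
        } for pe in self.pooled])

    def comparison_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model_a": c.model_a, "model_b": c.model_b, "metric": c.metric,
            "t": c.t_statistic, "df": c.df, "p": c.p_value,
        } for c in self.comparisons])

    def get_pooled(self, model: str, metric: str) -> PooledEstimate:
        for pe in self.pooled:
            if pe.model_id == model and pe.metric == metric:
                return pe
        raise KeyError(f"no pooled estimate for ({model}, {metric})")

    def get_comparison(self, model_a: str, model_b: str, metric: str
                       ) -> ComparisonResult:
        for c in self.comparisons:
            if c.metric == metric and {c.model_a, c.model_b} == {model_a, model_b}:
                return c
        raise KeyError(f"no comparison for ({model_a}, {model_b}, {metric})")

    def summary(self) -> str:
        """Pooled means with 95 % CIs per model and metric, one text table."""
        lines = ["Pooled model performance (Rubin's rules across imputations)",
                 "=" * 62,
                 f"{'model':<14}{'metric':<7}{'mean':>8}{'se':>8}"
                 f"{'ci_low':>9}{'ci_high':>9}{'df':>7}",
                 "-" * 62]
        for pe in self.pooled:
            lines.append(f"{pe.model_id:<14}{pe.metric:<7}{pe.mean:>8.4f}"
                         f"{pe.se:>8.4f}{pe.ci_low:>9.4f}{pe.ci_high:>9.4f}"
                         f"{pe.df:>7.2f}")
        lines.append("-" * 62)
        if self.comparisons:
            lines.append("Pairwise Welch comparisons (two-sided):")
            for c in self.comparisons:
                lines.append(f"  {c.model_a} vs {c.model_b} [{c.metric}]: "
                             f"t({c.df:.2f}) = {c.t_statistic:.2f}, p = {c.p_value:.4f}")
        return "\n".join(lines)


class OutcomeStudy:
    """The full imputation x nested-CV x pooling protocol as one object.

    Parameters
    ----------
    cohort, messages:
        Symptom table (missing assessments allowed) and message stream.
    families:
        Model families to compare; subset of ``MODEL_FAMILIES``.
    grid:
        Hyperparameter grid (default: the desk-scale grid).
    m, imputation_iterations:
        Number of imputed datasets and chained-equation sweeps.
    encoder_spec:
        Architecture of the transformer families.
    day_limit:
        Messages with ``day < day_limit`` enter the aggregated text.
    boilerplate_patterns:
        Literal strings stripped from every message before modelling.
    """

    def __init__(self, cohort: CohortTable, messages: MessageStream,
                 families: tuple[str, ...] = ("dummy", "linear"),
                 grid: HyperparameterGrid | None = None,
                 rule: DichotomizationRule | None = None,
                 encoder_spec: EncoderSpec | None = None,
                 m: int = 3, imputation_iterations: int = 10,
                 outer_folds: int = 10, inner_folds: int = 5,
                 day_limit: int = 29, boilerplate_patterns: tuple[str, ...] = (),
                 seed: int = 0):
        unknown = [f for f in families if f not in MODEL_FAMILIES]
        if unknown:
            raise ValueError(f"unknown model families {unknown}; "
                             f"choose from {MODEL_FAMILIES}")
        if not families:
            raise ValueError("at least one model family is required")
        self.cohort = cohort
        self.messages = messages
        self.families = tuple(families)
        self.grid = grid or HyperparameterGrid.desk_grid()
        self.rule = rule or DichotomizationRule()
        self.encoder_spec = encoder_spec or EncoderSpec()
        self.day_limit = day_limit
        self.boilerplate_patterns = tuple(boilerplate_patterns)
        self.seed = seed
        root = np.random.SeedSequence(seed)
        imp_seed, cv_seed = (int(s.generate_state(1)[0] % (2**31 - 1))
                             for s in root.spawn(2))
        self.seeds = {"root": seed, "imputation": imp_seed, "cv": cv_seed}
        self.imputation_config = ImputationConfig(m=m,
                                                  n_iterations=imputation_iterations,
                                                  seed=imp_seed)
        self.evaluation_config = EvaluationConfig(outer_folds=outer_folds,
                                                  inner_folds=inner_folds,
                                                  seed=cv_seed)

    # -- stages --------------------------------------------------------------
    def prepare_texts(self) -> pd.Series:
        texts = aggregate_messages(self.messages, self.cohort.patient_ids,
                                   day_limit=self.day_limit)
        return texts.map(lambda t: clean_text(t, self.boilerplate_patterns))

    def impute_cohorts(self) -> ImputedCohortSet:
        return impute(self.cohort, self.imputation_config)

    def run(self) -> StudyResults:
        """Execute the full protocol and pool the results."""
        logger.info("preparing texts (day < %d)", self.day_limit)
        texts = self.prepare_texts()
        logger.info("imputing m=%d datasets", self.imputation_config.m)
        imputed = self.impute_cohorts()
        datasets = [prepare_evaluation_data(tab, texts) for tab in imputed.tables]

        folds = make_outer_folds(self.cohort.treatments,
                                 self.evaluation_config.outer_folds,
                                 self.evaluation_config.seed)
        fold_metrics: list[FoldMetric] = []
        for family in self.families:
            for i, data in enumerate(datasets):
                logger.info("nested CV: %s on imputation %d", family, i)
                fold_metrics += nested_cv(
                    family, self.grid, data, self.evaluation_config, self.rule,
                    folds, imputation=i, encoder_spec=self.encoder_spec)

        pooled = []
        for family, metric in itertools.product(self.families, METRICS):
            fms = [fm for fm in fold_metrics
                   if fm.model_id == family and fm.metric == metric]
            pooled.append(pool_metric(fms, self.evaluation_config))
        comparisons = []
        for metric in METRICS:
            for fam_a, fam_b in itertools.combinations(self.families, 2):
                comparisons.append(compare(self.get_from(pooled, fam_a, metric),
                                           self.get_from(pooled, fam_b, metric)))
        return StudyResults(fold_metrics=fold_metrics, pooled=pooled,
                            comparisons=comparisons, seeds=dict(self.seeds),
                            families=self.families)

    @staticmethod
    def get_from(pooled: list[PooledEstimate], model: str, metric: str
                 ) -> PooledEstimate:
        for pe in pooled:
            if pe.model_id == model and pe.metric == metric:
                return pe
        raise KeyError((model, metric))
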