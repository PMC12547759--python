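"""Multiple imputation by chained equations with predictive mean matching,
and Rubin's-rules pooling of scalar estimates.

Imputation happens once, *before* any cross-validation, producing ``m``
completed cohorts. Each chain sweeps the assessment timepoints in
chronological order; the conditional model for a timepoint regresses its
scaled score on all other timepoints, treatment indicators and the
patient's mean of originally observed scaled scores. That patient-level
mean is a two-level shortcut: it carries the within-patient clustering that
a full linear mixed imputation model would capture, at a fraction of the
complexity. Missing cells are filled by predictive mean matching (PMM):
the imputed value is copied from a randomly chosen donor among the
``donor_pool_k`` observed cases whose model-predicted means are closest, so
every imputed value is an actually observed (scaled) value of its variable
and range restrictions hold automatically.

All conditional models operate on the min-max scaled [0, 1] scores, the
scale on which the three questionnaires are pooled; raw values are
recovered by multiplying with each patient's scale maximum.

Pooling follows Rubin's rules with the Barnard-Rubin small-sample degrees
of freedom: pooled mean = mean of the per-dataset estimates, total variance
= within + (1 + 1/m) * between.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable
from .errors import ConfigError
from .scales import TIMEPOINTS, TREATMENTS

logger = logging.getLogger(__name__)

__all__ = ["ImputationConfig", "ImputedCohortSet", "impute", "pool_scalar",
           "PooledScalar", "write_imputed_set", "read_imputed_set"]


@dataclass(frozen=True)
class ImputationConfig:
    """Chained-equations settings: ``m`` datasets, sweep count, PMM pool size."""

    m: int = 3
    n_iterations: int = 10
    donor_pool_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ConfigError("m", "must be >= 2 (multiple imputation)")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations", "must be >= 1")
        if self.donor_pool_k < 1:
            raise ConfigError("donor_pool_k", "must be >= 1")


@dataclass
class ImputedCohortSet:
    """``m`` completed cohorts plus the mask of originally missing cells.

    All tables agree exactly on originally observed cells; ``mean_trace``
    holds, per chain, the per-iteration mean of each variable's imputed
    values (a convergence diagnostic).
    """

    tables: list[CohortTable]
    imputed_mask: np.ndarray  # (n_patients, n_timepoints) bool
    mean_trace: list[dict[str, list[float]]] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.tables)


def _design(filled: np.ndarray, col: int, onehot: np.ndarray,
            patient_mean: np.ndarray) -> np.ndarray:
    others = np.delete(filled, col, axis=1)
    return np.column_stack([np.ones(len(filled)), others, onehot, patient_mean])


def _single_chain(scaled: np.ndarray, observed: np.ndarray, onehot: np.ndarray,
                  config: ImputationConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, dict[str, list[float]]]:
    """One chained-equations chain on the scaled score matrix."""
    n, p = scaled.shape
    filled = scaled.copy()

    # initial fill: random draw from each variable's observed marginal
    for j in range(p):
        miss = ~observed[:, j]
        if miss.any():
            donors = scaled[observed[:, j], j]
            filled[miss, j] = rng.choice(donors, size=miss.sum(), replace=True)

    trace: dict[str, list[float]] = {TIMEPOINTS[j]: [] for j in range(p)
                                     if (~observed[:, j]).any()}
    for _ in range(config.n_iterations):
        for j in range(p):
            miss = ~observed[:, j]
            if not miss.any():
                continue
            # cluster covariate from the current completed matrix, leaving
            # the target column out (a mean over observed cells only would
            # over-weight early, more severe, visits for exactly the
            # patients whose late visits are missing; including column j
            # would leak the current imputation into its own predictor)
            patient_mean = (filled.sum(axis=1) - filled[:, j]) / (p - 1)
            X = _design(filled, j, onehot, patient_mean)
            obs = observed[:, j]
            beta, *_ = np.linalg.lstsq(X[obs], scaled[obs, j], rcond=None)
            pred = X @ beta
            pred_obs, y_obs = pred[obs], scaled[obs, j]
            k = min(config.donor_pool_k, len(y_obs))
            for i in np.where(miss)[0]:
                d = np.abs(pred_obs - pred[i])
                pool = np.argpartition(d, k - 1)[:k]
                filled[i, j] = y_obs[rng.choice(pool)]
            trace[TIMEPOINTS[j]].append(float(filled[miss, j].mean()))
    return filled, trace


def impute(cohort: CohortTable, config: ImputationConfig) -> ImputedCohortSet:
    """Produce ``m`` completed cohorts by chained equations with PMM.

    Chains are independent (distinct sub-seeds spawned from ``config.seed``)
    and deterministic given the seed. A chain whose imputed-value means move
    by more than 0.5 observed-SD between the last two sweeps triggers a
    non-convergence warning carrying the mean trace.
    """
    config.validate()
    scores = cohort.scores()
    observed = ~np.isnan(scores)
    if observed.all():
        return ImputedCohortSet(tables=[cohort.with_scores(scores.copy())
                                        for _ in range(config.m)],
                                imputed_mask=np.zeros_like(observed))
    zero_obs = [TIMEPOINTS[j] for j in range(scores.shape[1]) if not observed[:, j].any()]
    if zero_obs:
        raise ValueError(f"variables with no observed values cannot be imputed: {zero_obs}")

    smax = cohort.scale_maxima[:, None]
    scaled = scores / smax
    onehot = np.column_stack([(cohort.treatments == arm).astype(float)
                              for arm in TREATMENTS[:-1]])  # drop-one coding

    seeds = np.random.SeedSequence(config.seed).spawn(config.m)
    tables, traces = [], []
    obs_sd = np.nanstd(scaled)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        filled, trace = _single_chain(scaled, observed, onehot, config, rng)
        for tp, means in trace.items():
            if len(means) >= 2 and abs(means[-1] - means[-2]) > 0.5 * obs_sd:
                warnings.warn(
                    f"imputation chain may not have converged at {tp}: "
                    f"mean trace {np.round(means, 4).tolist()}", RuntimeWarning)
        out = filled * smax
        out[observed] = scores[observed]  # observed cells bit-identical
        tables.append(cohort.with_scores(out))
        traces.append(trace)
    return ImputedCohortSet(tables=tables, imputed_mask=~observed, mean_trace=traces)


def write_imputed_set(imputed: ImputedCohortSet, directory) -> list[str]:
    """Serialize as ``imputed_0.csv .. imputed_{m-1}.csv`` plus ``mask.csv``
    (one 0/1 column per timepoint marking imputed cells)."""
    from pathlib import Path

    import pandas as pd

    from .cohort import write_cohort

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, table in enumerate(imputed.tables):
        p = out / f"imputed_{i}.csv"
        write_cohort(table, p)
        paths.append(str(p))
    mask = pd.DataFrame(imputed.imputed_mask.astype(int), columns=list(TIMEPOINTS))
    mask.insert(0, "patient_id", imputed.tables[0].patient_ids)
    mp = out / "mask.csv"
    mask.to_csv(mp, index=False)
    paths.append(str(mp))
    return paths


def read_imputed_set(directory) -> ImputedCohortSet:
    """Read the layout written by :func:`write_imputed_set`."""
    from pathlib import Path

    import pandas as pd

    from .cohort import read_cohort

    out = Path(directory)
    tables = []
    i = 0
    while (out / f"imputed_{i}.csv").exists():
        tables.append(read_cohort(out / f"imputed_{i}.csv"))
        i += 1
    if len(tables) < 2:
        raise ValueError(f"no imputed-set files found under {out}")
    mask_frame = pd.read_csv(out / "mask.csv")
    mask = mask_frame.loc[:, list(TIMEPOINTS)].to_numpy(bool)
    return ImputedCohortSet(tables=tables, imputed_mask=mask)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PooledScalar:
    """Rubin's-rules pooled scalar: mean, variance components, adjusted df."""

    mean: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def pool_scalar(estimates, within_variances, component_df: float) -> PooledScalar:
    """Pool ``m`` estimates with Rubin's rules and Barnard-Rubin df.

    ``Qbar = mean(Q_i)``; within ``W = mean(U_i)``; between ``B`` is the
    sample variance of the ``Q_i``; total ``T = W + (1 + 1/m) B``.
    ``component_df`` is the complete-data degrees of freedom of each
    estimate (here: number of outer folds minus one); the small-sample
    adjusted df combines the classical ``(m-1)/lambda^2`` with the observed-
    data df, and reduces to ``component_df`` when ``B = 0``.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(within_variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("pooling requires m >= 2 estimates")
    if len(u) != m:
        raise ValueError("estimates and within_variances must align")
    if (u < 0).any():
        raise ValueError("within variances must be nonnegative")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    nu_com = float(component_df)
    if t <= 0.0 or b == 0.0:
        # lambda -> 0 limit of the Barnard-Rubin formula (continuous in B)
        df = (nu_com + 1.0) / (nu_com + 3.0) * nu_com
    else:
        lam = (1.0 + 1.0 / m) * b / t
        nu_old = (m - 1) / lam**2
        nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
        df = 1.0 / (1.0 / nu_old + 1.0 / nu_obs) if nu_obs > 0 else nu_old
    return PooledScalar(mean=qbar, within_variance=w, between_variance=b,
                        total_variance=t, df=float(df))
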