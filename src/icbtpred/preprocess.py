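"""Outcome scaling, symptom features, dichotomization, text preparation.

Scores enter the models on a common [0, 1] scale: each raw questionnaire
score is divided by its scale maximum (min-max transform with min 0), so an
RMSE of 0.10 reads as "on average 10 percentage points of the scale wrong".
A continuous predicted post score is dichotomized *in retrospect* into
treatment success/failure: success when the raw prediction is below the
questionnaire's remission cutoff, or when it reflects at least a 50 %
reduction from the pre-treatment score.

Text preparation covers both modelling routes. The bag-of-words route
aggregates each patient's first-four-week messages (both senders), strips
configured boilerplate and markup, lowercases, removes punctuation and
stopwords, and applies a pluggable lemma map. The encoder route keeps the
aggregated text intact and reduces it to 510-token windows: either a single
head+tail window (first 128 tokens plus last 382), or five rolling windows
(two covering the first 1020 tokens, three tiling the last 1530).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, MessageStream
from .errors import MissingDataError
from .scales import EARLY_TIMEPOINTS, TREATMENTS, VALID_SCALE_MAXIMA

logger = logging.getLogger(__name__)

__all__ = [
    "scale_minmax",
    "inverse_scale",
    "FEATURE_NAMES",
    "build_feature_vector",
    "build_feature_matrix",
    "DichotomizationRule",
    "DEFAULT_CUTOFFS",
    "dichotomize",
    "aggregate_messages",
    "clean_text",
    "normalize_for_bow",
    "TokenWindowSet",
    "truncate_head_tail",
    "make_rolling_windows",
]

MESSAGE_SEPARATOR = "\n"

HEAD_LEN, TAIL_LEN, WINDOW_LEN = 128, 382, 510
N_WINDOWS, FRONT_WINDOWS, REAR_TOKEN_SPAN = 5, 2, 1530


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def scale_minmax(raw, scale_max):
    """Divide a raw score by its scale maximum; accepts scalars or arrays."""
    scale_max_arr = np.asarray(scale_max, dtype=float)
    if not np.isin(np.unique(scale_max_arr), sorted(VALID_SCALE_MAXIMA)).all():
        raise ValueError(f"scale_max must be one of {sorted(VALID_SCALE_MAXIMA)}")
    raw_arr = np.asarray(raw, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (raw_arr < 0) | (raw_arr > scale_max_arr)
    if np.nan_to_num(bad, nan=0).any():
        raise ValueError("raw score outside [0, scale_max]")
    out = raw_arr / scale_max_arr
    return float(out) if np.isscalar(raw) or out.ndim == 0 else out


def inverse_scale(value, scale_max):
    """Map a [0, 1] scaled score back to raw questionnaire points (exact)."""
    value_arr = np.asarray(value, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (value_arr < 0) | (value_arr > 1)
    if np.nan_to_num(bad, nan=0).any():
        raise ValueError("scaled score outside [0, 1]")
    out = value_arr * np.asarray(scale_max, dtype=float)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# symptom features
# ---------------------------------------------------------------------------

FEATURE_NAMES = tuple(f"scaled_{tp}" for tp in EARLY_TIMEPOINTS) + tuple(
    f"treatment_{arm}" for arm in TREATMENTS
)


def build_feature_vector(row: pd.Series) -> np.ndarray:
    """9-entry predictor vector for one cohort row.

    Six scaled scores (screening, pre, weeks 1-4) followed by a 3-way
    treatment one-hot. Requires complete early assessments: run imputation
    first.
    """
    raw = row.loc[list(EARLY_TIMEPOINTS)].to_numpy(float)
    if np.isnan(raw).any():
        missing = [tp for tp, v in zip(EARLY_TIMEPOINTS, raw) if np.isnan(v)]
        raise MissingDataError(
            f"patient {row['patient_id']}: missing {missing}; impute before building features"
        )
    scaled = scale_minmax(raw, float(row["scale_max"]))
    onehot = np.array([1.0 if row["treatment"] == arm else 0.0 for arm in TREATMENTS])
    return np.concatenate([scaled, onehot])


def build_feature_matrix(cohort: CohortTable) -> np.ndarray:
    """Stack :func:`build_feature_vector` over the cohort -> ``(n, 9)``."""
    return np.vstack([build_feature_vector(row) for _, row in cohort.frame.iterrows()])


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------

#: Conventional remission cutoffs in raw points; configurable per run.
DEFAULT_CUTOFFS: Mapping[str, float] = {"MADRS-S": 10.0, "PDSS-SR": 7.0, "LSAS-SR": 30.0}


@dataclass(frozen=True)
class DichotomizationRule:
    """Success = raw prediction below the remission cutoff, or at least a
    ``reduction_fraction`` (default 50 %) drop from the pre-treatment score."""

    cutoffs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    reduction_fraction: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.reduction_fraction < 1.0):
            raise ValueError("reduction_fraction must lie in (0, 1)")
        for sid, cut in self.cutoffs.items():
            if cut < 0:
                raise ValueError(f"cutoff for {sid} must be nonnegative")


def dichotomize(predicted_post_scaled, pre_scaled, scale_id, scale_max,
                rule: DichotomizationRule):
    """Map scaled predicted post score(s) to binary success.

    Comparison happens in raw units (cutoffs are defined on the raw scales):
    success iff ``raw_pred < cutoff`` or
    ``raw_pred <= reduction_fraction * raw_pre``. Monotone: lowering the
    prediction never flips success into failure.
    """
    raw_pred = np.asarray(inverse_scale(predicted_post_scaled, scale_max))
    raw_pre = np.asarray(inverse_scale(pre_scaled, scale_max))
    if isinstance(scale_id, str):
        cutoff = np.asarray(float(rule.cutoffs[scale_id]))
    else:
        cutoff = np.asarray([float(rule.cutoffs[s]) for s in scale_id])
    success = (raw_pred < cutoff) | (raw_pred <= rule.reduction_fraction * raw_pre)
    return bool(success) if success.ndim == 0 else success


# ---------------------------------------------------------------------------
# text aggregation and cleaning
# ---------------------------------------------------------------------------

def aggregate_messages(stream: MessageStream, patient_ids: Sequence | None = None,
                       day_limit: int = 29,
                       separator: str = MESSAGE_SEPARATOR) -> pd.Series:
    """Concatenate each patient's messages with ``day < day_limit``.

    Both senders are kept: the models read the whole therapeutic exchange.
    Messages are ordered by ``(day, original position)``, so the result is
    invariant to shuffling of the input records. Patients from
    ``patient_ids`` with no qualifying messages get an empty string (and are
    counted in a log message).
    """
    frame = stream.frame
    kept = frame[frame["day"] < day_limit]
    # restore original record order, then stable-sort by day: ties break by
    # original position, so shuffled input yields identical output
    kept = kept.sort_index(kind="stable").sort_values("day", kind="stable")
    texts = kept.groupby("patient_id")["text"].agg(separator.join)
    if patient_ids is not None:
        texts = texts.reindex(list(patient_ids), fill_value="")
    n_empty = int((texts.str.len() == 0).sum())
    if n_empty:
        logger.info("aggregate_messages: %d patient(s) with no messages before day %d",
                    n_empty, day_limit)
    return texts


_MARKUP_RE = re.compile(r"<[^<>]*>")
_WS_RE = re.compile(r"[ \t]+")


def clean_text(text: str, boilerplate_patterns: Sequence[str] = ()) -> str:
    """Strip configured boilerplate strings and markup-like tags.

    Boilerplate patterns are literal strings (e.g. an automated greeting);
    each is removed to a fixed point so the operation is idempotent. Markup
    tags of the form ``<...>`` (formatting code around homework questions
    and answers) are removed likewise; runs of spaces collapse to one.
    """
    out = text
    changed = True
    while changed:
        changed = False
        for pat in boilerplate_patterns:
            if pat and pat in out:
                out = out.replace(pat, " ")
                changed = True
        new = _MARKUP_RE.sub(" ", out)
        if new != out:
            out = new
            changed = True
    out = _WS_RE.sub(" ", out)
    return "\n".join(line.strip() for line in out.split("\n")).strip()


_PUNCT_STRIP_RE = re.compile(r"^\W+|\W+$", re.UNICODE)


def normalize_for_bow(text: str, stopwords: frozenset | set | None = None,
                      lemma_map: Mapping[str, str] | Callable[[str], str] | None = None,
                      ) -> list[str]:
    """Lowercase, strip punctuation, drop stopwords, apply a lemma map.

    The default lemma map is the identity: proper lemmatization is language-
    and tool-specific, so the interface takes any ``{form: lemma}`` mapping
    or callable instead.
    """
    stopwords = frozenset(w.lower() for w in (stopwords or ()))
    if lemma_map is None:
        lemmatize = lambda w: w
    elif callable(lemma_map):
        lemmatize = lemma_map
    else:
        lemmatize = lambda w, _m=lemma_map: _m.get(w, w)
    tokens = []
    for tok in text.lower().split():
        tok = _PUNCT_STRIP_RE.sub("", tok)
        if not tok or not re.search(r"\w", tok):
            continue
        if tok in stopwords:
            continue
        lemma = lemmatize(tok)
        if lemma and lemma not in stopwords:
            tokens.append(lemma)
    return tokens


# ---------------------------------------------------------------------------
# token windows
# ---------------------------------------------------------------------------

@dataclass
class TokenWindowSet:
    """Windows of at most 510 tokens ready for an encoder.

    ``head_tail`` mode holds exactly one window (full text when it fits,
    else first 128 + last 382 tokens). ``rolling`` mode holds exactly five
    windows, each padded to 510 with ``pad_token``.
    """

    mode: str
    windows: list[list]
    pad_token: object = 0

    def __post_init__(self):
        if self.mode not in ("head_tail", "rolling"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if self.mode == "head_tail" and len(self.windows) != 1:
            raise ValueError("head_tail mode holds exactly one window")
        if self.mode == "rolling" and len(self.windows) != N_WINDOWS:
            raise ValueError(f"rolling mode holds exactly {N_WINDOWS} windows")
        for w in self.windows:
            if len(w) > WINDOW_LEN:
                raise ValueError(f"window longer than {WINDOW_LEN} tokens")


def truncate_head_tail(tokens: Sequence) -> TokenWindowSet:
    """Single-window truncation: first 128 and last 382 tokens.

    A sequence of 510 tokens or fewer is kept whole (no padding here; the
    encoder pads batches itself).
    """
    tokens = list(tokens)
    if len(tokens) <= WINDOW_LEN:
        window = tokens
    else:
        window = tokens[:HEAD_LEN] + tokens[-TAIL_LEN:]
    return TokenWindowSet(mode="head_tail", windows=[window])


def make_rolling_windows(tokens: Sequence, pad_token=0) -> TokenWindowSet:
    """Five 510-token windows: two from the front, three tiling the rear.

    Windows 1-2 cover tokens [0, 510) and [510, 1020); windows 3-5 tile the
    final 1530 tokens starting at ``max(0, len - 1530)``. For texts shorter
    than 2550 tokens the rear windows may overlap the front coverage; any
    shortfall is right-padded with ``pad_token``. A text of exactly 2550
    tokens is tiled with no overlap and no padding.
    """
    tokens = list(tokens)
    L = len(tokens)

    def chunk(start: int) -> list:
        piece = tokens[start:start + WINDOW_LEN] if start < L else []
        return piece + [pad_token] * (WINDOW_LEN - len(piece))

    windows = [chunk(k * WINDOW_LEN) for k in range(FRONT_WINDOWS)]
    rear_start = max(0, L - REAR_TOKEN_SPAN)
    for k in range(N_WINDOWS - FRONT_WINDOWS):
        windows.append(chunk(rear_start + k * WINDOW_LEN))
    return TokenWindowSet(mode="rolling", windows=windows, pad_token=pad_token)
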