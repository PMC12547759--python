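"""Synthetic cohort and message-stream generation, plus on-disk formats.

The generator emulates the statistical structure of a guided ICBT cohort:
three treatment arms, each scored on its own questionnaire; symptom
trajectories that improve on average from roughly 44 % of the scale maximum
before treatment to roughly 27 % after; heavy-tailed per-patient word counts
in the first four treatment weeks; and message text whose token frequencies
carry a tunable amount of signal about each patient's latent improvement.

Data model
----------
``CohortTable`` wraps a :class:`pandas.DataFrame` with one row per patient:
``patient_id``, ``treatment``, ``scale_id``, ``scale_max`` and one float
column per assessment timepoint (NaN marks a missing assessment).

``MessageStream`` wraps a DataFrame with one row per message:
``patient_id``, ``sender`` (patient|therapist), ``day`` (integer offset from
treatment start) and ``text``.

On-disk formats (fixed dialects)
--------------------------------
Cohort: comma-separated file with header
``patient_id,treatment,scale_max,screening,pre,week1..week12,post``;
missing scores are empty fields. Messages: line-delimited JSON objects with
keys ``patient_id``, ``sender``, ``day``, ``text``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CohortParseError, ConfigError
from .scales import SCALE_MAX, TIMEPOINTS, TREATMENTS, scale_for_treatment

__all__ = [
    "GeneratorConfig",
    "CohortTable",
    "MessageStream",
    "generate_cohort",
    "inject_missingness",
    "default_missing_rates",
    "write_cohort",
    "read_cohort",
    "write_messages",
    "read_messages",
]

#: number of scheduled assessments (screening, pre, 12 weekly, post)
N_TIMEPOINTS = len(TIMEPOINTS)

#: vocabulary prefix for outcome-informative tokens
SIGNAL_PREFIX = "sig"
#: vocabulary prefix for background tokens
BACKGROUND_PREFIX = "w"

#: mean words per generated message (splits a patient's word budget)
_WORDS_PER_MESSAGE = 120.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Severity parameters are expressed as fractions of the questionnaire
    maximum so one configuration covers all three arms. Defaults reproduce
    the cohort-level descriptives of a large routine-care ICBT sample:
    pre-treatment severity 0.44 (SD 0.15) falling to 0.27 post-treatment
    with post SD ~0.18, arm proportions 3038/1740/1835 out of 6613, and
    log-normal first-four-week word counts whose top-5 %-trimmed mean/SD
    are 3194/2053 words.
    """

    n_patients: int = 500
    arm_proportions: tuple[float, float, float] = (3038 / 6613, 1740 / 6613, 1835 / 6613)
    pre_severity_mean: float = 0.44
    pre_severity_sd: float = 0.15
    post_severity_mean: float = 0.27
    improvement_sd: float = 0.10
    trajectory_noise_sd: float = 0.04
    missing_rate_range: tuple[float, float] = (0.03, 0.40)
    wordcount_log_mean: float = 7.93668
    wordcount_log_sd: float = 0.76152
    text_signal_strength: float = 0.0
    vocab_size: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients", "must be >= 1")
        if len(self.arm_proportions) != 3:
            raise ConfigError("arm_proportions", "must have exactly 3 entries")
        if any(p < 0 for p in self.arm_proportions):
            raise ConfigError("arm_proportions", "entries must be nonnegative")
        if abs(sum(self.arm_proportions) - 1.0) > 1e-9:
            raise ConfigError("arm_proportions", "must sum to 1 within 1e-9")
        for name in ("pre_severity_mean", "pre_severity_sd", "post_severity_mean",
                     "improvement_sd", "trajectory_noise_sd"):
            if getattr(self, name) < 0 or getattr(self, name) > 1:
                raise ConfigError(name, "must lie in [0, 1]")
        lo, hi = self.missing_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("missing_rate_range", "must be ordered and within [0, 1]")
        if self.wordcount_log_sd <= 0:
            raise ConfigError("wordcount_log_sd", "must be positive")
        if self.text_signal_strength < 0:
            raise ConfigError("text_signal_strength", "must be nonnegative")
        if self.vocab_size < 10:
            raise ConfigError("vocab_size", "must be >= 10")


class CohortTable:
    """One row per patient: identifiers, arm, questionnaire, raw scores.

    Scores are raw questionnaire points in ``[0, scale_max]``; NaN marks a
    missing assessment. Construction validates the schema and the score
    range invariant.
    """

    COLUMNS = ("patient_id", "treatment", "scale_id", "scale_max") + TIMEPOINTS

    def __init__(self, frame: pd.DataFrame):
        missing_cols = [c for c in self.COLUMNS if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"cohort frame lacks columns {missing_cols}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        bad_arm = ~frame["treatment"].isin(TREATMENTS)
        if bad_arm.any():
            raise ValueError(
                f"unknown treatment values: {sorted(frame.loc[bad_arm, 'treatment'].unique())}"
            )
        for arm in TREATMENTS:
            sid, smax = scale_for_treatment(arm)
            sub = frame["treatment"] == arm
            if not (frame.loc[sub, "scale_id"] == sid).all():
                raise ValueError(f"scale_id must be {sid} for treatment {arm}")
            if not (frame.loc[sub, "scale_max"] == smax).all():
                raise ValueError(f"scale_max must be {smax} for treatment {arm}")
        scores = frame.loc[:, list(TIMEPOINTS)].to_numpy(float)
        smax = frame["scale_max"].to_numpy(float)[:, None]
        with np.errstate(invalid="ignore"):
            out_of_range = (scores < 0) | (scores > smax)
        if np.nan_to_num(out_of_range, nan=0).any():
            rows = np.unique(np.where(out_of_range)[0])
            raise ValueError(
                f"raw scores outside [0, scale_max] for patient rows {rows.tolist()[:10]}"
            )
        if frame["patient_id"].duplicated().any():
            raise ValueError("duplicate patient_id")
        self.frame = frame

    # -- convenience accessors -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.frame)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.frame["patient_id"].to_numpy()

    @property
    def treatments(self) -> np.ndarray:
        return self.frame["treatment"].to_numpy()

    @property
    def scale_maxima(self) -> np.ndarray:
        return self.frame["scale_max"].to_numpy(float)

    def scores(self) -> np.ndarray:
        """Raw scores as an ``(n_patients, 15)`` float array (NaN = missing)."""
        return self.frame.loc[:, list(TIMEPOINTS)].to_numpy(float)

    def scaled_scores(self) -> np.ndarray:
        """Scores divided by each patient's scale maximum (min-max transform)."""
        return self.scores() / self.scale_maxima[:, None]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.scores())

    def with_scores(self, scores: np.ndarray) -> "CohortTable":
        """Return a copy of the table with the score block replaced."""
        frame = self.frame.copy()
        frame.loc[:, list(TIMEPOINTS)] = scores
        return CohortTable(frame)

    def equals(self, other: "CohortTable") -> bool:
        return self.frame.equals(other.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CohortTable(n_patients={self.n_patients})"


class MessageStream:
    """One row per message: patient_id, sender, day, text."""

    COLUMNS = ("patient_id", "sender", "day", "text")

    def __init__(self, frame: pd.DataFrame):
        missing_cols = [c for c in self.COLUMNS if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"message frame lacks columns {missing_cols}")
        # index labels are preserved: they record original message order even
        # if the frame arrives shuffled (aggregation sorts on them)
        frame = frame.loc[:, list(self.COLUMNS)]
        if len(frame):
            bad = ~frame["sender"].isin(("patient", "therapist"))
            if bad.any():
                raise ValueError("sender must be 'patient' or 'therapist'")
            if (frame["day"].to_numpy(int) < 0).any():
                raise ValueError("day must be >= 0")
            frame["day"] = frame["day"].astype(int)
        else:
            frame = frame.astype({"patient_id": object, "sender": object,
                                  "day": int, "text": object})
        self.frame = frame

    @property
    def n_messages(self) -> int:
        return len(self.frame)

    def equals(self, other: "MessageStream") -> bool:
        return self.frame.equals(other.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MessageStream(n_messages={self.n_messages})"


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _signal_token_count(vocab_size: int) -> int:
    return max(1, vocab_size // 10)


def vocabulary(config: GeneratorConfig) -> list[str]:
    """The generator's vocabulary: signal tokens first, then background."""
    n_sig = _signal_token_count(config.vocab_size)
    sig = [f"{SIGNAL_PREFIX}{i:03d}" for i in range(n_sig)]
    bg = [f"{BACKGROUND_PREFIX}{i:04d}" for i in range(config.vocab_size - n_sig)]
    return sig + bg


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, MessageStream]:
    """Generate a complete synthetic cohort and its message stream.

    Trajectory model: each patient draws a latent pre-treatment severity
    ``pre ~ N(pre_severity_mean, pre_severity_sd)`` (fraction of scale max)
    and a latent improvement
    ``delta ~ N(pre_severity_mean - post_severity_mean, improvement_sd)``;
    weekly scores interpolate linearly from pre to post = pre - delta with
    independent weekly noise, and all scores are clipped to the scale range.
    Early weekly scores therefore genuinely predict the post score, which is
    what makes a symptom-only benchmark informative on this data.

    Text model: each patient's first-four-week word budget is log-normal;
    words are multinomial draws from a fixed vocabulary in which the log-odds
    of the designated signal-token subset are shifted by
    ``text_signal_strength * z`` where ``z`` is the patient's standardised
    latent improvement (half the shift in therapist messages). With
    ``text_signal_strength = 0`` the text is pure noise.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    arms = rng.choice(len(TREATMENTS), size=n, p=np.asarray(config.arm_proportions))
    treatments = np.array(TREATMENTS, dtype=object)[arms]
    scale_ids = np.array([scale_for_treatment(t)[0] for t in treatments], dtype=object)
    scale_max = np.array([SCALE_MAX[s] for s in scale_ids], dtype=float)

    pre = rng.normal(config.pre_severity_mean, config.pre_severity_sd, size=n)
    shift = config.pre_severity_mean - config.post_severity_mean
    delta = rng.normal(shift, config.improvement_sd, size=n)
    post = pre - delta

    frac = np.empty((n, N_TIMEPOINTS))
    noise = rng.normal(0.0, config.trajectory_noise_sd, size=(n, N_TIMEPOINTS))
    frac[:, 0] = pre + noise[:, 0]                       # screening
    frac[:, 1] = pre + noise[:, 1]                       # pre
    for k in range(1, 13):                               # week1..week12
        w = k / 13.0
        frac[:, 1 + k] = pre + (post - pre) * w + noise[:, 1 + k]
    frac[:, 14] = post + noise[:, 14]                    # post
    scores = np.clip(frac, 0.0, 1.0) * scale_max[:, None]

    patient_ids = np.array([f"p{i:05d}" for i in range(n)], dtype=object)
    cohort = CohortTable(pd.DataFrame({
        "patient_id": patient_ids,
        "treatment": treatments,
        "scale_id": scale_ids,
        "scale_max": scale_max.astype(int),
        **{tp: scores[:, j] for j, tp in enumerate(TIMEPOINTS)},
    }))

    # --- messages ----------------------------------------------------------
    vocab = np.array(vocabulary(config), dtype=object)
    n_sig = _signal_token_count(config.vocab_size)
    sd_delta = config.improvement_sd if config.improvement_sd > 0 else 1.0
    z = (delta - shift) / sd_delta

    rows: list[tuple[str, str, int, str]] = []
    for i in range(n):
        words_pre = int(np.ceil(rng.lognormal(config.wordcount_log_mean,
                                              config.wordcount_log_sd)))
        n_msgs = max(2, int(round(words_pre / _WORDS_PER_MESSAGE)))
        days = np.sort(rng.integers(0, 29, size=n_msgs))
        # split the word budget roughly evenly with multinomial jitter
        counts = rng.multinomial(words_pre, np.full(n_msgs, 1.0 / n_msgs))
        # a few later messages outside the prediction window
        n_late = int(rng.integers(1, 4))
        late_days = np.sort(rng.integers(29, 84, size=n_late))
        late_counts = np.maximum(1, rng.poisson(_WORDS_PER_MESSAGE, size=n_late))

        for msg_days, msg_counts in ((days, counts), (late_days, late_counts)):
            for j, (day, n_words) in enumerate(zip(msg_days, msg_counts)):
                if n_words == 0:
                    continue
                sender = "patient" if (j % 2 == 0) else "therapist"
                shift_eff = config.text_signal_strength * z[i]
                if sender == "therapist":
                    shift_eff *= 0.5
                logits = np.zeros(config.vocab_size)
                logits[:n_sig] = shift_eff
                p = np.exp(logits - logits.max())
                p /= p.sum()
                token_ids = rng.choice(config.vocab_size, size=int(n_words), p=p)
                rows.append((patient_ids[i], sender, int(day),
                             " ".join(vocab[token_ids])))

    messages = MessageStream(pd.DataFrame(rows, columns=list(MessageStream.COLUMNS)))
    return cohort, messages


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def default_missing_rates(config: GeneratorConfig) -> dict[str, float]:
    """Per-timepoint missingness ramping linearly across the schedule.

    Screening gets the low end of ``missing_rate_range``, post the high end:
    late assessments in routine care are the most often skipped.
    """
    lo, hi = config.missing_rate_range
    n = N_TIMEPOINTS
    return {tp: lo + (hi - lo) * j / (n - 1) for j, tp in enumerate(TIMEPOINTS)}


def inject_missingness(
    cohort: CohortTable,
    rate_by_timepoint: dict[str, float],
    seed: int,
    mar_log_odds: float = 1.0,
) -> CohortTable:
    """Delete scores at the requested per-timepoint rates under a MAR law.

    The probability that a cell at timepoint *t* goes missing follows a
    logistic model in the patient's *observed* scaled pre-treatment score
    (screening score when deleting the pre assessment itself), with slope
    ``mar_log_odds`` per standardised unit; the intercept is solved by
    bisection so the marginal rate equals the request. Missingness never
    depends on the value being deleted (no MNAR).
    """
    for tp, r in rate_by_timepoint.items():
        if tp not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {tp!r}")
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"missing rate for {tp} outside [0, 1]: {r}")
    rng = np.random.default_rng(seed)
    scores = cohort.scores().copy()
    scaled = cohort.scaled_scores()
    tp_index = {tp: j for j, tp in enumerate(TIMEPOINTS)}

    def standardised_driver(col: int) -> np.ndarray:
        x = scaled[:, col].copy()
        x[np.isnan(x)] = np.nanmean(x) if np.isfinite(np.nanmean(x)) else 0.0
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    for tp in TIMEPOINTS:  # fixed order => deterministic
        r = rate_by_timepoint.get(tp, 0.0)
        if r <= 0.0:
            continue
        j = tp_index[tp]
        driver_col = tp_index["screening"] if tp == "pre" else tp_index["pre"]
        zsc = standardised_driver(driver_col) if tp != "screening" else np.zeros(len(scores))
        eta = mar_log_odds * zsc if tp != "screening" else zsc

        def mean_p(c: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(-(c + eta)))))

        lo_c, hi_c = -30.0, 30.0
        for _ in range(80):
            mid = 0.5 * (lo_c + hi_c)
            if mean_p(mid) < r:
                lo_c = mid
            else:
                hi_c = mid
        c = 0.5 * (lo_c + hi_c)
        p = 1.0 / (1.0 + np.exp(-(c + eta)))
        drop = rng.random(len(scores)) < p
        scores[drop, j] = np.nan

    return cohort.with_scores(scores)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortTable, path) -> None:
    """Write the fixed comma-separated cohort dialect (missing = empty field)."""
    out = cohort.frame.drop(columns=["scale_id"])
    out.to_csv(path, index=False, float_format="%.10g")


def read_cohort(path) -> CohortTable:
    """Read and validate the cohort dialect written by :func:`write_cohort`.

    Raises :class:`CohortParseError` with a 1-based line number on malformed
    rows or out-of-range scores.
    """
    header = ["patient_id", "treatment", "scale_max"] + list(TIMEPOINTS)
    try:
        frame = pd.read_csv(path, dtype={"patient_id": str, "treatment": str})
    except Exception as exc:
        raise CohortParseError(0, f"unreadable cohort file: {exc}") from None
    missing_cols = [c for c in header if c not in frame.columns]
    if missing_cols:
        raise CohortParseError(1, f"header lacks columns {missing_cols}")

    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        if row["treatment"] not in TREATMENTS:
            raise CohortParseError(line, f"unknown treatment {row['treatment']!r}")
        sid, smax = scale_for_treatment(row["treatment"])
        try:
            file_max = float(row["scale_max"])
        except (TypeError, ValueError):
            raise CohortParseError(line, f"non-numeric scale_max {row['scale_max']!r}") from None
        if file_max != smax:
            raise CohortParseError(line, f"scale_max {file_max} inconsistent with {sid} ({smax})")
        for tp in TIMEPOINTS:
            v = row[tp]
            if pd.isna(v):
                continue
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise CohortParseError(line, f"non-numeric score {v!r} at {tp}") from None
            if not (0.0 <= fv <= smax):
                raise CohortParseError(line, f"score {fv} at {tp} outside [0, {smax}] for {sid}")

    frame["scale_id"] = [scale_for_treatment(t)[0] for t in frame["treatment"]]
    frame["scale_max"] = frame["scale_max"].astype(int)
    for tp in TIMEPOINTS:
        frame[tp] = pd.to_numeric(frame[tp])
    return CohortTable(frame)


def write_messages(messages: MessageStream, path) -> None:
    """Write line-delimited JSON records (patient_id, sender, day, text)."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in messages.frame.itertuples(index=False):
            fh.write(json.dumps({"patient_id": row.patient_id, "sender": row.sender,
                                 "day": int(row.day), "text": row.text},
                                ensure_ascii=False) + "\n")


def read_messages(path) -> MessageStream:
    """Read line-delimited JSON messages; an empty file yields an empty stream."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                rows.append((rec["patient_id"], rec["sender"], int(rec["day"]),
                             rec["text"]))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise CohortParseError(lineno, f"malformed message record: {exc}") from None
    frame = pd.DataFrame(rows, columns=list(MessageStream.COLUMNS)) if rows else \
        pd.DataFrame(columns=list(MessageStream.COLUMNS))
    return MessageStream(frame)
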