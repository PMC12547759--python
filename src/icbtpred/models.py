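"""The compared model families, all sharing a fit/predict contract.

Eight variants of six families, as in the study design this package
implements:

* ``dummy``         - predicts the training-outcome mean (null model)
* ``linear``        - least squares on the 9 symptom/treatment features
* ``tfidf``         - TF-IDF bag-of-words + elastic net  (``tfidf_sym``
                      appends the 9 features as extra columns)
* ``encoder``       - transformer encoder on a single head+tail token
                      window (``encoder_sym`` fuses the 9 features in the
                      regression head)
* ``windowed``      - five independent encoders on rolling 510-token
                      windows, predictions mean-pooled (``windowed_sym``
                      fuses the features in every sub-model's head)

Each model's ``fit`` receives a :class:`ModelInputs` bundle for the
training patients and the scaled outcomes; ``predict`` returns one real
per test patient. All text featurization (TF-IDF vocabulary, encoder
tokenizer) is fitted inside ``fit`` on training patients only, so
cross-validation through these objects cannot leak test text.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import ElasticNet

from .nn.transformer import (N_SPECIAL_TOKENS, PAD_ID, UNK_ID, EncoderSpec,
                             TransformerRegressor)
from .preprocess import make_rolling_windows, truncate_head_tail

__all__ = [
    "ModelInputs",
    "HyperparameterGrid",
    "MeanPredictor",
    "SymptomLinearModel",
    "TfidfElasticNetModel",
    "EncoderModel",
    "WindowedEncoderModel",
    "MODEL_FAMILIES",
    "make_model",
    "save_model",
    "load_model",
]


@dataclass
class ModelInputs:
    """Per-patient inputs: cleaned aggregated text, bag-of-words tokens,
    and the 9-entry symptom/treatment feature matrix."""

    texts: list[str]
    bow_tokens: list[list[str]]
    features: np.ndarray  # (n, 9)

    def __len__(self) -> int:
        return len(self.texts)

    def subset(self, idx) -> "ModelInputs":
        idx = np.asarray(idx)
        return ModelInputs(texts=[self.texts[i] for i in idx],
                           bow_tokens=[self.bow_tokens[i] for i in idx],
                           features=self.features[idx])


@dataclass(frozen=True)
class HyperparameterGrid:
    """Tuning grid for the text models.

    :meth:`full_grid` returns the published full-scale grid (TF-IDF
    features 500/5000, uni/uni+bigrams, elastic-net alpha 3/1/0.5/0.2 with
    l1 ratio 0.2/0.5/0.8, encoder learning rates 5e-5/2e-5 at batch 32 for
    4 epochs, windowed at 2e-5, batch 8, 5 epochs, dropout 0.1).
    :meth:`desk_grid` is the reduced configuration sized for a small
    randomly initialised encoder on a laptop-scale synthetic cohort.
    """

    tfidf_n_features: tuple[int, ...] = (500, 5000)
    tfidf_ngram_max: tuple[int, ...] = (1, 2)
    en_alpha: tuple[float, ...] = (3.0, 1.0, 0.5, 0.2)
    en_l1_ratio: tuple[float, ...] = (0.2, 0.5, 0.8)
    encoder_learning_rate: tuple[float, ...] = (5e-5, 2e-5)
    encoder_batch_size: int = 32
    encoder_epochs: int = 4
    windowed_learning_rate: tuple[float, ...] = (2e-5,)
    windowed_batch_size: int = 8
    windowed_epochs: int = 5
    dropout_rate: float = 0.1

    def __post_init__(self):
        for name in ("tfidf_n_features", "tfidf_ngram_max", "en_alpha",
                     "en_l1_ratio", "encoder_learning_rate", "windowed_learning_rate"):
            vals = getattr(self, name)
            if not vals or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be a nonempty tuple of positive values")

    @classmethod
    def full_grid(cls) -> "HyperparameterGrid":
        return cls()

    @classmethod
    def desk_grid(cls) -> "HyperparameterGrid":
        return cls(tfidf_n_features=(100,), tfidf_ngram_max=(1,),
                   en_alpha=(0.1, 0.01), en_l1_ratio=(0.5,),
                   encoder_learning_rate=(1e-3,), encoder_batch_size=8,
                   encoder_epochs=8, windowed_learning_rate=(1e-3,),
                   windowed_batch_size=8, windowed_epochs=2)

    def configs(self, family: str) -> list[dict]:
        """Enumerate configurations in listed order (tie-break order)."""
        base = family.removesuffix("_sym")
        if base in ("dummy", "linear"):
            return [{}]
        if base == "tfidf":
            return [{"n_features": nf, "ngram_max": ng, "alpha": a, "l1_ratio": l1}
                    for nf in self.tfidf_n_features
                    for ng in self.tfidf_ngram_max
                    for a in self.en_alpha
                    for l1 in self.en_l1_ratio]
        if base == "encoder":
            return [{"learning_rate": lr, "batch_size": self.encoder_batch_size,
                     "epochs": self.encoder_epochs, "dropout_rate": self.dropout_rate}
                    for lr in self.encoder_learning_rate]
        if base == "windowed":
            return [{"learning_rate": lr, "batch_size": self.windowed_batch_size,
                     "epochs": self.windowed_epochs, "dropout_rate": self.dropout_rate}
                    for lr in self.windowed_learning_rate]
        raise ValueError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# simple families
# ---------------------------------------------------------------------------

class MeanPredictor:
    """Null model: predicts the training-outcome mean regardless of input."""

    def __init__(self, **_ignored):
        self.mean_: float | None = None

    def fit(self, inputs: ModelInputs, outcomes, rng=None) -> "MeanPredictor":
        y = np.asarray(outcomes, dtype=float)
        if y.size == 0:
            raise ValueError("empty training set")
        self.mean_ = float(y.mean())
        return self

    def predict(self, inputs: ModelInputs) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("fit before predict")
        return np.full(len(inputs), self.mean_)


class SymptomLinearModel:
    """Least squares on the 9 symptom/treatment features.

    The intercept plus the 3-way one-hot block is rank-deficient by
    construction; ``lstsq`` returns the minimum-norm solution, which leaves
    predictions unique.
    """

    def __init__(self, **_ignored):
        self.coef_: np.ndarray | None = None

    @staticmethod
    def _design(features: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(len(features)), features])

    def fit(self, inputs: ModelInputs, outcomes, rng=None) -> "SymptomLinearModel":
        X = self._design(inputs.features)
        y = np.asarray(outcomes, dtype=float)
        if len(y) <= X.shape[1] - 4:  # one-hot redundancy leaves 10-1 effective cols
            warnings.warn("fewer training rows than effective coefficients",
                          RuntimeWarning)
        self.coef_, *_ = np.linalg.lstsq(X, y, rcond=None)
        return self

    def predict(self, inputs: ModelInputs) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("fit before predict")
        return self._design(inputs.features) @ self.coef_


# ---------------------------------------------------------------------------
# TF-IDF + elastic net
# ---------------------------------------------------------------------------

class TfidfElasticNetModel:
    """TF-IDF document-term matrix + elastic-net regression.

    Weighting is term frequency times smoothed inverse document frequency,
    ``idf(t) = ln((1 + n) / (1 + df(t))) + 1``, followed by L2 row
    normalisation; terms appearing in more than 80 % of training documents
    are discarded and the vocabulary is capped at ``n_features`` by corpus
    frequency. The elastic net minimises
    ``1/(2n) * ||y - Xw||^2 + alpha * (l1_ratio * ||w||_1
    + (1 - l1_ratio)/2 * ||w||^2)``. With ``use_symptoms`` the 9 features
    are appended as extra (dense) columns of the design.
    """

    MAX_DOC_FREQ = 0.8

    def __init__(self, n_features: int = 500, ngram_max: int = 1,
                 alpha: float = 1.0, l1_ratio: float = 0.5,
                 use_symptoms: bool = False, max_iter: int = 5000, **_ignored):
        self.n_features = n_features
        self.ngram_max = ngram_max
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.use_symptoms = use_symptoms
        self.max_iter = max_iter
        self.vectorizer_: TfidfVectorizer | None = None
        self.regressor_: ElasticNet | None = None

    def _docs(self, inputs: ModelInputs) -> list[str]:
        return [" ".join(toks) for toks in inputs.bow_tokens]

    def build_matrix(self, inputs: ModelInputs, fit: bool) -> sp.csr_matrix:
        docs = self._docs(inputs)
        if fit:
            if not any(docs):
                raise ValueError("empty corpus: no tokens in any training document")
            # the >80 % document-frequency cut is undefined on one document
            max_df = self.MAX_DOC_FREQ if len(docs) > 1 else 1.0
            self.vectorizer_ = TfidfVectorizer(
                token_pattern=r"\S+", lowercase=False,
                ngram_range=(1, self.ngram_max), max_df=max_df,
                max_features=self.n_features, smooth_idf=True, norm="l2")
            try:
                X = self.vectorizer_.fit_transform(docs)
            except ValueError:
                # every term above the document-frequency cap: no text columns
                warnings.warn("document-frequency cap removed the entire "
                              "vocabulary; text block is empty", RuntimeWarning)
                self.vectorizer_ = None
                X = sp.csr_matrix((len(docs), 1))
        elif self.vectorizer_ is None:
            X = sp.csr_matrix((len(docs), 1))
        else:
            X = self.vectorizer_.transform(docs)
        if self.use_symptoms:
            X = sp.hstack([X, sp.csr_matrix(inputs.features)], format="csr")
        return X

    def fit(self, inputs: ModelInputs, outcomes, rng=None) -> "TfidfElasticNetModel":
        X = self.build_matrix(inputs, fit=True)
        y = np.asarray(outcomes, dtype=float)
        self.regressor_ = ElasticNet(alpha=self.alpha, l1_ratio=self.l1_ratio,
                                     max_iter=self.max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("always", ConvergenceWarning)
            self.regressor_.fit(X, y)
        return self

    def predict(self, inputs: ModelInputs) -> np.ndarray:
        if self.regressor_ is None:
            raise RuntimeError("fit before predict")
        return self.regressor_.predict(self.build_matrix(inputs, fit=False))


# ---------------------------------------------------------------------------
# encoder families
# ---------------------------------------------------------------------------

class WordTokenizer:
    """Whitespace word tokenizer with a frequency-capped vocabulary.

    Ids 0-2 are reserved (pad, unknown, sequence summary); the vocabulary is
    built on training texts only.
    """

    def __init__(self, max_vocab: int = 2000):
        self.max_vocab = max_vocab
        self.vocab_: dict[str, int] | None = None

    def fit(self, texts: list[str]) -> "WordTokenizer":
        counts = Counter(tok for t in texts for tok in t.split())
        most = [w for w, _ in counts.most_common(self.max_vocab - N_SPECIAL_TOKENS)]
        self.vocab_ = {w: i + N_SPECIAL_TOKENS for i, w in enumerate(most)}
        return self

    @property
    def vocab_size(self) -> int:
        return len(self.vocab_) + N_SPECIAL_TOKENS

    def encode(self, text: str) -> list[int]:
        return [self.vocab_.get(tok, UNK_ID) for tok in text.split()]


class EncoderModel:
    """Transformer encoder on the head+tail window, optional feature fusion."""

    def __init__(self, spec: EncoderSpec | None = None, use_symptoms: bool = False,
                 learning_rate: float = 1e-3, batch_size: int = 8, epochs: int = 3,
                 dropout_rate: float = 0.1, max_vocab: int = 2000, seed: int = 0,
                 **_ignored):
        base = spec or EncoderSpec()
        self.spec = replace(base, dropout_rate=dropout_rate,
                            n_fusion_features=9 if use_symptoms else 0)
        self.use_symptoms = use_symptoms
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_vocab = max_vocab
        self.seed = seed
        self.tokenizer_: WordTokenizer | None = None
        self.net_: TransformerRegressor | None = None
        self.loss_trace_: list[float] | None = None

    def _windows(self, inputs: ModelInputs) -> list[list[int]]:
        return [truncate_head_tail(self.tokenizer_.encode(t)).windows[0]
                for t in inputs.texts]

    def fit(self, inputs: ModelInputs, outcomes, rng=None) -> "EncoderModel":
        self.tokenizer_ = WordTokenizer(self.max_vocab).fit(inputs.texts)
        self.net_ = TransformerRegressor(
            replace(self.spec, vocab_size=self.tokenizer_.vocab_size), seed=self.seed)
        feats = inputs.features if self.use_symptoms else None
        self.loss_trace_ = self.net_.fit(
            self._windows(inputs), np.asarray(outcomes, float), feats,
            lr=self.learning_rate, batch_size=self.batch_size, epochs=self.epochs)
        return self

    def predict(self, inputs: ModelInputs) -> np.ndarray:
        if self.net_ is None:
            raise RuntimeError("fit before predict")
        feats = inputs.features if self.use_symptoms else None
        return self.net_.predict(self._windows(inputs), feats)


class WindowedEncoderModel:
    """Five independent encoders on rolling windows, predictions mean-pooled.

    Each window position gets its own encoder and head (no weight tying);
    the fusion variant concatenates the same 9 features inside every
    sub-model's head. The final prediction is the arithmetic mean of the
    five sub-model outputs.
    """

    N_WINDOWS = 5

    def __init__(self, spec: EncoderSpec | None = None, use_symptoms: bool = False,
                 learning_rate: float = 1e-3, batch_size: int = 8, epochs: int = 2,
                 dropout_rate: float = 0.1, max_vocab: int = 2000, seed: int = 0,
                 **_ignored):
        base = spec or EncoderSpec()
        self.spec = replace(base, dropout_rate=dropout_rate,
                            n_fusion_features=9 if use_symptoms else 0)
        self.use_symptoms = use_symptoms
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_vocab = max_vocab
        self.seed = seed
        self.tokenizer_: WordTokenizer | None = None
        self.nets_: list[TransformerRegressor] | None = None

    def _window_lists(self, inputs: ModelInputs) -> list[list[list[int]]]:
        """``[window_position][patient] -> token ids`` (pads stripped: the
        encoder pads batches itself and masks pad keys)."""
        per_patient = [make_rolling_windows(self.tokenizer_.encode(t),
                                            pad_token=PAD_ID).windows
                       for t in inputs.texts]
        out = []
        for w in range(self.N_WINDOWS):
            out.append([[tok for tok in pw[w] if tok != PAD_ID] for pw in per_patient])
        return out

    def fit(self, inputs: ModelInputs, outcomes, rng=None) -> "WindowedEncoderModel":
        self.tokenizer_ = WordTokenizer(self.max_vocab).fit(inputs.texts)
        y = np.asarray(outcomes, float)
        feats = inputs.features if self.use_symptoms else None
        spec = replace(self.spec, vocab_size=self.tokenizer_.vocab_size)
        self.nets_ = []
        for w, windows in enumerate(self._window_lists(inputs)):
            net = TransformerRegressor(spec, seed=self.seed + w)
            net.fit(windows, y, feats, lr=self.learning_rate,
                    batch_size=self.batch_size, epochs=self.epochs)
            self.nets_.append(net)
        return self

    def predict(self, inputs: ModelInputs) -> np.ndarray:
        if self.nets_ is None:
            raise RuntimeError("fit before predict")
        feats = inputs.features if self.use_symptoms else None
        preds = [net.predict(windows, feats)
                 for net, windows in zip(self.nets_, self._window_lists(inputs))]
        return np.mean(preds, axis=0)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a fitted model to one file.

    The bundle is a pickle of the model object and therefore carries
    everything a reload needs: hyperparameters, fitted weights, the TF-IDF
    vocabulary or encoder tokenizer, and training loss traces. Bundles are
    readable only by a matching package version.
    """
    import pickle

    with open(path, "wb") as fh:
        pickle.dump({"format": "icbtpred-model-v1", "model": model}, fh)


def load_model(path):
    """Load a model bundle written by :func:`save_model`."""
    import pickle

    with open(path, "rb") as fh:
        bundle = pickle.load(fh)
    if not (isinstance(bundle, dict) and bundle.get("format") == "icbtpred-model-v1"):
        raise ValueError(f"{path} is not an icbtpred model bundle")
    return bundle["model"]


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

MODEL_FAMILIES = ("dummy", "linear", "tfidf", "tfidf_sym",
                  "encoder", "encoder_sym", "windowed", "windowed_sym")


def make_model(family: str, params: dict | None = None,
               encoder_spec: EncoderSpec | None = None, seed: int = 0):
    """Instantiate a model family with one hyperparameter configuration."""
    params = dict(params or {})
    sym = family.endswith("_sym")
    base = family.removesuffix("_sym")
    if base == "dummy" and not sym:
        return MeanPredictor()
    if base == "linear" and not sym:
        return SymptomLinearModel()
    if base == "tfidf":
        return TfidfElasticNetModel(use_symptoms=sym, **params)
    if base == "encoder":
        return EncoderModel(spec=encoder_spec, use_symptoms=sym, seed=seed, **params)
    if base == "windowed":
        return WindowedEncoderModel(spec=encoder_spec, use_symptoms=sym, seed=seed,
                                    **params)
    raise ValueError(f"unknown model family {family!r}")
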