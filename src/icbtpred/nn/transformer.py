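"""Transformer encoder regressor with an optional tabular-fusion head.

Architecture: token + learned positional embeddings, pre-norm transformer
blocks (multi-head self-attention with key padding masks, GELU feed-
forward), a final layer norm, and a regression head that reads the
sequence-summary position (a [CLS] token prepended to every window). The
head is one dense layer with tanh, a dropout layer, and a linear scalar
output; in the fusion variant the dense layer reads the concatenation of
the encoder representation and the 9 symptom/treatment features, so with a
768-dimensional encoder its input is 777-dimensional.

The window budget is fixed at 510 content tokens (plus the summary token),
the sequence limit of the encoder family this mirrors. Training is plain
mini-batch Adam on squared error; dropout is active only during training
and every source of randomness is driven by one Generator, so fits are
reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Parameter, Tensor, concatenate

__all__ = ["EncoderSpec", "TransformerRegressor", "Adam"]

#: training dtype; float32 keeps 510-token attention buffers affordable
DTYPE = np.float32

MAX_CONTENT_TOKENS = 510

#: reserved token ids used by the tokenizer and the model
PAD_ID, UNK_ID, CLS_ID = 0, 1, 2
N_SPECIAL_TOKENS = 3


@dataclass(frozen=True)
class EncoderSpec:
    """Shape of the encoder: desk-scale by default, full-scale on request."""

    vocab_size: int = 2000
    embedding_dim: int = 32
    n_layers: int = 1
    n_heads: int = 2
    ffn_mult: int = 2
    dropout_rate: float = 0.1
    n_fusion_features: int = 0  # 9 when symptom features are fused
    max_tokens_per_window: int = MAX_CONTENT_TOKENS

    def validate(self) -> None:
        if self.max_tokens_per_window != MAX_CONTENT_TOKENS:
            raise ValueError(f"max_tokens_per_window is fixed at {MAX_CONTENT_TOKENS}")
        if self.embedding_dim % self.n_heads:
            raise ValueError("embedding_dim must be divisible by n_heads")
        if self.vocab_size <= N_SPECIAL_TOKENS:
            raise ValueError("vocab_size too small for the reserved special tokens")


class Adam:
    """Adam optimizer with global-norm gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 max_grad_norm: float | None = 1.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.max_grad_norm = max_grad_norm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _clip(self) -> None:
        if self.max_grad_norm is None:
            return
        total = np.sqrt(sum(float((p.grad**2).sum())
                            for p in self.params if p.grad is not None))
        if total > self.max_grad_norm:
            scale = self.max_grad_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self) -> None:
        self._clip()
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(DTYPE)


class _Linear:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = Parameter(_glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class _LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=DTYPE))
        self.beta = Parameter(np.zeros(dim, dtype=DTYPE))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class _SelfAttention:
    def __init__(self, rng, dim: int, n_heads: int):
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = _Linear(rng, dim, 3 * dim)
        self.proj = _Linear(rng, dim, dim)

    def __call__(self, x: Tensor, key_mask: np.ndarray, dropout: float,
                 rng, training: bool) -> Tensor:
        B, L, D = x.shape
        H, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x)                                 # (B, L, 3D)
        qkv = qkv.reshape(B, L, 3, H, hd).transpose(2, 0, 3, 1, 4)  # (3,B,H,L,hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (hd ** -0.5)       # (B,H,L,L)
        neg = np.where(key_mask[:, None, None, :], 0.0, -1e9).astype(x.data.dtype)
        # dropout lives on the residual branches, not the attention weights
        attn = scores.softmax(axis=-1, additive_mask=neg)
        out = attn @ v                                              # (B,H,L,hd)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.proj(out)

    def params(self):
        return self.qkv.params() + self.proj.params()


class _Block:
    """Pre-norm transformer block."""

    def __init__(self, rng, dim: int, n_heads: int, ffn_mult: int):
        self.ln1 = _LayerNorm(dim)
        self.attn = _SelfAttention(rng, dim, n_heads)
        self.ln2 = _LayerNorm(dim)
        self.ff1 = _Linear(rng, dim, ffn_mult * dim)
        self.ff2 = _Linear(rng, ffn_mult * dim, dim)

    def __call__(self, x, key_mask, dropout, rng, training):
        x = x + self.attn(self.ln1(x), key_mask, dropout, rng, training) \
            .dropout(dropout, rng, training)
        x = x + self.ff2(self.ff1(self.ln2(x)).gelu()).dropout(dropout, rng, training)
        return x

    def params(self):
        return (self.ln1.params() + self.attn.params() + self.ln2.params()
                + self.ff1.params() + self.ff2.params())


class TransformerRegressor:
    """Encoder + regression head predicting one real per token window."""

    def __init__(self, spec: EncoderSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        rng = self.rng
        d = spec.embedding_dim
        self.tok_emb = Parameter(rng.normal(0, 0.02, size=(spec.vocab_size, d)).astype(DTYPE))
        self.pos_emb = Parameter(rng.normal(
            0, 0.02, size=(spec.max_tokens_per_window + 1, d)).astype(DTYPE))
        self.blocks = [_Block(rng, d, spec.n_heads, spec.ffn_mult)
                       for _ in range(spec.n_layers)]
        self.ln_f = _LayerNorm(d)
        self.head_input_dim = d + spec.n_fusion_features
        self.head_dense = _Linear(rng, self.head_input_dim, d)
        self.head_out = _Linear(rng, d, 1)

    def params(self) -> list[Parameter]:
        ps = [self.tok_emb, self.pos_emb]
        for b in self.blocks:
            ps += b.params()
        return ps + self.ln_f.params() + self.head_dense.params() + self.head_out.params()

    # -- forward ------------------------------------------------------------
    def _prepare(self, token_ids: list[list[int]]) -> tuple[np.ndarray, np.ndarray]:
        """Prepend [CLS], pad to the batch max length, build the key mask."""
        L = max((len(t) for t in token_ids), default=0) + 1
        ids = np.full((len(token_ids), L), PAD_ID, dtype=np.int64)
        mask = np.zeros((len(token_ids), L), dtype=bool)
        for i, toks in enumerate(token_ids):
            if len(toks) > self.spec.max_tokens_per_window:
                raise ValueError(
                    f"window of {len(toks)} tokens exceeds the "
                    f"{self.spec.max_tokens_per_window}-token limit")
            ids[i, 0] = CLS_ID
            ids[i, 1:1 + len(toks)] = toks
            mask[i, :1 + len(toks)] = True
        return ids, mask

    def forward(self, token_ids: list[list[int]], features: np.ndarray | None = None,
                training: bool = False) -> Tensor:
        """Scalar prediction per sequence; ``features`` is the (B, 9) block
        concatenated before the dense head layer in the fusion variant."""
        spec = self.spec
        if (features is None) != (spec.n_fusion_features == 0):
            raise ValueError("features must be supplied iff the spec declares fusion features")
        ids, mask = self._prepare(token_ids)
        rng, p = self.rng, spec.dropout_rate
        x = self.tok_emb.embedding(ids) + self.pos_emb.embedding(np.arange(ids.shape[1]))
        x = x.dropout(p, rng, training)
        for block in self.blocks:
            x = block(x, mask, p, rng, training)
        x = self.ln_f(x)
        summary = x[:, 0, :]                       # sequence-summary position
        if features is not None:
            summary = concatenate([summary, Tensor(np.asarray(features, dtype=DTYPE))], axis=-1)
        h = self.head_dense(summary).tanh().dropout(p, rng, training)
        return self.head_out(h).reshape(-1)

    # -- training -----------------------------------------------------------
    def fit(self, token_ids: list[list[int]], outcomes: np.ndarray,
            features: np.ndarray | None = None, lr: float = 1e-3,
            batch_size: int = 16, epochs: int = 3,
            warmup_fraction: float = 0.1) -> list[float]:
        """Mini-batch Adam on squared error with linear warmup then linear
        decay of the learning rate (the schedule conventional for
        fine-tuning this architecture family); returns per-epoch mean loss."""
        y = np.asarray(outcomes, dtype=float)
        n = len(token_ids)
        if n == 0:
            raise ValueError("empty training set")
        if float(self.head_out.b.data[0]) == 0.0:
            # start from the outcome mean so early steps model structure,
            # not the grand offset
            self.head_out.b.data[0] = y.mean()
        opt = Adam(self.params(), lr=lr)
        n_steps = epochs * int(np.ceil(n / batch_size))
        warmup = max(1, int(warmup_fraction * n_steps))
        step = 0
        losses = []
        lengths = np.array([len(t) for t in token_ids])
        for _ in range(epochs):
            # length-bucketed batches in random order: random ties within a
            # length keep batches stochastic while padding stays minimal
            order = self.rng.permutation(n)
            order = order[np.argsort(lengths[order], kind="stable")]
            batches = [order[s:s + batch_size] for s in range(0, n, batch_size)]
            self.rng.shuffle(batches)
            epoch_loss = 0.0
            for idx in batches:
                batch_feats = features[idx] if features is not None else None
                pred = self.forward([token_ids[i] for i in idx], batch_feats,
                                    training=True)
                err = pred - Tensor(y[idx].astype(DTYPE))
                loss = (err**2.0).mean()
                opt.zero_grad()
                loss.backward()
                step += 1
                if step <= warmup:
                    opt.lr = lr * step / warmup
                else:
                    opt.lr = lr * max(0.0, (n_steps - step) / (n_steps - warmup))
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            losses.append(epoch_loss / n)
        return losses

    def predict(self, token_ids: list[list[int]],
                features: np.ndarray | None = None,
                batch_size: int = 64) -> np.ndarray:
        n = len(token_ids)
        if n == 0:
            return np.empty(0)
        order = np.argsort([len(t) for t in token_ids], kind="stable")
        preds = np.empty(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            feats = features[idx] if features is not None else None
            preds[idx] = self.forward([token_ids[i] for i in idx], feats,
                                      training=False).data
        return preds
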