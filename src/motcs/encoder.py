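"""Positional-encoding-free transformer encoder for tabular omics features.

Each scalar feature value becomes a D-dimensional token through a
feature-specific linear map (value * w_i + b_i).  Tokens attend to each
other with multi-head scaled dot-product self-attention, pass through a
position-wise feed-forward network, with residual connections and layer
normalisation around each sub-layer, and are finally mean-pooled over the
feature axis into one D-vector per sample.  Positional encodings are
deliberately absent: tabular features have no order, and the mean-pooled
representation is exactly invariant under consistent feature permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor, concat, dropout, softmax


@dataclass
class EncoderConfig:
    """Architecture hyperparameters for one encoder branch.

    embed_dim D must be divisible by num_heads h; each head has width
    d_k = D / h.  ffn_hidden defaults to 4 * D.  Dropout applies only in
    training mode, after the attention and feed-forward sub-layers.
    """

    embed_dim: int = 64
    num_heads: int = 4
    num_layers: int = 2
    ffn_hidden: int | None = None
    dropout_rate: float = 0.1

    def __post_init__(self):
        if self.embed_dim % self.num_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by "
                f"num_heads {self.num_heads}")
        if self.ffn_hidden is None:
            self.ffn_hidden = 4 * self.embed_dim
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads


def self_attention(Q, K, V, d_k: int) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V with row-wise softmax.

    Accepts 2-D (tokens x width) or batched 3-D arrays/tensors; every row of
    the attention-weight matrix sums to 1.
    """
    Q, K, V = as_tensor(Q), as_tensor(K), as_tensor(V)
    for t in (Q, K, V):
        if not np.all(np.isfinite(t.data)):
            raise ValueError("self_attention: non-finite input")
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    return softmax(scores, axis=-1) @ V


def position_wise_ffn(X, W1, b1, W2, b2) -> Tensor:
    """max(0, X W1 + b1) W2 + b2 applied token-wise."""
    X = as_tensor(X)
    return (X @ as_tensor(W1) + as_tensor(b1)).relu() @ as_tensor(W2) \
        + as_tensor(b2)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with learnable scale/shift."""
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred / ((var + eps) ** 0.5) * gamma + beta


@dataclass
class EncoderLayerParams:
    """Learnable weights for one encoder layer (per-head projections,
    output projection, two layer norms, feed-forward weights)."""

    W_Q: list[Tensor]
    W_K: list[Tensor]
    W_V: list[Tensor]
    W_O: Tensor
    ln1_gamma: Tensor
    ln1_beta: Tensor
    W_1: Tensor
    b_1: Tensor
    W_2: Tensor
    b_2: Tensor
    ln2_gamma: Tensor
    ln2_beta: Tensor

    def parameters(self) -> list[Tensor]:
        return (self.W_Q + self.W_K + self.W_V
                + [self.W_O, self.ln1_gamma, self.ln1_beta, self.W_1,
                   self.b_1, self.W_2, self.b_2, self.ln2_gamma,
                   self.ln2_beta])


@dataclass
class EncoderParams:
    """All learnable weights of one encoder branch for N input features."""

    embed_W: Tensor  # (N, D): per-feature embedding direction
    embed_b: Tensor  # (N, D): per-feature bias
    layers: list[EncoderLayerParams] = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        out = [self.embed_W, self.embed_b]
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    @property
    def n_features(self) -> int:
        return self.embed_W.data.shape[0]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape) -> Tensor:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return Tensor(rng.normal(0.0, std, size=shape))


def init_encoder_params(n_features: int, config: EncoderConfig,
                        rng: np.random.Generator) -> EncoderParams:
    """Glorot-style initialisation of a full encoder branch."""
    D, dk, F = config.embed_dim, config.head_dim, config.ffn_hidden
    params = EncoderParams(
        embed_W=Tensor(rng.normal(0.0, 1.0 / np.sqrt(D), size=(n_features, D))),
        embed_b=Tensor(np.zeros((n_features, D))),
    )
    for _ in range(config.num_layers):
        params.layers.append(EncoderLayerParams(
            W_Q=[_glorot(rng, D, dk, (D, dk)) for _ in range(config.num_heads)],
            W_K=[_glorot(rng, D, dk, (D, dk)) for _ in range(config.num_heads)],
            W_V=[_glorot(rng, D, dk, (D, dk)) for _ in range(config.num_heads)],
            W_O=_glorot(rng, D, D, (D, D)),
            ln1_gamma=Tensor(np.ones(D)), ln1_beta=Tensor(np.zeros(D)),
            W_1=_glorot(rng, D, F, (D, F)), b_1=Tensor(np.zeros(F)),
            W_2=_glorot(rng, F, D, (F, D)), b_2=Tensor(np.zeros(D)),
            ln2_gamma=Tensor(np.ones(D)), ln2_beta=Tensor(np.zeros(D)),
        ))
    return params


def embed_features(X, params: EncoderParams) -> Tensor:
    """Per-feature linear token embedding: token(s, i) = x_{s,i} w_i + b_i.

    Input (M, N) -> output (M, N, D).  Feature-specific maps keep feature
    identity without positional encodings; a single shared scalar map would
    make all tokens colinear.
    """
    X = as_tensor(X)
    if X.ndim != 2 or X.shape[1] != params.n_features:
        raise ValueError(
            f"embed_features: input has {X.shape} but params expect "
            f"N={params.n_features}")
    M, N = X.shape
    D = params.embed_W.data.shape[1]
    x3 = X.reshape(M, N, 1)
    return x3 * params.embed_W.reshape(1, N, D) + params.embed_b.reshape(1, N, D)


def multi_head_attention(E: Tensor, layer: EncoderLayerParams,
                         config: EncoderConfig) -> Tensor:
    """h parallel attention heads on per-head projections of width d_k,
    concatenated and projected by W_O.

    Computed fused: the per-head projection matrices are concatenated so
    each of Q/K/V is a single matmul, and all heads attend in one batched
    call — algebraically identical to looping over heads (the unit tests
    check this against a per-head oracle).
    """
    E = as_tensor(E)
    h, dk = config.num_heads, config.head_dim
    M, N, D = E.shape

    def heads(W: list) -> Tensor:  # (M,N,D) @ (D,h*dk) -> (M,h,N,dk)
        return (E @ concat(W, axis=-1)).reshape(M, N, h, dk).swapaxes(1, 2)

    att = self_attention(heads(layer.W_Q), heads(layer.W_K),
                         heads(layer.W_V), dk)
    return att.swapaxes(1, 2).reshape(M, N, h * dk) @ layer.W_O


def encode(X, params: EncoderParams, config: EncoderConfig,
           training: bool = False,
           rng: np.random.Generator | None = None) -> Tensor:
    """Full branch: embed -> [MHA + residual + LN, FFN + residual + LN] x
    num_layers -> mean-pool over the feature/token axis.  (M, N) -> (M, D).

    Deterministic (a pure function of inputs and parameters) when
    ``training`` is False; dropout requires an RNG in training mode.
    """
    X = as_tensor(X)
    if X.shape[1] == 0:
        raise ValueError("encode: zero features; disable this branch upstream")
    if training and config.dropout_rate > 0 and rng is None:
        raise ValueError("encode: training mode with dropout needs an rng")
    h = embed_features(X, params)
    for layer in params.layers:
        att = multi_head_attention(h, layer, config)
        att = dropout(att, config.dropout_rate, rng, training)
        h = layer_norm(h + att, layer.ln1_gamma, layer.ln1_beta)
        ff = position_wise_ffn(h, layer.W_1, layer.b_1, layer.W_2, layer.b_2)
        ff = dropout(ff, config.dropout_rate, rng, training)
        h = layer_norm(h + ff, layer.ln2_gamma, layer.ln2_beta)
    return h.mean(axis=1)
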