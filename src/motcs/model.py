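"""The MOTCS network.

Per omics view, two transformer-encoder branches (driver features and
L1-SVC-selected non-driver features) produce sample representations that
are horizontally concatenated and classified by a per-view MLP into
subtype probabilities.  With several views, each sample's per-view
probability rows form a cross-omics tensor C[c1, c2, c3] =
p1[c1] * p2[c2] * p3[c3], whose row-major vectorisation a small fully
connected network (the view-correlation decision network, VCDN) maps to
the final class probabilities.  The training objective is the unweighted
sum of every view's cross-entropy plus the VCDN cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor, concat, dropout, softmax
from .encoder import EncoderConfig, EncoderParams, encode, init_encoder_params
from .io import MotcsError
from .preprocess import ViewFeatureSet


# ----------------------------------------------------------------- components

@dataclass
class MLPParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


def _glorot(rng, fan_in, fan_out, shape) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), shape))


def init_mlp(d_in: int, hidden: int, d_out: int,
             rng: np.random.Generator) -> MLPParams:
    return MLPParams(_glorot(rng, d_in, hidden, (d_in, hidden)),
                     Tensor(np.zeros(hidden)),
                     _glorot(rng, hidden, d_out, (hidden, d_out)),
                     Tensor(np.zeros(d_out)))


def concat_view_embeddings(Z_dg: Tensor | None,
                           Z_svc: Tensor | None) -> Tensor:
    """Column-wise concat in (driver, non-driver) order; with one branch
    disabled the other passes through unchanged."""
    if Z_dg is None and Z_svc is None:
        raise MotcsError("both encoder branches absent")
    if Z_dg is None:
        return as_tensor(Z_svc)
    if Z_svc is None:
        return as_tensor(Z_dg)
    return concat([as_tensor(Z_dg), as_tensor(Z_svc)], axis=-1)


def mlp_view_classify(Z, params: MLPParams, training: bool = False,
                      dropout_rate: float = 0.0,
                      rng: np.random.Generator | None = None) -> Tensor:
    """One hidden ReLU layer (dropout in training) -> linear -> softmax;
    rows of the returned matrix sum to 1."""
    if params.W2.data.shape[1] < 2:
        raise MotcsError("mlp_view_classify needs >= 2 classes")
    h = (as_tensor(Z) @ params.W1 + params.b1).relu()
    h = dropout(h, dropout_rate, rng, training)
    return softmax(h @ params.W2 + params.b2, axis=-1)


def view_cross_entropy(probs, labels, eps: float = 1e-8) -> Tensor:
    """-(1/n) sum_j sum_k y_{j,k} log(p_{j,k} + eps), y one-hot.

    With one-hot y this equals -(1/n) sum_j log(p_{j, y_j} + eps); gathering
    the true-class probability first keeps eps=0 well defined when some
    off-target probability is exactly zero.
    """
    probs = as_tensor(probs)
    labels = np.asarray(labels, dtype=np.int64)
    n, c = probs.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    p_true = (probs * as_tensor(onehot)).sum(axis=1)
    return -((p_true + eps).log()).sum() * (1.0 / n)


def build_cross_omics_tensor(rows: list[np.ndarray],
                             tol: float = 1e-6) -> tuple[np.ndarray,
                                                         np.ndarray]:
    """One sample's cross-omics probability tensor and its vectorisation.

    rows: one length-c probability row per view (normally 3).  Entry
    (c1, .., cV) is the product of the per-view probabilities; the
    vectorisation is row-major (first view's index slowest).  Rows must sum
    to 1 within ``tol``.
    """
    rows = [np.asarray(r, dtype=np.float64) for r in rows]
    if len(rows) < 2:
        raise MotcsError("cross-omics tensor needs >= 2 views")
    c = rows[0].shape[0]
    for r in rows:
        if r.shape != (c,):
            raise MotcsError("cross-omics tensor rows must share length c")
        if abs(r.sum() - 1.0) > tol:
            raise MotcsError(f"probability row sums to {r.sum():.8f}, not 1")
    t = rows[0]
    for r in rows[1:]:
        t = np.multiply.outer(t, r)
    return t, t.reshape(-1)


def cross_omics_vectorized(view_probs: list[Tensor]) -> Tensor:
    """Batched differentiable tensor product: (n, c) per view ->
    (n, c^V) row-major vectorisations."""
    n, c = view_probs[0].shape
    V = len(view_probs)
    out = None
    for m, p in enumerate(view_probs):
        shape = [n] + [1] * V
        shape[1 + m] = c
        p = as_tensor(p).reshape(*shape)
        out = p if out is None else out * p
    return out.reshape(n, c**V)


@dataclass
class VCDNParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


def init_vcdn(num_classes: int, num_views: int,
              rng: np.random.Generator) -> VCDNParams:
    d = num_classes**num_views
    return VCDNParams(_glorot(rng, d, d, (d, d)), Tensor(np.zeros(d)),
                      _glorot(rng, d, num_classes, (d, num_classes)),
                      Tensor(np.zeros(num_classes)))


def vcdn_classify(vec, params: VCDNParams, training: bool = False) -> Tensor:
    """Fully connected fusion head: hidden width c^V, leaky-ReLU, softmax."""
    h = (as_tensor(vec) @ params.W1 + params.b1).leaky_relu(0.01)
    return softmax(h @ params.W2 + params.b2, axis=-1)


def vcdn_loss(final_probs, labels, eps: float = 1e-8) -> Tensor:
    """Mean cross-entropy of the fused output (same kernel as the view
    loss)."""
    return view_cross_entropy(final_probs, labels, eps)


def total_loss(view_losses: list[Tensor], l_vcdn: Tensor | None) -> Tensor:
    """L = sum_m L_MLP,m + L_VCDN; with one view the VCDN term is absent."""
    if not view_losses:
        raise MotcsError("total_loss needs at least one view loss")
    out = view_losses[0]
    for vl in view_losses[1:]:
        out = out + vl
    if l_vcdn is not None:
        out = out + l_vcdn
    return out


# ---------------------------------------------------------------- full model

@dataclass
class MOTCSConfig:
    """Architecture configuration for the full model."""

    views: list[str]
    num_classes: int
    encoder_driver: EncoderConfig = field(default_factory=EncoderConfig)
    encoder_nondriver: EncoderConfig = field(default_factory=EncoderConfig)
    mlp_hidden: int = 64
    epsilon: float = 1e-8
    driver_branch_enabled: bool = True

    def __post_init__(self):
        if not (1 <= len(self.views) <= 3):
            raise MotcsError("MOTCS supports 1 to 3 views")
        if self.num_classes < 2:
            raise MotcsError("need >= 2 classes")


@dataclass
class ViewBranches:
    driver: EncoderParams | None
    nondriver: EncoderParams | None
    mlp: MLPParams


class MOTCSModel:
    """Parameter bundle + forward pass for the full network.

    ``feature_sets`` fixes, per view, which matrix columns feed the driver
    and non-driver branches; inputs to :meth:`forward` are dicts
    view -> (n, len(all_features)) arrays in that column order.
    """

    def __init__(self, config: MOTCSConfig,
                 feature_sets: dict[str, ViewFeatureSet],
                 rng: np.random.Generator):
        self.config = config
        self.feature_sets = {v: feature_sets[v] for v in config.views}
        self.branches: dict[str, ViewBranches] = {}
        c = config.num_classes
        for view in config.views:
            fs = self.feature_sets[view]
            n_dg = len(fs.driver_features)
            n_svc = len(fs.selected_nondriver_features)
            use_driver = config.driver_branch_enabled and n_dg > 0
            d_in = 0
            driver = nondriver = None
            if use_driver:
                driver = init_encoder_params(n_dg, config.encoder_driver, rng)
                d_in += config.encoder_driver.embed_dim
            if n_svc > 0:
                nondriver = init_encoder_params(n_svc,
                                                config.encoder_nondriver, rng)
                d_in += config.encoder_nondriver.embed_dim
            if d_in == 0:
                raise MotcsError(f"view {view}: both branches empty")
            self.branches[view] = ViewBranches(
                driver, nondriver, init_mlp(d_in, config.mlp_hidden, c, rng))
        self.vcdn = (init_vcdn(c, len(config.views), rng)
                     if len(config.views) >= 2 else None)

    # ------------------------------------------------------------------ infra
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for view in self.config.views:
            br = self.branches[view]
            if br.driver is not None:
                out.extend(br.driver.parameters())
            if br.nondriver is not None:
                out.extend(br.nondriver.parameters())
            out.extend(br.mlp.parameters())
        if self.vcdn is not None:
            out.extend(self.vcdn.parameters())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def set_state_arrays(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays):
            p.data = a.copy()

    def _split_view(self, view: str, X: np.ndarray) -> tuple:
        fs = self.feature_sets[view]
        n_dg = len(fs.driver_features)
        if X.shape[1] != len(fs.all_features):
            raise MotcsError(
                f"view {view}: got {X.shape[1]} columns, expected "
                f"{len(fs.all_features)}")
        return X[:, :n_dg], X[:, n_dg:]

    # ---------------------------------------------------------------- forward
    def forward(self, views_X: dict[str, np.ndarray], training: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[dict[str, Tensor], Tensor | None]:
        """Returns (per-view probability tensors, fused probabilities or
        None in single-view mode)."""
        cfg = self.config
        view_probs: dict[str, Tensor] = {}
        for view in cfg.views:
            br = self.branches[view]
            X_dg, X_svc = self._split_view(view, np.asarray(views_X[view]))
            Z_dg = Z_svc = None
            if br.driver is not None:
                Z_dg = encode(X_dg, br.driver, cfg.encoder_driver,
                              training, rng)
            if br.nondriver is not None:
                Z_svc = encode(X_svc, br.nondriver, cfg.encoder_nondriver,
                               training, rng)
            Z = concat_view_embeddings(Z_dg, Z_svc)
            view_probs[view] = mlp_view_classify(
                Z, br.mlp, training, cfg.encoder_nondriver.dropout_rate, rng)
        final = None
        if self.vcdn is not None:
            vec = cross_omics_vectorized(
                [view_probs[v] for v in cfg.views])
            final = vcdn_classify(vec, self.vcdn, training)
        return view_probs, final

    def loss(self, views_X: dict[str, np.ndarray], labels: np.ndarray,
             training: bool = False,
             rng: np.random.Generator | None = None) -> Tensor:
        view_probs, final = self.forward(views_X, training, rng)
        eps = self.config.epsilon
        view_losses = [view_cross_entropy(view_probs[v], labels, eps)
                       for v in self.config.views]
        l_vcdn = vcdn_loss(final, labels, eps) if final is not None else None
        return total_loss(view_losses, l_vcdn)

    def predict_final(self, views_X: dict[str, np.ndarray]
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode prediction: (class indices, probabilities).  Multi-view
        uses the VCDN output, single-view the view head; argmax ties break
        toward the lowest class index."""
        view_probs, final = self.forward(views_X, training=False)
        probs = (final if final is not None
                 else view_probs[self.config.views[0]]).data
        return np.argmax(probs, axis=1), probs
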