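"""Cross-validated training harness.

Protocol: stratified 5-fold CV; inside each fold, non-driver feature
selection (L1-SVC) is fitted on the training samples only, features are
standardised with training-fold statistics, and the network is optimised
with Adam on mini-batches of the joint loss.  Early stopping monitors the
total loss on a stratified 10% holdout of the training fold and restores
the best-epoch weights.  Metrics are accuracy, weighted F1 and macro F1 —
the weighted variant reflects performance under subtype imbalance, the
macro variant exposes minority-class failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .autograd import Adam
from .io import DriverCatalog, MotcsError, OmicsMatrix, SubtypeLabelSet
from .model import MOTCSConfig, MOTCSModel
from .preprocess import ViewFeatureSet, partition_features, select_l1svc

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimisation settings (defaults follow the published protocol)."""

    learning_rate: float = 1e-5
    batch_size: int = 128
    max_epochs: int = 100
    early_stop_patience: int = 50
    seed: int = 42
    val_fraction: float = 0.1
    svc_C: float = 0.1

    def __post_init__(self):
        if self.early_stop_patience > self.max_epochs:
            raise MotcsError("patience must be <= max_epochs")
        for name in ("batch_size", "max_epochs", "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise MotcsError(f"{name} must be positive")
        if self.learning_rate < 0:  # 0 is the legal null update
            raise MotcsError("learning_rate must be >= 0")


@dataclass
class FoldSplit:
    fold: int
    train_ids: list[str]
    test_ids: list[str]


@dataclass
class MetricsReport:
    """Per-fold and aggregate ACC / F1_weighted / F1_macro."""

    per_fold: list[dict]

    def _col(self, key: str) -> np.ndarray:
        return np.array([f[key] for f in self.per_fold])

    def mean(self, key: str) -> float:
        return float(self._col(key).mean())

    def sd(self, key: str) -> float:
        return float(self._col(key).std(ddof=1)) if len(self.per_fold) > 1 \
            else 0.0

    def summary(self) -> dict:
        return {k: {"mean": self.mean(k), "sd": self.sd(k)}
                for k in ("acc", "f1_weighted", "f1_macro")}


def make_cv_splits(labels: SubtypeLabelSet, n_folds: int = 5,
                   seed: int = 42) -> list[FoldSplit]:
    """Stratified k-fold partition of the samples, deterministic in seed."""
    counts = np.bincount(labels.labels, minlength=labels.n_classes)
    for name, cnt in zip(labels.class_names, counts):
        if cnt < n_folds:
            raise MotcsError(
                f"class {name!r} has {cnt} samples, fewer than "
                f"{n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    ids = np.array(labels.sample_ids)
    return [FoldSplit(i, list(ids[tr]), list(ids[te]))
            for i, (tr, te) in enumerate(skf.split(ids, labels.labels))]


def evaluate_metrics(y_true, y_pred) -> dict:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise MotcsError("label vectors must have equal length")
    return {
        "acc": float(accuracy_score(y_true, y_pred)),
        "f1_weighted": float(f1_score(y_true, y_pred, average="weighted",
                                      zero_division=0)),
        "f1_macro": float(f1_score(y_true, y_pred, average="macro",
                                   zero_division=0)),
    }


# ------------------------------------------------------------------ training

def train_motcs(model: MOTCSModel, views_X: dict[str, np.ndarray],
                y: np.ndarray, cfg: TrainConfig) -> dict:
    """Mini-batch Adam on the joint loss with early stopping.

    ``views_X`` holds standardised training matrices in the model's feature
    order.  Returns a history dict with per-epoch train/validation losses
    and the restored best epoch.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    idx = np.arange(n)
    if cfg.val_fraction > 0 and np.min(np.bincount(y)) >= 2:
        tr_idx, val_idx = train_test_split(
            idx, test_size=cfg.val_fraction, stratify=y,
            random_state=cfg.seed)
        use_holdout = True
    else:  # no holdout: monitor the epoch-mean training loss instead
        tr_idx, val_idx = idx, idx
        use_holdout = False
    Xtr = {v: X[tr_idx] for v, X in views_X.items()}
    Xval = {v: X[val_idx] for v, X in views_X.items()}
    ytr, yval = y[tr_idx], y[val_idx]

    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = [p.copy() for p in model.state_arrays()]
    best_epoch = -1
    wait = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ytr))
        ep_losses = []
        for start in range(0, len(ytr), cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            loss = model.loss({v: X[b] for v, X in Xtr.items()}, ytr[b],
                              training=True, rng=rng)
            if not np.isfinite(loss.data):
                raise MotcsError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(float(loss.data))
        if use_holdout:
            val_loss = float(model.loss(Xval, yval, training=False).data)
        else:
            val_loss = float(np.mean(ep_losses))
        history["train_loss"].append(float(np.mean(ep_losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = [p.copy() for p in model.state_arrays()]
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.early_stop_patience:
                break
    model.set_state_arrays(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return history


@dataclass
class FittedFold:
    """Everything needed to score and ablate one CV fold."""

    split: FoldSplit
    model: MOTCSModel
    feature_sets: dict[str, ViewFeatureSet]
    scaler_mean: dict[str, np.ndarray]
    scaler_std: dict[str, np.ndarray]
    history: dict
    metrics: dict


@dataclass
class CVResult:
    report: MetricsReport
    folds: list[FittedFold]


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return mean, std


def prepare_fold_inputs(views: list[OmicsMatrix], labels: SubtypeLabelSet,
                        catalog: DriverCatalog, split: FoldSplit,
                        cfg: TrainConfig, driver_branch: bool = True
                        ) -> tuple[dict, dict, dict, dict, dict]:
    """Within-fold feature selection and standardisation.

    Selection sees only the training samples (structural leakage guard);
    scalers are fitted on the training fold and applied to both partitions.
    Returns (feature_sets, Xtr, Xte, means, stds) keyed by view name.
    """
    feature_sets: dict[str, ViewFeatureSet] = {}
    Xtr: dict[str, np.ndarray] = {}
    Xte: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    stds: dict[str, np.ndarray] = {}
    for view in views:
        driver_ids, nondriver_ids = partition_features(view, catalog)
        if not driver_branch:
            driver_ids = []
        train_view = view.subset_samples(split.train_ids)
        selected: list[str] = []
        if nondriver_ids:
            nd_train = train_view.subset_features(nondriver_ids)
            selected = select_l1svc(nd_train, labels, C=cfg.svc_C,
                                    seed=cfg.seed)
        fs = ViewFeatureSet(view.view_name, driver_ids, selected,
                            selection_C=cfg.svc_C)
        feature_sets[view.view_name] = fs
        tr = train_view.subset_features(fs.all_features).values
        te = view.subset_samples(split.test_ids) \
                 .subset_features(fs.all_features).values
        mean, std = _standardize_fit(tr)
        Xtr[view.view_name] = (tr - mean) / std
        Xte[view.view_name] = (te - mean) / std
        means[view.view_name] = mean
        stds[view.view_name] = std
    return feature_sets, Xtr, Xte, means, stds


def run_cv(views: list[OmicsMatrix], labels: SubtypeLabelSet,
           catalog: DriverCatalog, model_cfg: MOTCSConfig,
           train_cfg: TrainConfig, n_folds: int = 5) -> CVResult:
    """Full stratified-CV protocol; returns per-fold metrics and fitted
    models (the latter feed the ablation importance analysis)."""
    view_by_name = {v.view_name: v for v in views}
    use_views = [view_by_name[name] for name in model_cfg.views]
    splits = make_cv_splits(labels, n_folds, train_cfg.seed)
    folds: list[FittedFold] = []
    for split in splits:
        feature_sets, Xtr, Xte, means, stds = prepare_fold_inputs(
            use_views, labels, catalog, split, train_cfg,
            model_cfg.driver_branch_enabled)
        rng = np.random.default_rng(train_cfg.seed + split.fold)
        model = MOTCSModel(model_cfg, feature_sets, rng)
        ytr = labels.subset(split.train_ids).labels
        yte = labels.subset(split.test_ids).labels
        fold_cfg = replace(train_cfg, seed=train_cfg.seed + split.fold)
        history = train_motcs(model, Xtr, ytr, fold_cfg)
        y_pred, _ = model.predict_final(Xte)
        metrics = evaluate_metrics(yte, y_pred)
        log.info("fold %d: acc=%.3f f1w=%.3f f1m=%.3f (best epoch %d)",
                 split.fold, metrics["acc"], metrics["f1_weighted"],
                 metrics["f1_macro"], history["best_epoch"])
        folds.append(FittedFold(split, model, feature_sets, means, stds,
                                history, metrics))
    return CVResult(MetricsReport([f.metrics for f in folds]), folds)


def run_variant(variant: str, views: list[OmicsMatrix],
                labels: SubtypeLabelSet, catalog: DriverCatalog,
                model_cfg: MOTCSConfig, train_cfg: TrainConfig,
                n_folds: int = 5) -> CVResult:
    """Model variants sharing one CV protocol (folds align for pairing).

    ``full``: all configured views, driver branch on.
    ``no_driver``: all views, driver branch off (the L1-SVC-only ablation).
    ``single_view:<name>``: one view, no cross-omics fusion.
    """
    cfg = model_cfg
    if variant == "full":
        pass
    elif variant == "no_driver":
        cfg = replace(model_cfg, driver_branch_enabled=False)
    elif variant.startswith("single_view:"):
        view = variant.split(":", 1)[1]
        if view not in [v.view_name for v in views]:
            raise MotcsError(f"unknown view {view!r}")
        cfg = replace(model_cfg, views=[view])
        views = [v for v in views if v.view_name == view]
    else:
        raise MotcsError(f"unknown variant {variant!r}")
    return run_cv(views, labels, catalog, cfg, train_cfg, n_folds)


def paired_significance(metric_a, metric_b,
                        alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided paired t-test on per-fold metric differences.

    Degenerate cases: all differences zero -> p = 1; zero variance with a
    nonzero mean -> p = 0 (certain difference).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise MotcsError("need equal-length per-fold vectors of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        p = 1.0 if np.allclose(d.mean(), 0.0) else 0.0
        return p, p < alpha
    t, p = stats.ttest_rel(a, b)
    return float(p), bool(p < alpha)


# -------------------------------------------------------------- persistence

def save_cv_result(cv: CVResult, model_cfg: MOTCSConfig, out_dir) -> None:
    """Write one checkpoint per fold (weights as .npz, config/feature
    lists/split/scalers as JSON-compatible sidecars) plus the metrics table."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "model_config": {
            "views": model_cfg.views,
            "num_classes": model_cfg.num_classes,
            "encoder_driver": asdict(model_cfg.encoder_driver),
            "encoder_nondriver": asdict(model_cfg.encoder_nondriver),
            "mlp_hidden": model_cfg.mlp_hidden,
            "epsilon": model_cfg.epsilon,
            "driver_branch_enabled": model_cfg.driver_branch_enabled,
        },
        "folds": [],
    }
    for fold in cv.folds:
        arrays = {f"param_{i}": a for i, a in
                  enumerate(fold.model.state_arrays())}
        for view, m in fold.scaler_mean.items():
            arrays[f"mean_{view}"] = m
            arrays[f"std_{view}"] = fold.scaler_std[view]
        np.savez(out / f"fold{fold.split.fold}.npz", **arrays)
        meta["folds"].append({
            "fold": fold.split.fold,
            "train_ids": fold.split.train_ids,
            "test_ids": fold.split.test_ids,
            "feature_sets": {
                v: {"driver_features": fs.driver_features,
                    "selected_nondriver_features":
                        fs.selected_nondriver_features,
                    "selection_C": fs.selection_C}
                for v, fs in fold.feature_sets.items()},
            "metrics": fold.metrics,
            "history": fold.history,
        })
    with open(out / "cv_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    pd.DataFrame([f.metrics for f in cv.folds]).to_csv(
        out / "metrics_per_fold.tsv", sep="\t", index_label="fold")


def load_cv_result(out_dir) -> tuple[CVResult, MOTCSConfig]:
    """Rebuild a :class:`CVResult` (models, scalers, splits) from
    :func:`save_cv_result` output; prediction-ready, histories included."""
    import json
    from pathlib import Path

    from .encoder import EncoderConfig

    out = Path(out_dir)
    with open(out / "cv_meta.json") as fh:
        meta = json.load(fh)
    mc = meta["model_config"]
    model_cfg = MOTCSConfig(
        views=mc["views"], num_classes=mc["num_classes"],
        encoder_driver=EncoderConfig(**mc["encoder_driver"]),
        encoder_nondriver=EncoderConfig(**mc["encoder_nondriver"]),
        mlp_hidden=mc["mlp_hidden"], epsilon=mc["epsilon"],
        driver_branch_enabled=mc["driver_branch_enabled"])
    folds = []
    for fm in meta["folds"]:
        data = np.load(out / f"fold{fm['fold']}.npz")
        feature_sets = {
            v: ViewFeatureSet(v, d["driver_features"],
                              d["selected_nondriver_features"],
                              d["selection_C"])
            for v, d in fm["feature_sets"].items()}
        model = MOTCSModel(model_cfg, feature_sets,
                           np.random.default_rng(0))
        n_params = len(model.parameters())
        model.set_state_arrays([data[f"param_{i}"]
                                for i in range(n_params)])
        folds.append(FittedFold(
            FoldSplit(fm["fold"], fm["train_ids"], fm["test_ids"]),
            model, feature_sets,
            {v: data[f"mean_{v}"] for v in feature_sets},
            {v: data[f"std_{v}"] for v in feature_sets},
            fm["history"], fm["metrics"]))
    return CVResult(MetricsReport([f.metrics for f in folds]), folds), \
        model_cfg
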