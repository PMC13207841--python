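"""Zero-ablation biomarker ranking.

A trained model's sensitivity to each input feature is measured by setting
that feature's (standardised) column to zero on the held-out fold,
re-scoring, and recording the F1 drop.  Drops are summed over the five CV
folds' models; within each view, features are sorted by summed drop
(descending, ties broken by feature id) and the top k exported as
candidate biomarkers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import MotcsError, OmicsMatrix, SubtypeLabelSet
from .train import CVResult, evaluate_metrics

log = logging.getLogger(__name__)


def ablate_feature(X: np.ndarray, feature_ids: list[str],
                   feature_id: str) -> np.ndarray:
    """Return a copy of X with ``feature_id``'s column zeroed; the original
    array is untouched."""
    if feature_id not in feature_ids:
        raise MotcsError(f"unknown feature {feature_id!r}")
    out = np.array(X, copy=True)
    out[:, feature_ids.index(feature_id)] = 0.0
    return out


def _fold_test_inputs(fold, views: list[OmicsMatrix]) -> dict[str, np.ndarray]:
    by_name = {v.view_name: v for v in views}
    out = {}
    for view_name, fs in fold.feature_sets.items():
        te = by_name[view_name].subset_samples(fold.split.test_ids) \
                               .subset_features(fs.all_features).values
        out[view_name] = (te - fold.scaler_mean[view_name]) \
            / fold.scaler_std[view_name]
    return out


def importance_scores(cv: CVResult, views: list[OmicsMatrix],
                      labels: SubtypeLabelSet,
                      metric: str = "f1_weighted") -> pd.DataFrame:
    """Per-feature summed F1 drop across the CV folds' models.

    Columns: view, feature, branch, delta_f1_fold<i> per fold, sum_delta_f1,
    rank (1 = most important within its view).  A feature absent from a
    fold's input set contributes 0 for that fold.
    """
    n_folds = len(cv.folds)
    union: dict[tuple[str, str], str] = {}  # (view, feature) -> branch
    for fold in cv.folds:
        for view_name, fs in fold.feature_sets.items():
            for f in fs.driver_features:
                union[(view_name, f)] = "driver"
            for f in fs.selected_nondriver_features:
                union.setdefault((view_name, f), "nondriver")
    deltas = {key: np.zeros(n_folds) for key in union}
    for i, fold in enumerate(cv.folds):
        Xte = _fold_test_inputs(fold, views)
        yte = labels.subset(fold.split.test_ids).labels
        y_pred, _ = fold.model.predict_final(Xte)
        baseline = evaluate_metrics(yte, y_pred)[metric]
        for view_name, fs in fold.feature_sets.items():
            feats = fs.all_features
            for f in feats:
                perturbed = dict(Xte)
                perturbed[view_name] = ablate_feature(Xte[view_name],
                                                      feats, f)
                y_abl, _ = fold.model.predict_final(perturbed)
                deltas[(view_name, f)][i] = \
                    baseline - evaluate_metrics(yte, y_abl)[metric]
    rows = []
    for (view_name, f), d in deltas.items():
        row = {"view": view_name, "feature": f, "branch": union[(view_name, f)]}
        for i in range(n_folds):
            row[f"delta_f1_fold{i}"] = d[i]
        row["sum_delta_f1"] = float(d.sum())
        rows.append(row)
    df = pd.DataFrame(rows)
    # deterministic ranking: descending summed drop, ties by feature id
    df = df.sort_values(["view", "sum_delta_f1", "feature"],
                        ascending=[True, False, True], kind="stable")
    df["rank"] = df.groupby("view").cumcount() + 1
    return df.reset_index(drop=True)


def top_k_biomarkers(table: pd.DataFrame, k: int = 30) -> dict[str, list[str]]:
    """First k features by within-view rank; short views return all."""
    if k < 0:
        raise MotcsError("k must be >= 0")
    out = {}
    for view_name, grp in table.groupby("view", sort=True):
        out[view_name] = list(grp.sort_values("rank")["feature"].head(k))
    return out
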