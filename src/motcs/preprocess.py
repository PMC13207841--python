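"""Preprocessing chain for each omics view.

Order of operations mirrors the standard pipeline for TCGA-style data:

1. expression views: drop features that are zero in more than 25% of samples;
2. methylation: drop probes missing in more than 25% of samples (beta values
   are rarely exactly zero, so missingness is the operative notion), drop
   blacklisted and X/Y-chromosome probes, KNN-impute the rest, then average
   probes within 1500 bp upstream of a gene's TSS into one gene-level value;
3. split every view's features into driver and non-driver sets against the
   curated catalogs — driver features are kept wholesale;
4. reduce the non-driver set with an L1-penalised linear SVC (C = 0.1),
   fitted on training samples only, keeping features with any nonzero
   coefficient;
5. report cross-fold selection stability as mean pairwise overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .io import DriverCatalog, MotcsError, OmicsMatrix, ProbeAnnotation, \
    SubtypeLabelSet

log = logging.getLogger(__name__)


@dataclass
class ViewFeatureSet:
    """Driver / selected-non-driver feature partition for one view."""

    view_name: str
    driver_features: list[str]
    selected_nondriver_features: list[str]
    selection_C: float = 0.1

    def __post_init__(self):
        overlap = set(self.driver_features) & set(
            self.selected_nondriver_features)
        if overlap:
            raise MotcsError(
                f"driver and selected non-driver sets overlap: {sorted(overlap)}")

    @property
    def all_features(self) -> list[str]:
        return list(self.driver_features) + list(
            self.selected_nondriver_features)


@dataclass
class StabilityReport:
    """Cross-fold feature-selection stability."""

    per_fold_sets: list[set]
    pairwise_overlaps: dict = field(default_factory=dict)
    mean_overlap: float = float("nan")


def filter_zero_fraction(m: OmicsMatrix,
                         max_zero_fraction: float = 0.25) -> OmicsMatrix:
    """Keep features whose fraction of zero entries is <= the threshold."""
    frac = (m.values == 0).mean(axis=0)
    keep = [f for f, fr in zip(m.feature_ids, frac) if fr <= max_zero_fraction]
    if not keep:
        raise MotcsError(f"{m.view_name}: zero-fraction filter removed "
                         "every feature")
    return m.subset_features(keep)


def filter_missing_fraction(m: OmicsMatrix,
                            max_missing_fraction: float = 0.25) -> OmicsMatrix:
    """Missingness analogue of the zero filter, used for probe-level
    methylation before imputation."""
    frac = np.isnan(m.values).mean(axis=0)
    keep = [f for f, fr in zip(m.feature_ids, frac)
            if fr <= max_missing_fraction]
    if not keep:
        raise MotcsError(f"{m.view_name}: missing-fraction filter removed "
                         "every feature")
    return m.subset_features(keep)


def filter_probes(beta: OmicsMatrix, ann: ProbeAnnotation) -> OmicsMatrix:
    """Drop blacklisted probes and probes on the X/Y chromosomes; probes
    absent from the annotation are dropped with a logged count."""
    t = ann.table.set_index("probe_id")
    keep, unannotated = [], 0
    for p in beta.feature_ids:
        if p not in t.index:
            unannotated += 1
            continue
        row = t.loc[p]
        chrom = str(row["chrom"]).removeprefix("chr")
        if bool(row["flagged"]) or chrom in ("X", "Y"):
            continue
        keep.append(p)
    if unannotated:
        log.warning("filter_probes: dropped %d probes absent from the "
                    "annotation", unannotated)
    if not keep:
        raise MotcsError("probe filtering removed every probe")
    return beta.subset_features(keep)


def impute_knn(beta: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """KNN imputation with features as neighbours.

    Follows the convention of the classic microarray imputation routine
    (matrix oriented genes x samples): for a missing entry (sample s,
    feature f), find the k features nearest to f by Euclidean distance over
    the samples where both are observed (scaled to the per-sample mean so
    different overlaps compare fairly), restricted to features observed at
    s, and fill with the unweighted mean of their values at s.
    """
    if k < 1:
        raise MotcsError("impute_knn: k must be >= 1")
    V = beta.values.copy()
    miss = np.isnan(V)
    if not miss.any():
        return beta
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = [f for f, b in zip(beta.feature_ids, all_missing) if b]
        raise MotcsError(f"feature(s) missing in every sample: {bad}")
    obs = ~miss
    filled = V.copy()
    V0 = np.where(obs, V, 0.0)
    for f in np.flatnonzero(miss.any(axis=0)):
        # mean squared difference over shared observed samples, vectorised
        # across all candidate features at once
        shared = obs & obs[:, [f]]
        diff = np.where(shared, V0 - V0[:, [f]], 0.0)
        counts = shared.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dists = np.sqrt((diff * diff).sum(axis=0) / counts)
        dists[counts == 0] = np.inf
        dists[f] = np.inf
        order = np.argsort(dists, kind="stable")
        for s in np.flatnonzero(miss[:, f]):
            donors = [g for g in order
                      if np.isfinite(dists[g]) and obs[s, g]][:k]
            if not donors:
                raise MotcsError(
                    f"impute_knn: no donor feature observed at sample "
                    f"{beta.sample_ids[s]!r} for feature "
                    f"{beta.feature_ids[f]!r}")
            filled[s, f] = np.mean([V[s, g] for g in donors])
    return OmicsMatrix(beta.view_name, list(beta.sample_ids),
                       list(beta.feature_ids), filled)


def aggregate_methylation(beta: OmicsMatrix, ann: ProbeAnnotation,
                          window_bp: int = 1500) -> OmicsMatrix:
    """Average probe betas within ``window_bp`` upstream of each gene's TSS.

    A probe qualifies when 0 < dist_tss <= window_bp (positive distances are
    upstream, already strand-resolved in the annotation).  Genes with no
    qualifying probe are absent from the output.
    """
    if beta.has_missing():
        raise MotcsError("aggregate_methylation requires an imputed matrix")
    t = ann.table
    in_window = t[(t["dist_tss"] > 0) & (t["dist_tss"] <= window_bp)]
    probe_pos = {p: i for i, p in enumerate(beta.feature_ids)}
    genes: list[str] = []
    cols: list[np.ndarray] = []
    for gene, grp in in_window.groupby("gene", sort=True):
        idx = [probe_pos[p] for p in grp["probe_id"] if p in probe_pos]
        if not idx:
            continue
        genes.append(str(gene))
        cols.append(beta.values[:, idx].mean(axis=1))
    if not genes:
        raise MotcsError("TSS-window aggregation produced no genes")
    return OmicsMatrix(beta.view_name, list(beta.sample_ids), genes,
                       np.column_stack(cols))


def partition_features(m: OmicsMatrix,
                       catalog: DriverCatalog) -> tuple[list[str], list[str]]:
    """Split the matrix's features into (driver, non-driver) lists by the
    catalog namespace matching the view; order follows the matrix."""
    drivers = catalog.for_view(m.view_name)
    driver_ids = [f for f in m.feature_ids if f in drivers]
    nondriver_ids = [f for f in m.feature_ids if f not in drivers]
    return driver_ids, nondriver_ids


def select_l1svc(m: OmicsMatrix, labels: SubtypeLabelSet, C: float = 0.1,
                 seed: int = 0, fallback_k: int = 50) -> list[str]:
    """Embedded feature selection with an L1-penalised linear SVC.

    Squared-hinge loss, one-vs-rest for multiclass; features standardised
    before the fit.  Returns features with a nonzero coefficient in at least
    one class weight vector, in original column order.  If the penalty zeros
    everything, falls back to the top ``fallback_k`` by absolute coefficient
    with a logged warning.
    """
    y = labels.subset(m.sample_ids).labels
    if len(np.unique(y)) < 2:
        raise MotcsError("select_l1svc needs >= 2 classes in the training set")
    X = StandardScaler().fit_transform(m.values)
    clf = LinearSVC(penalty="l1", loss="squared_hinge", dual=False, C=C,
                    max_iter=5000, random_state=seed)
    clf.fit(X, y)
    coef = np.atleast_2d(clf.coef_)
    score = np.abs(coef).max(axis=0)
    mask = score > 1e-10
    if not mask.any():
        log.warning("select_l1svc: L1 penalty zeroed every coefficient; "
                    "falling back to top %d by |coef|", fallback_k)
        top = np.argsort(-score, kind="stable")[:fallback_k]
        mask = np.zeros_like(mask)
        mask[top] = True
    return [f for f, keep in zip(m.feature_ids, mask) if keep]


def selection_stability(per_fold_sets: list[set]) -> StabilityReport:
    """Pairwise overlap |A∩B| / min(|A|,|B|) across fold selections; an empty
    fold set contributes overlap 0 to its pairs."""
    sets = [set(s) for s in per_fold_sets]
    if len(sets) < 2:
        raise MotcsError("selection_stability needs >= 2 folds")
    overlaps = {}
    for i, j in combinations(range(len(sets)), 2):
        a, b = sets[i], sets[j]
        denom = min(len(a), len(b))
        overlaps[(i, j)] = len(a & b) / denom if denom else 0.0
    return StabilityReport(sets, overlaps,
                           float(np.mean(list(overlaps.values()))))


def preprocess_expression(m: OmicsMatrix,
                          max_zero_fraction: float = 0.25) -> OmicsMatrix:
    """Full expression-view chain (currently just the zero filter)."""
    return filter_zero_fraction(m, max_zero_fraction)


def preprocess_methylation(beta: OmicsMatrix, ann: ProbeAnnotation,
                           max_missing_fraction: float = 0.25,
                           knn_k: int = 10,
                           window_bp: int = 1500) -> OmicsMatrix:
    """Full probe-level methylation chain: missingness filter, probe
    blacklist/XY filter, KNN imputation, TSS-window gene aggregation."""
    beta = filter_missing_fraction(beta, max_missing_fraction)
    beta = filter_probes(beta, ann)
    beta = impute_knn(beta, knn_k)
    return aggregate_methylation(beta, ann, window_bp)
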