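"""Frozen synthetic benchmark studies.

These are the package's desk-scale reference experiments: each function
regenerates its data from a seed, runs the full pipeline, and returns the
measured quantity.  The problem sizes and optimisation settings here are
deliberately small — hundreds of samples, tens-to-hundreds of features per
view, compact encoders — chosen so the studies are reproducible on a
single CPU in minutes; with ~10^2 training samples the TCGA-scale
optimisation settings would take vastly more epochs than signal-recovery
needs, so these runs use a larger learning rate and fewer epochs, and
monitor the training loss rather than holding out a validation split
(at this n a stratified holdout is too small to rank epochs reliably).

Studies
-------
recovery
    Full 5-fold CV on the generator's default regime (n=300, 3 imbalanced
    subtypes, 500 features/view of which 50 informative, latent effect
    size 2): the classifier should recover the planted structure almost
    perfectly.
driver_ablation
    Data whose planted signal lives only in driver-flagged features;
    compares the full model against the L1-SVC-only variant on matched
    folds (replicated over seeds for a sign test).
dominant_biomarker
    Data with one dominant marker (the only feature separating two
    otherwise-identical subtypes); checks zero-ablation ranks it first in
    its view.
selection_sparsity
    |selected(C=0.1)| vs |selected(C=1.0)| for the L1-SVC step on small
    labelled expression-like matrices.
"""

from __future__ import annotations

import numpy as np

from .encoder import EncoderConfig
from .io import OmicsMatrix, SubtypeLabelSet
from .model import MOTCSConfig
from .importance import importance_scores
from .preprocess import select_l1svc
from .synthetic import SyntheticSpec, preprocess_bundle, simulate_multiomics
from .train import CVResult, TrainConfig, run_variant

THREE_VIEWS = ["mRNA", "miRNA", "methylation"]

#: encoder/optimiser for the default-regime recovery study
RECOVERY_ENCODER = EncoderConfig(embed_dim=32, num_heads=4, num_layers=1,
                                 dropout_rate=0.1)
RECOVERY_TRAIN = TrainConfig(learning_rate=2e-3, batch_size=128,
                             max_epochs=30, early_stop_patience=30,
                             val_fraction=0.0)

#: compact encoder/optimiser for the replicated small-n studies (n=150)
SMALL_ENCODER = EncoderConfig(embed_dim=16, num_heads=2, num_layers=1,
                              dropout_rate=0.1)
SMALL_TRAIN = TrainConfig(learning_rate=1e-2, batch_size=128,
                          max_epochs=40, early_stop_patience=40,
                          val_fraction=0.0)

#: small-n generator settings shared by the replicated studies
SMALL_N = 150
SMALL_FEATURES = 60
SMALL_INFORMATIVE = 15


def _model_config(encoder: EncoderConfig, num_classes: int,
                  mlp_hidden: int) -> MOTCSConfig:
    return MOTCSConfig(views=list(THREE_VIEWS), num_classes=num_classes,
                       encoder_driver=encoder, encoder_nondriver=encoder,
                       mlp_hidden=mlp_hidden)


def recovery_benchmark(seed: int = 42) -> CVResult:
    """Default-regime 5-fold CV; returns the fitted CV result (the report
    carries mean/sd ACC, F1_weighted, F1_macro)."""
    bundle = simulate_multiomics(SyntheticSpec(seed=seed))
    views = preprocess_bundle(bundle)
    cfg = _model_config(RECOVERY_ENCODER, len(bundle.labels.class_names), 64)
    tc = TrainConfig(**{**RECOVERY_TRAIN.__dict__, "seed": seed})
    return run_variant("full", views, bundle.labels, bundle.catalog,
                       cfg, tc)


def driver_ablation_replicate(seed: int) -> tuple[float, float]:
    """(mean ACC full, mean ACC no_driver) on one replicate where every
    informative feature is driver-flagged (plus uninformative decoys)."""
    spec = SyntheticSpec(n_samples=SMALL_N, n_features=SMALL_FEATURES,
                         n_informative=SMALL_INFORMATIVE,
                         n_informative_driver=SMALL_INFORMATIVE,
                         n_decoy_drivers=8, seed=seed)
    bundle = simulate_multiomics(spec)
    views = preprocess_bundle(bundle)
    cfg = _model_config(SMALL_ENCODER, len(bundle.labels.class_names), 32)
    tc = TrainConfig(**{**SMALL_TRAIN.__dict__, "seed": seed})
    full = run_variant("full", views, bundle.labels, bundle.catalog, cfg, tc)
    nodr = run_variant("no_driver", views, bundle.labels, bundle.catalog,
                       cfg, tc)
    return full.report.mean("acc"), nodr.report.mean("acc")


def dominant_biomarker_replicate(seed: int) -> int:
    """Within-view importance rank of the planted dominant mRNA marker on
    one replicate (balanced classes: a ranking study weights every subtype
    equally)."""
    spec = SyntheticSpec(n_samples=SMALL_N, class_proportions=(1/3, 1/3, 1/3),
                         n_features=SMALL_FEATURES,
                         n_informative=SMALL_INFORMATIVE,
                         n_informative_driver=6, n_decoy_drivers=6,
                         dominant_view="mRNA", seed=seed)
    bundle = simulate_multiomics(spec)
    views = preprocess_bundle(bundle)
    cfg = _model_config(SMALL_ENCODER, len(bundle.labels.class_names), 32)
    tc = TrainConfig(**{**SMALL_TRAIN.__dict__, "seed": seed})
    cv = run_variant("full", views, bundle.labels, bundle.catalog, cfg, tc)
    table = importance_scores(cv, views, bundle.labels)
    dom = bundle.truth.dominant["mRNA"]
    row = table[(table.view == "mRNA") & (table.feature == dom)]
    return int(row["rank"].iloc[0])


def selection_sparsity_replicate(seed: int, n: int = 150,
                                 p: int = 100) -> tuple[int, int]:
    """(|selected(C=0.1)|, |selected(C=1.0)|) on one simulated binary
    problem: 5 informative features, the rest independent noise."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, p))
    X[:, :5] += 1.5 * y[:, None]
    m = OmicsMatrix("mRNA", [f"S{i}" for i in range(n)],
                    [f"F{j}" for j in range(p)], X - X.min() + 0.01)
    labels = SubtypeLabelSet(list(m.sample_ids), ["a", "b"], y)
    small = len(select_l1svc(m, labels, C=0.1, seed=seed))
    large = len(select_l1svc(m, labels, C=1.0, seed=seed))
    return small, large
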