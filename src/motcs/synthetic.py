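"""Synthetic multi-omics generator.

Emulates the statistical regime the classifier targets: three views
(mRNA, miRNA, gene-level DNA methylation measured probe-wise) on the same
samples, imbalanced multi-class subtype structure, and a planted subset of
class-discriminative features of which some are flagged as drivers.

Signals are additive on a latent Gaussian scale — for an informative
feature, one subtype's mean is shifted by ``effect_size`` — then pushed
through a view-specific link: ``exp`` for expression (nonnegative,
right-skewed) and a logistic squash to [0, 1] for methylation betas.
A fraction of uninformative expression features carries structural zeros
heavy enough to trip the 25% zero filter; methylation is emitted at probe
level (about 3 probes per gene, TSS distances straddling the 1500 bp
window) with missing entries, a few blacklisted probes, and a couple of
X-chromosome genes, so the whole preprocessing chain is exercised.  Decoy
drivers (driver-flagged but uninformative) keep the driver-branch ablation
honest.  All randomness flows from one seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DriverCatalog, MotcsError, OmicsMatrix, ProbeAnnotation, \
    SubtypeLabelSet
from .preprocess import preprocess_expression, preprocess_methylation

#: COAD-like 3-class imbalance (177:34:47 normalised)
DEFAULT_PROPORTIONS = (177 / 258, 34 / 258, 47 / 258)

#: BRCA-like 5-class imbalance (417:139:127:46:34 normalised)
BRCA_PROPORTIONS = tuple(np.array([417, 139, 127, 46, 34]) / 763)


@dataclass
class SyntheticSpec:
    """Generator settings; defaults define the package's benchmark regime."""

    n_samples: int = 300
    class_proportions: tuple = DEFAULT_PROPORTIONS
    n_features: int = 500          # per view
    n_informative: int = 50        # per view, class-shifted
    n_informative_driver: int = 15  # leading informative features, driver-flagged
    n_decoy_drivers: int = 15      # driver-flagged but uninformative
    effect_size: float = 2.0       # latent-scale mean shift
    noise_sd: float = 1.0
    missing_rate: float = 0.05     # methylation probes only
    zero_heavy_fraction: float = 0.10  # uninformative expression features
    dominant_view: str | None = None   # view holding a dominant marker
    dominant_multiplier: float = 2.5   # shift boost for that marker
    probes_per_gene: int = 3
    seed: int = 42

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise MotcsError("n_informative exceeds n_features")
        if self.n_informative_driver > self.n_informative:
            raise MotcsError("n_informative_driver exceeds n_informative")
        if (self.n_informative + self.n_decoy_drivers) > self.n_features:
            raise MotcsError("informative + decoy drivers exceed n_features")
        p = np.asarray(self.class_proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-8 or (p <= 0).any() or len(p) < 2:
            raise MotcsError("class_proportions must be positive and sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, keyed by view name."""

    informative: dict[str, list[str]]
    driver_informative: dict[str, list[str]]
    decoy_drivers: dict[str, list[str]]
    dominant: dict[str, str]
    class_of_feature: dict[str, dict[str, int]]


@dataclass
class SyntheticBundle:
    views: list[OmicsMatrix]          # [mRNA, miRNA, methylation(probe-level)]
    labels: SubtypeLabelSet
    catalog: DriverCatalog
    annotation: ProbeAnnotation
    truth: SyntheticTruth


def _feature_ids(view: str, n: int) -> list[str]:
    prefix = {"mRNA": "G", "miRNA": "hsa-mir-", "methylation": "MG"}[view]
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def _class_shifts(spec: SyntheticSpec, n_classes: int,
                  mode: str) -> np.ndarray:
    """(n_informative, n_classes) latent mean-shift table.

    ``default``: informative feature j is up-shifted in class j mod c, so
    every subtype has several redundant markers in every view.

    Zero-ablation importance is a *marginal* quantity: a feature can only
    dominate the ranking if it carries signal that nothing else — in its
    own view, in the other views, or in the complement of the other
    markers — duplicates.  When ``spec.dominant_view`` is set, every
    informative feature except the dominant one is a marker of "any
    non-first subtype" (mode ``merged_minor``: identical shift in all
    classes but the first), so the non-first subtypes are mutually
    indistinguishable without the dominant feature, which alone contrasts
    them (mode ``dominant``: boosted shift down in the second subtype, up
    in the last).  Zeroing it merges the minor classes; zeroing anything
    else is absorbed by redundant markers.
    """
    shifts = np.zeros((spec.n_informative, n_classes))
    if mode == "dominant":
        boost = spec.effect_size * spec.dominant_multiplier
        shifts[0, 1] = -boost
        shifts[0, n_classes - 1] = boost
        shifts[1:, 1:] = spec.effect_size
    elif mode == "merged_minor":
        shifts[:, 1:] = spec.effect_size
    else:
        for j in range(spec.n_informative):
            shifts[j, j % n_classes] = spec.effect_size
    return shifts


def _shift_mode(spec: SyntheticSpec, view: str) -> str:
    if spec.dominant_view is None:
        return "default"
    return "dominant" if view == spec.dominant_view else "merged_minor"


def _latent(spec: SyntheticSpec, y: np.ndarray, n_classes: int,
            rng: np.random.Generator, mode: str) -> np.ndarray:
    """(n_samples, n_features) latent Gaussian matrix with planted shifts in
    the leading n_informative columns."""
    Z = rng.normal(0.0, spec.noise_sd,
                   size=(spec.n_samples, spec.n_features))
    shifts = _class_shifts(spec, n_classes, mode)
    Z[:, :spec.n_informative] += shifts[:, y].T
    return Z


def _expression_view(view: str, spec: SyntheticSpec, y: np.ndarray,
                     n_classes: int, samples: list[str],
                     rng: np.random.Generator) -> OmicsMatrix:
    Z = _latent(spec, y, n_classes, rng, _shift_mode(spec, view))
    X = np.exp(Z)
    feats = _feature_ids(view, spec.n_features)
    # structural zeros: heavy in a block of uninformative features (exercises
    # the 25% filter), light elsewhere among uninformative features
    start = spec.n_informative + spec.n_decoy_drivers
    n_heavy = int(round(spec.zero_heavy_fraction * spec.n_features))
    heavy = slice(start, min(start + n_heavy, spec.n_features))
    X[:, heavy] *= rng.random((spec.n_samples, X[:, heavy].shape[1])) >= 0.40
    light = np.zeros(spec.n_features, dtype=bool)
    light[spec.n_informative:] = True
    light[heavy] = False
    X[:, light] *= rng.random((spec.n_samples, light.sum())) >= 0.02
    return OmicsMatrix(view, samples, feats, X)


def _methylation_view(spec: SyntheticSpec, y: np.ndarray, n_classes: int,
                      samples: list[str], rng: np.random.Generator
                      ) -> tuple[OmicsMatrix, ProbeAnnotation]:
    Z = _latent(spec, y, n_classes, rng,
                _shift_mode(spec, 'methylation'))  # gene-level latent
    genes = _feature_ids("methylation", spec.n_features)
    # ~probes_per_gene probes per gene; TSS distances straddle the 1500 bp
    # window (two inside, the rest outside)
    base_dists = [500, 1200] + [2200] * max(0, spec.probes_per_gene - 2)
    probe_ids, probe_gene, probe_dist = [], [], []
    for gi, g in enumerate(genes):
        for pi, d0 in enumerate(base_dists[:spec.probes_per_gene]):
            probe_ids.append(f"cg{gi + 1:05d}{pi}")
            probe_gene.append(g)
            probe_dist.append(int(d0 + rng.integers(-100, 101)))
    n_probes = len(probe_ids)
    gene_idx = np.array([genes.index(g) for g in probe_gene])
    offsets = rng.normal(0.0, 0.5, size=n_probes)
    noise = rng.normal(0.0, 0.3, size=(spec.n_samples, n_probes))
    logits = Z[:, gene_idx] + offsets + noise
    beta = 1.0 / (1.0 + np.exp(-logits))
    # missingness
    if spec.missing_rate > 0:
        mask = rng.random(beta.shape) < spec.missing_rate
        # never blank out a whole probe
        full = mask.all(axis=0)
        mask[0, full] = False
        beta[mask] = np.nan
    # annotation: last two uninformative genes sit on chrX; the first three
    # uninformative genes get one blacklisted (SNP-overlap) probe each
    chrx_genes = set(genes[-2:])
    flag_genes = set(genes[spec.n_informative:spec.n_informative + 3])
    chrom, flagged = [], []
    seen_flag: set[str] = set()
    for g, d in zip(probe_gene, probe_dist):
        chrom.append("X" if g in chrx_genes else "1")
        if g in flag_genes and g not in seen_flag:
            flagged.append(True)
            seen_flag.add(g)
        else:
            flagged.append(False)
    ann = ProbeAnnotation(pd.DataFrame({
        "probe_id": probe_ids, "gene": probe_gene, "dist_tss": probe_dist,
        "chrom": chrom, "flagged": flagged}))
    return OmicsMatrix("methylation", samples, probe_ids, beta), ann


def simulate_multiomics(spec: SyntheticSpec) -> SyntheticBundle:
    """Generate the three views, labels, driver catalog, probe annotation
    and ground truth; bit-reproducible given ``spec.seed``."""
    ss = np.random.SeedSequence(spec.seed)
    rng_labels, rng_mrna, rng_mirna, rng_meth = \
        (np.random.default_rng(s) for s in ss.spawn(4))
    p = np.asarray(spec.class_proportions, dtype=float)
    n_classes = len(p)
    counts = rng_labels.multinomial(spec.n_samples, p)
    if (counts == 0).any():
        raise MotcsError("a class drew zero samples; increase n_samples")
    y = rng_labels.permutation(np.repeat(np.arange(n_classes), counts))
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    class_names = [f"subtype{k + 1}" for k in range(n_classes)]
    labels = SubtypeLabelSet(samples, class_names, y)

    mrna = _expression_view("mRNA", spec, y, n_classes, samples, rng_mrna)
    mirna = _expression_view("miRNA", spec, y, n_classes, samples, rng_mirna)
    meth, ann = _methylation_view(spec, y, n_classes, samples, rng_meth)

    informative, driver_inf, decoys, dominant, cls_of = {}, {}, {}, {}, {}
    coding: set[str] = set()
    noncoding: set[str] = set()
    for view in ("mRNA", "miRNA", "methylation"):
        ids = _feature_ids(view, spec.n_features)
        inf = ids[:spec.n_informative]
        informative[view] = inf
        driver_inf[view] = inf[:spec.n_informative_driver]
        decoys[view] = ids[spec.n_informative:
                           spec.n_informative + spec.n_decoy_drivers]
        if spec.dominant_view == view:
            dominant[view] = ids[0]
        cls_of[view] = {f: j % n_classes for j, f in enumerate(inf)}
        target = noncoding if view == "miRNA" else coding
        target.update(driver_inf[view])
        target.update(decoys[view])
    catalog = DriverCatalog(coding, noncoding)
    truth = SyntheticTruth(informative, driver_inf, decoys, dominant, cls_of)
    return SyntheticBundle([mrna, mirna, meth], labels, catalog, ann, truth)


def preprocess_bundle(bundle: SyntheticBundle,
                      knn_k: int = 10) -> list[OmicsMatrix]:
    """Run the standard per-view preprocessing chain on a bundle, returning
    model-ready matrices [mRNA, miRNA, methylation(gene-level)]."""
    mrna, mirna, meth = bundle.views
    return [preprocess_expression(mrna), preprocess_expression(mirna),
            preprocess_methylation(meth, bundle.annotation, knn_k=knn_k)]


def make_worked_fixture() -> SyntheticBundle:
    """Deterministic 8-sample, 2-class toy bundle with hand-checkable
    preprocessing arithmetic, shared across unit tests.

    Hand-fixed facts (verify against the arrays below):

    * mRNA zeros per feature: G0001:0, G0002:2, G0003:3, G0004:0, G0005:1,
      G0006:4 -> fractions 0, .25, .375, 0, .125, .5 -> the 25% zero filter
      keeps exactly [G0001, G0002, G0004, G0005].
    * miRNA zeros: m1:0, m2:0, m3:5, m4:0, m5:0, m6:2 -> keeps all but
      hsa-mir-0003.
    * methylation probes: cg01a/cg01b -> MG0001 (500, 1200 bp upstream),
      cg02a -> MG0002 (2000 bp: outside the 1500 window),
      cg02b -> MG0002 (800 bp), cg03a -> MG0003 (700 bp, chrX),
      cg01c -> MG0001 (300 bp, blacklist-flagged).
      filter_probes removes cg03a (chrX) and cg01c (flagged) -> 4 survive.
    * one missing beta at (S2, cg01a); with k=1 the nearest feature is
      cg01b (values differ by 0.02 everywhere) -> imputed 0.42.
    * TSS-window aggregation: MG0001 = mean(cg01a, cg01b) -> S1:
      (0.20+0.22)/2 = 0.21, S2: (0.42+0.42)/2 = 0.42; MG0002 = cg02b alone
      (cg02a outside window); MG0003 absent (its only probe removed).
    * drivers: coding {G0001, MG0002}, noncoding {hsa-mir-0001}.
    """
    samples = [f"S{i}" for i in range(1, 9)]
    labels = SubtypeLabelSet(samples, ["A", "B"],
                             np.array([0, 0, 0, 0, 1, 1, 1, 1]))
    mrna = OmicsMatrix("mRNA", samples, _feature_ids("mRNA", 6), np.array([
        [5, 0, 0, 1, 0, 0],
        [6, 0, 0, 2, 2, 0],
        [5, 3, 0, 3, 3, 0],
        [6, 4, 1, 4, 4, 0],
        [1, 2, 2, 5, 5, 1],
        [2, 3, 3, 6, 6, 2],
        [1, 4, 4, 7, 7, 3],
        [2, 5, 5, 8, 8, 4],
    ], dtype=float))
    mirna = OmicsMatrix("miRNA", samples, _feature_ids("miRNA", 6), np.array([
        [4, 1, 0, 2, 3, 0],
        [5, 1, 0, 2, 1, 1],
        [4, 2, 0, 2, 4, 0],
        [5, 2, 0, 2, 1, 2],
        [1, 3, 0, 2, 5, 3],
        [1, 3, 1, 2, 9, 4],
        [2, 4, 2, 2, 2, 5],
        [1, 4, 3, 2, 6, 6],
    ], dtype=float))
    nan = np.nan
    beta = np.array([
        # cg01a  cg01b  cg02a  cg02b  cg03a  cg01c
        [0.20, 0.22, 0.50, 0.10, 0.33, 0.60],
        [nan,  0.42, 0.50, 0.12, 0.33, 0.60],
        [0.30, 0.32, 0.50, 0.14, 0.33, 0.60],
        [0.25, 0.27, 0.50, 0.16, 0.33, 0.60],
        [0.70, 0.72, 0.50, 0.80, 0.33, 0.60],
        [0.75, 0.77, 0.50, 0.82, 0.33, 0.60],
        [0.80, 0.82, 0.50, 0.84, 0.33, 0.60],
        [0.72, 0.74, 0.50, 0.86, 0.33, 0.60],
    ])
    meth = OmicsMatrix("methylation", samples,
                       ["cg01a", "cg01b", "cg02a", "cg02b", "cg03a", "cg01c"],
                       beta)
    ann = ProbeAnnotation(pd.DataFrame({
        "probe_id": ["cg01a", "cg01b", "cg02a", "cg02b", "cg03a", "cg01c"],
        "gene": ["MG0001", "MG0001", "MG0002", "MG0002", "MG0003", "MG0001"],
        "dist_tss": [500, 1200, 2000, 800, 700, 300],
        "chrom": ["1", "1", "1", "1", "X", "1"],
        "flagged": [False, False, False, False, False, True],
    }))
    catalog = DriverCatalog({"G0001", "MG0002"}, {"hsa-mir-0001"})
    truth = SyntheticTruth(
        informative={"mRNA": ["G0001"], "miRNA": ["hsa-mir-0001"],
                     "methylation": ["MG0002"]},
        driver_informative={"mRNA": ["G0001"], "miRNA": ["hsa-mir-0001"],
                            "methylation": ["MG0002"]},
        decoy_drivers={"mRNA": [], "miRNA": [], "methylation": []},
        dominant={"mRNA": "G0001", "miRNA": "hsa-mir-0001",
                  "methylation": "MG0002"},
        class_of_feature={"mRNA": {"G0001": 0},
                          "miRNA": {"hsa-mir-0001": 0},
                          "methylation": {"MG0002": 0}},
    )
    return SyntheticBundle([mrna, mirna, meth], labels, catalog, ann, truth)
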