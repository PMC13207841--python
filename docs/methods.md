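# Methods

## The model

MOTCS classifies cancer subtypes from three omics views measured on the
same samples — mRNA expression, miRNA expression, and gene-level DNA
methylation — and ranks candidate biomarkers by ablation. The design rests
on three ideas.

**Driver genes get their own branch.** Curated cancer driver genes (coding
symbols and, for miRNA, oncogenic miRNA identifiers) are few, biologically
meaningful, and easily diluted when mixed with thousands of background
features. Each view's features are therefore split against the catalogs:
driver features are kept wholesale, while non-driver features pass through
embedded selection with an L1-penalised linear SVC (squared hinge,
one-vs-rest, C = 0.1; features standardised before the fit; selection is
fitted on training folds only). Features with any nonzero class
coefficient survive. Each branch is encoded separately.

**A transformer encoder without positional encodings.** A sample's feature
vector x ∈ R^N becomes N tokens via feature-specific linear maps
t_i = x_i·w_i + b_i ∈ R^D (a shared scalar map would make all tokens
colinear; feature-specific maps preserve feature identity, which is the
job positional encodings do in sequence models). Tokens pass through
encoder layers of multi-head scaled dot-product self-attention
(softmax(QKᵀ/√d_k)V per head, d_k = D/h, heads concatenated and projected)
and a position-wise feed-forward network max(0, XW₁+b₁)W₂+b₂, each
sub-layer wrapped in residual + layer normalisation, with dropout after
both sub-layers in training. Because tabular omics features have no order,
positional encodings are omitted; the mean-pooled sample representation is
then exactly invariant under consistent feature permutation, and the test
suite asserts this literally. Pooling is the mean over tokens (no CLS
token exists in this design; flattening would break the invariance).

**Label-space fusion (VCDN).** Per view, the concatenated driver and
non-driver representations feed a one-hidden-layer MLP with softmax output
Ŷ^(m) ∈ R^{n×c}. For each sample the three per-view probability rows form
a cross-omics tensor C[c1,c2,c3] = ŷ^(1)_{c1}·ŷ^(2)_{c2}·ŷ^(3)_{c3}
(sums to 1 for normalised rows), whose row-major vectorisation (first
view's index slowest) a fully connected head — hidden width c³,
leaky-ReLU — maps to the final class probabilities. The training loss is
the unweighted sum of all view cross-entropies and the fusion
cross-entropy, L = Σ_m L_MLP,m + L_VCDN, with log(p + ε), ε = 1e-8.
Single-view models skip fusion; two-view inputs use the analogous c²
tensor (experimental — the reference protocol never runs it).

### Numerical and procedural choices

- Optimisation: Adam on mini-batches; library defaults follow the
  reference protocol (lr 1e-5, batch 128, 100 epochs, patience 50,
  seed 42). Early stopping monitors the total loss on a stratified 10%
  holdout of the training fold and restores the best-epoch weights.
  With `val_fraction = 0` the monitor is the epoch-mean training loss —
  the right choice at small n, where a dozen-sample holdout ranks epochs
  by noise and can restore a fusion head that still predicts the
  majority class.
- Cross-validation is stratified 5-fold (the cohorts this method targets
  are heavily imbalanced); feature selection and standardisation are
  fitted inside each training fold. Model inputs are per-feature
  standardised; zero-ablation therefore replaces a feature with its
  training-fold mean, the neutral value under this scaling.
- Gradients come from a small in-package reverse-mode autodiff
  (`motcs.autograd`); a finite-difference check on the full joint loss is
  part of the test suite. All forward passes in eval mode are pure
  functions; every stochastic step is seeded.
- Ties: argmax prediction breaks ties toward the lowest class index;
  importance ranking breaks ΔF1 ties by feature id.
- Degenerate inputs: empty branches must be disabled rather than passed
  through; all-zero selection falls back to the top-50 coefficients with
  a warning; paired tests define p = 1 for all-zero fold differences and
  p = 0 for zero-variance nonzero differences.

## Preprocessing

Expression views drop features that are zero in more than 25% of samples.
Probe-level methylation drops probes missing in more than 25% of samples
(beta values are rarely exactly zero, so missingness is the operative
reading of that filter), drops blacklisted probes and probes on
chromosomes X/Y, imputes the rest by feature-neighbour KNN (k = 10;
distance = root mean squared difference over shared observed samples,
which keeps different overlap sizes comparable; donors must be observed
at the target sample; imputed value = unweighted donor mean), and then
averages probes lying 0 < d ≤ 1500 bp upstream of a gene's TSS into one
gene-level beta. Distances are assumed strand-resolved by the annotation.
Selection stability across folds is summarised as the mean pairwise
|A∩B| / min(|A|, |B|), which stays interpretable when fold set sizes
differ (Jaccard is stricter and can be substituted downstream).

## The synthetic generator

`motcs.synthetic` emulates the statistical regime the classifier assumes:
class-conditional Gaussian signals on a latent scale (informative feature
j up-shifted by `effect_size` in class j mod c), pushed through `exp` for
expression (nonnegative, right-skewed) and a logistic squash for
methylation betas; imbalanced subtypes (default proportions 177:34:47,
a colorectal-cohort-like 3-class split; a 5-class breast-like preset is
provided); structural zeros heavy enough to trip the 25% filter in a
block of uninformative expression features; probe-level methylation with
~3 probes/gene straddling the 1500 bp window, 5% missingness, two
X-chromosome genes and a few blacklisted probes; and a driver catalog
containing the flagged informative features plus uninformative decoys,
so that disabling the driver branch is a meaningful ablation. All
randomness derives from one seed through named substreams.

What it does not emulate: inter-feature correlation structure, batch and
platform effects, count noise, missingness that depends on signal, or
realistic feature dimensions. Passing recovery benchmarks on this
generator therefore demonstrates that the implementation can find the
structure it is designed for — not that it will match published accuracy
on real cohorts.

The `dominant_view` mode exists for validating ablation importance, which
is a *marginal* quantity: a feature can only dominate the ranking if its
signal is not duplicated by other features, other views, or the
complement of the other markers. In this mode every other informative
feature (in all views) marks "any non-first subtype" with an identical
shift, and the dominant feature alone contrasts the two minor subtypes
(down-shifted in one, up-shifted in the other, scaled by
`dominant_multiplier`); zeroing it provably merges those classes.

## Benchmark studies (`motcs.benchmarks`)

The frozen desk-scale studies behind the acceptance checks and
`scripts/acceptance.py`:

| study | data | model / optimiser |
|---|---|---|
| recovery | default spec: n=300, c=3 (imbalanced), 500 features/view, 50 informative, effect 2 | D=32, 4 heads, 1 layer, dropout 0.1; lr 2e-3, 30 epochs, batch 128 |
| driver ablation | n=150, 60 features/view, all 15 informative features driver-flagged + 8 decoys | D=16, 2 heads, 1 layer; lr 1e-2, 40 epochs |
| dominant biomarker | n=150, balanced c=3, 60 features/view, dominant marker in mRNA | same as driver ablation |
| selection sparsity | n=150, 100 features, 5 informative, binary labels | L1-SVC at C = 0.1 vs 1.0 |

These sizes are the package's reproducibility choice: single-CPU minutes
per study. The optimisation settings differ from the library defaults for
a structural reason — with ~10² training samples and mini-batches of 128,
one epoch is one or two Adam steps, so the reference protocol's lr 1e-5 ×
100 epochs moves parameters by ~10⁻³ from initialisation and cannot fit
anything at this scale; the benchmark configs use proportionally larger
steps and fewer epochs. The single encoder layer (library default: 2)
follows the same reasoning. The replicated studies (driver ablation,
dominant biomarker) use 10 fixed seeds each in the test suite; the
balanced class proportions in the dominant-biomarker study reflect that a
ranking study should weight every subtype's markers equally.

## Known limitations

- The NumPy autodiff is single-threaded and unbatched across views; it is
  sized for desk-scale data, not TCGA-scale matrices.
- KNN imputation is O(features² · samples) per view in the worst case;
  fine for probe panels of ~10³–10⁴, slow beyond.
- The two-view tensor path and the empty-selection fallback are
  implemented and tested only at the unit level.
- Attention maps are not exported; importance is ablation-based only.
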