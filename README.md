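# motcs

Multi-omics cancer subtype classification with driver-gene-aware
transformer encoders and cross-omics tensor fusion, plus zero-ablation
biomarker ranking.

Molecular subtypes (e.g. breast-cancer Luminal A/B, Basal-like,
HER2-enriched) guide therapy, but no single omics layer captures them
fully. `motcs` is for computational biologists who have matched mRNA
expression, miRNA expression and DNA methylation profiles per patient
(TCGA-style) and want (1) a subtype classifier that treats curated cancer
driver genes as first-class citizens rather than letting them drown in
thousands of background features, and (2) a ranked list of candidate
biomarkers per omics layer.

## The method

Per omics view *m*, features are split into **driver features** (present
in curated catalogs such as coding-driver and oncogenic-miRNA lists; kept
wholesale) and **non-driver features** (reduced by an L1-penalised linear
SVC with C = 0.1, fitted on training folds only). Each branch is encoded
by a transformer encoder *without positional encodings*: feature *i* of a
sample becomes a token x_i·w_i + b_i ∈ R^D; tokens interact through
multi-head scaled dot-product self-attention

    Attention(Q, K, V) = softmax(QKᵀ / √d_k) V,   d_k = D / h,

followed by a position-wise feed-forward network
FFN(X) = max(0, XW₁+b₁)W₂+b₂, with residual connections and layer
normalisation, then mean-pool to a per-sample vector Z_m^dg / Z_m^svc.
The concatenation Z_m = [Z_m^dg, Z_m^svc] feeds a per-view MLP producing
subtype probabilities Ŷ^(m) ∈ R^{n×c}. Cross-omics fusion builds, per
sample, the tensor

    C[c1, c2, c3] = ŷ^(1)_{c1} · ŷ^(2)_{c2} · ŷ^(3)_{c3} ∈ R^{c×c×c},

whose vectorisation a small fully connected head (the view-correlation
decision network, VCDN) maps to the final prediction. Training minimises
L = Σ_m L_MLP,m + L_VCDN (cross-entropies) with Adam under stratified
5-fold cross-validation; metrics are ACC, weighted F1 and macro F1.
Biomarkers are ranked per view by summed ΔF1 over folds when a feature's
input column is zeroed in the trained model.

The network is implemented on a small reverse-mode autodiff over NumPy
(`motcs.autograd`); everything is deterministic given a seed. A synthetic
multi-omics generator (`motcs.synthetic`) with planted, driver-flagged
discriminative features makes the whole pipeline runnable and testable
without any download. See `docs/methods.md` for modelling details and
limitations.

## Worked example

```python
from motcs.benchmarks import recovery_benchmark
from motcs.importance import importance_scores, top_k_biomarkers
from motcs.synthetic import SyntheticSpec, simulate_multiomics, preprocess_bundle

cv = recovery_benchmark(seed=42)   # ~4 min on one CPU
print(cv.report.summary())
```

prints (run on this machine):

```
{'acc': {'mean': 0.9533333333333334, 'sd': 0.0639009650422694},
 'f1_weighted': {'mean': 0.931719298245614, 'sd': 0.0934972014828994},
 'f1_macro': {'mean': 0.8568421052631578, 'sd': 0.1960270205807963}}
```

i.e. on the default synthetic regime — 300 samples, three imbalanced
subtypes, 500 features per view of which 50 carry a class signal — the
full 5-fold pipeline (per-fold feature selection, dual-branch encoders,
VCDN fusion) recovers the planted structure with ~95% test accuracy; the
lower macro F1 reflects the hardest minority subtype. The same object
feeds the ablation ranking:

```python
bundle = simulate_multiomics(SyntheticSpec(seed=42))
views = preprocess_bundle(bundle)
table = importance_scores(cv, views, bundle.labels)
print(top_k_biomarkers(table, 30)["mRNA"][:5])
```

The command line mirrors this: `motcs simulate`, `motcs preprocess`,
`motcs train`, `motcs importance`, `motcs sweep`, or all stages at once:

```sh
motcs run-all --config config.yaml --out results/
```

with a YAML holding the simulation spec (or dataset paths) and the
training hyperparameters (learning rate, batch size, epochs, early-stop
patience, attention heads, dropout).

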