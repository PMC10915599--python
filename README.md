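# mocogcn

Case–control classification from paired **microbiome** and **exposome**
data with a two-view co-training graph convolutional network and a
cross-view label-integration head.

The package targets studies in which each participant is observed through
two complementary views — a species relative-abundance profile
(compositional, real-valued) and a panel of binary exposures (lifestyle,
medication, comorbidity) — and the goal is a binary diagnosis (e.g.
pancreatic cancer vs. control) that uses both views *and* their
interplay. It is a library first (import `mocogcn`), with a thin
`mocogcn` command-line wrapper and runnable scripts under `examples/`.

## The model

**Sample-similarity graphs.** For each view, samples become nodes and
edges carry cosine similarity s(xᵢ,xⱼ) kept when s ≥ ε. The threshold is
not set directly: the edge-density parameter *k* asks for an average of
at least *k* retained edges per node and ε is the largest similarity
achieving that. At k=1 the graph has no edges and the model degenerates
to a plain fully connected network.

**Per-view GCN.** Each view gets a stack of graph-convolution layers

    H(l+1) = σ( D̂^{-1/2}(A+I)D̂^{-1/2} · H(l) · W(l) ),

with D̂ the degree matrix of A+I, σ a leaky rectifier, and a final
softmax over the two classes.

**Co-training.** The two GCNs are trained semi-supervised: each round,
every view pseudo-labels its most confident unlabeled samples (max-class
probability ≥ τ) and hands them to the *partner* view's training pool.
Originally labeled samples always keep their true labels. Training ends
when the unlabeled pool is exhausted and assignments are stable.

**VCDN integration.** Per sample, the two views' class distributions are
combined into the 2×2 cross-view tensor cᵢ = yᵢ^exposome (yᵢ^species)ᵀ,
flattened and passed to a small fully connected head that outputs the
final distribution. Training alternates under the composite loss

    L = L_GCN^species + L_GCN^exposome + L_VCDN,

each term a cross-entropy over labeled samples: fix the head and update
both GCNs, then fix the GCNs and update the head.

**Evaluation & biomarkers.** A stratified 4-fold *transductive*
cross-validation (test samples stay in the graphs and the unlabeled pool;
their labels are withheld) reports ACC, F1, AUROC, sensitivity,
specificity and MCC as mean ± SD, with a sensitivity sweep over
k = 2..10. Feature importance is measured by test-time ablation: zero a
feature's column, rebuild the ablated view's graph, and record the drop
in test-fold F1.

Upstream of the model, `wilcoxon_select` performs the usual
differential-abundance screen (two-sided rank-sum test, raw p < 0.05)
with the generalized fold change (mean case-minus-control quantile
difference) as the signed effect size.

## Worked example

```python
from mocogcn import TrainConfig, cross_validate, generate_cohort

cohort = generate_cohort(species_effect=3.0, seed=11)  # 57 cases / 50 controls
cfg = TrainConfig(k=5, seed=11)
report = cross_validate(cohort.species_view, cohort.exposome_view,
                        cohort.labels, cfg)
print(report.summary().round(3))
```

prints

```
        mean     sd
acc    0.879  0.046
f1     0.886  0.049
auroc  0.916  0.032
sn     0.895  0.091
sp     0.859  0.081
mcc    0.762  0.093
```

— the mean ± SD over the four folds on a synthetic cohort with the study
shape (107 samples, 125 species + 23 binary exposures) and ten strongly
case-enriched species: the model recovers the planted signal with mean
AUROC above 0.9. The scripts in `examples/` walk through feature
selection, graph construction, co-training, cross-validation, the k
sweep and importance ranking, each printing and explaining its output.

Real data enter through delimited text: two sample×feature tables with a
`sample_id` first column, plus a two-column label file; see
`mocogcn train --help` and friends (`evaluate`, `sweep-k`, `importance`,
`simulate`).

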