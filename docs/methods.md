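# Methods

This note documents the model, the choices made where the design was
genuinely open, the synthetic-data generator, and the limits of what the
test suite shows.

## Model and training procedure

The classifier integrates two views of one cohort — species relative
abundances (n×d_s, rows on the simplex) and binary exposures (n×d_e) —
through per-view graph convolutional networks (GCNs) co-trained on
sample-similarity graphs, fused by a view-correlation head (VCDN).

**Graphs.** Cosine similarity per view; an edge i–j is kept when
s(xᵢ,xⱼ) ≥ ε. ε is derived from the edge-density parameter k: the
largest off-diagonal similarity such that the mean number of retained
off-diagonal entries per node is at least k (ties at ε retained; found
exactly by a descending sort of the off-diagonal values). k = 1 is
special-cased to the edgeless graph: the propagation operator becomes
the identity and each view's GCN reduces, bit for bit, to a dense
network — the documented degeneracy. The propagation operator is the
symmetric renormalization D̂^{-1/2}(A+I)D̂^{-1/2} with D̂ the degree of
A+I; taking the degree of A alone would be singular for isolated nodes
and would make the k=1 degeneracy impossible, so the self-loop is
included in the degree.

**Per-view GCN.** Default stack d→64→32→2 without biases (the layer is
exactly σ(ÂHW)), leaky-rectifier slope 0.25, dropout 0.5 on hidden
activations during training only, softmax output. Layer sizes and the
slope are conventional defaults for cohort-scale inputs; all are
configurable (`hidden_dims=()` gives a single linear layer).

**Co-training.** Both views start from the same true-label pool. Per
round: each view is fitted (full-batch Adam, summed cross-entropy,
`pretrain_epochs=200`) on its pool, then proposes up to
m = max(1, ⌈0.05·|U|⌉) pseudo-labels from the unlabeled pool U with
max-class probability ≥ τ = 0.8. Accepted samples leave U and join the
*partner* view's pool — the classical co-training exchange. If both
views propose the same sample with conflicting classes, the
higher-confidence proposal wins; an exact tie defers the sample to a
later round. The loop ends when U is empty (assignments are by
construction stable — a pseudo-label is never revised) or at
`max_rounds=50`, in which case a warning is logged and the best state is
returned. True labels are asserted unchanged every round, and unlabeled
samples' ground truth is never read on any code path.

**Joint stage.** After the warm start, 100 alternating epochs: (a) with
the head fixed, both GCNs receive the gradient of their own
cross-entropy term plus the VCDN term flowing through the outer-product
tensor and the softmaxes; (b) with the GCNs fixed (evaluation-mode
outputs), the head is updated on its cross-entropy. The loss trace
records evaluation-mode L_species, L_exposome, L_VCDN and their exact
sum each epoch; a non-finite total aborts with a diagnostic. All three
loss terms use the originally labeled samples with their true labels
(pseudo-labels only shape the warm start); this keeps the loss semantics
clean and the test-label firewall auditable.

**Optimizer.** Adam, full batch. lr 1e-3 for the GCNs. For the VCDN
head lr is 1e-2: the head starts from a random init and Adam steps are
lr-bounded, so at 1e-3 a 100-epoch run cannot move it far from its
arbitrary initial class bias — the final output then shows a
seed-dependent sensitivity/specificity skew even when per-view AUROC is
high. 1e-2 restores threshold calibration without affecting AUROC.
Cross-entropies are sums (not means) over labeled samples; with Adam the
scaling is immaterial to step sizes.

**Determinism.** One config seed drives weight inits (seed, seed+1 for
the views, seed+2 for the head) and the dropout stream; identical
config + data reproduce identical parameters and predictions bit for
bit.

## Evaluation

Stratified 4-fold cross-validation, transductive: graphs are built once
on the full cohort, each fold trains with the test fold in the unlabeled
pool, and metrics are computed on the test fold's final class-1
probability. ACC/F1/Sn/Sp/MCC threshold at 0.5 (the package takes no
position on threshold tuning); AUROC is the rank statistic. Degenerate
cases: single-class test fold → AUROC reported as NaN with a warning;
any zero confusion-matrix marginal → MCC defined as 0. Aggregation is
mean ± SD over folds (ddof=1). The k sweep re-runs the CV for each k
under one fixed fold plan, so only the graphs change.

**Feature-ablation importance.** For each feature: zero its column in
the (transductive) inputs, re-predict per fold with the trained model —
no retraining — and record the mean drop in test-fold F1, sorted
descending. Two refinements, both label-free: the ablated view's
similarity graph is rebuilt from the ablated inputs, because in a
transductive model the graph is part of the test-time computation (if
ablation would zero an entire sample row, the original graph is kept for
that feature); and exact ties in the coarse F1 delta are broken by the
mean absolute shift of the test-fold case probability. F1 on a ~27-sample
fold moves in steps of ~0.03, so without the tie-break many features
share the delta caused by a single borderline sample. A retrain-per-
feature mode is deliberately out of scope for cost.

## Differential abundance

Two-sided Wilcoxon rank-sum test per feature (exact null below 20 per
group, tie-corrected normal approximation otherwise), raw p-values —
the screen is the conventional unadjusted p < 0.05, so no FDR control.
A feature constant and identical in both groups is assigned p = 1. The
generalized fold change is the mean of Q_case(q) − Q_control(q) over
q = 0.05, 0.10, …, 0.95 (linear-interpolation quantiles); it is
antisymmetric and positive for case enrichment. The abundance table is
not renormalized after selection (a deliberate default; renormalization
would change cosine similarities downstream). Missing values are
rejected at load time — imputation is an upstream preprocessing concern.

## Synthetic cohorts

The generator emulates the target study's shapes: defaults are 57 cases
vs 50 controls with 125 species and 23 binary exposures. Species:
per-feature baseline mean μⱼ ~ N(0,1), log-abundance N(μⱼ,1), informative
features shifted by `species_effect` SD in cases, then exponentiation and
closure to the simplex. Exposures: Bernoulli(p₀=0.3), informative ones
Bernoulli(p₀+`exposure_effect`) in cases; an all-zero exposome row (rare,
possible at small d) gets one random exposure switched on so cosine
similarity is defined for every sample. Optional coupling adds
`coupling`·x_exposure to a paired informative species' log-abundance,
creating cross-view dependence. `hide_labels` performs stratified
masking for semi-supervised experiments; `generate_null_cohort` sets all
effects to zero with random labels.

What it does *not* emulate: real taxon–taxon correlation structure,
zero inflation and detection limits, overdispersion beyond log-normal,
cohort batch effects, or realistic exposure co-occurrence. Passing the
recovery tests therefore shows that the pipeline detects planted
location-shift signal under compositional closure — not that it matches
the numbers reported on any real cohort.

Experiment sizes used by the test suite and `scripts/acceptance.py`,
chosen once as representative: signal recovery at the study shape
(107 samples, effect 3 SD on 10 species); chance-level check on five
60-sample null cohorts; pseudo-label accuracy on a 100-sample separable
cohort (both views informative) with half the labels hidden; importance
recovery on 200 samples with 5 of 100 species planted at 2 SD and a
pure-noise exposome — moderate effect, so each planted species is
individually necessary and its ablation visibly dents F1 (at large
effects the five are mutually redundant and single ablations are
absorbed); k-sweep shape on a 40-sample cohort with reduced epochs.

## Known limitations

- Compositional closure spreads planted signal across all species
  (cases' non-planted relative abundances shift down), so ablation
  importance of a single feature understates redundant signal; ranks are
  meaningful, magnitudes are not effect sizes.
- The 0.5 threshold is uncalibrated; on imbalanced cohorts Sn/Sp can be
  asymmetric even at high AUROC.
- Transductive evaluation requires the test samples' features at
  training time; the model does not support inductive prediction on
  samples absent from the graphs.
- Exactly two views; the head's 2×2 tensor does not generalize to more
  views or classes without change.
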