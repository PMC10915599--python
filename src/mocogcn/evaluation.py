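"""Cross-validation harness, evaluation metrics, k-sweep and feature ablation.

Evaluation is transductive: in each stratified fold the test samples keep
their nodes in both similarity graphs and sit in the co-training
unlabeled pool, but their labels are invisible to every training
computation. Metrics are ACC, F1 (positive class = case), rank-based
AUROC, sensitivity, specificity and Matthews correlation, reported per
fold and as mean +/- SD across folds.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

from .config import TrainConfig
from .data_io import CohortLabels, OmicsView
from .similarity import SimilarityGraph, build_graph
from .vcdn import MocoGCNBundle, predict, train_mocogcn

logger = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "f1", "auroc", "sn", "sp", "mcc")


@dataclass
class FoldPlan:
    """Stratified partition of the cohort into test folds."""

    n_folds: int
    test_indices: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.test_indices)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("test folds overlap")


@dataclass
class Metrics:
    acc: float
    f1: float
    auroc: float
    sn: float
    sp: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class CVReport:
    """Fold-wise metrics with mean and SD aggregation."""

    folds: list[Metrics]
    plan: FoldPlan
    bundles: list[MocoGCNBundle] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.folds])

    @property
    def mean(self) -> Metrics:
        df = self.to_frame()
        return Metrics(**{m: float(df[m].mean()) for m in METRIC_NAMES})

    @property
    def sd(self) -> Metrics:
        df = self.to_frame()
        return Metrics(**{m: float(df[m].std(ddof=1)) for m in METRIC_NAMES})

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean.as_dict(), "sd": self.sd.as_dict()})


def stratified_kfold(labels: CohortLabels, n_folds: int = 4, seed: int = 0) -> FoldPlan:
    """Deterministic stratified partition into ``n_folds`` test sets."""
    counts = np.bincount(labels.y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; needs >= {n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tests = [test for _, test in skf.split(np.zeros(labels.n_samples), labels.y)]
    return FoldPlan(n_folds=n_folds, test_indices=tests, seed=seed)


def compute_metrics(y_true: np.ndarray, class1_prob: np.ndarray,
                    threshold: float = 0.5) -> Metrics:
    """The six evaluation metrics at the given classification threshold.

    AUROC is threshold-free (rank statistic; ties average out to 0.5 for
    a constant score). If ``y_true`` is single-class, AUROC is undefined
    and reported as NaN with a warning. A degenerate MCC denominator
    (any zero confusion marginal) yields MCC = 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    class1_prob = np.asarray(class1_prob, dtype=float)
    if y_true.shape != class1_prob.shape:
        raise ValueError("y_true and class1_prob must have equal length")
    y_pred = (class1_prob >= threshold).astype(int)
    tn, fp, fn, tp = skm.confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class y_true: AUROC undefined, reporting NaN")
        auroc = float("nan")
    else:
        auroc = float(skm.roc_auc_score(y_true, class1_prob))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns on zero MCC marginals
        mcc = float(skm.matthews_corrcoef(y_true, y_pred))
    return Metrics(
        acc=float(skm.accuracy_score(y_true, y_pred)),
        f1=float(skm.f1_score(y_true, y_pred, pos_label=1, zero_division=0)),
        auroc=auroc,
        sn=float(sn),
        sp=float(sp),
        mcc=mcc,
    )


def cross_validate(
    view_s: OmicsView,
    view_e: OmicsView,
    labels: CohortLabels,
    config: TrainConfig | None = None,
    n_folds: int = 4,
    plan: FoldPlan | None = None,
    keep_bundles: bool = False,
    graphs: dict[str, SimilarityGraph] | None = None,
) -> CVReport:
    """Stratified k-fold transductive evaluation of the full pipeline.

    Graphs are built once on the whole cohort (they depend only on the
    features and ``k``); each fold trains with the test samples unlabeled
    and scores the final class-1 probability on the test fold.
    """
    config = config or TrainConfig()
    if plan is None:
        plan = stratified_kfold(labels, n_folds, seed=config.seed)
    if graphs is None:
        graphs = {
            "species": build_graph(view_s, config.k, config.z_score),
            "exposome": build_graph(view_e, config.k, config.z_score),
        }
    folds: list[Metrics] = []
    bundles: list[MocoGCNBundle] = []
    for f, test_idx in enumerate(plan.test_indices):
        mask = labels.labeled_mask.copy()
        mask[test_idx] = False
        fold_labels = CohortLabels(list(labels.sample_ids), labels.y.copy(), mask)
        bundle, _ = train_mocogcn(view_s, view_e, fold_labels, config, graphs=graphs)
        final, _ = predict(bundle, view_s, view_e, graphs)
        m = compute_metrics(labels.y[test_idx], final[test_idx, 1])
        logger.info("fold %d/%d: %s", f + 1, plan.n_folds, m.as_dict())
        folds.append(m)
        if keep_bundles:
            bundles.append(bundle)
    return CVReport(folds=folds, plan=plan, bundles=bundles if keep_bundles else None)


def k_sensitivity(
    view_s: OmicsView,
    view_e: OmicsView,
    labels: CohortLabels,
    config: TrainConfig | None = None,
    k_values: tuple[float, ...] = tuple(range(2, 11)),
    n_folds: int = 4,
) -> pd.DataFrame:
    """Cross-validated metrics for each k, under one fixed fold plan.

    Only the similarity graphs change between rows; folds and seeds are
    shared, mirroring a sensitivity sweep of the edge-density parameter.
    """
    config = config or TrainConfig()
    plan = stratified_kfold(labels, n_folds, seed=config.seed)
    rows = []
    for k in k_values:
        cfg = dataclasses.replace(config, k=k)
        report = cross_validate(view_s, view_e, labels, cfg, plan=plan)
        row = {"k": k}
        row.update({f"mean_{m}": v for m, v in report.mean.as_dict().items()})
        row.update({f"sd_{m}": v for m, v in report.sd.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)


def feature_ablation_importance(
    bundles: list[MocoGCNBundle],
    view_s: OmicsView,
    view_e: OmicsView,
    labels: CohortLabels,
    plan: FoldPlan,
    graphs: dict[str, SimilarityGraph] | None = None,
    threshold: float = 0.5,
    rebuild_graph: bool = True,
) -> pd.DataFrame:
    """Feature importance by test-time ablation.

    For every feature of both views, its column is set to zero in the
    (transductive) input matrix, the per-fold trained model re-predicts,
    and the drop in test-fold F1 relative to the unablated inputs is
    recorded; drops are averaged over folds and sorted descending. No
    retraining takes place. With ``rebuild_graph`` (default) the ablated
    view's similarity graph is recomputed from the ablated inputs, since
    in a transductive model the graph is part of the test-time
    computation; if ablation leaves a sample with an all-zero row (its
    similarity would be undefined) the trained graph is kept for that
    feature. A feature whose column is already all-zero has importance
    exactly 0.

    F1 on a small test fold moves in coarse steps, so exact ties in
    ``delta_f1`` are broken by ``prob_shift``, the mean absolute change
    of the test-fold case probability under ablation (a continuous,
    label-free sensitivity measure).
    """
    if len(bundles) != plan.n_folds:
        raise ValueError("need one trained bundle per fold")
    config = bundles[0].config
    if graphs is None:
        graphs = {
            "species": build_graph(view_s, config.k, config.z_score),
            "exposome": build_graph(view_e, config.k, config.z_score),
        }
    views = {"species": view_s, "exposome": view_e}
    base_f1 = []
    base_final = []
    for bundle, test_idx in zip(bundles, plan.test_indices):
        final, _ = predict(bundle, view_s, view_e, graphs)
        base_f1.append(compute_metrics(labels.y[test_idx], final[test_idx, 1],
                                       threshold).f1)
        base_final.append(final)
    rows = []
    for vname, view in views.items():
        for j, fid in enumerate(view.feature_ids):
            if not view.X[:, j].any():
                rows.append({"view": vname, "feature_id": fid,
                             "delta_f1": 0.0, "prob_shift": 0.0})
                continue
            Xa = view.X.copy()
            Xa[:, j] = 0.0
            view_a = OmicsView(vname, list(view.sample_ids),
                               list(view.feature_ids), Xa)
            pair = {"species": (view_a, view_e), "exposome": (view_s, view_a)}[vname]
            g = graphs
            if rebuild_graph:
                try:
                    g = dict(graphs)
                    g[vname] = build_graph(view_a, config.k, config.z_score)
                except ValueError:
                    g = graphs  # ablation zeroed a whole sample row
            deltas, shifts = [], []
            for f, (bundle, test_idx) in enumerate(zip(bundles, plan.test_indices)):
                final, _ = predict(bundle, pair[0], pair[1], g)
                f1 = compute_metrics(labels.y[test_idx], final[test_idx, 1],
                                     threshold).f1
                deltas.append(base_f1[f] - f1)
                shifts.append(np.mean(np.abs(
                    final[test_idx, 1] - base_final[f][test_idx, 1])))
            rows.append({"view": vname, "feature_id": fid,
                         "delta_f1": float(np.mean(deltas)),
                         "prob_shift": float(np.mean(shifts))})
    table = pd.DataFrame(rows).sort_values(
        ["delta_f1", "prob_shift"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return table
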