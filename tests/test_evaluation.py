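import math

import numpy as np
import pytest

from mocogcn import (
    CohortLabels,
    TrainConfig,
    compute_metrics,
    cross_validate,
    feature_ablation_importance,
    generate_cohort,
    k_sensitivity,
    stratified_kfold,
)


def oracle_metrics(y, prob, thr=0.5):
    """Independent confusion-matrix / rank-statistic oracle."""
    pred = (prob >= thr).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    n = len(y)
    acc = (tp + tn) / n
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    # AUROC by pairwise rank comparison with half credit for ties
    pos, neg = prob[y == 1], prob[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    auroc = wins / (len(pos) * len(neg)) if len(pos) and len(neg) else float("nan")
    return acc, f1, auroc, sn, sp, mcc


class TestStratifiedKFold:
    def test_study_shape_fold_sizes(self):
        y = np.array([1] * 57 + [0] * 50)
        lab = CohortLabels([f"s{i}" for i in range(107)], y)
        plan = stratified_kfold(lab, 4, seed=0)
        sizes = sorted(len(t) for t in plan.test_indices)
        assert sizes == [26, 27, 27, 27]
        for t in plan.test_indices:
            cases = int(y[t].sum())
            assert abs(cases - 57 / 4) <= 1

    def test_partition_properties_and_determinism(self):
        y = np.array([0, 1] * 20)
        lab = CohortLabels([f"s{i}" for i in range(40)], y)
        p1 = stratified_kfold(lab, 4, seed=3)
        p2 = stratified_kfold(lab, 4, seed=3)
        allidx = np.sort(np.concatenate(p1.test_indices))
        assert np.array_equal(allidx, np.arange(40))
        for a, b in zip(p1.test_indices, p2.test_indices):
            assert np.array_equal(a, b)

    def test_small_class_error(self):
        lab = CohortLabels(["a", "b", "c", "d", "e"], [1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            stratified_kfold(lab, 4)


class TestComputeMetrics:
    def test_perfect_separation_all_ones(self):
        y = np.array([0, 0, 1, 1])
        m = compute_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_hand_confusion_case(self):
        # TP=3, FP=1, TN=2, FN=2
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2])
        m = compute_metrics(y, p)
        assert m.acc == pytest.approx(0.625)
        assert m.sn == pytest.approx(0.6)
        assert m.sp == pytest.approx(2 / 3)
        assert m.mcc == pytest.approx(4 / math.sqrt(240))

    def test_constant_probability_auroc_half(self):
        y = np.array([0, 1, 0, 1])
        m = compute_metrics(y, np.full(4, 0.7))
        assert m.auroc == pytest.approx(0.5)

    def test_agrees_with_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            prob = np.round(rng.random(n), 2)  # rounding forces ties
            m = compute_metrics(y, prob)
            acc, f1, auroc, sn, sp, mcc = oracle_metrics(y, prob)
            assert m.acc == pytest.approx(acc)
            assert m.f1 == pytest.approx(f1)
            assert m.auroc == pytest.approx(auroc)
            assert m.sn == pytest.approx(sn)
            assert m.sp == pytest.approx(sp)
            assert m.mcc == pytest.approx(mcc, abs=1e-12)

    def test_auroc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        p = rng.random(50)
        base = compute_metrics(y, p).auroc
        assert compute_metrics(y, 1 / (1 + np.exp(-7 * p))).auroc == pytest.approx(base)

    def test_degenerate_mcc_is_zero(self):
        y = np.array([0, 0, 1, 1])
        m = compute_metrics(y, np.array([0.9, 0.9, 0.9, 0.9]))  # all predicted case
        assert m.mcc == 0.0

    def test_single_class_auroc_nan_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            m = compute_metrics(np.array([1, 1, 1]), np.array([0.2, 0.6, 0.9]))
        assert math.isnan(m.auroc)


@pytest.fixture(scope="module")
def tiny_cv():
    cohort = generate_cohort(n_case=16, n_control=16, d_species=25, d_exposome=8,
                             n_inf_species=5, n_inf_exposome=2,
                             species_effect=3.0, seed=8)
    cfg = TrainConfig(k=4, pretrain_epochs=40, joint_epochs=20,
                      max_rounds=20, seed=8)
    report = cross_validate(cohort.species_view, cohort.exposome_view,
                            cohort.labels, cfg, keep_bundles=True)
    return cohort, cfg, report


class TestCrossValidate:
    def test_report_has_one_row_per_fold(self, tiny_cv):
        _, _, report = tiny_cv
        assert len(report.folds) == 4
        assert report.to_frame().shape == (4, 6)

    def test_metric_ranges(self, tiny_cv):
        _, _, report = tiny_cv
        df = report.to_frame()
        assert (df.drop(columns="mcc") >= 0).all().all()
        assert (df.drop(columns="mcc") <= 1).all().all()
        assert df["mcc"].between(-1, 1).all()

    def test_separable_cohort_learns(self, tiny_cv):
        _, _, report = tiny_cv
        assert report.mean.auroc >= 0.8

    def test_test_labels_do_not_leak_into_training(self, tiny_cv):
        """Sentinel audit: flipping one fold's test labels leaves the trained
        parameters bit-identical."""
        cohort, cfg, report = tiny_cv
        test_idx = report.plan.test_indices[0]
        from mocogcn import train_mocogcn
        mask = np.ones(cohort.labels.n_samples, dtype=bool)
        mask[test_idx] = False
        lab_clean = CohortLabels(list(cohort.labels.sample_ids),
                                 cohort.labels.y.copy(), mask)
        y_bad = cohort.labels.y.copy()
        y_bad[test_idx] = 1 - y_bad[test_idx]
        lab_bad = CohortLabels(list(cohort.labels.sample_ids), y_bad, mask)
        b1, _ = train_mocogcn(cohort.species_view, cohort.exposome_view, lab_clean, cfg)
        b2, _ = train_mocogcn(cohort.species_view, cohort.exposome_view, lab_bad, cfg)
        for w1, w2 in zip(
            b1.gcn_species.weights + b1.gcn_exposome.weights + b1.head.weights,
            b2.gcn_species.weights + b2.gcn_exposome.weights + b2.head.weights,
        ):
            assert np.array_equal(w1, w2)


class TestKSensitivity:
    def test_sweep_shape_and_shared_folds(self):
        cohort = generate_cohort(n_case=10, n_control=10, d_species=15,
                                 d_exposome=6, n_inf_species=3, n_inf_exposome=1,
                                 species_effect=3.0, seed=9)
        cfg = TrainConfig(pretrain_epochs=10, joint_epochs=5, max_rounds=5, seed=9)
        table = k_sensitivity(cohort.species_view, cohort.exposome_view,
                              cohort.labels, cfg, k_values=(2, 3, 4), n_folds=4)
        assert list(table["k"]) == [2, 3, 4]
        assert np.isfinite(table["mean_auroc"]).all()


class TestImportance:
    def test_all_zero_feature_importance_zero_and_row_count(self):
        # a species column zeroed before training must get importance exactly 0
        from mocogcn.data_io import OmicsView
        cohort = generate_cohort(n_case=10, n_control=10, d_species=12,
                                 d_exposome=5, n_inf_species=3, n_inf_exposome=1,
                                 species_effect=3.0, seed=15)
        vs = cohort.species_view
        Xs = vs.X.copy()
        Xs[:, 7] = 0.0
        vs0 = OmicsView("species", list(vs.sample_ids), list(vs.feature_ids), Xs)
        cfg = TrainConfig(k=3, pretrain_epochs=15, joint_epochs=5,
                          max_rounds=5, seed=15)
        report = cross_validate(vs0, cohort.exposome_view, cohort.labels, cfg,
                                keep_bundles=True)
        table = feature_ablation_importance(report.bundles, vs0,
                                            cohort.exposome_view, cohort.labels,
                                            report.plan)
        assert len(table) == vs0.n_features + cohort.exposome_view.n_features
        row = table[(table["view"] == "species") & (table["feature_id"] == "sp007")]
        assert float(row["delta_f1"].iloc[0]) == 0.0
        assert float(row["prob_shift"].iloc[0]) == 0.0

    def test_table_sorted_descending(self, tiny_cv):
        cohort, cfg, report = tiny_cv
        table = feature_ablation_importance(report.bundles, cohort.species_view,
                                            cohort.exposome_view, cohort.labels,
                                            report.plan)
        d = table["delta_f1"].to_numpy()
        assert (d[:-1] >= d[1:]).all()

    def test_unknown_bundle_count_error(self, tiny_cv):
        cohort, cfg, report = tiny_cv
        with pytest.raises(ValueError):
            feature_ablation_importance(report.bundles[:2], cohort.species_view,
                                        cohort.exposome_view, cohort.labels,
                                        report.plan)
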