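import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from svmpanel import (
    ConfusionCounts,
    SplitScheme,
    SyntheticSpec,
    counts_from_predictions,
    cross_cohort_validate,
    fit_banded,
    floor_log_transform,
    generate_cohort_pair,
    generate_grouped_cohort,
    grouped_loocv,
    loocv_accuracy,
    metrics_from_counts,
    panel_correlations,
    repeated_split_cv,
    roc_auc,
)
from conftest import make_dataset


class TestMetricsFromCounts:
    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(tp=10, fp=0, tn=20, fn=0))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1, 1, 1, 1)
        assert (m.fdr, m.for_rate) == (0, 0)

    def test_mixed_counts_arithmetic(self):
        m = metrics_from_counts(ConfusionCounts(tp=9, fp=2, tn=18, fn=1))
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.9)
        assert m.ppv == pytest.approx(9 / 11)
        assert m.npv == pytest.approx(18 / 19)
        assert m.fdr == pytest.approx(2 / 11)
        assert m.for_rate == pytest.approx(1 / 19)
        assert m.accuracy == pytest.approx(27 / 30)

    def test_zero_denominator_is_undefined(self):
        m = metrics_from_counts(ConfusionCounts(tp=10, fp=20, tn=0, fn=0))
        assert m.specificity == 0
        assert np.isnan(m.npv) and np.isnan(m.for_rate)

    @given(tp=st.integers(0, 15), fp=st.integers(0, 15),
           tn=st.integers(0, 15), fn=st.integers(0, 15))
    @settings(max_examples=200, derandomize=True)
    def test_complement_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = metrics_from_counts(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        if not np.isnan(m.ppv):
            assert m.fdr == 1 - m.ppv
        if not np.isnan(m.npv):
            assert m.for_rate == 1 - m.npv
        assert m.accuracy == (tp + tn) / (tp + fp + tn + fn)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=1, fn=0)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, pts = roc_auc([0.1, 0.2, 5.0, 6.0], [0, 0, 1, 1])
        assert auc == 1.0
        assert pts.iloc[0].tolist() == [np.inf, 0.0, 0.0]
        assert pts.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(scores, 1 - labels)
        assert a1 + a2 == pytest.approx(1.0)

    def test_ties_against_pair_counting_oracle(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 0, 1, 1, 1])
        auc, _ = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        oracle = np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                          for p in pos for q in neg])
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_auc_equals_trapezoid_of_emitted_points(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = np.round(rng.normal(size=40), 1)  # force ties
            labels = rng.integers(0, 2, size=40)
            if labels.sum() in (0, 40):
                continue
            auc, pts = roc_auc(scores, labels)
            trap = np.trapezoid(pts["tpr"], pts["fpr"])
            assert auc == pytest.approx(trap, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestRepeatedSplitCv:
    def test_single_repeat_equals_its_split(self, small_cohort):
        ds, truth = small_cohort
        scheme = SplitScheme(n_train_pos=10, n_train_neg=8, n_repeats=1, seed=3)
        res = repeated_split_cv(ds, truth.banded_ids, scheme=scheme)
        row = res.per_repeat.iloc[0]
        for key in ("sensitivity", "specificity", "accuracy"):
            assert getattr(res.mean_metrics, key) == row[key]

    def test_same_seed_identical_tables(self, small_cohort):
        ds, truth = small_cohort
        scheme = SplitScheme(n_train_pos=10, n_train_neg=8, n_repeats=25, seed=9)
        r1 = repeated_split_cv(ds, truth.banded_ids, scheme=scheme)
        r2 = repeated_split_cv(ds, truth.banded_ids, scheme=scheme)
        pd.testing.assert_frame_equal(r1.per_repeat, r2.per_repeat)

    def test_repeat_prefix_stability(self, small_cohort):
        """Growing n_repeats must extend, not reshuffle, the repeat table."""
        ds, truth = small_cohort
        short = repeated_split_cv(ds, truth.banded_ids,
                                  scheme=SplitScheme(10, 8, 10, seed=4))
        long = repeated_split_cv(ds, truth.banded_ids,
                                 scheme=SplitScheme(10, 8, 30, seed=4))
        pd.testing.assert_frame_equal(short.per_repeat, long.per_repeat.iloc[:10])

    def test_planted_panel_reaches_high_sensitivity_specificity(self, small_cohort):
        ds, truth = small_cohort
        res = repeated_split_cv(ds, truth.banded_ids,
                                scheme=SplitScheme(10, 8, 200, seed=5))
        assert res.mean_metrics.sensitivity >= 0.9
        assert res.mean_metrics.specificity >= 0.9

    def test_insufficient_class_count_errors(self, small_cohort):
        ds, truth = small_cohort
        with pytest.raises(ValueError, match="positive"):
            repeated_split_cv(ds, truth.banded_ids,
                              scheme=SplitScheme(n_train_pos=100, n_train_neg=2))


class TestCrossCohortValidate:
    def test_same_cohort_equals_resubstitution(self, small_cohort):
        from svmpanel import train_svm
        ds, truth = small_cohort
        metrics, _ = cross_cohort_validate(ds, ds, truth.banded_ids)
        model = train_svm(ds.matrix(truth.banded_ids), ds.binary_labels())
        pred = model.predict(ds.matrix(truth.banded_ids))
        resub = metrics_from_counts(
            counts_from_predictions(ds.binary_labels(), pred))
        assert metrics.accuracy == resub.accuracy

    def test_missing_panel_feature_errors(self, small_cohort):
        ds, truth = small_cohort
        stripped = ds.select_features(
            [f for f in ds.feature_ids if f != truth.banded_ids[0]])
        # also remove its gene so symbol-matching cannot rescue it
        stripped.feature_meta.loc[:, "gene_symbol"] = "X"
        with pytest.raises(ValueError, match="missing"):
            cross_cohort_validate(ds, stripped, truth.banded_ids)

    def test_gene_symbol_matching_across_probe_ids(self, small_spec):
        disc, val, truth = generate_cohort_pair(small_spec, seed=21)
        disc, val = floor_log_transform(disc), floor_log_transform(val)
        metrics, pts = cross_cohort_validate(disc, val, truth.banded_ids)
        assert 0.0 <= metrics.auc <= 1.0
        assert metrics.accuracy > 0.5  # markers transfer despite the shift

    def test_shift_degrades_auc_monotonically(self):
        from svmpanel import CohortShift
        aucs = []
        for scale in (1.0, 1.8, 2.6):
            spec = SyntheticSpec(n_pos=20, n_neg=16, n_noise_features=10,
                                 val_n_pos=20, val_n_neg=24,
                                 cohort_shift=CohortShift(location=0.0, scale=scale))
            disc, val, truth = generate_cohort_pair(spec, seed=33)
            disc, val = floor_log_transform(disc), floor_log_transform(val)
            m, _ = cross_cohort_validate(disc, val, truth.banded_ids)
            aucs.append(m.auc)
        assert aucs[0] >= aucs[1] >= aucs[2]
        assert aucs[0] > aucs[2]


class TestGroupedLoocv:
    def test_identical_groups_equal_accuracy(self):
        rng = np.random.default_rng(2)
        y = np.array([1, 0] * 6)
        X = np.column_stack([np.where(y == 1, 4.0, 0.0) + rng.normal(0, 1, 12)])
        Xdup = np.vstack([X, X])
        ds = make_dataset(Xdup, list(np.where(y == 1, "AD", "CONTROL")) * 2,
                          group=["g1"] * 12 + ["g2"] * 12)
        table = grouped_loocv(ds, ds.feature_ids)
        accs = table.set_index("group")["loocv_accuracy"]
        assert accs["g1"] == accs["g2"]

    def test_underpowered_group_skipped(self):
        ds = make_dataset(np.arange(14, dtype=float).reshape(7, 2),
                          ["AD", "CONTROL", "AD", "CONTROL", "AD", "CONTROL", "AD"],
                          group=["a"] * 6 + ["b"])
        table = grouped_loocv(ds, ds.feature_ids).set_index("group")
        assert table.loc["b", "status"] == "skipped"
        assert np.isnan(table.loc["b", "loocv_accuracy"])
        assert table.loc["a", "status"] == "ok"

    def test_signal_groups_score_highest(self):
        spec = SyntheticSpec(n_pos=30, n_neg=24, n_noise_features=10)
        ds, truth = generate_grouped_cohort(spec, n_groups=4, signal_groups=(0, 1),
                                            seed=13)
        ds = floor_log_transform(ds)
        table = grouped_loocv(ds, truth.banded_ids).set_index("group")
        accs = table["loocv_accuracy"]
        signal = accs[["G1", "G2"]].min()
        background = accs[["G3", "G4"]].max()
        assert signal > background


class TestFitBanded:
    def test_recovers_planted_interval_exactly(self):
        rng = np.random.default_rng(3)
        healthy = rng.uniform(2, 4, size=40)
        ad = np.concatenate([rng.uniform(0, 1, 25), rng.uniform(5, 6, 25)])
        values = np.concatenate([ad, healthy])
        labels = np.array([1] * 50 + [0] * 40)
        fit = fit_banded(values, labels)
        assert fit.interval_accuracy == 1.0
        assert 1.0 < fit.lower < 2.0
        assert 4.0 < fit.upper < 5.0
        assert fit.is_banded

    def test_one_sided_marker_is_not_banded(self):
        rng = np.random.default_rng(4)
        healthy = rng.uniform(0, 2, 30)
        ad = rng.uniform(3, 5, 30)
        fit = fit_banded(np.concatenate([ad, healthy]),
                         np.array([1] * 30 + [0] * 30))
        assert not fit.is_banded
        assert fit.interval_accuracy == fit.best_single_threshold_accuracy
        assert np.isinf(fit.lower)  # one flank is empty

    def test_interval_never_worse_than_single_threshold(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            values = rng.normal(size=30)
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                continue
            fit = fit_banded(values, labels)
            assert fit.interval_accuracy >= fit.best_single_threshold_accuracy - 1e-12

    def test_shuffled_labels_near_majority_rate(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=60)
        labels = np.array([1] * 36 + [0] * 24)
        majority = 36 / 60
        accs = []
        for _ in range(200):
            rng.shuffle(labels)
            accs.append(fit_banded(values, labels).interval_accuracy)
        # overfitting lifts accuracy above majority, but only by a modest margin
        assert majority <= np.mean(accs) < majority + 0.2

    def test_matches_brute_force_search(self):
        rng = np.random.default_rng(7)
        values = np.round(rng.normal(size=18), 1)
        labels = rng.integers(0, 2, size=18)
        labels[:2] = [0, 1]
        fit = fit_banded(values, labels)
        distinct = np.unique(values)
        mids = np.concatenate([[-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]])
        best = -1.0
        for lo in mids:
            for hi in mids:
                if lo > hi:
                    continue
                inside = (values > lo) & (values <= hi)
                best = max(best, np.mean(np.where(inside, labels == 0, labels == 1)))
        assert fit.interval_accuracy == pytest.approx(best, abs=1e-12)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_banded(np.ones(10), np.array([0, 1] * 5))

    def test_radial_svm_beats_single_threshold_on_banded_marker(self):
        """The mechanism that makes two-boundary markers usable: the RBF SVM
        can carve out the healthy interval, a single threshold cannot."""
        rng = np.random.default_rng(8)
        healthy = rng.uniform(2, 4, 40)
        ad = np.concatenate([rng.uniform(0.5, 1.5, 25), rng.uniform(4.5, 5.5, 25)])
        values = np.concatenate([ad, healthy])
        labels = np.array([1] * 50 + [0] * 40)
        fit = fit_banded(values, labels)
        svm_acc = loocv_accuracy(values.reshape(-1, 1), labels)
        assert svm_acc - fit.best_single_threshold_accuracy >= 0.15


class TestPanelCorrelations:
    def test_duplicate_and_negated_features(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=20)
        ds = make_dataset(np.column_stack([base, base, -base]),
                          ["AD", "CONTROL"] * 10)
        corr = panel_correlations(ds, ds.feature_ids)["all"]
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert corr.iloc[0, 2] == pytest.approx(-1.0)

    def test_per_class_strata_present(self, small_cohort):
        ds, truth = small_cohort
        out = panel_correlations(ds, truth.banded_ids)
        assert set(out) == {"all", "AD", "CONTROL"}

    def test_planted_pair_matches_copula_target(self, small_cohort):
        ds, truth = small_cohort
        out = panel_correlations(ds, truth.banded_ids)
        target = truth.expected_ad_correlation.iloc[0, 1]
        assert out["AD"].iloc[0, 1] == pytest.approx(target, abs=0.03)

    def test_zero_variance_feature_gives_nan(self):
        ds = make_dataset(np.column_stack([np.ones(10), np.arange(10.0)]),
                          ["AD", "CONTROL"] * 5)
        corr = panel_correlations(ds, ds.feature_ids)["all"]
        assert np.isnan(corr.iloc[0, 1])
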