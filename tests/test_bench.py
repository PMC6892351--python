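"""Two-class benchmark: metrics convention, CV machinery, classifiers,
published-table audit."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from eegcharge.bench import (AveragedPerceptron, BenchError, ConfusionMatrix,
                             audit_published_benchmark, build_feature_table,
                             confusion_from_predictions, feature_matrix,
                             load_published_benchmark, make_classifier,
                             metrics, run_cv, stratified_kfold)
from eegcharge.simulate import make_charge_cohort

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


class TestMetrics:
    @pytest.mark.parametrize("counts,expected", [
        # published broadband logistic-regression row
        ((55, 32, 39, 16), (0.662, 0.549, 0.709)),
        # published broadband Bayes point machine row
        ((33, 15, 56, 38), (0.627, 0.789, 0.596)),
        ((10, 0, 12, 0), (1.0, 1.0, 1.0)),
    ])
    def test_confusion_arithmetic(self, counts, expected):
        """STD-positive accuracy/recall/precision from the four counts."""
        got = metrics(ConfusionMatrix(*counts)).rounded()
        assert got == expected

    def test_class_totals(self):
        cm = ConfusionMatrix(55, 32, 39, 16)
        assert cm.n_tgt == 71 and cm.n_std == 71 and cm.total == 142

    def test_degenerate_all_tgt_predictor(self):
        # always predicting TGT on balanced data: accuracy .5, recall 0
        y = np.array([0] * 10 + [1] * 10)  # 1 = STD
        cm = confusion_from_predictions(y, np.zeros_like(y))
        m = metrics(cm)
        assert m.accuracy == 0.5
        assert m.recall == 0.0
        assert m.precision is None  # no STD predictions: undefined, not 0

    def test_accuracy_is_weighted_recall(self):
        cm = ConfusionMatrix(41, 29, 42, 30)
        m = metrics(cm)
        rec_tgt = cm.corr_tgt / cm.n_tgt
        assert m.accuracy == pytest.approx(
            (m.recall * cm.n_std + rec_tgt * cm.n_tgt) / cm.total)

    def test_negative_counts_rejected(self):
        with pytest.raises(BenchError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestFeatureTable:
    def test_cohort_yields_142_rows(self):
        tidy = make_charge_cohort(n_subjects=71, seed=0)
        table = build_feature_table(tidy)
        assert len(table) == 142
        assert table["label"].value_counts().to_dict() == {"TGT": 71,
                                                           "STD": 71}

    def test_feature_width_parcels_times_bands(self):
        tidy = make_charge_cohort(n_subjects=2, seed=0)
        table = build_feature_table(tidy)
        n_feat = sum(c.startswith("iota_") for c in table.columns)
        assert n_feat == 12 * 6

    def test_row_order_invariance(self):
        tidy = make_charge_cohort(n_subjects=5, seed=1)
        shuffled = tidy.sample(frac=1.0, random_state=9)
        a = build_feature_table(tidy)
        b = build_feature_table(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_band_rejected(self):
        tidy = make_charge_cohort(n_subjects=2, seed=0)
        broken = tidy[~((tidy.subject == "S001")
                        & (tidy.band == "gamma"))]
        with pytest.raises(BenchError):
            build_feature_table(broken)

    def test_missing_parcel_fills_zero(self):
        tidy = make_charge_cohort(n_subjects=2, seed=0)
        broken = tidy[~((tidy.subject == "S001")
                        & (tidy.parcel == "BA17"))]
        table = build_feature_table(broken,
                                    parcels=tuple(sorted(set(tidy.parcel))))
        row = table[(table.subject == "S001")]
        assert (row[[c for c in table.columns
                     if c.endswith("_BA17")]] == 0).all().all()


class TestStratifiedKFold:
    def test_fold_sizes_142_rows(self):
        tidy = make_charge_cohort(n_subjects=71, seed=0)
        table = build_feature_table(tidy)
        folds = stratified_kfold(table, 5, seed=0)
        sizes = sorted(np.bincount(folds).tolist(), reverse=True)
        assert sizes == [29, 29, 28, 28, 28]

    def test_partition_and_stratification(self):
        tidy = make_charge_cohort(n_subjects=20, seed=2)
        table = build_feature_table(tidy)
        folds = stratified_kfold(table, 5, seed=3)
        assert len(folds) == 40
        _, y = feature_matrix(table)
        for f in range(5):
            counts = np.bincount(y[folds == f], minlength=2)
            assert abs(counts[0] - counts[1]) <= 1

    def test_deterministic_per_seed(self):
        tidy = make_charge_cohort(n_subjects=20, seed=2)
        table = build_feature_table(tidy)
        assert np.array_equal(stratified_kfold(table, 5, 7),
                              stratified_kfold(table, 5, 7))

    def test_k_exceeding_class_rejected(self):
        tidy = make_charge_cohort(n_subjects=3, seed=0)
        with pytest.raises(BenchError):
            stratified_kfold(build_feature_table(tidy), 5, 0)


class TestClassifiers:
    def test_logistic_matches_convex_oracle(self):
        """Elastic-net logistic coefficients vs a generic optimizer."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = (X @ np.array([1.5, -2.0, 0.5])
             + 0.3 * rng.normal(size=20) > 0).astype(int)
        clf = make_classifier("logistic", seed=0, tol=1e-10).fit(X, y)
        w_impl = np.r_[clf.coef_[0], clf.intercept_]

        C, l1r = 5.0, 0.5  # 1/(l1+l2), l1/(l1+l2)
        s = 2 * y - 1

        def objective(p):  # w = u - v with u, v >= 0 handles the L1 term
            u, v, b = p[:3], p[3:6], p[6]
            w = u - v
            loss = np.logaddexp(0, -s * (X @ w + b)).sum()
            return l1r * (u + v).sum() + 0.5 * (1 - l1r) * (w @ w) + C * loss

        res = minimize(objective, np.zeros(7), method="L-BFGS-B",
                       bounds=[(0, None)] * 6 + [(None, None)],
                       options={"ftol": 1e-15, "gtol": 1e-12,
                                "maxiter": 10000})
        w_oracle = np.r_[res.x[:3] - res.x[3:6], res.x[6]]
        assert np.abs(w_impl - w_oracle).max() < 1e-3

    def test_logistic_separable_toy(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        y = np.array([0, 1])
        clf = make_classifier("logistic", seed=0).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_perceptron_separable_toy(self):
        X = np.array([[1., 1.], [2., 2.], [-1., -1.], [-2., -2.]])
        y = np.array([1, 1, 0, 0])
        ap = AveragedPerceptron(seed=0).fit(X, y)
        assert (ap.predict(X) == y).all()

    def test_perceptron_seed_reproducible(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        a = AveragedPerceptron(seed=5).fit(X, y)
        b = AveragedPerceptron(seed=5).fit(X, y)
        assert np.array_equal(a.w_avg_, b.w_avg_)

    def test_perceptron_averaging_reduces_variance(self):
        # across seeds, averaged weights give more stable scores than the
        # last iterate on noisy non-separable data
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] + 0.8 * rng.normal(size=40) > 0).astype(int)
        pts = np.array([[0.3, 0.2], [-0.4, 0.1], [0.1, -0.5]])
        avg_scores, last_scores = [], []
        for seed in range(20):
            m = AveragedPerceptron(seed=seed).fit(X, y)
            avg_scores.append(m._scores(pts, average=True))
            last_scores.append(m._scores(pts, average=False))

        def norm_var(scores):
            arr = np.array(scores)
            return np.var(arr / np.abs(arr).mean(), axis=0).sum()

        assert norm_var(avg_scores) < norm_var(last_scores)

    def test_svm_max_margin_on_square(self):
        # two point pairs at x=0 and x=2: the maximum-margin boundary is
        # the vertical line x=1 (recovered as lambda -> 0)
        X = np.array([[0., 0.], [0., 1.], [2., 0.], [2., 1.]])
        y = np.array([0, 0, 1, 1])
        clf = make_classifier("linear_svm", seed=0, lam=1e-4).fit(X, y)
        w = clf._clf.coef_[0]
        b = clf._clf.intercept_[0]
        assert abs(w[1] / w[0]) < 0.01  # no tilt
        assert -b / w[0] == pytest.approx(1.0, abs=0.01)

    def test_svm_lambda_shrinks_weights(self):
        X = np.array([[0., 0.], [0., 1.], [2., 0.], [2., 1.]])
        y = np.array([0, 0, 1, 1])
        small = make_classifier("linear_svm", seed=0, lam=1.0).fit(X, y)
        large = make_classifier("linear_svm", seed=0, lam=1e3).fit(X, y)
        assert (np.linalg.norm(large._clf.coef_)
                < 0.1 * np.linalg.norm(small._clf.coef_))

    def test_nn_learns_xor(self):
        X = np.array([[0., 0.], [0., 1.], [1., 0.], [1., 1.]])
        y = np.array([0, 1, 1, 0])
        clf = make_classifier("neural_network", seed=0).fit(
            np.tile(X, (25, 1)), np.tile(y, 25))
        assert (clf.predict(X) == y).all()

    def test_nn_seed_reproducible(self):
        X = np.random.default_rng(2).normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        a = make_classifier("neural_network", seed=3).fit(X, y).predict(X)
        b = make_classifier("neural_network", seed=3).fit(X, y).predict(X)
        assert np.array_equal(a, b)


class TestRunCV:
    def test_strong_effect_recovered(self):
        # amygdala reward/punishment difference of 2 sd: logistic CV
        # accuracy stays >= 0.9 across seeds
        for seed in range(3):
            tidy = make_charge_cohort(n_subjects=71, effect_sd=2.0,
                                      seed=seed)
            rep = run_cv(build_feature_table(tidy), "logistic", k=5,
                         seed=seed)
            assert rep.metrics.accuracy >= 0.9

    def test_null_accuracy_near_chance(self):
        for seed in range(5):
            tidy = make_charge_cohort(n_subjects=71, effect_sd=2.0,
                                      seed=seed)
            table = build_feature_table(tidy)
            table["label"] = np.random.default_rng(100 + seed).permutation(
                table["label"].to_numpy())
            rep = run_cv(table, "logistic", k=5, seed=seed)
            assert 0.38 <= rep.metrics.accuracy <= 0.62

    def test_bit_reproducible(self):
        tidy = make_charge_cohort(n_subjects=20, effect_sd=1.0, seed=4)
        table = build_feature_table(tidy)
        a = run_cv(table, "logistic", k=5, seed=11)
        b = run_cv(table, "logistic", k=5, seed=11)
        assert a.cm == b.cm


class TestPublishedAudit:
    def test_all_rows_satisfy_class_totals(self):
        table = load_published_benchmark()
        assert ((table.corr_tgt + table.inc_std) == 71).all()
        assert ((table.corr_std + table.inc_tgt) == 71).all()

    def test_consistent_rows_match_to_three_decimals(self):
        audit = audit_published_benchmark()
        ok = audit[audit.consistent]
        assert len(ok) > 0
        assert np.allclose(ok.acc, ok.acc_rc, atol=5e-4)
        assert np.allclose(ok.recall, ok.recall_rc, atol=5e-4)
        assert np.allclose(ok.prec, ok.prec_rc, atol=5e-4)

    def test_broadband_logistic_row_consistent(self):
        audit = audit_published_benchmark()
        row = audit[(audit.band == "broadband")
                    & (audit.classifier == "Logistic regression")].iloc[0]
        assert row.consistent
        assert (row.acc_rc, row.recall_rc, row.prec_rc) == (0.662, 0.549,
                                                            0.709)

    def test_known_inconsistent_cells_flagged(self):
        # the broadband neural-network accuracy cell duplicates the
        # precision value; the audit must flag it, not reproduce it
        audit = audit_published_benchmark().set_index(["band", "classifier"])
        nn = audit.loc[("broadband", "Neural network")]
        assert not nn.acc_ok
        assert nn.prec_ok and nn.recall_ok
        ap = audit.loc[("broadband", "Avg. perceptron classifier")]
        assert not ap.acc_ok
        assert ap.prec_ok and ap.recall_ok
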