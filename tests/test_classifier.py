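"""Labeling, bundle construction, feature selection, ensemble, metrics."""
from __future__ import annotations

import warnings

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

import iped
from iped._align import ReferenceSet
from iped.classifier import (
    CORRECT,
    ERROR,
    VotingEnsemble,
    dereplicate_instances,
)
from oracles import bf_mcc


def _random_ref(rng, n=100):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLabelByReference:
    def test_identical_contig_all_correct(self, rng):
        ref = _random_ref(rng)
        labels = iped.label_by_reference(ref, [("r", ref)])
        assert labels is not None and not labels.any()

    def test_single_substitution_at_57(self, rng):
        ref = _random_ref(rng)
        alt = "G" if ref[57] != "G" else "T"
        contig = ref[:57] + alt + ref[58:]
        labels = iped.label_by_reference(contig, [("r", ref)])
        assert np.flatnonzero(labels).tolist() == [57]

    def test_insertion_labeled_at_own_position(self, rng):
        ref = _random_ref(rng)
        contig = ref[:40] + "A" + ref[40:]
        # avoid ambiguity: make sure the inserted base differs from neighbours
        if ref[39] == "A" or ref[40] == "A":
            contig = ref[:40] + ("C" if ref[39] != "C" and ref[40] != "C" else "G") + ref[40:]
        labels = iped.label_by_reference(contig, [("r", ref)])
        assert labels.sum() == 1
        assert 38 <= int(np.flatnonzero(labels)[0]) <= 42

    def test_deletion_labels_position_left_of_gap(self, rng):
        ref = _random_ref(rng)
        contig = ref[:40] + ref[41:]
        labels = iped.label_by_reference(contig, [("r", ref)])
        assert labels.sum() == 1
        assert 37 <= int(np.flatnonzero(labels)[0]) <= 41

    def test_low_identity_contig_skipped(self, rng):
        ref = _random_ref(rng)
        junk = _random_ref(rng)  # ~25 % identity in expectation
        assert iped.label_by_reference(junk, [("r", ref)], min_identity=0.9) is None

    def test_best_reference_wins(self, rng):
        ref_a, ref_b = _random_ref(rng), _random_ref(rng)
        refs = ReferenceSet([("a", ref_a), ("b", ref_b)])
        labels = iped.label_by_reference(ref_b, refs)
        assert not labels.any()

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            ReferenceSet([])


class TestBuildTrainingBundle:
    def _data(self, rng, n_err=1000, n_cor=9000, p=4):
        X_err = rng.normal(1.0, 1.0, size=(n_err, p))
        X_cor = rng.normal(-1.0, 1.0, size=(n_cor, p))
        X = np.vstack([X_err, X_cor])
        y = np.concatenate([np.ones(n_err, np.int8), np.zeros(n_cor, np.int8)])
        return X, y

    def test_subset_a_respects_ratio(self, rng):
        X, y = self._data(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = iped.build_training_bundle(X, y, ratio_a="1:3", seed=1)
        n_err, n_cor = bundle.class_counts()["a"]
        assert abs(n_cor - 3 * n_err) <= 3

    def test_subset_b_balanced(self, rng):
        X, y = self._data(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = iped.build_training_bundle(X, y, seed=1)
        n_err, n_cor = bundle.class_counts()["b"]
        assert n_err == n_cor > 0

    def test_same_seed_identical(self, rng):
        X, y = self._data(rng, 400, 2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1 = iped.build_training_bundle(X, y, seed=9)
            b2 = iped.build_training_bundle(X, y, seed=9)
        np.testing.assert_array_equal(b1.X_a, b2.X_a)
        np.testing.assert_array_equal(b1.y_c, b2.y_c)

    def test_caps_warning_when_scarce(self, rng):
        X, y = self._data(rng, 100, 1000)
        with pytest.warns(UserWarning, match="achievable"):
            iped.build_training_bundle(X, y, seed=0)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(50, 3))
        with pytest.raises(ValueError):
            iped.build_training_bundle(X, np.zeros(50, np.int8))

    def test_dereplication_collapses_duplicates(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        y = np.array([1, 1, 0], np.int8)
        Xd, yd = dereplicate_instances(X, y)
        assert Xd.shape[0] == 2


class TestSelectFeatures:
    def test_label_copy_dominates(self, rng):
        y = rng.integers(0, 2, size=1000).astype(np.int8)
        X = np.column_stack([y.astype(float), rng.normal(size=(1000, 4))])
        assert iped.select_features(X, y, seed=0) == [0]

    def test_duplicate_informative_feature_selected_once(self, rng):
        y = rng.integers(0, 2, size=1000).astype(np.int8)
        signal = y + rng.normal(0, 0.5, size=1000)
        X = np.column_stack([signal, signal, rng.normal(size=1000)])
        chosen = iped.select_features(X, y, seed=0)
        assert len([j for j in chosen if j in (0, 1)]) <= 1

    def test_pure_noise_selects_nothing_informative(self, rng):
        y = rng.integers(0, 2, size=1000).astype(np.int8)
        X = rng.normal(size=(1000, 5))
        chosen = iped.select_features(X, y, seed=0)
        assert len(chosen) <= 1  # chance-level correlations stay out

    def test_names_returned_when_given(self, rng):
        y = rng.integers(0, 2, size=500).astype(np.int8)
        X = np.column_stack([y.astype(float), rng.normal(size=500)])
        assert iped.select_features(X, y, seed=0, names=["copy", "noise"]) == ["copy"]


def _blob_bundle(rng, n=200, p=4):
    X_err = rng.normal(3.0, 0.3, size=(n // 2, p))
    X_cor = rng.normal(-3.0, 0.3, size=(n // 2, p))
    # margin check: the blobs are linearly separable by construction
    assert X_err.min() > X_cor.max()
    X = np.vstack([X_err, X_cor])
    y = np.concatenate([np.ones(n // 2, np.int8), np.zeros(n // 2, np.int8)])
    order = rng.permutation(n)
    X, y = X[order], y[order]
    half = n // 2
    return iped.TrainingBundle(
        X[:half], y[:half], X[half:], y[half:], X[half:], y[half:],
        feature_names=tuple(f"f{i}" for i in range(p)),
    )


class TestVotingEnsemble:
    def test_separable_blobs_perfect_accuracy(self, rng):
        bundle = _blob_bundle(rng)
        model = iped.train_ensemble(bundle, seed=3)
        assert (model.predict(bundle.X_a) == bundle.y_a).all()
        assert (model.predict(bundle.X_b) == bundle.y_b).all()

    def test_determinism(self, rng):
        bundle = _blob_bundle(rng)
        m1 = iped.train_ensemble(bundle, seed=5)
        m2 = iped.train_ensemble(bundle, seed=5)
        np.testing.assert_array_equal(
            m1.error_confidence(bundle.X_c), m2.error_confidence(bundle.X_c)
        )

    def test_plurality_takes_highest_confidence(self):
        class Stub:
            classes_ = np.array([0, 1])

            def __init__(self, p_error):
                self.p = p_error

            def predict_proba(self, X):
                return np.tile([1 - self.p, self.p], (len(X), 1))

        # MLP-like member says ERROR at 0.9, forest-like says CORRECT at 0.6
        ens = VotingEnsemble(
            members=[("a", Stub(0.9)), ("b", Stub(0.4))], feature_names=("x",)
        )
        X = np.zeros((3, 1))
        assert (ens.predict(X) == ERROR).all()
        # both members CORRECT -> unmasked
        ens2 = VotingEnsemble(
            members=[("a", Stub(0.2)), ("b", Stub(0.4))], feature_names=("x",)
        )
        assert (ens2.predict(X) == CORRECT).all()
        # exact tie resolves to CORRECT (conservative: no masking)
        ens3 = VotingEnsemble(members=[("a", Stub(0.5))], feature_names=("x",))
        assert (ens3.predict(X) == CORRECT).all()

    def test_duplicate_member_equals_single(self, rng):
        bundle = _blob_bundle(rng)
        model = iped.train_ensemble(bundle, seed=2)
        single = VotingEnsemble([model.members[1]], model.feature_names)
        double = VotingEnsemble(
            [model.members[1], model.members[1]], model.feature_names
        )
        np.testing.assert_array_equal(
            single.predict(bundle.X_c), double.predict(bundle.X_c)
        )

    def test_threshold_extremes(self, rng):
        bundle = _blob_bundle(rng)
        model = iped.train_ensemble(bundle, seed=2)
        all_mask = iped.predict_mask(model, bundle.X_b, threshold=0.0)
        none_mask = iped.predict_mask(model, bundle.X_b, threshold=1.01)
        assert all_mask.sum() == (model.predict(bundle.X_b) == ERROR).sum()
        assert not none_mask.any()

    def test_feature_width_mismatch_rejected(self, rng):
        bundle = _blob_bundle(rng)
        model = iped.train_ensemble(bundle, seed=2)
        with pytest.raises(ValueError, match="feature width"):
            model.predict(np.zeros((3, 7)))

    def test_save_load_roundtrip(self, tmp_path, rng):
        bundle = _blob_bundle(rng)
        model = iped.train_ensemble(bundle, seed=2)
        model.save(tmp_path / "model")
        back = VotingEnsemble.load(tmp_path / "model")
        np.testing.assert_array_equal(
            model.error_confidence(bundle.X_c), back.error_confidence(bundle.X_c)
        )
        assert back.feature_names == model.feature_names

    def test_non_finite_features_rejected(self, rng):
        bundle = _blob_bundle(rng)
        bundle.X_a[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            iped.train_ensemble(bundle, seed=2)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        truth = np.array([1, 0, 1, 0, 1])
        m = iped.confusion_metrics(truth, truth)
        assert (m.sensitivity, m.specificity, m.mcc) == (1.0, 1.0, 1.0)

    def test_printed_formula_example(self):
        # TP=5 TN=15 FP=1 FN=4 -> MCC = 71/sqrt(6*9*16*19)
        pred = [1] * 5 + [0] * 15 + [1] * 1 + [0] * 4
        truth = [1] * 5 + [0] * 15 + [0] * 1 + [1] * 4
        m = iped.confusion_metrics(pred, truth)
        assert (m.tp, m.tn, m.fp, m.fn) == (5, 15, 1, 4)
        assert m.mcc == pytest.approx(71 / np.sqrt(6 * 9 * 16 * 19))
        assert m.mcc == pytest.approx(0.554, abs=5e-4)

    def test_all_correct_prediction_zero_convention(self):
        truth = np.array([1, 1, 0, 0])
        m = iped.confusion_metrics(np.zeros(4), truth)
        assert m.tp == 0 and m.mcc == 0.0

    def test_matches_sklearn_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 60))
            pred = rng.integers(0, 2, n)
            truth = rng.integers(0, 2, n)
            m = iped.confusion_metrics(pred, truth)
            assert m.mcc == pytest.approx(bf_mcc(pred, truth))
            if len(np.unique(truth)) == 2 and len(np.unique(pred)) == 2:
                assert m.mcc == pytest.approx(matthews_corrcoef(truth, pred))


class TestRocCurve:
    def test_perfect_and_inverted(self):
        truth = np.array([0, 0, 1, 1])
        conf = np.array([0.1, 0.2, 0.8, 0.9])
        assert iped.roc_curve(conf, truth)[3] == 1.0
        assert iped.roc_curve(1 - conf, truth)[3] == 0.0

    def test_inversion_symmetry(self, rng):
        truth = rng.integers(0, 2, 500)
        conf = rng.random(500)
        auc = iped.roc_curve(conf, truth)[3]
        auc_inv = iped.roc_curve(1 - conf, truth)[3]
        assert auc + auc_inv == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            iped.roc_curve([0.1, 0.9], [1, 1])

    def test_monotone_from_origin_to_one(self, rng):
        truth = rng.integers(0, 2, 200)
        fpr, tpr, _, _ = iped.roc_curve(rng.random(200), truth)
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
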