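"""Model training, probability ranking and the directional replacement rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.ensemble import RandomForestClassifier

from conftest import perfect_model
from ffqadjust.error_adjust import (
    CONSERVATIVE,
    DIRECTIONAL_ARGMAX,
    OVERREPORT,
    UNDERREPORT,
    AdjustmentPolicy,
    CategoryProbabilities,
    TrainedResponseModel,
    adjust_dataset,
    adjust_response,
    predict_probabilities,
    tune_and_train,
)


def probs_from(mapping, reported):
    cats = np.array(list(mapping))
    ps = np.array([mapping[c] for c in cats], dtype=float)
    return CategoryProbabilities.from_vector(cats, ps, reported=reported)


class TestCategoryProbabilities:
    def test_sorted_descending_with_ascending_category_ties(self):
        cp = CategoryProbabilities.from_vector([3, 1, 2, 4], [0.2, 0.3, 0.3, 0.2])
        np.testing.assert_array_equal(cp.categories, [1, 2, 3, 4])
        np.testing.assert_allclose(cp.probabilities, [0.3, 0.3, 0.2, 0.2])

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CategoryProbabilities(np.array([1, 2]), np.array([0.6, 0.5]))


class TestTuneAndTrain:
    def test_same_seed_identical_cv_table(self, corrupted_small):
        data, _ = corrupted_small
        t = data.trusted_mask
        kwargs = dict(depth_grid=[2, 4], cv_folds=3, seed=5, n_estimators=30)
        a = tune_and_train(data.features[t], data.true_labels[t], **kwargs)
        b = tune_and_train(data.features[t], data.true_labels[t], **kwargs)
        pd.testing.assert_frame_equal(a.cv_table, b.cv_table)
        assert a.best_depth == b.best_depth

    def test_single_class_predicts_it_with_certainty(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        model = tune_and_train(X, np.full(20, 4), depth_grid=[1, 2], n_estimators=10)
        probs = predict_probabilities(model, X[:5])
        for p in probs:
            assert p.top_category == 4
            assert p.probabilities[0] == 1.0

    def test_rare_category_reduces_folds_with_warning(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(33, 2))
        y = np.array([1] * 15 + [2] * 15 + [3] * 3)
        X[y == 2] += 3
        X[y == 3] += 6
        with pytest.warns(UserWarning, match="reducing to 3 folds"):
            model = tune_and_train(X, y, depth_grid=[2], cv_folds=5, n_estimators=10)
        assert model.cv_folds == 3

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            tune_and_train(np.empty((0, 2)), np.empty(0))

    def test_depth_grid_must_be_positive(self):
        with pytest.raises(ValueError, match="depth"):
            tune_and_train(np.zeros((4, 1)), [1, 1, 2, 2], depth_grid=[0, 2])

    def test_probabilities_sum_to_one_over_training_categories(self, corrupted_small):
        data, _ = corrupted_small
        t = data.trusted_mask
        model = tune_and_train(
            data.features[t], data.true_labels[t], depth_grid=[4], n_estimators=30
        )
        probs = predict_probabilities(model, data.features[~t][:20])
        for p in probs:
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(np.diff(p.probabilities) <= 1e-12)
            assert set(p.categories) == set(model.categories)

    def test_schema_mismatch_names_columns(self, corrupted_small):
        data, _ = corrupted_small
        t = data.trusted_mask
        cols = [f"f{i}" for i in range(data.n_features)]
        model = tune_and_train(
            pd.DataFrame(data.features[t], columns=cols),
            data.true_labels[t],
            depth_grid=[3],
            n_estimators=10,
        )
        bad = pd.DataFrame(data.features[:3, :-1], columns=cols[:-1]).assign(extra=1.0)
        with pytest.raises(ValueError, match="f4.*extra|extra.*f4"):
            predict_probabilities(model, bad)

    def test_save_load_round_trip(self, corrupted_small, tmp_path):
        data, _ = corrupted_small
        t = data.trusted_mask
        model = tune_and_train(
            data.features[t], data.true_labels[t], depth_grid=[3, 5], n_estimators=20
        )
        model.save(tmp_path / "model.joblib")
        back = TrainedResponseModel.load(tmp_path / "model.joblib")
        np.testing.assert_array_equal(back.categories, model.categories)
        assert back.best_depth == model.best_depth
        np.testing.assert_allclose(
            back.classifier.predict_proba(data.features[:10]),
            model.classifier.predict_proba(data.features[:10]),
        )


class TestStumpOracle:
    def test_single_tree_depth_one_matches_hand_rolled_stump(self):
        # A depth-1, single-tree, no-bootstrap forest is just a decision
        # stump: its predicted probabilities must equal the leaf class
        # frequencies of the best Gini split found by exhaustive search.
        X = np.arange(1, 11, dtype=float).reshape(-1, 1)
        y = np.array([1, 1, 1, 1, 2, 2, 2, 3, 3, 3])

        def gini(labels):
            _, counts = np.unique(labels, return_counts=True)
            f = counts / counts.sum()
            return 1.0 - np.sum(f**2)

        best = None
        xs = np.sort(X[:, 0])
        for thr in (xs[:-1] + xs[1:]) / 2:
            left, right = y[X[:, 0] <= thr], y[X[:, 0] > thr]
            score = (len(left) * gini(left) + len(right) * gini(right)) / len(y)
            if best is None or score < best[0]:
                best = (score, thr, left, right)
        _, thr, left, right = best
        cats = np.array([1, 2, 3])

        def leaf_freq(labels):
            return np.array([(labels == c).mean() for c in cats])

        clf = RandomForestClassifier(
            n_estimators=1, max_depth=1, bootstrap=False, max_features=None, random_state=0
        ).fit(X, y)
        model = TrainedResponseModel(
            classifier=clf,
            categories=cats,
            best_depth=1,
            cv_folds=2,
            n_estimators=1,
            cv_table=pd.DataFrame({"depth": [1], "cv_accuracy": [np.nan]}),
            training_accuracy=float(clf.score(X, y)),
        )
        for probe in [2.0, 7.0, 9.5]:
            expected = leaf_freq(left if probe <= thr else right)
            got = predict_probabilities(model, [[probe]])[0]
            for c, e in zip(cats, expected):
                assert got.probability_of(c) == pytest.approx(e)


class TestAdjustResponse:
    def test_conservative_replaces_when_top_exceeds_report(self):
        cp = probs_from({2: 0.5, 3: 0.4, 1: 0.1}, reported=1)
        rec = adjust_response(cp, AdjustmentPolicy(UNDERREPORT, CONSERVATIVE))
        assert rec.adjusted == 2 and rec.changed

    def test_conservative_keeps_when_top_below_report(self):
        cp = probs_from({2: 0.6, 1: 0.25, 3: 0.15}, reported=3)
        rec = adjust_response(cp, AdjustmentPolicy(UNDERREPORT, CONSERVATIVE))
        assert rec.adjusted == 3 and not rec.changed

    def test_directional_argmax_takes_best_higher_category(self):
        cp = probs_from({1: 0.5, 4: 0.3, 3: 0.2}, reported=2)
        rec = adjust_response(cp, AdjustmentPolicy(UNDERREPORT, DIRECTIONAL_ARGMAX))
        assert rec.adjusted == 4

    @pytest.mark.parametrize("mode", [CONSERVATIVE, DIRECTIONAL_ARGMAX])
    @pytest.mark.parametrize("direction", [UNDERREPORT, OVERREPORT])
    def test_agreement_case_unchanged(self, mode, direction):
        cp = probs_from({3: 0.7, 2: 0.2, 4: 0.1}, reported=3)
        assert adjust_response(cp, AdjustmentPolicy(direction, mode)).adjusted == 3

    def test_overreport_mirrors(self):
        cp = probs_from({2: 0.5, 3: 0.4, 1: 0.1}, reported=3)
        rec = adjust_response(cp, AdjustmentPolicy(OVERREPORT, CONSERVATIVE))
        assert rec.adjusted == 2

    def test_tie_breaks_toward_category_nearest_report(self):
        cp = probs_from({2: 0.4, 5: 0.4, 1: 0.2}, reported=1)
        rec = adjust_response(cp, AdjustmentPolicy(UNDERREPORT, DIRECTIONAL_ARGMAX))
        assert rec.adjusted == 2

    def test_probability_floor_blocks_weak_evidence(self):
        cp = probs_from({1: 0.9, 3: 0.1}, reported=2)
        low = AdjustmentPolicy(UNDERREPORT, DIRECTIONAL_ARGMAX, probability_floor=0.2)
        assert adjust_response(cp, low).adjusted == 2
        assert (
            adjust_response(cp, AdjustmentPolicy(UNDERREPORT, DIRECTIONAL_ARGMAX)).adjusted
            == 3
        )

    def test_missing_reported_raises(self):
        cp = probs_from({1: 0.5, 2: 0.5}, reported=None)
        with pytest.raises(ValueError, match="C_R"):
            adjust_response(cp, AdjustmentPolicy())

    @settings(derandomize=True, max_examples=200)
    @given(
        raw=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=7),
        reported_idx=st.integers(0, 6),
        direction=st.sampled_from([UNDERREPORT, OVERREPORT]),
        mode=st.sampled_from([CONSERVATIVE, DIRECTIONAL_ARGMAX]),
    )
    def test_monotone_in_the_policy_direction(self, raw, reported_idx, direction, mode):
        ps = np.array(raw) / np.sum(raw)
        cats = np.arange(1, len(ps) + 1)
        reported = int(cats[reported_idx % len(cats)])
        cp = CategoryProbabilities.from_vector(cats, ps, reported=reported)
        rec = adjust_response(cp, AdjustmentPolicy(direction, mode))
        if direction == UNDERREPORT:
            assert rec.adjusted >= reported
        else:
            assert rec.adjusted <= reported
        assert rec.adjusted in cats


class TestAdjustDataset:
    def test_perfect_model_true_reports_unchanged(self):
        cats = [1, 2, 3, 4]
        model = perfect_model(cats)
        true = np.array([1, 2, 3, 4, 2, 3])
        X = true.reshape(-1, 1).astype(float)
        adjusted, log = adjust_dataset(model, X, true)
        np.testing.assert_array_equal(adjusted, true)
        assert not log["changed"].any()

    def test_empty_input(self):
        model = perfect_model([1, 2])
        adjusted, log = adjust_dataset(model, np.empty((0, 1)), np.empty(0, dtype=int))
        assert len(adjusted) == 0 and len(log) == 0

    def test_row_order_preserved_and_permutation_invariant(self, corrupted_small):
        data, _ = corrupted_small
        t, u = data.trusted_mask, data.untrusted_mask
        model = tune_and_train(
            data.features[t], data.true_labels[t], depth_grid=[6], n_estimators=50, seed=2
        )
        X, rep = data.features[u], data.reported_labels[u]
        adjusted, log = adjust_dataset(model, X, rep)
        assert len(log) == len(rep)
        np.testing.assert_array_equal(log["reported"], rep)
        perm = np.random.default_rng(3).permutation(len(rep))
        adjusted_perm, _ = adjust_dataset(model, X[perm], rep[perm])
        np.testing.assert_array_equal(adjusted_perm, adjusted[perm])

    def test_conservative_idempotent_on_real_model(self, corrupted_small):
        data, _ = corrupted_small
        t, u = data.trusted_mask, data.untrusted_mask
        model = tune_and_train(
            data.features[t], data.true_labels[t], depth_grid=[6], n_estimators=50, seed=2
        )
        once, _ = adjust_dataset(model, data.features[u], data.reported_labels[u])
        twice, _ = adjust_dataset(model, data.features[u], once)
        np.testing.assert_array_equal(once, twice)
        assert np.all(once >= data.reported_labels[u])
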