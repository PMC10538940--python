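"""Uniform train/score contract, similarity baseline, and ensembles."""

import numpy as np
import pytest

from vscreen.fingerprints import Fingerprint, to_dense_matrix
from vscreen.metrics import RankedScores, normalized_enrichment_factor, roc_auc
from vscreen.models import (
    EcdfNormalizer,
    MaxVoteModel,
    ModelSpec,
    SimilarityBaselineModel,
    load_model,
    max_vote_ensemble,
    rank_normalize,
    save_model,
    score_compounds,
    similarity_baseline_score,
    stacked_ensemble,
    train_model,
)


def separable_toy(n=60, n_bits=64, seed=0):
    """Actives have bits {0..7}, inactives bits {40..47}, plus noise."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, n_bits), dtype=np.uint8)
    y = np.zeros(n, dtype=np.int64)
    for i in range(n):
        active = i < n // 3
        base = range(0, 8) if active else range(40, 48)
        X[i, list(base)] = 1
        X[i, rng.choice(np.arange(16, 36), 3, replace=False)] = 1
        y[i] = int(active)
    return X, y


class TestTrainModel:
    def test_rf_separable_training_auc_is_one(self):
        X, y = separable_toy()
        model = train_model(ModelSpec("RF-C", {"n_estimators": 20}), X, y, seed=1)
        rs = score_compounds(model, [f"c{i}" for i in range(len(y))], X)
        assert roc_auc(rs, {f"c{i}": bool(v) for i, v in enumerate(y)}) == 1.0

    @pytest.mark.parametrize("cls,hp", [
        ("RF-C", {"n_estimators": 10}),
        ("XGB-C", {"n_estimators": 10, "max_depth": 3}),
        ("XGB-R", {"n_estimators": 10, "max_depth": 3}),
        ("NN-C", {"hidden_layer_sizes": (8,), "max_iter": 10}),
        ("NN-R", {"hidden_layer_sizes": (8,), "max_iter": 10}),
        ("similarity", {}),
    ])
    def test_same_spec_and_seed_reproduce_identical_scores(self, cls, hp):
        X, y = separable_toy()
        spec = ModelSpec(cls, hp)
        target = y.astype(float) * 80.0 if spec.task == "regression" else y
        a = train_model(spec, X, target, seed=7).predict_scores(X)
        b = train_model(spec, X, target, seed=7).predict_scores(X)
        np.testing.assert_array_equal(a, b)

    def test_regression_on_constant_target_predicts_constant(self):
        X, _ = separable_toy()
        y = np.full(X.shape[0], 12.5)
        model = train_model(ModelSpec("XGB-R", {"n_estimators": 10}), X, y, seed=0)
        preds = model.predict_scores(X)
        assert np.allclose(preds, preds[0], atol=1e-3)

    def test_single_class_training_rejected(self):
        X, _ = separable_toy()
        with pytest.raises(ValueError, match="single-class"):
            train_model(ModelSpec("RF-C"), X, np.zeros(X.shape[0]), seed=0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("SVM-C")


class TestScoreCompounds:
    def test_score_independent_of_input_order(self):
        X, y = separable_toy()
        model = train_model(ModelSpec("RF-C", {"n_estimators": 15}), X, y, seed=2)
        ids = [f"c{i}" for i in range(len(y))]
        fwd = score_compounds(model, ids, X).as_mapping()
        rev = score_compounds(model, ids[::-1], X[::-1]).as_mapping()
        assert fwd == rev

    def test_equal_scores_ordered_by_id(self):
        rs = RankedScores.from_arrays(["z", "a"], [0.7, 0.7])
        assert rs.ranked_ids() == ["a", "z"]

    def test_width_mismatch_rejected(self):
        X, y = separable_toy(n_bits=64)
        model = train_model(ModelSpec("RF-C", {"n_estimators": 5}), X, y, seed=0)
        with pytest.raises(ValueError, match="width"):
            model.predict_scores(np.zeros((3, 128), dtype=np.uint8))


class TestSimilarityBaseline:
    def test_query_equal_to_an_active_scores_one(self):
        actives = [Fingerprint((1, 2, 3), 64), Fingerprint((9, 10), 64)]
        assert similarity_baseline_score(Fingerprint((9, 10), 64), actives) == 1.0

    def test_maximum_over_actives(self):
        q = Fingerprint((0, 1, 2, 3, 4), 64)
        actives = [
            Fingerprint((0, 50, 51, 52), 64),      # sim 1/8
            Fingerprint((0, 1, 2, 3, 4, 5, 6), 64),  # sim 5/7
            Fingerprint((0, 1, 40, 41), 64),       # sim 2/7
        ]
        assert similarity_baseline_score(q, actives) == pytest.approx(5 / 7)

    def test_no_shared_bits_scores_zero(self):
        assert similarity_baseline_score(
            Fingerprint((1,), 64), [Fingerprint((2,), 64)]
        ) == 0.0

    def test_empty_active_set_rejected(self):
        with pytest.raises(ValueError):
            similarity_baseline_score(Fingerprint((1,), 64), [])

    def test_training_ignores_inactives(self):
        X, y = separable_toy()
        model = train_model(ModelSpec("similarity"), X, y, seed=0)
        only_actives = SimilarityBaselineModel(X[y.astype(bool)])
        np.testing.assert_allclose(model.predict_scores(X), only_actives.predict_scores(X))


class TestMaxVote:
    def test_elementwise_maximum(self):
        m1 = RankedScores.from_arrays(["a", "b"], [0.1, 0.9])
        m2 = RankedScores.from_arrays(["a", "b"], [0.5, 0.2])
        out = max_vote_ensemble([m1, m2])
        assert out.as_mapping() == {"a": 0.5, "b": 0.9}

    def test_single_member_is_identity(self):
        m = RankedScores.from_arrays(["a", "b"], [0.3, 0.6])
        assert max_vote_ensemble([m]).as_mapping() == m.as_mapping()

    def test_dominated_member_changes_nothing(self):
        m1 = RankedScores.from_arrays(["a", "b"], [0.8, 0.9])
        dominated = RankedScores.from_arrays(["a", "b"], [0.1, 0.2])
        assert max_vote_ensemble([m1, dominated]).as_mapping() == m1.as_mapping()

    def test_identical_members_equal_the_member(self):
        m = RankedScores.from_arrays(["a", "b", "c"], [0.2, 0.5, 0.1])
        assert max_vote_ensemble([m, m, m]).as_mapping() == m.as_mapping()

    def test_mismatched_compound_sets_rejected(self):
        m1 = RankedScores.from_arrays(["a"], [0.1])
        m2 = RankedScores.from_arrays(["b"], [0.1])
        with pytest.raises(ValueError):
            max_vote_ensemble([m1, m2])


class TestNormalization:
    def test_ecdf_is_monotone_and_unit_range(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=200) * 50
        norm = EcdfNormalizer(ref)
        xs = np.sort(rng.normal(size=100) * 50)
        out = norm(xs)
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_rank_normalize_preserves_order(self):
        rs = RankedScores.from_arrays(["a", "b", "c"], [30.0, -5.0, 90.0])
        out = rank_normalize(rs)
        assert out.ranked_ids() == rs.ranked_ids()


class TestStackedEnsemble:
    def _fold_setup(self, seed=0):
        X, y = separable_toy(n=200, seed=seed)
        y_reg = y * 70.0 + np.random.default_rng(seed).normal(0, 5, len(y))
        rng = np.random.default_rng(seed + 1)
        fold_of = rng.integers(0, 10, len(y))
        return X, y, y_reg, fold_of

    def test_single_base_with_monotone_meta_preserves_nef(self):
        X, y, y_reg, fold_of = self._fold_setup()
        base_spec = ModelSpec("RF-C", {"n_estimators": 20})
        stacked = stacked_ensemble([base_spec], X, y, y_reg, fold_of, seed=3)
        # independent reference: the base model retrained on folds 0-8
        mask = fold_of <= 8
        base = train_model(base_spec, X[mask], y[mask], seed=3)
        test = fold_of == 9
        ids = [f"c{i}" for i in np.flatnonzero(test)]
        labels = {cid: bool(v) for cid, v in zip(ids, y[test])}
        rs_base = RankedScores.from_arrays(ids, base.predict_scores(X[test]))
        rs_stack = RankedScores.from_arrays(ids, stacked.predict_scores(X[test]))
        assert rs_base.ranked_ids() == rs_stack.ranked_ids()
        assert normalized_enrichment_factor(
            rs_base, labels, 0.1
        ) == normalized_enrichment_factor(rs_stack, labels, 0.1)

    def test_informative_bases_give_perfect_test_auc(self):
        X, y, y_reg, fold_of = self._fold_setup(seed=2)
        specs = [ModelSpec("RF-C", {"n_estimators": 20}),
                 ModelSpec("XGB-R", {"n_estimators": 10, "max_depth": 3})]
        stacked = stacked_ensemble(specs, X, y, y_reg, fold_of, seed=5)
        test = fold_of == 9
        ids = [f"c{i}" for i in np.flatnonzero(test)]
        rs = RankedScores.from_arrays(ids, stacked.predict_scores(X[test]))
        assert roc_auc(rs, {cid: bool(v) for cid, v in zip(ids, y[test])}) == 1.0

    def test_fixed_seed_reproducible(self):
        X, y, y_reg, fold_of = self._fold_setup(seed=3)
        specs = [ModelSpec("RF-C", {"n_estimators": 10}),
                 ModelSpec("NN-C", {"hidden_layer_sizes": (8,), "max_iter": 10})]
        a = stacked_ensemble(specs, X, y, y_reg, fold_of, seed=11).predict_scores(X)
        b = stacked_ensemble(specs, X, y, y_reg, fold_of, seed=11).predict_scores(X)
        np.testing.assert_array_equal(a, b)

    def test_missing_folds_rejected(self):
        X, y, y_reg, _ = self._fold_setup()
        fold_of = np.zeros(len(y), dtype=int)  # only fold 0 present
        with pytest.raises(ValueError, match="fold"):
            stacked_ensemble([ModelSpec("RF-C")], X, y, y_reg, fold_of, seed=0)


class TestMaxVoteModel:
    def test_regression_member_normalized_before_voting(self):
        X, y = separable_toy(n=100, seed=5)
        y_reg = y * 70.0
        rf = train_model(ModelSpec("RF-C", {"n_estimators": 10}), X, y, seed=0)
        xgbr = train_model(ModelSpec("XGB-R", {"n_estimators": 10}), X, y_reg, seed=0)
        norm = EcdfNormalizer(xgbr.predict_scores(X))
        ens = MaxVoteModel([(rf, None), (xgbr, norm)])
        out = ens.predict_scores(X)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestModelStore:
    def test_save_load_roundtrip_preserves_scores(self, tmp_path):
        X, y = separable_toy()
        model = train_model(ModelSpec("RF-C", {"n_estimators": 10}), X, y, seed=1)
        save_model(tmp_path / "artifact", model, {"radius": 2, "n_bits": 64})
        loaded = load_model(tmp_path / "artifact")
        np.testing.assert_array_equal(loaded.predict_scores(X), model.predict_scores(X))
        assert (tmp_path / "artifact" / "spec.json").exists()
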