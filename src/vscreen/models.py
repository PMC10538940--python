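"""Model zoo: a uniform train/score contract over five supervised model
classes, a similarity baseline, and two ensembles.

Model classes follow the -C / -R naming convention: classification variants
predict the probability that a compound is active, regression variants
predict continuous % inhibition.  All models consume binary Morgan
fingerprint matrices and emit one score per compound; higher is more likely
active.  Classes:

* ``RF-C``  random forest classifier (no RF-R: regression forests grow
  impractically large on sparse fingerprints and are excluded by design)
* ``XGB-C`` / ``XGB-R``  gradient-boosted trees
* ``NN-C`` / ``NN-R``  fully connected multilayer perceptrons
* ``similarity``  maximum Tanimoto similarity to the training actives
  (ignores every inactive)
* ``max-vote-ensemble`` / ``stacked-ensemble``  combinations of base models

Regression members of ensembles score on the % inhibition scale, which is
not comparable to probabilities; they are mapped onto [0, 1] through a
*frozen* empirical-CDF rank normalizer fit on training-set predictions, so
the mapping is monotone and per-compound deterministic (a compound's
normalized score never depends on which batch it is scored in).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier, MLPRegressor
from xgboost import XGBClassifier, XGBRegressor

from .fingerprints import Fingerprint, bulk_tanimoto_similarity, to_dense_matrix
from .metrics import RankedScores

CLASSIFICATION_CLASSES = ("RF-C", "XGB-C", "NN-C")
REGRESSION_CLASSES = ("XGB-R", "NN-R")
BASE_MODEL_CLASSES = CLASSIFICATION_CLASSES + REGRESSION_CLASSES
ENSEMBLE_CLASSES = ("max-vote-ensemble", "stacked-ensemble")
ALL_MODEL_CLASSES = BASE_MODEL_CLASSES + ("similarity",) + ENSEMBLE_CLASSES

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "train_model",
    "score_compounds",
    "similarity_baseline_score",
    "SimilarityBaselineModel",
    "EcdfNormalizer",
    "rank_normalize",
    "max_vote_ensemble",
    "MaxVoteModel",
    "stacked_ensemble",
    "StackedModel",
    "DEFAULT_GRIDS",
    "save_model",
    "load_model",
]


def task_of(model_class: str) -> str:
    if model_class in CLASSIFICATION_CLASSES or model_class in (
        "similarity",
        "max-vote-ensemble",
        "stacked-ensemble",
    ):
        return "classification"
    if model_class in REGRESSION_CLASSES:
        return "regression"
    raise ValueError(f"unknown model class {model_class!r}")


@dataclass(frozen=True)
class ModelSpec:
    """One model class + hyperparameter setting, identified within its class
    by an integer ``hyperparameter_id``.

    ``hyperparameters`` may be given as a mapping; it is stored as a
    key-sorted tuple of pairs so specs are hashable and comparable.
    """

    model_class: str
    hyperparameters: tuple[tuple[str, object], ...] = ()
    hyperparameter_id: int = 0

    def __post_init__(self) -> None:
        if self.model_class not in ALL_MODEL_CLASSES:
            raise ValueError(f"unknown model class {self.model_class!r}")
        hp = self.hyperparameters
        if isinstance(hp, Mapping):
            hp = tuple(sorted(hp.items(), key=lambda kv: kv[0]))
        else:
            hp = tuple(sorted(tuple(hp), key=lambda kv: kv[0]))
        object.__setattr__(self, "hyperparameters", hp)

    @property
    def hp(self) -> dict[str, object]:
        return dict(self.hyperparameters)

    @property
    def task(self) -> str:
        return task_of(self.model_class)

    @property
    def name(self) -> str:
        return f"{self.model_class}#{self.hyperparameter_id}"


class TrainedModel:
    """Uniform scoring surface: ``predict_scores(X) -> np.ndarray``."""

    spec: ModelSpec
    seed: int
    n_features: int

    def predict_scores(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _check_width(self, X: np.ndarray) -> None:
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"fingerprint width {X.shape[1]} does not match training width {self.n_features}"
            )


class _SklearnModel(TrainedModel):
    def __init__(self, spec: ModelSpec, estimator, seed: int, n_features: int):
        self.spec = spec
        self.seed = seed
        self.n_features = n_features
        self.estimator = estimator

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        self._check_width(X)
        if self.spec.task == "classification":
            proba = self.estimator.predict_proba(X)
            return np.asarray(proba[:, 1], dtype=np.float64)
        return np.asarray(self.estimator.predict(X), dtype=np.float64)


class SimilarityBaselineModel(TrainedModel):
    """Scores a query by its maximum Tanimoto similarity to the training
    actives; inactive training compounds are ignored entirely."""

    def __init__(self, active_matrix: np.ndarray, seed: int = 0,
                 spec: ModelSpec | None = None):
        if active_matrix.shape[0] == 0:
            raise ValueError("similarity baseline needs at least one training active")
        self.spec = spec or ModelSpec(model_class="similarity")
        self.seed = seed
        self.n_features = active_matrix.shape[1]
        self.active_matrix = active_matrix.astype(np.uint8)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        self._check_width(X)
        out = np.empty(X.shape[0], dtype=np.float64)
        block = 4096
        for start in range(0, X.shape[0], block):
            stop = min(start + block, X.shape[0])
            sim = bulk_tanimoto_similarity(X[start:stop], self.active_matrix)
            out[start:stop] = sim.max(axis=1)
        return out


def _build_estimator(spec: ModelSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.model_class == "RF-C":
        hp.setdefault("n_jobs", 1)
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.model_class == "XGB-C":
        hp.setdefault("n_jobs", 1)
        hp.setdefault("tree_method", "hist")
        return XGBClassifier(random_state=seed, eval_metric="logloss", **hp)
    if spec.model_class == "XGB-R":
        hp.setdefault("n_jobs", 1)
        hp.setdefault("tree_method", "hist")
        return XGBRegressor(random_state=seed, **hp)
    if spec.model_class == "NN-C":
        return MLPClassifier(random_state=seed, **hp)
    if spec.model_class == "NN-R":
        return MLPRegressor(random_state=seed, **hp)
    raise ValueError(f"{spec.model_class!r} is not a directly trainable class")


def train_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int) -> TrainedModel:
    """Train one model; deterministic given (spec, data, seed).

    ``y`` is binary activity for classification specs and the similarity
    baseline, continuous % inhibition for regression specs.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise ValueError("X and y must be non-empty and the same length")
    if spec.model_class == "similarity":
        active_matrix = X[y.astype(bool)]
        return SimilarityBaselineModel(active_matrix, seed=seed, spec=spec)
    if spec.task == "classification":
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(f"single-class training set for {spec.name}")
        y = y.astype(np.int64)
    else:
        y = y.astype(np.float64)
    est = _build_estimator(spec, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return _SklearnModel(spec, est, seed, X.shape[1])


def score_compounds(model: TrainedModel, ids: Sequence[str], X: np.ndarray) -> RankedScores:
    """Score a compound set and return deterministically ordered results."""
    scores = model.predict_scores(np.asarray(X))
    return RankedScores.from_arrays(ids, scores)


def similarity_baseline_score(query: Fingerprint, training_actives: Sequence[Fingerprint]) -> float:
    """Single-query similarity baseline: max Tanimoto similarity to actives."""
    if not training_actives:
        raise ValueError("empty training-active set")
    model = SimilarityBaselineModel(to_dense_matrix(list(training_actives)))
    return float(model.predict_scores(query.to_dense()[None, :])[0])


# --- score normalization and ensembles --------------------------------------


class EcdfNormalizer:
    """Frozen empirical-CDF map from raw scores onto [0, 1].

    Fit once on a reference score sample (training-set predictions); the
    transform is monotone non-decreasing and independent of the batch a
    compound is scored in.
    """

    def __init__(self, reference_scores: np.ndarray):
        ref = np.sort(np.asarray(reference_scores, dtype=np.float64))
        if ref.size == 0:
            raise ValueError("empty reference sample")
        self._ref = ref

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        ranks = np.searchsorted(self._ref, np.asarray(scores, dtype=np.float64), side="right")
        return ranks / self._ref.size


def rank_normalize(ranked: RankedScores) -> RankedScores:
    """Map a score table onto [0, 1] via its own empirical CDF."""
    norm = EcdfNormalizer(np.array(ranked.scores))
    return RankedScores.from_arrays(ranked.ids, norm(np.array(ranked.scores)))


def max_vote_ensemble(member_scores: Sequence[RankedScores]) -> RankedScores:
    """Elementwise max over member score tables (already on a common scale)."""
    if not member_scores:
        raise ValueError("no ensemble members")
    id_set = set(member_scores[0].ids)
    for m in member_scores[1:]:
        if set(m.ids) != id_set:
            raise ValueError("ensemble members score different compound sets")
    ids = sorted(id_set)
    stacked = np.array([[m.as_mapping()[cid] for cid in ids] for m in member_scores])
    return RankedScores.from_arrays(ids, stacked.max(axis=0))


class MaxVoteModel(TrainedModel):
    """Max-vote ensemble over trained members, regression members mapped
    through frozen ECDF normalizers."""

    def __init__(self, members: Sequence[tuple[TrainedModel, EcdfNormalizer | None]],
                 spec: ModelSpec | None = None, seed: int = 0):
        if not members:
            raise ValueError("no ensemble members")
        self.members = list(members)
        self.spec = spec or ModelSpec(model_class="max-vote-ensemble")
        self.seed = seed
        self.n_features = self.members[0][0].n_features

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for model, norm in self.members:
            s = model.predict_scores(X)
            cols.append(norm(s) if norm is not None else s)
        return np.max(np.column_stack(cols), axis=1)


class StackedModel(TrainedModel):
    """Two-layer stacking ensemble: base models feed a meta-classifier."""

    def __init__(self, bases: Sequence[tuple[TrainedModel, EcdfNormalizer | None]],
                 meta, spec: ModelSpec | None = None, seed: int = 0):
        self.bases = list(bases)
        self.meta = meta
        self.spec = spec or ModelSpec(model_class="stacked-ensemble")
        self.seed = seed
        self.n_features = self.bases[0][0].n_features

    def _base_features(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for model, norm in self.bases:
            s = model.predict_scores(X)
            cols.append(norm(s) if norm is not None else s)
        return np.column_stack(cols)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.meta.predict_proba(self._base_features(X))[:, 1]


def _fit_member(spec: ModelSpec, X, y_cls, y_reg, mask, seed) -> TrainedModel:
    y = y_reg if spec.task == "regression" else y_cls
    return train_model(spec, X[mask], y[mask], seed)


def _normalizer_for(spec: ModelSpec, model: TrainedModel, X_ref: np.ndarray) -> EcdfNormalizer | None:
    if spec.task == "regression":
        return EcdfNormalizer(model.predict_scores(X_ref))
    return None


def stacked_ensemble(
    base_specs: Sequence[ModelSpec],
    X: np.ndarray,
    y_cls: np.ndarray,
    y_reg: np.ndarray,
    fold_of: np.ndarray,
    seed: int,
    train_folds: Sequence[int] = tuple(range(8)),
    validation_fold: int = 8,
    meta_spec: Mapping[str, object] | None = None,
) -> StackedModel:
    """Build a stacking ensemble on the selection-stage fold plan.

    Base models are trained on the training folds, the meta-classifier (a
    regularized linear classifier by default) is trained on their
    validation-fold outputs, and finally every base model is retrained on
    the complete training data (training + validation folds) for scoring.
    """
    if len(base_specs) < 1:
        raise ValueError("stacked ensemble needs at least one base spec")
    present = set(np.unique(fold_of).tolist())
    needed = set(train_folds) | {validation_fold}
    if not needed <= present:
        raise ValueError(f"fold plan requires folds {sorted(needed)} but data has {sorted(present)}")
    train_mask = np.isin(fold_of, list(train_folds))
    val_mask = fold_of == validation_fold

    stage1 = []
    for spec in base_specs:
        model = _fit_member(spec, X, y_cls, y_reg, train_mask, seed)
        stage1.append((spec, model, _normalizer_for(spec, model, X[train_mask])))

    val_features = np.column_stack(
        [norm(m.predict_scores(X[val_mask])) if norm else m.predict_scores(X[val_mask])
         for _, m, norm in stage1]
    )
    y_val = y_cls[val_mask].astype(np.int64)
    if np.unique(y_val).size < 2:
        raise ValueError("validation fold contains a single class; cannot fit meta-classifier")
    meta = LogisticRegression(random_state=seed, max_iter=1000, **(meta_spec or {}))
    meta.fit(val_features, y_val)

    full_mask = train_mask | val_mask
    final_bases = []
    for spec in base_specs:
        model = _fit_member(spec, X, y_cls, y_reg, full_mask, seed)
        final_bases.append((model, _normalizer_for(spec, model, X[full_mask])))
    return StackedModel(final_bases, meta, seed=seed)


# --- default hyperparameter grids -------------------------------------------
# Grids are configuration data; these defaults are deliberately small so the
# full tuning stage runs at desk scale.  Each class exposes the
# hyperparameter families appropriate to it (trees / feature sampling /
# leaf size / class weight for RF; depth / learning rate / rounds for XGB;
# layers / units / regularization / learning rate / activation for NN).

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "RF-C": [
        {"n_estimators": 64, "max_features": "sqrt", "min_samples_leaf": 1, "class_weight": None},
        {"n_estimators": 128, "max_features": "sqrt", "min_samples_leaf": 1,
         "class_weight": "balanced_subsample"},
    ],
    "XGB-C": [
        {"max_depth": 4, "learning_rate": 0.1, "n_estimators": 60},
        {"max_depth": 6, "learning_rate": 0.3, "n_estimators": 60},
    ],
    "XGB-R": [
        {"max_depth": 4, "learning_rate": 0.1, "n_estimators": 60},
        {"max_depth": 6, "learning_rate": 0.3, "n_estimators": 60},
    ],
    "NN-C": [
        {"hidden_layer_sizes": (64,), "alpha": 1e-4, "learning_rate_init": 1e-3,
         "activation": "relu", "max_iter": 15},
        {"hidden_layer_sizes": (32,), "alpha": 1e-3, "learning_rate_init": 2e-3,
         "activation": "relu", "max_iter": 15},
    ],
    "NN-R": [
        {"hidden_layer_sizes": (64,), "alpha": 1e-4, "learning_rate_init": 1e-3,
         "activation": "relu", "max_iter": 15},
        {"hidden_layer_sizes": (32,), "alpha": 1e-3, "learning_rate_init": 2e-3,
         "activation": "relu", "max_iter": 15},
    ],
}


# --- model store ------------------------------------------------------------


def save_model(directory, model: TrainedModel, fingerprint_settings: Mapping | None = None) -> Path:
    """Persist a trained model + its spec/seed/fingerprint settings."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, directory / "model.joblib")
    meta = {
        "format_version": 1,
        "model_class": model.spec.model_class,
        "hyperparameter_id": model.spec.hyperparameter_id,
        "hyperparameters": {k: repr(v) for k, v in model.spec.hp.items()},
        "seed": model.seed,
        "n_features": model.n_features,
        "fingerprint_settings": dict(fingerprint_settings or {}),
    }
    (directory / "spec.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_model(directory) -> TrainedModel:
    return joblib.load(Path(directory) / "model.joblib")
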