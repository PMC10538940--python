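"""The staged screening pipeline: hyperparameter tuning -> model selection ->
prospective batch scoring.

Stage 1 (tuning) evaluates every hyperparameter setting of every base model
class over four cross-validation runs confined to folds 0-7 and prunes each
class to its top-k (with ties) settings by mean NEF_1%.

Stage 2 (selection) trains every surviving setting once (folds 0-7 train,
fold 8 validation, fold 9 test), adds the similarity baseline and the two
ensembles built from the survivors, and picks the single best candidate by
fold-9 NEF_1% with ties broken by AP, then hyperparameter id.

Stage 3 (prospective scoring) retrains the winner on all folds and streams
scores over an arbitrarily large library in batches; batching is pure
plumbing and never changes any compound's score.
"""

from __future__ import annotations

import hashlib
import heapq
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CVRun, FoldAssignment, ScreeningRecord, cv_plan
from .fingerprints import Fingerprint, fingerprint_from_smiles, to_dense_matrix
from .metrics import MetricReport, RankedScores, evaluate_ranking
from .models import (
    BASE_MODEL_CLASSES,
    EcdfNormalizer,
    MaxVoteModel,
    ModelSpec,
    TrainedModel,
    stacked_ensemble,
    train_model,
)

__all__ = [
    "EvaluatedSpec",
    "StageResult",
    "top_k_with_ties",
    "hyperparameter_tuning_stage",
    "model_selection_stage",
    "retrain_on_folds",
    "batch_score_library",
    "ScoredRow",
    "collect_scores",
    "top_k_stream",
]


@dataclass
class EvaluatedSpec:
    """One candidate spec with its per-run metric reports."""

    spec: ModelSpec
    reports: list[MetricReport] = field(default_factory=list)
    failed: bool = False
    error: str = ""

    @property
    def mean_nef1(self) -> float:
        if self.failed or not self.reports:
            return float("-inf")
        return float(np.mean([r.nef1 for r in self.reports]))

    @property
    def mean_ap(self) -> float:
        if self.failed or not self.reports:
            return float("-inf")
        return float(np.mean([r.ap for r in self.reports]))


@dataclass
class StageResult:
    """Outcome of one pipeline stage, with provenance for reproducibility."""

    stage: str
    evaluated: list[EvaluatedSpec]
    survivors: list[ModelSpec]
    provenance: dict

    def leaderboard(self) -> pd.DataFrame:
        rows = []
        for ev in self.evaluated:
            rows.append(
                {
                    "model_class": ev.spec.model_class,
                    "hyperparameter_id": ev.spec.hyperparameter_id,
                    "mean_nef1": None if ev.failed else ev.mean_nef1,
                    "mean_ap": None if ev.failed else ev.mean_ap,
                    "mean_auc": None
                    if ev.failed
                    else float(np.mean([r.auc_roc for r in ev.reports])),
                    "failed": ev.failed,
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["mean_nef1", "mean_ap"], ascending=False, na_position="last"
        ).reset_index(drop=True)


def top_k_with_ties(
    scored_specs: Sequence[tuple[ModelSpec, float]], k: int = 20
) -> list[ModelSpec]:
    """Specs with the top-k metric values, keeping everything tied at the
    k-th boundary value.  |survivors| >= min(k, |specs|)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not scored_specs:
        raise ValueError("no specs to prune")
    ordered = sorted(scored_specs, key=lambda sv: (-sv[1], sv[0].hyperparameter_id))
    if len(ordered) <= k:
        return [s for s, _ in ordered]
    boundary = ordered[k - 1][1]
    return [s for s, v in ordered if v >= boundary]


def _provenance(seed: int, plan: Sequence[CVRun], extra: Mapping | None = None) -> dict:
    prov = {
        "seed": seed,
        "fold_plan": [
            {"train": list(r.train_folds), "validation": r.validation_fold, "test": r.test_fold}
            for r in plan
        ],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        prov.update(extra)
    return prov


def _training_arrays(
    records: Sequence[ScreeningRecord], folds: FoldAssignment
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    for rec in records:
        if rec.fingerprint is None:
            raise ValueError(f"record {rec.id} has no fingerprint")
        if rec.active is None:
            raise ValueError(f"record {rec.id} has no activity label")
    ids = [r.id for r in records]
    X = to_dense_matrix([r.fingerprint for r in records])
    y_cls = np.array([bool(r.active) for r in records], dtype=np.int64)
    y_reg = np.array([r.median_primary for r in records], dtype=np.float64)
    fold_of = folds.as_array(ids)
    return ids, X, y_cls, y_reg, fold_of


def _grid_hash(grids: Mapping[str, Sequence[Mapping]]) -> str:
    payload = json.dumps({k: [dict(h) for h in v] for k, v in grids.items()},
                         sort_keys=True, default=repr)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _eval_run(
    spec: ModelSpec,
    run: CVRun,
    ids: Sequence[str],
    X: np.ndarray,
    y_cls: np.ndarray,
    y_reg: np.ndarray,
    fold_of: np.ndarray,
    seed: int,
    fractions: Sequence[float],
) -> MetricReport:
    train_mask = np.isin(fold_of, list(run.train_folds))
    test_mask = fold_of == run.test_fold
    y_train = y_reg if spec.task == "regression" else y_cls
    model = train_model(spec, X[train_mask], y_train[train_mask], seed)
    test_ids = [cid for cid, m in zip(ids, test_mask) if m]
    ranked = RankedScores.from_arrays(test_ids, model.predict_scores(X[test_mask]))
    labels = {cid: bool(v) for cid, v in zip(test_ids, y_cls[test_mask])}
    return evaluate_ranking(ranked, labels, fractions=fractions)


def hyperparameter_tuning_stage(
    grids: Mapping[str, Sequence[Mapping]],
    records: Sequence[ScreeningRecord],
    folds: FoldAssignment,
    seed: int,
    k_survivors: int = 20,
    plan: Sequence[CVRun] | None = None,
    fractions: Sequence[float] = (0.01,),
) -> StageResult:
    """Evaluate every grid setting over the tuning CV runs and prune each
    model class to its top-k (with ties) by mean NEF_1%.

    A spec whose training fails on any run is recorded with a failure flag
    and excluded from survival.
    """
    if not grids or not any(len(g) for g in grids.values()):
        raise ValueError("empty hyperparameter grids")
    unknown = set(grids) - set(BASE_MODEL_CLASSES)
    if unknown:
        raise ValueError(f"grids contain non-base model classes: {sorted(unknown)}")
    plan = list(plan) if plan is not None else cv_plan("tuning", k=folds.k)
    ids, X, y_cls, y_reg, fold_of = _training_arrays(records, folds)

    evaluated: list[EvaluatedSpec] = []
    survivors: list[ModelSpec] = []
    for model_class in sorted(grids):
        class_evals: list[EvaluatedSpec] = []
        for hp_id, hp in enumerate(grids[model_class]):
            spec = ModelSpec(model_class=model_class, hyperparameters=dict(hp),
                             hyperparameter_id=hp_id)
            ev = EvaluatedSpec(spec=spec)
            try:
                for run in plan:
                    ev.reports.append(
                        _eval_run(spec, run, ids, X, y_cls, y_reg, fold_of, seed, fractions)
                    )
            except Exception as exc:  # noqa: BLE001 - failure is a recorded outcome
                ev.failed = True
                ev.error = f"{type(exc).__name__}: {exc}"
                ev.reports = []
            class_evals.append(ev)
        evaluated.extend(class_evals)
        ok = [(ev.spec, ev.mean_nef1) for ev in class_evals if not ev.failed]
        if ok:
            survivors.extend(top_k_with_ties(ok, k_survivors))

    return StageResult(
        stage="tuning",
        evaluated=evaluated,
        survivors=survivors,
        provenance=_provenance(seed, plan, {"grid_hash": _grid_hash(grids),
                                            "k_survivors": k_survivors}),
    )


DEFAULT_ENSEMBLE_RULE = "top1_per_class"


def _default_member_sets(
    survivor_means: Mapping[str, list[tuple[ModelSpec, float]]]
) -> list[list[ModelSpec]]:
    """One member set: the best surviving spec of each base class."""
    members = []
    for model_class in sorted(survivor_means):
        ranked = sorted(survivor_means[model_class], key=lambda sv: (-sv[1], sv[0].hyperparameter_id))
        if ranked:
            members.append(ranked[0][0])
    return [members] if len(members) >= 2 else []


def model_selection_stage(
    tuning: StageResult,
    records: Sequence[ScreeningRecord],
    folds: FoldAssignment,
    seed: int,
    include_baseline: bool = True,
    ensemble_member_sets: Sequence[Sequence[ModelSpec]] | None = None,
    select_on: str = "fold9",
    fractions: Sequence[float] = (0.01,),
) -> StageResult:
    """Train every candidate once on the selection split and pick a winner.

    Candidates: tuning survivors, the similarity baseline, and max-vote /
    stacked ensembles over configurable member sets (default: the best
    survivor of each class).  Ranking: test-fold NEF_1% descending, ties by
    AP, then hyperparameter_id, then class name.  ``select_on="tuning_mean"``
    instead ranks base candidates by their tuning-stage mean NEF_1%.
    """
    if select_on not in ("fold9", "tuning_mean"):
        raise ValueError("select_on must be 'fold9' or 'tuning_mean'")
    plan = cv_plan("selection", k=folds.k)
    run = plan[0]
    ids, X, y_cls, y_reg, fold_of = _training_arrays(records, folds)
    train_mask = np.isin(fold_of, list(run.train_folds))
    test_mask = fold_of == run.test_fold
    test_ids = [cid for cid, m in zip(ids, test_mask) if m]
    test_labels = {cid: bool(v) for cid, v in zip(test_ids, y_cls[test_mask])}

    survivor_means: dict[str, list[tuple[ModelSpec, float]]] = {}
    for ev in tuning.evaluated:
        if not ev.failed and ev.spec in tuning.survivors:
            survivor_means.setdefault(ev.spec.model_class, []).append((ev.spec, ev.mean_nef1))

    candidates: list[ModelSpec] = list(tuning.survivors)
    if include_baseline:
        candidates.append(ModelSpec(model_class="similarity"))
    member_sets = (
        [list(ms) for ms in ensemble_member_sets]
        if ensemble_member_sets is not None
        else _default_member_sets(survivor_means)
    )
    ensemble_specs: list[tuple[ModelSpec, list[ModelSpec]]] = []
    for i, members in enumerate(member_sets):
        for cls in ("max-vote-ensemble", "stacked-ensemble"):
            ensemble_specs.append(
                (ModelSpec(model_class=cls, hyperparameter_id=i,
                           hyperparameters={"members": tuple(m.name for m in members)}),
                 members)
            )

    evaluated: list[EvaluatedSpec] = []

    def evaluate(spec: ModelSpec, model: TrainedModel) -> None:
        ranked = RankedScores.from_arrays(test_ids, model.predict_scores(X[test_mask]))
        evaluated.append(
            EvaluatedSpec(spec=spec, reports=[evaluate_ranking(ranked, test_labels, fractions)])
        )

    for spec in candidates:
        try:
            y_train = y_reg if spec.task == "regression" else y_cls
            model = train_model(spec, X[train_mask], y_train[train_mask], seed)
            evaluate(spec, model)
        except Exception as exc:  # noqa: BLE001
            evaluated.append(EvaluatedSpec(spec=spec, failed=True,
                                           error=f"{type(exc).__name__}: {exc}"))

    for spec, members in ensemble_specs:
        try:
            if spec.model_class == "stacked-ensemble":
                model = stacked_ensemble(
                    members, X, y_cls, y_reg, fold_of, seed,
                    train_folds=run.train_folds, validation_fold=run.validation_fold,
                )
            else:
                pairs = []
                for mspec in members:
                    y_train = y_reg if mspec.task == "regression" else y_cls
                    m = train_model(mspec, X[train_mask], y_train[train_mask], seed)
                    norm = (
                        EcdfNormalizer(m.predict_scores(X[train_mask]))
                        if mspec.task == "regression"
                        else None
                    )
                    pairs.append((m, norm))
                model = MaxVoteModel(pairs, spec=spec, seed=seed)
            evaluate(spec, model)
        except Exception as exc:  # noqa: BLE001
            evaluated.append(EvaluatedSpec(spec=spec, failed=True,
                                           error=f"{type(exc).__name__}: {exc}"))

    ok = [ev for ev in evaluated if not ev.failed]
    if not ok:
        raise RuntimeError("every candidate failed in the model selection stage")

    tuning_mean_of = {
        ev.spec: ev.mean_nef1 for ev in tuning.evaluated if not ev.failed
    }

    def sort_key(ev: EvaluatedSpec):
        primary = (
            tuning_mean_of.get(ev.spec, ev.reports[0].nef1)
            if select_on == "tuning_mean"
            else ev.reports[0].nef1
        )
        return (-primary, -ev.reports[0].ap, ev.spec.hyperparameter_id, ev.spec.model_class)

    winner = min(ok, key=sort_key).spec
    return StageResult(
        stage="selection",
        evaluated=evaluated,
        survivors=[winner],
        provenance=_provenance(seed, plan, {"select_on": select_on,
                                            "n_candidates": len(evaluated)}),
    )


def retrain_on_folds(
    spec: ModelSpec,
    records: Sequence[ScreeningRecord],
    folds: FoldAssignment,
    seed: int,
    use_folds: Sequence[int] | None = None,
) -> TrainedModel:
    """Retrain a spec on the given folds (default: all of them), as done
    before prospective scoring."""
    ids, X, y_cls, y_reg, fold_of = _training_arrays(records, folds)
    mask = (
        np.ones(len(ids), dtype=bool)
        if use_folds is None
        else np.isin(fold_of, list(use_folds))
    )
    y = y_reg if spec.task == "regression" else y_cls
    return train_model(spec, X[mask], y[mask], seed)


# --- streaming prospective scoring ------------------------------------------


@dataclass(frozen=True)
class ScoredRow:
    """One scored library row; ``ok=False`` marks unparseable structures,
    which are reported (score NaN), never silently dropped."""

    id: str
    score: float
    ok: bool


def _resolve_fingerprint(item) -> Fingerprint | None:
    if isinstance(item, Fingerprint):
        return item
    if isinstance(item, str):
        try:
            return fingerprint_from_smiles(item)
        except ValueError:
            return None
    return None


def batch_score_library(
    model: TrainedModel,
    library: Iterable[tuple[str, Fingerprint | str | None]],
    batch_size: int = 8192,
    on_invalid: Callable[[str], None] | None = None,
) -> Iterator[ScoredRow]:
    """Stream model scores over a compound library in batches.

    Batching is pure plumbing: scores are identical for any ``batch_size``
    and output rows appear in input order, one per input row.  Items are
    ``(id, Fingerprint)`` or ``(id, SMILES)``; unparseable structures yield
    NaN-scored rows flagged ``ok=False`` and are passed to ``on_invalid``.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    batch: list[tuple[str, Fingerprint | None]] = []

    def flush() -> Iterator[ScoredRow]:
        valid = [(i, fp) for i, (_, fp) in enumerate(batch) if fp is not None]
        scores = np.full(len(batch), np.nan)
        if valid:
            mat = to_dense_matrix([fp for _, fp in valid])
            s = model.predict_scores(mat)
            for (i, _), v in zip(valid, s):
                scores[i] = v
        for (cid, fp), v in zip(batch, scores):
            ok = fp is not None
            if not ok and on_invalid is not None:
                on_invalid(cid)
            yield ScoredRow(id=cid, score=float(v), ok=ok)
        batch.clear()

    for cid, item in library:
        batch.append((cid, _resolve_fingerprint(item)))
        if len(batch) >= batch_size:
            yield from flush()
    if batch:
        yield from flush()


def collect_scores(rows: Iterable[ScoredRow]) -> tuple[RankedScores, pd.DataFrame]:
    """Materialize streamed rows: a score table (all rows) and the
    deterministic ranking over the valid ones."""
    rows = list(rows)
    df = pd.DataFrame({"id": [r.id for r in rows],
                       "score": [r.score for r in rows],
                       "ok": [r.ok for r in rows]})
    valid = df[df["ok"]]
    ranked = RankedScores.from_arrays(valid["id"].tolist(), valid["score"].tolist())
    return ranked, df


def top_k_stream(rows: Iterable[ScoredRow], k: int) -> list[ScoredRow]:
    """Top-k valid rows from a stream in O(k) memory, ordered score
    descending with ties broken by id ascending (matches a full sort)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    filtered = (r for r in rows if r.ok and not math.isnan(r.score))
    return heapq.nsmallest(k, filtered, key=lambda r: (-r.score, r.id))
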