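"""Prospective compound selection: the two-model top-K/filter/union workflow,
the confirmatory hit call, and the multi-stage diversity funnel.

Two selection workflows are implemented:

* the in-stock workflow: two models (typically the selected classifier and
  the similarity baseline) each nominate their top-N library compounds; a
  business-attribute filter (cost, delivery, vendor predicates) prunes each
  list, the remaining top per-model budgets are unioned and purchased, and
  activity is confirmed with a stricter replicate-based hit call;

* the synthesize-on-demand funnel: prioritized candidates pass through
  cluster novelty -> structural filters (PAINS / Inpharmatica / Lipinski)
  -> distance novelty -> per-cluster representatives -> greedy max-min
  diversity picking, with a full per-stage audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .clustering import ClusterAssignment
from .fingerprints import (
    Fingerprint,
    bulk_nearest_distance,
    bulk_tanimoto_similarity,
    to_dense_matrix,
)
from .metrics import RankedScores

__all__ = [
    "Candidate",
    "FunnelAudit",
    "StructuralFilterSet",
    "ams_select",
    "AmsSelection",
    "ams_hit_call",
    "cluster_novelty_filter",
    "apply_structural_filters",
    "distance_novelty_filter",
    "cluster_representatives",
    "greedy_diverse_select",
    "enamine_funnel",
    "lipinski_pass",
    "rdkit_catalog_filter",
]


@dataclass(frozen=True)
class Candidate:
    """A prospective compound entering the selection funnel."""

    id: str
    fingerprint: Fingerprint
    score: float
    smiles: str | None = None
    flags: Mapping[str, bool] = field(default_factory=dict)


@dataclass
class FunnelAudit:
    """Per-stage survivor accounting for a multi-stage selection funnel."""

    stages: list[tuple[str, int, int, str]] = field(default_factory=list)
    final_ids: list[str] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int, reason: str) -> None:
        if n_out > n_in:
            raise ValueError("a funnel stage cannot add compounds")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError("stage input count must equal previous stage output count")
        self.stages.append((name, n_in, n_out, reason))

    def as_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s, "in": i, "out": o, "reason": r} for s, i, o, r in self.stages
            ],
            "final_ids": list(self.final_ids),
        }


# --- in-stock (AMS-style) workflow ------------------------------------------


@dataclass(frozen=True)
class AmsSelection:
    """Union selection of two models with per-model credit membership."""

    union_ids: tuple[str, ...]
    selected_by: Mapping[str, tuple[str, ...]]  # per-model post-filter budget lists
    credited_to: Mapping[str, frozenset]  # per-model original top-N membership


def ams_select(
    model_scores: Mapping[str, RankedScores],
    top_n: int = 1500,
    attribute_filter: Callable[[str], bool] | None = None,
    per_model_budget: int = 600,
) -> AmsSelection:
    """Two-model top-N / attribute-filter / union selection.

    Per model: take the top ``top_n`` ranked compounds, drop those failing
    the business-attribute predicate, truncate to ``per_model_budget``, and
    union the surviving lists.  Hit accounting later credits a model for
    any ordered compound inside its original top ``top_n`` (not only its
    post-filter budget list), which is what ``credited_to`` records.
    """
    if top_n < per_model_budget:
        raise ValueError("top_n must be >= per_model_budget")
    if len(model_scores) < 1:
        raise ValueError("at least one model's scores required")
    keep = attribute_filter or (lambda cid: True)
    common = set.intersection(*(set(rs.ids) for rs in model_scores.values()))
    if not common:
        raise ValueError("models scored disjoint compound sets")
    selected_by: dict[str, tuple[str, ...]] = {}
    credited_to: dict[str, frozenset] = {}
    union: list[str] = []
    seen: set = set()
    for name, rs in model_scores.items():
        top = rs.top(top_n)
        credited_to[name] = frozenset(top)
        budget = [cid for cid in top if keep(cid)][:per_model_budget]
        selected_by[name] = tuple(budget)
        for cid in budget:
            if cid not in seen:
                seen.add(cid)
                union.append(cid)
    return AmsSelection(
        union_ids=tuple(sorted(union)), selected_by=selected_by, credited_to=credited_to
    )


def ams_hit_call(
    replicate_inhibitions: Sequence[float],
    pains_pass: bool,
    threshold: float = 50.0,
    strict: bool = False,
) -> bool:
    """Confirmatory hit call on replicate % inhibition readouts.

    Hit iff every replicate reaches the threshold (>= by default; ``strict``
    switches to >) and the compound passes the PAINS filter.  Requires at
    least two replicates.
    """
    if len(replicate_inhibitions) < 2:
        raise ValueError("hit call requires at least two replicates")
    if strict:
        ok = all(v > threshold for v in replicate_inhibitions)
    else:
        ok = all(v >= threshold for v in replicate_inhibitions)
    return ok and bool(pains_pass)


def median_hit_call(
    replicate_inhibitions: Sequence[float], threshold: float = 50.0
) -> bool:
    """Initial hit call on the median of replicate % inhibition values
    (the synthesize-on-demand screening variant)."""
    if not replicate_inhibitions:
        raise ValueError("no replicates")
    return float(np.median(replicate_inhibitions)) >= threshold


# --- structural filters ------------------------------------------------------


class StructuralFilterSet:
    """Named pass/fail predicates over candidates, fail-closed.

    Each filter is either a callable ``(Candidate) -> bool | None`` or the
    name of a precomputed flag in ``Candidate.flags``.  ``None`` /
    missing-flag means *unavailable*, which is never treated as a pass:
    evaluating it raises.
    """

    def __init__(self, filters: Mapping[str, Callable[[Candidate], bool | None] | str]):
        if not filters:
            raise ValueError("empty filter set")
        self.filters = dict(filters)

    def evaluate(self, candidate: Candidate) -> dict[str, bool]:
        results = {}
        for name, rule in self.filters.items():
            if isinstance(rule, str):
                value = candidate.flags.get(rule)
            else:
                value = rule(candidate)
            if value is None:
                raise ValueError(
                    f"filter {name!r} unavailable for candidate {candidate.id!r} "
                    "(no rule result and no precomputed flag)"
                )
            results[name] = bool(value)
        return results

    @classmethod
    def from_flags(cls, names: Sequence[str]) -> "StructuralFilterSet":
        """Filter set reading precomputed pass/fail flags of these names."""
        return cls({name: name for name in names})


def lipinski_pass(smiles: str, max_violations: int = 1) -> bool:
    """Rule-of-five check: MW <= 500, logP <= 5, H-bond donors <= 5,
    H-bond acceptors <= 10; pass when at most ``max_violations`` rules are
    broken (the classic usage tolerates one)."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for Lipinski check: {smiles!r}")
    violations = sum(
        [
            Descriptors.MolWt(mol) > 500.0,
            Crippen.MolLogP(mol) > 5.0,
            Lipinski.NumHDonors(mol) > 5,
            Lipinski.NumHAcceptors(mol) > 10,
        ]
    )
    return violations <= max_violations


def rdkit_catalog_filter(catalog_name: str) -> Callable[[Candidate], bool | None]:
    """Substructure-alert filter backed by an RDKit FilterCatalog.

    ``catalog_name`` is ``"PAINS"`` or ``"Inpharmatica"``.  Returns a rule
    that passes compounds matching no alert; candidates without SMILES
    yield ``None`` (unavailable -> fail-closed upstream).
    """
    from rdkit import Chem
    from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

    params = FilterCatalogParams()
    if catalog_name == "PAINS":
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
    elif catalog_name == "Inpharmatica":
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.CHEMBL_Inpharmatica)
    else:
        raise ValueError(f"unknown catalog {catalog_name!r}")
    catalog = FilterCatalog(params)

    def rule(candidate: Candidate) -> bool | None:
        if candidate.smiles is None:
            return None
        mol = Chem.MolFromSmiles(candidate.smiles)
        if mol is None:
            return None
        return not catalog.HasMatch(mol)

    return rule


# --- funnel stages -----------------------------------------------------------


def cluster_novelty_filter(
    candidates: Sequence[Candidate],
    clusters: ClusterAssignment,
    known_actives: set,
) -> list[Candidate]:
    """Keep candidates whose cluster contains no previously known active."""
    known_clusters = clusters.clusters_of(known_actives)
    out = []
    for cand in candidates:
        if cand.id not in clusters.cluster_of:
            raise ValueError(f"candidate {cand.id!r} is not clustered")
        if clusters.cluster_of[cand.id] not in known_clusters:
            out.append(cand)
    return out


def apply_structural_filters(
    candidates: Sequence[Candidate], filter_set: StructuralFilterSet
) -> tuple[list[Candidate], dict[str, int]]:
    """Keep candidates passing ALL filters; report per-filter rejections.

    A candidate failing several filters counts once per failed filter in
    the rejection tally.
    """
    survivors = []
    rejections = {name: 0 for name in filter_set.filters}
    for cand in candidates:
        results = filter_set.evaluate(cand)
        failed = [name for name, ok in results.items() if not ok]
        for name in failed:
            rejections[name] += 1
        if not failed:
            survivors.append(cand)
    return survivors, rejections


def distance_novelty_filter(
    candidates: Sequence[Candidate],
    known_active_fps: Sequence[Fingerprint],
    min_distance: float = 0.35,
) -> list[Candidate]:
    """Keep candidates at Tanimoto distance >= min_distance (inclusive)
    from their nearest known active."""
    if not known_active_fps:
        raise ValueError("empty known-active set")
    if not candidates:
        return []
    cand_mat = to_dense_matrix([c.fingerprint for c in candidates])
    ref_mat = to_dense_matrix(list(known_active_fps))
    dist, _ = bulk_nearest_distance(cand_mat, ref_mat)
    return [c for c, d in zip(candidates, dist) if d >= min_distance - 1e-12]


def cluster_representatives(
    candidates: Sequence[Candidate], clusters: ClusterAssignment
) -> list[Candidate]:
    """One candidate per occupied cluster: the highest score, ties by id."""
    best: dict[int, Candidate] = {}
    for cand in candidates:
        if cand.id not in clusters.cluster_of:
            raise ValueError(f"candidate {cand.id!r} is not clustered")
        c = clusters.cluster_of[cand.id]
        cur = best.get(c)
        if cur is None or (cand.score, _neg_id(cand.id)) > (cur.score, _neg_id(cur.id)):
            best[c] = cand
    return sorted(best.values(), key=lambda c: c.id)


class _neg_id(str):
    """String wrapper inverting comparison, so (score, _neg_id) max-compare
    means higher score first, then id ascending."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def greedy_diverse_select(
    candidates: Sequence[Candidate],
    n: int,
    strategy: str = "maxmin",
) -> list[str]:
    """Greedy diversity picking.

    The first pick is the highest-scoring candidate (ties: id ascending).
    Each subsequent pick maximizes the minimum (``maxmin``, default) or the
    mean (``maxavg``) Tanimoto distance to the already-selected compounds;
    ties resolve by higher score, then id ascending.  Stops after
    ``min(n, len(candidates))`` picks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not candidates:
        raise ValueError("empty candidate set")
    if strategy not in ("maxmin", "maxavg"):
        raise ValueError(f"unknown strategy {strategy!r}")
    cands = list(candidates)
    mat = to_dense_matrix([c.fingerprint for c in cands]).astype(np.float32)
    scores = np.array([c.score for c in cands])
    ids = [c.id for c in cands]
    m = len(cands)

    first = min(range(m), key=lambda i: (-scores[i], ids[i]))
    selected = [first]
    remaining = set(range(m)) - {first}
    # distance of every candidate to each selected compound, built up lazily
    dist_to_sel = 1.0 - bulk_tanimoto_similarity(mat, mat[[first]])  # (m, 1)
    crit = dist_to_sel.copy()  # min or mean distance column

    while remaining and len(selected) < min(n, m):
        if strategy == "maxmin":
            objective = crit[:, 0]
        else:
            objective = dist_to_sel.mean(axis=1)
        best = min(remaining, key=lambda i: (-objective[i], -scores[i], ids[i]))
        selected.append(best)
        remaining.discard(best)
        new_d = 1.0 - bulk_tanimoto_similarity(mat, mat[[best]])
        dist_to_sel = np.hstack([dist_to_sel, new_d])
        crit[:, 0] = np.minimum(crit[:, 0], new_d[:, 0])
    return [ids[i] for i in selected]


def enamine_funnel(
    candidates: Sequence[Candidate],
    clusters: ClusterAssignment,
    known_actives: set,
    known_active_fps: Sequence[Fingerprint],
    filter_set: StructuralFilterSet,
    min_distance: float = 0.35,
    final_n: int = 100,
    diversity_strategy: str = "maxmin",
) -> tuple[list[str], FunnelAudit]:
    """Full synthesize-on-demand selection funnel with audit trail.

    Stages: cluster novelty -> structural filters -> distance novelty ->
    per-cluster representative -> greedy diversity pick of ``final_n``.
    Raises (naming the stage) if any stage empties the candidate list.
    """
    audit = FunnelAudit()
    current = list(candidates)

    def run_stage(name: str, new: list[Candidate], reason: str) -> list[Candidate]:
        audit.record(name, len(current), len(new), reason)
        if not new:
            raise ValueError(f"funnel stage {name!r} removed every candidate")
        return new

    current = run_stage(
        "cluster_novelty",
        cluster_novelty_filter(current, clusters, known_actives),
        "cluster contains a known active",
    )
    survivors, rejections = apply_structural_filters(current, filter_set)
    reason = "; ".join(f"{k}: {v}" for k, v in sorted(rejections.items()))
    current = run_stage("structural_filters", survivors, reason or "none rejected")
    current = run_stage(
        "distance_novelty",
        distance_novelty_filter(current, known_active_fps, min_distance),
        f"nearest known active closer than {min_distance}",
    )
    current = run_stage(
        "cluster_representatives",
        cluster_representatives(current, clusters),
        "kept highest-scoring member per cluster",
    )
    final_ids = greedy_diverse_select(current, final_n, strategy=diversity_strategy)
    audit.record("greedy_diversity", len(current), len(final_ids), f"max-{diversity_strategy[3:]} diversity pick")
    audit.final_ids = list(final_ids)
    return final_ids, audit
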