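"""Rank-based retrieval metrics for highly imbalanced screening data.

The central early-retrieval statistic is the normalized enrichment factor.
For a library of N compounds with A actives, take the top s = ceil(F*N)
compounds of a ranking and count the actives A_s among them:

    EF_F  = (A_s / s) / (A / N)          -- enrichment over random picking
    NEF_F = A_s / min(A, s)              -- EF normalized by a perfect ranking

NEF lies in [0, 1]; NEF_1% (F = 0.01) is the model-selection statistic used
throughout the pipeline.  ROC-AUC and average precision are delegated to
scikit-learn, whose implementations carry the pair-counting (ties as 1/2)
and step-wise (no interpolation) semantics required here; both are checked
against brute-force oracles in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "RankedScores",
    "MetricReport",
    "roc_auc",
    "average_precision",
    "enrichment_factor",
    "normalized_enrichment_factor",
    "random_expected_nef",
    "evaluate_ranking",
    "hit_rate_table",
    "hit_accumulation_curve",
]


@dataclass(frozen=True)
class RankedScores:
    """Per-compound scores with a deterministic total order.

    The order sorts by score descending with ties broken by compound id
    ascending, so every downstream cutoff (top-K, top-F%) is reproducible
    regardless of the score source or input ordering.
    """

    ids: tuple[str, ...]
    scores: tuple[float, ...]
    _order: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate compound ids")
        order = sorted(range(len(self.ids)), key=lambda i: (-self.scores[i], self.ids[i]))
        object.__setattr__(self, "_order", tuple(order))

    @classmethod
    def from_mapping(cls, scores: Mapping[str, float]) -> "RankedScores":
        ids = tuple(scores.keys())
        return cls(ids=ids, scores=tuple(float(scores[i]) for i in ids))

    @classmethod
    def from_arrays(cls, ids: Sequence[str], scores: Sequence[float]) -> "RankedScores":
        return cls(ids=tuple(ids), scores=tuple(float(s) for s in scores))

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def order(self) -> tuple[int, ...]:
        return self._order

    def ranked_ids(self) -> list[str]:
        """Compound ids from best to worst."""
        return [self.ids[i] for i in self._order]

    def top(self, n: int) -> list[str]:
        return self.ranked_ids()[:n]

    def score_of(self, cid: str) -> float:
        try:
            return self.scores[self.ids.index(cid)]
        except ValueError:
            raise KeyError(cid) from None

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.ids, self.scores))


def _aligned_arrays(ranked: RankedScores, labels: Mapping[str, bool]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([bool(labels[cid]) for cid in ranked.ids], dtype=bool)
    s = np.array(ranked.scores, dtype=np.float64)
    return y, s


def roc_auc(ranked: RankedScores, labels: Mapping[str, bool]) -> float:
    """Area under the ROC curve; equals the correctly-ranked pair fraction
    with score ties counted as 1/2.  Requires both classes present."""
    y, s = _aligned_arrays(ranked, labels)
    if y.all() or not y.any():
        raise ValueError("ROC-AUC requires at least one active and one inactive")
    return float(roc_auc_score(y, s))


def average_precision(ranked: RankedScores, labels: Mapping[str, bool]) -> float:
    """Step-wise average precision: sum_k (R_k - R_{k-1}) * P_k over
    descending score thresholds, without interpolation."""
    y, s = _aligned_arrays(ranked, labels)
    if not y.any():
        raise ValueError("average precision requires at least one active")
    return float(average_precision_score(y, s))


def _top_counts(
    ranked: RankedScores, labels: Mapping[str, bool], fraction: float, cutoff: str
) -> tuple[int, int, int, int]:
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(ranked)
    n_active = sum(bool(labels[cid]) for cid in ranked.ids)
    if n_active == 0:
        raise ValueError("no actives in the labeled set")
    if cutoff == "ceil":
        s = math.ceil(fraction * n)
    elif cutoff == "floor":
        s = max(1, math.floor(fraction * n))
    else:
        raise ValueError("cutoff must be 'ceil' or 'floor'")
    top = ranked.ranked_ids()[:s]
    a_s = sum(bool(labels[cid]) for cid in top)
    return n, n_active, s, a_s


def enrichment_factor(
    ranked: RankedScores, labels: Mapping[str, bool], fraction: float, cutoff: str = "ceil"
) -> float:
    """EF_F = (A_s/s) / (A/N) for the top s = ceil(F*N) compounds."""
    n, n_active, s, a_s = _top_counts(ranked, labels, fraction, cutoff)
    return (a_s / s) / (n_active / n)


def normalized_enrichment_factor(
    ranked: RankedScores, labels: Mapping[str, bool], fraction: float, cutoff: str = "ceil"
) -> float:
    """NEF_F = A_s / min(A, s): enrichment relative to a perfect ranking.

    Ties straddling the top-s boundary resolve by the deterministic
    RankedScores order (score descending, id ascending).
    """
    _, n_active, s, a_s = _top_counts(ranked, labels, fraction, cutoff)
    return a_s / min(n_active, s)


def random_expected_nef(n: int, n_active: int, fraction: float, cutoff: str = "ceil") -> float:
    """Expected NEF_F of a uniformly random ranking: (s*A/N) / min(A, s)."""
    if n_active <= 0 or n <= 0:
        raise ValueError("need n > 0 and n_active > 0")
    s = math.ceil(fraction * n) if cutoff == "ceil" else max(1, math.floor(fraction * n))
    return (s * n_active / n) / min(n_active, s)


@dataclass(frozen=True)
class MetricReport:
    """ROC-AUC, AP and NEF at one or more fractions for one ranking."""

    auc_roc: float
    ap: float
    nef: Mapping[float, float]
    n: int
    n_actives: int

    @property
    def nef1(self) -> float:
        """NEF at the 1% fraction (the pipeline's selection statistic)."""
        return self.nef[0.01]


def evaluate_ranking(
    ranked: RankedScores,
    labels: Mapping[str, bool],
    fractions: Sequence[float] = (0.01,),
    cutoff: str = "ceil",
) -> MetricReport:
    """Compute the full metric report for one ranking."""
    n = len(ranked)
    n_actives = sum(bool(labels[cid]) for cid in ranked.ids)
    return MetricReport(
        auc_roc=roc_auc(ranked, labels),
        ap=average_precision(ranked, labels),
        nef={f: normalized_enrichment_factor(ranked, labels, f, cutoff) for f in fractions},
        n=n,
        n_actives=n_actives,
    )


def hit_rate_table(selections: Mapping[str, set], hits: set) -> pd.DataFrame:
    """Set-algebra hit accounting over one or more compound selectors.

    Emits one row per selector plus the union ("A or B"), the intersection
    ("A and B"), and each exclusive difference ("A but not B"), with
    columns selector, count, hits, misses, hit_rate (% to 2 decimals;
    empty selections get a null hit rate).
    """
    names = list(selections.keys())
    union = set().union(*selections.values()) if selections else set()
    stray = hits - union
    if stray:
        raise ValueError(f"{len(stray)} hit ids outside the union of all selections")

    rows: list[tuple[str, set]] = []
    if len(names) > 1:
        rows.append((" or ".join(names), union))
    for name in names:
        rows.append((name, set(selections[name])))
    if len(names) > 1:
        inter = set.intersection(*(set(selections[n]) for n in names))
        rows.append((" and ".join(names), inter))
        for name in names:
            others = set().union(*(selections[o] for o in names if o != name))
            rows.append((f"{name} but not {' or '.join(n for n in names if n != name)}", set(selections[name]) - others))

    out = []
    for label, ids in rows:
        count = len(ids)
        h = len(ids & hits)
        rate = round(100.0 * h / count, 2) if count else None
        out.append({"selector": label, "count": count, "hits": h, "misses": count - h, "hit_rate": rate})
    return pd.DataFrame(out, columns=["selector", "count", "hits", "misses", "hit_rate"])


def hit_accumulation_curve(
    ranked: RankedScores, hits: set, budgets: Sequence[int]
) -> list[tuple[int, int]]:
    """Cumulative hits found in the top-`budget` compounds, per budget."""
    n = len(ranked)
    order = ranked.ranked_ids()
    is_hit = np.array([cid in hits for cid in order], dtype=np.int64)
    cum = np.cumsum(is_hit)
    out = []
    for b in budgets:
        if b <= 0 or b > n:
            raise ValueError(f"budget {b} outside [1, {n}]")
        out.append((int(b), int(cum[b - 1])))
    return out
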