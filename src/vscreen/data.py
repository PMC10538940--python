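"""Screening records, activity labeling, and library-stratified cross-validation.

A training compound is called *active* when the median % inhibition of its
primary screens is at or above a threshold (default 35%), the retest median
(when a retest exists) also clears the threshold, and the compound passes
the PAINS structural-alert filter.  % inhibition is an assay readout
normalized to controls and may be negative or exceed 100.

Folds are built by grouping compounds on their source library and dealing
each group cyclically over a seeded fold permutation, actives first, so per
library group both the active count and the total count differ by at most
one between folds.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .fingerprints import Fingerprint

DEFAULT_ACTIVITY_THRESHOLD = 35.0
DEFAULT_REQUIRED_FILTER = "PAINS"

__all__ = [
    "ScreeningRecord",
    "FoldAssignment",
    "CVRun",
    "assign_training_labels",
    "stratified_library_split",
    "cv_plan",
    "read_screening_csv",
    "write_screening_csv",
    "write_fold_csv",
]


@dataclass(frozen=True)
class ScreeningRecord:
    """One compound's screening history and (once assigned) activity label."""

    id: str
    library: str
    primary_inhibitions: tuple[float, ...]
    retest_inhibitions: tuple[float, ...] | None = None
    filter_flags: Mapping[str, bool] = field(default_factory=dict)
    active: bool | None = None
    fingerprint: Fingerprint | None = None
    smiles: str | None = None

    @property
    def median_primary(self) -> float:
        return statistics.median(self.primary_inhibitions)

    @property
    def median_retest(self) -> float | None:
        if self.retest_inhibitions is None:
            return None
        return statistics.median(self.retest_inhibitions)


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of compound ids into k cross-validation folds."""

    fold_of: Mapping[str, int]
    k: int

    def ids_in_fold(self, fold: int) -> list[str]:
        return [cid for cid, f in self.fold_of.items() if f == fold]

    def as_array(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.fold_of[cid] for cid in ids], dtype=np.int64)


def assign_training_labels(
    records: Sequence[ScreeningRecord],
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    required_filter: str = DEFAULT_REQUIRED_FILTER,
) -> list[ScreeningRecord]:
    """Return records with ``active`` set from the screening rule.

    active <=> median(primary) >= threshold
               and (no retest, or median(retest) >= threshold)
               and filter_flags[required_filter] passes.

    A record missing the required filter flag raises: structural-alert
    status is never defaulted to pass.  Records never retested are labeled
    from the primary screens and the filter alone (in the screening
    workflow only compounds clearing the primary threshold were retested).
    """
    labeled = []
    for rec in records:
        if not rec.primary_inhibitions:
            raise ValueError(f"record {rec.id} has no primary % inhibition values")
        if required_filter not in rec.filter_flags:
            raise ValueError(f"record {rec.id} is missing required filter flag {required_filter!r}")
        active = rec.median_primary >= threshold and bool(rec.filter_flags[required_filter])
        if active and rec.retest_inhibitions is not None:
            active = rec.median_retest >= threshold
        labeled.append(replace(rec, active=active))
    return labeled


def stratified_library_split(
    records: Sequence[ScreeningRecord], k: int = 10, seed: int = 0
) -> FoldAssignment:
    """Library-grouped, activity-stratified k-fold split.

    Within each library group, shuffled actives then shuffled inactives are
    dealt cyclically over a seeded permutation of folds, so per group the
    per-fold active counts differ by <= 1 and the per-fold totals differ
    by <= 1.  Deterministic given the seed; independent of record order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    for rec in records:
        if rec.active is None:
            raise ValueError(f"record {rec.id} has no activity label; run assign_training_labels")
        if not rec.library:
            raise ValueError(f"record {rec.id} has no library tag")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    libraries = sorted({rec.library for rec in records})
    by_library = {lib: [r for r in records if r.library == lib] for lib in libraries}
    for lib in libraries:
        group = by_library[lib]
        if len(group) < k:
            import warnings

            warnings.warn(
                f"library group {lib!r} has {len(group)} members (< k={k}); "
                "spreading as evenly as possible",
                stacklevel=2,
            )
        actives = sorted((r.id for r in group if r.active))
        inactives = sorted((r.id for r in group if not r.active))
        rng.shuffle(actives)
        rng.shuffle(inactives)
        perm = rng.permutation(k)
        for i, cid in enumerate(actives + inactives):
            fold_of[cid] = int(perm[i % k])
    return FoldAssignment(fold_of=fold_of, k=k)


@dataclass(frozen=True)
class CVRun:
    """One cross-validation run: which folds train, validate, and test."""

    train_folds: tuple[int, ...]
    test_fold: int
    validation_fold: int | None = None


DEFAULT_TUNING_TEST_FOLDS = (4, 5, 6, 7)


def cv_plan(
    stage: str,
    k: int = 10,
    tuning_test_folds: Sequence[int] = DEFAULT_TUNING_TEST_FOLDS,
) -> list[CVRun]:
    """Cross-validation plan for a pipeline stage.

    ``tuning``: four runs confined to folds 0-7, each holding out one of
    ``tuning_test_folds`` for testing and training on the other seven.
    ``selection``: a single run training on folds 0-7 with fold k-2 for
    validation and fold k-1 for testing.
    """
    if k != 10:
        raise ValueError("the staged pipeline is defined for k = 10 folds")
    if stage == "tuning":
        first_eight = tuple(range(8))
        runs = []
        for t in tuning_test_folds:
            if t not in first_eight:
                raise ValueError("tuning runs may only use the first eight folds")
            runs.append(CVRun(train_folds=tuple(f for f in first_eight if f != t), test_fold=t))
        return runs
    if stage == "selection":
        return [CVRun(train_folds=tuple(range(8)), validation_fold=8, test_fold=9)]
    raise ValueError(f"unknown stage {stage!r}; expected 'tuning' or 'selection'")


# --- CSV interchange --------------------------------------------------------


def write_screening_csv(path, records: Sequence[ScreeningRecord]) -> None:
    """Write records as CSV: id,smiles,library,primary_*,retest_*,pains_pass.

    When records carry fingerprints an ``fp_bits`` column holds the on-bit
    indices (semicolon-separated) prefixed by the width, e.g. ``1024:3;17``,
    so fingerprint-native libraries survive the roundtrip without SMILES.
    """
    n_primary = max(len(r.primary_inhibitions) for r in records)
    n_retest = max((len(r.retest_inhibitions or ()) for r in records), default=0)
    with_fp = any(r.fingerprint is not None for r in records)
    header = (
        ["id", "smiles", "library"]
        + [f"primary_inhib_{i + 1}" for i in range(n_primary)]
        + [f"retest_inhib_{i + 1}" for i in range(n_retest)]
        + ["pains_pass"]
        + (["fp_bits"] if with_fp else [])
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            prim = list(r.primary_inhibitions) + [""] * (n_primary - len(r.primary_inhibitions))
            ret = list(r.retest_inhibitions or ())
            ret += [""] * (n_retest - len(ret))
            row = (
                [r.id, r.smiles or "", r.library]
                + [f"{v:.4f}" if v != "" else "" for v in prim]
                + [f"{v:.4f}" if v != "" else "" for v in ret]
                + [int(bool(r.filter_flags.get("PAINS", False)))]
            )
            if with_fp:
                fp = r.fingerprint
                row.append(
                    f"{fp.n_bits}:" + ";".join(str(b) for b in fp.on_bits) if fp else ""
                )
            writer.writerow(row)


def read_screening_csv(path) -> list[ScreeningRecord]:
    """Read the CSV written by :func:`write_screening_csv`."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            primary = tuple(
                float(v)
                for key, v in row.items()
                if key.startswith("primary_inhib_") and v not in ("", None)
            )
            retest = tuple(
                float(v)
                for key, v in row.items()
                if key.startswith("retest_inhib_") and v not in ("", None)
            )
            fingerprint = None
            raw_fp = row.get("fp_bits")
            if raw_fp:
                width, _, bits = raw_fp.partition(":")
                fingerprint = Fingerprint(
                    on_bits=tuple(int(b) for b in bits.split(";") if b),
                    n_bits=int(width),
                )
            records.append(
                ScreeningRecord(
                    id=row["id"],
                    library=row["library"],
                    primary_inhibitions=primary,
                    retest_inhibitions=retest or None,
                    filter_flags={"PAINS": bool(int(row["pains_pass"]))},
                    smiles=row.get("smiles") or None,
                    fingerprint=fingerprint,
                )
            )
    return records


def write_fold_csv(path, records: Sequence[ScreeningRecord], folds: FoldAssignment) -> None:
    """Write the fold assignment as CSV: id,fold,active."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "fold", "active"])
        for r in records:
            writer.writerow([r.id, folds.fold_of[r.id], int(bool(r.active))])
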