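"""Synthetic screening libraries with the statistical structure of a real
high-throughput screen.

The generator emulates the features the analysis pipeline relies on:

* **chemotype structure** — compounds belong to chemotype series, each
  defined by a template bit-signature; fingerprints are the template core
  plus symmetric bit-flip noise, so within-series Tanimoto distances are
  small and between-series distances large;
* **extreme class imbalance** — activity lives in a small minority of
  chemotypes; the member allocation is calibrated (by Gauss-Hermite
  integration over the latent % inhibition distribution) so the *labeled*
  active fraction matches a target rate, 0.13% by default;
* **activity cliffs** — each active chemotype carries a deactivation-motif
  bit set; a ``cliff_rate`` fraction of its members get the motif and
  background activity, making inactives informative: a supervised model can
  learn the motif while a pure similarity search cannot;
* **assay noise** — replicate % inhibition readouts are Gaussian around a
  latent per-compound inhibition (negative values permitted, as in real
  screens); compounds clearing the primary threshold are retested, mirroring
  the screening workflow; a small fraction carries PAINS flags;
* **multiple source libraries** — records carry library tags in configured
  proportions for the library-stratified fold split.

Everything is bit-reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .data import ScreeningRecord
from .fingerprints import Fingerprint, fingerprint_from_dense

__all__ = [
    "ChemotypeTemplate",
    "SyntheticLibraryConfig",
    "generate_chemotypes",
    "generate_screening_library",
    "generate_prospective_library",
    "ProspectiveOracle",
    "generate_smiles_library",
]


@dataclass(frozen=True)
class ChemotypeTemplate:
    """A chemotype series: core bit signature plus activity parameters.

    ``cliff_bits`` is the deactivation motif: members carrying it draw
    their activity from the background distribution regardless of the
    series' potency.
    """

    template_id: int
    core_bits: tuple[int, ...]
    active_propensity: float
    inhibition_mean: float
    inhibition_sd: float
    cliff_bits: tuple[int, ...] = ()


@dataclass(frozen=True)
class SyntheticLibraryConfig:
    """Study conditions for the synthetic screen.

    Defaults emulate the screening campaign the pipeline targets: a labeled
    active rate of 0.13%, two source libraries in roughly 1:3 proportion,
    a 35% single-point activity threshold set at ~3 standard deviations of
    the background % inhibition readout, and duplicate primary/retest
    measurements.
    """

    n_compounds: int = 100_000
    n_bits: int = 1024
    n_chemotypes: int = 50
    active_chemotype_fraction: float = 0.1
    active_fraction_target: float = 0.0013
    libraries: tuple[tuple[str, float], ...] = (("LC1234", 0.234), ("MLPCN", 0.766))
    chemotype_member_fraction: float = 0.7
    core_popcount: int = 45
    cliff_popcount: int = 12
    core_distance_margin: float = 0.6
    bit_flip_noise: float = 0.01
    replicate_sd: float = 8.0
    background_sd: float = 8.5
    inhibition_mean_range: tuple[float, float] = (45.0, 95.0)
    inhibition_sd_range: tuple[float, float] = (5.0, 12.0)
    cliff_rate: float = 0.15
    pains_fail_rate: float = 0.02
    n_primary_replicates: int = 2
    n_retest_replicates: int = 2
    activity_threshold: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(p for _, p in self.libraries) - 1.0) > 1e-9:
            raise ValueError("library proportions must sum to 1")
        for name, p in (
            ("active_fraction_target", self.active_fraction_target),
            ("bit_flip_noise", self.bit_flip_noise),
            ("cliff_rate", self.cliff_rate),
            ("pains_fail_rate", self.pains_fail_rate),
            ("chemotype_member_fraction", self.chemotype_member_fraction),
            ("active_chemotype_fraction", self.active_chemotype_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")


def _core_distance(a: set, b: set) -> float:
    union = len(a | b)
    return 1.0 - (len(a & b) / union if union else 1.0)


def generate_chemotypes(
    config: SyntheticLibraryConfig, rng: np.random.Generator | None = None
) -> list[ChemotypeTemplate]:
    """Draw chemotype templates with mutually distant core signatures.

    Cores are random ``core_popcount``-bit subsets, rejected until every
    pairwise core Tanimoto distance exceeds ``core_distance_margin``.  A
    minority (``active_chemotype_fraction``) of templates is active, with
    per-series potency above the labeling threshold and a deactivation
    motif for cliff members.
    """
    if config.n_chemotypes < 2:
        raise ValueError("need at least 2 chemotypes")
    if config.core_popcount * 2 > config.n_bits:
        raise ValueError("n_bits too small to host mutually distant cores")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cores: list[set] = []
    attempts = 0
    while len(cores) < config.n_chemotypes:
        attempts += 1
        if attempts > 200 * config.n_chemotypes:
            raise ValueError(
                "could not place mutually distant chemotype cores; "
                "n_bits too small for the requested margin"
            )
        cand = set(rng.choice(config.n_bits, size=config.core_popcount, replace=False).tolist())
        if all(_core_distance(cand, c) > config.core_distance_margin for c in cores):
            cores.append(cand)

    n_active = max(1, round(config.active_chemotype_fraction * config.n_chemotypes))
    active_ids = set(rng.choice(config.n_chemotypes, size=n_active, replace=False).tolist())
    templates = []
    for tid, core in enumerate(cores):
        if tid in active_ids:
            mean = float(rng.uniform(*config.inhibition_mean_range))
            sd = float(rng.uniform(*config.inhibition_sd_range))
            off_core = np.array(sorted(set(range(config.n_bits)) - core))
            cliff = tuple(
                int(b) for b in rng.choice(off_core, size=config.cliff_popcount, replace=False)
            )
            templates.append(
                ChemotypeTemplate(
                    template_id=tid,
                    core_bits=tuple(sorted(core)),
                    active_propensity=1.0 - config.cliff_rate,
                    inhibition_mean=mean,
                    inhibition_sd=sd,
                    cliff_bits=tuple(sorted(cliff)),
                )
            )
        else:
            templates.append(
                ChemotypeTemplate(
                    template_id=tid,
                    core_bits=tuple(sorted(core)),
                    active_propensity=0.0,
                    inhibition_mean=0.0,
                    inhibition_sd=config.background_sd,
                )
            )
    return templates


def _label_pass_prob(
    mean: float, sd: float, threshold: float, replicate_sd: float, n_reps: int
) -> float:
    """P(primary median >= t AND retest median >= t) for latent inhibition
    mu ~ N(mean, sd), via 64-node Gauss-Hermite integration."""
    nodes, weights = np.polynomial.hermite.hermgauss(64)
    mu = mean + sd * math.sqrt(2.0) * nodes
    se = replicate_sd / math.sqrt(n_reps)
    g = norm.cdf((mu - threshold) / se)
    return float((weights * g**2).sum() / math.sqrt(math.pi))


def _calibrated_active_members(
    templates: Sequence[ChemotypeTemplate], config: SyntheticLibraryConfig, n: int
) -> int:
    """Number of active-chemotype members needed for the target labeled rate."""
    active = [t for t in templates if t.active_propensity > 0]
    if not active:
        raise ValueError("no active chemotypes")
    p_act = float(
        np.mean(
            [
                _label_pass_prob(
                    t.inhibition_mean,
                    t.inhibition_sd,
                    config.activity_threshold,
                    config.replicate_sd,
                    config.n_primary_replicates,
                )
                for t in active
            ]
        )
    )
    p_bg = _label_pass_prob(
        0.0,
        config.background_sd,
        config.activity_threshold,
        config.replicate_sd,
        config.n_primary_replicates,
    )
    q_pains = 1.0 - config.pains_fail_rate
    denom = (1.0 - config.cliff_rate) * (p_act - p_bg) * q_pains
    if denom <= 0:
        raise ValueError("active chemotypes are not separable from background; infeasible target")
    m = (config.active_fraction_target * n - n * p_bg * q_pains) / denom
    n_members = round(config.chemotype_member_fraction * n)
    if m < 1 or m > n_members:
        raise ValueError(
            f"active fraction target {config.active_fraction_target} infeasible "
            f"(needs {m:.0f} active-chemotype members of {n_members} available)"
        )
    return int(round(m))


def _split_counts(total: int, k: int) -> list[int]:
    base, extra = divmod(total, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _member_fingerprints(
    rng: np.random.Generator,
    core: np.ndarray,
    count: int,
    noise: float,
    n_bits: int,
    add_bits: Sequence[int] = (),
) -> list[Fingerprint]:
    out: list[Fingerprint] = []
    block = 4096
    for start in range(0, count, block):
        g = min(block, count - start)
        flips = rng.random((g, n_bits)) < noise
        rows = np.logical_xor(core[None, :].astype(bool), flips)
        if len(add_bits):
            rows[:, list(add_bits)] = True
        for row in rows:
            out.append(fingerprint_from_dense(row.astype(np.uint8)))
    return out


def _background_fingerprints(
    rng: np.random.Generator, count: int, popcount_mean: int, n_bits: int
) -> list[Fingerprint]:
    out = []
    pops = np.clip(rng.poisson(popcount_mean, size=count), 1, n_bits)
    for p in pops:
        bits = rng.choice(n_bits, size=int(p), replace=False)
        out.append(Fingerprint(on_bits=tuple(int(b) for b in bits), n_bits=n_bits))
    return out


@dataclass
class _CompoundPlan:
    template_id: int | None  # None = background
    is_cliff: bool


def _plan_member_pool(
    templates: Sequence[ChemotypeTemplate],
    config: SyntheticLibraryConfig,
    n_members: int,
    rng: np.random.Generator,
) -> list[_CompoundPlan]:
    """Plan ``n_members`` chemotype members with the calibrated active share."""
    active = [t for t in templates if t.active_propensity > 0]
    inactive = [t for t in templates if t.active_propensity == 0]
    implied_n = max(1, round(n_members / max(config.chemotype_member_fraction, 1e-9)))
    m_active = min(_calibrated_active_members(templates, config, implied_n), n_members)
    plans: list[_CompoundPlan] = []
    for t, cnt in zip(active, _split_counts(m_active, len(active))):
        cliff_mask = rng.random(cnt) < config.cliff_rate
        plans.extend(_CompoundPlan(t.template_id, bool(c)) for c in cliff_mask)
    if inactive:
        for t, cnt in zip(inactive, _split_counts(n_members - m_active, len(inactive))):
            plans.extend(_CompoundPlan(t.template_id, False) for _ in range(cnt))
    return plans


def _plan_compounds(
    templates: Sequence[ChemotypeTemplate],
    config: SyntheticLibraryConfig,
    n: int,
    rng: np.random.Generator,
) -> list[_CompoundPlan]:
    n_members = round(config.chemotype_member_fraction * n)
    plans = _plan_member_pool(templates, config, n_members, rng)
    plans.extend(_CompoundPlan(None, False) for _ in range(n - len(plans)))
    return plans


def _realize_fingerprints(
    plans: Sequence[_CompoundPlan],
    templates: Sequence[ChemotypeTemplate],
    config: SyntheticLibraryConfig,
    rng: np.random.Generator,
) -> list[Fingerprint]:
    by_template: dict[int, ChemotypeTemplate] = {t.template_id: t for t in templates}
    fps: list[Fingerprint | None] = [None] * len(plans)
    # group contiguous runs per (template, cliff) for vectorized generation
    groups: dict[tuple[int | None, bool], list[int]] = {}
    for i, p in enumerate(plans):
        groups.setdefault((p.template_id, p.is_cliff), []).append(i)
    for (tid, is_cliff), idxs in groups.items():
        if tid is None:
            gen = _background_fingerprints(rng, len(idxs), config.core_popcount, config.n_bits)
        else:
            t = by_template[tid]
            core = np.zeros(config.n_bits, dtype=np.uint8)
            core[list(t.core_bits)] = 1
            add = t.cliff_bits if is_cliff else ()
            gen = _member_fingerprints(
                rng, core, len(idxs), config.bit_flip_noise, config.n_bits, add
            )
        for i, fp in zip(idxs, gen):
            fps[i] = fp
    return fps  # type: ignore[return-value]


def _latent_inhibitions(
    plans: Sequence[_CompoundPlan],
    templates: Sequence[ChemotypeTemplate],
    config: SyntheticLibraryConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    by_template = {t.template_id: t for t in templates}
    mu = np.empty(len(plans))
    for i, p in enumerate(plans):
        if p.template_id is None or p.is_cliff:
            mu[i] = rng.normal(0.0, config.background_sd)
        else:
            t = by_template[p.template_id]
            if t.active_propensity > 0:
                mu[i] = rng.normal(t.inhibition_mean, t.inhibition_sd)
            else:
                mu[i] = rng.normal(0.0, config.background_sd)
    return mu


def generate_screening_library(
    templates: Sequence[ChemotypeTemplate],
    config: SyntheticLibraryConfig,
    seed: int | None = None,
    id_prefix: str = "SYN",
    return_truth: bool = False,
):
    """Generate a labeled-screen-ready library of ScreeningRecords.

    Emulates the screening workflow: every compound gets
    ``n_primary_replicates`` % inhibition readouts around its latent
    inhibition; compounds whose primary median clears the activity
    threshold and that pass PAINS are retested.  Labels are *not* assigned
    here — run ``assign_training_labels`` — but the member allocation is
    calibrated so the realized labeled active fraction matches
    ``active_fraction_target`` in expectation.

    With ``return_truth=True`` also returns ``{id: template_id | None}``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_compounds
    plans = _plan_compounds(templates, config, n, rng)
    fps = _realize_fingerprints(plans, templates, config, rng)
    mu = _latent_inhibitions(plans, templates, config, rng)

    lib_names = [name for name, _ in config.libraries]
    lib_probs = [p for _, p in config.libraries]
    lib_idx = rng.choice(len(lib_names), size=n, p=lib_probs)
    pains_fail = rng.random(n) < config.pains_fail_rate
    primary = mu[:, None] + rng.normal(0.0, config.replicate_sd, size=(n, config.n_primary_replicates))

    records = []
    truth: dict[str, int | None] = {}
    width = len(str(n))
    for i in range(n):
        cid = f"{id_prefix}-{i:0{width}d}"
        prim = tuple(float(v) for v in primary[i])
        retest = None
        if float(np.median(prim)) >= config.activity_threshold and not pains_fail[i]:
            retest = tuple(
                float(mu[i] + rng.normal(0.0, config.replicate_sd))
                for _ in range(config.n_retest_replicates)
            )
        records.append(
            ScreeningRecord(
                id=cid,
                library=lib_names[lib_idx[i]],
                primary_inhibitions=prim,
                retest_inhibitions=retest,
                filter_flags={"PAINS": not pains_fail[i]},
                fingerprint=fps[i],
            )
        )
        truth[cid] = plans[i].template_id
    if return_truth:
        return records, truth
    return records


class ProspectiveOracle:
    """Hidden ground truth for a prospective library.

    Holds each compound's latent % inhibition, PAINS status, and chemotype
    provenance; used only by tests and simulated confirmatory screens,
    never by the pipeline itself.
    """

    def __init__(
        self,
        latent_inhibition: Mapping[str, float],
        pains_pass: Mapping[str, bool],
        template_of: Mapping[str, int | None],
        novel_templates: frozenset,
        activity_threshold: float,
        replicate_sd: float,
    ):
        self._mu = dict(latent_inhibition)
        self._pains = dict(pains_pass)
        self._template = dict(template_of)
        self.novel_templates = novel_templates
        self.activity_threshold = activity_threshold
        self.replicate_sd = replicate_sd

    def true_active(self, cid: str) -> bool:
        return self._mu[cid] >= self.activity_threshold

    def latent_inhibition(self, cid: str) -> float:
        return self._mu[cid]

    def pains_pass(self, cid: str) -> bool:
        return self._pains[cid]

    def template_of(self, cid: str) -> int | None:
        return self._template[cid]

    def is_novel(self, cid: str) -> bool:
        return self._template[cid] in self.novel_templates

    def simulate_assay(
        self, ids: Sequence[str], n_replicates: int = 2, seed: int = 0
    ) -> dict[str, tuple[float, ...]]:
        """Simulated confirmatory screen: replicate readouts per compound."""
        rng = np.random.default_rng(seed)
        return {
            cid: tuple(
                float(v)
                for v in self._mu[cid] + rng.normal(0.0, self.replicate_sd, size=n_replicates)
            )
            for cid in ids
        }


def _related_core(
    rng: np.random.Generator,
    parent_core: set,
    all_cores: Sequence[set],
    relatedness: float,
    popcount: int,
    n_bits: int,
    min_distance: float,
) -> set:
    """Draw a 'scaffold hop' core: inherits a fraction of a parent active
    chemotype's bits, fills the rest with fresh bits, and stays at least
    ``min_distance`` from every existing core."""
    n_inherit = int(round(relatedness * min(popcount, len(parent_core))))
    outside = np.array(sorted(set(range(n_bits)) - parent_core))
    for _ in range(200):
        inherited = set(
            rng.choice(sorted(parent_core), size=n_inherit, replace=False).tolist()
        )
        fresh = set(rng.choice(outside, size=popcount - n_inherit, replace=False).tolist())
        core = inherited | fresh
        if all(_core_distance(core, c) >= min_distance for c in all_cores):
            return core
    raise ValueError("could not place a related novel core at the requested distance")


def generate_prospective_library(
    templates: Sequence[ChemotypeTemplate],
    config: SyntheticLibraryConfig,
    novel_chemotype_fraction: float = 0.2,
    n_compounds: int | None = None,
    seed: int | None = None,
    id_prefix: str = "PRO",
    novel_relatedness: float = 0.6,
    min_novel_core_distance: float = 0.45,
    novel_active_fraction: float | None = None,
) -> tuple[list[tuple[str, Fingerprint]], ProspectiveOracle]:
    """Generate an unlabeled prospective library plus its hidden oracle.

    A ``novel_chemotype_fraction`` share of chemotype members comes from
    templates unseen in training (with the usual active minority), so
    selectors can be scored on genuinely novel chemotypes.  Novel *active*
    chemotypes are scaffold hops: they inherit ``novel_relatedness`` of
    their core bits from a training active chemotype — close enough in
    substructure for a trained model to reach, yet at least
    ``min_novel_core_distance`` from every training core so they cluster
    separately.  Novel inactive chemotypes are drawn fresh.

    ``novel_active_fraction`` sets the active share among novel chemotypes
    (default: the config's ``active_chemotype_fraction``); prospective
    slices aimed at hit discovery can carry several undiscovered active
    series.
    """
    if not 0.0 <= novel_chemotype_fraction <= 1.0:
        raise ValueError("novel_chemotype_fraction must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = n_compounds if n_compounds is not None else config.n_compounds

    novel_templates: list[ChemotypeTemplate] = []
    if novel_chemotype_fraction > 0:
        n_novel = max(2, round(novel_chemotype_fraction * config.n_chemotypes))
        active_share = (
            config.active_chemotype_fraction
            if novel_active_fraction is None
            else novel_active_fraction
        )
        if not 0.0 <= active_share <= 1.0:
            raise ValueError("novel_active_fraction must be in [0, 1]")
        n_novel_active = max(1, round(active_share * n_novel))
        parents = [t for t in templates if t.active_propensity > 0]
        if not parents:
            raise ValueError("no active training chemotypes to relate novel actives to")
        existing_cores = [set(t.core_bits) for t in templates]
        offset = max(t.template_id for t in templates) + 1
        all_cores = list(existing_cores)
        for i in range(n_novel):
            tid = offset + i
            if i < n_novel_active:
                parent = parents[int(rng.integers(0, len(parents)))]
                core = _related_core(
                    rng, set(parent.core_bits), all_cores, novel_relatedness,
                    config.core_popcount, config.n_bits, min_novel_core_distance,
                )
                off_core = np.array(sorted(set(range(config.n_bits)) - core))
                cliff = rng.choice(off_core, size=config.cliff_popcount, replace=False)
                novel_templates.append(
                    ChemotypeTemplate(
                        template_id=tid,
                        core_bits=tuple(sorted(core)),
                        active_propensity=1.0 - config.cliff_rate,
                        inhibition_mean=float(rng.uniform(*config.inhibition_mean_range)),
                        inhibition_sd=float(rng.uniform(*config.inhibition_sd_range)),
                        cliff_bits=tuple(int(b) for b in sorted(cliff)),
                    )
                )
            else:
                for _ in range(200):
                    cand = set(
                        rng.choice(config.n_bits, size=config.core_popcount,
                                   replace=False).tolist()
                    )
                    if all(
                        _core_distance(cand, c) >= min_novel_core_distance
                        for c in all_cores
                    ):
                        break
                else:
                    raise ValueError("could not place novel chemotype cores")
                novel_templates.append(
                    ChemotypeTemplate(
                        template_id=tid,
                        core_bits=tuple(sorted(cand)),
                        active_propensity=0.0,
                        inhibition_mean=0.0,
                        inhibition_sd=config.background_sd,
                    )
                )
            all_cores.append(set(novel_templates[-1].core_bits))

    # split chemotype members between training-series and novel-series pools
    n_members = round(config.chemotype_member_fraction * n)
    n_novel_members = round(novel_chemotype_fraction * n_members) if novel_templates else 0
    n_train_members = n_members - n_novel_members

    plans: list[_CompoundPlan] = []
    if n_train_members:
        plans.extend(_plan_member_pool(templates, config, n_train_members, rng))
    if novel_templates and n_novel_members:
        plans.extend(_plan_member_pool(novel_templates, config, n_novel_members, rng))
    plans.extend(_CompoundPlan(None, False) for _ in range(n - len(plans)))

    all_templates = list(templates) + novel_templates
    fps = _realize_fingerprints(plans, all_templates, config, rng)
    mu = _latent_inhibitions(plans, all_templates, config, rng)
    pains_fail = rng.random(n) < config.pains_fail_rate

    width = len(str(n))
    ids = [f"{id_prefix}-{i:0{width}d}" for i in range(n)]
    compounds = list(zip(ids, fps))
    oracle = ProspectiveOracle(
        latent_inhibition=dict(zip(ids, mu)),
        pains_pass={cid: not f for cid, f in zip(ids, pains_fail)},
        template_of={cid: p.template_id for cid, p in zip(ids, plans)},
        novel_templates=frozenset(t.template_id for t in novel_templates),
        activity_threshold=config.activity_threshold,
        replicate_sd=config.replicate_sd,
    )
    return compounds, oracle


# --- optional SMILES mode ----------------------------------------------------

_SCAFFOLDS = (
    "c1ccc({})cc1",
    "c1ccnc({})c1",
    "c1ccc2[nH]c({})cc2c1",
    "c1ccc(-c2ccc({})cc2)cc1",
    "C1CCN({})CC1",
    "c1ccc2ncc({})cc2c1",
    "c1cnc2[nH]ccc2c1{}",
    "O=C(c1ccccc1){}",
)

_SUBSTITUENTS = (
    "C", "CC", "CCC", "O", "OC", "N", "NC", "Cl", "Br", "F",
    "C(=O)O", "C(=O)NC", "C#N", "CO", "C(F)(F)F", "S(=O)(=O)N",
)

_COUNTER_IONS = ("", ".Cl", ".[Na+].[Cl-]", ".Br")


def generate_smiles_library(
    n_compounds: int, seed: int = 0, n_scaffolds: int = 4, salt_fraction: float = 0.2
) -> list[tuple[str, str, int]]:
    """Small scaffold+substituent SMILES library for end-to-end tests.

    Returns ``[(smiles, id, scaffold_index)]``; chemotypes are scaffolds,
    members differ in their substituent, and a fraction carries counter-ion
    suffixes to exercise salt stripping.
    """
    if not 1 <= n_scaffolds <= len(_SCAFFOLDS):
        raise ValueError(f"n_scaffolds must be in [1, {len(_SCAFFOLDS)}]")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_compounds):
        s = int(rng.integers(0, n_scaffolds))
        sub = _SUBSTITUENTS[int(rng.integers(0, len(_SUBSTITUENTS)))]
        smiles = _SCAFFOLDS[s].format(sub)
        if rng.random() < salt_fraction:
            smiles += _COUNTER_IONS[int(rng.integers(1, len(_COUNTER_IONS)))]
        out.append((smiles, f"SMI-{i:05d}", s))
    return out
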