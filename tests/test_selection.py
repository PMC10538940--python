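"""AMS-style union selection, hit calls, and the diversity funnel."""

import itertools

import numpy as np
import pytest

from conftest import random_fingerprints
from vscreen.clustering import taylor_butina
from vscreen.fingerprints import Fingerprint, tanimoto_distance
from vscreen.metrics import RankedScores
from vscreen.selection import (
    Candidate,
    FunnelAudit,
    StructuralFilterSet,
    ams_hit_call,
    ams_select,
    apply_structural_filters,
    cluster_novelty_filter,
    cluster_representatives,
    distance_novelty_filter,
    enamine_funnel,
    greedy_diverse_select,
    lipinski_pass,
    median_hit_call,
)


def fp(bits, n_bits=64):
    return Fingerprint(tuple(bits), n_bits)


class TestAmsSelect:
    def _scores(self, mapping):
        return RankedScores.from_mapping(mapping)

    def test_identical_models_union_equals_budget(self):
        scores = self._scores({f"c{i}": 1.0 - i * 0.01 for i in range(20)})
        sel = ams_select({"A": scores, "B": scores}, top_n=10, per_model_budget=5)
        assert len(sel.union_ids) == 5

    def test_disjoint_top_lists_double_the_budget(self):
        a = self._scores({f"a{i}": 1.0 - i * 0.01 for i in range(10)}
                         | {f"b{i}": 0.0 for i in range(10)})
        b = self._scores({f"b{i}": 1.0 - i * 0.01 for i in range(10)}
                         | {f"a{i}": 0.0 for i in range(10)})
        sel = ams_select({"A": a, "B": b}, top_n=5, per_model_budget=5)
        assert len(sel.union_ids) == 10

    def test_hand_enumerated_overlap_and_membership(self):
        # model A top3 = x1,x2,x3 ; model B top3 = x3,y1,y2 -> union of budgets = 5
        ids = ["x1", "x2", "x3", "y1", "y2", "z1", "z2", "z3", "z4", "z5"]
        a_scores = {"x1": 0.9, "x2": 0.8, "x3": 0.7}
        b_scores = {"x3": 0.9, "y1": 0.8, "y2": 0.7}
        a = self._scores({i: a_scores.get(i, 0.1) for i in ids})
        b = self._scores({i: b_scores.get(i, 0.1) for i in ids})
        sel = ams_select({"A": a, "B": b}, top_n=3, per_model_budget=3)
        assert sorted(sel.union_ids) == ["x1", "x2", "x3", "y1", "y2"]
        assert set(sel.selected_by["A"]) == {"x1", "x2", "x3"}
        assert "x3" in sel.credited_to["A"] and "x3" in sel.credited_to["B"]
        assert len(sel.union_ids) == len(sel.selected_by["A"]) + len(sel.selected_by["B"]) - 1

    def test_union_cardinality_identity_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        ids = [f"c{i:03d}" for i in range(100)]
        for _ in range(10):
            a = self._scores(dict(zip(ids, rng.random(100))))
            b = self._scores(dict(zip(ids, rng.random(100))))
            sel = ams_select({"A": a, "B": b}, top_n=30, per_model_budget=20)
            sa, sb = set(sel.selected_by["A"]), set(sel.selected_by["B"])
            assert len(sel.union_ids) == len(sa) + len(sb) - len(sa & sb)

    def test_attribute_filter_prunes_before_budget(self):
        scores = self._scores({f"c{i}": 1.0 - i * 0.01 for i in range(10)})
        sel = ams_select(
            {"A": scores}, top_n=6, per_model_budget=3,
            attribute_filter=lambda cid: cid not in {"c0", "c1"},
        )
        assert sel.selected_by["A"] == ("c2", "c3", "c4")
        # credit still covers the filtered-out top compounds
        assert "c0" in sel.credited_to["A"]

    def test_budget_exceeding_top_n_rejected(self):
        scores = self._scores({"a": 1.0})
        with pytest.raises(ValueError):
            ams_select({"A": scores}, top_n=5, per_model_budget=10)


class TestHitCall:
    @pytest.mark.parametrize("reps,pains,expect", [
        ((55.0, 62.0), True, True),
        ((55.0, 48.0), True, False),
        ((80.0, 80.0), False, False),
        ((50.0, 50.0), True, True),  # inclusive boundary by default
    ])
    def test_hit_rule(self, reps, pains, expect):
        assert ams_hit_call(reps, pains) is expect

    def test_strict_boundary_option(self):
        assert ams_hit_call((50.0, 55.0), True, strict=True) is False

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            ams_hit_call((60.0,), True)

    def test_monotone_in_each_replicate(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            reps = tuple(rng.uniform(0, 100, 2))
            if ams_hit_call(reps, True):
                assert ams_hit_call((reps[0] + 5, reps[1]), True)
                assert ams_hit_call((reps[0], reps[1] + 5), True)

    def test_median_variant(self):
        assert median_hit_call((40.0, 55.0, 60.0, 70.0)) is True
        assert median_hit_call((10.0, 20.0, 60.0, 70.0)) is False


def make_candidates(spec):
    """spec: list of (id, bits, score[, flags])"""
    out = []
    for item in spec:
        cid, bits, score = item[:3]
        flags = item[3] if len(item) > 3 else {}
        out.append(Candidate(id=cid, fingerprint=fp(bits), score=score, flags=flags))
    return out


class TestFunnelStages:
    def test_cluster_novelty_removes_cohabiting_candidates(self):
        fps = [("cand1", fp({1, 2})), ("cand2", fp({30, 31})), ("act", fp({1, 2}))]
        clusters = taylor_butina(fps, 0.3)
        cands = make_candidates([("cand1", {1, 2}, 0.9), ("cand2", {30, 31}, 0.8)])
        out = cluster_novelty_filter(cands, clusters, known_actives={"act"})
        assert [c.id for c in out] == ["cand2"]

    def test_cluster_novelty_identity_without_known_actives(self):
        fps = [("cand1", fp({1, 2})), ("cand2", fp({30, 31}))]
        clusters = taylor_butina(fps, 0.3)
        cands = make_candidates([("cand1", {1, 2}, 0.9), ("cand2", {30, 31}, 0.8)])
        assert cluster_novelty_filter(cands, clusters, set()) == cands

    def test_structural_filters_from_precomputed_flags(self):
        cands = make_candidates([
            ("a", {1}, 0.9, {"PAINS": True, "Inpharmatica": True}),
            ("b", {2}, 0.8, {"PAINS": False, "Inpharmatica": True}),
            ("c", {3}, 0.7, {"PAINS": True, "Inpharmatica": False}),
            ("d", {4}, 0.6, {"PAINS": False, "Inpharmatica": False}),
        ])
        fs = StructuralFilterSet.from_flags(["PAINS", "Inpharmatica"])
        survivors, rejections = apply_structural_filters(cands, fs)
        assert [c.id for c in survivors] == ["a"]
        assert rejections == {"PAINS": 2, "Inpharmatica": 2}

    def test_unavailable_filter_fails_closed(self):
        cands = make_candidates([("a", {1}, 0.9, {"PAINS": True})])
        fs = StructuralFilterSet.from_flags(["PAINS", "Inpharmatica"])
        with pytest.raises(ValueError, match="Inpharmatica"):
            apply_structural_filters(cands, fs)

    def test_alert_catalog_rule_flags_known_interferer(self):
        from vscreen.selection import rdkit_catalog_filter

        rule = rdkit_catalog_filter("PAINS")
        rhodanine = Candidate(id="r", fingerprint=fp({1}), score=0.5,
                              smiles="O=C1CSC(=S)N1CC=Cc1ccccc1")
        benign = Candidate(id="b", fingerprint=fp({1}), score=0.5, smiles="CCO")
        assert rule(rhodanine) is False
        assert rule(benign) is True
        # no structure available -> unavailable, to be handled fail-closed
        assert rule(Candidate(id="n", fingerprint=fp({1}), score=0.1)) is None

    def test_lipinski_descriptor_rule(self):
        assert lipinski_pass("CCO")  # ethanol: no violations
        # a large, very lipophilic molecule: violates MW and logP
        big = "C" * 60
        assert not lipinski_pass(big)
        assert lipinski_pass(big, max_violations=4)

    def test_distance_novelty_inclusive_boundary(self):
        # distances to the single known active: 0.0, ~0.33, 1.0
        known = [fp(set(range(9)))]
        cands = make_candidates([
            ("same", set(range(9)), 0.9),
            ("near", set(range(6)) | {20, 21, 22}, 0.8),   # d = 1 - 6/12 = 0.5
            ("far", {40, 41}, 0.7),
        ])
        out = distance_novelty_filter(cands, known, min_distance=0.5)
        assert [c.id for c in out] == ["near", "far"]
        assert distance_novelty_filter(cands, known, min_distance=0.0) == list(cands)

    def test_distance_novelty_needs_known_actives(self):
        with pytest.raises(ValueError):
            distance_novelty_filter([], [], 0.35)

    def test_cluster_representatives_max_score_tie_by_id(self):
        fps = [("a", fp({1, 2})), ("b", fp({1, 2})), ("c", fp({30, 31}))]
        clusters = taylor_butina(fps, 0.3)
        cands = make_candidates([("a", {1, 2}, 0.7), ("b", {1, 2}, 0.9), ("c", {30, 31}, 0.5)])
        reps = cluster_representatives(cands, clusters)
        assert sorted(c.id for c in reps) == ["b", "c"]
        tied = make_candidates([("a", {1, 2}, 0.9), ("b", {1, 2}, 0.9)])
        reps = cluster_representatives(tied, clusters)
        assert [c.id for c in reps] == ["a"]


class TestGreedyDiverseSelect:
    def test_selects_everything_when_n_large(self):
        cands = make_candidates([("a", {1}, 0.9), ("b", {2}, 0.5), ("c", {3}, 0.7)])
        picks = greedy_diverse_select(cands, n=10)
        assert picks[0] == "a" and set(picks) == {"a", "b", "c"}

    def test_three_candidate_hand_case(self):
        # c1 top score; c3 farther from c1 than c2 -> picks [c1, c3]
        c1 = set(range(10))
        c2 = set(range(7)) | {20, 21, 22}   # d(c2,c1) = 1 - 7/13
        c3 = {40, 41, 42}                   # d(c3,c1) = 1
        cands = make_candidates([("c1", c1, 0.9), ("c2", c2, 0.8), ("c3", c3, 0.7)])
        assert greedy_diverse_select(cands, n=2) == ["c1", "c3"]

    def test_matches_exhaustive_oracle_on_small_sets(self):
        from oracles import greedy_maxmin_stepwise

        rng = np.random.default_rng(6)
        for trial in range(15):
            m = int(rng.integers(2, 9))
            fps = random_fingerprints(rng, m, n_bits=32, popcount=6)
            cands = [
                Candidate(id=f"c{i}", fingerprint=f, score=float(rng.integers(0, 5)) / 4)
                for i, f in enumerate(fps)
            ]
            n = int(rng.integers(1, m + 1))
            assert greedy_diverse_select(cands, n) == greedy_maxmin_stepwise(cands, n)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            greedy_diverse_select([], 1)


class TestEnamineFunnel:
    def _fixture(self):
        # three chemotype blocks; block 1 shares a cluster with the known active
        blocks = {
            "k": set(range(10)),          # known active chemotype
            "n1": set(range(20, 30)),     # novel chemotype 1
            "n2": set(range(40, 50)),     # novel chemotype 2
        }
        entries = []
        entries.append(("act", blocks["k"], None))
        specs = [
            ("c_known", blocks["k"], 0.95, {"PAINS": True}),            # dies: cluster novelty
            ("c_pains", blocks["n1"], 0.90, {"PAINS": False}),          # dies: PAINS
            ("c_good1", blocks["n1"] | {60}, 0.85, {"PAINS": True}),    # survives
            ("c_good1b", blocks["n1"] | {61}, 0.80, {"PAINS": True}),   # loses representative
            ("c_good2", blocks["n2"], 0.75, {"PAINS": True}),           # survives
            ("c_close", blocks["k"] | {62, 63}, 0.70, {"PAINS": True}),  # dies: cluster novelty
        ]
        all_fps = [("act", fp(blocks["k"], 128))] + [
            (cid, fp(bits, 128)) for cid, bits, _, _ in specs
        ]
        clusters = taylor_butina(all_fps, threshold=0.4)
        cands = [
            Candidate(id=cid, fingerprint=fp(bits, 128), score=s, flags=flags)
            for cid, bits, s, flags in specs
        ]
        return cands, clusters

    def test_stage_counts_match_hand_enumeration(self):
        cands, clusters = self._fixture()
        known_fp = [fp(set(range(10)), 128)]
        final, audit = enamine_funnel(
            cands, clusters, known_actives={"act"}, known_active_fps=known_fp,
            filter_set=StructuralFilterSet.from_flags(["PAINS"]),
            min_distance=0.35, final_n=10,
        )
        stage_io = [(s, i, o) for s, i, o, _ in audit.stages]
        assert stage_io == [
            ("cluster_novelty", 6, 4),
            ("structural_filters", 4, 3),
            ("distance_novelty", 3, 3),
            ("cluster_representatives", 3, 2),
            ("greedy_diversity", 2, 2),
        ]
        assert sorted(final) == ["c_good1", "c_good2"]

    def test_audit_counts_monotone_and_chained(self):
        cands, clusters = self._fixture()
        _, audit = enamine_funnel(
            cands, clusters, {"act"}, [fp(set(range(10)), 128)],
            StructuralFilterSet.from_flags(["PAINS"]), final_n=1,
        )
        for (_, n_in, n_out, _), (_, next_in, _, _) in zip(audit.stages, audit.stages[1:]):
            assert n_out <= n_in and next_in == n_out
        assert len(audit.final_ids) == audit.stages[-1][2]

    def test_emptying_stage_error_names_the_stage(self):
        cands, clusters = self._fixture()
        doomed = StructuralFilterSet({"always_fail": lambda c: False})
        with pytest.raises(ValueError, match="structural_filters"):
            enamine_funnel(cands, clusters, {"act"}, [fp(set(range(10)), 128)],
                           doomed, final_n=5)

    def test_audit_rejects_inconsistent_counts(self):
        audit = FunnelAudit()
        audit.record("a", 10, 5, "r")
        with pytest.raises(ValueError):
            audit.record("b", 6, 2, "r")
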