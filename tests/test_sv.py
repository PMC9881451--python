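"""SV consensus merging, PON counting, feature extraction, per-caller
training and vote integration."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from tos.core import BreakpointIndex, GenomicInterval, IntervalIndex, SVBreakpointPair
from tos.resources import REGION_ORDINAL, ResourceSet
from tos.sv import (
    SV_FEATURES,
    SVFeatureExtractor,
    SVTYPE_ORDINAL,
    ConsensusEvent,
    MergeParams,
    build_sv_feature_table,
    classify_sv_callsets,
    count_pon_near_breakpoints,
    extract_sv_features,
    integrate_somatic_svs,
    merge_callsets,
    train_sv_models,
)


def _sv(pos1, pos2, svtype="DEL", caller="callerA", chrom="chr1", chrom2=None,
        qual=10.0, strands=None, call_id=""):
    o1, o2 = strands or {"DEL": "+-", "DUP": "-+", "INV": "++",
                         "INS": "+-", "TRA": "+-"}[svtype]
    return SVBreakpointPair(
        chrom, pos1, o1, chrom2 or chrom, pos2, o2, svtype=svtype,
        caller_quality=qual, caller_id=caller, call_id=call_id or f"{caller}:{pos1}",
    )


def _random_callsets(rng, n_per_caller=200, span=2_000_000):
    callsets = {}
    uid = itertools.count()
    for caller in ("callerA", "callerB", "callerC"):
        calls = []
        for _ in range(n_per_caller):
            svtype = str(rng.choice(["DEL", "DUP", "INV"]))
            p1 = int(rng.integers(10_000, span))
            length = int(rng.integers(200, 50_000))
            calls.append(_sv(p1, p1 + length, svtype, caller,
                             call_id=f"{caller}:{next(uid)}"))
        callsets[caller] = calls
    return callsets


def _brute_force_merge(callsets, p):
    """Oracle: full pairwise graph + transitive closure via networkx."""
    calls = [c for caller in callsets for c in callsets[caller]]
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            a, b = calls[i], calls[j]
            ok = (
                a.chrom1 == b.chrom1 and a.chrom2 == b.chrom2
                and abs(a.pos1 - b.pos1) <= p.max_breakpoint_distance
                and abs(a.pos2 - b.pos2) <= p.max_breakpoint_distance
                and (not p.require_type_match or a.svtype == b.svtype)
                and (not p.require_strand_match
                     or (a.orient1, a.orient2) == (b.orient1, b.orient2))
            )
            if ok:
                g.add_edge(i, j)
    return {frozenset(calls[i].call_id for i in comp)
            for comp in nx.connected_components(g)}


class TestMerge:
    def test_identical_calls_from_three_callers(self):
        callsets = {c: [_sv(1000, 2000, "DEL", c)] for c in ("callerA", "callerB", "callerC")}
        events = merge_callsets(callsets)
        assert len(events) == 1
        assert events[0].support_count == 3

    def test_beyond_distance_stays_separate(self):
        callsets = {
            "callerA": [_sv(1000, 9000, "DEL")],
            "callerB": [_sv(2500, 9100, "DEL", "callerB")],
        }
        events = merge_callsets(callsets, MergeParams(max_breakpoint_distance=1000))
        assert len(events) == 2

    def test_type_and_strand_gating(self):
        callsets = {
            "callerA": [_sv(1000, 2000, "DEL")],
            "callerB": [_sv(1000, 2000, "DUP", "callerB")],
        }
        assert len(merge_callsets(callsets)) == 2
        relaxed = MergeParams(require_type_match=False, require_strand_match=False)
        assert len(merge_callsets(callsets, relaxed)) == 1

    def test_matches_brute_force_oracle(self, rng):
        """200 random SVs x 3 callers: clustering equals the O(n^2)
        transitive-closure oracle."""
        callsets = _random_callsets(rng, n_per_caller=200)
        p = MergeParams(max_breakpoint_distance=5000)
        events = merge_callsets(callsets, p)
        got = {frozenset(m.call_id for m in ev.members) for ev in events}
        assert got == _brute_force_merge(callsets, p)

    def test_invariant_under_caller_permutation(self, rng):
        callsets = _random_callsets(rng, n_per_caller=60)
        p = MergeParams(max_breakpoint_distance=5000)
        reference = None
        for perm in itertools.permutations(callsets):
            shuffled = {k: callsets[k] for k in perm}
            clusters = sorted(
                sorted(m.call_id for m in ev.members)
                for ev in merge_callsets(shuffled, p)
            )
            reps = sorted(
                ev.representative.call_id for ev in merge_callsets(shuffled, p)
            )
            if reference is None:
                reference = (clusters, reps)
            assert (clusters, reps) == reference

    def test_idempotent_on_representatives(self, rng):
        callsets = _random_callsets(rng, n_per_caller=100)
        p = MergeParams(max_breakpoint_distance=300)
        events = merge_callsets(callsets, p)
        reps = {"merged": [ev.representative for ev in events]}
        again = merge_callsets(reps, p)
        # representatives of distinct events may still sit within the
        # distance of each other only if they belonged to one closure
        assert len(again) == len(events)

    def test_zero_distance_equals_exact_equality(self, rng):
        callsets = _random_callsets(rng, n_per_caller=80, span=100_000)
        p = MergeParams(max_breakpoint_distance=0)
        events = merge_callsets(callsets, p)
        keys = {}
        for caller, calls in callsets.items():
            for c in calls:
                k = (c.chrom1, c.pos1, c.chrom2, c.pos2, c.svtype, c.orient1, c.orient2)
                keys.setdefault(k, []).append(c.call_id)
        assert len(events) == len(keys)

    def test_no_member_lost(self, rng):
        callsets = _random_callsets(rng, n_per_caller=150)
        events = merge_callsets(callsets, MergeParams(max_breakpoint_distance=2000))
        n_in = sum(len(v) for v in callsets.values())
        assert sum(len(ev.members) for ev in events) == n_in

    def test_representative_has_highest_quality(self):
        callsets = {
            "callerB": [_sv(1000, 2000, "DEL", "callerB", qual=50)],
            "callerA": [_sv(1000, 2000, "DEL", "callerA", qual=50)],
            "callerC": [_sv(1001, 2001, "DEL", "callerC", qual=80)],
        }
        ev = merge_callsets(callsets)[0]
        assert ev.representative.caller_id == "callerC"
        callsets["callerC"][0].caller_quality = 50.0
        ev = merge_callsets(callsets)[0]
        assert ev.representative.caller_id == "callerA"  # lexicographic tie


class TestPONCounts:
    def test_empty_pon(self):
        sv = _sv(1000, 2000)
        assert count_pon_near_breakpoints(sv, BreakpointIndex()) == (0, 0)

    def test_entry_exactly_at_breakpoint(self):
        pon = BreakpointIndex([("chr1", 1000)])
        sv = _sv(1000, 2000)
        c1, c2 = count_pon_near_breakpoints(sv, pon, window=200)
        assert c1 >= 1 and c2 == 0

    def test_matches_naive_scan(self, rng):
        """1,000 random SVs vs 5,000 PON entries: counts equal the naive
        per-entry scan exactly."""
        entries = [("chr1", int(p)) for p in rng.integers(0, 5_000_000, size=5000)]
        pon = BreakpointIndex(entries)
        w = 200
        for _ in range(1000):
            p1 = int(rng.integers(0, 5_000_000))
            sv = _sv(p1, p1 + int(rng.integers(100, 10_000)))
            c1, c2 = count_pon_near_breakpoints(sv, pon, window=w)
            n1 = sum(1 for _, p in entries if sv.pos1 - w <= p < sv.pos1 + w)
            n2 = sum(1 for _, p in entries if sv.pos2 - w <= p < sv.pos2 + w)
            assert (c1, c2) == (n1, n2)


def _sv_resources():
    return ResourceSet(
        pon_sv=BreakpointIndex([("chr1", 1000), ("chr1", 1100), ("chr1", 50_000)]),
        sv_db=BreakpointIndex(
            [("chr1", 1200), ("chr1", 49_500), ("chr1", 200_000)],
            values=[0.12, 0.05, 0.0],
            labels=["pop", "pop", "pancancer"],
        ),
        gene_features=IntervalIndex([GenomicInterval("chr1", 900, 2000, "CDS")]),
        conserved=IntervalIndex([GenomicInterval("chr1", 49_000, 51_000)]),
        cancer_genes=IntervalIndex([GenomicInterval("chr1", 800, 3000, "GENE1")]),
    )


class TestFeatures:
    def test_translocation_log_length_zero(self):
        sv = SVBreakpointPair("chr1", 1000, "+", "chr2", 2000, "-", svtype="TRA")
        row = extract_sv_features(sv, _sv_resources())
        assert row["log_length"] == 0.0
        assert row["svtype"] == float(SVTYPE_ORDINAL["TRA"])

    def test_cancer_gene_flag_from_either_breakpoint(self):
        sv = _sv(1000, 50_000)
        row = extract_sv_features(sv, _sv_resources())
        assert row["cancer_gene_flag"] == 1.0
        assert row["gene_class_bp1"] == 3.0  # CDS
        assert row["conserved_bp2"] == 1.0
        assert row["pon_count_bp1"] == 2.0
        assert row["log_length"] == pytest.approx(math.log1p(49_000))

    def test_feature_count_and_names(self):
        assert len(SV_FEATURES) == 19
        row = extract_sv_features(_sv(1000, 2000), _sv_resources())
        assert list(row) == SV_FEATURES

    def test_matches_independent_row_extractor(self, small_cohort):
        """Extractor vs an independently coded per-row reimplementation
        on the synthetic fixture."""
        res = small_cohort.resources
        merged = 1000
        pw = 200
        pop = [(c, q, v) for c, q, v, l in res.sv_db.all_entries() if l != "pancancer"]
        pan = [(c, q) for c, q, v, l in res.sv_db.all_entries() if l == "pancancer"]
        extractor = SVFeatureExtractor(res, merged, pw)
        calls = small_cohort.samples[0].sv_calls["callerB"][:40]
        for sv in calls:
            row = extractor(sv)
            # naive database features
            hits1 = [(q2, v) for c2, q2, v in pop
                     if c2 == sv.chrom1 and sv.pos1 - merged <= q2 <= sv.pos1 + merged]
            hits2 = [(q2, v) for c2, q2, v in pop
                     if c2 == sv.chrom2 and sv.pos2 - merged <= q2 <= sv.pos2 + merged]
            assert row["svdb_overlap"] == (1.0 if hits1 and hits2 else 0.0)
            afs = [v for _, v in hits1 + hits2]
            assert row["svdb_af_max"] == pytest.approx(max(afs) if afs else 0.0)
            d1 = min((abs(q2 - sv.pos1) for c2, q2, _ in pop if c2 == sv.chrom1),
                     default=BreakpointIndex.NO_ENTRY_DISTANCE)
            d2 = min((abs(q2 - sv.pos2) for c2, q2, _ in pop if c2 == sv.chrom2),
                     default=BreakpointIndex.NO_ENTRY_DISTANCE)
            assert row["svdb_nearest_distance"] == float(min(d1, d2))
            naive_pan = any(
                c2 == c and q - merged <= q2 <= q + merged
                for c2, q2 in pan for c, q in [(sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2)]
            )
            assert row["pancancer_overlap"] == (1.0 if naive_pan else 0.0)
            # naive caller features
            assert row["allele_fraction"] == pytest.approx(sv.allele_fraction)
            assert row["imprecise_flag"] == (1.0 if sv.imprecise else 0.0)
            expect_ll = 0.0 if sv.svtype == "TRA" or sv.length < 0 else math.log1p(sv.length)
            assert row["log_length"] == pytest.approx(expect_ll)


class TestTrainAndIntegrate:
    def test_identical_tables_identical_reports(self, small_cohort):
        res = small_cohort.resources
        ext = SVFeatureExtractor(res)
        calls = [c for s in small_cohort.samples for c in s.sv_calls["callerA"]]
        table = build_sv_feature_table(calls, ext)
        models = train_sv_models({"x": table.copy(), "y": table.copy(), "z": table.copy()},
                                 seed=4)
        reports = [rep.to_dict() for _, rep in models.values()]
        assert reports[0] == reports[1] == reports[2]

    def test_default_scenario_accuracy_and_importances(self, small_cohort):
        """Held-out accuracy >= 0.85 per caller; PON counts, allele
        fraction, read depth and length all inside the top 6."""
        ext = SVFeatureExtractor(small_cohort.resources)
        tables = {}
        for caller in ("callerA", "callerB", "callerC"):
            calls = [c for s in small_cohort.samples for c in s.sv_calls[caller]]
            tables[caller] = build_sv_feature_table(calls, ext)
        models = train_sv_models(tables, seed=4)
        needed = {"pon_count_bp1", "pon_count_bp2", "allele_fraction",
                  "read_depth", "log_length"}
        for caller, (res, rep) in models.items():
            assert rep["accuracy"] >= 0.85
            assert needed <= set(res.top_features(6))

    def test_vote_rules(self):
        def event(n_callers, votes):
            members = [_sv(1000, 2000, "DEL", f"caller{c}", call_id=f"c{c}")
                       for c in range(n_callers)]
            ev = ConsensusEvent(representative=members[0], members=members)
            classes = {f"c{c}": ("somatic" if c < votes else "germline")
                       for c in range(n_callers)}
            return ev, classes

        ev, classes = event(3, 3)
        assert integrate_somatic_svs([ev], classes) == [ev]
        assert ev.final_class == "somatic" and ev.somatic_votes == 3

        ev, classes = event(2, 1)  # split vote on double support: rejected
        assert integrate_somatic_svs([ev], classes) == []
        assert ev.final_class == "germline"

        ev, classes = event(1, 1)  # unanimous single support: retained
        assert integrate_somatic_svs([ev], classes) == [ev]

        ev, classes = event(3, 2)  # two of three agree somatic: retained
        assert integrate_somatic_svs([ev], classes) == [ev]

    def test_unclassified_member_errors(self):
        ev, _ = None, None
        m = _sv(1000, 2000, call_id="orphan")
        event = ConsensusEvent(representative=m, members=[m])
        with pytest.raises(ValueError, match="orphan"):
            integrate_somatic_svs([event], {})

    def test_rule_replay_on_synthetic_cohort(self, small_cohort):
        """End-to-end: merge + classify + integrate equals an independent
        row-by-row replay of the vote rule."""
        ext = SVFeatureExtractor(small_cohort.resources)
        tables, models = {}, {}
        callsets_all = {}
        for caller in ("callerA", "callerB", "callerC"):
            calls = [c for s in small_cohort.samples for c in s.sv_calls[caller]]
            callsets_all[caller] = calls
            tables[caller] = build_sv_feature_table(calls, ext)
        trained = {k: v[0] for k, v in train_sv_models(tables, seed=4).items()}
        classes = classify_sv_callsets(trained, callsets_all, ext)
        s = small_cohort.samples[0]
        events = merge_callsets(s.sv_calls)
        retained = integrate_somatic_svs(events, classes)
        for ev in events:
            votes = {
                m.caller_id: any(
                    classes[x.call_id] == "somatic"
                    for x in ev.members if x.caller_id == m.caller_id
                )
                for m in ev.members
            }
            nv = sum(votes.values())
            expect = nv >= 1 and (nv == ev.support_count or nv >= 2)
            assert (ev in retained) == expect
            assert ev.somatic_votes == nv
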