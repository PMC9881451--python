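"""Structural-variant consensus merging and per-caller classification.

Calls from three SV callers are merged into consensus events when both
breakpoints fall within a maximum distance (1 kb by default, the common
multi-caller merging convention) with matching type and orientations;
clustering is the transitive closure of that pairwise relation, so the
result is invariant under caller ordering.  Each caller's calls are
classified somatic/germline by a per-caller random forest over 19
features (known-SV database, panel-of-normals breakpoint counts, region
annotation at both breakpoints, and the caller's own metrics), and the
per-event votes are integrated into the final somatic consensus set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BreakpointIndex, SVBreakpointPair
from .forest import (
    LABEL_COLUMN,
    SV_DEFAULT,
    RFHyperparams,
    SomaticClassifier,
    SomaticClassifierResults,
    SplitConfig,
    balance_one_to_one,
    split_train_test,
)
from .resources import REGION_ORDINAL, ResourceSet

__all__ = [
    "MergeParams",
    "ConsensusEvent",
    "SV_FEATURES",
    "merge_callsets",
    "count_pon_near_breakpoints",
    "SVFeatureExtractor",
    "extract_sv_features",
    "build_sv_feature_table",
    "train_sv_models",
    "classify_sv_callsets",
    "integrate_somatic_svs",
]

SVTYPE_ORDINAL = {"DEL": 0, "DUP": 1, "INV": 2, "INS": 3, "TRA": 4}

SV_FEATURES = [
    # known-SV database block
    "svdb_overlap", "svdb_af_max", "svdb_nearest_distance", "pancancer_overlap",
    # panel-of-normals block
    "pon_count_bp1", "pon_count_bp2",
    # region block
    "cancer_gene_flag", "gene_class_bp1", "gene_class_bp2",
    "conserved_bp1", "conserved_bp2",
    # caller block
    "svtype", "log_length", "allele_fraction", "read_depth",
    "split_reads", "discordant_pairs", "caller_quality", "imprecise_flag",
]


@dataclass(frozen=True)
class MergeParams:
    max_breakpoint_distance: int = 1000
    require_type_match: bool = True
    require_strand_match: bool = True

    def __post_init__(self):
        if self.max_breakpoint_distance < 0:
            raise ValueError("max_breakpoint_distance must be >= 0")


@dataclass
class ConsensusEvent:
    """One merged SV event across callers."""

    representative: SVBreakpointPair
    members: list[SVBreakpointPair] = field(default_factory=list)
    somatic_votes: int | None = None
    final_class: str | None = None

    @property
    def support_count(self) -> int:
        return len({m.caller_id for m in self.members})

    @property
    def callers(self) -> set[str]:
        return {m.caller_id for m in self.members}


def _compatible(a: SVBreakpointPair, b: SVBreakpointPair, p: MergeParams) -> bool:
    if a.chrom1 != b.chrom1 or a.chrom2 != b.chrom2:
        return False
    if abs(a.pos1 - b.pos1) > p.max_breakpoint_distance:
        return False
    if abs(a.pos2 - b.pos2) > p.max_breakpoint_distance:
        return False
    if p.require_type_match and a.svtype != b.svtype:
        return False
    if p.require_strand_match and (a.orient1, a.orient2) != (b.orient1, b.orient2):
        return False
    return True


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_callsets(
    callsets: dict[str, list[SVBreakpointPair]],
    p: MergeParams = MergeParams(),
) -> list[ConsensusEvent]:
    """Merge per-caller SV calls of one sample into consensus events.

    Two calls co-cluster when both breakpoint distances are within the
    maximum (with type/strand matching as configured); events are the
    transitive closure.  The representative is the member with the
    highest caller quality (ties to lexicographically smallest
    caller_id, then call_id).  No call is lost: members across events
    partition the input.
    """
    calls: list[SVBreakpointPair] = []
    for caller in sorted(callsets):
        calls.extend(callsets[caller])
    n = len(calls)
    # canonical, caller-order-independent indexing
    order = sorted(
        range(n),
        key=lambda i: (
            calls[i].chrom1, calls[i].pos1, calls[i].chrom2, calls[i].pos2,
            calls[i].svtype, calls[i].orient1, calls[i].orient2,
            calls[i].caller_id, calls[i].call_id,
        ),
    )
    calls = [calls[i] for i in order]
    ds = _DisjointSet(n)
    # sweep on pos1 within each chromosome pair: beyond the distance on
    # pos1 nothing can merge, so only a local window is examined
    for i in range(n):
        a = calls[i]
        for j in range(i + 1, n):
            b = calls[j]
            if b.chrom1 != a.chrom1 or b.pos1 - a.pos1 > p.max_breakpoint_distance:
                break
            if _compatible(a, b, p):
                ds.union(i, j)
    groups: dict[int, list[SVBreakpointPair]] = {}
    for i in range(n):
        groups.setdefault(ds.find(i), []).append(calls[i])
    events = []
    for root in sorted(groups):
        members = groups[root]
        rep = min(
            members,
            key=lambda m: (-m.caller_quality, m.caller_id, m.call_id),
        )
        events.append(ConsensusEvent(representative=rep, members=members))
    return events


def count_pon_near_breakpoints(
    sv: SVBreakpointPair, pon: BreakpointIndex, window: int = 200
) -> tuple[int, int]:
    """Panel-of-normals entries within the half-open window of width
    2*window centred on each breakpoint."""
    c1 = pon.count_window(sv.chrom1, sv.pos1 - window, sv.pos1 + window)
    c2 = pon.count_window(sv.chrom2, sv.pos2 - window, sv.pos2 + window)
    return c1, c2


class SVFeatureExtractor:
    """Caches label-split views of the known-SV database so per-call
    extraction stays O(log n)."""

    def __init__(
        self,
        resources: ResourceSet,
        merge_distance: int = 1000,
        pon_window: int = 200,
    ):
        self.resources = resources
        self.merge_distance = merge_distance
        self.pon_window = pon_window
        pop, pancancer = [], []
        for chrom, pos, val, lab in resources.sv_db.all_entries():
            (pancancer if lab == "pancancer" else pop).append((chrom, pos, val))
        self._pop = BreakpointIndex(
            [(c, p) for c, p, _ in pop], values=[v for _, _, v in pop]
        )
        self._pancancer = BreakpointIndex([(c, p) for c, p, _ in pancancer])

    def __call__(self, sv: SVBreakpointPair) -> dict[str, float]:
        res = self.resources
        d = self.merge_distance
        bps = [(sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2)]
        pop_hits = [self._pop.entries_within(c, p - d, p + d + 1) for c, p in bps]
        svdb_overlap = 1.0 if all(pop_hits) else 0.0
        afs = [v for hits in pop_hits for _, v, _ in hits]
        nearest = min(self._pop.nearest_distance(c, p) for c, p in bps)
        pancancer = any(
            self._pancancer.count_window(c, p - d, p + d + 1) for c, p in bps
        )
        pon1, pon2 = count_pon_near_breakpoints(sv, res.pon_sv, self.pon_window)
        gene_class = [
            float(REGION_ORDINAL[res.region_class(c, p)]) for c, p in bps
        ]
        if sv.svtype == "TRA" or sv.length < 0:
            log_length = 0.0
        else:
            log_length = math.log1p(sv.length)
        return {
            "svdb_overlap": svdb_overlap,
            "svdb_af_max": max(afs) if afs else 0.0,
            "svdb_nearest_distance": float(nearest),
            "pancancer_overlap": 1.0 if pancancer else 0.0,
            "pon_count_bp1": float(pon1),
            "pon_count_bp2": float(pon2),
            "cancer_gene_flag": 1.0
            if any(res.cancer_genes.covers(c, p) for c, p in bps)
            else 0.0,
            "gene_class_bp1": gene_class[0],
            "gene_class_bp2": gene_class[1],
            "conserved_bp1": 1.0 if res.conserved.covers(*bps[0]) else 0.0,
            "conserved_bp2": 1.0 if res.conserved.covers(*bps[1]) else 0.0,
            "svtype": float(SVTYPE_ORDINAL[sv.svtype]),
            "log_length": log_length,
            "allele_fraction": float(sv.allele_fraction),
            "read_depth": float(sv.read_depth),
            "split_reads": float(sv.split_reads),
            "discordant_pairs": float(sv.discordant_pairs),
            "caller_quality": float(sv.caller_quality),
            "imprecise_flag": 1.0 if sv.imprecise else 0.0,
        }


def extract_sv_features(
    sv: SVBreakpointPair,
    resources: ResourceSet,
    merge_distance: int = 1000,
    pon_window: int = 200,
) -> dict[str, float]:
    return SVFeatureExtractor(resources, merge_distance, pon_window)(sv)


def build_sv_feature_table(
    calls: list[SVBreakpointPair],
    extractor: SVFeatureExtractor,
    with_labels: bool = True,
) -> pd.DataFrame:
    df = pd.DataFrame([extractor(sv) for sv in calls], columns=SV_FEATURES)
    if with_labels:
        df[LABEL_COLUMN] = [sv.truth_label for sv in calls]
    return df


def train_sv_models(
    tables: dict[str, pd.DataFrame],
    hp: RFHyperparams = SV_DEFAULT,
    split: SplitConfig = SplitConfig(),
    seed: int = 0,
) -> dict[str, tuple[SomaticClassifierResults, pd.Series]]:
    """One forest per caller, trained at 1:1 class balance on the
    stratified 75/25 split and evaluated on its held-out quarter."""
    out = {}
    for caller in sorted(tables):
        balanced = balance_one_to_one(tables[caller][SV_FEATURES + [LABEL_COLUMN]], seed=seed)
        train, test = split_train_test(balanced, split)
        res = SomaticClassifier(train, feature_names=SV_FEATURES).fit(
            RFHyperparams(hp.features_per_split, hp.num_trees, hp.min_node_size, seed=seed)
        )
        out[caller] = (res, res.evaluate(test).as_series())
    return out


def classify_sv_callsets(
    models: dict[str, SomaticClassifierResults],
    callsets: dict[str, list[SVBreakpointPair]],
    extractor: SVFeatureExtractor,
    threshold: float = 0.5,
) -> dict[str, str]:
    """Per-call classes keyed by call_id, each caller's calls classified
    by that caller's model."""
    classes: dict[str, str] = {}
    for caller, calls in callsets.items():
        if not calls:
            continue
        model = models[caller]
        table = build_sv_feature_table(calls, extractor, with_labels=False)
        pred = model.classify(table, threshold=threshold)
        for sv, cls in zip(calls, pred):
            classes[sv.call_id] = cls
    return classes


def integrate_somatic_svs(
    events: list[ConsensusEvent],
    classifications: dict[str, str],
) -> list[ConsensusEvent]:
    """Fill per-event somatic votes and return the final somatic set.

    A caller votes somatic when any of its member calls in the event is
    classified somatic.  An event is somatic when the vote is unanimous
    across its supporting callers, or when at least two callers vote
    somatic.  Every event keeps its support count for downstream
    filtering.
    """
    retained = []
    for ev in events:
        votes_by_caller: dict[str, bool] = {}
        for m in ev.members:
            if m.call_id not in classifications:
                raise ValueError(f"member call {m.call_id!r} has no classification")
            votes_by_caller.setdefault(m.caller_id, False)
            if classifications[m.call_id] == "somatic":
                votes_by_caller[m.caller_id] = True
        votes = sum(votes_by_caller.values())
        ev.somatic_votes = votes
        support = ev.support_count
        somatic = votes >= 1 and (votes == support or votes >= 2)
        ev.final_class = "somatic" if somatic else "germline"
        if somatic:
            retained.append(ev)
    return retained


def events_table(events: list[ConsensusEvent]) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(events):
        r = ev.representative
        rows.append(
            {
                "event_id": i,
                "chrom1": r.chrom1, "pos1": r.pos1, "chrom2": r.chrom2, "pos2": r.pos2,
                "svtype": r.svtype,
                "support": ev.support_count,
                "callers": ",".join(sorted(ev.callers)),
                "somatic_votes": ev.somatic_votes if ev.somatic_votes is not None else -1,
                "final_class": ev.final_class or "unclassified",
            }
        )
    return pd.DataFrame(rows)
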