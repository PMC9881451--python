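"""Core genomic domain types and interval lookup structures.

Coordinates are 0-based half-open everywhere inside the package; the
1-based convention of VCF is converted at the I/O boundary and nowhere
else.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "SmallVariant",
    "SVBreakpointPair",
    "IntervalIndex",
    "BreakpointIndex",
    "chrom_sort_key",
    "breakpoints_ordered",
]

_CANONICAL = {f"chr{i}": i for i in range(1, 23)}
_CANONICAL["chrX"] = 23
_CANONICAL["chrY"] = 24


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Deterministic chromosome ordering: chr1..chr22, chrX, chrY, then
    unknown contigs lexicographically.  Accepts names with or without the
    ``chr`` prefix."""
    name = chrom if chrom.startswith("chr") else "chr" + chrom
    if name in _CANONICAL:
        return (0, _CANONICAL[name])
    return (1, chrom)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``.

    ``label`` and ``value`` carry optional annotation payloads (a region
    class, a gene name, a population allele frequency) for interval
    resources loaded from BED.
    """

    chrom: str
    start: int
    end: int
    label: str = ""
    value: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class SmallVariant:
    """One normalized point mutation or short indel call.

    ``pos`` is 1-based (as printed in VCF); callers' quality metrics are
    carried verbatim with ``-1.0`` as the sentinel for a missing
    annotation.  ``context`` is the reference trinucleotide centred on the
    site when known.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    allele_fraction: float = -1.0
    total_depth: int = -1
    alt_count: int = -1
    median_base_quality: float = -1.0
    median_mapping_quality: float = -1.0
    strand_balance: float = -1.0
    caller_confidence: float = -1.0
    filter_pass: bool = True
    multiallelic: bool = False
    truth_label: str = "unknown"
    context: str | None = None
    homopolymer_run: int = -1
    sample: str = ""

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[ACGTN]+", self.ref) or not re.fullmatch(
            r"[ACGTN]+", self.alt
        ):
            raise ValueError(f"bad alleles {self.ref}>{self.alt}")
        if 0 <= self.total_depth < self.alt_count:
            raise ValueError("alt_count exceeds total_depth")

    @property
    def vclass(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def is_snv(self) -> bool:
        return self.vclass == "SNV"

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Exact-match identity used for database and truth lookups."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


_SVTYPES = ("DEL", "DUP", "INV", "INS", "TRA")


@dataclass
class SVBreakpointPair:
    """A structural variant as an oriented breakpoint pair.

    Breakpoints are stored in the fixed chromosome ordering
    (chrom1,pos1) <= (chrom2,pos2); ``length`` is ``pos2 - pos1`` for
    intra-chromosomal events and the sentinel ``-1`` for translocations
    (for insertions it is the inserted length when the caller reports it,
    else ``-1``).
    """

    chrom1: str
    pos1: int
    orient1: str
    chrom2: str
    pos2: int
    orient2: str
    svtype: str
    length: int = -1
    allele_fraction: float = -1.0
    read_depth: int = -1
    split_reads: int = -1
    discordant_pairs: int = -1
    caller_quality: float = -1.0
    imprecise: bool = False
    caller_id: str = ""
    truth_label: str = "unknown"
    call_id: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in _SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype}")
        if self.orient1 not in "+-" or self.orient2 not in "+-":
            raise ValueError("orientations must be '+' or '-'")
        if (self.svtype == "TRA") != (self.chrom1 != self.chrom2):
            raise ValueError("svtype TRA iff inter-chromosomal")
        if not breakpoints_ordered(self.chrom1, self.pos1, self.chrom2, self.pos2):
            raise ValueError("breakpoints not in canonical order")
        if self.chrom1 == self.chrom2 and self.svtype != "INS":
            self.length = self.pos2 - self.pos1

    def normalized(self) -> "SVBreakpointPair":
        return self

    @property
    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chrom1, self.pos1), (self.chrom2, self.pos2))


def breakpoints_ordered(chrom1: str, pos1: int, chrom2: str, pos2: int) -> bool:
    return (chrom_sort_key(chrom1), pos1) <= (chrom_sort_key(chrom2), pos2)


class IntervalIndex:
    """Query structure over a set of (possibly overlapping) intervals.

    Per chromosome the intervals are kept sorted by start; a window query
    bisects on starts and filters the candidate prefix by end with a
    vectorised comparison.  Adequate for resource sets up to ~1e5
    intervals; exactness is checked against a naive all-pairs scan in the
    test suite.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._ivs: dict[str, list[GenomicInterval]] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._n = 0
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            self._ivs[chrom] = ivs
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._n += len(ivs)

    def __len__(self) -> int:
        return self._n

    def query(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All intervals overlapping the half-open window [start, end)."""
        if chrom not in self._ivs or end <= start:
            return []
        starts = self._starts[chrom]
        k = int(np.searchsorted(starts, end, side="left"))
        if k == 0:
            return []
        hit = self._ends[chrom][:k] > start
        ivs = self._ivs[chrom]
        return [ivs[i] for i in np.nonzero(hit)[0]]

    def query_point(self, chrom: str, pos: int) -> list[GenomicInterval]:
        return self.query(chrom, pos, pos + 1)

    def covers(self, chrom: str, pos: int) -> bool:
        if chrom not in self._ivs:
            return False
        starts = self._starts[chrom]
        k = int(np.searchsorted(starts, pos + 1, side="left"))
        return bool(k and (self._ends[chrom][:k] > pos).any())

    def count(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._ivs or end <= start:
            return 0
        starts = self._starts[chrom]
        k = int(np.searchsorted(starts, end, side="left"))
        return int((self._ends[chrom][:k] > start).sum())


def build_interval_index(intervals: Iterable[GenomicInterval]) -> IntervalIndex:
    return IntervalIndex(intervals)


class BreakpointIndex:
    """Sorted point set per chromosome with optional payloads.

    Backs the panel-of-normals and known-SV databases: counting entries
    in a window around a breakpoint and nearest-entry distance are both
    O(log n) via ``searchsorted``.
    """

    #: distance reported when a chromosome holds no entry at all
    NO_ENTRY_DISTANCE = 10**8

    def __init__(
        self,
        entries: Iterable[tuple[str, int]] | None = None,
        *,
        values: Sequence[float] | None = None,
        labels: Sequence[str] | None = None,
    ):
        entries = list(entries or [])
        values = list(values) if values is not None else [0.0] * len(entries)
        labels = list(labels) if labels is not None else [""] * len(entries)
        if not (len(entries) == len(values) == len(labels)):
            raise ValueError("entries, values and labels must align")
        order = sorted(
            range(len(entries)),
            key=lambda i: (chrom_sort_key(entries[i][0]), entries[i][1]),
        )
        self._pos: dict[str, list[int]] = {}
        self._val: dict[str, list[float]] = {}
        self._lab: dict[str, list[str]] = {}
        for i in order:
            chrom, pos = entries[i]
            self._pos.setdefault(chrom, []).append(int(pos))
            self._val.setdefault(chrom, []).append(float(values[i]))
            self._lab.setdefault(chrom, []).append(labels[i])
        self._n = len(entries)

    def __len__(self) -> int:
        return self._n

    def count_window(self, chrom: str, lo: int, hi: int) -> int:
        """Entries with position in the half-open window [lo, hi)."""
        pos = self._pos.get(chrom)
        if not pos:
            return 0
        return bisect_left(pos, hi) - bisect_left(pos, lo)

    def entries_within(self, chrom: str, lo: int, hi: int):
        pos = self._pos.get(chrom)
        if not pos:
            return []
        i, j = bisect_left(pos, lo), bisect_left(pos, hi)
        val, lab = self._val[chrom], self._lab[chrom]
        return [(pos[k], val[k], lab[k]) for k in range(i, j)]

    def all_entries(self):
        """Yield (chrom, pos, value, label) over every entry, in the
        canonical chromosome/position order."""
        for chrom in sorted(self._pos, key=chrom_sort_key):
            for p, v, l in zip(self._pos[chrom], self._val[chrom], self._lab[chrom]):
                yield chrom, p, v, l

    def nearest_distance(self, chrom: str, pos: int) -> int:
        entries = self._pos.get(chrom)
        if not entries:
            return self.NO_ENTRY_DISTANCE
        i = bisect_right(entries, pos)
        best = self.NO_ENTRY_DISTANCE
        if i > 0:
            best = min(best, pos - entries[i - 1])
        if i < len(entries):
            best = min(best, entries[i] - pos)
        return best
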