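"""Deterministic synthetic-cohort simulator.

Generates matched and tumor-only call sets with known truth on a
miniature genome (three 50-Mbp autosomes plus a 30-Mbp X and a 10-Mbp
Y), so every stage of the tumor-only pipeline — labeling, feature
extraction, forest training, SV consensus, copy-number post-processing
and cohort QC — is testable without any external download.  The
statistical structure mirrors what the classifiers exploit in real
cohorts:

* germline small variants sit at diploid allele fractions (~0.5 het,
  ~1.0 hom, beta noise) and are present in the population database with
  high probability; somatic fractions scale with tumor purity
  (clonal copy-neutral expectation purity/2) and are enriched in the
  cancer catalogue;
* germline SVs attract panel-of-normals breakpoints and known-SV
  database entries, somatic SVs are longer and PON-free;
* three SV "callers" re-emit the true SVs with caller-specific
  breakpoint jitter, metric noise and dropout, in three VCF dialects;
* tumor-only copy-number profiles are the matched profiles plus value
  noise, occasional negative estimates (half slightly negative in
  (-0.5, 0), half below -0.5) and artifactual focal peaks inside the
  telomeric/centromeric exclusion zones;
* per-sample sex evidence across coverage/expression/methylation is
  consistent with the assigned sex, with one optional male tumor whose
  somatic Y loss leaves intermediate Y coverage.

Identical seeds produce byte-identical output directories.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnv import CNCallset, CNSegment
from .core import (
    GenomicInterval,
    IntervalIndex,
    SVBreakpointPair,
    SmallVariant,
    breakpoints_ordered,
)
from .qc import SexEvidence
from .resources import ResourceSet
from .vcfio import (
    write_bed,
    write_cn_callset,
    write_small_variants,
    write_sv_calls,
)

__all__ = [
    "GENOME",
    "AUTOSOMES",
    "SimulationParams",
    "SimulatedSample",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_cn_profiles",
    "default_exclusion_intervals",
]

#: miniature genome: desk-scale, so brute-force oracles run in seconds
GENOME: dict[str, int] = {
    "chr1": 50_000_000,
    "chr2": 50_000_000,
    "chr3": 50_000_000,
    "chrX": 30_000_000,
    "chrY": 10_000_000,
}
AUTOSOMES = ("chr1", "chr2", "chr3")
_BASES = np.array(list("ACGT"))

SV_CALLERS = ("callerA", "callerB", "callerC")
SV_DIALECT_BY_CALLER = {
    "callerA": "bnd",
    "callerB": "symbolic",
    "callerC": "symbolic_signed",
}

#: telomeric/centromeric flank width of the shipped exclusion list
EXCLUSION_FLANK = 1_000_000
CENTROMERE_HALF = 500_000


def default_exclusion_intervals(genome: dict[str, int] = GENOME) -> list[GenomicInterval]:
    """Telomeric flanks and a centromeric band per chromosome — the
    stand-in for the curated artifact-region list."""
    out = []
    for chrom, length in genome.items():
        mid = length // 2
        out.append(GenomicInterval(chrom, 0, EXCLUSION_FLANK, "telomere_p"))
        out.append(
            GenomicInterval(chrom, mid - CENTROMERE_HALF, mid + CENTROMERE_HALF, "centromere")
        )
        out.append(GenomicInterval(chrom, length - EXCLUSION_FLANK, length, "telomere_q"))
    return out


@dataclass
class SimulationParams:
    """The stated world of the simulator; every probability/size is
    serializable to config and echoed next to the cohort."""

    n_samples: int = 20
    male_fraction: float = 0.8
    purity_range: tuple[float, float] = (0.2, 0.9)
    seed: int = 42

    # small variants
    n_germline_small: int = 5000
    n_somatic_small: int = 500
    indel_fraction: float = 0.1
    germline_het_fraction: float = 2.0 / 3.0
    af_concentration: float = 200.0
    exact_af: bool = False  # separable mode: record the exact AF
    depth_matched: float = 60.0
    depth_tumor_only: float = 30.0
    small_variant_dropout: float = 0.0

    # database membership
    popdb_p_germline: float = 0.95
    popdb_p_somatic: float = 0.01
    cancerdb_p_somatic: float = 0.10
    cancerdb_p_germline: float = 0.001

    # structural variants
    n_germline_sv: int = 40
    n_somatic_sv: int = 25
    sv_type_weights: dict = field(
        default_factory=lambda: {"DEL": 0.4, "DUP": 0.2, "INV": 0.15, "INS": 0.1, "TRA": 0.15}
    )
    germline_sv_log_length: tuple[float, float] = (8.0, 1.0)   # ln-scale mean, sd
    somatic_sv_log_length: tuple[float, float] = (11.3, 1.2)
    caller_dropout: dict = field(
        default_factory=lambda: {"callerA": 0.05, "callerB": 0.10, "callerC": 0.15}
    )
    breakpoint_jitter_sd: float = 30.0
    imprecise_prob: float = 0.08

    # resources
    pon_density_per_mbp: float = 2.0
    pon_p_germline_sv: float = 0.9
    pon_entries_mean: float = 3.0
    svdb_p_germline: float = 0.35
    svdb_p_somatic_pancancer: float = 0.1
    svdb_background_per_mbp: float = 8.0
    n_genes: int = 400
    n_cancer_genes: int = 30
    n_conserved: int = 1500
    n_repeats: int = 3000

    # copy number
    n_cn_segments: int = 40
    cn_noise_sd: float = 0.05
    purity_noise_sd: float = 0.02
    negative_noise_prob: float = 0.05
    artifact_peak_prob: float = 0.3

    # QC evidence
    inject_y_loss: bool = True
    genomic_purity_missing_prob: float = 0.05

    def __post_init__(self):
        for name in (
            "popdb_p_germline", "popdb_p_somatic", "cancerdb_p_somatic",
            "cancerdb_p_germline", "small_variant_dropout", "negative_noise_prob",
            "artifact_peak_prob", "male_fraction", "indel_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_samples", "n_germline_small", "n_somatic_small",
                     "n_germline_sv", "n_somatic_sv", "n_cn_segments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total_positions = sum(GENOME[c] for c in AUTOSOMES)
        if self.n_germline_small + self.n_somatic_small > total_positions // 100:
            raise ValueError("requested more small variants than the genome can host")

    @classmethod
    def separable(cls, **overrides) -> "SimulationParams":
        """Separable-limit scenario: disjoint class AF supports and
        perfectly separating databases, so a forest must reach held-out
        accuracy 1.0 exactly."""
        base = dict(
            purity_range=(0.2, 0.7),
            exact_af=True,
            af_concentration=1e6,
            popdb_p_germline=1.0,
            popdb_p_somatic=0.0,
            cancerdb_p_somatic=1.0,
            cancerdb_p_germline=0.0,
            pon_density_per_mbp=0.0,
            pon_p_germline_sv=1.0,
            svdb_p_germline=1.0,
            svdb_p_somatic_pancancer=0.0,
            svdb_background_per_mbp=0.0,
            imprecise_prob=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["purity_range"] = list(self.purity_range)
        d["germline_sv_log_length"] = list(self.germline_sv_log_length)
        d["somatic_sv_log_length"] = list(self.somatic_sv_log_length)
        return d


@dataclass
class SimulatedSample:
    sample: str
    sex: str
    purity: float
    y_loss: bool
    tumor_only_small: list[SmallVariant]
    matched_somatic_small: list[SmallVariant]
    sv_truth: pd.DataFrame
    sv_calls: dict[str, list[SVBreakpointPair]]
    cn_matched: CNCallset
    cn_tumor_only: CNCallset
    cn_injections: pd.DataFrame
    sex_evidence: SexEvidence


@dataclass
class SimulatedCohort:
    params: SimulationParams
    samples: list[SimulatedSample]
    resources: ResourceSet
    gene_spans: list[GenomicInterval]
    exclusion: list[GenomicInterval]
    resource_intervals: dict[str, list[GenomicInterval]]
    popdb: dict
    cancerdb: dict
    purity_estimates: pd.DataFrame
    truth_small: pd.DataFrame
    truth_sv: pd.DataFrame
    truth_samples: pd.DataFrame

    def sample_by_name(self, name: str) -> SimulatedSample:
        return next(s for s in self.samples if s.sample == name)

    # -- writing ----------------------------------------------------------

    def write(self, outdir) -> Path:
        out = Path(outdir)
        (out / "resources").mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        (out / "evidence").mkdir(exist_ok=True)
        with (out / "params.yaml").open("w") as fh:
            yaml.safe_dump(self.params.to_dict(), fh, sort_keys=True)
        with (out / "genome.tsv").open("w") as fh:
            fh.write("chrom\tlength\n")
            for c, l in GENOME.items():
                fh.write(f"{c}\t{l}\n")
        self._write_resources(out / "resources")
        for s in self.samples:
            d = out / "samples" / s.sample
            d.mkdir(parents=True, exist_ok=True)
            write_small_variants(s.tumor_only_small, d / "small_tumor_only.vcf",
                                 sample=s.sample, contigs=GENOME)
            write_small_variants(s.matched_somatic_small, d / "small_matched_somatic.vcf",
                                 sample=s.sample, contigs=GENOME)
            for caller in SV_CALLERS:
                write_sv_calls(s.sv_calls[caller], d / f"sv_{caller}.vcf",
                               dialect=SV_DIALECT_BY_CALLER[caller], contigs=GENOME)
            write_cn_callset(s.cn_matched, d / "cn_matched.tsv")
            write_cn_callset(s.cn_tumor_only, d / "cn_tumor_only.tsv")
        ev = pd.DataFrame(
            [dataclasses.asdict(s.sex_evidence) for s in self.samples]
        )
        ev.to_csv(out / "evidence" / "sex_evidence.tsv", sep="\t", index=False,
                  float_format="%.6f")
        self.purity_estimates.to_csv(out / "evidence" / "purity_estimates.tsv",
                                     sep="\t", index=False, float_format="%.6f")
        self.truth_small.to_csv(out / "truth" / "small_variants.tsv", sep="\t",
                                index=False, float_format="%.6f")
        self.truth_sv.to_csv(out / "truth" / "svs.tsv", sep="\t", index=False,
                             float_format="%.6f")
        inj_frames = [
            s.cn_injections.assign(sample=s.sample)
            for s in self.samples
            if len(s.cn_injections)
        ]
        inj = (
            pd.concat(inj_frames, ignore_index=True)
            if inj_frames
            else pd.DataFrame(columns=["kind", "chrom", "start", "end", "value", "sample"])
        )
        inj.to_csv(out / "truth" / "cn_injections.tsv", sep="\t", index=False,
                   float_format="%.6f")
        self.truth_samples.to_csv(out / "truth" / "samples.tsv", sep="\t",
                                  index=False, float_format="%.6f")
        return out

    def _write_resources(self, d: Path) -> None:
        contigs = "".join(f"##contig=<ID={c},length={l}>\n" for c, l in GENOME.items())
        with (d / "popdb.vcf").open("w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(contigs)
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for (chrom, pos, ref, alt), af in sorted(self.popdb.items()):
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tAF={af:.6f}\n")
        with (d / "cancerdb.vcf").open("w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(contigs)
            fh.write('##INFO=<ID=CNT,Number=A,Type=Integer,Description="Catalogue occurrence count">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for (chrom, pos, ref, alt), cnt in sorted(self.cancerdb.items()):
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tCNT={int(cnt)}\n")
        ri = self.resource_intervals
        write_bed(ri["pon"], d / "pon.bed")
        write_bed(ri["sv_db"], d / "sv_db.bed", scores=True)
        write_bed(ri["gene_features"], d / "genes.bed")
        write_bed(self.gene_spans, d / "gene_spans.bed")
        write_bed(ri["conserved"], d / "conserved.bed")
        write_bed(ri["cancer_genes"], d / "cancer_genes.bed")
        write_bed(ri["repeats"], d / "repeats.bed")
        write_bed(self.exclusion, d / "exclusion.bed")


# ---------------------------------------------------------------------------
# helpers


def _draw_positions(rng: np.random.Generator, n: int) -> list[tuple[str, int]]:
    """n distinct (chrom, pos) sites on the autosomes."""
    lengths = np.array([GENOME[c] for c in AUTOSOMES], dtype=float)
    probs = lengths / lengths.sum()
    seen: set[tuple[str, int]] = set()
    out: list[tuple[str, int]] = []
    while len(out) < n:
        k = max(64, int((n - len(out)) * 1.2))
        chroms = rng.choice(len(AUTOSOMES), size=k, p=probs)
        for ci in chroms:
            chrom = AUTOSOMES[int(ci)]
            pos = int(rng.integers(EXCLUSION_FLANK + 1, GENOME[chrom] - EXCLUSION_FLANK))
            if (chrom, pos) not in seen:
                seen.add((chrom, pos))
                out.append((chrom, pos))
                if len(out) == n:
                    break
    return out


def _alleles(rng: np.random.Generator, is_indel: bool) -> tuple[str, str, str]:
    """(ref, alt, context) for a random variant."""
    left, mid, right = rng.choice(_BASES, size=3)
    if not is_indel:
        alt = str(rng.choice([b for b in "ACGT" if b != mid]))
        return str(mid), alt, f"{left}{mid}{right}"
    tail = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
    if rng.random() < 0.5:
        return str(mid), str(mid) + tail, f"{left}{mid}{right}"  # insertion
    return str(mid) + tail, str(mid), f"{left}{mid}{right}"      # deletion


def _germline_af(rng: np.random.Generator, p: SimulationParams) -> float:
    k = p.af_concentration
    if rng.random() < p.germline_het_fraction:
        return float(np.clip(rng.beta(0.5 * k, 0.5 * k), 0.01, 1.0))
    return float(np.clip(rng.beta(0.99 * k, 0.01 * k), 0.01, 1.0))


def _observe_af(rng, af_true: float, depth_mean: float, exact: bool):
    depth = max(int(rng.poisson(depth_mean)), 8)
    if exact:
        alt = int(round(af_true * depth))
    else:
        alt = int(rng.binomial(depth, af_true))
    alt = min(max(alt, 1), depth)
    return depth, alt, alt / depth


def _small_variant(
    rng, p: SimulationParams, sample: str, site, cls: str, purity: float,
    depth_mean: float,
) -> SmallVariant:
    chrom, pos = site["site"]
    af_true = site["af_true"]
    depth, alt, af = _observe_af(rng, af_true, depth_mean, p.exact_af)
    mbq = float(np.clip(rng.normal(30, 3), 10, 45))
    mmq = float(np.clip(rng.normal(58, 4), 20, 60))
    strb = float(np.clip(rng.beta(50, 50), 0.01, 0.99))
    tlod = float(max(alt * 1.1 + rng.normal(0, 2), 0.1))
    return SmallVariant(
        chrom=chrom, pos=pos, ref=site["ref"], alt=site["alt"],
        allele_fraction=af, total_depth=depth, alt_count=alt,
        median_base_quality=mbq, median_mapping_quality=mmq,
        strand_balance=strb, caller_confidence=tlod,
        filter_pass=bool(rng.random() < 0.98),
        multiallelic=False, truth_label=cls,
        context=site["context"], homopolymer_run=site["hrun"], sample=sample,
    )


def _random_sv(rng, p: SimulationParams, cls: str) -> dict:
    types = sorted(p.sv_type_weights)
    weights = np.array([p.sv_type_weights[t] for t in types], dtype=float)
    svtype = str(types[int(rng.choice(len(types), p=weights / weights.sum()))])
    mu, sd = p.germline_sv_log_length if cls == "germline" else p.somatic_sv_log_length
    if svtype == "TRA":
        c1, c2 = rng.choice(len(AUTOSOMES), size=2, replace=False)
        chrom1, chrom2 = AUTOSOMES[int(c1)], AUTOSOMES[int(c2)]
        pos1 = int(rng.integers(EXCLUSION_FLANK, GENOME[chrom1] - EXCLUSION_FLANK))
        pos2 = int(rng.integers(EXCLUSION_FLANK, GENOME[chrom2] - EXCLUSION_FLANK))
        if not breakpoints_ordered(chrom1, pos1, chrom2, pos2):
            chrom1, pos1, chrom2, pos2 = chrom2, pos2, chrom1, pos1
        length = -1
    else:
        chrom1 = chrom2 = AUTOSOMES[int(rng.choice(len(AUTOSOMES)))]
        length = int(np.clip(rng.lognormal(mu, sd), 60, 5_000_000))
        if svtype == "INS":
            length = int(rng.integers(60, 800))
        pos1 = int(rng.integers(EXCLUSION_FLANK, GENOME[chrom1] - EXCLUSION_FLANK - length - 1))
        pos2 = pos1 + 1 if svtype == "INS" else pos1 + length
    o1, o2 = {"DEL": "+-", "DUP": "-+", "INV": "++", "INS": "+-", "TRA": "+-"}[svtype]
    return dict(svtype=svtype, chrom1=chrom1, pos1=pos1, orient1=o1,
                chrom2=chrom2, pos2=pos2, orient2=o2, length=length, cls=cls)


def _emit_sv_call(
    rng, p: SimulationParams, truth: dict, caller: str, af_true: float,
    purity: float,
) -> SVBreakpointPair:
    jitter = p.breakpoint_jitter_sd
    d1 = int(round(rng.normal(0, jitter)))
    d2 = int(round(rng.normal(0, jitter)))
    pos1, pos2 = truth["pos1"] + d1, truth["pos2"] + d2
    c1, c2 = truth["chrom1"], truth["chrom2"]
    o1, o2 = truth["orient1"], truth["orient2"]
    if c1 == c2 and pos2 <= pos1:
        pos2 = pos1 + 1
    if not breakpoints_ordered(c1, pos1, c2, pos2):
        c1, pos1, o1, c2, pos2, o2 = c2, pos2, o2, c1, pos1, o1
    # somatic breakpoints sit on purity-diluted rearranged copies, so
    # their local read depth runs below the germline expectation
    depth_mean = p.depth_tumor_only
    if truth["cls"] == "somatic":
        depth_mean *= 0.35 + purity / 2.0
    depth = max(int(rng.poisson(depth_mean)), 5)
    if p.exact_af:
        af = af_true
    else:
        af = float(np.clip(rng.normal(af_true, 0.03), 0.01, 1.0))
    sr = int(rng.poisson(2 + depth * af * 0.25))
    pe = int(rng.poisson(2 + depth * af * 0.30))
    bias = {"callerA": 5.0, "callerB": 0.0, "callerC": -5.0}[caller]
    qual = float(max((sr + pe) * 2.0 + bias + rng.normal(0, 5), 0.0))
    imprecise = bool(rng.random() < p.imprecise_prob)
    if imprecise:
        sr = 0
    length = truth["length"]
    if truth["svtype"] in ("DEL", "DUP", "INV"):
        length = pos2 - pos1
    return SVBreakpointPair(
        c1, pos1, o1, c2, pos2, o2, svtype=truth["svtype"], length=length,
        allele_fraction=af, read_depth=depth, split_reads=sr,
        discordant_pairs=pe, caller_quality=qual, imprecise=imprecise,
        caller_id=caller, truth_label=truth["cls"],
    )


def _random_intervals(rng, n: int, min_len: int, max_len: int,
                      chroms=AUTOSOMES, label: str = "") -> list[GenomicInterval]:
    out = []
    lengths = np.array([GENOME[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(n):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        l = int(rng.integers(min_len, max_len))
        start = int(rng.integers(0, GENOME[chrom] - l))
        out.append(GenomicInterval(chrom, start, start + l, label))
    return out


def _gene_models(rng, p: SimulationParams):
    """Random gene spans with a UTR-CDS/intron-UTR internal structure."""
    spans, features = [], []
    chroms = AUTOSOMES + ("chrX",)
    lengths = np.array([GENOME[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    for i in range(p.n_genes):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        glen = int(rng.integers(20_000, 80_000))
        start = int(rng.integers(EXCLUSION_FLANK, GENOME[chrom] - EXCLUSION_FLANK - glen))
        name = f"GENE{i:04d}"
        spans.append(GenomicInterval(chrom, start, start + glen, name))
        utr = int(rng.integers(500, 2500))
        features.append(GenomicInterval(chrom, start, start + utr, "UTR"))
        features.append(GenomicInterval(chrom, start + glen - utr, start + glen, "UTR"))
        pos = start + utr
        exon = True
        while pos < start + glen - utr:
            block = int(rng.integers(200, 500)) if exon else int(rng.integers(1500, 4000))
            end = min(pos + block, start + glen - utr)
            features.append(GenomicInterval(chrom, pos, end, "CDS" if exon else "intron"))
            exon = not exon
            pos = end
    return spans, features


# ---------------------------------------------------------------------------
# copy number


def _matched_cn_profile(rng, p: SimulationParams, sample: str, purity: float) -> CNCallset:
    n_seg = max(int(p.n_cn_segments + rng.integers(-10, 11)), 8)
    ploidy_center = float(rng.uniform(1.8, 3.6))
    lengths = np.array([GENOME[c] for c in AUTOSOMES], dtype=float)
    per_chrom = np.maximum(np.round(n_seg * lengths / lengths.sum()).astype(int), 2)
    segments = []
    for chrom, k in zip(AUTOSOMES, per_chrom):
        cuts = np.sort(rng.choice(np.arange(1, GENOME[chrom] // 1000), size=k - 1,
                                  replace=False)) * 1000
        bounds = np.concatenate([[0], cuts, [GENOME[chrom]]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if rng.random() < 0.08:
                cn = float(rng.uniform(0.05, 0.4))
            else:
                cn = float(max(rng.normal(ploidy_center, 0.6), 0.0))
            minor = float(np.clip(rng.normal(cn * 0.4, 0.25), 0.0, cn / 2.0))
            segments.append(CNSegment(chrom, int(a), int(b), cn, cn - minor, minor))
    total = sum(s.length for s in segments)
    ploidy = sum(s.total_cn * s.length for s in segments) / total
    return CNCallset(sample=sample, purity=purity, ploidy=ploidy, segments=segments)


def _tumor_only_cn_profile(
    rng, p: SimulationParams, matched: CNCallset, exclusion: list[GenomicInterval]
) -> tuple[CNCallset, pd.DataFrame]:
    injections = []
    segments: list[CNSegment] = []
    excl_index = IntervalIndex(exclusion)
    for seg in matched.segments:
        total = seg.total_cn + float(rng.normal(0, p.cn_noise_sd))
        minor = seg.minor_cn + float(rng.normal(0, p.cn_noise_sd / 2))
        minor = float(np.clip(minor, 0.0, max(total, 0.0) / 2.0)) if total > 0 else 0.0
        major = total - minor
        in_exclusion = excl_index.count(seg.chrom, seg.start, seg.end) > 0
        if not in_exclusion and rng.random() < p.negative_noise_prob:
            if rng.random() < 0.5:
                total = float(rng.uniform(-0.45, -0.05))
                kind = "slightly_negative"
            else:
                total = float(rng.uniform(-1.5, -0.55))
                kind = "largely_negative"
            major, minor = total, 0.0
            injections.append({"kind": kind, "chrom": seg.chrom, "start": seg.start,
                               "end": seg.end, "value": total})
        segments.append(CNSegment(seg.chrom, seg.start, seg.end,
                                  round(total, 6), round(major, 6), round(minor, 6)))
    # artifactual focal peaks inside exclusion zones, carved into the tiling
    zones_by_chrom: dict[str, list[GenomicInterval]] = {}
    for z in exclusion:
        if z.chrom in AUTOSOMES:
            zones_by_chrom.setdefault(z.chrom, []).append(z)
    for chrom in AUTOSOMES:
        if rng.random() >= p.artifact_peak_prob:
            continue
        zones = zones_by_chrom[chrom]
        zone = zones[int(rng.choice(len(zones)))]
        plen = int(rng.integers(50_000, 300_000))
        start = int(rng.integers(zone.start, zone.end - plen))
        end = start + plen
        cn = float(rng.uniform(6.0, 12.0))
        carved: list[CNSegment] = []
        for seg in segments:
            if seg.chrom != chrom or seg.end <= start or seg.start >= end:
                carved.append(seg)
                continue
            if seg.start < start:
                carved.append(CNSegment(chrom, seg.start, start, seg.total_cn,
                                        seg.major_cn, seg.minor_cn))
            if seg.end > end:
                carved.append(CNSegment(chrom, end, seg.end, seg.total_cn,
                                        seg.major_cn, seg.minor_cn))
        carved.append(CNSegment(chrom, start, end, cn, cn - 1.0, 1.0))
        carved.sort(key=lambda s: (s.chrom, s.start))
        segments = carved
        injections.append({"kind": "artifact_peak", "chrom": chrom, "start": start,
                           "end": end, "value": cn})
    purity = float(np.clip(matched.purity + rng.normal(0, p.purity_noise_sd), 0.05, 1.0))
    total = sum(s.length for s in segments)
    ploidy = sum(s.total_cn * s.length for s in segments) / total
    cs = CNCallset(sample=matched.sample, purity=purity, ploidy=ploidy, segments=segments)
    inj = pd.DataFrame(injections, columns=["kind", "chrom", "start", "end", "value"])
    return cs, inj


def simulate_cn_profiles(
    p: SimulationParams,
    rng: np.random.Generator | None = None,
    purities: list[float] | None = None,
) -> list[tuple[CNCallset, CNCallset, pd.DataFrame]]:
    """Per-sample (matched, tumor-only, injection log) copy-number
    profiles; the tumor-only table is the matched one plus value noise,
    negative-value injections and artifact peaks in the exclusion
    zones."""
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    exclusion = default_exclusion_intervals()
    out = []
    for i in range(p.n_samples):
        sample = f"S{i + 1:03d}"
        purity = (
            float(purities[i]) if purities is not None
            else float(rng.uniform(*p.purity_range))
        )
        matched = _matched_cn_profile(rng, p, sample, purity)
        tumor_only, inj = _tumor_only_cn_profile(rng, p, matched, exclusion)
        out.append((matched, tumor_only, inj))
    return out


# ---------------------------------------------------------------------------
# the cohort


def simulate_cohort(p: SimulationParams, outdir=None) -> SimulatedCohort:
    """Simulate the full cohort (and optionally write it to ``outdir``).

    The returned object carries all call sets, resources and truth
    tables in memory; ``write`` emits the on-disk layout consumed by the
    I/O layer.  Identical parameters (including seed) give identical
    output, byte for byte.
    """
    rng = np.random.default_rng(p.seed)
    exclusion = default_exclusion_intervals()

    # sample frame: sex, purity, Y loss
    n = p.n_samples
    names = [f"S{i + 1:03d}" for i in range(n)]
    n_male = int(round(p.male_fraction * n))
    sexes = ["M"] * n_male + ["F"] * (n - n_male)
    rng.shuffle(sexes)
    purities = rng.uniform(*p.purity_range, size=n)
    y_loss_idx = -1
    if p.inject_y_loss and "M" in sexes:
        y_loss_idx = sexes.index("M")

    # gene models and static interval resources
    gene_spans, gene_features = _gene_models(rng, p)
    cancer_idx = sorted(rng.choice(len(gene_spans), size=min(p.n_cancer_genes, len(gene_spans)),
                                   replace=False))
    cancer_genes = [gene_spans[int(i)] for i in cancer_idx]
    conserved = _random_intervals(rng, p.n_conserved, 200, 2000)
    repeats = _random_intervals(rng, p.n_repeats, 100, 1000)

    popdb: dict = {}
    cancerdb: dict = {}
    pon_entries: list[tuple[str, int]] = []
    svdb_entries: list[GenomicInterval] = []

    samples: list[SimulatedSample] = []
    truth_small_rows: list[dict] = []
    truth_sv_rows: list[dict] = []
    purity_rows: list[dict] = []

    cn_rng = np.random.default_rng(int(rng.integers(0, 2**31)))
    cn_profiles = simulate_cn_profiles(
        p, rng=cn_rng, purities=[float(x) for x in purities]
    )

    for si, (name, sex) in enumerate(zip(names, sexes)):
        purity = float(purities[si])
        y_loss = si == y_loss_idx

        # ---- small variants ------------------------------------------
        n_sites = p.n_germline_small + p.n_somatic_small
        positions = _draw_positions(rng, n_sites)
        sites = []
        for j, (chrom, pos) in enumerate(positions):
            cls = "germline" if j < p.n_germline_small else "somatic"
            is_indel = bool(rng.random() < p.indel_fraction)
            ref, alt, context = _alleles(rng, is_indel)
            af_true = (
                _germline_af(rng, p) if cls == "germline" else purity / 2.0
            )
            hrun = int(rng.integers(1, 4)) if not is_indel else int(rng.integers(1, 9))
            sites.append({"site": (chrom, pos), "ref": ref, "alt": alt,
                          "context": context, "hrun": hrun, "cls": cls,
                          "af_true": af_true})
        tumor_only, matched_somatic = [], []
        for site in sites:
            cls = site["cls"]
            key = (site["site"][0], site["site"][1], site["ref"], site["alt"])
            if key not in popdb and key not in cancerdb:
                p_pop = p.popdb_p_germline if cls == "germline" else p.popdb_p_somatic
                p_can = p.cancerdb_p_germline if cls == "germline" else p.cancerdb_p_somatic
                if rng.random() < p_pop:
                    popdb[key] = float(np.clip(rng.beta(0.8, 3.0), 0.0005, 0.999))
                if rng.random() < p_can:
                    cancerdb[key] = int(rng.integers(1, 50))
            dropped = rng.random() < p.small_variant_dropout
            if not dropped:
                tumor_only.append(
                    _small_variant(rng, p, name, site, cls, purity, p.depth_tumor_only)
                )
            if cls == "somatic":
                matched_somatic.append(
                    _small_variant(rng, p, name, site, cls, purity, p.depth_matched)
                )
            truth_small_rows.append(
                {"sample": name, "chrom": key[0], "pos": key[1], "ref": key[2],
                 "alt": key[3], "cls": cls, "af_true": site["af_true"],
                 "in_tumor_only": not dropped}
            )
        tumor_only.sort(key=lambda v: v.sort_key)
        matched_somatic.sort(key=lambda v: v.sort_key)

        # ---- structural variants -------------------------------------
        sv_truths = []
        for j in range(p.n_germline_sv + p.n_somatic_sv):
            cls = "germline" if j < p.n_germline_sv else "somatic"
            t = _random_sv(rng, p, cls)
            t["sv_id"] = f"{name}_sv{j:03d}"
            if cls == "germline":
                t["af_true"] = _germline_af(rng, p)
            else:
                t["af_true"] = purity / 2.0
            sv_truths.append(t)
            # cohort resources fed by the truth
            for chrom, pos in ((t["chrom1"], t["pos1"]), (t["chrom2"], t["pos2"])):
                if cls == "germline":
                    if rng.random() < p.pon_p_germline_sv:
                        for _ in range(1 + int(rng.poisson(p.pon_entries_mean - 1))):
                            jp = int(np.clip(pos + rng.integers(-100, 101), 0,
                                             GENOME[chrom] - 1))
                            pon_entries.append((chrom, jp))
                    if rng.random() < p.svdb_p_germline:
                        svdb_entries.append(
                            GenomicInterval(chrom, pos, pos + 1, "pop",
                                            float(rng.beta(2, 8)))
                        )
                elif rng.random() < p.svdb_p_somatic_pancancer:
                    svdb_entries.append(GenomicInterval(chrom, pos, pos + 1, "pancancer"))
        sv_calls: dict[str, list[SVBreakpointPair]] = {c: [] for c in SV_CALLERS}
        for t in sv_truths:
            emitted = {}
            for caller in SV_CALLERS:
                if rng.random() < p.caller_dropout[caller]:
                    emitted[caller] = False
                    continue
                call = _emit_sv_call(rng, p, t, caller, t["af_true"], purity)
                call.sample = name
                sv_calls[caller].append(call)
                emitted[caller] = True
            truth_sv_rows.append(
                {"sample": name, "sv_id": t["sv_id"], "svtype": t["svtype"],
                 "chrom1": t["chrom1"], "pos1": t["pos1"],
                 "chrom2": t["chrom2"], "pos2": t["pos2"], "cls": t["cls"],
                 **{f"emitted_{c}": emitted[c] for c in SV_CALLERS}}
            )
        for caller in SV_CALLERS:
            sv_calls[caller].sort(key=lambda s: (s.chrom1, s.pos1, s.chrom2, s.pos2))
            for k, call in enumerate(sv_calls[caller]):
                call.call_id = f"{name}:{caller}:{k}"

        # ---- copy number ---------------------------------------------
        cn_matched, cn_tumor_only, cn_inj = cn_profiles[si]

        # ---- QC evidence ---------------------------------------------
        if sex == "M":
            x_cov = float(rng.normal(0.52, 0.02))
            y_cov = float(rng.normal(0.15, 0.02)) if y_loss else float(rng.normal(0.50, 0.03))
            x_expr = float(rng.normal(1000, 60))
            y_expr = float(rng.normal(800, 60))
            mx = float(rng.normal(11.5, 0.2))
            my = mx + float(rng.normal(0.0, 0.3))
        else:
            x_cov = float(rng.normal(1.0, 0.03))
            y_cov = float(max(rng.normal(0.01, 0.005), 0.0))
            x_expr = float(rng.normal(1800, 100))
            y_expr = float(max(rng.normal(80, 20), 0.0))
            mx = float(rng.normal(11.5, 0.2))
            my = mx - 4.0 + float(rng.normal(0.0, 0.4))
        evidence = SexEvidence(
            sample=name, clinical_sex=sex,
            x_coverage=x_cov, y_coverage=y_cov,
            x_expression=x_expr, y_expression=y_expr,
            meth_x_median=mx, meth_y_median=my,
        )
        genomic = float(np.clip(purity + rng.normal(0, 0.03), 0.02, 1.0))
        if rng.random() < p.genomic_purity_missing_prob:
            genomic = float("nan")
        purity_rows.append(
            {"sample": name,
             "pathologic": float(np.clip(purity + rng.normal(0, 0.08), 0.02, 1.0)),
             "genomic": genomic,
             "transcriptomic": float(np.clip(purity + rng.normal(0, 0.06), 0.02, 1.0)),
             "true_purity": purity}
        )

        samples.append(
            SimulatedSample(
                sample=name, sex=sex, purity=purity, y_loss=y_loss,
                tumor_only_small=tumor_only, matched_somatic_small=matched_somatic,
                sv_truth=pd.DataFrame([r for r in truth_sv_rows if r["sample"] == name]),
                sv_calls=sv_calls,
                cn_matched=cn_matched, cn_tumor_only=cn_tumor_only,
                cn_injections=cn_inj, sex_evidence=evidence,
            )
        )

    # background PON and known-SV database noise
    for chrom in AUTOSOMES:
        k = int(round(p.pon_density_per_mbp * GENOME[chrom] / 1e6))
        for pos in sorted(rng.integers(0, GENOME[chrom], size=k).tolist()):
            pon_entries.append((chrom, int(pos)))
        kdb = int(round(p.svdb_background_per_mbp * GENOME[chrom] / 1e6))
        for pos in sorted(rng.integers(0, GENOME[chrom] - 1, size=kdb).tolist()):
            svdb_entries.append(
                GenomicInterval(chrom, int(pos), int(pos) + 1, "pop",
                                float(rng.beta(1.2, 20)))
            )

    pon_intervals = [GenomicInterval(c, q, q + 1, "pon") for c, q in pon_entries]
    resource_intervals = {
        "pon": pon_intervals,
        "sv_db": svdb_entries,
        "gene_features": gene_features,
        "conserved": conserved,
        "cancer_genes": cancer_genes,
        "repeats": repeats,
    }
    from .core import BreakpointIndex, IntervalIndex

    resources = ResourceSet(
        popdb_small=dict(popdb),
        cancerdb_small={k: int(v) for k, v in cancerdb.items()},
        pon_sv=BreakpointIndex(pon_entries),
        sv_db=BreakpointIndex(
            [(iv.chrom, iv.start) for iv in svdb_entries],
            values=[iv.value for iv in svdb_entries],
            labels=[iv.label for iv in svdb_entries],
        ),
        gene_features=IntervalIndex(gene_features),
        conserved=IntervalIndex(conserved),
        cancer_genes=IntervalIndex(cancer_genes),
        repeats=IntervalIndex(repeats),
    )

    cohort = SimulatedCohort(
        params=p,
        samples=samples,
        resources=resources,
        gene_spans=gene_spans,
        exclusion=exclusion,
        resource_intervals=resource_intervals,
        popdb=popdb,
        cancerdb=cancerdb,
        purity_estimates=pd.DataFrame(purity_rows),
        truth_small=pd.DataFrame(truth_small_rows),
        truth_sv=pd.DataFrame(truth_sv_rows),
        truth_samples=pd.DataFrame(
            {"sample": names, "sex": sexes,
             "purity": [float(x) for x in purities],
             "y_loss": [i == y_loss_idx for i in range(n)]}
        ),
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort
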