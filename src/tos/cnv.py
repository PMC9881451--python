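"""Copy-number callset post-processing and matched vs tumor-only benchmarking.

Tumor-only copy-number callers leave two classes of artifacts that a
matched normal would have absorbed: spurious focal peaks near telomeres
and centromeres, and negative copy-number estimates in noisy regions
(the upstream caller penalises rather than truncates negative values).
This module removes segments overlapping a curated exclusion list,
rounds slightly negative estimates (in (-0.5, 0)) to 0, drops largely
negative ones (< -0.5), and quantifies tumor-only vs matched concordance
per sample and per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GenomicInterval, IntervalIndex
from .qc import pearson_correlation

__all__ = [
    "CNSegment",
    "CNCallset",
    "PostprocessResult",
    "ConcordanceReport",
    "postprocess_tumor_only",
    "genome_state_fractions",
    "gene_level_cn",
    "compare_callsets",
]

#: largest negative copy number still rounded up to zero; anything below
#: is treated as an unreliable call and removed
NEGATIVE_ROUND_FLOOR = -0.5


@dataclass
class CNSegment:
    """One copy-number segment, half-open [start, end).  Values are real;
    ``major_cn + minor_cn`` tracks ``total_cn`` within 1e-6 when both are
    present (negative noise can break the decomposition, which is exactly
    what post-processing repairs or removes)."""

    chrom: str
    start: int
    end: int
    total_cn: float
    major_cn: float
    minor_cn: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def values(self) -> tuple[float, float, float]:
        return (self.total_cn, self.major_cn, self.minor_cn)


@dataclass
class CNCallset:
    sample: str
    purity: float
    ploidy: float
    segments: list[CNSegment] = field(default_factory=list)

    def total_bp(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass
class PostprocessResult:
    callset: CNCallset
    removal_log: pd.DataFrame  # columns: chrom start end reason bp
    rounded: int
    excluded_fraction: float  # of input segment length

    @property
    def removed_bp(self) -> int:
        return int(self.removal_log["bp"].sum()) if len(self.removal_log) else 0


def postprocess_tumor_only(
    cs: CNCallset, exclusion: list[GenomicInterval] | IntervalIndex
) -> PostprocessResult:
    """Apply the tumor-only cleaning rules, in order:

    1. any segment overlapping an exclusion interval is removed whole;
    2. copy-number values in (-0.5, 0) are rounded to 0;
    3. segments with any value < -0.5 are removed.

    Every removal is logged with a reason and the bp it accounts for, so
    retained + removed bp always reconstitutes the input.
    """
    index = exclusion if isinstance(exclusion, IntervalIndex) else IntervalIndex(exclusion)
    kept: list[CNSegment] = []
    log_rows: list[dict] = []
    rounded = 0
    total_bp = cs.total_bp()
    for seg in cs.segments:
        if index.count(seg.chrom, seg.start, seg.end) > 0:
            log_rows.append(
                {"chrom": seg.chrom, "start": seg.start, "end": seg.end,
                 "reason": "artifact_region", "bp": seg.length}
            )
            continue
        if any(v < NEGATIVE_ROUND_FLOOR for v in seg.values):
            log_rows.append(
                {"chrom": seg.chrom, "start": seg.start, "end": seg.end,
                 "reason": "largely_negative", "bp": seg.length}
            )
            continue
        if any(v < 0 for v in seg.values):
            seg = replace(
                seg,
                total_cn=max(seg.total_cn, 0.0),
                major_cn=max(seg.major_cn, 0.0),
                minor_cn=max(seg.minor_cn, 0.0),
            )
            rounded += 1
        kept.append(seg)
    log = pd.DataFrame(log_rows, columns=["chrom", "start", "end", "reason", "bp"])
    removed = int(log["bp"].sum()) if len(log) else 0
    frac = removed / total_bp if total_bp else 0.0
    out = CNCallset(cs.sample, cs.purity, cs.ploidy, kept)
    return PostprocessResult(out, log, rounded, frac)


def _state(total_cn: float) -> str:
    # half-up rounding: 1.5 -> diploid, 2.5 -> amplified
    r = math.floor(total_cn + 0.5)
    if r < 2:
        return "deleted"
    if r == 2:
        return "diploid"
    return "amplified"


def genome_state_fractions(cs: CNCallset) -> tuple[float, float, float]:
    """Length-weighted (deleted, diploid, amplified) fractions of the
    covered genome, by rounding each segment's total copy number against
    the diploid state 2."""
    total = cs.total_bp()
    if total == 0:
        raise ValueError(f"callset {cs.sample!r} has zero segment length")
    acc = {"deleted": 0, "diploid": 0, "amplified": 0}
    for seg in cs.segments:
        acc[_state(seg.total_cn)] += seg.length
    return (acc["deleted"] / total, acc["diploid"] / total, acc["amplified"] / total)


def gene_level_cn(
    cs: CNCallset, genes: list[GenomicInterval] | IntervalIndex
) -> pd.DataFrame:
    """Major/minor copy number per gene, taken from the overlapping
    segment with the largest overlap (ties to the lower total copy
    number).  Genes without any overlapping segment are absent from the
    result."""
    gene_list = list(genes) if not isinstance(genes, IntervalIndex) else None
    if gene_list is None:
        raise TypeError("pass the gene intervals themselves, not an index")
    seg_index = IntervalIndex(
        GenomicInterval(s.chrom, s.start, s.end, label=str(i))
        for i, s in enumerate(cs.segments)
    )
    rows = []
    for gene in gene_list:
        hits = seg_index.query(gene.chrom, gene.start, gene.end)
        if not hits:
            continue
        best = None
        for iv in hits:
            seg = cs.segments[int(iv.label)]
            ov = min(gene.end, seg.end) - max(gene.start, seg.start)
            cand = (-ov, seg.total_cn)
            if best is None or cand < best[0]:
                best = (cand, seg)
        seg = best[1]
        rows.append(
            {"gene": gene.label or f"{gene.chrom}:{gene.start}-{gene.end}",
             "major_cn": seg.major_cn, "minor_cn": seg.minor_cn}
        )
    return pd.DataFrame(rows, columns=["gene", "major_cn", "minor_cn"])


SAMPLE_METRICS = (
    "purity",
    "ploidy",
    "segment_count",
    "diploid_fraction",
    "amplified_fraction",
    "deleted_fraction",
)


@dataclass
class ConcordanceReport:
    """Paired tumor-only vs matched metric vectors and their Pearson r.

    ``sample_metrics`` maps metric name -> DataFrame with columns
    (sample, tumor_only, matched); ``gene_metrics`` maps major_cn /
    minor_cn -> DataFrame pooled over genes x samples.
    """

    sample_metrics: dict[str, pd.DataFrame]
    gene_metrics: dict[str, pd.DataFrame]
    r: dict[str, float]

    def summary(self) -> pd.DataFrame:
        rows = [
            {"metric": m, "n": len(self.sample_metrics[m]), "pearson_r": self.r[m]}
            for m in SAMPLE_METRICS
        ]
        for m in ("gene_major_cn", "gene_minor_cn"):
            key = m.removeprefix("gene_")
            rows.append({"metric": m, "n": len(self.gene_metrics[key]), "pearson_r": self.r[m]})
        return pd.DataFrame(rows)

    def plot(self, metric: str = "purity", ax=None):
        import matplotlib.pyplot as plt

        df = self.sample_metrics[metric]
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(df["matched"], df["tumor_only"], s=12)
        lim = [df[["matched", "tumor_only"]].min().min(), df[["matched", "tumor_only"]].max().max()]
        ax.plot(lim, lim, lw=0.8, color="grey")
        ax.set_xlabel(f"matched {metric}")
        ax.set_ylabel(f"tumor-only {metric}")
        ax.set_title(f"r = {self.r[metric]:.3f}")
        return ax


def _sample_metric_row(cs: CNCallset) -> dict[str, float]:
    deleted, diploid, amplified = genome_state_fractions(cs)
    return {
        "purity": cs.purity,
        "ploidy": cs.ploidy,
        "segment_count": float(len(cs.segments)),
        "diploid_fraction": diploid,
        "amplified_fraction": amplified,
        "deleted_fraction": deleted,
    }


def compare_callsets(
    tumor_only: list[CNCallset],
    matched: list[CNCallset],
    genes: list[GenomicInterval],
) -> ConcordanceReport:
    """Concordance benchmark between tumor-only and matched callsets of
    the same samples: per-sample purity/ploidy/segment-count/genome-state
    Pearson r, plus gene-level major/minor copy-number r pooled over all
    (gene, sample) pairs present in both callsets."""
    to_by = {cs.sample: cs for cs in tumor_only}
    ma_by = {cs.sample: cs for cs in matched}
    unpaired = sorted(set(to_by) ^ set(ma_by))
    if unpaired:
        raise ValueError(f"unpaired samples: {', '.join(unpaired)}")
    samples = sorted(to_by)

    sample_metrics: dict[str, pd.DataFrame] = {}
    r: dict[str, float] = {}
    to_rows = {s: _sample_metric_row(to_by[s]) for s in samples}
    ma_rows = {s: _sample_metric_row(ma_by[s]) for s in samples}
    for metric in SAMPLE_METRICS:
        df = pd.DataFrame(
            {
                "sample": samples,
                "tumor_only": [to_rows[s][metric] for s in samples],
                "matched": [ma_rows[s][metric] for s in samples],
            }
        )
        sample_metrics[metric] = df
        r[metric] = pearson_correlation(df["tumor_only"].to_numpy(), df["matched"].to_numpy())

    gene_metrics: dict[str, pd.DataFrame] = {}
    frames = []
    for s in samples:
        a = gene_level_cn(to_by[s], genes).set_index("gene")
        b = gene_level_cn(ma_by[s], genes).set_index("gene")
        common = a.index.intersection(b.index)
        frames.append(
            pd.DataFrame(
                {
                    "sample": s,
                    "gene": common,
                    "major_to": a.loc[common, "major_cn"].to_numpy(),
                    "major_ma": b.loc[common, "major_cn"].to_numpy(),
                    "minor_to": a.loc[common, "minor_cn"].to_numpy(),
                    "minor_ma": b.loc[common, "minor_cn"].to_numpy(),
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    for which in ("major", "minor"):
        gene_metrics[f"{which}_cn"] = pd.DataFrame(
            {
                "sample": pooled["sample"],
                "gene": pooled["gene"],
                "tumor_only": pooled[f"{which}_to"],
                "matched": pooled[f"{which}_ma"],
            }
        )
        r[f"gene_{which}_cn"] = pearson_correlation(
            pooled[f"{which}_to"].to_numpy(), pooled[f"{which}_ma"].to_numpy()
        )
    return ConcordanceReport(sample_metrics, gene_metrics, r)
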