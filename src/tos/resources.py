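"""Annotation resource bundle backing feature extraction.

A :class:`ResourceSet` carries exact-match small-variant databases (a
population allele-frequency database and a cancer mutation catalogue),
breakpoint sets (panel of normals, known-SV database with population and
pan-cancer entries), and interval resources (gene features, conserved
elements, cancer genes, repeats).  Every lookup returns an explicit
"absent" value rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .core import BreakpointIndex, GenomicInterval, IntervalIndex
from .vcfio import read_bed

__all__ = ["ResourceSet", "load_resources"]

#: region-class ordinal used by both feature blocks
REGION_ORDINAL = {"CDS": 3, "UTR": 2, "intron": 1, "intergenic": 0}


@dataclass
class ResourceSet:
    popdb_small: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    cancerdb_small: dict[tuple[str, int, str, str], int] = field(default_factory=dict)
    pon_sv: BreakpointIndex = field(default_factory=BreakpointIndex)
    sv_db: BreakpointIndex = field(default_factory=BreakpointIndex)
    gene_features: IntervalIndex = field(default_factory=lambda: IntervalIndex([]))
    conserved: IntervalIndex = field(default_factory=lambda: IntervalIndex([]))
    cancer_genes: IntervalIndex = field(default_factory=lambda: IntervalIndex([]))
    repeats: IntervalIndex = field(default_factory=lambda: IntervalIndex([]))

    def popdb_af(self, key) -> float | None:
        return self.popdb_small.get(key)

    def cancerdb_count(self, key) -> int:
        return self.cancerdb_small.get(key, 0)

    def region_class(self, chrom: str, pos0: int) -> str:
        """Highest-priority gene feature covering the 0-based position."""
        hits = self.gene_features.query_point(chrom, pos0)
        if not hits:
            return "intergenic"
        return max((h.label for h in hits), key=lambda c: REGION_ORDINAL.get(c, 0))


def _read_site_db(path, value_info_key: str):
    """Small-variant database VCF -> {(chrom,pos,ref,alt): value}."""
    from cyvcf2 import VCF

    out = {}
    vcf = VCF(str(path))
    for v in vcf:
        val = v.INFO.get(value_info_key)
        for ai, alt in enumerate(v.ALT):
            if val is None:
                entry = 0.0
            elif isinstance(val, tuple):
                entry = float(val[min(ai, len(val) - 1)])
            else:
                entry = float(val)
            out[(v.CHROM, v.POS, v.REF, alt)] = entry
    vcf.close()
    return out


def _breakpoint_index_from_bed(intervals: list[GenomicInterval]) -> BreakpointIndex:
    return BreakpointIndex(
        [(iv.chrom, iv.start) for iv in intervals],
        values=[iv.value for iv in intervals],
        labels=[iv.label for iv in intervals],
    )


def load_resources(directory) -> ResourceSet:
    """Load the standard resource layout:

    ``popdb.vcf`` (INFO/AF), ``cancerdb.vcf`` (INFO/CNT), ``pon.bed``,
    ``sv_db.bed`` (name pop|pancancer, score = population AF),
    ``genes.bed`` (name = CDS/UTR/intron), ``conserved.bed``,
    ``cancer_genes.bed`` (name = gene symbol), ``repeats.bed``.
    Missing files yield empty resources.
    """
    d = Path(directory)

    def bed(name):
        p = d / name
        return read_bed(p) if p.exists() else []

    popdb = _read_site_db(d / "popdb.vcf", "AF") if (d / "popdb.vcf").exists() else {}
    cancerdb = (
        {k: int(v) for k, v in _read_site_db(d / "cancerdb.vcf", "CNT").items()}
        if (d / "cancerdb.vcf").exists()
        else {}
    )
    return ResourceSet(
        popdb_small=popdb,
        cancerdb_small=cancerdb,
        pon_sv=_breakpoint_index_from_bed(bed("pon.bed")),
        sv_db=_breakpoint_index_from_bed(bed("sv_db.bed")),
        gene_features=IntervalIndex(bed("genes.bed")),
        conserved=IntervalIndex(bed("conserved.bed")),
        cancer_genes=IntervalIndex(bed("cancer_genes.bed")),
        repeats=IntervalIndex(bed("repeats.bed")),
    )
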