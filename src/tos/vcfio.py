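"""Readers and writers for the on-disk artifacts.

Small variants and SVs travel as VCF 4.2; interval resources as BED;
copy-number callsets as tab-separated segment tables with a per-sample
purity/ploidy header.  Reading goes through cyvcf2; writing emits plain
text in the dialects this package controls.

Three SV caller dialects are supported:

``bnd``
    intra- and inter-chromosomal events as paired BND records with
    bracket ALTs joined via MATEID (insertions fall back to symbolic
    records); allele fraction under INFO/VF.
``symbolic``
    symbolic ALT (<DEL> etc.) with INFO END/SVLEN/STRANDS; inter-
    chromosomal events as SVTYPE=TRA with CHR2; allele fraction under
    INFO/AF.
``symbolic_signed``
    as ``symbolic`` but SVLEN signed (negative for deletions) and the
    allele fraction under INFO/VAF.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np

from .core import (
    GenomicInterval,
    SVBreakpointPair,
    SmallVariant,
    breakpoints_ordered,
    chrom_sort_key,
)
from .cnv import CNCallset, CNSegment

__all__ = [
    "read_small_variants",
    "write_small_variants",
    "write_classified_variants",
    "read_sv_calls",
    "write_sv_calls",
    "read_bed",
    "write_bed",
    "read_cn_callset",
    "write_cn_callset",
    "SMALL_VARIANT_DIALECTS",
    "SV_DIALECTS",
]

SMALL_VARIANT_DIALECTS = ("tumor",)
SV_DIALECTS = ("bnd", "symbolic", "symbolic_signed")

_VCF_HEADER = "##fileformat=VCFv4.2\n"


def _open_vcf(path):
    from cyvcf2 import VCF

    return VCF(str(path))


# ---------------------------------------------------------------------------
# small variants


def _info(v, key, default=-1.0):
    val = v.INFO.get(key)
    return default if val is None else val


def read_small_variants(path, dialect: str = "tumor") -> list[SmallVariant]:
    """Parse a small-variant VCF into normalized records, one per
    (variant, alt allele); multi-allelic rows are split and flagged.

    A missing mandatory annotation (AD/DP) triggers a per-record warning
    and the sentinel ``-1``; a malformed row raises with its data line
    number.  Records come back sorted by (chrom, pos).
    """
    if dialect not in SMALL_VARIANT_DIALECTS:
        raise ValueError(f"unknown small-variant dialect {dialect!r}")
    out: list[SmallVariant] = []
    vcf = _open_vcf(path)
    it = iter(vcf)
    i = 0
    while True:
        try:
            v = next(it)
        except StopIteration:
            break
        except Exception as exc:  # pragma: no cover - cyvcf2 error path
            raise ValueError(f"malformed VCF record at data line {i + 1} of {path}") from exc
        i += 1
        def fmt(key):
            try:
                return v.format(key)
            except Exception:
                return None

        ad, dp, af = fmt("AD"), fmt("DP"), fmt("AF")
        multi = len(v.ALT) > 1 or _info(v, "MULTI", None) is not None
        for ai, alt in enumerate(v.ALT):
            alt_count = -1
            depth = -1
            if ad is not None and ad.shape[1] > ai + 1:
                alt_count = int(ad[0, ai + 1])
            if dp is not None:
                depth = int(np.ravel(dp)[0])
            if ad is None or dp is None:
                warnings.warn(
                    f"{path}: record {v.CHROM}:{v.POS} lacks AD/DP; using sentinels",
                    stacklevel=2,
                )
            if af is not None:
                frac = float(np.ravel(af)[min(ai, np.ravel(af).size - 1)])
            elif depth > 0 and alt_count >= 0:
                frac = alt_count / depth
            else:
                frac = -1.0
            context = v.INFO.get("TNC")
            out.append(
                SmallVariant(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    allele_fraction=frac,
                    total_depth=depth,
                    alt_count=alt_count,
                    median_base_quality=float(_info(v, "MBQ")),
                    median_mapping_quality=float(_info(v, "MMQ")),
                    strand_balance=float(_info(v, "STRB")),
                    caller_confidence=float(_info(v, "TLOD")),
                    filter_pass=v.FILTER is None,
                    multiallelic=multi,
                    context=context,
                    homopolymer_run=int(_info(v, "HRUN", -1)),
                )
            )
    vcf.close()
    out.sort(key=lambda r: r.sort_key)
    return out


_SMALL_INFO_HEADER = """\
##INFO=<ID=TLOD,Number=1,Type=Float,Description="Caller confidence score">
##INFO=<ID=MBQ,Number=1,Type=Float,Description="Median base quality">
##INFO=<ID=MMQ,Number=1,Type=Float,Description="Median mapping quality">
##INFO=<ID=STRB,Number=1,Type=Float,Description="Fraction of alt reads on forward strand">
##INFO=<ID=TNC,Number=1,Type=String,Description="Reference trinucleotide context">
##INFO=<ID=HRUN,Number=1,Type=Integer,Description="Homopolymer run length at site">
##INFO=<ID=MULTI,Number=0,Type=Flag,Description="Split from a multi-allelic row">
##FILTER=<ID=FAIL,Description="Failed caller filters">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
"""


def _contig_lines(contigs: dict[str, int] | None) -> str:
    if not contigs:
        return ""
    return "".join(
        f"##contig=<ID={c},length={l}>\n"
        for c, l in sorted(contigs.items(), key=lambda kv: chrom_sort_key(kv[0]))
    )


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def _small_variant_row(r: SmallVariant, extra_info: str = "") -> str:
    info = [
        f"TLOD={_fmt_float(r.caller_confidence)}",
        f"MBQ={_fmt_float(r.median_base_quality)}",
        f"MMQ={_fmt_float(r.median_mapping_quality)}",
        f"STRB={_fmt_float(r.strand_balance)}",
    ]
    if r.context:
        info.append(f"TNC={r.context}")
    if r.homopolymer_run >= 0:
        info.append(f"HRUN={r.homopolymer_run}")
    if r.multiallelic:
        info.append("MULTI")
    if extra_info:
        info.append(extra_info)
    filt = "PASS" if r.filter_pass else "FAIL"
    ref_count = max(r.total_depth - r.alt_count, 0) if r.total_depth >= 0 else -1
    fmt = f"0/1:{ref_count},{r.alt_count}:{r.total_depth}:{r.allele_fraction:.6f}"
    return (
        f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{filt}\t"
        f"{';'.join(info)}\tGT:AD:DP:AF\t{fmt}\n"
    )


def write_small_variants(
    records: list[SmallVariant],
    path,
    sample: str = "TUMOR",
    contigs: dict[str, int] | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(contigs))
        fh.write(_SMALL_INFO_HEADER)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in sorted(records, key=lambda r: r.sort_key):
            fh.write(_small_variant_row(r))


def write_classified_variants(
    records: list[SmallVariant],
    probabilities,
    path,
    sample: str = "TUMOR",
    threshold: float = 0.5,
    contigs: dict[str, int] | None = None,
) -> None:
    """Emit classified calls with INFO SOMATIC_PROB / RF_CLASS; FILTER is
    PASS for the somatic class and GERMLINE otherwise."""
    probabilities = list(probabilities)
    if len(probabilities) != len(records):
        raise ValueError("one probability per record required")
    path = Path(path)
    order = sorted(range(len(records)), key=lambda i: records[i].sort_key)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(contigs))
        fh.write(_SMALL_INFO_HEADER)
        fh.write('##INFO=<ID=SOMATIC_PROB,Number=1,Type=Float,Description="RF somatic probability">\n')
        fh.write('##INFO=<ID=RF_CLASS,Number=1,Type=String,Description="RF class at threshold">\n')
        fh.write('##FILTER=<ID=GERMLINE,Description="Classified germline">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for i in order:
            r, p = records[i], float(probabilities[i])
            cls = "somatic" if p >= threshold else "germline"
            row = _small_variant_row(r, extra_info=f"SOMATIC_PROB={p:.6f};RF_CLASS={cls}")
            cols = row.split("\t")
            cols[6] = "PASS" if cls == "somatic" else "GERMLINE"
            fh.write("\t".join(cols))


def read_classified_variants(path):
    """Read back a classified VCF as (records, probabilities, classes)."""
    vcf = _open_vcf(path)
    records, probs, classes = [], [], []
    for v in vcf:
        probs.append(float(v.INFO.get("SOMATIC_PROB")))
        classes.append(v.INFO.get("RF_CLASS"))
    vcf.close()
    records = read_small_variants(path)
    return records, probs, classes


# ---------------------------------------------------------------------------
# structural variants

_BRACKET_RE = re.compile(
    r"^(?:(?P<t1>[ACGTN]+)(?P<b1>[\[\]])(?P<chr>[^:\[\]]+):(?P<pos>\d+)(?P=b1)"
    r"|(?P<b2>[\[\]])(?P<chr2>[^:\[\]]+):(?P<pos2>\d+)(?P=b2)(?P<t2>[ACGTN]+))$"
)

_DEFAULT_STRANDS = {"DEL": "+-", "DUP": "-+", "INV": "++", "INS": "+-", "TRA": "+-"}


def _bracket_alt(local_orient: str, remote_orient: str, mate_chrom: str, mate_pos: int, ref: str) -> str:
    b = "]" if remote_orient == "+" else "["
    mate = f"{b}{mate_chrom}:{mate_pos}{b}"
    return f"{ref}{mate}" if local_orient == "+" else f"{mate}{ref}"


def _parse_bracket_alt(alt: str):
    """Return (local_orient, remote_orient, mate_chrom, mate_pos)."""
    m = _BRACKET_RE.match(alt)
    if not m:
        raise ValueError(f"not a bracket ALT: {alt}")
    if m.group("t1"):
        local = "+"
        bracket = m.group("b1")
        chrom, pos = m.group("chr"), int(m.group("pos"))
    else:
        local = "-"
        bracket = m.group("b2")
        chrom, pos = m.group("chr2"), int(m.group("pos2"))
    remote = "+" if bracket == "]" else "-"
    return local, remote, chrom, pos


def _svtype_from_geometry(chrom1, chrom2, o1, o2) -> str:
    if chrom1 != chrom2:
        return "TRA"
    if (o1, o2) == ("+", "-"):
        return "DEL"
    if (o1, o2) == ("-", "+"):
        return "DUP"
    return "INV"


def _af_key(dialect: str) -> str:
    return {"bnd": "VF", "symbolic": "AF", "symbolic_signed": "VAF"}[dialect]


def _normalize_pair(chrom1, pos1, o1, chrom2, pos2, o2):
    if breakpoints_ordered(chrom1, pos1, chrom2, pos2):
        return chrom1, pos1, o1, chrom2, pos2, o2
    return chrom2, pos2, o2, chrom1, pos1, o1


def read_sv_calls(
    path,
    dialect: str,
    caller_id: str = "",
    return_dropped: bool = False,
):
    """Parse one caller's SV VCF into oriented breakpoint pairs.

    BND mates are joined on MATEID and collapsed to a single record with
    breakpoints in canonical chromosome order; symbolic records are
    expanded via END/SVLEN.  Unpaired BND mates are dropped with a
    warning and counted.
    """
    if dialect not in SV_DIALECTS:
        raise ValueError(f"unknown SV dialect {dialect!r}")
    afk = _af_key(dialect)
    vcf = _open_vcf(path)
    pending: dict[str, object] = {}
    done_ids: set[str] = set()
    pairs: list[SVBreakpointPair] = []
    dropped = 0

    def metrics(v):
        return dict(
            allele_fraction=float(_info(v, afk)),
            read_depth=int(_info(v, "DP", -1)),
            split_reads=int(_info(v, "SR", -1)),
            discordant_pairs=int(_info(v, "PE", -1)),
            caller_quality=float(v.QUAL) if v.QUAL is not None else -1.0,
            imprecise=v.INFO.get("IMPRECISE") is not None,
        )

    for v in vcf:
        alt = v.ALT[0]
        if alt.startswith("<"):
            svtype = v.INFO.get("SVTYPE") or alt.strip("<>")
            end = v.INFO.get("POS2") if v.INFO.get("POS2") is not None else v.INFO.get("END")
            chr2 = v.INFO.get("CHR2") or v.CHROM
            strands = v.INFO.get("STRANDS") or _DEFAULT_STRANDS.get(svtype, "+-")
            svlen = v.INFO.get("SVLEN")
            length = abs(int(svlen)) if svlen is not None else -1
            if svtype == "INS":
                end = v.POS + 1 if end is None else end
            elif end is None:
                end = v.POS + length
            c1, p1, o1, c2, p2, o2 = _normalize_pair(
                v.CHROM, v.POS, strands[0], chr2, int(end), strands[1]
            )
            svtype = "TRA" if c1 != c2 else svtype
            pair = SVBreakpointPair(
                c1, p1, o1, c2, p2, o2, svtype=svtype,
                length=length if svtype in ("INS", "TRA") else int(end) - v.POS,
                caller_id=caller_id, **metrics(v),
            )
            pairs.append(pair)
        elif "[" in alt or "]" in alt:
            vid = v.ID
            mate_id = v.INFO.get("MATEID")
            if vid in done_ids:
                continue
            if mate_id in pending:
                first = pending.pop(mate_id)
                done_ids.add(mate_id)
                lo1, ro1, mc1, mp1 = _parse_bracket_alt(first["alt"])
                c1, p1, o1 = first["chrom"], first["pos"], lo1
                lo2, _, _, _ = _parse_bracket_alt(alt)
                c2, p2, o2 = v.CHROM, v.POS, lo2
                c1, p1, o1, c2, p2, o2 = _normalize_pair(c1, p1, o1, c2, p2, o2)
                svtype = _svtype_from_geometry(c1, c2, o1, o2)
                pairs.append(
                    SVBreakpointPair(
                        c1, p1, o1, c2, p2, o2, svtype=svtype,
                        caller_id=caller_id, **first["metrics"],
                    )
                )
            else:
                pending[vid] = {
                    "alt": alt, "chrom": v.CHROM, "pos": v.POS, "metrics": metrics(v),
                }
        else:
            raise ValueError(f"unrecognised SV ALT {alt!r} in {path}")
    vcf.close()
    if pending:
        dropped = len(pending)
        warnings.warn(f"{path}: dropped {dropped} unpaired BND mate(s)", stacklevel=2)
    pairs.sort(key=lambda s: (chrom_sort_key(s.chrom1), s.pos1, chrom_sort_key(s.chrom2), s.pos2))
    for i, p in enumerate(pairs):
        p.call_id = f"{caller_id or dialect}:{i}"
    if return_dropped:
        return pairs, dropped
    return pairs


_SV_INFO_HEADER = """\
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome">
##INFO=<ID=POS2,Number=1,Type=Integer,Description="Mate position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=STRANDS,Number=1,Type=String,Description="Breakpoint orientations">
##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend ID">
##INFO=<ID=PE,Number=1,Type=Integer,Description="Discordant pair support">
##INFO=<ID=SR,Number=1,Type=Integer,Description="Split read support">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at breakpoint">
##INFO=<ID=VF,Number=1,Type=Float,Description="Variant allele fraction">
##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">
"""


def write_sv_calls(
    pairs: list[SVBreakpointPair],
    path,
    dialect: str,
    contigs: dict[str, int] | None = None,
) -> None:
    if dialect not in SV_DIALECTS:
        raise ValueError(f"unknown SV dialect {dialect!r}")
    afk = _af_key(dialect)
    path = Path(path)
    rows = []
    for i, s in enumerate(
        sorted(pairs, key=lambda s: (chrom_sort_key(s.chrom1), s.pos1, chrom_sort_key(s.chrom2), s.pos2))
    ):
        common = [
            f"PE={s.discordant_pairs}", f"SR={s.split_reads}", f"DP={s.read_depth}",
            f"{afk}={s.allele_fraction:.6f}",
        ]
        if s.imprecise:
            common.append("IMPRECISE")
        qual = f"{s.caller_quality:.2f}" if s.caller_quality >= 0 else "."
        if dialect == "bnd" and s.svtype != "INS":
            id1, id2 = f"bnd_{i}_1", f"bnd_{i}_2"
            alt1 = _bracket_alt(s.orient1, s.orient2, s.chrom2, s.pos2, "N")
            alt2 = _bracket_alt(s.orient2, s.orient1, s.chrom1, s.pos1, "N")
            info1 = ";".join(["SVTYPE=BND", f"MATEID={id2}"] + common)
            info2 = ";".join(["SVTYPE=BND", f"MATEID={id1}"] + common)
            rows.append((s.chrom1, s.pos1, f"{s.chrom1}\t{s.pos1}\t{id1}\tN\t{alt1}\t{qual}\tPASS\t{info1}\n"))
            rows.append((s.chrom2, s.pos2, f"{s.chrom2}\t{s.pos2}\t{id2}\tN\t{alt2}\t{qual}\tPASS\t{info2}\n"))
        else:
            svlen = s.length
            if dialect == "symbolic_signed" and s.svtype == "DEL" and svlen > 0:
                svlen = -svlen
            if s.svtype == "TRA":
                # POS2 instead of END: END < POS trips VCF sanity checks
                info = [f"SVTYPE={s.svtype}", f"CHR2={s.chrom2}", f"POS2={s.pos2}",
                        f"STRANDS={s.orient1}{s.orient2}"]
            else:
                info = [f"SVTYPE={s.svtype}", f"END={s.pos2}",
                        f"STRANDS={s.orient1}{s.orient2}"]
            if s.length >= 0:
                info.append(f"SVLEN={svlen}")
            info += common
            rows.append((s.chrom1, s.pos1, f"{s.chrom1}\t{s.pos1}\tsv_{i}\tN\t<{s.svtype}>\t{qual}\tPASS\t{';'.join(info)}\n"))
    rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1]))
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(contigs))
        fh.write(_SV_INFO_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, _, row in rows:
            fh.write(row)


# ---------------------------------------------------------------------------
# BED and segment tables


def read_bed(path) -> list[GenomicInterval]:
    """BED3+ with optional name (col 4) and score (col 5) columns."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            label = cols[3] if len(cols) > 3 else ""
            value = float(cols[4]) if len(cols) > 4 and cols[4] not in (".", "") else 0.0
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), label, value))
    return out


def write_bed(intervals: list[GenomicInterval], path, scores: bool = False) -> None:
    with Path(path).open("w") as fh:
        for iv in sorted(intervals, key=lambda iv: (chrom_sort_key(iv.chrom), iv.start, iv.end)):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label or scores:
                cols.append(iv.label or ".")
            if scores:
                cols.append(f"{iv.value:.6g}")
            fh.write("\t".join(cols) + "\n")


def read_cn_callset(path) -> CNCallset:
    sample = purity = ploidy = None
    segments = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                if key == "sample":
                    sample = val
                elif key == "purity":
                    purity = float(val)
                elif key == "ploidy":
                    ploidy = float(val)
                continue
            if line.startswith("#") or not line:
                continue
            cols = line.split("\t")
            segments.append(
                CNSegment(
                    chrom=cols[1], start=int(cols[2]), end=int(cols[3]),
                    total_cn=float(cols[4]), major_cn=float(cols[5]), minor_cn=float(cols[6]),
                )
            )
            if sample is None:
                sample = cols[0]
    if sample is None or purity is None or ploidy is None:
        raise ValueError(f"{path}: missing ##sample/##purity/##ploidy header")
    return CNCallset(sample=sample, purity=purity, ploidy=ploidy, segments=segments)


def write_cn_callset(cs: CNCallset, path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"##sample={cs.sample}\n##purity={cs.purity:.6f}\n##ploidy={cs.ploidy:.6f}\n")
        fh.write("#sample\tchrom\tstart\tend\tcopyNumber\tmajorAlleleCopyNumber\tminorAlleleCopyNumber\n")
        for s in sorted(cs.segments, key=lambda s: (chrom_sort_key(s.chrom), s.start)):
            fh.write(
                f"{cs.sample}\t{s.chrom}\t{s.start}\t{s.end}\t"
                f"{s.total_cn:.6f}\t{s.major_cn:.6f}\t{s.minor_cn:.6f}\n"
            )
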