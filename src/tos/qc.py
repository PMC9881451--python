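"""Cross-omic cohort validation: sex inference and purity concordance.

Sex is called independently from three modalities — genome coverage of
the sex chromosomes (normalized by the autosomal mean), summed
variance-stabilized expression of chrX/chrY genes, and log2 median
methylation-array intensity on the sex chromosomes — and reconciled by
majority vote against the clinical annotation.  A male tumor that has
somatically lost chromosome Y shows intermediate Y coverage between the
male and female clouds while the other modalities still read male; the
reconciliation flags that configuration rather than calling a
discordance.

Purity estimates from pathology review, genomic fits, and
immune-deconvolution of expression are compared pairwise with Pearson
tests under Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SexEvidence",
    "SexCall",
    "CorrelationResult",
    "pearson_correlation",
    "sex_from_methylation",
    "sex_from_coverage",
    "expression_sex_threshold",
    "reconcile_sex",
    "reconcile_cohort",
    "purity_concordance",
]

#: log2 intensity difference (Y - X) below which the methylation
#: predictor calls female
METH_SEX_CUTOFF = -2.0
#: normalized Y coverage at or above which the genome predictor calls
#: male; below COVERAGE_Y_FEMALE_MAX it calls female; in between the
#: call is ambiguous and a somatic Y loss is suspected
COVERAGE_Y_MALE_MIN = 0.25
COVERAGE_Y_FEMALE_MAX = 0.10


@dataclass
class SexEvidence:
    """Per-sample inputs to sex reconciliation; any modality may be NaN."""

    sample: str
    clinical_sex: str = "unknown"  # {M, F, unknown}
    x_coverage: float = math.nan
    y_coverage: float = math.nan
    x_expression: float = math.nan
    y_expression: float = math.nan
    meth_x_median: float = math.nan
    meth_y_median: float = math.nan


@dataclass
class SexCall:
    sample: str
    coverage_call: str = "ambiguous"
    expression_call: str = "ambiguous"
    methylation_call: str = "ambiguous"
    consensus: str = "ambiguous"
    discordance_flag: bool | None = None  # None when clinical sex unknown
    y_loss_suspected: bool = False


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on length mismatch, n < 3 or a
    zero-variance vector rather than returning NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def sex_from_methylation(
    meth_x_median: float, meth_y_median: float, cutoff: float = METH_SEX_CUTOFF
) -> str:
    """F iff (Y - X) median log2 intensity falls strictly below the
    cutoff; a difference exactly at the cutoff reads male."""
    if math.isnan(meth_x_median) or math.isnan(meth_y_median):
        return "ambiguous"
    return "F" if (meth_y_median - meth_x_median) < cutoff else "M"


def sex_from_coverage(
    x_coverage: float,
    y_coverage: float,
    male_min: float = COVERAGE_Y_MALE_MIN,
    female_max: float = COVERAGE_Y_FEMALE_MAX,
) -> str:
    """Call from autosome-normalized Y coverage: an XY genome sits near
    0.5, an XX genome near 0; the intermediate band is left ambiguous as
    a somatic Y-loss candidate."""
    if math.isnan(x_coverage) or math.isnan(y_coverage):
        return "ambiguous"
    if y_coverage >= male_min:
        return "M"
    if y_coverage < female_max:
        return "F"
    return "ambiguous"


def expression_sex_threshold(y_expression: Sequence[float], seed: int = 0) -> float:
    """Cohort-level decision boundary on summed chrY expression: a
    two-means split (initialized at the observed min/max, iterated to
    convergence) and the midpoint of the two class means.

    Returns NaN when the cohort carries no usable spread (single sex or
    near-constant values), in which case expression calls are ambiguous.
    """
    vals = np.asarray([v for v in y_expression if not math.isnan(v)], dtype=float)
    if vals.size < 2 or np.ptp(vals) < 1e-9:
        return math.nan
    lo, hi = float(vals.min()), float(vals.max())
    for _ in range(100):
        mid = (lo + hi) / 2.0
        low, high = vals[vals <= mid], vals[vals > mid]
        if low.size == 0 or high.size == 0:
            return math.nan
        nlo, nhi = float(low.mean()), float(high.mean())
        if nlo == lo and nhi == hi:
            break
        lo, hi = nlo, nhi
    # a genuine two-cluster structure separates by well more than the
    # within-cluster spread (a unimodal cloud split at its mean only
    # reaches ~1.6 sd of separation); otherwise refuse to call
    if (hi - lo) < 4.0 * max(low.std(), high.std(), 1e-9):
        return math.nan
    return (lo + hi) / 2.0


def _expression_call(y_expression: float, threshold: float) -> str:
    if math.isnan(y_expression) or math.isnan(threshold):
        return "ambiguous"
    return "M" if y_expression > threshold else "F"


def reconcile_sex(evidence: SexEvidence, expression_threshold: float = math.nan) -> SexCall:
    """Combine the modality calls for one sample into a consensus.

    Consensus is the majority of non-ambiguous modality calls;
    ``discordance_flag`` compares it with the clinical annotation when
    known.  Y loss is suspected when coverage is ambiguous (intermediate
    Y) while the consensus of the remaining evidence reads male.
    """
    cov = sex_from_coverage(evidence.x_coverage, evidence.y_coverage)
    expr = _expression_call(evidence.y_expression, expression_threshold)
    meth = sex_from_methylation(evidence.meth_x_median, evidence.meth_y_median)
    votes = [c for c in (cov, expr, meth) if c != "ambiguous"]
    if not votes:
        consensus = "ambiguous"
    else:
        m = votes.count("M")
        f = votes.count("F")
        consensus = "M" if m > f else ("F" if f > m else "ambiguous")
    known = evidence.clinical_sex in ("M", "F")
    flag = (consensus != evidence.clinical_sex) if known and consensus != "ambiguous" else (None if not known else True)
    y_loss = cov == "ambiguous" and (consensus == "M" or (not votes and evidence.clinical_sex == "M"))
    return SexCall(
        sample=evidence.sample,
        coverage_call=cov,
        expression_call=expr,
        methylation_call=meth,
        consensus=consensus,
        discordance_flag=flag,
        y_loss_suspected=y_loss,
    )


def reconcile_cohort(evidence: Sequence[SexEvidence], seed: int = 0) -> list[SexCall]:
    """Reconcile a whole cohort; the expression threshold is fitted on
    the cohort's chrY expression sums before per-sample calls."""
    thr = expression_sex_threshold([e.y_expression for e in evidence], seed=seed)
    return [reconcile_sex(e, thr) for e in evidence]


@dataclass
class CorrelationResult:
    pair: str
    r: float
    p: float
    q: float
    n: int


def purity_concordance(
    pathologic: Sequence[float],
    genomic: Sequence[float],
    transcriptomic: Sequence[float],
) -> list[CorrelationResult]:
    """Pairwise Pearson tests between the three purity estimates with
    Benjamini-Hochberg adjustment over the three tests.  Samples missing
    an estimate (NaN — e.g. no somatic copy-number segments, so no
    genomic fit) are excluded pairwise."""
    df = pd.DataFrame(
        {"pathologic": pathologic, "genomic": genomic, "transcriptomic": transcriptomic},
        dtype=float,
    )
    pairs = [
        ("pathologic", "genomic"),
        ("pathologic", "transcriptomic"),
        ("genomic", "transcriptomic"),
    ]
    rs, ps, ns = [], [], []
    for a, b in pairs:
        sub = df[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete pairs for {a} vs {b}")
        res = stats.pearsonr(sub[a], sub[b])
        rs.append(float(res.statistic))
        ps.append(float(res.pvalue))
        ns.append(len(sub))
    qs = multipletests(ps, method="fdr_bh")[1]
    return [
        CorrelationResult(pair=f"{a}_vs_{b}", r=r, p=p, q=float(q), n=n)
        for (a, b), r, p, q, n in zip(pairs, rs, ps, qs, ns)
    ]
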