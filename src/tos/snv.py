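"""Small-variant (SNV/indel) germline-vs-somatic classification pipeline.

Tumor-only call sets mix somatic mutations with the patient's germline
variants.  With matched tumor/normal pairs available for a training
subset, each tumor-only call is labeled somatic when it exactly matches
a matched-mode somatic call and germline otherwise, a 20-dimensional
feature vector is extracted per variant, and random forests are trained
after 1:1 class balancing on a stratified 75/25 split.  Two models are
fitted: one on SNVs with all 20 features, and one including indels with
the SNV-indicator feature removed (19 features).

The features fall in three blocks:

* database — presence/AF in a population variant database, presence/
  count in a cancer mutation catalogue;
* location/impact/signature — gene-feature region class, a coarse
  impact ordinal, the 96-channel pyrimidine-strand trinucleotide
  substitution index, repeat and conserved-element flags, homopolymer
  run length;
* caller — allele fraction, depths, base/mapping quality medians,
  strand balance, caller confidence, filter/multi-allelic flags, and
  the SNV indicator.

Allele fraction is expected to dominate the importances: germline
variants sit at diploid fractions (~0.5 or ~1.0) while somatic
fractions scale with tumor purity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SmallVariant
from .forest import (
    LABEL_COLUMN,
    SNV_OPTIMUM,
    RFHyperparams,
    SomaticClassifier,
    SomaticClassifierResults,
    SplitConfig,
    balance_one_to_one,
    split_train_test,
)
from .resources import REGION_ORDINAL, ResourceSet

__all__ = [
    "SNV_FEATURES",
    "INDEL_FEATURES",
    "trinucleotide_index",
    "label_against_ground_truth",
    "extract_snv_features",
    "build_feature_table",
    "SmallVariantModels",
    "fit_small_variant_models",
    "classify_cohort",
]

SNV_FEATURES = [
    # database block
    "popdb_present", "popdb_af", "cancerdb_present", "cancerdb_count",
    # location / impact / signature block
    "region_class", "impact_class", "trinucleotide_context",
    "repeat_flag", "conserved_flag", "homopolymer_run",
    # caller block
    "allele_fraction", "total_depth", "alt_count", "median_base_quality",
    "median_mapping_quality", "strand_balance", "caller_confidence",
    "filter_pass", "multiallelic", "is_snv",
]
INDEL_FEATURES = [f for f in SNV_FEATURES if f != "is_snv"]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_SUB_INDEX = {s: i for i, s in enumerate(_SUBSTITUTIONS)}

_IMPACT = {"CDS": 2, "UTR": 1, "intron": 1, "intergenic": 0}


def trinucleotide_index(context: str, ref: str, alt: str) -> int:
    """96-channel substitution index on the pyrimidine strand.

    ``context`` is the reference trinucleotide centred on the variant.
    Purine references are reverse-complemented first.  The index is
    ``sub*16 + left*4 + right`` with substitutions ordered C>A, C>G,
    C>T, T>A, T>C, T>G and flanking bases ordered A, C, G, T.  Returns
    the sentinel ``-1`` for indels or unusable context.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return -1
    if context is None or len(context) != 3 or context[1] != ref:
        return -1
    if any(b not in _BASES for b in context) or alt not in _BASES:
        return -1
    if ref in "AG":
        context = context.translate(_COMPLEMENT)[::-1]
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    sub = _SUB_INDEX.get(f"{ref}>{alt}")
    if sub is None:
        return -1
    return sub * 16 + _BASES.index(context[0]) * 4 + _BASES.index(context[2])


def label_against_ground_truth(
    tumor_only_calls: list[SmallVariant],
    matched_somatic_calls: list[SmallVariant],
) -> tuple[list[SmallVariant], list[SmallVariant]]:
    """Label tumor-only calls against the matched-mode somatic set.

    A tumor-only record is somatic iff its exact (chrom, pos, ref, alt)
    key appears among the matched somatic calls, germline otherwise
    (labels set in place).  Matched somatic calls absent from the
    tumor-only set are returned as recall misses.
    """
    truth = {v.key for v in matched_somatic_calls}
    seen = set()
    for v in tumor_only_calls:
        v.truth_label = "somatic" if v.key in truth else "germline"
        seen.add(v.key)
    misses = [v for v in matched_somatic_calls if v.key not in seen]
    return tumor_only_calls, misses


def extract_snv_features(
    v: SmallVariant, resources: ResourceSet, context_provider=None
) -> dict[str, float]:
    """One 20-feature row for a small variant.

    Database features come from exact-key lookups, region features from
    interval queries at the (0-based) position, and the signature
    feature from the pyrimidine-strand trinucleotide index.  Missing
    annotations keep the sentinel ``-1`` (tree models split around it).
    """
    key = v.key
    af = resources.popdb_af(key)
    cnt = resources.cancerdb_count(key)
    pos0 = v.pos - 1
    region = resources.region_class(v.chrom, pos0)
    context = context_provider(v) if context_provider is not None else v.context
    return {
        "popdb_present": 1.0 if af is not None else 0.0,
        "popdb_af": af if af is not None else -1.0,
        "cancerdb_present": 1.0 if cnt > 0 else 0.0,
        "cancerdb_count": float(cnt),
        "region_class": float(REGION_ORDINAL[region]),
        "impact_class": float(_IMPACT[region]),
        "trinucleotide_context": float(trinucleotide_index(context, v.ref, v.alt)),
        "repeat_flag": 1.0 if resources.repeats.covers(v.chrom, pos0) else 0.0,
        "conserved_flag": 1.0 if resources.conserved.covers(v.chrom, pos0) else 0.0,
        "homopolymer_run": float(v.homopolymer_run),
        "allele_fraction": float(v.allele_fraction),
        "total_depth": float(v.total_depth),
        "alt_count": float(v.alt_count),
        "median_base_quality": float(v.median_base_quality),
        "median_mapping_quality": float(v.median_mapping_quality),
        "strand_balance": float(v.strand_balance),
        "caller_confidence": float(v.caller_confidence),
        "filter_pass": 1.0 if v.filter_pass else 0.0,
        "multiallelic": 1.0 if v.multiallelic else 0.0,
        "is_snv": 1.0 if v.is_snv else 0.0,
    }


def build_feature_table(
    variants: list[SmallVariant],
    resources: ResourceSet,
    context_provider=None,
    with_labels: bool = True,
) -> pd.DataFrame:
    rows = [extract_snv_features(v, resources, context_provider) for v in variants]
    df = pd.DataFrame(rows, columns=SNV_FEATURES)
    if with_labels:
        df[LABEL_COLUMN] = [v.truth_label for v in variants]
    return df


@dataclass
class SmallVariantModels:
    """The fitted SNV and indel results with their held-out reports."""

    snv: SomaticClassifierResults
    indel: SomaticClassifierResults
    snv_report: "pd.Series"
    indel_report: "pd.Series"

    def summary(self) -> str:
        return (
            self.snv.summary() + "\n\n[SNV held-out] "
            + self.snv_report.to_string()
            + "\n\n" + self.indel.summary()
            + "\n\n[indel held-out] " + self.indel_report.to_string()
        )


def fit_small_variant_models(
    labeled_table: pd.DataFrame,
    hp: RFHyperparams = SNV_OPTIMUM,
    split: SplitConfig = SplitConfig(),
    seed: int = 0,
) -> SmallVariantModels:
    """Train the SNV model (SNV rows, 20 features) and the indel model
    (all rows, SNV-indicator removed) with 1:1 balancing and a
    stratified split; held-out evaluation on each model's own quarter."""
    snv_rows = labeled_table[labeled_table["is_snv"] == 1.0]
    results = {}
    reports = {}
    for name, rows, feats in (
        ("snv", snv_rows, SNV_FEATURES),
        ("indel", labeled_table, INDEL_FEATURES),
    ):
        balanced = balance_one_to_one(rows[feats + [LABEL_COLUMN]], seed=seed)
        train, test = split_train_test(balanced, split)
        res = SomaticClassifier(train, feature_names=feats).fit(
            RFHyperparams(hp.features_per_split, hp.num_trees, hp.min_node_size, seed=seed)
        )
        results[name] = res
        reports[name] = res.evaluate(test).as_series()
    return SmallVariantModels(
        snv=results["snv"], indel=results["indel"],
        snv_report=reports["snv"], indel_report=reports["indel"],
    )


def classify_cohort(
    models: SmallVariantModels,
    samples: dict[str, list[SmallVariant]],
    resources: ResourceSet,
    threshold: float = 0.5,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Classify every variant of every sample: SNVs with the SNV model,
    indels with the indel model.  Returns per-sample tables (variant key,
    probability, class) and a per-sample summary of somatic/germline
    counts; record counts are conserved."""
    per_sample: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for sample, variants in samples.items():
        if not variants:
            per_sample[sample] = pd.DataFrame(
                columns=["chrom", "pos", "ref", "alt", "somatic_prob", "rf_class"]
            )
            summary_rows.append({"sample": sample, "n": 0, "n_somatic": 0, "n_germline": 0})
            continue
        table = build_feature_table(variants, resources, with_labels=False)
        is_snv = table["is_snv"].to_numpy() == 1.0
        probs = np.empty(len(table))
        if is_snv.any():
            probs[is_snv] = models.snv.predict_proba(table.loc[is_snv])
        if (~is_snv).any():
            probs[~is_snv] = models.indel.predict_proba(table.loc[~is_snv, INDEL_FEATURES])
        classes = np.where(probs >= threshold, "somatic", "germline")
        df = pd.DataFrame(
            {
                "chrom": [v.chrom for v in variants],
                "pos": [v.pos for v in variants],
                "ref": [v.ref for v in variants],
                "alt": [v.alt for v in variants],
                "somatic_prob": probs,
                "rf_class": classes,
            }
        )
        per_sample[sample] = df
        summary_rows.append(
            {
                "sample": sample,
                "n": len(df),
                "n_somatic": int((classes == "somatic").sum()),
                "n_germline": int((classes == "germline").sum()),
            }
        )
    return per_sample, pd.DataFrame(summary_rows)
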