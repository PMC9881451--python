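# Methods

This note records the models, conventions and numerical choices behind
`tos`, in the spirit of a package methods appendix: what is assumed,
what is configurable, and what a green test does and does not establish.

## Problem setting

Tumor-only whole-genome variant calling cannot subtract the patient's
constitutional genome. The contaminant class (germline) outnumbers the
signal (somatic) by roughly an order of magnitude in small-variant call
sets, and germline structural variants and copy-number artifacts
likewise survive into tumor-only output. `tos` treats germline removal
as supervised classification, trained on the subset of a cohort for
which matched normals exist, and post-processes copy-number output with
deterministic rules.

## Small-variant classification

**Labeling.** A tumor-only call is labeled somatic iff its exact
(chrom, pos, ref, alt) key occurs in the matched-mode somatic call set
of the same sample, germline otherwise. Matching is literal: no indel
left-alignment or realignment is attempted, mirroring how annotation
tools transfer database tags. Matched somatic calls absent from the
tumor-only set are reported separately as recall misses.

**Features (20).** Three blocks:

* *database* (4): presence and allele frequency in a population variant
  database; presence and occurrence count in a cancer mutation
  catalogue. Exact-key lookups; an absent variant yields
  (present = 0, value sentinel).
* *location / impact / signature* (6): gene-region class as an ordinal
  (CDS 3 / UTR 2 / intron 1 / intergenic 0); a coarse impact ordinal
  derived from the same overlap (CDS 2 / transcribed 1 / intergenic 0 —
  a deliberate simplification, no external effect predictor is
  consulted); the 96-channel pyrimidine-strand trinucleotide
  substitution index (sentinel −1 for indels); repeat and
  conserved-element flags; homopolymer run length.
* *caller* (10): allele fraction, total depth, alt count, median base
  and mapping quality, strand balance, caller confidence, filter-pass
  and multi-allelic flags, and an SNV indicator.

The indel model removes the SNV indicator (19 features) and trains on
all variants; the SNV model trains on SNVs only. Missing annotations
keep the sentinel −1 rather than being imputed — decision trees split
around it, and a second imputation model would add opacity for no
measured benefit.

**Training protocol.** Classes are balanced 1:1 by uniform down-sampling
of the majority class, then split 75/25 stratified by label. The forest
maps the classic hyperparameter vocabulary onto scikit-learn
(`features_per_split` → `max_features`, `num_trees` → `n_estimators`,
`min_node_size` → `min_samples_leaf`). Defaults: (8, 1000, 5) for small
variants, (4, 400, 1) for SVs. Grid search, when requested, maximizes
mean accuracy under stratified k-fold CV (default 5) over
mtry ∈ {2,4,8} × ntree ∈ {400,1000} × nodesize ∈ {1,5}, breaking exact
ties toward the cheaper model (fewer trees, then larger node size, then
smaller mtry) so results are reproducible. Somatic is the positive class
and is called at probability threshold 0.5; no threshold tuning is
performed because the evaluation metrics are reported symmetrically.

## SV consensus and classification

**Merging.** Two calls co-cluster when chromosome pairs match, both
breakpoint distances are ≤ `max_breakpoint_distance` (default 1000 bp,
the common multi-caller merging convention; configurable), and type and
orientations match (both gates can be relaxed). Events are connected
components of this relation — the implementation prunes by a sorted
sweep on the first breakpoint but is checked against a full O(n²)
transitive-closure oracle in the tests. The representative is the
highest-quality member; ties break lexicographically on caller id and
call id, making the merge invariant to caller ordering.

**Features (19).** Known-SV database block (overlap within the merge
distance at both breakpoints, maximum database allele frequency nearby,
nearest-entry distance, pan-cancer overlap), PON block (breakpoint
counts within ±200 bp of each end; window configurable and recorded in
the model manifest), region block (cancer-gene flag, gene class and
conservation at both ends), caller block (type ordinal, log1p length
with 0 for translocations, allele fraction, read depth, split reads,
discordant pairs, quality, imprecise flag). Insertions use the reported
inserted length where available, else the sentinel.

**Integration.** A caller votes somatic for an event if any of its
member calls is classified somatic. An event enters the final somatic
set iff the vote is unanimous across its supporting callers or at least
two callers vote somatic. The rule is deliberately conservative for
double-support events with a split vote (rejected); every retained event
carries its support count for downstream filtering.

## Copy-number post-processing and benchmark

Rules apply in order: (1) any segment overlapping a curated artifact
interval (telomeric/centromeric) is removed whole — overlap means any
shared bp, no trimming; (2) values in (−0.5, 0) are rounded to 0;
(3) segments with any value below −0.5 are removed as unreliable. Every
removal is logged with a reason and bp, so retained + removed always
equals the input. Genome-state fractions classify each segment by
half-up rounding of total copy number against the absolute diploid
state 2 (not against sample ploidy) and are length-weighted over the
covered genome. Gene-level values come from the overlapping segment with
the largest overlap, ties to the lower total copy number. The benchmark
reports Pearson r for six per-sample metrics and pooled gene-level
major/minor copy number; correlation on a zero-variance metric raises
rather than returning NaN.

The shipped exclusion list is a stand-in generated for the simulator's
miniature genome (1 Mb telomeric flanks plus a 1 Mb centromeric band per
chromosome); real deployments substitute their own curated BED.

## Cohort QC

Coverage-based sex uses autosome-normalized Y coverage with thresholds
0.25 (male) / 0.10 (female) and an explicit ambiguous band between —
the original assessment of such cohorts is visual, so the thresholds are
declared artifacts of this implementation, chosen to separate XY (≈ 0.5)
from XX (≈ 0) with a wide Y-loss corridor. Methylation sex is female iff
the chrY−chrX median log2 intensity difference is strictly below −2 (the
boundary value reads male). Expression sex fits a cohort-level two-means
split on summed chrY expression and refuses to call (all-ambiguous) when
the two cluster means are separated by less than four within-cluster
standard deviations, which rejects unimodal cohorts. Consensus is the
majority of non-ambiguous modality calls; ambiguous coverage with a male
consensus flags a suspected somatic Y loss instead of a discordance.
Purity concordance computes pairwise Pearson r/p over complete pairs
(samples without a genomic estimate are excluded pairwise) and adjusts
the three p-values by Benjamini–Hochberg.

## The synthetic cohort

The simulator is a stated world, not a tuning knob: its defaults encode
the signal structure the classifiers are supposed to exploit, and the
tests then measure whether the implementation recovers it.

* Genome: chr1–3 at 50 Mb, chrX 30 Mb, chrY 10 Mb — small enough that
  brute-force oracles run in seconds.
* Cohort: 20 samples, 80 % male (the disease context is heavily
  male-skewed), purity uniform on (0.2, 0.9).
* Small variants per sample: 5,000 germline (heterozygous fraction 2/3,
  allele fractions beta-distributed around 0.5 and 0.99), 500 somatic at
  clonal copy-neutral AF = purity/2; depths Poisson(60) matched /
  Poisson(30) tumor-only with binomial allele sampling; 10 % indels.
  Database membership: population database 0.95 germline / 0.01 somatic;
  cancer catalogue 0.10 somatic / 0.001 germline. Population allele
  frequencies of database entries are drawn independently of the
  carrier's genotype — membership, not frequency, carries the linkage.
* SVs per sample: 40 germline (ln-lengths N(8, 1), ≈ 3 kb) and
  25 somatic (N(11.3, 1.2), ≈ 80 kb, i.e. somatic events run longer);
  three callers re-emit each true SV with dropout 5/10/15 %, breakpoint
  jitter sd 30 bp, caller-specific quality offsets, and an 8 % imprecise
  rate. PON entries cluster around germline SV breakpoints (90 % of
  breakpoints, ≈ 3 entries each, ±100 bp) over a 2/Mb background. The
  known-SV database is deliberately weak (35 % germline coverage over an
  8/Mb background): the qualitative importance structure being emulated
  puts PON counts, allele fraction, read depth and length — not database
  membership — at the top, so somatic breakpoint depth is additionally
  diluted by purity (mean × (0.35 + purity/2)).
* Copy number: ~40 segments/sample around a per-sample ploidy center;
  tumor-only = matched + Gaussian value noise (sd 0.05), purity noise
  (sd 0.02), negative-value injections (5 % of segments, half in
  (−0.5, 0), half below −0.5, placed only outside exclusion zones so the
  rounding rule is the unique handler) and artifactual focal peaks
  inside the telomeric/centromeric zones (per-chromosome probability
  0.3). Injected negatives set minor = 0 and major = total, so a single
  rule covers all three value columns.
* QC evidence: per-sex Gaussian clouds for coverage, expression and
  methylation; one male tumor (when present) receives intermediate
  Y coverage (≈ 0.15) while its expression and methylation stay male —
  tumor RNA/DNA in such samples is admixed with non-tumor cells, which
  is also why the consensus remains male. Purity estimates are the true
  purity plus noise (sd 0.08 pathology, 0.06 transcriptomic, 0.03
  genomic; 5 % of genomic estimates missing).

A separable scenario (`SimulationParams.separable()`) makes the classes
exactly separable — disjoint allele-fraction supports (recorded AFs made
exact, purity capped at 0.7 so somatic ≤ 0.35 while germline ≥ ~0.5) and
perfectly separating databases — so held-out accuracy must hit 1.0
exactly; any shortfall is an implementation defect, not noise.

**What the simulator does not model:** read-level errors, mutational
signature spectra, subclonal structure, shared population haplotypes
across samples, caller-specific systematic biases beyond Gaussian
offsets, and sex-chromosome small variants. A green test therefore
establishes that the machinery (labeling, features, protocol,
rules) is correct and that the forests recover designed signal; it does
not certify real-cohort accuracy figures.

## Determinism

Every stochastic component draws from a single `numpy` generator seeded
from the parameter set, files are written with fixed float formatting
and deterministic ordering, and forests carry explicit seeds — identical
seeds give byte-identical cohort directories and bitwise-identical
predictions.

## Known limitations

* Exact-key variant matching misclassifies representations that differ
  by normalization; acceptable for simulator-generated data, a caveat on
  real VCFs not normalized beforehand.
* The impact feature is a region-class proxy; no transcript-aware effect
  prediction.
* The SV merge is transitive, so long chains can bridge calls farther
  apart than the pairwise distance — inherent to closure-based merging.
* `BreakpointIndex.nearest_distance` reports 10⁸ for chromosomes with no
  database entry, a scale sentinel rather than a true distance.
* The two-means expression sex caller abstains on single-sex cohorts by
  design; coverage and methylation then carry the consensus.
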