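"""Copy-number post-processing rules and the concordance benchmark."""

import math

import numpy as np
import pytest

from tos.cnv import (
    CNCallset,
    CNSegment,
    compare_callsets,
    gene_level_cn,
    genome_state_fractions,
    postprocess_tumor_only,
)
from tos.core import GenomicInterval
from tos.simulate import (
    SimulationParams,
    default_exclusion_intervals,
    simulate_cn_profiles,
)


def _callset(segs, sample="S1", purity=0.6, ploidy=2.0):
    return CNCallset(sample, purity, ploidy, segs)


EXCL = [GenomicInterval("chr1", 0, 1000)]


class TestPostprocess:
    def test_slightly_negative_rounded_to_zero(self):
        cs = _callset([CNSegment("chr1", 5000, 6000, -0.3, -0.3, 0.0)])
        res = postprocess_tumor_only(cs, EXCL)
        assert len(res.callset.segments) == 1
        assert res.callset.segments[0].total_cn == 0.0
        assert res.rounded == 1

    def test_largely_negative_removed(self):
        cs = _callset([CNSegment("chr1", 5000, 6000, -0.7, -0.7, 0.0)])
        res = postprocess_tumor_only(cs, EXCL)
        assert res.callset.segments == []
        assert list(res.removal_log["reason"]) == ["largely_negative"]

    def test_clean_diploid_segment_untouched(self):
        seg = CNSegment("chr1", 5000, 6000, 2.0, 1.0, 1.0)
        res = postprocess_tumor_only(_callset([seg]), EXCL)
        assert res.callset.segments == [seg]
        assert res.excluded_fraction == 0.0

    def test_exclusion_overlap_removes_whole_segment(self):
        # 1 bp of overlap suffices; no trimming
        cs = _callset([CNSegment("chr1", 999, 5000, 2.0, 1.0, 1.0)])
        res = postprocess_tumor_only(cs, EXCL)
        assert res.callset.segments == []
        assert list(res.removal_log["reason"]) == ["artifact_region"]

    def test_bp_conservation_and_no_negatives(self, rng):
        segs, pos = [], 0
        for _ in range(200):
            length = int(rng.integers(100, 5000))
            cn = float(rng.normal(2, 1.5))
            segs.append(CNSegment("chr1", pos, pos + length, cn, max(cn, 0) / 2, 0.0))
            pos += length
        cs = _callset(segs)
        res = postprocess_tumor_only(cs, EXCL)
        kept = sum(s.length for s in res.callset.segments)
        removed = res.removed_bp
        assert kept + removed == cs.total_bp()
        for s in res.callset.segments:
            assert min(s.values) >= 0.0
            assert not any(
                s.chrom == e.chrom and s.start < e.end and e.start < s.end for e in EXCL
            )

    def test_removal_monotone_in_exclusion_list(self, rng):
        segs = [
            CNSegment("chr1", i * 1000, (i + 1) * 1000, 2.0, 1.0, 1.0) for i in range(50)
        ]
        small = [GenomicInterval("chr1", 0, 3000)]
        large = small + [GenomicInterval("chr1", 10_000, 20_000)]
        kept_small = sum(
            s.length for s in postprocess_tumor_only(_callset(segs), small).callset.segments
        )
        kept_large = sum(
            s.length for s in postprocess_tumor_only(_callset(segs), large).callset.segments
        )
        assert kept_large <= kept_small


class TestStateFractions:
    def test_single_diploid_segment(self):
        cs = _callset([CNSegment("chr1", 0, 1000, 2.0, 1.0, 1.0)])
        assert genome_state_fractions(cs) == (0.0, 1.0, 0.0)

    def test_length_weighting(self):
        cs = _callset(
            [
                CNSegment("chr1", 0, 1000, 1.0, 1.0, 0.0),
                CNSegment("chr1", 1000, 2000, 3.0, 2.0, 1.0),
            ]
        )
        assert genome_state_fractions(cs) == (0.5, 0.0, 0.5)

    def test_matches_per_bp_tally(self, rng):
        """Random 50-segment profile vs a naive per-bp state count."""
        segs, pos = [], 0
        for _ in range(50):
            length = int(rng.integers(10, 200))
            cn = float(rng.uniform(0, 5))
            segs.append(CNSegment("chr1", pos, pos + length, cn, cn / 2, cn / 2))
            pos += length
        cs = _callset(segs)
        tally = {"deleted": 0, "diploid": 0, "amplified": 0}
        for s in segs:
            r = math.floor(s.total_cn + 0.5)
            state = "deleted" if r < 2 else ("diploid" if r == 2 else "amplified")
            tally[state] += s.length
        total = sum(tally.values())
        deleted, diploid, amplified = genome_state_fractions(cs)
        assert deleted == pytest.approx(tally["deleted"] / total, abs=1e-12)
        assert diploid == pytest.approx(tally["diploid"] / total, abs=1e-12)
        assert amplified == pytest.approx(tally["amplified"] / total, abs=1e-12)
        assert deleted + diploid + amplified == pytest.approx(1.0, abs=1e-12)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            genome_state_fractions(_callset([]))


class TestGeneLevel:
    SEGS = [
        CNSegment("chr1", 0, 10_000, 3.0, 2.0, 1.0),
        CNSegment("chr1", 10_000, 20_000, 1.0, 1.0, 0.0),
    ]

    def test_gene_inside_one_segment(self):
        genes = [GenomicInterval("chr1", 2000, 3000, "G1")]
        df = gene_level_cn(_callset(self.SEGS), genes)
        assert df.iloc[0]["major_cn"] == 2.0 and df.iloc[0]["minor_cn"] == 1.0

    def test_gene_takes_largest_overlap(self):
        genes = [GenomicInterval("chr1", 9_300, 10_300, "G1")]  # 70% in seg 1
        df = gene_level_cn(_callset(self.SEGS), genes)
        assert df.iloc[0]["major_cn"] == 2.0

    def test_no_overlap_gene_absent(self):
        genes = [GenomicInterval("chr2", 0, 1000, "G1")]
        assert len(gene_level_cn(_callset(self.SEGS), genes)) == 0

    def test_matches_brute_force(self, rng):
        segs, pos = [], 0
        for _ in range(80):
            length = int(rng.integers(500, 3000))
            cn = float(rng.uniform(0, 5))
            minor = float(rng.uniform(0, cn / 2))
            segs.append(CNSegment("chr1", pos, pos + length, cn, cn - minor, minor))
            pos += length
        genes = []
        for i in range(500):
            s = int(rng.integers(0, pos - 400))
            genes.append(GenomicInterval("chr1", s, s + int(rng.integers(100, 4000)), f"G{i}"))
        df = gene_level_cn(_callset(segs), genes).set_index("gene")
        for gene in genes:
            best = None
            for seg in segs:
                ov = min(gene.end, seg.end) - max(gene.start, seg.start)
                if ov <= 0:
                    continue
                cand = (-ov, seg.total_cn, seg)
                if best is None or cand[:2] < best[:2]:
                    best = cand
            if best is None:
                assert gene.label not in df.index
            else:
                assert df.loc[gene.label, "major_cn"] == best[2].major_cn
                assert df.loc[gene.label, "minor_cn"] == best[2].minor_cn


class TestCompareCallsets:
    def _cohort(self, n=8, seed=0):
        params = SimulationParams(n_samples=n, seed=seed, n_germline_small=0,
                                  n_somatic_small=0)
        profiles = simulate_cn_profiles(params)
        matched = [m for m, _, _ in profiles]
        tumor_only = [t for _, t, _ in profiles]
        return matched, tumor_only

    def _genes(self, rng, n=60):
        genes = []
        for i in range(n):
            chrom = f"chr{int(rng.integers(1, 4))}"
            s = int(rng.integers(2_000_000, 40_000_000))
            genes.append(GenomicInterval(chrom, s, s + 50_000, f"G{i}"))
        return genes

    def test_identity_limit_all_r_one(self, rng):
        """A callset compared against itself gives r = 1 for every
        sample-level metric and both gene-level metrics."""
        matched, _ = self._cohort()
        genes = self._genes(rng)
        report = compare_callsets(matched, matched, genes)
        for metric, r in report.r.items():
            assert r == pytest.approx(1.0, abs=1e-12), metric
        for df in report.sample_metrics.values():
            assert (df["tumor_only"] == df["matched"]).all()

    @staticmethod
    def _varied_toy(purities):
        # every benchmark metric must carry variance across samples
        out = []
        for i, p in enumerate(purities):
            segs = []
            for j in range(i + 2):
                cn = 1.0 + 0.5 * ((i + j) % 5)
                minor = 0.2 + 0.05 * ((i + j) % 4)
                segs.append(CNSegment("chr1", j * 1000, (j + 1) * 1000, cn, cn - minor, minor))
            out.append(CNCallset(f"S{i}", p, 2.0 + 0.1 * i, segs))
        return out

    def test_anti_ordered_purity(self):
        ups = self._varied_toy([0.1, 0.3, 0.5, 0.7, 0.9])
        downs = self._varied_toy([0.9, 0.7, 0.5, 0.3, 0.1])
        report = compare_callsets(ups, downs, [GenomicInterval("chr1", 0, 500, "G")])
        assert report.r["purity"] == pytest.approx(-1.0)

    def test_purity_noise_keeps_high_r(self, rng):
        """Additive purity noise sd 0.02 over 50 samples leaves r >= 0.98
        (noise sd is a tenth of the purity spread)."""
        matched, _ = self._cohort(n=50, seed=3)
        noisy = [
            CNCallset(m.sample, float(np.clip(m.purity + rng.normal(0, 0.02), 0.01, 1.0)),
                      m.ploidy, m.segments)
            for m in matched
        ]
        genes = self._genes(rng)
        report = compare_callsets(noisy, matched, genes)
        assert report.r["purity"] >= 0.98

    def test_symmetry_under_swap(self, rng):
        matched, tumor_only = self._cohort()
        genes = self._genes(rng)
        a = compare_callsets(tumor_only, matched, genes)
        b = compare_callsets(matched, tumor_only, genes)
        for metric in a.r:
            assert a.r[metric] == pytest.approx(b.r[metric], abs=1e-12)

    def test_unpaired_sample_errors(self):
        a = [CNCallset("S1", 0.5, 2.0, [CNSegment("chr1", 0, 1000, 2.0, 1.0, 1.0)])]
        b = [CNCallset("S2", 0.5, 2.0, [CNSegment("chr1", 0, 1000, 2.0, 1.0, 1.0)])]
        with pytest.raises(ValueError, match="S1|S2"):
            compare_callsets(a, b, [])
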