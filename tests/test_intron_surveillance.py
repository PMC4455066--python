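"""Coverage normalisation, intron filtering/ranking, meta-intron profiles,
junction quantification and the stabilization diagnostic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nexsurv.genome_model import FORWARD, Read, ReadSet, StrandedSignal
from nexsurv.intron_surveillance import (
    IntronFilter,
    boundary_span_fraction,
    filter_introns,
    intron_composite,
    intronless_gene_medians,
    normalize_coverage,
    quantify_splicing,
    rank_and_select_introns,
    select_upper_quartile,
    select_upper_quartile_count,
    stabilization_diagnostic,
)
from nexsurv import synthetic_data as sd

from conftest import build_annotation


def signal_with_gene_medians(medians, gene_len=100):
    """Intronless genes whose per-base sense coverage equals the stated
    per-gene medians."""
    genes = [(f"g{k}", FORWARD, 1000 * (k + 1), 1000 * (k + 1) + gene_len)
             for k in range(len(medians))]
    ann = build_annotation(genes=genes, chrom_len=1000 * (len(medians) + 2))
    sig = StrandedSignal.zeros(ann)
    for (gid, _, s, e), m in zip(genes, medians):
        sig.values["chrI"][FORWARD][s:e] = m
    return ann, sig


class TestNormalizeCoverage:
    @pytest.mark.parametrize("medians,factor", [
        ([50, 100, 150], 1.0),
        ([50, 50, 50], 2.0),
        ([10, 20, 30, 40], 4.0),  # median 25 by direct computation
    ])
    def test_scale_factor(self, medians, factor):
        ann, sig = signal_with_gene_medians(medians)
        out = normalize_coverage(sig, ann)
        np.testing.assert_allclose(
            out.values["chrI"][FORWARD],
            sig.values["chrI"][FORWARD] * factor)

    def test_postcondition_median_exactly_100(self):
        ann = sd.make_toy_genome(60, seed=31)
        wt, _ = sd.simulate_signals(ann, sd.EffectProfile(seed=31))
        out = normalize_coverage(wt, ann)
        assert float(intronless_gene_medians(out, ann).median()) == 100.0

    def test_idempotent(self):
        ann = sd.make_toy_genome(30, seed=32)
        wt, _ = sd.simulate_signals(ann, sd.EffectProfile(seed=32))
        once = normalize_coverage(wt, ann)
        twice = normalize_coverage(once, ann)
        np.testing.assert_allclose(twice.values["chrI"][FORWARD],
                                   once.values["chrI"][FORWARD])

    def test_errors(self):
        ann, sig = signal_with_gene_medians([0, 0, 0])
        with pytest.raises(ValueError, match="zero"):
            normalize_coverage(sig, ann)
        no_genes = build_annotation(
            genes=[("g", FORWARD, 0, 100, False)], chrom_len=1000)
        with pytest.raises(ValueError, match="intronless"):
            normalize_coverage(StrandedSignal.zeros(no_genes), no_genes)


class TestFilterIntrons:
    def _annotation_with_intron_lengths(self, lengths):
        genes, introns = [], []
        for k, ilen in enumerate(lengths):
            s = 5000 * (k + 1)
            genes.append((f"g{k}", FORWARD, s, s + ilen + 2000))
            introns.append((f"g{k}.i", f"g{k}", s + 500, s + 500 + ilen))
        ann = build_annotation(genes=genes, introns=introns,
                               chrom_len=5000 * (len(lengths) + 2))
        sig = StrandedSignal.zeros(ann)
        sig.values["chrI"][FORWARD][:] = 100.0
        return ann, sig

    def test_length_boundaries_inclusive(self):
        ann, sig = self._annotation_with_intron_lengths([19, 20, 400, 401])
        kept = filter_introns(ann, sig, IntronFilter(low_pct=0, high_pct=0))
        assert kept == ["g1.i", "g2.i"]

    def test_orf_only_excludes_non_orf_parents(self):
        ann = build_annotation(
            genes=[("orf", FORWARD, 1000, 3000), ("nc", FORWARD, 5000, 7000, False)],
            introns=[("orf.i", "orf", 1500, 1600), ("nc.i", "nc", 5500, 5600)],
            chrom_len=10_000)
        sig = StrandedSignal.zeros(ann)
        sig.values["chrI"][FORWARD][:] = 50.0
        kept = filter_introns(ann, sig, IntronFilter(low_pct=0, high_pct=0))
        assert kept == ["orf.i"]

    def test_percentile_exclusion_by_rank(self):
        """10 introns with distinct proxies, 10/10 % exclusion -> the lowest
        and highest are dropped, 8 survive."""
        ann, sig = self._annotation_with_intron_lengths([100] * 10)
        for k, g in enumerate(ann.genes):  # distinct flank proxies
            sig.values["chrI"][FORWARD][g.start:g.end] = 10.0 * (k + 1)
        kept = filter_introns(ann, sig, IntronFilter(low_pct=10, high_pct=10))
        assert len(kept) == 8
        assert "g0.i" not in kept and "g9.i" not in kept


class TestRanking:
    def test_score_arithmetic(self, single_intron_annotation):
        ann = single_intron_annotation
        wt = StrandedSignal.zeros(ann)
        mut = StrandedSignal.zeros(ann)
        i = ann.introns[0]
        wt.values["chrI"][FORWARD][:] = 100.0
        mut.values["chrI"][FORWARD][:] = 100.0
        wt.values["chrI"][FORWARD][i.start:i.end] = 10.0
        mut.values["chrI"][FORWARD][i.start:i.end] = 30.0
        rk = rank_and_select_introns([i.id], ann, wt, mut)
        assert rk.table.loc[0, "score"] == pytest.approx((30 - 10) / 100)

    def test_zero_flank_coverage_drops_intron(self, single_intron_annotation):
        ann = single_intron_annotation
        wt = StrandedSignal.zeros(ann)
        mut = StrandedSignal.zeros(ann)
        rk = rank_and_select_introns([ann.introns[0].id], ann, wt, mut)
        assert rk.dropped == [ann.introns[0].id]
        assert rk.table.empty

    def test_upper_quartile_of_3935_is_984(self):
        rng = np.random.default_rng(0)
        mask = select_upper_quartile(rng.normal(size=3935))
        assert int(mask.sum()) == 984

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(1, 10_000))
    def test_upper_quartile_count_is_ceil_n_over_4(self, n):
        assert select_upper_quartile_count(n) == math.ceil(n / 4)
        assert int(select_upper_quartile(np.arange(n)).sum()) == math.ceil(n / 4)


class TestIntronComposite:
    def test_uniform_coverage_gives_log2_everywhere(self, single_intron_annotation):
        ann = single_intron_annotation
        sig = StrandedSignal.zeros(ann)
        sig.values["chrI"][FORWARD][:] = 100.0
        prof = intron_composite([ann.introns[0].id], ann, sig)
        assert len(prof) == 42  # exon5 + 40 bins + exon3
        np.testing.assert_allclose(prof.values, np.log2(100.0))

    def test_column_geometric_mean_oracle(self):
        """Two introns with coverages 4 and 16 in a column -> geometric
        mean 8 -> log2 = 3."""
        ann = build_annotation(
            genes=[("a", FORWARD, 1000, 3000), ("b", FORWARD, 5000, 7000)],
            introns=[("a.i", "a", 1800, 1880), ("b.i", "b", 5800, 5880)],
            chrom_len=10_000)
        sig = StrandedSignal.zeros(ann)
        sig.values["chrI"][FORWARD][:] = 4.0
        sig.values["chrI"][FORWARD][4500:7500] = 16.0
        prof = intron_composite(["a.i", "b.i"], ann, sig)
        np.testing.assert_allclose(prof.values, 3.0)

    def test_retention_elevation_matches_generator(self):
        """WT intron coverage 25, mutant 75, exons 100: mutant minus WT
        intron columns = log2 3 exactly."""
        ann = sd.make_toy_genome(40, seed=33, intron_rate=1.0)
        eff = sd.EffectProfile(intron_retention_wt=0.25, intron_retention_mut=0.75,
                               noise_sd=0.0)
        wt, mut = sd.simulate_signals(ann, eff)
        ids = [i.id for i in ann.introns]
        pw = intron_composite(ids, ann, wt)
        pm = intron_composite(ids, ann, mut)
        bins = [c for c in pw.index if c.startswith("bin")]
        np.testing.assert_allclose((pm - pw)[bins].values, np.log2(3.0),
                                   atol=1e-9)
        np.testing.assert_allclose((pm - pw)[["exon5", "exon3"]].values, 0.0,
                                   atol=1e-9)

    def test_short_intron_fractional_bins_still_defined(self):
        ann = build_annotation(genes=[("g", FORWARD, 1000, 3000)],
                               introns=[("g.i", "g", 1800, 1820)],
                               chrom_len=10_000)
        sig = StrandedSignal.zeros(ann)
        sig.values["chrI"][FORWARD][:] = 64.0
        prof = intron_composite(["g.i"], ann, sig)
        np.testing.assert_allclose(prof.values, 6.0)


class TestBoundarySpan:
    def test_counting(self, single_intron_annotation):
        ann = single_intron_annotation
        i = ann.introns[0]  # [1800, 1900)
        reads = ReadSet(reads=[
            Read("chrI", FORWARD, ((1780, 1830),)),  # crosses 5' boundary
            Read("chrI", FORWARD, ((1870, 1920),)),  # crosses 3' boundary
            Read("chrI", FORWARD, ((1795, 1845),)),  # crosses 5' boundary
            Read("chrI", FORWARD, ((1830, 1870),)),  # fully inside intron
            Read("chrI", FORWARD, ((1800, 1900), (2500, 2550))),  # gapped, not this intron
            Read("chrI", FORWARD, ((1700, 1800), (1900, 1950))),  # spliced: excluded
        ])
        frac = boundary_span_fraction(reads, [i], ann)
        assert frac == pytest.approx(3 / 4)

    def test_no_informative_reads_is_missing(self, single_intron_annotation):
        ann = single_intron_annotation
        reads = ReadSet(reads=[Read("chrI", FORWARD, ((100, 150),))])
        assert math.isnan(boundary_span_fraction(reads, ann.introns, ann))

    def test_simulated_reads_mostly_span_boundaries(self):
        """With short fission-yeast-like introns and any retention > 0,
        most intron-overlapping reads cross an exon-intron boundary."""
        ann = sd.make_toy_genome(60, seed=34, intron_rate=1.0)
        reads = sd.simulate_reads(ann, sd.EffectProfile(), 6000, seed=34,
                                  retention=0.15)
        assert boundary_span_fraction(reads, ann.introns, ann) > 0.5


class TestQuantifySplicing:
    def test_count_arithmetic(self, single_intron_annotation):
        ann = single_intron_annotation
        i = ann.introns[0]
        spliced = [Read("chrI", FORWARD, ((1750, 1800), (1900, 1950),))] * 3
        unspliced = [Read("chrI", FORWARD, ((1780, 1830),))]
        c = quantify_splicing(ReadSet(reads=spliced + unspliced), i, ann)
        assert (c.spliced, c.unspliced) == (3, 1)
        assert c.us_over_s == pytest.approx(1 / 3)

    def test_normalized_ratio(self, single_intron_annotation):
        ann = single_intron_annotation
        i = ann.introns[0]
        def mk(s, us):
            return ReadSet(reads=[Read("chrI", FORWARD, ((1750, 1800), (1900, 1950)))] * s
                           + [Read("chrI", FORWARD, ((1780, 1830),))] * us)
        c = quantify_splicing(mk(2, 1), i, ann, wt_reads=mk(4, 1))
        assert c.ratio_vs_wt == pytest.approx(0.5 / 0.25)

    def test_conservation_each_read_counted_once(self):
        ann = sd.make_toy_genome(40, seed=35, intron_rate=1.0)
        reads = sd.simulate_reads(ann, sd.EffectProfile(), 3000, seed=35,
                                  retention=0.3)
        by_id = ann.genes_by_id
        for i in ann.introns[:20]:
            c = quantify_splicing(reads, i, ann)
            g = by_id[i.parent_gene]
            informative = 0
            for r in reads:
                if r.chrom != g.chrom or r.strand != g.strand:
                    continue
                if r.is_gapped:
                    gap = r.gap
                    if gap == i.span or (gap[0] < i.end and i.start < gap[1]):
                        informative += 1
                elif r.segments[0][0] < i.end and i.start < r.segments[0][1]:
                    informative += 1
            assert c.spliced + c.unspliced + c.intron_internal + c.mis_spliced \
                == informative

    def test_zero_spliced_reads_gives_missing_ratio(self, single_intron_annotation):
        ann = single_intron_annotation
        reads = ReadSet(reads=[Read("chrI", FORWARD, ((1780, 1830),))])
        c = quantify_splicing(reads, ann.introns[0], ann)
        assert c.unspliced == 1 and c.spliced == 0
        assert math.isnan(c.us_over_s)

    def test_binomial_oracle_for_retention_odds(self):
        """Simulated retention 0.2 vs WT 0.05: the WT-normalised US/S ratio
        matches the retention odds ratio within 3 binomial SEs."""
        ann = build_annotation(genes=[("g", FORWARD, 0, 2000)],
                               introns=[("g.i1", "g", 900, 1000)],
                               chrom_len=3000)
        eff = sd.EffectProfile()
        i = ann.introns[0]
        mut_reads = sd.simulate_reads(ann, eff, 10_000, seed=36, retention=0.2)
        wt_reads = sd.simulate_reads(ann, eff, 10_000, seed=37, retention=0.05)
        c = quantify_splicing(mut_reads, i, ann, wt_reads=wt_reads)
        expected = (0.2 / 0.8) / (0.05 / 0.95)
        # delta-method SE of log odds-ratio from the four junction counts
        cw = quantify_splicing(wt_reads, i, ann)
        se_log = math.sqrt(1 / c.spliced + 1 / c.unspliced
                           + 1 / cw.spliced + 1 / cw.unspliced)
        assert abs(math.log(c.ratio_vs_wt) - math.log(expected)) < 3 * se_log


class TestStabilizationDiagnostic:
    def _scaled_signals(self, intron_scale, exon_scale, intronless_scale):
        ann = sd.make_toy_genome(40, seed=38, intron_rate=0.5)
        eff = sd.EffectProfile(noise_sd=0.0, intron_retention_wt=0.2,
                               intron_retention_mut=0.2)
        wt, _ = sd.simulate_signals(ann, eff)
        mut = wt.copy()
        with_introns = {i.parent_gene for i in ann.introns}
        by_id = ann.genes_by_id
        for g in ann.genes:
            arr = mut.values[g.chrom][g.strand]
            if g.id in with_introns:
                arr[g.start:g.end] *= exon_scale
                for i in ann.introns_of(g.id):
                    arr[i.start:i.end] *= intron_scale / exon_scale
            else:
                arr[g.start:g.end] *= intronless_scale
        ids = [i.id for i in ann.introns]
        return ann, wt, mut, ids

    @pytest.mark.parametrize("scales,verdict", [
        ((3.0, 2.9, 1.0), "stabilization"),
        ((3.0, 1.0, 1.0), "splicing defect"),
        ((1.0, 1.0, 1.0), "no change"),
    ])
    def test_verdict_rule(self, scales, verdict):
        ann, wt, mut, ids = self._scaled_signals(*scales)
        rep = stabilization_diagnostic(wt, mut, ids, ann, tau_log2=0.5)
        assert rep.verdict == verdict
        assert rep.intron_fold == pytest.approx(scales[0], rel=1e-9)
        assert rep.exon_fold == pytest.approx(scales[1], rel=1e-9)
        assert rep.intronless_fold == pytest.approx(scales[2], rel=1e-9)

    def test_empty_intron_list_rejected(self, single_intron_annotation):
        ann = single_intron_annotation
        sig = StrandedSignal.zeros(ann)
        with pytest.raises(ValueError):
            stabilization_diagnostic(sig, sig, [], ann)
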