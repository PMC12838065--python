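"""Downstream filtering: merging, knockout subtraction, CI, gene scores."""

import numpy as np
import pytest

from tsscan import (Gene, TsRegion, ValidationError, confidence_indicator,
                    confidence_pipeline, derive_introns, gene_scores,
                    intersect_features, merge_within, subtract_overlapping)
from tsscan.annot import GeneInterval, Repeat


def region(contig, start, end, ts_type="AG", **kw):
    return TsRegion(contig=contig, span=(start, end), ts_type=ts_type, **kw)


def quant(contig, start, end, ts_type="AG", rtf=0.2, sites=6, error=None):
    if error:
        return TsRegion(contig=contig, span=(start, end), ts_type=ts_type,
                        error=error)
    return TsRegion(contig=contig, span=(start, end), ts_type=ts_type,
                    rtf_exact=rtf, p_exact=1e-6, ts_site_count=sites,
                    ts_pos=tuple(range(start, start + sites)))


# ---------------------------------------------------------------- merge ----

def merge_oracle(spans, max_gap):
    """Fixpoint pairwise merging: the transitive closure of 'within gap'."""
    spans = [list(s) for s in spans]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                a, b = spans[i], spans[j]
                gap = max(a[0], b[0]) - min(a[1], b[1])
                if gap <= max_gap:
                    spans[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    del spans[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(s) for s in spans)


class TestMergeWithin:
    def test_gap_80_merges(self):
        merged = merge_within([region("c", 100, 200), region("c", 280, 350)])
        assert [r.span for r in merged] == [(100, 350)]
        assert merged[0].rtf_exact is None  # statistics invalidated

    def test_gap_150_or_cross_type_unmerged(self):
        merged = merge_within([region("c", 100, 200), region("c", 350, 400)])
        assert [r.span for r in merged] == [(100, 200), (350, 400)]
        merged = merge_within([region("c", 100, 200),
                               region("c", 210, 300, "TC")])
        assert len(merged) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        regions = [region("c", int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 2000, 40),
                                   rng.integers(1, 300, 40))]
        once = merge_within(regions)
        twice = merge_within(once)
        assert [r.span for r in once] == [r.span for r in twice]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        regions = [region("c", int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 1500, n),
                                   rng.integers(1, 250, n))]
        gap = int(rng.integers(0, 200))
        merged = sorted(r.span for r in merge_within(regions, max_gap=gap))
        assert merged == merge_oracle([r.span for r in regions], gap)


# ------------------------------------------------------------- subtract ----

def overlap_fraction_oracle(wt_span, ko_spans):
    length = wt_span[1] - wt_span[0]
    covered = np.zeros(length, dtype=bool)
    for s, e in ko_spans:
        s, e = max(s, wt_span[0]), min(e, wt_span[1])
        if e > s:
            covered[s - wt_span[0]:e - wt_span[0]] = True
    return covered.sum() / length


class TestSubtractOverlapping:
    def test_majority_overlap_removed(self):
        wt = [region("c", 100, 300)]           # 200 nt
        ko = [region("c", 150, 270)]           # 120 nt overlap
        assert subtract_overlapping(wt, ko) == []

    def test_no_overlap_retained(self):
        wt = [region("c", 100, 300)]
        assert subtract_overlapping(wt, [region("c", 500, 600)]) == wt

    def test_exact_half_overlap_removed(self):
        wt = [region("c", 0, 200)]
        assert subtract_overlapping(wt, [region("c", 100, 300)]) == []

    def test_cross_type_overlap_ignored(self):
        wt = [region("c", 0, 200, "AG")]
        ko = [region("c", 0, 200, "TC")]
        assert subtract_overlapping(wt, ko) == wt

    def test_clip_variant_cuts_pieces(self):
        wt = [region("c", 0, 200)]
        pieces = subtract_overlapping(wt, [region("c", 50, 150)], clip=True)
        assert [p.span for p in pieces] == [(0, 50), (150, 200)]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_base_fraction_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        wt = [region("c", int(s), int(s) + int(l))
              for s, l in zip(rng.integers(0, 1000, 15),
                              rng.integers(10, 200, 15))]
        ko = [region("c", int(s), int(s) + int(l))
              for s, l in zip(rng.integers(0, 1000, 15),
                              rng.integers(10, 200, 15))]
        frac = float(rng.uniform(0.2, 0.8))
        kept = subtract_overlapping(wt, ko, min_fraction=frac)
        expected = [r for r in wt if overlap_fraction_oracle(
            r.span, [k.span for k in ko]) < frac]
        assert [r.span for r in kept] == [r.span for r in expected]

    def test_monotone_in_min_fraction(self):
        rng = np.random.default_rng(5)
        wt = [region("c", int(s), int(s) + 100)
              for s in rng.integers(0, 1000, 20)]
        ko = [region("c", int(s), int(s) + 100)
              for s in rng.integers(0, 1000, 20)]
        sizes = [len(subtract_overlapping(wt, ko, min_fraction=f))
                 for f in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert sizes == sorted(sizes)  # raising threshold removes fewer


# ----------------------------------------------------- confidence filter ----

class TestConfidencePipeline:
    def test_full_knockout_gives_ci_one(self):
        wt = [quant("c", 0, 100, rtf=0.20)]
        ko = [quant("c", 0, 100, rtf=0.00)]
        (d,) = confidence_pipeline(wt, ko)
        assert d.ci == 1.0

    def test_threshold_arithmetic(self):
        """(0.20 - 0.03) / 0.20 == 0.85 is retained at min_ci 0.85."""
        assert confidence_indicator(0.20, 0.03) == pytest.approx(0.85,
                                                                 abs=1e-12)
        wt = [quant("c", 0, 100, rtf=0.20)]
        ko = [quant("c", 0, 100, rtf=0.03)]
        (d,) = confidence_pipeline(wt, ko, min_ci=0.85)
        assert d.ci == pytest.approx(0.85, abs=1e-12)

    def test_low_site_count_discarded(self):
        wt = [quant("c", 0, 100, rtf=0.20, sites=4)]
        ko = [quant("c", 0, 100, rtf=0.00, sites=0)]
        assert confidence_pipeline(wt, ko) == []

    def test_not_analyzable_dropped(self):
        err = "not analyzed: no position has min. coverage"
        wt = [quant("c", 0, 100), quant("c", 200, 300, error=err),
              quant("c", 400, 500, rtf=0.0)]
        ko = [quant("c", 0, 100, error=err), quant("c", 200, 300),
              quant("c", 400, 500, rtf=0.0)]
        assert confidence_pipeline(wt, ko) == []

    def test_unpaired_lists_rejected(self):
        with pytest.raises(ValidationError):
            confidence_pipeline([quant("c", 0, 100)],
                                [quant("c", 0, 100), quant("c", 1, 2)])
        with pytest.raises(ValidationError):
            confidence_pipeline([quant("c", 0, 100)], [quant("c", 5, 100)])

    def test_ci_strictly_decreasing_in_ko_rtf(self):
        cis = [confidence_indicator(0.4, ko) for ko in (0.0, 0.1, 0.2, 0.3)]
        assert all(a > b for a, b in zip(cis, cis[1:]))


# ------------------------------------------------------------ gene scores ----

GENES = [Gene("g1", "c", 1000, 2000, "+"), Gene("g2", "c", 3000, 4000, "-")]


class TestGeneScores:
    def test_no_overlap_scores_zero(self):
        (s1, s2) = gene_scores([quant("c", 5000, 5100)], None, GENES)
        assert (s1.delta_sum_rtf, s1.n_regions) == (0.0, 0)

    def test_forced_arithmetic(self):
        """WT AG 0.40 + TC 0.20 minus KO residual 0.10 -> 0.50."""
        wt = [quant("c", 1100, 1200, "AG", rtf=0.40, sites=7),
              quant("c", 1300, 1400, "TC", rtf=0.20, sites=5)]
        ko = [quant("c", 1100, 1200, "AG", rtf=0.10, sites=2)]
        scores = {s.gene_id: s for s in gene_scores(wt, ko, GENES)}
        assert scores["g1"].delta_sum_rtf == pytest.approx(0.50, abs=1e-12)
        assert scores["g1"].delta_sum_ts_sites == 10
        assert scores["g1"].n_regions == 2

    def test_non_target_types_excluded(self):
        wt = [quant("c", 1100, 1200, "CT", rtf=0.9, sites=9)]
        scores = {s.gene_id: s for s in gene_scores(wt, None, GENES)}
        assert scores["g1"].delta_sum_rtf == 0.0

    def test_ko_omitted_when_absent(self):
        wt = [quant("c", 1100, 1200, "AG", rtf=0.40, sites=7)]
        scores = {s.gene_id: s for s in gene_scores(wt, None, GENES)}
        assert scores["g1"].delta_sum_rtf == pytest.approx(0.40)


# ---------------------------------------------------- feature assignment ----

EXONS = [GeneInterval("g1", "c", 1000, 1100, "+"),
         GeneInterval("g1", "c", 1900, 2000, "+")]


class TestIntersectFeatures:
    def test_exonic_region(self):
        (a,) = intersect_features([region("c", 1020, 1080)], GENES, EXONS)
        assert a.element_class == "exon/UTR"
        assert a.gene_ids == ("g1",)

    def test_intronic_region(self):
        (a,) = intersect_features([region("c", 1200, 1300)], GENES, EXONS)
        assert a.element_class == "intron"

    def test_exon_priority_over_intron(self):
        """Straddling an exon/intron boundary classifies as exon/UTR."""
        (a,) = intersect_features([region("c", 1050, 1300)], GENES, EXONS)
        assert a.element_class == "exon/UTR"

    def test_intergenic_iff_no_gene(self):
        (a,) = intersect_features([region("c", 9000, 9100)], GENES, EXONS)
        assert a.element_class == "intergenic"
        assert a.gene_ids == ()

    def test_repeat_hits(self):
        reps = [Repeat("B1_Mus1", "SINE/Alu", "c", 1010, 1060)]
        (a,) = intersect_features([region("c", 1020, 1080)], GENES, EXONS,
                                  reps)
        assert a.repeat_hits == (("B1_Mus1", "SINE/Alu"),)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        genes = [Gene(f"g{i}", "c", int(s), int(s) + int(l), "+")
                 for i, (s, l) in enumerate(zip(rng.integers(0, 800, 8),
                                                rng.integers(50, 300, 8)))]
        exons = [GeneInterval(g.gene_id, "c", g.start, g.start + 30, "+")
                 for g in genes]
        regions = [region("c", int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 1000, 25),
                                   rng.integers(5, 150, 25))]
        out = intersect_features(regions, genes, exons)
        for r, a in zip(regions, out):
            pos = set(range(*r.span))
            g_hit = {g.gene_id for g in genes
                     if pos & set(range(g.start, g.end))}
            e_hit = any(pos & set(range(e.start, e.end)) for e in exons)
            assert set(a.gene_ids) == g_hit
            expected = ("exon/UTR" if g_hit and e_hit
                        else "intron" if g_hit else "intergenic")
            assert a.element_class == expected


# --------------------------------------------------------------- introns ----

class TestDeriveIntrons:
    def test_two_exon_gene(self):
        gene = Gene("g", "c", 0, 1000, "+")
        exons = [GeneInterval("g", "c", 0, 100, "+"),
                 GeneInterval("g", "c", 900, 1000, "+")]
        (intron,) = derive_introns([gene], exons)
        assert (intron.start, intron.end) == (100, 900)

    def test_single_exon_gene_has_no_introns(self):
        gene = Gene("g", "c", 0, 500, "+")
        assert derive_introns([gene], [GeneInterval("g", "c", 0, 500, "+")]) == []

    def test_opposite_strand_exon_ignored(self):
        gene = Gene("g", "c", 0, 500, "+")
        introns = derive_introns([gene], [GeneInterval("g", "c", 0, 500, "-")])
        assert [(i.start, i.end) for i in introns] == [(0, 500)]

    def test_exon_outside_gene_clipped_with_warning(self):
        gene = Gene("g", "c", 100, 500, "+")
        exons = [GeneInterval("g", "c", 50, 200, "+")]
        with pytest.warns(UserWarning, match="clipping"):
            introns = derive_introns([gene], exons)
        assert [(i.start, i.end) for i in introns] == [(200, 500)]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        gene = Gene("g", "c", 0, 600, "+")
        exons = [GeneInterval("g", "c", int(s), int(s) + int(l),
                              "+" if rng.random() < 0.7 else "-")
                 for s, l in zip(rng.integers(0, 550, 6),
                                 rng.integers(10, 120, 6))]
        introns = derive_introns([gene], exons)
        is_intron = np.ones(600, dtype=bool)
        for e in exons:
            if e.strand == "+":
                is_intron[max(e.start, 0):min(e.end, 600)] = False
        expected = np.zeros(600, dtype=bool)
        for i in introns:
            expected[i.start:i.end] = True
        assert np.array_equal(is_intron, expected)
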