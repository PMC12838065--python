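"""Downstream filtering of TsRegions and gene-level editing scores.

The discovery scan is deliberately permissive (no multiple-testing
correction), so candidate regions are cleaned up afterwards:

1. merge same-type regions within 100 nt of each other;
2. re-quantify the merged regions in both wild-type (WT) and knockout (KO)
   samples (``tsscan.regio``);
3. drop WT regions that are >= 50% covered by matching KO regions;
4. keep regions with at least 5 TsSites in WT;
5. score the remaining regions with the confidence indicator
   CI = (RTF_exact(WT) - RTF_exact(KO)) / RTF_exact(WT) and keep CI >= 0.85.

Gene-level editing is then summarized as Delta(sum RTF) — the sum of
rtf_exact over all target-type (AG, TC) regions overlapping a gene in WT
minus the same sum in KO — and the analogous Delta(sum TsSiteCount).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from .annot import Gene, GeneInterval, Repeat
from .errors import ValidationError
from .scan import TARGET_TYPES, TsRegion

__all__ = [
    "DifferentialRegion", "GeneScore", "FeatureAssignment",
    "merge_within", "subtract_overlapping", "confidence_indicator",
    "confidence_pipeline", "gene_scores", "intersect_features",
    "derive_introns",
]


@dataclass(frozen=True)
class DifferentialRegion:
    """A WT/KO-paired region with its confidence indicator."""

    contig: str
    span: tuple[int, int]
    ts_type: str
    rtf_exact_wt: float
    rtf_exact_ko: float
    ts_site_count_wt: int
    ts_site_count_ko: int
    ci: float


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    delta_sum_rtf: float
    delta_sum_ts_sites: int
    n_regions: int


@dataclass(frozen=True)
class FeatureAssignment:
    contig: str
    span: tuple[int, int]
    ts_type: str
    gene_ids: tuple[str, ...]
    element_class: str  # "exon/UTR" | "intron" | "intergenic"
    repeat_hits: tuple[tuple[str, str], ...]


def merge_within(regions: Sequence[TsRegion], max_gap: int = 100) -> list[TsRegion]:
    """Merge same-contig, same-type regions separated by <= ``max_gap`` nt.

    Statistics are invalidated on purpose — the caller re-quantifies the
    merged spans (Regio mode), which is how exact values are defined for
    merged regions.
    """
    groups: dict[tuple[str, str], list[TsRegion]] = {}
    for r in regions:
        groups.setdefault((r.contig, r.ts_type), []).append(r)
    out: list[TsRegion] = []
    for (contig, ts_type), group in groups.items():
        group.sort(key=lambda r: r.span)
        cur: tuple[int, int] | None = None
        for r in group:
            s, e = r.span
            if cur is not None and s - cur[1] <= max_gap:
                cur = (cur[0], max(cur[1], e))
            else:
                if cur is not None:
                    out.append(TsRegion(contig=contig, span=cur, ts_type=ts_type))
                cur = (s, e)
        if cur is not None:
            out.append(TsRegion(contig=contig, span=cur, ts_type=ts_type))
    out.sort(key=lambda r: (r.contig, r.span, r.ts_type))
    return out


def _overlap_union(span: tuple[int, int],
                   others: Sequence[tuple[int, int]]) -> int:
    """Total number of positions of ``span`` covered by the union of ``others``."""
    clipped = sorted((max(s, span[0]), min(e, span[1])) for s, e in others)
    covered = 0
    cur_end = span[0]
    for s, e in clipped:
        if e <= cur_end:
            continue
        covered += e - max(s, cur_end)
        cur_end = e
    return covered


def subtract_overlapping(wt_regions: Sequence[TsRegion],
                         ko_regions: Sequence[TsRegion],
                         min_fraction: float = 0.5,
                         clip: bool = False) -> list[TsRegion]:
    """Remove WT regions sufficiently covered by matching KO regions.

    A WT region is dropped when same-type KO regions cover at least
    ``min_fraction`` of its length ("matching" = same TsType; cross-type
    overlap never triggers removal). Removal is whole-region by default;
    with ``clip=True`` the KO-covered parts are cut out instead and the
    uncovered pieces survive with invalidated statistics.
    """
    ko_by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in ko_regions:
        ko_by_key.setdefault((r.contig, r.ts_type), []).append(r.span)
    retained: list[TsRegion] = []
    for r in wt_regions:
        spans = [s for s in ko_by_key.get((r.contig, r.ts_type), ())
                 if s[0] < r.span[1] and s[1] > r.span[0]]
        covered = _overlap_union(r.span, spans) if spans else 0
        if covered >= min_fraction * r.length:
            if clip:
                retained.extend(_clip_region(r, spans))
            continue
        retained.append(r)
    return retained


def _clip_region(r: TsRegion, ko_spans: Sequence[tuple[int, int]]) -> list[TsRegion]:
    pieces: list[TsRegion] = []
    cur = r.span[0]
    for s, e in sorted(ko_spans):
        s, e = max(s, r.span[0]), min(e, r.span[1])
        if s > cur:
            pieces.append(TsRegion(contig=r.contig, span=(cur, s), ts_type=r.ts_type))
        cur = max(cur, e)
    if cur < r.span[1]:
        pieces.append(TsRegion(contig=r.contig, span=(cur, r.span[1]),
                               ts_type=r.ts_type))
    return pieces


def confidence_indicator(rtf_wt: float, rtf_ko: float) -> float:
    """CI = (RTF_exact(WT) - RTF_exact(KO)) / RTF_exact(WT); requires WT > 0."""
    if rtf_wt <= 0:
        raise ValueError("confidence indicator undefined for RTF_exact(WT) == 0")
    return (rtf_wt - rtf_ko) / rtf_wt


def confidence_pipeline(wt_quant: Sequence[TsRegion],
                        ko_quant: Sequence[TsRegion],
                        min_ts_sites: int = 5,
                        min_ci: float = 0.85) -> list[DifferentialRegion]:
    """TsSite-count and confidence-indicator filtering of paired quantifications.

    ``wt_quant`` and ``ko_quant`` must be Regio outputs over the identical
    region list (1:1 by identity). Regions not analyzable in either sample
    (low-coverage error, or RTF_exact(WT) == 0), or with fewer than
    ``min_ts_sites`` WT TsSites, are dropped; survivors require
    CI >= ``min_ci``.
    """
    if len(wt_quant) != len(ko_quant):
        raise ValidationError("WT and KO quantifications differ in length")
    out: list[DifferentialRegion] = []
    for wt, ko in zip(wt_quant, ko_quant):
        if wt.identity() != ko.identity():
            raise ValidationError(
                f"unpaired region lists: {wt.identity()} vs {ko.identity()}")
        if wt.error is not None or ko.error is not None:
            continue
        if wt.rtf_exact is None or wt.rtf_exact == 0:
            continue
        if wt.ts_site_count is None or wt.ts_site_count < min_ts_sites:
            continue
        ci = confidence_indicator(wt.rtf_exact, ko.rtf_exact or 0.0)
        if ci >= min_ci:
            out.append(DifferentialRegion(
                contig=wt.contig, span=wt.span, ts_type=wt.ts_type,
                rtf_exact_wt=wt.rtf_exact, rtf_exact_ko=ko.rtf_exact or 0.0,
                ts_site_count_wt=wt.ts_site_count,
                ts_site_count_ko=ko.ts_site_count or 0, ci=ci))
    return out


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def gene_scores(wt_regions: Sequence[TsRegion],
                ko_regions: Sequence[TsRegion] | None,
                genes: Sequence[Gene]) -> list[GeneScore]:
    """Per-gene editing scores over target-type (AG, TC) regions.

    For each gene, rtf_exact and TsSiteCount are summed over all target
    regions overlapping the gene by >= 1 bp (strand-agnostic, as the scan
    itself is not strand-specific) in WT; when KO data is given the same
    sums computed from the KO regions are subtracted, otherwise the
    corrective term is omitted. Genes without overlapping target regions
    score 0.
    """
    def sums(regions: Sequence[TsRegion] | None, gene: Gene):
        total_rtf, total_sites, n = 0.0, 0, 0
        if regions:
            for r in regions:
                if r.ts_type not in TARGET_TYPES or r.contig != gene.contig:
                    continue
                if not _overlaps(r.span, gene.span):
                    continue
                total_rtf += r.rtf_exact or 0.0
                total_sites += r.ts_site_count or 0
                n += 1
        return total_rtf, total_sites, n

    out: list[GeneScore] = []
    for gene in genes:
        wt_rtf, wt_sites, n_wt = sums(wt_regions, gene)
        ko_rtf, ko_sites, _ = sums(ko_regions, gene)
        out.append(GeneScore(gene_id=gene.gene_id,
                             delta_sum_rtf=wt_rtf - ko_rtf,
                             delta_sum_ts_sites=wt_sites - ko_sites,
                             n_regions=n_wt))
    return out


def _tree(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def intersect_features(regions: Sequence[TsRegion],
                       genes: Sequence[Gene],
                       exons: Sequence[GeneInterval],
                       repeats: Sequence[Repeat] = ()) -> list[FeatureAssignment]:
    """Assign each region to genes, a transcript element class, and repeats.

    ``element_class`` follows the priority exon/UTR > intron > intergenic:
    any overlap with an exon/UTR base classifies the whole region as
    exon/UTR, a gene overlap without exon overlap as intron, and no gene
    overlap as intergenic (so intergenic iff ``gene_ids`` is empty).
    """
    gene_trees = _tree(genes)
    exon_trees = _tree(exons)
    repeat_trees = _tree(repeats)
    out: list[FeatureAssignment] = []
    for r in regions:
        s, e = r.span
        hits = gene_trees.get(r.contig, IntervalTree()).overlap(s, e)
        gene_ids = tuple(sorted({h.data.gene_id for h in hits}))
        in_exon = bool(exon_trees.get(r.contig, IntervalTree()).overlap(s, e))
        if gene_ids and in_exon:
            element = "exon/UTR"
        elif gene_ids:
            element = "intron"
        else:
            element = "intergenic"
        rep_hits = tuple(sorted(
            (h.data.name, h.data.family)
            for h in repeat_trees.get(r.contig, IntervalTree()).overlap(s, e)))
        out.append(FeatureAssignment(contig=r.contig, span=r.span,
                                     ts_type=r.ts_type, gene_ids=gene_ids,
                                     element_class=element,
                                     repeat_hits=rep_hits))
    return out


def derive_introns(genes: Sequence[Gene],
                   exons: Sequence[GeneInterval]) -> list[GeneInterval]:
    """Strand-specific subtraction of exon/UTR intervals from gene spans.

    Per gene, the intron set is the gene span minus the union of its
    same-strand exons; exons extending past their gene raise a warning and
    are clipped. Genes fully covered by exons yield no introns.
    """
    exons_by_gene: dict[str, list[GeneInterval]] = {}
    for ex in exons:
        exons_by_gene.setdefault(ex.gene_id, []).append(ex)
    introns: list[GeneInterval] = []
    for gene in genes:
        spans: list[tuple[int, int]] = []
        for ex in exons_by_gene.get(gene.gene_id, ()):
            if ex.strand != gene.strand or ex.contig != gene.contig:
                continue
            s, e = ex.span
            if s < gene.start or e > gene.end:
                warnings.warn(
                    f"exon [{s}, {e}) outside gene {gene.gene_id} "
                    f"[{gene.start}, {gene.end}); clipping", stacklevel=2)
                s, e = max(s, gene.start), min(e, gene.end)
            if s < e:
                spans.append((s, e))
        cur = gene.start
        for s, e in sorted(spans):
            if s > cur:
                introns.append(GeneInterval(gene_id=gene.gene_id,
                                            contig=gene.contig, start=cur,
                                            end=s, strand=gene.strand))
            cur = max(cur, e)
        if cur < gene.end:
            introns.append(GeneInterval(gene_id=gene.gene_id, contig=gene.contig,
                                        start=cur, end=gene.end,
                                        strand=gene.strand))
    return introns
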