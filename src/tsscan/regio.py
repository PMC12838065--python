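"""Region re-quantification ("Regio" mode).

Instead of scanning de novo, quantify editing statistics over a fixed list
of regions — typically the de novo output of one sample re-measured in
another (e.g. a knockout) for differential filtering. Each region is treated
as a single window: rtf_exact, p_exact, TsSiteCount and TsPos are computed
over the full span with the Regio coverage default (min_cov 8). Regions in
which no position reaches the minimum coverage are reported with the error
marker instead of statistics.
"""

from __future__ import annotations

from typing import Sequence

from .counts import ScanParams, open_bam, pileup_count_table
from .errors import ContigError
from .scan import TsRegion, exact_region_stats

__all__ = ["regio_quantify", "LOW_COVERAGE_ERROR"]

#: verbatim per-region error marker for low-coverage regions
LOW_COVERAGE_ERROR = "not analyzed: no position has min. coverage"


def regio_quantify(bam_path: str, fasta_path: str,
                   regions: Sequence[TsRegion],
                   params: ScanParams | None = None) -> list[TsRegion]:
    """Quantify each input region against one sample.

    Input order is preserved and every input region yields exactly one
    output record, so two samples quantified over the same list pair 1:1
    by position for downstream WT/KO comparison. Only exact statistics are
    emitted (mean values are window-derived and Regio has no windows).
    """
    params = params or ScanParams.for_regio()
    with open_bam(bam_path) as bam:
        known = set(bam.references)
    out: list[TsRegion] = []
    for region in regions:
        if region.contig not in known:
            raise ContigError(
                f"region contig {region.contig!r} not in BAM header of {bam_path}")
        table = pileup_count_table(
            bam_path, fasta_path, region.contig, region.span,
            min_base_quality=params.min_base_quality,
            min_mapping_quality=params.min_mapping_quality)
        stats = exact_region_stats(table, region.span, region.ts_type, params)
        if stats is None:
            out.append(TsRegion(contig=region.contig, span=region.span,
                                ts_type=region.ts_type, error=LOW_COVERAGE_ERROR))
            continue
        rtf_exact, p_exact, ts_pos = stats
        out.append(TsRegion(
            contig=region.contig, span=region.span, ts_type=region.ts_type,
            rtf_exact=rtf_exact, p_exact=p_exact,
            ts_site_count=len(ts_pos), ts_pos=ts_pos))
    return out
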