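"""Genome-wide de novo scan driver.

Walks the selected contigs of a BAM in overlapping chunks, runs the rolling
transition scan per chunk (one pass per transition type over a shared count
table), pools the significant windows per contig while deduplicating windows
seen in two chunk overlaps, and finalizes TsRegions. Chunk overlap equals
the window size, so every window fits wholly inside at least one chunk and
chunked runs produce region sets identical to whole-contig runs.
"""

from __future__ import annotations

import numpy as np

from .counts import (CountTable, ScanParams, make_chunks, open_bam,
                     pileup_count_table, select_contigs)
from .scan import (TsRegion, WindowStat, exact_region_stats, finalize_regions,
                   merge_window_runs, scan_windows)

__all__ = ["denovo_scan", "denovo_scan_contig"]


def denovo_scan_contig(bam_path: str, fasta_path: str, contig: str,
                       contig_length: int,
                       params: ScanParams) -> dict[str, list[TsRegion]]:
    """Scan one contig and return ``{ts_type: [TsRegion, ...]}``."""
    chunks = make_chunks(contig_length, params.chunk_size, overlap=params.w_size)
    windows: dict[str, dict[int, WindowStat]] = {t: {} for t in params.ts_types}
    single_table: CountTable | None = None
    for interval in chunks:
        table = pileup_count_table(
            bam_path, fasta_path, contig, interval,
            min_base_quality=params.min_base_quality,
            min_mapping_quality=params.min_mapping_quality)
        if len(chunks) == 1:
            single_table = table
        for ts_type in params.ts_types:
            for win in scan_windows(table, ts_type, params):
                windows[ts_type].setdefault(win.window[0], win)

    results: dict[str, list[TsRegion]] = {}
    for ts_type in params.ts_types:
        pooled = sorted(windows[ts_type].values(), key=lambda w: w.window)
        if not pooled:
            results[ts_type] = []
        elif single_table is not None:
            results[ts_type] = finalize_regions(pooled, single_table, params)
        else:
            # chunked run: re-pileup each merged span for the exact statistics
            regions: list[TsRegion] = []
            for span, members in merge_window_runs(pooled):
                span_table = pileup_count_table(
                    bam_path, fasta_path, contig, span,
                    min_base_quality=params.min_base_quality,
                    min_mapping_quality=params.min_mapping_quality)
                stats = exact_region_stats(span_table, span, ts_type, params)
                if stats is None:
                    continue
                rtf_exact, p_exact, ts_pos = stats
                regions.append(TsRegion(
                    contig=contig, span=span, ts_type=ts_type,
                    rtf_mean=float(np.mean([m.rtf for m in members])),
                    p_mean=float(np.mean([m.p_value for m in members])),
                    rtf_exact=rtf_exact, p_exact=p_exact,
                    ts_site_count=len(ts_pos), ts_pos=ts_pos))
            results[ts_type] = regions
    return results


def denovo_scan(bam_path: str, fasta_path: str,
                params: ScanParams | None = None) -> dict[tuple[str, str], list[TsRegion]]:
    """Full de novo scan.

    Returns ``{(contig, ts_type_label): [TsRegion, ...]}`` for every selected
    contig and every requested transition type.
    """
    params = params or ScanParams()
    with open_bam(bam_path) as bam:
        names = list(bam.references)
        lengths = dict(zip(bam.references, bam.lengths))
    results: dict[tuple[str, str], list[TsRegion]] = {}
    for contig in select_contigs(names, params):
        per_type = denovo_scan_contig(bam_path, fasta_path, contig,
                                      lengths[contig], params)
        for ts_type, regions in per_type.items():
            results[(contig, ts_type)] = regions
    return results
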