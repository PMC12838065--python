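"""The de novo transition scan.

A-to-I editing by ADAR deaminases clusters many edited adenosines inside one
double-stranded RNA structure. In non-strand-resolved RNA-seq alignments the
signal appears as locally enriched A>G (sense) or T>C (antisense) mismatches.
This module detects such clusters: for each transition type it accumulates a
2x2 contingency table over a window (reads carrying the query transition vs.
all other reads at query-source-base positions, against the same split at the
other reference bases), tests for enrichment with a one-sided Fisher's exact
test, slides the window 1 nt at a time, and merges overlapping significant
windows into TsRegions whose statistics are re-computed over the full span.

No multiple-testing correction is applied: the raw per-window p-value is
gated by ``alpha``, and false positives are controlled downstream by the
TsSite-count, relative-frequency and knockout-subtraction filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .counts import BASE_INDEX, BASES, TRANSITION_PARTNER, CountTable, ScanParams

__all__ = [
    "TsType", "TS_TYPES", "TARGET_TYPES", "NONTARGET_TYPES",
    "ContingencyTable", "WindowStat", "TsRegion",
    "build_contingency", "fisher_one_sided", "scan_windows",
    "finalize_regions", "exact_region_stats",
]


@dataclass(frozen=True)
class TsType:
    """One of the four transition classes (AG, CT, GA, TC)."""

    label: str
    source_base: str
    target_base: str

    def __post_init__(self):
        assert TRANSITION_PARTNER[self.source_base] == self.target_base


TS_TYPES: dict[str, TsType] = {
    "AG": TsType("AG", "A", "G"),
    "CT": TsType("CT", "C", "T"),
    "GA": TsType("GA", "G", "A"),
    "TC": TsType("TC", "T", "C"),
}
#: ADAR-indicative types; CT/GA act as internal negative controls
TARGET_TYPES: tuple[str, ...] = ("AG", "TC")
NONTARGET_TYPES: tuple[str, ...] = ("CT", "GA")

#: transition partner of each base code, as codes (A<->G, C<->T)
_PARTNER_CODE = np.array(
    [BASE_INDEX[TRANSITION_PARTNER[b]] for b in BASES], dtype=np.int64)


def as_ts_type(ts_type: "TsType | str") -> TsType:
    if isinstance(ts_type, TsType):
        return ts_type
    try:
        return TS_TYPES[ts_type]
    except KeyError:
        raise ValueError(f"unknown TsType label: {ts_type!r}") from None


@dataclass(frozen=True)
class ContingencyTable:
    """Accumulated read-base counts for one window and one transition type.

    ``q_ts``: reads carrying the query transition at query-source-base
    positions; ``q_nts``: all other reads at those positions; ``nq_ts``:
    reads carrying the respective base's own transition at the other three
    reference bases; ``nq_nts``: all other reads there.
    """

    q_ts: int
    q_nts: int
    nq_ts: int
    nq_nts: int

    def __post_init__(self):
        assert min(self.q_ts, self.q_nts, self.nq_ts, self.nq_nts) >= 0

    @property
    def total(self) -> int:
        return self.q_ts + self.q_nts + self.nq_ts + self.nq_nts

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    @property
    def rtf(self) -> float:
        """Relative transition frequency: q_ts / (q_ts + q_nts), 0 if empty."""
        denom = self.q_ts + self.q_nts
        return self.q_ts / denom if denom else 0.0


@dataclass(frozen=True)
class WindowStat:
    """One significant scan window."""

    contig: str
    window: tuple[int, int]
    ts_type: str
    p_value: float
    rtf: float
    ts_sites: tuple[int, ...]


@dataclass
class TsRegion:
    """A merged run of overlapping significant windows (or a Regio record).

    ``rtf_mean``/``p_mean`` are arithmetic means over the member windows;
    ``rtf_exact``/``p_exact`` are re-computed treating the full span as one
    window. Regio-mode records carry exact statistics only; low-coverage
    regions carry ``error`` instead of statistics.
    """

    contig: str
    span: tuple[int, int]
    ts_type: str
    rtf_mean: float | None = None
    rtf_exact: float | None = None
    p_mean: float | None = None
    p_exact: float | None = None
    ts_site_count: int | None = None
    ts_pos: tuple[int, ...] = ()
    ci: float | None = None
    error: str | None = None

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def identity(self) -> tuple[str, int, int, str]:
        return (self.contig, self.span[0], self.span[1], self.ts_type)


def _accumulators(table: CountTable, ts_type: TsType, params: ScanParams):
    """Per-position contingency contributions and TsSite mask.

    Returns arrays aligned with ``table.pos``: q_ts, q_nts, nq_ts, nq_nts
    (all zero at positions below ``min_cov``) and a boolean TsSite mask.
    """
    depth = table.depth
    passing = depth >= params.min_cov
    src = BASE_INDEX[ts_type.source_base]
    tgt = BASE_INDEX[ts_type.target_base]
    is_src = (table.ref == src) & passing
    is_other = (~(table.ref == src)) & passing

    n = table.n_sites
    partner_reads = table.counts[np.arange(n), _PARTNER_CODE[table.ref]]
    ref_reads = table.counts[np.arange(n), table.ref]

    q_ts = np.where(is_src, table.counts[:, tgt], 0)
    nq_ts = np.where(is_other, partner_reads, 0)
    if params.mismatch_only_test:
        q_nts = np.where(is_src, depth - table.counts[:, tgt] - ref_reads, 0)
        nq_nts = np.where(is_other, depth - partner_reads - ref_reads, 0)
    else:
        q_nts = np.where(is_src, depth - table.counts[:, tgt], 0)
        nq_nts = np.where(is_other, depth - partner_reads, 0)

    tgt_reads = table.counts[:, tgt]
    site = is_src & (tgt_reads >= params.min_ts_count)
    if params.min_ts_freq > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            site &= np.where(depth > 0, tgt_reads / depth, 0.0) >= params.min_ts_freq
    return q_ts, q_nts, nq_ts, nq_nts, site


def build_contingency(table: CountTable, window: tuple[int, int],
                      ts_type: TsType | str, min_cov: int,
                      mismatch_only: bool = False) -> ContingencyTable:
    """Accumulate the 2x2 table over ``window`` (0-based half-open).

    Only positions with depth >= ``min_cov`` contribute. A window with no
    qualifying position yields the all-zero table (flagged via
    :attr:`ContingencyTable.is_empty`), not an exception.
    """
    ts_type = as_ts_type(ts_type)
    sub = table.restrict(window)
    params = ScanParams(min_cov=min_cov, mismatch_only_test=mismatch_only)
    q_ts, q_nts, nq_ts, nq_nts, _ = _accumulators(sub, ts_type, params)
    return ContingencyTable(int(q_ts.sum()), int(q_nts.sum()),
                            int(nq_ts.sum()), int(nq_nts.sum()))


def fisher_one_sided(t: ContingencyTable) -> float:
    """One-sided Fisher's exact p-value for enrichment of q_ts.

    Returns P(X >= q_ts) under the hypergeometric null with the table's
    margins. Any zero margin admits only one table, so p = 1.
    """
    row_q = t.q_ts + t.q_nts
    row_nq = t.nq_ts + t.nq_nts
    col_ts = t.q_ts + t.nq_ts
    col_nts = t.q_nts + t.nq_nts
    if min(row_q, row_nq, col_ts, col_nts) == 0:
        return 1.0
    p = float(hypergeom.sf(t.q_ts - 1, t.total, col_ts, row_q))
    return min(p, 1.0)


def _window_sums(values: np.ndarray, w: int) -> np.ndarray:
    """Sliding-window sums of a dense array, window length ``w``, step 1."""
    c = np.concatenate(([0], np.cumsum(values)))
    return c[w:] - c[:-w]


def scan_windows(table: CountTable, ts_type: TsType | str,
                 params: ScanParams) -> list[WindowStat]:
    """Roll a ``w_size`` window 1 nt at a time and keep significant windows.

    Windows are placed on genomic coordinates across the covered span (first
    to last covered position); uncovered positions simply contribute nothing.
    A window is significant iff p < alpha, it holds at least
    ``min_ts_sites_window`` TsSites, and its RTF >= ``min_window_rtf``.
    """
    ts_type = as_ts_type(ts_type)
    if table.n_sites == 0:
        return []
    first, last = int(table.pos[0]), int(table.pos[-1])
    span_len = last + 1 - first
    w = params.w_size
    if span_len < w:
        return []

    q_ts_p, q_nts_p, nq_ts_p, nq_nts_p, site_p = _accumulators(table, ts_type, params)
    # densify onto the covered span
    off = table.pos - first
    dense = np.zeros((5, span_len), dtype=np.int64)
    dense[0, off] = q_ts_p
    dense[1, off] = q_nts_p
    dense[2, off] = nq_ts_p
    dense[3, off] = nq_nts_p
    dense[4, off] = site_p

    a = _window_sums(dense[0], w)
    b = _window_sums(dense[1], w)
    c = _window_sums(dense[2], w)
    d = _window_sums(dense[3], w)
    nsites = _window_sums(dense[4], w)

    with np.errstate(invalid="ignore", divide="ignore"):
        rtf = np.where(a + b > 0, a / np.maximum(a + b, 1), 0.0)
    # p < alpha needs a nonzero q_ts and all four margins nonzero
    cand = (a > 0) & (c + d > 0) & (b + d > 0) & \
           (nsites >= params.min_ts_sites_window) & (rtf >= params.min_window_rtf)
    idx = np.nonzero(cand)[0]
    if idx.size == 0:
        return []
    total = a[idx] + b[idx] + c[idx] + d[idx]
    p = hypergeom.sf(a[idx] - 1, total, a[idx] + c[idx], a[idx] + b[idx])
    p = np.minimum(p, 1.0)
    keep = idx[p < params.alpha]
    pvals = dict(zip(keep.tolist(), p[p < params.alpha].tolist()))

    site_pos = table.pos[site_p]
    out: list[WindowStat] = []
    for i in keep.tolist():
        w_start = first + i
        lo = np.searchsorted(site_pos, w_start, side="left")
        hi = np.searchsorted(site_pos, w_start + w, side="left")
        out.append(WindowStat(
            contig=table.contig, window=(w_start, w_start + w),
            ts_type=ts_type.label, p_value=float(pvals[i]),
            rtf=float(rtf[i]), ts_sites=tuple(int(x) for x in site_pos[lo:hi])))
    return out


def exact_region_stats(table: CountTable, span: tuple[int, int],
                       ts_type: TsType | str, params: ScanParams):
    """(rtf_exact, p_exact, ts_pos) treating ``span`` as a single window.

    Returns None when no position inside the span reaches ``min_cov``
    (the Regio low-coverage case).
    """
    ts_type = as_ts_type(ts_type)
    sub = table.restrict(span)
    if sub.n_sites == 0 or not np.any(sub.depth >= params.min_cov):
        return None
    q_ts, q_nts, nq_ts, nq_nts, site = _accumulators(sub, ts_type, params)
    t = ContingencyTable(int(q_ts.sum()), int(q_nts.sum()),
                         int(nq_ts.sum()), int(nq_nts.sum()))
    ts_pos = tuple(int(x) for x in sub.pos[site])
    return t.rtf, fisher_one_sided(t), ts_pos


def merge_window_runs(windows: Sequence[WindowStat]) -> list[tuple[tuple[int, int], list[WindowStat]]]:
    """Group sorted windows into maximal runs of mutually overlapping ones.

    Strict interval overlap (>= 1 shared position) merges; adjacency does
    not. Returns ``(span, member_windows)`` pairs.
    """
    runs: list[tuple[tuple[int, int], list[WindowStat]]] = []
    cur_span: tuple[int, int] | None = None
    members: list[WindowStat] = []
    for win in sorted(windows, key=lambda x: x.window):
        s, e = win.window
        if cur_span is not None and s < cur_span[1]:
            cur_span = (cur_span[0], max(cur_span[1], e))
            members.append(win)
        else:
            if cur_span is not None:
                runs.append((cur_span, members))
            cur_span, members = (s, e), [win]
    if cur_span is not None:
        runs.append((cur_span, members))
    return runs


def finalize_regions(windows: Sequence[WindowStat], table: CountTable,
                     params: ScanParams) -> list[TsRegion]:
    """Merge overlapping significant windows into TsRegions.

    Windows must share contig and TsType and be sortable by start. Mean
    statistics average the member windows; exact statistics re-analyze the
    merged span as one window against ``table``.
    """
    if not windows:
        return []
    contigs = {w.contig for w in windows}
    types = {w.ts_type for w in windows}
    if len(contigs) > 1 or len(types) > 1:
        raise ValueError("finalize_regions requires one contig and one TsType")
    ts_type = types.pop()
    out: list[TsRegion] = []
    for span, members in merge_window_runs(windows):
        stats = exact_region_stats(table, span, ts_type, params)
        if stats is None:  # cannot happen for truly significant windows
            continue
        rtf_exact, p_exact, ts_pos = stats
        out.append(TsRegion(
            contig=members[0].contig, span=span, ts_type=ts_type,
            rtf_mean=float(np.mean([m.rtf for m in members])),
            p_mean=float(np.mean([m.p_value for m in members])),
            rtf_exact=rtf_exact, p_exact=p_exact,
            ts_site_count=len(ts_pos), ts_pos=ts_pos))
    return out
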