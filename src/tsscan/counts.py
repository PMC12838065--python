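"""Per-position base counting from BAM alignments.

This module turns a coordinate-sorted, indexed BAM plus its reference FASTA
into dense per-position read count tables: for every covered reference
position the depth and the number of reads supporting each of A/C/G/T.
These tables are the substrate for the rolling-window transition scan.

Coordinates are 0-based half-open throughout; GFF conversion happens only
in :mod:`tsscan.gff`.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pysam

from .errors import ContigError, InputError

BASES = "ACGT"
BASE_INDEX: Mapping[str, int] = {b: i for i, b in enumerate(BASES)}
#: transition partner of each base (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION_PARTNER: Mapping[str, str] = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: contig names excluded under primary-assembly selection (user-overridable)
DEFAULT_PRIMARY_EXCLUDE = r"(_random|_alt|chrUn|scaffold|_decoy|EBV)"


@dataclass(frozen=True)
class SiteCounts:
    """Read base counts at a single covered reference position."""

    contig: str
    pos: int
    ref_base: str
    depth: int
    base_counts: Mapping[str, int]

    def __post_init__(self):
        assert self.ref_base in BASE_INDEX
        assert self.depth >= 1
        assert sum(self.base_counts.values()) == self.depth


@dataclass
class CountTable:
    """Dense per-position counts over one contig span.

    Internally array-backed for the vectorized window scan: ``pos`` is
    strictly increasing, ``ref`` holds base codes (A=0,C=1,G=2,T=3) and
    ``counts[i, j]`` is the number of reads carrying base ``BASES[j]`` at
    ``pos[i]``. Uncovered and reference-N positions are absent.
    """

    contig: str
    span: tuple[int, int]
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=np.uint8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.pos.size:
            if not np.all(np.diff(self.pos) > 0):
                raise ValueError("positions must be strictly increasing")
            if self.pos[0] < self.span[0] or self.pos[-1] >= self.span[1]:
                raise ValueError("positions outside span")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def sites(self) -> Iterator[SiteCounts]:
        """Yield per-position records in coordinate order."""
        depth = self.depth
        for i in range(self.pos.size):
            yield SiteCounts(
                contig=self.contig,
                pos=int(self.pos[i]),
                ref_base=BASES[self.ref[i]],
                depth=int(depth[i]),
                base_counts={b: int(self.counts[i, j]) for j, b in enumerate(BASES)},
            )

    @classmethod
    def from_sites(cls, contig: str, span: tuple[int, int],
                   sites: Sequence[tuple[int, str, Mapping[str, int]]]) -> "CountTable":
        """Build a table from ``(pos, ref_base, base_counts)`` tuples (tests, toys)."""
        sites = sorted(sites, key=lambda s: s[0])
        pos = np.array([s[0] for s in sites], dtype=np.int64)
        ref = np.array([BASE_INDEX[s[1]] for s in sites], dtype=np.uint8)
        counts = np.zeros((len(sites), 4), dtype=np.int64)
        for i, (_, _, bc) in enumerate(sites):
            for b, n in bc.items():
                counts[i, BASE_INDEX[b]] = n
        return cls(contig=contig, span=span, pos=pos, ref=ref, counts=counts)

    def restrict(self, window: tuple[int, int]) -> "CountTable":
        """Sub-table covering positions inside ``window`` (0-based half-open)."""
        lo = np.searchsorted(self.pos, window[0], side="left")
        hi = np.searchsorted(self.pos, window[1], side="left")
        return CountTable(contig=self.contig, span=window,
                          pos=self.pos[lo:hi], ref=self.ref[lo:hi],
                          counts=self.counts[lo:hi])


@dataclass
class ScanParams:
    """Parameters of the transition scan (names follow the tool vocabulary).

    ``min_cov`` defaults to 4 for the de novo scan; region re-quantification
    uses 8 (see :meth:`for_regio`). ``ts_types`` defaults to the
    ADAR-indicative target types AG and TC.
    """

    w_size: int = 100
    min_cov: int = 4
    chunk_size: int = 50_000_000
    ts_types: tuple[str, ...] = ("AG", "TC")
    alpha: float = 0.05
    min_ts_sites_window: int = 1
    min_window_rtf: float = 0.0
    min_ts_count: int = 1
    min_ts_freq: float = 0.0
    primary_only: bool = True
    contigs: tuple[str, ...] | None = None
    primary_exclude: str = DEFAULT_PRIMARY_EXCLUDE
    min_base_quality: int = 0
    min_mapping_quality: int = 0
    mismatch_only_test: bool = False

    def __post_init__(self):
        if self.w_size < 2:
            raise ValueError("w_size must be >= 2")
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.chunk_size <= self.w_size:
            raise ValueError("chunk_size must exceed w_size")
        bad = set(self.ts_types) - {"AG", "CT", "GA", "TC"}
        if bad:
            raise ValueError(f"unknown TsType(s): {sorted(bad)}")

    @classmethod
    def for_regio(cls, **kwargs) -> "ScanParams":
        """Defaults for region re-quantification mode (min_cov 8)."""
        kwargs.setdefault("min_cov", 8)
        return cls(**kwargs)

    def replace(self, **kwargs) -> "ScanParams":
        return replace(self, **kwargs)


def _check_alignment_inputs(bam_path: str, fasta_path: str) -> None:
    for path in (bam_path, fasta_path):
        if not os.path.exists(path):
            raise InputError(f"input file not found: {path}")
    if not any(os.path.exists(bam_path + ext) for ext in (".bai", ".csi")) and \
            not any(os.path.exists(os.path.splitext(bam_path)[0] + ext)
                    for ext in (".bai", ".csi")):
        raise InputError(f"BAM index (.bai/.csi) not found for: {bam_path}")


def open_bam(bam_path: str) -> pysam.AlignmentFile:
    if not os.path.exists(bam_path):
        raise InputError(f"input file not found: {bam_path}")
    return pysam.AlignmentFile(bam_path, "rb")


_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

# CIGAR ops consuming query and/or reference
_OPS_ALIGNED = (0, 7, 8)  # M, =, X
_OPS_QUERY_ONLY = (1, 4)  # I, S
_OPS_REF_ONLY = (2, 3)    # D, N


def _accumulate_read(read: pysam.AlignedSegment, start: int, stop: int,
                     min_base_quality: int, pos_chunks: list, code_chunks: list) -> None:
    seq = read.query_sequence
    if seq is None:
        return
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if min_base_quality > 0:
        quals = read.query_qualities
        if quals is not None:
            codes = np.where(np.asarray(quals) >= min_base_quality, codes, 255)
    qpos, rpos = 0, read.reference_start
    for op, length in read.cigartuples:
        if op in _OPS_ALIGNED:
            lo = max(rpos, start)
            hi = min(rpos + length, stop)
            if hi > lo:
                q0 = qpos + (lo - rpos)
                block = codes[q0:q0 + (hi - lo)]
                valid = block != 255  # skip read Ns / quality-masked bases
                pos_chunks.append(np.arange(lo, hi, dtype=np.int64)[valid])
                code_chunks.append(block[valid])
            qpos += length
            rpos += length
        elif op in _OPS_QUERY_ONLY:
            qpos += length
        elif op in _OPS_REF_ONLY:
            rpos += length


def pileup_count_table(bam_path: str, fasta_path: str, contig: str,
                       interval: tuple[int, int] | None = None,
                       min_base_quality: int = 0,
                       min_mapping_quality: int = 0) -> CountTable:
    """Count read bases per reference position over ``interval``.

    Secondary, supplementary, duplicate-marked, QC-fail and unmapped
    alignments are excluded. Deletions, reference skips (spliced ``N``
    segments), insertions and soft-clips contribute nothing; read bases
    below ``min_base_quality`` are dropped. Positions with reference base
    N, or without any surviving read base, are absent from the result.
    """
    _check_alignment_inputs(bam_path, fasta_path)
    with pysam.AlignmentFile(bam_path, "rb") as bam, \
            pysam.FastaFile(fasta_path) as fasta:
        if contig not in bam.references:
            raise ContigError(f"contig {contig!r} not in BAM header of {bam_path}")
        if contig not in fasta.references:
            raise ContigError(f"contig {contig!r} not in reference {fasta_path}")
        clen = bam.get_reference_length(contig)
        start, stop = interval if interval is not None else (0, clen)
        if not (0 <= start < stop <= clen):
            raise ContigError(
                f"interval [{start}, {stop}) outside contig {contig!r} "
                f"of length {clen}")

        span_len = stop - start
        flat = np.zeros(span_len * 4, dtype=np.int64)
        pos_chunks: list[np.ndarray] = []
        code_chunks: list[np.ndarray] = []
        pending = 0
        for read in bam.fetch(contig, start, stop):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or read.is_qcfail
                    or read.mapping_quality < min_mapping_quality):
                continue
            _accumulate_read(read, start, stop, min_base_quality,
                             pos_chunks, code_chunks)
            pending += 1
            if pending >= 20_000:  # bound scratch memory on deep chunks
                flat += np.bincount(
                    (np.concatenate(pos_chunks) - start) * 4
                    + np.concatenate(code_chunks), minlength=span_len * 4)
                pos_chunks, code_chunks, pending = [], [], 0
        if pos_chunks:
            flat += np.bincount(
                (np.concatenate(pos_chunks) - start) * 4
                + np.concatenate(code_chunks), minlength=span_len * 4)
        counts = flat.reshape(span_len, 4)
        refseq = fasta.fetch(contig, start, stop)

    ref = _CODE_LUT[np.frombuffer(refseq.encode("ascii"), dtype=np.uint8)]
    covered = (counts.sum(axis=1) >= 1) & (ref != 255)
    idx = np.nonzero(covered)[0]
    return CountTable(contig=contig, span=(start, stop),
                      pos=idx + start, ref=ref[idx], counts=counts[idx])


def select_contigs(all_contig_names: Sequence[str], params: ScanParams) -> list[str]:
    """Resolve the contig set to analyze.

    Explicit ``params.contigs`` wins; otherwise primary-assembly filtering
    drops decoy/scaffold-style names; otherwise all names pass in order.
    """
    if not all_contig_names:
        raise ValueError("contig name list is empty")
    if params.contigs:
        missing = [c for c in params.contigs if c not in set(all_contig_names)]
        if missing:
            raise ContigError(f"requested contig(s) not in BAM header: {missing}")
        return list(params.contigs)
    if params.primary_only:
        pat = re.compile(params.primary_exclude, re.IGNORECASE)
        return [c for c in all_contig_names if not pat.search(c)]
    return list(all_contig_names)


def make_chunks(contig_length: int, chunk_size: int, overlap: int) -> list[tuple[int, int]]:
    """Split ``[0, contig_length)`` into chunks overlapping by ``overlap``.

    Consecutive chunks share exactly ``overlap`` positions so any scan
    window of length <= ``overlap`` lies wholly inside at least one chunk.
    """
    if contig_length < 1:
        raise ValueError("contig_length must be >= 1")
    if overlap >= chunk_size:
        raise ValueError("overlap must be smaller than chunk_size")
    chunks: list[tuple[int, int]] = []
    start = 0
    step = chunk_size - overlap
    while True:
        end = min(start + chunk_size, contig_length)
        chunks.append((start, end))
        if end >= contig_length:
            return chunks
        start += step
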