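"""Deterministic simulator of aligned RNA-seq reads with planted editing.

Emulates the data regime the transition scan targets: uniform-ish coverage,
per-base sequencing error around 1e-3, clustered edited adenosines (A>G on
the sense strand, T>C on the antisense strand) with per-site editing
frequencies, isolated SNP-like variants, and spliced reads (N CIGAR).
Reads are emitted pre-aligned at their sampled positions — evaluation against
planted truth requires alignment-free ground truth, and read alignment is a
separate upstream concern.

Everything is driven by one pseudo-random stream keyed by the seed, with a
fixed sampling order (per contig: reference bases, cluster site placement,
read starts, per-site editing draws, SNP draws, sequencing errors), so the
same config reproduces byte-identical FASTA/SAM/truth files. Crucially, the
random draws consumed do not depend on editing *frequencies* — only on
placements — so a wild-type config and its knockout counterpart
(:func:`knockout_config`, frequencies zeroed) share the identical reference,
read placement and error realization and differ only at edited bases.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pysam

from .annot import Gene, GeneInterval, Repeat
from .counts import BASE_INDEX, BASES
from .errors import ValidationError
from .scan import TS_TYPES

__all__ = [
    "ClusterSpec", "SnpSpec", "SpliceSpec", "SimConfig",
    "SiteTruth", "ClusterTruth", "SnpTruth", "SimTruth", "SimResult",
    "simulate_dataset", "knockout_config", "standard_fixture_config",
]

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ClusterSpec:
    """A planted editing cluster: edited source-base sites within a span."""

    contig: str
    start: int
    end: int
    ts_type: str  # AG (sense) or TC (antisense)
    n_sites: int = 10
    sites: tuple[int, ...] | None = None  # explicit positions override n_sites
    editing_freq: float = 0.3

    def __post_init__(self):
        if self.ts_type not in ("AG", "TC"):
            raise ValidationError("cluster ts_type must be AG or TC")
        if not (0.0 <= self.editing_freq <= 1.0):
            raise ValidationError("editing_freq must be in [0, 1]")


@dataclass(frozen=True)
class SnpSpec:
    contig: str
    pos: int
    alt: str
    alt_fraction: float = 0.5

    def __post_init__(self):
        if self.alt not in BASE_INDEX:
            raise ValidationError(f"SNP alt base must be one of {BASES}")
        if not (0.0 <= self.alt_fraction <= 1.0):
            raise ValidationError("alt_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SpliceSpec:
    """Reads straddling ``pos`` skip ``gap`` reference bases via an N CIGAR."""

    contig: str
    pos: int
    gap: int


@dataclass
class SimConfig:
    seed: int
    contigs: Mapping[str, int]  # name -> length, in output order
    gc_fraction: float = 0.5
    coverage: float = 30.0
    read_length: int = 100
    paired: bool = False
    error_rate: float = 1e-3
    clusters: Sequence[ClusterSpec] = field(default_factory=list)
    snps: Sequence[SnpSpec] = field(default_factory=list)
    splices: Sequence[SpliceSpec] = field(default_factory=list)
    genes: Sequence[Gene] = field(default_factory=list)
    exons: Sequence[GeneInterval] = field(default_factory=list)
    repeats: Sequence[Repeat] = field(default_factory=list)

    def validate(self) -> None:
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValidationError("error_rate must be in [0, 1]")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValidationError("gc_fraction must be in (0, 1)")
        for cl in self.clusters:
            length = self.contigs.get(cl.contig)
            if length is None:
                raise ValidationError(f"cluster contig {cl.contig!r} not in contigs")
            if not (0 <= cl.start < cl.end <= length):
                raise ValidationError(
                    f"cluster span [{cl.start}, {cl.end}) outside contig "
                    f"{cl.contig!r} of length {length}")
            n = len(cl.sites) if cl.sites is not None else cl.n_sites
            if n < 1 or n > cl.end - cl.start:
                raise ValidationError("cluster site count does not fit its span")
        for snp in self.snps:
            length = self.contigs.get(snp.contig)
            if length is None or not (0 <= snp.pos < length):
                raise ValidationError(f"SNP position outside contig {snp.contig!r}")


@dataclass(frozen=True)
class SiteTruth:
    contig: str
    pos: int
    ts_type: str
    freq: float
    depth: int
    edited_reads: int  # realized, before sequencing error


@dataclass(frozen=True)
class ClusterTruth:
    contig: str
    start: int
    end: int
    ts_type: str
    freq: float
    sites: tuple[SiteTruth, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class SnpTruth:
    contig: str
    pos: int
    alt: str
    alt_fraction: float
    depth: int
    alt_reads: int


@dataclass(frozen=True)
class SimTruth:
    seed: int
    clusters: tuple[ClusterTruth, ...]
    snps: tuple[SnpTruth, ...]
    read_counts: Mapping[str, int]


@dataclass(frozen=True)
class SimResult:
    fasta_path: str
    sam_path: str
    bam_path: str
    truth_bed: str
    truth_tsv: str
    truth: SimTruth
    genes_gff: str | None = None
    repeats_bed: str | None = None


def knockout_config(config: SimConfig,
                    keep_clusters: Sequence[int] = ()) -> SimConfig:
    """Knockout counterpart of ``config``: editing frequencies zeroed.

    Clusters whose indices appear in ``keep_clusters`` retain their editing
    (clusters present in both samples); all site placements are preserved so
    the simulated genome is identical between the pair.
    """
    keep = set(keep_clusters)
    clusters = [cl if i in keep else replace(cl, editing_freq=0.0)
                for i, cl in enumerate(config.clusters)]
    return replace(config, clusters=clusters)


def standard_fixture_config(seed: int, n_clusters: int = 20,
                            contig_length: int = 1_000_000,
                            sites_per_cluster: int = 10,
                            editing_freq: float = 0.3,
                            coverage: float = 30.0,
                            error_rate: float = 1e-3,
                            cluster_width: int = 150) -> SimConfig:
    """The standard two-contig benchmark: well-separated planted clusters.

    Clusters alternate between AG and TC and are laid out evenly along two
    contigs, each cluster's sites falling within a ``cluster_width`` span
    (Alu-duplex scale, ~15 nt site spacing at the defaults).
    """
    contigs = {"sim1": contig_length, "sim2": contig_length}
    per_contig = (n_clusters + 1) // 2
    clusters = []
    for i in range(n_clusters):
        contig = "sim1" if i < per_contig else "sim2"
        j = i if i < per_contig else i - per_contig
        step = (contig_length - 100_000) // max(per_contig, 1)
        start = 50_000 + j * step
        clusters.append(ClusterSpec(
            contig=contig, start=start, end=start + cluster_width,
            ts_type="AG" if i % 2 == 0 else "TC",
            n_sites=sites_per_cluster, editing_freq=editing_freq))
    return SimConfig(seed=seed, contigs=contigs, coverage=coverage,
                     error_rate=error_rate, clusters=clusters)


def simconfig_from_dict(data: Mapping) -> SimConfig:
    """Build a SimConfig from a plain mapping (YAML/JSON config files)."""
    kwargs = dict(data)
    kwargs["clusters"] = [ClusterSpec(**c) if not isinstance(c, ClusterSpec)
                          else c for c in kwargs.get("clusters", [])]
    kwargs["snps"] = [SnpSpec(**s) if not isinstance(s, SnpSpec) else s
                      for s in kwargs.get("snps", [])]
    kwargs["splices"] = [SpliceSpec(**s) if not isinstance(s, SpliceSpec)
                         else s for s in kwargs.get("splices", [])]
    for key, cls in (("genes", Gene), ("exons", GeneInterval),
                     ("repeats", Repeat)):
        kwargs[key] = [cls(**g) if not isinstance(g, cls) else g
                       for g in kwargs.get(key, [])]
    return SimConfig(**kwargs)


def _write_fasta(path: str, seqs: Mapping[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for name, codes in seqs.items():
            fh.write(f">{name}\n")
            text = _ASCII[codes].tobytes().decode("ascii")
            for i in range(0, len(text), 60):
                fh.write(text[i:i + 60] + "\n")


def _sam_to_bam(sam_path: str, bam_path: str) -> None:
    with pysam.AlignmentFile(sam_path, "r") as sam, \
            pysam.AlignmentFile(bam_path, "wb", template=sam) as bam:
        for read in sam:
            bam.write(read)
    pysam.index(bam_path)


def simulate_dataset(config: SimConfig, out_dir: str,
                     prefix: str = "sim") -> SimResult:
    """Generate FASTA + coordinate-sorted SAM/BAM + ground truth in ``out_dir``."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    gc = config.gc_fraction
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    fasta_path = os.path.join(out_dir, f"{prefix}.fa")
    sam_path = os.path.join(out_dir, f"{prefix}.sam")
    bam_path = os.path.join(out_dir, f"{prefix}.bam")
    truth_bed = os.path.join(out_dir, f"{prefix}.truth.bed")
    truth_tsv = os.path.join(out_dir, f"{prefix}.truth.tsv")

    seqs: dict[str, np.ndarray] = {}
    cluster_truth: list[ClusterTruth] = []
    snp_truth: list[SnpTruth] = []
    read_counts: dict[str, int] = {}

    header = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in config.contigs.items():
        header.append(f"@SQ\tSN:{name}\tLN:{length}")

    with open(sam_path, "w") as sam:
        sam.write("\n".join(header) + "\n")
        for contig, length in config.contigs.items():
            _simulate_contig(sam, rng, config, contig, length, base_probs,
                             prefix, seqs, cluster_truth, snp_truth,
                             read_counts)

    _write_fasta(fasta_path, seqs)
    pysam.faidx(fasta_path)
    _sam_to_bam(sam_path, bam_path)

    with open(truth_bed, "w") as fh:
        for i, cl in enumerate(cluster_truth):
            fh.write(f"{cl.contig}\t{cl.start}\t{cl.end}\t"
                     f"cluster{i}:{cl.ts_type}\t{cl.freq:g}\n")
    with open(truth_tsv, "w") as fh:
        fh.write("record\tcontig\tpos\tkind\tfreq\tdepth\taltered_reads\n")
        for i, cl in enumerate(cluster_truth):
            for s in cl.sites:
                fh.write(f"cluster{i}\t{s.contig}\t{s.pos}\t{s.ts_type}\t"
                         f"{s.freq:g}\t{s.depth}\t{s.edited_reads}\n")
        for i, s in enumerate(snp_truth):
            fh.write(f"snp{i}\t{s.contig}\t{s.pos}\tSNP:{s.alt}\t"
                     f"{s.alt_fraction:g}\t{s.depth}\t{s.alt_reads}\n")

    genes_gff = repeats_bed = None
    if config.genes:
        genes_gff = os.path.join(out_dir, f"{prefix}.genes.gff3")
        _write_annotation_gff(genes_gff, config.genes, config.exons)
    if config.repeats:
        repeats_bed = os.path.join(out_dir, f"{prefix}.repeats.bed")
        with open(repeats_bed, "w") as fh:
            for rep in config.repeats:
                fh.write(f"{rep.contig}\t{rep.start}\t{rep.end}\t"
                         f"{rep.name}#{rep.family}\n")

    truth = SimTruth(seed=config.seed, clusters=tuple(cluster_truth),
                     snps=tuple(snp_truth), read_counts=read_counts)
    truth_json = os.path.join(out_dir, f"{prefix}.truth.json")
    with open(truth_json, "w") as fh:
        json.dump({"seed": config.seed, "read_counts": read_counts,
                   "n_clusters": len(cluster_truth),
                   "n_snps": len(snp_truth)}, fh, indent=1, sort_keys=True)
    return SimResult(fasta_path=fasta_path, sam_path=sam_path,
                     bam_path=bam_path, truth_bed=truth_bed,
                     truth_tsv=truth_tsv, truth=truth,
                     genes_gff=genes_gff, repeats_bed=repeats_bed)


def _simulate_contig(sam, rng, config: SimConfig, contig: str, length: int,
                     base_probs, prefix, seqs, cluster_truth, snp_truth,
                     read_counts) -> None:
    rl = config.read_length

    # 1. reference sequence, then force cluster source bases into place
    ref = rng.choice(4, size=length, p=base_probs).astype(np.uint8)
    contig_clusters = [cl for cl in config.clusters if cl.contig == contig]
    cluster_sites: list[np.ndarray] = []
    for cl in contig_clusters:
        if cl.sites is not None:
            sites = np.array(sorted(cl.sites), dtype=np.int64)
        else:
            sites = np.sort(rng.choice(cl.end - cl.start, size=cl.n_sites,
                                       replace=False)) + cl.start
        ref[sites] = BASE_INDEX[TS_TYPES[cl.ts_type].source_base]
        cluster_sites.append(sites)
    seqs[contig] = ref

    # 2. read placement (single-end; pairs are two placed mates of a fragment)
    splices = [sp for sp in config.splices if sp.contig == contig]
    if config.paired and splices:
        raise ValidationError("spliced reads are not supported in paired mode")
    if config.paired:
        frag_len = 2 * rl + 60
        n_frags = int(round(config.coverage * length / rl / 2))
        frag_starts = np.sort(rng.integers(0, max(length - frag_len, 0) + 1,
                                           size=n_frags))
        starts = np.concatenate([frag_starts, frag_starts + frag_len - rl])
        mate_of = np.concatenate([np.arange(n_frags) + n_frags,
                                  np.arange(n_frags)])
        is_first = np.concatenate([np.ones(n_frags, bool),
                                   np.zeros(n_frags, bool)])
        frag_id = np.concatenate([np.arange(n_frags), np.arange(n_frags)])
        order = np.argsort(starts, kind="stable")
        inverse = np.empty_like(order)
        inverse[order] = np.arange(order.size)
        starts = starts[order]
        mate_of = inverse[mate_of[order]]
        is_first = is_first[order]
        frag_id = frag_id[order]
    else:
        n_reads = int(round(config.coverage * length / rl))
        starts = np.sort(rng.integers(0, max(length - rl, 0) + 1,
                                      size=n_reads))
        mate_of = is_first = frag_id = None
        # splice gaps are intronic: no read originates inside them
        for sp in splices:
            starts = starts[(starts < sp.pos) | (starts >= sp.pos + sp.gap)]
    n = starts.size

    # 3. reference index per read base; splice-straddling reads skip the gap
    idx = (starts[:, None] + np.arange(rl)[None, :]).astype(np.int64)
    cigars: dict[int, str] = {}
    spliced = np.zeros(n, dtype=bool)
    for sp in splices:
        sel = ((starts > sp.pos - rl) & (starts < sp.pos)
               & (starts + rl + sp.gap <= length) & ~spliced)
        rows = np.nonzero(sel)[0]
        if rows.size == 0:
            continue
        sub = idx[rows]
        idx[rows] = np.where(sub >= sp.pos, sub + sp.gap, sub)
        spliced[rows] = True
        for r in rows.tolist():
            m1 = sp.pos - int(starts[r])
            cigars[r] = f"{m1}M{sp.gap}N{rl - m1}M"

    base = ref[idx].copy()
    max_gap = max((sp.gap for sp in splices), default=0)

    def covering(pos: int):
        lo = np.searchsorted(starts, pos - rl - max_gap, side="left")
        hi = np.searchsorted(starts, pos, side="right")
        rows, cols = np.nonzero(idx[lo:hi] == pos)
        return rows + lo, cols

    # 4. planted editing, per cluster site (draw order fixed by config order)
    for cl, sites in zip(contig_clusters, cluster_sites):
        tgt = BASE_INDEX[TS_TYPES[cl.ts_type].target_base]
        site_records = []
        for pos in sites.tolist():
            rows, cols = covering(pos)
            edit = rng.random(rows.size) < cl.editing_freq
            base[rows[edit], cols[edit]] = tgt
            site_records.append(SiteTruth(
                contig=contig, pos=pos, ts_type=cl.ts_type,
                freq=cl.editing_freq, depth=int(rows.size),
                edited_reads=int(edit.sum())))
        cluster_truth.append(ClusterTruth(
            contig=contig, start=cl.start, end=cl.end, ts_type=cl.ts_type,
            freq=cl.editing_freq, sites=tuple(site_records)))

    # 5. SNP-like variants
    for snp in (s for s in config.snps if s.contig == contig):
        rows, cols = covering(snp.pos)
        hit = rng.random(rows.size) < snp.alt_fraction
        base[rows[hit], cols[hit]] = BASE_INDEX[snp.alt]
        snp_truth.append(SnpTruth(
            contig=contig, pos=snp.pos, alt=snp.alt,
            alt_fraction=snp.alt_fraction, depth=int(rows.size),
            alt_reads=int(hit.sum())))

    # 6. uniform sequencing error: substitute with one of the 3 other bases
    err = rng.random(base.shape) < config.error_rate
    n_err = int(err.sum())
    if n_err:
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        base[err] = (base[err] + shift) % 4
    else:
        rng.integers(1, 4, size=0)

    # 7. emit SAM records (coordinate order == start order)
    text = _ASCII[base].tobytes().decode("ascii")
    qual = "I" * rl
    default_cigar = f"{rl}M"
    lines = []
    for i in range(n):
        seq = text[i * rl:(i + 1) * rl]
        cigar = cigars.get(i, default_cigar)
        if config.paired:
            name = f"{prefix}.{contig}.f{frag_id[i]:07d}"
            flag = 99 if is_first[i] else 147
            mpos = int(starts[mate_of[i]]) + 1
            tlen = (int(starts[mate_of[i]]) + rl - int(starts[i])
                    if is_first[i] else
                    -(int(starts[i]) + rl - int(starts[mate_of[i]])))
            lines.append(f"{name}\t{flag}\t{contig}\t{int(starts[i]) + 1}\t60\t"
                         f"{cigar}\t=\t{mpos}\t{tlen}\t{seq}\t{qual}")
        else:
            name = f"{prefix}.{contig}.r{i:07d}"
            lines.append(f"{name}\t0\t{contig}\t{int(starts[i]) + 1}\t60\t"
                         f"{cigar}\t*\t0\t0\t{seq}\t{qual}")
    sam.write("\n".join(lines) + ("\n" if lines else ""))
    read_counts[contig] = n


def _write_annotation_gff(path: str, genes: Sequence[Gene],
                          exons: Sequence[GeneInterval]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.contig}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
        for ex in exons:
            fh.write(f"{ex.contig}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                     f"{ex.strand}\t.\tParent={ex.gene_id}\n")
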