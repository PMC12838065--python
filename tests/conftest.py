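"""Shared fixtures: hand-built alignments and session-scoped simulations."""

from __future__ import annotations

import os
from math import comb

import pysam
import pytest

from tsscan import (ClusterSpec, ScanParams, SimConfig, SnpSpec, SpliceSpec,
                    denovo_scan, knockout_config, simulate_dataset,
                    standard_fixture_config)


def build_alignment(out_dir, refs: dict[str, str],
                    reads: list[tuple[str, int, str, str | None]],
                    quals: dict[int, str] | None = None):
    """Write a FASTA + sorted/indexed BAM from explicit reads.

    ``reads`` entries are ``(contig, 0-based pos, seq, cigar-or-None)``;
    a None CIGAR means full-length match. Returns (bam_path, fasta_path).
    """
    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, "ref.fa")
    with open(fasta_path, "w") as fh:
        for name, seq in refs.items():
            fh.write(f">{name}\n{seq}\n")
    pysam.faidx(fasta_path)

    sam_path = os.path.join(out_dir, "reads.sam")
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, seq in refs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        order = {name: i for i, name in enumerate(refs)}
        for i, (contig, pos, seq, cigar) in enumerate(
                sorted(reads, key=lambda r: (order[r[0]], r[1]))):
            cigar = cigar or f"{len(seq)}M"
            qual = (quals or {}).get(i, "I" * len(seq))
            fh.write(f"r{i:04d}\t0\t{contig}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t"
                     f"{seq}\t{qual}\n")
    bam_path = os.path.join(out_dir, "reads.bam")
    with pysam.AlignmentFile(sam_path) as sam, \
            pysam.AlignmentFile(bam_path, "wb", template=sam) as bam:
        for read in sam:
            bam.write(read)
    pysam.index(bam_path)
    return bam_path, fasta_path


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric oracle for the one-sided enrichment p-value.

    Sums P(X = x) for x >= a over all 2x2 tables with the observed margins,
    in exact integer arithmetic.
    """
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    total = a + b + c + d
    row = a + b
    col = a + c
    x_max = min(row, col)
    numerator = sum(comb(col, x) * comb(total - col, row - x)
                    for x in range(a, x_max + 1))
    return numerator / comb(total, row)


# --- session-scoped simulated datasets (seeds fixed once) -------------------

SMALL_SEED = 7
STANDARD_SEED = 1234
NULL_SEED = 99
DIFF_SEED = 4321


def small_cluster_config(seed: int = SMALL_SEED) -> SimConfig:
    """100 kb contig: one AG and one TC cluster, a homozygous transition SNP,
    and a spliced junction — the compact end-to-end fixture."""
    return SimConfig(
        seed=seed, contigs={"c1": 100_000}, coverage=30.0, error_rate=1e-3,
        clusters=[ClusterSpec("c1", 20_000, 20_150, "AG", 10, editing_freq=0.3),
                  ClusterSpec("c1", 60_000, 60_150, "TC", 10, editing_freq=0.3)],
        snps=[SnpSpec("c1", 40_000, "G", 1.0)],
        splices=[SpliceSpec("c1", 80_000, 1_000)])


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("small")
    return simulate_dataset(small_cluster_config(), str(out))


@pytest.fixture(scope="session")
def small_denovo(small_dataset):
    return denovo_scan(small_dataset.bam_path, small_dataset.fasta_path,
                       ScanParams())


@pytest.fixture(scope="session")
def standard_dataset(tmp_path_factory):
    """The two-contig, 20-cluster recovery benchmark."""
    out = tmp_path_factory.mktemp("standard")
    return simulate_dataset(standard_fixture_config(STANDARD_SEED), str(out))


@pytest.fixture(scope="session")
def null_datasets(tmp_path_factory):
    """200 kb contig without clusters: error-free and error 1e-3 variants."""
    out0 = tmp_path_factory.mktemp("null_e0")
    out1 = tmp_path_factory.mktemp("null_e3")
    cfg0 = SimConfig(seed=NULL_SEED, contigs={"n1": 200_000}, coverage=30.0,
                     error_rate=0.0)
    cfg1 = SimConfig(seed=NULL_SEED, contigs={"n1": 200_000}, coverage=30.0,
                     error_rate=1e-3)
    return (simulate_dataset(cfg0, str(out0)),
            simulate_dataset(cfg1, str(out1)))


def differential_configs(seed: int = DIFF_SEED):
    """WT/KO pair: 12 clusters on two 300 kb contigs, 6 of them shared.

    Sequencing error is zero in this pair: the differential filter's
    exactness contract (CI == 1.0 for fully knocked-out regions) is only
    defined in the noise-free regime. A transition SNP shared by both
    samples is planted as a known single-site confounder.
    """
    contigs = {"d1": 300_000, "d2": 300_000}
    clusters = []
    for i in range(12):
        contig = "d1" if i < 6 else "d2"
        j = i % 6
        start = 30_000 + j * 45_000
        clusters.append(ClusterSpec(contig, start, start + 150,
                                    "AG" if i % 2 == 0 else "TC",
                                    10, editing_freq=0.3))
    shared = (1, 3, 5, 7, 9, 11)
    wt = SimConfig(seed=seed, contigs=contigs, coverage=30.0, error_rate=0.0,
                   clusters=clusters,
                   snps=[SnpSpec("d1", 150_000, "G", 1.0)])
    ko = knockout_config(wt, keep_clusters=shared)
    wt_only = tuple(i for i in range(12) if i not in shared)
    return wt, ko, wt_only, shared


@pytest.fixture(scope="session")
def differential_pair(tmp_path_factory):
    wt_cfg, ko_cfg, wt_only, shared = differential_configs()
    wt = simulate_dataset(wt_cfg, str(tmp_path_factory.mktemp("diff_wt")), "wt")
    ko = simulate_dataset(ko_cfg, str(tmp_path_factory.mktemp("diff_ko")), "ko")
    return wt, ko, wt_only, shared
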