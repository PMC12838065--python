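"""Lightweight annotation containers and loaders (genes, exons, repeats).

Downstream classification needs only intervals with identity and strand, so
annotations are plain dataclasses with 0-based half-open coordinates. The
loaders accept the minimal GFF3/BED dialects the pipeline produces and
consumes; they are not general-purpose annotation parsers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .errors import InputError, ParseError

__all__ = ["Gene", "GeneInterval", "Repeat",
           "read_genes_gff", "read_exons_gff", "read_repeats_bed"]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "."

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GeneInterval:
    """An exon/UTR or derived intron interval tied to a gene."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "."

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Repeat:
    name: str
    family: str
    contig: str
    start: int
    end: int


def _gff_records(path: str, wanted_features: set[str]):
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"expected 9 columns, got {len(cols)}", lineno)
            if cols[2] not in wanted_features:
                continue
            attrs = {}
            for item in cols[8].rstrip(";").split(";"):
                if "=" in item:
                    k, _, v = item.partition("=")
                    attrs[k.strip()] = v
            yield cols, attrs, lineno


def read_genes_gff(path: str) -> list[Gene]:
    genes = []
    for cols, attrs, lineno in _gff_records(path, {"gene"}):
        gene_id = attrs.get("ID") or attrs.get("gene_id")
        if not gene_id:
            raise ParseError("gene record without ID/gene_id attribute", lineno)
        genes.append(Gene(gene_id=gene_id, contig=cols[0],
                          start=int(cols[3]) - 1, end=int(cols[4]),
                          strand=cols[6]))
    return genes


def read_exons_gff(path: str) -> list[GeneInterval]:
    exons = []
    for cols, attrs, lineno in _gff_records(path, {"exon", "UTR",
                                                   "five_prime_UTR",
                                                   "three_prime_UTR"}):
        gene_id = attrs.get("Parent") or attrs.get("gene_id") or attrs.get("ID")
        if not gene_id:
            raise ParseError("exon record without Parent/gene_id attribute", lineno)
        exons.append(GeneInterval(gene_id=gene_id, contig=cols[0],
                                  start=int(cols[3]) - 1, end=int(cols[4]),
                                  strand=cols[6]))
    return exons


def read_repeats_bed(path: str) -> list[Repeat]:
    """BED with name in column 4; ``name#family`` carries the repeat family."""
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    repeats = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError("BED line with fewer than 3 columns", lineno)
            name = cols[3] if len(cols) > 3 else "repeat"
            rep_name, _, family = name.partition("#")
            repeats.append(Repeat(name=rep_name, family=family or ".",
                                  contig=cols[0], start=int(cols[1]),
                                  end=int(cols[2])))
    return repeats
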