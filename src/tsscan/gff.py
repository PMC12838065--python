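"""GFF3 serialization of TsRegions.

The attribute schema carries the region statistics: ``type`` (TsType),
``rtf_mean``/``rtf_exact`` (relative transition frequencies), ``p_mean``/
``p_exact`` (Fisher p-values), ``TsSiteCount`` and ``TsPos`` (1-based site
coordinates), plus optional ``ci`` and ``error``. Internal coordinates are
0-based half-open; GFF columns 4/5 are 1-based inclusive. Formatting is
deterministic (rtf/ci: 6 decimals, p-values: scientific with 3 significant
digits) so outputs diff and round-trip stably.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from .errors import InputError, ParseError, ValidationError
from .scan import TS_TYPES, TsRegion

__all__ = ["write_regions_gff", "read_regions_gff", "write_regions_bed",
           "GFF_SOURCE"]

GFF_SOURCE = "tsscan"
_FEATURE = "TsRegion"
#: deterministic attribute order (statistics absent from a record are omitted)
_ATTR_ORDER = ("type", "rtf_mean", "rtf_exact", "p_mean", "p_exact",
               "TsSiteCount", "TsPos", "ci", "error")

# GFF3 reserves ; = & and the percent sign inside attribute values
# (commas stay raw: they separate multi-valued attributes such as TsPos)
_ESCAPES = [("%", "%25"), (";", "%3B"), ("=", "%3D"), ("&", "%26"),
            ("\t", "%09"), ("\n", "%0A")]


def _escape(value: str) -> str:
    for raw, enc in _ESCAPES:
        value = value.replace(raw, enc)
    return value


def _unescape(value: str) -> str:
    for raw, enc in reversed(_ESCAPES):
        value = value.replace(enc, raw)
    return value


def _fmt_f(x: float) -> str:
    return f"{x:.6f}"


def _fmt_p(x: float) -> str:
    return f"{x:.2e}"


def _region_attributes(r: TsRegion) -> dict[str, str]:
    attrs: dict[str, str] = {"type": r.ts_type}
    if r.rtf_mean is not None:
        attrs["rtf_mean"] = _fmt_f(r.rtf_mean)
    if r.rtf_exact is not None:
        attrs["rtf_exact"] = _fmt_f(r.rtf_exact)
    if r.p_mean is not None:
        attrs["p_mean"] = _fmt_p(r.p_mean)
    if r.p_exact is not None:
        attrs["p_exact"] = _fmt_p(r.p_exact)
    if r.ts_site_count is not None:
        attrs["TsSiteCount"] = str(r.ts_site_count)
        attrs["TsPos"] = ",".join(str(p + 1) for p in r.ts_pos)
    if r.ci is not None:
        attrs["ci"] = _fmt_f(r.ci)
    if r.error is not None:
        attrs["error"] = r.error
    return attrs


def region_to_gff_line(r: TsRegion, source: str = GFF_SOURCE) -> str:
    attrs = _region_attributes(r)
    attr_col = ";".join(f"{k}={_escape(attrs[k])}" for k in _ATTR_ORDER
                        if k in attrs)
    score = _fmt_f(r.rtf_exact) if r.rtf_exact is not None else "."
    return "\t".join([r.contig, source, _FEATURE, str(r.span[0] + 1),
                      str(r.span[1]), score, ".", ".", attr_col])


def write_regions_gff(regions: Iterable[TsRegion], path: str,
                      source: str = GFF_SOURCE) -> None:
    """Write regions as GFF3 (1-based inclusive coordinates)."""
    try:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in regions:
                fh.write(region_to_gff_line(r, source) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write GFF to {path}: {exc}") from exc


def _parse_attributes(col: str, line_number: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if col in (".", ""):
        return attrs
    for item in col.rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"malformed attribute {item!r}", line_number)
        key, _, value = item.partition("=")
        attrs[key.strip()] = _unescape(value)
    return attrs


def read_regions_gff(path: str) -> list[TsRegion]:
    """Parse a GFF3 file into TsRegions.

    Tolerant of third-party records that lack the statistics attributes
    (the Regio input case): coordinates plus a TsType (``type=`` attribute,
    or column 3 naming one of AG/CT/GA/TC) suffice; missing statistics stay
    ``None``. Unknown TsType labels raise a validation error.
    """
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    regions: list[TsRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"expected 9 tab-separated columns, got {len(cols)}",
                                 lineno)
            seqid, _, feature, start_s, end_s, _, _, _, attr_col = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}",
                                 lineno) from None
            if start < 1 or end < start:
                raise ParseError(f"invalid coordinate range {start}..{end}", lineno)
            attrs = _parse_attributes(attr_col, lineno)
            label = attrs.get("type", feature if feature in TS_TYPES else None)
            if label is None:
                raise ParseError("no TsType (missing type= attribute)", lineno)
            if label not in TS_TYPES:
                raise ValidationError(
                    f"line {lineno}: unknown TsType label {label!r}")
            region = TsRegion(contig=seqid, span=(start - 1, end), ts_type=label)
            if "rtf_mean" in attrs:
                region.rtf_mean = float(attrs["rtf_mean"])
            if "rtf_exact" in attrs:
                region.rtf_exact = float(attrs["rtf_exact"])
            if "p_mean" in attrs:
                region.p_mean = float(attrs["p_mean"])
            if "p_exact" in attrs:
                region.p_exact = float(attrs["p_exact"])
            if "TsSiteCount" in attrs:
                region.ts_site_count = int(attrs["TsSiteCount"])
                pos_s = attrs.get("TsPos", "")
                region.ts_pos = tuple(int(p) - 1 for p in pos_s.split(",") if p)
            if "ci" in attrs:
                region.ci = float(attrs["ci"])
            if "error" in attrs:
                region.error = attrs["error"]
            regions.append(region)
    return regions


def write_regions_bed(regions: Iterable[TsRegion], path: str) -> None:
    """Convenience BED export: chrom, start, end, name=TsType, score=rtf_exact."""
    with open(path, "w") as fh:
        for r in regions:
            score = _fmt_f(r.rtf_exact) if r.rtf_exact is not None else "0"
            fh.write(f"{r.contig}\t{r.span[0]}\t{r.span[1]}\t{r.ts_type}\t{score}\n")
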