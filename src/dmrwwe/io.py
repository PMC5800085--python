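"""Reading and writing methylation count files in multiple dialects.

Per-cytosine count files come in many near-identical tab-separated layouts.
Each supported layout is a :class:`FormatDialect` in a registry;
:func:`detect_format` identifies the dialect of a file from the column
count and per-column type signature of its first data line, and refuses to
guess when more than one dialect matches.

Registered dialects
-------------------
``generic``
    chrom, pos (1-based), strand, meth count, coverage.
``bismark_coverage``
    chrom, start, end (both 1-based, equal), %methylation, count
    methylated, count unmethylated.
``bismark_cytosine``
    chrom, pos (1-based), strand (+/-), count methylated, count
    unmethylated, context, trinucleotide.
``methylkit``
    site id ("chrom.pos"), chrom, pos (1-based), strand (F/R/+/-),
    coverage, freqC (%), freqT (%).
``bedmethyl``
    ENCODE bedMethyl: chrom, start (0-based), end, name, score, strand,
    thickStart, thickEnd, rgb, coverage, %methylation.

Internal coordinates are always 1-based inclusive; 0-based dialects are
converted on read and back on write.  Percent-based dialects convert to
counts via ``round(percent/100 * coverage)`` rounding half away from zero.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (DMR, SITE_COLUMNS, GeneInterval, MethylationDataError,
                         GroupedCounts, SiteTable, dmrs_to_frame)


class FormatError(ValueError):
    """Base class for input-format problems."""


class UnknownFormatError(FormatError):
    """No registered dialect matches the file."""


class AmbiguousFormatError(FormatError):
    """More than one registered dialect matches; pass the dialect explicitly."""


class ParseError(FormatError):
    """A line failed to parse under the chosen dialect."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        suffix = f" (line {line_number})" if line_number is not None else ""
        super().__init__(message + suffix)


class CoordinateError(FormatError):
    """A converted coordinate fell below 1."""


class EmptyIntersectionError(ValueError):
    """No genomic site is shared by every sample of both groups."""


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


_STRAND_MAP = {"+": "+", "-": "-", "F": "+", "R": "-", ".": "."}


@dataclass(frozen=True)
class FormatDialect:
    """One file layout: how to recognise, parse and write it.

    ``matches`` inspects the split fields of the first data line;
    ``parse_row`` returns ``(chrom, pos, strand, meth, coverage)`` in
    internal 1-based coordinates; ``format_row`` is its inverse.
    """

    name: str
    description: str
    n_columns: int
    counts_based: bool
    coordinate_base: int
    matches: Callable[[list[str]], bool]
    parse_row: Callable[[list[str]], tuple[str, int, str, int, int]]
    format_row: Callable[[str, int, str, int, int], list[str]]
    header: str | None = None

    def has_header_line(self, line: str) -> bool:
        if self.header is None:
            return False
        return line.strip().split("\t")[0] == self.header.split("\t")[0]


def _generic_parse(f):
    return f[0], int(f[1]), _STRAND_MAP[f[2]], int(f[3]), int(f[4])


def _bismark_cov_parse(f):
    meth, unmeth = int(f[4]), int(f[5])
    return f[0], int(f[1]), ".", meth, meth + unmeth


def _bismark_cov_format(chrom, pos, strand, meth, cov):
    pct = 100.0 * meth / cov if cov > 0 else 0.0
    return [chrom, str(pos), str(pos), repr(pct), str(meth), str(cov - meth)]


def _bismark_cyt_parse(f):
    meth, unmeth = int(f[3]), int(f[4])
    return f[0], int(f[1]), _STRAND_MAP[f[2]], meth, meth + unmeth


def _methylkit_parse(f):
    cov = int(f[4])
    meth = _round_half_away(float(f[5]) / 100.0 * cov)
    return f[1], int(f[2]), _STRAND_MAP[f[3]], meth, cov


def _methylkit_format(chrom, pos, strand, meth, cov):
    freq_c = 100.0 * meth / cov if cov > 0 else 0.0
    return [f"{chrom}.{pos}", chrom, str(pos),
            {"+": "F", "-": "R", ".": "F"}[strand],
            str(cov), repr(freq_c), repr(100.0 - freq_c)]


def _bedmethyl_parse(f):
    cov = int(f[9])
    meth = _round_half_away(float(f[10]) / 100.0 * cov)
    return f[0], int(f[1]) + 1, _STRAND_MAP[f[5]], meth, cov


def _bedmethyl_format(chrom, pos, strand, meth, cov):
    pct = 100.0 * meth / cov if cov > 0 else 0.0
    return [chrom, str(pos - 1), str(pos), ".", str(min(cov, 1000)),
            strand if strand in "+-" else ".",
            str(pos - 1), str(pos), "0,0,0", str(cov), repr(pct)]


DIALECTS: dict[str, FormatDialect] = {}


def register_dialect(dialect: FormatDialect) -> None:
    """Add a dialect to the registry (name must be unique)."""
    if dialect.name in DIALECTS:
        raise ValueError(f"dialect {dialect.name!r} already registered")
    DIALECTS[dialect.name] = dialect


register_dialect(FormatDialect(
    name="generic",
    description="chrom, pos (1-based), strand, meth count, coverage",
    n_columns=5, counts_based=True, coordinate_base=1,
    matches=lambda f: (len(f) == 5 and _is_int(f[1]) and f[2] in _STRAND_MAP
                       and _is_int(f[3]) and _is_int(f[4])),
    parse_row=_generic_parse,
    format_row=lambda c, p, s, m, v: [c, str(p), s, str(m), str(v)],
))

register_dialect(FormatDialect(
    name="bismark_coverage",
    description="chrom, start, end (1-based), %meth, count meth, count unmeth",
    n_columns=6, counts_based=True, coordinate_base=1,
    matches=lambda f: (len(f) == 6 and _is_int(f[1]) and _is_int(f[2])
                       and _is_float(f[3]) and _is_int(f[4]) and _is_int(f[5])),
    parse_row=_bismark_cov_parse,
    format_row=_bismark_cov_format,
))

register_dialect(FormatDialect(
    name="bismark_cytosine",
    description=("chrom, pos (1-based), strand, count meth, count unmeth, "
                 "context, trinucleotide"),
    n_columns=7, counts_based=True, coordinate_base=1,
    matches=lambda f: (len(f) == 7 and _is_int(f[1]) and f[2] in ("+", "-")
                       and _is_int(f[3]) and _is_int(f[4])
                       and not _is_float(f[5]) and not _is_float(f[6])),
    parse_row=_bismark_cyt_parse,
    format_row=lambda c, p, s, m, v: [c, str(p), s if s in "+-" else "+",
                                      str(m), str(v - m), "CpG", "CGN"],
))

register_dialect(FormatDialect(
    name="methylkit",
    description="id, chrom, pos (1-based), strand (F/R), coverage, freqC, freqT",
    n_columns=7, counts_based=False, coordinate_base=1,
    matches=lambda f: (len(f) == 7 and _is_int(f[2]) and f[3] in _STRAND_MAP
                       and _is_int(f[4]) and _is_float(f[5]) and _is_float(f[6])),
    parse_row=_methylkit_parse,
    format_row=_methylkit_format,
    header="chrBase\tchr\tbase\tstrand\tcoverage\tfreqC\tfreqT",
))

register_dialect(FormatDialect(
    name="bedmethyl",
    description="ENCODE bedMethyl (bed9+2, 0-based half-open)",
    n_columns=11, counts_based=False, coordinate_base=0,
    matches=lambda f: (len(f) == 11 and _is_int(f[1]) and _is_int(f[2])
                       and _is_int(f[9]) and _is_float(f[10])),
    parse_row=_bedmethyl_parse,
    format_row=_bedmethyl_format,
))


def _resolve_dialect(dialect) -> FormatDialect:
    if isinstance(dialect, FormatDialect):
        return dialect
    if dialect in DIALECTS:
        return DIALECTS[dialect]
    raise UnknownFormatError(f"unknown dialect {dialect!r}")


def detect_format(first_lines: Iterable[str]) -> FormatDialect:
    """Identify the dialect of a file from its leading raw lines.

    The first non-comment, non-header data line is split on tabs (falling
    back to any whitespace) and matched against every registered dialect's
    signature.  Exactly one dialect must match.
    """
    for raw in first_lines:
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith(("#", "track ", "browser ")):
            continue
        if any(d.has_header_line(line) for d in DIALECTS.values()):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        hits = [d for d in DIALECTS.values() if d.matches(fields)]
        if not hits:
            raise UnknownFormatError(
                f"no registered dialect matches a {len(fields)}-column line")
        if len(hits) > 1:
            names = ", ".join(d.name for d in hits)
            raise AmbiguousFormatError(
                f"line matches multiple dialects ({names}); "
                "pass the dialect explicitly")
        return hits[0]
    raise UnknownFormatError("no data line found")


def read_sample(path, dialect="auto", sample_id: str | None = None,
                context: str | None = None) -> SiteTable:
    """Read one sample's methylation counts into a :class:`SiteTable`.

    Parameters
    ----------
    path : str or os.PathLike
    dialect : "auto", dialect name, or FormatDialect
        With ``"auto"`` the dialect is detected from the first data line.
    sample_id : str, optional
        Defaults to the file's base name without extension.
    context : str, optional
        For dialects carrying a context column (bismark_cytosine), keep
        only sites of this context (e.g. ``"CpG"``).  Default: keep all.
    """
    path = os.fspath(path)
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    with open(path) as fh:
        lines = fh.readlines()
    if dialect == "auto":
        d = detect_format(lines)
    else:
        d = _resolve_dialect(dialect)

    rows = []
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith(("#", "track ", "browser ")):
            continue
        if d.has_header_line(line):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if not d.matches(fields):
            raise ParseError(
                f"line does not parse as dialect {d.name!r}", line_number=i)
        if context is not None and d.name == "bismark_cytosine" and fields[5] != context:
            continue
        try:
            chrom, pos, strand, meth, cov = d.parse_row(fields)
        except (ValueError, KeyError, IndexError) as exc:
            raise ParseError(f"bad field in dialect {d.name!r}: {exc}",
                             line_number=i) from exc
        if pos < 1:
            raise CoordinateError(
                f"position {pos} < 1 after coordinate conversion (line {i})")
        if meth < 0 or cov < 0 or meth > cov:
            raise ParseError(
                f"invalid counts meth={meth} coverage={cov}", line_number=i)
        rows.append((chrom, pos, strand, meth, cov))

    df = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
    if df.duplicated(["chrom", "pos"]).any():
        dup = df.loc[df.duplicated(["chrom", "pos"]), ["chrom", "pos"]].iloc[0]
        raise ParseError(f"duplicate position {dup.chrom}:{dup.pos}")
    return SiteTable(sample_id=sample_id, data=df)


def write_sample(table: SiteTable, path, dialect) -> None:
    """Write a :class:`SiteTable` in the given dialect (round-trippable)."""
    d = _resolve_dialect(dialect)
    with open(os.fspath(path), "w") as fh:
        if d.header is not None:
            fh.write(d.header + "\n")
        for chrom, pos, strand, meth, cov in table.data.itertuples(index=False):
            fh.write("\t".join(d.format_row(chrom, int(pos), strand,
                                            int(meth), int(cov))) + "\n")


def merge_cpg_strands(table: SiteTable) -> SiteTable:
    """Merge counts of CpG strand pairs onto the plus-strand cytosine.

    For every (+) site at position p with a (-) site at p+1 on the same
    chromosome, both counts are summed onto position p.  Unpaired sites
    pass through unchanged; tables without strand information are returned
    as-is.  Total methylated and total coverage counts are conserved.
    """
    df = table.data
    if not (df["strand"] == "-").any() or not (df["strand"] == "+").any():
        return table
    plus = df[df["strand"] == "+"]
    minus = df[df["strand"] == "-"]
    pairing = minus.merge(
        plus[["chrom", "pos"]].assign(pos=plus["pos"] + 1),
        on=["chrom", "pos"], how="inner")
    paired_minus_keys = set(zip(pairing["chrom"], pairing["pos"]))
    add = {(c, p - 1): (m, v) for c, p, _, m, v in pairing.itertuples(index=False)}

    out_rows = []
    for chrom, pos, strand, meth, cov in df.itertuples(index=False):
        if strand == "-" and (chrom, pos) in paired_minus_keys:
            continue
        if strand == "+" and (chrom, pos) in add:
            am, av = add[(chrom, pos)]
            out_rows.append((chrom, pos, "+", meth + am, cov + av))
        else:
            out_rows.append((chrom, pos, strand, meth, cov))
    return SiteTable(sample_id=table.sample_id,
                     data=pd.DataFrame(out_rows, columns=list(SITE_COLUMNS)))


def align_groups(group_a: Sequence[SiteTable], group_b: Sequence[SiteTable],
                 policy: str = "intersection") -> GroupedCounts:
    """Align two groups of samples into position-matched count matrices.

    The default (and only) policy keeps exactly the (chrom, pos) sites
    present in every sample of both groups; sites missing from any
    replicate are dropped, since missing nucleotides can introduce false
    positives downstream.
    """
    if policy != "intersection":
        raise ValueError(f"unsupported alignment policy {policy!r}")
    if not group_a or not group_b:
        raise ValueError("each group needs at least one sample")
    tables = list(group_a) + list(group_b)
    common = tables[0].site_index
    for t in tables[1:]:
        common = common.intersection(t.site_index)
    if len(common) == 0:
        raise EmptyIntersectionError("no genomic site shared by all samples")
    common = common.sortlevel([0, 1])[0]

    def matrices(tables):
        meth = np.empty((len(common), len(tables)), dtype=np.int64)
        cov = np.empty_like(meth)
        for j, t in enumerate(tables):
            sub = t.data.set_index(["chrom", "pos"]).loc[common]
            meth[:, j] = sub["meth"].to_numpy()
            cov[:, j] = sub["coverage"].to_numpy()
        return meth, cov

    meth_a, cov_a = matrices(list(group_a))
    meth_b, cov_b = matrices(list(group_b))
    chroms = common.get_level_values(0).to_numpy(dtype=object)
    pos = common.get_level_values(1).to_numpy(dtype=np.int64)
    return GroupedCounts(
        chrom=chroms, pos=pos,
        meth_a=meth_a, cov_a=cov_a, meth_b=meth_b, cov_b=cov_b,
        samples_a=tuple(t.sample_id for t in group_a),
        samples_b=tuple(t.sample_id for t in group_b),
    )


_DMR_TSV_COLUMNS = ["chrom", "start", "end", "n_cpn", "mean_a", "mean_b",
                    "diff", "p", "q", "direction"]


def write_dmrs(dmrs: Sequence[DMR], path, format: str = "tsv") -> None:
    """Write called DMRs as TSV (all fields) or BED (0-based half-open)."""
    fmt = format.lower()
    path = os.fspath(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_DMR_TSV_COLUMNS) + "\n")
            for d in dmrs:
                fh.write("\t".join([
                    d.chrom, str(d.start), str(d.end), str(d.n_cpn),
                    repr(d.mean_a), repr(d.mean_b), repr(d.diff),
                    repr(d.p), repr(d.q), d.direction]) + "\n")
    elif fmt == "bed":
        with open(path, "w") as fh:
            fh.write('track name="DMRs"\n')
            for d in dmrs:
                score = min(1000, int(round(abs(d.diff) * 1000)))
                fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t"
                         f"{d.direction}\t{score}\t.\n")
    else:
        raise ValueError(f"unknown DMR output format {format!r}")


def read_dmrs(path) -> list[DMR]:
    """Read back a TSV written by :func:`write_dmrs` (exact round-trip)."""
    dmrs: list[DMR] = []
    with open(os.fspath(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _DMR_TSV_COLUMNS:
            raise ParseError("not a DMR TSV file", line_number=1)
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            dmrs.append(DMR(
                chrom=f[0], start=int(f[1]), end=int(f[2]), n_cpn=int(f[3]),
                mean_a=float(f[4]), mean_b=float(f[5]), diff=float(f[6]),
                p=float(f[7]), q=float(f[8])))
    return dmrs


def read_genes(path) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based) or a header-ed 1-based TSV.

    BED columns: chrom, start, end[, name[, score[, strand]]].
    TSV (with a header line ``chrom start end name strand``): 1-based
    inclusive coordinates.
    """
    genes: list[GeneInterval] = []
    with open(os.fspath(path)) as fh:
        lines = [l.rstrip("\n") for l in fh
                 if l.strip() and not l.startswith(("#", "track", "browser"))]
    if not lines:
        return genes
    first = lines[0].split("\t") if "\t" in lines[0] else lines[0].split()
    header_tsv = first[:3] == ["chrom", "start", "end"]
    for i, line in enumerate(lines):
        if header_tsv and i == 0:
            continue
        f = line.split("\t") if "\t" in line else line.split()
        if header_tsv:
            chrom, start, end = f[0], int(f[1]), int(f[2])
        else:
            chrom, start, end = f[0], int(f[1]) + 1, int(f[2])
        name = f[3] if len(f) > 3 else f"feature_{i}"
        strand = "."
        if header_tsv and len(f) > 4:
            strand = f[4]
        elif not header_tsv and len(f) > 5:
            strand = f[5]
        genes.append(GeneInterval(chrom=chrom, start=start, end=end,
                                  name=name, strand=strand))
    return genes
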