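"""Readers and writers for the genomic file formats the toolkit touches.

Two formats are handled: the 10x-style fragments file (5 tab-separated
columns: chrom, start, end, cell barcode, read-pair support; no header,
leading ``#`` lines tolerated) and BED3/BED6 for peaks and TSS annotations.
All coordinates are 0-based half-open throughout the package; no module
ever exposes a 1-based position.

Fragment collections circulate in two interchangeable shapes: an iterable
of :class:`Fragment` records (the streaming surface) and a pandas
``DataFrame`` with columns :data:`FRAGMENT_COLUMNS` (the vectorised
surface). :func:`as_frame` converts either into the latter.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
import os
import re
from typing import IO, Iterable, Iterator, NamedTuple

import pandas as pd

from .errors import InputError, ParseError

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "support"]

#: plain ACGT barcode, optionally carrying a 10x GEM-group suffix like "-1"
_BARCODE_RE = re.compile(r"^[ACGT]+(-\d+)?$")
_STRICT_BARCODE_RE = re.compile(r"^[ACGT]+$")
_SUFFIX_RE = re.compile(r"-\d+$")

GZIP_MAGIC = b"\x1f\x8b"


class Fragment(NamedTuple):
    """One transposition-derived interval tagged with a cell barcode.

    ``start``/``end`` are 0-based half-open; ``support`` is the number of
    read pairs backing the fragment (>= 1).
    """

    chrom: str
    start: int
    end: int
    barcode: str
    support: int = 1


class GenomicInterval(NamedTuple):
    """A strand-less 0-based half-open interval (peak, window, ...)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."


class TssSite(NamedTuple):
    """A transcription start site: a single 0-based coordinate plus strand."""

    chrom: str
    position: int
    strand: str


def strip_barcode_suffix(barcode: str) -> str:
    """Drop a trailing GEM-group suffix (``-1``, ``-12``, ...) if present."""
    return _SUFFIX_RE.sub("", barcode)


def _is_gzip(path: str | os.PathLike) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


def open_text(path: str | os.PathLike) -> IO[str]:
    """Open a possibly-gzipped text file, sniffing gzip by magic bytes."""
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    if _is_gzip(path):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_fragment_line(line: str, lineno: int, allow_suffix: bool) -> Fragment:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise ParseError(f"line {lineno}: expected >=5 tab-separated fields, got {len(fields)}")
    chrom, start_s, end_s, barcode, support_s = fields[:5]
    try:
        start, end, support = int(start_s), int(end_s), int(support_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinate or support: {exc}") from None
    if not (0 <= start < end):
        raise ParseError(f"line {lineno}: require 0 <= start < end, got [{start}, {end})")
    if support < 1:
        raise ParseError(f"line {lineno}: support must be >= 1, got {support}")
    pattern = _BARCODE_RE if allow_suffix else _STRICT_BARCODE_RE
    if not pattern.match(barcode):
        raise ParseError(f"line {lineno}: malformed cell barcode {barcode!r}")
    return Fragment(chrom, start, end, barcode, support)


def read_fragments(
    path: str | os.PathLike,
    validate: bool = True,
    allow_suffix: bool = True,
) -> Iterator[Fragment]:
    """Stream fragments from a fragments.tsv(.gz) file in file order.

    With ``validate=True`` a malformed line raises :class:`ParseError`
    naming the line number; with ``validate=False`` malformed lines are
    skipped and their count reported through logging.
    """
    skipped = 0
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            try:
                yield _parse_fragment_line(line, lineno, allow_suffix)
            except ParseError:
                if validate:
                    raise
                skipped += 1
    if skipped:
        logger.warning("skipped %d malformed fragment lines in %s", skipped, path)


def read_fragments_frame(
    path: str | os.PathLike,
    validate: bool = True,
    allow_suffix: bool = True,
) -> pd.DataFrame:
    """Read a whole fragments file into a DataFrame (vectorised path)."""
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    compression = "gzip" if _is_gzip(path) else None
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=range(5),
            names=FRAGMENT_COLUMNS,
            dtype={"chrom": str, "barcode": str},
            compression=compression,
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    if validate and len(df):
        for col in ("start", "end", "support"):
            if not pd.api.types.is_integer_dtype(df[col]):
                raise ParseError(f"{path}: non-integer values in column {col!r}")
        bad = (df["start"] < 0) | (df["start"] >= df["end"]) | (df["support"] < 1)
        if bad.any():
            raise ParseError(f"{path}: {int(bad.sum())} fragments violate coordinate invariants")
        pattern = _BARCODE_RE if allow_suffix else _STRICT_BARCODE_RE
        uniq = df["barcode"].unique()
        bad_bc = [b for b in uniq if not pattern.match(b)]
        if bad_bc:
            raise ParseError(f"{path}: malformed cell barcode {bad_bc[0]!r}")
    return df


def as_frame(fragments: Iterable[Fragment] | pd.DataFrame) -> pd.DataFrame:
    """Coerce a fragment stream or DataFrame to the canonical frame shape."""
    if isinstance(fragments, pd.DataFrame):
        missing = [c for c in FRAGMENT_COLUMNS if c not in fragments.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns {missing}")
        return fragments
    return pd.DataFrame.from_records(
        list(fragments), columns=FRAGMENT_COLUMNS
    ).astype({"start": "int64", "end": "int64", "support": "int64"})


def iter_fragments(fragments: Iterable[Fragment] | pd.DataFrame) -> Iterator[Fragment]:
    """Iterate any fragment collection as :class:`Fragment` records."""
    if isinstance(fragments, pd.DataFrame):
        for row in fragments[FRAGMENT_COLUMNS].itertuples(index=False):
            yield Fragment(str(row.chrom), int(row.start), int(row.end), str(row.barcode), int(row.support))
    else:
        yield from fragments


def write_fragments(
    fragments: Iterable[Fragment] | pd.DataFrame,
    path: str | os.PathLike,
    compress: bool = False,
) -> int:
    """Write fragments as a 5-column fragments.tsv, optionally gzipped.

    Records are written exactly in the order provided (sorting is the
    caller's concern). Returns the number of records written. Gzip output
    is written with a zeroed mtime so identical inputs give byte-identical
    files.
    """
    df = as_frame(fragments)
    n = len(df)
    if compress:
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as gz:
                with _io.TextIOWrapper(gz, encoding="utf-8", newline="") as text:
                    df.to_csv(text, sep="\t", header=False, index=False)
    else:
        df.to_csv(path, sep="\t", header=False, index=False)
    return n


def read_bed(path: str | os.PathLike, min_columns: int = 3) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into sorted :class:`GenomicInterval` records.

    ``min_columns`` must be 3 or 6; with 6, the name and strand columns are
    parsed (strand used downstream for TSS orientation). Intervals are
    returned sorted by (chrom, start, end).
    """
    if min_columns not in (3, 6):
        raise ValueError("min_columns must be 3 or 6")
    out: list[GenomicInterval] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < min_columns:
                raise ParseError(
                    f"line {lineno}: expected >={min_columns} BED columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer BED coordinate: {exc}") from None
            if not (0 <= start < end):
                raise ParseError(f"line {lineno}: require 0 <= start < end, got [{start}, {end})")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            if min_columns == 6 and strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
            out.append(GenomicInterval(chrom, start, end, name, strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def read_tss(path: str | os.PathLike) -> list[TssSite]:
    """Read TSS anchor points from a BED6 file.

    The TSS coordinate is the interval start for "+" entries and ``end - 1``
    for "-" entries (for the common 1-bp TSS BED the two coincide).
    """
    sites = []
    for iv in read_bed(path, min_columns=6):
        pos = iv.start if iv.strand == "+" else iv.end - 1
        sites.append(TssSite(iv.chrom, pos, iv.strand))
    return sites


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> int:
    """Write intervals as BED; emits 6 columns when any strand is set."""
    ivs = list(intervals)
    stranded = any(iv.strand in ("+", "-") for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if stranded:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return len(ivs)
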