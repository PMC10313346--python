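"""Reading and writing chromatin-contact records.

Supported dialects: the 4DN ``.pairs`` text format (optionally gzip)
and HiC-Pro's ``allValidPairs``.  Internally every record is a
:class:`ContactRecord` with 0-based positions; readers and the writer
do the 1-based translation at the file boundary.  Output is always
4DN pairs, upper-triangular under the chromosome order given by the
target chromosome-sizes file (never lexicographic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import IO, Iterable, Iterator, Mapping, Sequence

from ._fileutil import PathOrHandle, open_text
from .errors import PairsFormatError, SortOrderError

__all__ = [
    "ContactRecord",
    "ChromOrder",
    "PairsHeader",
    "read_pairs",
    "read_validpairs",
    "canonicalize",
    "write_pairs",
]

PAIRS_MAGIC = "## pairs format v1.0"
_STRANDS = frozenset("+-.")


@dataclass(frozen=True)
class ContactRecord:
    """One (possibly weighted) chromatin contact.

    ``weight`` is 1 for read-level pairs and the bin-pair count for
    contacts derived from a binned matrix.
    """

    read_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand1: str = "."
    strand2: str = "."
    pair_type: str = "."
    weight: float = 1.0


class ChromOrder:
    """Target-assembly chromosome names in file order, with lengths."""

    def __init__(self, names_sizes: Iterable[tuple[str, int]]):
        self.names: list[str] = []
        self.sizes: dict[str, int] = {}
        for name, size in names_sizes:
            if name in self.sizes:
                raise ValueError(f"duplicate chromosome {name!r} in sizes table")
            if size <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")
            self.names.append(name)
            self.sizes[name] = int(size)
        self._rank = {name: i for i, name in enumerate(self.names)}

    @classmethod
    def from_file(cls, path: PathOrHandle) -> "ChromOrder":
        pairs = []
        with open_text(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise PairsFormatError(
                        f"sizes line {lineno}: expected 'name<TAB>length'"
                    )
                try:
                    pairs.append((fields[0], int(fields[1])))
                except ValueError as exc:
                    raise PairsFormatError(
                        f"sizes line {lineno}: non-numeric length"
                    ) from exc
        return cls(pairs)

    def rank(self, name: str) -> int:
        return self._rank[name]

    def size(self, name: str) -> int:
        return self.sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class PairsHeader:
    """Parsed ``#``-prefixed header of a 4DN pairs file."""

    lines: list[str]
    columns: list[str] | None = None

    @property
    def has_magic(self) -> bool:
        return bool(self.lines) and self.lines[0].startswith("## pairs format")


_DEFAULT_COLUMNS = ["readID", "chr1", "pos1", "chr2", "pos2", "strand1", "strand2"]


def read_pairs(source: PathOrHandle) -> tuple[PairsHeader, Iterator[ContactRecord]]:
    """Read a 4DN pairs file; returns the parsed header and a lazy record iterator.

    Missing optional columns default to ``'.'`` and weight 1.  A file
    without the ``## pairs format`` magic line is parsed anyway, with a
    warning.  Body positions shift from the file's 1-based convention
    to internal 0-based.
    """

    def records() -> Iterator[ContactRecord]:
        with open_text(source) as fh:
            header_lines: list[str] = []
            columns: list[str] | None = None
            body_started = False
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not body_started and line.startswith("#"):
                    header_lines.append(line)
                    if line.startswith("#columns:"):
                        columns = line.split(":", 1)[1].split()
                    continue
                if not body_started:
                    body_started = True
                    header.lines = header_lines
                    header.columns = columns
                    if not header.has_magic:
                        warnings.warn(
                            "pairs file lacks the '## pairs format' magic line; "
                            "parsing anyway",
                            stacklevel=2,
                        )
                    yield _HEADER_DONE  # type: ignore[misc]
                if not line:
                    continue
                yield _parse_pairs_line(line, lineno, columns)
            if not body_started:
                header.lines = header_lines
                header.columns = columns
                yield _HEADER_DONE  # type: ignore[misc]

    header = PairsHeader(lines=[])
    gen = records()
    # advance through the header so callers get it eagerly parsed
    for item in gen:
        if item is _HEADER_DONE:
            break
    return header, gen


_HEADER_DONE = object()


def _parse_pairs_line(
    line: str, lineno: int, columns: Sequence[str] | None
) -> ContactRecord:
    fields = line.split("\t")
    if len(fields) == 1:
        fields = line.split()
    if len(fields) < 7:
        raise PairsFormatError(
            f"line {lineno}: pairs body line has {len(fields)} columns, expected >= 7"
        )
    cols = list(columns) if columns else list(_DEFAULT_COLUMNS)

    def col(name: str, default_idx: int) -> int:
        try:
            return cols.index(name)
        except ValueError:
            return default_idx

    try:
        pos1 = int(fields[col("pos1", 2)])
        pos2 = int(fields[col("pos2", 4)])
    except ValueError as exc:
        raise PairsFormatError(f"line {lineno}: non-numeric position") from exc
    if pos1 < 1 or pos2 < 1:
        raise PairsFormatError(f"line {lineno}: positions are 1-based; got < 1")

    def opt(name: str, idx: int) -> str:
        i = col(name, idx)
        return fields[i] if i < len(fields) else "."

    weight = 1.0
    if columns and "count" in columns:
        i = columns.index("count")
        if i < len(fields):
            weight = float(fields[i])
    return ContactRecord(
        read_id=fields[col("readID", 0)],
        chrom1=fields[col("chr1", 1)],
        pos1=pos1 - 1,
        chrom2=fields[col("chr2", 3)],
        pos2=pos2 - 1,
        strand1=opt("strand1", 5),
        strand2=opt("strand2", 6),
        pair_type=opt("pair_type", 7),
        weight=weight,
    )


def read_validpairs(source: PathOrHandle) -> Iterator[ContactRecord]:
    """Read HiC-Pro ``allValidPairs``: readID chr1 pos1 strand1 chr2 pos2 strand2 …

    Note the strand precedes the mate's chromosome, unlike pairs.
    Strand fields are validated so a pairs-format file fed here fails
    on its first body line instead of silently mis-parsing.
    """
    with open_text(source) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 7:
                raise PairsFormatError(
                    f"line {lineno}: allValidPairs line has {len(fields)} columns, "
                    "expected >= 7"
                )
            read_id, chrom1, pos1, strand1, chrom2, pos2, strand2 = fields[:7]
            if strand1 not in _STRANDS or strand2 not in _STRANDS:
                raise PairsFormatError(
                    f"line {lineno}: bad strand field "
                    f"({strand1!r}/{strand2!r}); is this really allValidPairs?"
                )
            try:
                p1, p2 = int(pos1), int(pos2)
            except ValueError as exc:
                raise PairsFormatError(f"line {lineno}: non-numeric position") from exc
            if p1 < 1 or p2 < 1:
                raise PairsFormatError(f"line {lineno}: positions are 1-based; got < 1")
            yield ContactRecord(
                read_id=read_id,
                chrom1=chrom1,
                pos1=p1 - 1,
                chrom2=chrom2,
                pos2=p2 - 1,
                strand1=strand1,
                strand2=strand2,
                pair_type=".",
                weight=1.0,
            )


def canonicalize(record: ContactRecord, order: ChromOrder) -> ContactRecord:
    """Put a record in upper-triangular form under ``order``.

    If side 2 precedes side 1 the sides are swapped wholesale (chrom,
    position and strand together).  Idempotent.
    """
    key1 = (order.rank(record.chrom1), record.pos1)
    key2 = (order.rank(record.chrom2), record.pos2)
    if key2 < key1:
        return replace(
            record,
            chrom1=record.chrom2,
            pos1=record.pos2,
            strand1=record.strand2,
            chrom2=record.chrom1,
            pos2=record.pos1,
            strand2=record.strand1,
        )
    return record


def _sort_key(record: ContactRecord, order: ChromOrder):
    return (
        order.rank(record.chrom1),
        order.rank(record.chrom2),
        record.pos1,
        record.pos2,
        record.read_id,
    )


def format_weight(weight: float) -> str:
    return str(int(weight)) if float(weight).is_integer() else repr(weight)


def write_pairs(
    records: Iterable[ContactRecord],
    order: ChromOrder,
    stream: PathOrHandle,
    header_meta: Mapping[str, str] | None = None,
    include_weight: bool = False,
    check_sorted: bool = True,
) -> int:
    """Write records as a 4DN pairs file; returns the number written.

    Records must already be canonical and sorted by
    (chrom1, chrom2, pos1, pos2) under ``order`` — a violation raises
    :class:`SortOrderError` rather than producing an unsorted file.
    With ``include_weight`` a trailing ``count`` column carries the
    record weights (used for matrix-derived contacts).
    """
    columns = list(_DEFAULT_COLUMNS) + ["pair_type"] + (["count"] if include_weight else [])
    n = 0
    with open_text(stream, "w") as fh:
        fh.write(PAIRS_MAGIC + "\n")
        fh.write(
            "#sorted: chr1-chr2-pos1-pos2\n" if check_sorted else "#sorted: none\n"
        )
        fh.write("#shape: upper triangle\n")
        for name in order.names:
            fh.write(f"#chromsize: {name} {order.sizes[name]}\n")
        for key, value in (header_meta or {}).items():
            fh.write(f"#{key}: {value}\n")
        fh.write("#columns: " + " ".join(columns) + "\n")
        prev_key = None
        for record in records:
            if record.chrom1 not in order or record.chrom2 not in order:
                raise SortOrderError(
                    f"record {record.read_id!r}: chromosome "
                    f"{record.chrom1!r}/{record.chrom2!r} not in the chromosome order"
                )
            if check_sorted:
                key = _sort_key(record, order)
                if prev_key is not None and key < prev_key:
                    raise SortOrderError(
                        f"record {record.read_id!r} out of sort order"
                    )
                prev_key = key
            fields = [
                record.read_id,
                record.chrom1,
                str(record.pos1 + 1),
                record.chrom2,
                str(record.pos2 + 1),
                record.strand1,
                record.strand2,
                record.pair_type,
            ]
            if include_weight:
                fields.append(format_weight(record.weight))
            fh.write("\t".join(fields) + "\n")
            n += 1
    return n
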