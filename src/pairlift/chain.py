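"""UCSC chain-file parsing and single-base liftover.

A chain file describes a pairwise alignment between two genome
assemblies as chains of ungapped blocks.  In UCSC jargon the "target"
(``t``) side is the assembly the chain file is *from* and the "query"
(``q``) side the assembly it maps *to*; here we call them source and
target assembly respectively, but keep the ``t``/``q`` field names so
the header fields line up with the format documentation.

Coordinates are 0-based half-open throughout.  ``q`` coordinates are
stored in ``q_strand`` orientation, exactly as the file records them;
:func:`lift_point` converts minus-strand hits back to plus-strand
target coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from ._fileutil import PathOrHandle, open_text
from .errors import ChainConsistencyError, ChainFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "ChainHeader",
    "ChainBlock",
    "Chain",
    "LiftedPoint",
    "LiftFailure",
    "LiftoverIndex",
    "parse_chain",
    "build_index",
    "lift_point",
    "invert_chains",
    "chains_to_text",
]


@dataclass(frozen=True)
class ChainHeader:
    """The 13-field ``chain`` header line."""

    score: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped aligned segment, with absolute coordinates.

    ``q_lo`` is the target start in ``q_strand`` orientation; the block
    covers ``q_lo .. q_lo + (t_hi - t_lo)`` on that strand.
    """

    t_lo: int
    t_hi: int
    q_lo: int
    q_strand: str
    q_name: str
    q_size: int
    score: int
    chain_id: int


Chain = tuple[ChainHeader, list[ChainBlock]]


@dataclass(frozen=True)
class LiftedPoint:
    """A source base resolved to the target assembly plus strand."""

    chrom: str
    pos: int
    inverted: bool
    score: int


class LiftFailure(Enum):
    """Why a base could not be lifted."""

    UNMAPPED = "unmapped"
    AMBIGUOUS = "ambiguous"


UNMAPPED = LiftFailure.UNMAPPED
AMBIGUOUS = LiftFailure.AMBIGUOUS


def _parse_header(fields: list[str], lineno: int) -> ChainHeader:
    if len(fields) != 13:
        raise ChainFormatError(
            f"line {lineno}: chain header has {len(fields)} fields, expected 13"
        )
    try:
        header = ChainHeader(
            score=int(fields[1]),
            t_name=fields[2],
            t_size=int(fields[3]),
            t_strand=fields[4],
            t_start=int(fields[5]),
            t_end=int(fields[6]),
            q_name=fields[7],
            q_size=int(fields[8]),
            q_strand=fields[9],
            q_start=int(fields[10]),
            q_end=int(fields[11]),
            chain_id=int(fields[12]),
        )
    except ValueError as exc:
        raise ChainFormatError(f"line {lineno}: non-numeric chain header field: {exc}") from exc
    if header.score < 0:
        raise ChainFormatError(f"line {lineno}: negative chain score")
    if header.t_strand != "+":
        raise ChainFormatError(
            f"line {lineno}: t_strand {header.t_strand!r} unsupported "
            "(UCSC chains always use '+' on the source side)"
        )
    if header.q_strand not in ("+", "-"):
        raise ChainFormatError(f"line {lineno}: bad q_strand {header.q_strand!r}")
    if not (0 <= header.t_start < header.t_end <= header.t_size):
        raise ChainFormatError(f"line {lineno}: chain {header.chain_id}: bad t interval")
    if not (0 <= header.q_start < header.q_end <= header.q_size):
        raise ChainFormatError(f"line {lineno}: chain {header.chain_id}: bad q interval")
    return header


def parse_chain(source: PathOrHandle) -> list[Chain]:
    """Parse a UCSC chain file (plain or gzip) into chains of blocks.

    Each data line ``size [dt dq]`` advances the source cursor by
    ``size + dt`` and the target cursor by ``size + dq``; the final
    line of a chain carries ``size`` only.  The cursor walk must
    reconcile exactly with the header's ``t_end``/``q_end``.
    """
    chains: list[Chain] = []
    with open_text(source) as fh:
        header: ChainHeader | None = None
        blocks: list[ChainBlock] = []
        t_cur = q_cur = 0
        chain_done = False  # saw the 1-field terminal line

        def finish(lineno: int) -> None:
            nonlocal header, blocks, chain_done
            if header is None:
                return
            if not chain_done:
                raise ChainFormatError(
                    f"line {lineno}: chain {header.chain_id} has no terminal data line"
                )
            if t_cur != header.t_end or q_cur != header.q_end:
                raise ChainConsistencyError(
                    f"chain {header.chain_id}: data lines sum to t={t_cur}, q={q_cur} "
                    f"but header declares t_end={header.t_end}, q_end={header.q_end}"
                )
            chains.append((header, blocks))
            header, blocks, chain_done = None, [], False

        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                finish(lineno)
                continue
            fields = line.split()
            if fields[0] == "chain":
                finish(lineno)
                header = _parse_header(fields, lineno)
                t_cur, q_cur = header.t_start, header.q_start
                continue
            if header is None:
                raise ChainFormatError(f"line {lineno}: data line outside any chain")
            if chain_done:
                raise ChainFormatError(
                    f"line {lineno}: data after the terminal line of chain {header.chain_id}"
                )
            if len(fields) not in (1, 3):
                raise ChainFormatError(
                    f"line {lineno}: data line has {len(fields)} fields, expected 1 or 3"
                )
            try:
                size = int(fields[0])
                dt = int(fields[1]) if len(fields) == 3 else 0
                dq = int(fields[2]) if len(fields) == 3 else 0
            except ValueError as exc:
                raise ChainFormatError(f"line {lineno}: non-numeric data field") from exc
            if size < 0 or dt < 0 or dq < 0:
                raise ChainFormatError(f"line {lineno}: negative size/gap")
            blocks.append(
                ChainBlock(
                    t_lo=t_cur,
                    t_hi=t_cur + size,
                    q_lo=q_cur,
                    q_strand=header.q_strand,
                    q_name=header.q_name,
                    q_size=header.q_size,
                    score=header.score,
                    chain_id=header.chain_id,
                )
            )
            t_cur += size + dt
            q_cur += size + dq
            if t_cur > header.t_end or q_cur > header.q_end:
                raise ChainConsistencyError(
                    f"line {lineno}: chain {header.chain_id} cursor overruns its header "
                    f"(t={t_cur}>{header.t_end} or q={q_cur}>{header.q_end})"
                )
            if len(fields) == 1:
                chain_done = True
        finish(lineno + 1)
    return chains


@dataclass
class LiftoverIndex:
    """Per-source-chromosome interval index over chain blocks."""

    trees: dict[str, IntervalTree]
    source_chroms: set[str]
    target_chroms: set[str]
    target_sizes: dict[str, int]
    skipped_chains: int = 0


def build_index(
    chains: Iterable[Chain],
    min_score: int = 0,
    target_sizes: Mapping[str, int] | None = None,
) -> LiftoverIndex:
    """Index chain blocks for point queries.

    Chains scoring below ``min_score`` are excluded.  When
    ``target_sizes`` is given, chains whose target chromosome is absent
    from it are skipped with a warning (this is how users restrict
    output to canonical chromosomes).  Blocks from distinct chains may
    overlap on the source axis; :func:`lift_point` resolves overlaps.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    trees: dict[str, IntervalTree] = {}
    source_chroms: set[str] = set()
    target_chroms: set[str] = set()
    sizes: dict[str, int] = dict(target_sizes) if target_sizes is not None else {}
    skipped = 0
    for header, blocks in chains:
        if header.score < min_score:
            continue
        if target_sizes is not None and header.q_name not in target_sizes:
            logger.warning(
                "chain %d skipped: target chromosome %r not in the sizes table",
                header.chain_id,
                header.q_name,
            )
            skipped += 1
            continue
        tree = trees.setdefault(header.t_name, IntervalTree())
        for block in blocks:
            if block.t_hi > block.t_lo:  # zero-length blocks carry no bases
                tree.addi(block.t_lo, block.t_hi, block)
        source_chroms.add(header.t_name)
        target_chroms.add(header.q_name)
        if target_sizes is None:
            sizes.setdefault(header.q_name, header.q_size)
    return LiftoverIndex(
        trees=trees,
        source_chroms=source_chroms,
        target_chroms=target_chroms,
        target_sizes=sizes,
        skipped_chains=skipped,
    )


def lift_point(index: LiftoverIndex, chrom: str, pos: int) -> LiftedPoint | LiftFailure:
    """Resolve one source base to the target assembly.

    Overlapping blocks from different chains resolve to the highest
    chain score; an exact score tie is reported as
    :data:`LiftFailure.AMBIGUOUS`.  A chromosome absent from the index
    is simply unmapped — assemblies differ in chromosome sets.
    """
    if pos < 0:
        raise ValueError("pos must be >= 0")
    tree = index.trees.get(chrom)
    if tree is None:
        return UNMAPPED
    hits = tree[pos]
    if not hits:
        return UNMAPPED
    blocks = [iv.data for iv in hits]
    best = max(b.score for b in blocks)
    top = [b for b in blocks if b.score == best]
    if len(top) > 1 and len({b.chain_id for b in top}) > 1:
        return AMBIGUOUS
    block = top[0]
    offset = pos - block.t_lo
    if block.q_strand == "+":
        return LiftedPoint(block.q_name, block.q_lo + offset, inverted=False, score=block.score)
    # minus-strand chains record q in reverse orientation
    q_plus = block.q_size - 1 - (block.q_lo + offset)
    return LiftedPoint(block.q_name, q_plus, inverted=True, score=block.score)


def _invert_block(block: ChainBlock, header: ChainHeader) -> ChainBlock:
    length = block.t_hi - block.t_lo
    if block.q_strand == "+":
        return ChainBlock(
            t_lo=block.q_lo,
            t_hi=block.q_lo + length,
            q_lo=block.t_lo,
            q_strand="+",
            q_name=header.t_name,
            q_size=header.t_size,
            score=block.score,
            chain_id=block.chain_id,
        )
    # forward: t_lo+i -> q_size-1-(q_lo+i).  The inverse maps the plus-strand
    # interval [q_size-q_lo-length, q_size-q_lo) back through another '-' chain
    # with q_lo' = t_size - t_hi.
    return ChainBlock(
        t_lo=block.q_size - block.q_lo - length,
        t_hi=block.q_size - block.q_lo,
        q_lo=header.t_size - block.t_hi,
        q_strand="-",
        q_name=header.t_name,
        q_size=header.t_size,
        score=block.score,
        chain_id=block.chain_id,
    )


def invert_chains(chains: Iterable[Chain]) -> list[Chain]:
    """Swap the source and target sides of every chain.

    For every base the forward index lifts uniquely, the inverted
    index lifts the image back to that base; minus-strand chains stay
    minus-strand (inversion is an involution).
    """
    inverted: list[Chain] = []
    for header, blocks in chains:
        new_blocks = sorted(
            (_invert_block(b, header) for b in blocks), key=lambda b: b.t_lo
        )
        if not new_blocks:
            continue
        first, last = new_blocks[0], new_blocks[-1]
        new_header = ChainHeader(
            score=header.score,
            t_name=header.q_name,
            t_size=header.q_size,
            t_strand="+",
            t_start=first.t_lo,
            t_end=last.t_hi,
            q_name=header.t_name,
            q_size=header.t_size,
            q_strand=header.q_strand,
            q_start=first.q_lo,
            q_end=last.q_lo + (last.t_hi - last.t_lo),
            chain_id=header.chain_id,
        )
        inverted.append((new_header, new_blocks))
    return inverted


def chains_to_text(chains: Sequence[Chain]) -> str:
    """Serialize chains back to UCSC chain text (inverse of parsing)."""
    out: list[str] = []
    for header, blocks in chains:
        out.append(
            "chain {score} {t_name} {t_size} {t_strand} {t_start} {t_end} "
            "{q_name} {q_size} {q_strand} {q_start} {q_end} {chain_id}".format(
                **vars(header)
            )
        )
        for i, block in enumerate(blocks):
            size = block.t_hi - block.t_lo
            if i + 1 < len(blocks):
                nxt = blocks[i + 1]
                dt = nxt.t_lo - block.t_hi
                dq = nxt.q_lo - (block.q_lo + size)
                out.append(f"{size} {dt} {dq}")
            else:
                out.append(f"{size}")
        out.append("")
    return "\n".join(out) + "\n"
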