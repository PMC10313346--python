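"""Streaming conversion pipeline.

Reads contacts, lifts both anchors through the chain index, filters,
canonicalizes, sorts externally and writes a sorted 4DN pairs file on
the target assembly, plus a conversion report.  Peak memory is a
function of ``chunk_size`` only: sorted chunks spill to temporary
files and are k-way merged, so running time grows linearly with the
number of contacts while memory stays flat.  The pipeline is fully
deterministic — repeated runs on identical input are byte-identical,
and the chunk size never changes the output bytes (the merge key ends
with the read ID, making the order total).
"""

from __future__ import annotations

import heapq
import logging
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Iterator

from ._fileutil import PathOrHandle, open_text
from .chain import LiftedPoint, LiftFailure, LiftoverIndex, build_index, lift_point, parse_chain
from .contacts import (
    ChromOrder,
    ContactRecord,
    canonicalize,
    read_pairs,
    read_validpairs,
    write_pairs,
)
from .errors import ParameterError
from .matrix import pixels_to_contacts, read_bins, read_pixels

logger = logging.getLogger(__name__)

__all__ = [
    "DropReason",
    "ConversionStats",
    "PipelineConfig",
    "lift_contact",
    "run_conversion",
    "summarize",
    "parse_report",
]


class DropReason(Enum):
    UNMAPPED_SIDE1 = "unmapped_side1"
    UNMAPPED_SIDE2 = "unmapped_side2"
    BOTH_UNMAPPED = "both_unmapped"
    AMBIGUOUS = "ambiguous"
    OFFTARGET_CHROM = "offtarget_chrom"


@dataclass
class ConversionStats:
    """Accounting of lifted vs dropped contacts.

    Invariant (asserted by :meth:`check`): total = lifted + Σ dropped,
    and total weight = lifted weight + dropped weight, exactly.
    Per-target-chromosome counts are lifted *anchors* (two per contact).
    """

    total: int = 0
    lifted: int = 0
    dropped: dict[DropReason, int] = field(
        default_factory=lambda: {reason: 0 for reason in DropReason}
    )
    total_weight: float = 0.0
    lifted_weight: float = 0.0
    dropped_weight: float = 0.0
    lifted_anchors_by_chrom: dict[str, int] = field(default_factory=dict)

    def record_lift(self, record: ContactRecord) -> None:
        self.lifted += 1
        self.lifted_weight += record.weight
        for chrom in (record.chrom1, record.chrom2):
            self.lifted_anchors_by_chrom[chrom] = (
                self.lifted_anchors_by_chrom.get(chrom, 0) + 1
            )

    def record_drop(self, reason: DropReason, weight: float) -> None:
        self.dropped[reason] += 1
        self.dropped_weight += weight

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())

    @property
    def percent_lifted(self) -> float:
        return 100.0 * self.lifted / self.total if self.total else 100.0

    def check(self) -> None:
        assert self.total == self.lifted + self.total_dropped, "count conservation violated"
        assert self.total_weight == self.lifted_weight + self.dropped_weight, (
            "weight conservation violated"
        )


@dataclass
class PipelineConfig:
    """Everything one conversion run needs.  The pipeline is seedless."""

    input_path: str
    input_format: str  # 'pairs' | 'validpairs' | 'bins+pixels'
    chain_path: str
    target_sizes_path: str
    output_path: str
    pixels_path: str | None = None  # required for bins+pixels
    min_score: int = 0
    chunk_size: int = 1_000_000
    tmp_dir: str | None = None
    report_path: str | None = None
    command: str | None = None

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ParameterError("chunk_size must be >= 1")
        if self.input_format not in ("pairs", "validpairs", "bins+pixels"):
            raise ParameterError(f"unknown input format {self.input_format!r}")
        if self.input_format == "bins+pixels" and not self.pixels_path:
            raise ParameterError("bins+pixels input needs a pixels path")


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+"}.get(strand, strand)


def lift_contact(
    index: LiftoverIndex, record: ContactRecord, order: ChromOrder
) -> tuple[ContactRecord | None, DropReason | None]:
    """Lift both anchors of one contact.

    Success requires both anchors to resolve uniquely to chromosomes
    present in the target sizes table.  An anchor resolved through a
    minus-strand chain block has its strand flipped ('.' stays '.').
    Unmapped outranks ambiguous when both failure modes occur.
    """
    r1 = lift_point(index, record.chrom1, record.pos1)
    r2 = lift_point(index, record.chrom2, record.pos2)
    u1 = r1 is LiftFailure.UNMAPPED
    u2 = r2 is LiftFailure.UNMAPPED
    if u1 and u2:
        return None, DropReason.BOTH_UNMAPPED
    if u1:
        return None, DropReason.UNMAPPED_SIDE1
    if u2:
        return None, DropReason.UNMAPPED_SIDE2
    if r1 is LiftFailure.AMBIGUOUS or r2 is LiftFailure.AMBIGUOUS:
        return None, DropReason.AMBIGUOUS
    assert isinstance(r1, LiftedPoint) and isinstance(r2, LiftedPoint)
    if r1.chrom not in order or r2.chrom not in order:
        return None, DropReason.OFFTARGET_CHROM
    lifted = ContactRecord(
        read_id=record.read_id,
        chrom1=r1.chrom,
        pos1=r1.pos,
        chrom2=r2.chrom,
        pos2=r2.pos,
        strand1=_flip(record.strand1) if r1.inverted else record.strand1,
        strand2=_flip(record.strand2) if r2.inverted else record.strand2,
        pair_type=record.pair_type,
        weight=record.weight,
    )
    return lifted, None


def _open_reader(config: PipelineConfig) -> Iterator[ContactRecord]:
    if config.input_format == "pairs":
        _, records = read_pairs(config.input_path)
        return records
    if config.input_format == "validpairs":
        return read_validpairs(config.input_path)
    bins = read_bins(config.input_path)
    return pixels_to_contacts(bins, read_pixels(config.pixels_path))


def _encode(record: ContactRecord, order: ChromOrder) -> str:
    return "\t".join(
        (
            str(order.rank(record.chrom1)),
            str(order.rank(record.chrom2)),
            str(record.pos1),
            str(record.pos2),
            record.read_id,
            record.strand1,
            record.strand2,
            record.pair_type,
            repr(record.weight),
        )
    )


def _decode(line: str, order: ChromOrder) -> ContactRecord:
    c1, c2, p1, p2, rid, s1, s2, ptype, w = line.rstrip("\n").split("\t")
    return ContactRecord(
        read_id=rid,
        chrom1=order.names[int(c1)],
        pos1=int(p1),
        chrom2=order.names[int(c2)],
        pos2=int(p2),
        strand1=s1,
        strand2=s2,
        pair_type=ptype,
        weight=float(w),
    )


def _merge_key(line: str):
    c1, c2, p1, p2, rest = line.split("\t", 4)
    # read_id (prefix of `rest`) is the final tiebreaker; comparing the
    # whole remainder keeps the order total even for duplicate IDs.
    # rstrip: spill lines carry a newline, in-memory lines do not.
    return (int(c1), int(c2), int(p1), int(p2), rest.rstrip("\n"))


def run_conversion(config: PipelineConfig) -> ConversionStats:
    """Run one streaming conversion; returns the final statistics.

    Output is a sorted, upper-triangular 4DN pairs file on the target
    assembly.  Sorted chunks of at most ``chunk_size`` records spill to
    ``tmp_dir`` and are merged; the temporary directory is always
    removed, and a failed run does not leave a partial output file.
    """
    order = ChromOrder.from_file(config.target_sizes_path)
    chains = parse_chain(config.chain_path)
    index = build_index(chains, min_score=config.min_score, target_sizes=order.sizes)
    include_weight = config.input_format == "bins+pixels"

    stats = ConversionStats()
    tmp_root = tempfile.mkdtemp(prefix="pairlift-sort-", dir=config.tmp_dir)
    tmp_output = config.output_path + ".part"
    spill_paths: list[str] = []
    try:
        buffer: list[str] = []
        for record in _open_reader(config):
            stats.total += 1
            stats.total_weight += record.weight
            lifted, reason = lift_contact(index, record, order)
            if reason is not None:
                stats.record_drop(reason, record.weight)
                continue
            assert lifted is not None
            lifted = canonicalize(lifted, order)
            stats.record_lift(lifted)
            buffer.append(_encode(lifted, order))
            if len(buffer) >= config.chunk_size:
                spill_paths.append(_spill(buffer, tmp_root, len(spill_paths)))
                buffer = []

        runs: list[Iterable[str]] = [sorted(buffer, key=_merge_key)]
        spill_handles: list[IO[str]] = [open(p) for p in spill_paths]
        try:
            runs.extend(spill_handles)
            merged = heapq.merge(*runs, key=_merge_key)
            records_out = (_decode(line, order) for line in merged)
            meta = {"command": config.command} if config.command else None
            write_pairs(
                records_out,
                order,
                tmp_output,
                header_meta=meta,
                include_weight=include_weight,
            )
        finally:
            for fh in spill_handles:
                fh.close()
        os.replace(tmp_output, config.output_path)
    except BaseException:
        if os.path.exists(tmp_output):
            os.unlink(tmp_output)
        raise
    finally:
        shutil.rmtree(tmp_root, ignore_errors=True)

    stats.check()
    if config.report_path:
        with open(config.report_path, "w") as fh:
            summarize(stats, fh)
    return stats


def _spill(buffer: list[str], tmp_root: str, idx: int) -> str:
    path = os.path.join(tmp_root, f"chunk{idx:06d}.tsv")
    buffer.sort(key=_merge_key)
    with open(path, "w") as fh:
        fh.write("\n".join(buffer) + "\n")
    return path


_REPORT_ORDER = [
    "total",
    "lifted",
    "dropped_unmapped_side1",
    "dropped_unmapped_side2",
    "dropped_both_unmapped",
    "dropped_ambiguous",
    "dropped_offtarget_chrom",
    "total_weight",
    "lifted_weight",
    "dropped_weight",
    "percent_lifted",
]


def summarize(stats: ConversionStats, stream: PathOrHandle) -> None:
    """Write the conversion report as key<TAB>value text.

    The same file serves humans and machines: totals, per-reason
    drops, weights, percent lifted, then per-target-chromosome lifted
    anchor counts.  :func:`parse_report` reads it back losslessly.
    """
    stats.check()
    with open_text(stream, "w") as fh:
        fh.write(f"total\t{stats.total}\n")
        fh.write(f"lifted\t{stats.lifted}\n")
        for reason in DropReason:
            fh.write(f"dropped_{reason.value}\t{stats.dropped[reason]}\n")
        fh.write(f"total_weight\t{repr(stats.total_weight)}\n")
        fh.write(f"lifted_weight\t{repr(stats.lifted_weight)}\n")
        fh.write(f"dropped_weight\t{repr(stats.dropped_weight)}\n")
        fh.write(f"percent_lifted\t{stats.percent_lifted:.4f}\n")
        for chrom in sorted(stats.lifted_anchors_by_chrom):
            fh.write(f"lifted_anchors_{chrom}\t{stats.lifted_anchors_by_chrom[chrom]}\n")


def parse_report(stream: PathOrHandle) -> ConversionStats:
    """Parse a report written by :func:`summarize` back into stats."""
    stats = ConversionStats()
    by_value = {f"dropped_{reason.value}": reason for reason in DropReason}
    with open_text(stream) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            key, value = line.split("\t", 1)
            if key == "total":
                stats.total = int(value)
            elif key == "lifted":
                stats.lifted = int(value)
            elif key in by_value:
                stats.dropped[by_value[key]] = int(value)
            elif key == "total_weight":
                stats.total_weight = float(value)
            elif key == "lifted_weight":
                stats.lifted_weight = float(value)
            elif key == "dropped_weight":
                stats.dropped_weight = float(value)
            elif key == "percent_lifted":
                pass  # derived
            elif key.startswith("lifted_anchors_"):
                stats.lifted_anchors_by_chrom[key[len("lifted_anchors_"):]] = int(value)
    stats.check()
    return stats
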