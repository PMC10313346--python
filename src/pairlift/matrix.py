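"""Bridging binned contact matrices and contact records.

Coarse-resolution input arrives as a bin table plus upper-triangular
sparse pixels (the layout of a cooler text dump).  Each pixel is
turned into one weighted pseudo-contact anchored at the midpoints of
its two bins; after liftover, contacts can be re-aggregated onto a
target-assembly bin table.  The midpoint is the sole per-bin policy —
a pixel whose bin midpoint cannot be lifted is dropped whole, never
split across chain blocks, which keeps the accounting auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from ._fileutil import PathOrHandle, open_text
from .contacts import ChromOrder, ContactRecord, format_weight
from .errors import PairsFormatError

__all__ = [
    "BinTable",
    "Pixel",
    "DroppedWeight",
    "pixels_to_contacts",
    "contacts_to_pixels",
    "read_bins",
    "read_pixels",
    "write_bins",
    "write_pixels",
]

Pixel = tuple[int, int, float]


@dataclass(frozen=True)
class DroppedWeight:
    """Pixels/records that fell off the genome during aggregation."""

    n: int = 0
    weight: float = 0.0


class BinTable:
    """Ordered fixed-resolution genomic bins tiling each chromosome.

    The last bin of a chromosome may be short.  Bin lookup is
    arithmetic (``offset + pos // resolution``), which the constructor
    validates against the supplied bins.
    """

    def __init__(self, bins: Iterable[tuple[str, int, int]], resolution: int):
        self.bins: list[tuple[str, int, int]] = list(bins)
        self.resolution = int(resolution)
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self._offsets: dict[str, int] = {}
        self._lengths: dict[str, int] = {}
        expected_start = 0
        prev_chrom: str | None = None
        for i, (chrom, start, end) in enumerate(self.bins):
            if chrom != prev_chrom:
                if chrom in self._offsets:
                    raise ValueError(f"bins for {chrom!r} are not contiguous")
                if prev_chrom is not None and self._lengths[prev_chrom] == 0:
                    raise ValueError(f"chromosome {prev_chrom!r} has no bins")
                self._offsets[chrom] = i
                prev_chrom = chrom
                expected_start = 0
            if start != expected_start or end <= start:
                raise ValueError(
                    f"bin {i} ({chrom}:{start}-{end}) does not tile its chromosome"
                )
            width = end - start
            if width > self.resolution or (
                width < self.resolution and i + 1 < len(self.bins) and self.bins[i + 1][0] == chrom
            ):
                raise ValueError(
                    f"bin {i} width {width} inconsistent with resolution {self.resolution}"
                )
            expected_start = end
            self._lengths[chrom] = end
        if prev_chrom is not None and self._lengths[prev_chrom] == 0:
            raise ValueError(f"chromosome {prev_chrom!r} has no bins")

    @classmethod
    def from_chromsizes(cls, order: ChromOrder, resolution: int) -> "BinTable":
        bins = []
        for name in order.names:
            size = order.sizes[name]
            for start in range(0, size, resolution):
                bins.append((name, start, min(start + resolution, size)))
        return cls(bins, resolution)

    def __len__(self) -> int:
        return len(self.bins)

    def bin_id(self, chrom: str, pos: int) -> int | None:
        """Index of the bin containing ``pos``; None if off the genome."""
        offset = self._offsets.get(chrom)
        if offset is None or pos < 0 or pos >= self._lengths[chrom]:
            return None
        return offset + pos // self.resolution

    def chrom_length(self, chrom: str) -> int | None:
        return self._lengths.get(chrom)


def pixels_to_contacts(
    bins: BinTable, pixels: Iterable[Pixel]
) -> Iterator[ContactRecord]:
    """Turn sparse upper-triangular pixels into weighted pseudo-contacts.

    Anchors are the floor-midpoints of the two bins; strands are ``'.'``
    (unknowable after binning) and the pixel count becomes the weight.
    Total emitted weight equals total pixel count.
    """
    n_bins = len(bins)
    for i, (b1, b2, count) in enumerate(pixels):
        if not (0 <= b1 < n_bins and 0 <= b2 < n_bins):
            raise PairsFormatError(f"pixel {i}: bin index out of range ({b1}, {b2})")
        if b1 > b2:
            raise PairsFormatError(f"pixel {i}: not upper-triangular ({b1} > {b2})")
        if count <= 0:
            raise PairsFormatError(f"pixel {i}: non-positive count {count}")
        chrom1, start1, end1 = bins.bins[b1]
        chrom2, start2, end2 = bins.bins[b2]
        yield ContactRecord(
            read_id=f"px{i}",
            chrom1=chrom1,
            pos1=(start1 + end1) // 2,
            chrom2=chrom2,
            pos2=(start2 + end2) // 2,
            strand1=".",
            strand2=".",
            pair_type=".",
            weight=float(count),
        )


def contacts_to_pixels(
    records: Iterable[ContactRecord], target_bins: BinTable
) -> tuple[list[Pixel], DroppedWeight]:
    """Aggregate contacts onto a bin table as upper-triangular pixels.

    Records whose anchors fall outside the binned chromosomes are
    dropped and accounted in the returned :class:`DroppedWeight`, so
    lifted + dropped weight always reconciles with the input.
    """
    acc: dict[tuple[int, int], float] = {}
    dropped_n = 0
    dropped_w = 0.0
    for record in records:
        b1 = target_bins.bin_id(record.chrom1, record.pos1)
        b2 = target_bins.bin_id(record.chrom2, record.pos2)
        if b1 is None or b2 is None:
            dropped_n += 1
            dropped_w += record.weight
            continue
        if b1 > b2:
            b1, b2 = b2, b1
        acc[(b1, b2)] = acc.get((b1, b2), 0.0) + record.weight
    pixels = [(b1, b2, w) for (b1, b2), w in sorted(acc.items())]
    return pixels, DroppedWeight(n=dropped_n, weight=dropped_w)


def read_bins(source: PathOrHandle) -> BinTable:
    """Read a TSV bin table (chrom, start, end); resolution is inferred."""
    bins: list[tuple[str, int, int]] = []
    with open_text(source) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PairsFormatError(f"bins line {lineno}: expected chrom<TAB>start<TAB>end")
            try:
                bins.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise PairsFormatError(f"bins line {lineno}: non-numeric coordinate") from exc
    if not bins:
        raise PairsFormatError("empty bin table")
    resolution = max(end - start for _, start, end in bins)
    return BinTable(bins, resolution)


def read_pixels(source: PathOrHandle) -> Iterator[Pixel]:
    """Read TSV pixels (bin1_id, bin2_id, count)."""
    with open_text(source) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PairsFormatError(
                    f"pixels line {lineno}: expected bin1<TAB>bin2<TAB>count"
                )
            try:
                yield (int(fields[0]), int(fields[1]), float(fields[2]))
            except ValueError as exc:
                raise PairsFormatError(f"pixels line {lineno}: non-numeric field") from exc


def write_bins(bins: BinTable, stream: PathOrHandle) -> None:
    with open_text(stream, "w") as fh:
        for chrom, start, end in bins.bins:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_pixels(pixels: Iterable[Pixel], stream: PathOrHandle) -> None:
    with open_text(stream, "w") as fh:
        for b1, b2, count in pixels:
            fh.write(f"{b1}\t{b2}\t{format_weight(count)}\n")
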