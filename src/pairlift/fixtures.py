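"""Synthetic test inputs: toy genomes, rearrangement chains, contacts.

Everything the test suite needs is generated here — no download ever.
A :class:`RearrangementPlan` lists non-overlapping edits (deletions,
insertions, inversions, translocations) on a small source genome;
:func:`make_chain` derives the rearranged target genome, emits a
format-valid UCSC chain file for the source→target mapping, and
builds a :class:`BaseMapOracle` — the exhaustive per-base mapping
table obtained by walking the chain cursors directly, independent of
the interval index, so it can serve as the reference implementation
`lift_point` is tested against.

Genomes are kept small (≤ 100 kb) so the exhaustive per-base
comparison runs in seconds.  Insertions in the target are represented
as dq-gaps and therefore create no unmapped source bases; the
asymmetry is deliberate (only deletions lose source bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Union

import numpy as np

from .chain import (
    AMBIGUOUS,
    Chain,
    LiftedPoint,
    LiftFailure,
    UNMAPPED,
    parse_chain,
)
from .contacts import ContactRecord
from .errors import ParameterError, PlanError
import io

__all__ = [
    "Deletion",
    "Insertion",
    "Inversion",
    "Translocation",
    "RearrangementPlan",
    "BaseMapOracle",
    "FixtureChain",
    "make_chain",
    "oracle_lift",
    "simulate_contacts",
    "random_plan",
]


@dataclass(frozen=True)
class Deletion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Insertion:
    """Novel target sequence of ``length`` bp at source breakpoint ``at``."""

    chrom: str
    at: int
    length: int


@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class Translocation:
    """Source interval moved to ``dest_chrom`` at source breakpoint ``dest_at``."""

    chrom: str
    start: int
    end: int
    dest_chrom: str
    dest_at: int


Edit = Union[Deletion, Insertion, Inversion, Translocation]


def _span(edit: Edit) -> tuple[int, int]:
    if isinstance(edit, Insertion):
        return (edit.at, edit.at)
    return (edit.start, edit.end)


@dataclass
class RearrangementPlan:
    """Source chromosome lengths plus an ordered, non-overlapping edit list."""

    chrom_sizes: dict[str, int]
    edits: list[Edit] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        spans: dict[str, list[tuple[int, int]]] = {}
        for edit in self.edits:
            size = self.chrom_sizes.get(edit.chrom)
            if size is None:
                raise PlanError(f"edit on unknown chromosome {edit.chrom!r}")
            lo, hi = _span(edit)
            if not (0 <= lo <= hi <= size):
                raise PlanError(f"edit {edit} outside chromosome bounds")
            if not isinstance(edit, Insertion) and lo == hi:
                raise PlanError(f"zero-length edit {edit}")
            if isinstance(edit, Insertion) and edit.length <= 0:
                raise PlanError(f"non-positive insertion length: {edit}")
            spans.setdefault(edit.chrom, []).append((lo, hi))
            if isinstance(edit, Translocation):
                if edit.dest_chrom not in self.chrom_sizes:
                    raise PlanError(f"translocation to unknown chromosome {edit.dest_chrom!r}")
                if not (0 <= edit.dest_at <= self.chrom_sizes[edit.dest_chrom]):
                    raise PlanError(f"translocation breakpoint out of bounds: {edit}")
        for chrom, intervals in spans.items():
            intervals.sort()
            for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
                if hi1 > lo2:
                    raise PlanError(
                        f"overlapping edits on {chrom}: [{lo1},{hi1}) and [{lo2},{hi2})"
                    )
        # a translocation landing strictly inside an inverted or moved segment
        # would require splitting that segment; plans keep breakpoints outside
        for edit in self.edits:
            if not isinstance(edit, Translocation):
                continue
            for other in self.edits:  # includes the edit itself
                if isinstance(other, (Deletion, Insertion)):
                    continue
                lo, hi = _span(other)
                if other.chrom == edit.dest_chrom and lo < edit.dest_at < hi:
                    raise PlanError(
                        f"translocation breakpoint {edit.dest_at} falls inside {other}"
                    )


@dataclass
class _Mapped:
    """A source segment carried into the target; strand '-' = inverted."""

    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class _Inserted:
    length: int


_Atom = Union[_Mapped, _Inserted]


class BaseMapOracle:
    """Exhaustive source-base → target mapping table.

    Built by walking chain-file cursors directly (numpy slice writes),
    never through the interval index, and applying the same overlap
    policy as ``lift_point``: highest chain score wins, exact score
    ties between different chains are ambiguous.
    """

    def __init__(self, chrom_sizes: Mapping[str, int], target_names: list[str]):
        self.chrom_sizes = dict(chrom_sizes)
        self.target_names = list(target_names)
        self._tindex = {name: i for i, name in enumerate(target_names)}
        self._tchrom: dict[str, np.ndarray] = {}
        self._tpos: dict[str, np.ndarray] = {}
        self._strand: dict[str, np.ndarray] = {}  # 1 = '+', -1 = '-'
        self._score: dict[str, np.ndarray] = {}
        self._ambiguous: dict[str, np.ndarray] = {}
        self._chain: dict[str, np.ndarray] = {}
        for chrom, size in self.chrom_sizes.items():
            self._tchrom[chrom] = np.full(size, -1, dtype=np.int32)
            self._tpos[chrom] = np.zeros(size, dtype=np.int64)
            self._strand[chrom] = np.zeros(size, dtype=np.int8)
            self._score[chrom] = np.full(size, -1, dtype=np.int64)
            self._ambiguous[chrom] = np.zeros(size, dtype=bool)
            self._chain[chrom] = np.full(size, -1, dtype=np.int64)

    @classmethod
    def from_chains(
        cls, chains: list[Chain], chrom_sizes: Mapping[str, int]
    ) -> "BaseMapOracle":
        target_names: list[str] = []
        for header, _ in chains:
            if header.q_name not in target_names:
                target_names.append(header.q_name)
        oracle = cls(chrom_sizes, target_names)
        for header, blocks in chains:
            for block in blocks:
                _paint_block(oracle, header.t_name, block)
        return oracle

    def lift(self, chrom: str, pos: int) -> LiftedPoint | LiftFailure:
        arr = self._tchrom.get(chrom)
        if arr is None or pos < 0 or pos >= arr.shape[0]:
            return UNMAPPED
        if arr[pos] < 0:
            return UNMAPPED
        if self._ambiguous[chrom][pos]:
            return AMBIGUOUS
        return LiftedPoint(
            chrom=self.target_names[int(arr[pos])],
            pos=int(self._tpos[chrom][pos]),
            inverted=bool(self._strand[chrom][pos] < 0),
            score=int(self._score[chrom][pos]),
        )

    def mapped_mask(self, chrom: str) -> np.ndarray:
        """Boolean mask of uniquely-mappable bases on one source chromosome."""
        return (self._tchrom[chrom] >= 0) & ~self._ambiguous[chrom]

    def n_mapped(self) -> int:
        return int(sum(self.mapped_mask(c).sum() for c in self.chrom_sizes))

    def n_bases(self) -> int:
        return int(sum(self.chrom_sizes.values()))


def _paint_block(oracle: BaseMapOracle, t_name: str, block) -> None:
    """Write one ungapped block into the per-base tables."""
    size = oracle.chrom_sizes.get(t_name)
    if size is None:
        return
    lo, hi = block.t_lo, min(block.t_hi, size)
    if hi <= lo:
        return
    n = hi - lo
    offs = np.arange(n, dtype=np.int64)
    if block.q_strand == "+":
        tpos = block.q_lo + offs
        strand = np.int8(1)
    else:
        tpos = block.q_size - 1 - (block.q_lo + offs)
        strand = np.int8(-1)
    tchrom_idx = oracle._tindex[block.q_name]
    sl = slice(lo, hi)
    cur_score = oracle._score[t_name][sl]
    cur_chain = oracle._chain[t_name][sl]
    higher = block.score > cur_score
    tie = (block.score == cur_score) & (cur_chain != block.chain_id)
    oracle._ambiguous[t_name][sl] |= tie
    oracle._ambiguous[t_name][sl] &= ~higher
    for arr, val in (
        (oracle._tchrom[t_name], tchrom_idx),
        (oracle._score[t_name], block.score),
        (oracle._chain[t_name], block.chain_id),
    ):
        arr[sl] = np.where(higher, val, arr[sl])
    oracle._tpos[t_name][sl] = np.where(higher, tpos, oracle._tpos[t_name][sl])
    oracle._strand[t_name][sl] = np.where(higher, strand, oracle._strand[t_name][sl])


def oracle_lift(
    oracle: BaseMapOracle, chrom: str, pos: int
) -> LiftedPoint | LiftFailure:
    """Table lookup with the same contract as ``lift_point``."""
    return oracle.lift(chrom, pos)


@dataclass
class FixtureChain:
    """Everything :func:`make_chain` produces for one plan."""

    chain_text: str
    oracle: BaseMapOracle
    target_sizes: dict[str, int]
    chains: list[Chain]


def _atoms_for_plan(plan: RearrangementPlan) -> dict[str, list[_Atom]]:
    """Phase 1: home-atom lists per target chromosome, translocations applied."""
    pending: list[tuple[_Mapped, str, int]] = []
    atoms: dict[str, list[_Atom]] = {}
    for chrom, size in plan.chrom_sizes.items():
        edits = sorted(
            (e for e in plan.edits if e.chrom == chrom), key=lambda e: _span(e)[0]
        )
        out: list[_Atom] = []
        cursor = 0
        for edit in edits:
            lo, hi = _span(edit)
            if lo > cursor:
                out.append(_Mapped(chrom, cursor, lo))
            if isinstance(edit, Deletion):
                pass  # source bases vanish: neither atom nor target span
            elif isinstance(edit, Insertion):
                out.append(_Inserted(edit.length))
            elif isinstance(edit, Inversion):
                out.append(_Mapped(chrom, lo, hi, strand="-"))
            elif isinstance(edit, Translocation):
                pending.append((_Mapped(chrom, lo, hi), edit.dest_chrom, edit.dest_at))
            cursor = hi
        if cursor < size:
            out.append(_Mapped(chrom, cursor, size))
        atoms[chrom] = out

    for segment, dest_chrom, dest_at in pending:
        dest = atoms[dest_chrom]
        idx = len(dest)
        for i, atom in enumerate(dest):
            if not isinstance(atom, _Mapped) or atom.chrom != dest_chrom:
                continue
            if dest_at <= atom.start:
                idx = i
                break
            if atom.start < dest_at < atom.end:
                # split a plus-strand segment at the breakpoint
                dest[i : i + 1] = [
                    _Mapped(atom.chrom, atom.start, dest_at, atom.strand),
                    _Mapped(atom.chrom, dest_at, atom.end, atom.strand),
                ]
                idx = i + 1
                break
            if dest_at == atom.end:
                idx = i + 1
                break
        dest.insert(idx, segment)
    return atoms


def make_chain(plan: RearrangementPlan) -> FixtureChain:
    """Derive the target genome and emit chain text + exhaustive oracle.

    One chain per contiguous mapped segment; inversions become
    minus-strand chains; deletions surface as chain breaks; insertions
    only widen the target.  Chain scores equal segment lengths.
    """
    plan.validate()
    atoms = _atoms_for_plan(plan)

    target_sizes: dict[str, int] = {}
    placements: list[tuple[_Mapped, str, int]] = []  # (segment, target chrom, t0)
    for tchrom, atom_list in atoms.items():
        cursor = 0
        for atom in atom_list:
            if isinstance(atom, _Inserted):
                cursor += atom.length
            else:
                placements.append((atom, tchrom, cursor))
                cursor += atom.end - atom.start
        if cursor > 0:
            target_sizes[tchrom] = cursor

    lines: list[str] = []
    for chain_id, (seg, tchrom, t0) in enumerate(placements, start=1):
        length = seg.end - seg.start
        t_size = plan.chrom_sizes[seg.chrom]
        q_size = target_sizes[tchrom]
        score = length
        if seg.strand == "+":
            q_start, q_end = t0, t0 + length
            strand = "+"
        else:
            q_start, q_end = q_size - (t0 + length), q_size - t0
            strand = "-"
        lines.append(
            f"chain {score} {seg.chrom} {t_size} + {seg.start} {seg.end} "
            f"{tchrom} {q_size} {strand} {q_start} {q_end} {chain_id}"
        )
        lines.append(f"{length}")
        lines.append("")
    chain_text = "\n".join(lines) + ("\n" if lines else "")

    chains = parse_chain(io.StringIO(chain_text)) if chain_text.strip() else []
    oracle = BaseMapOracle.from_chains(chains, plan.chrom_sizes)
    return FixtureChain(
        chain_text=chain_text,
        oracle=oracle,
        target_sizes=target_sizes,
        chains=chains,
    )


def simulate_contacts(
    chrom_sizes: Mapping[str, int],
    n: int,
    decay_exponent: float = 1.0,
    trans_fraction: float = 0.05,
    seed: int = 0,
) -> Iterator[ContactRecord]:
    """Simulate Hi-C-like contacts with power-law distance decay.

    Cis pairs draw their genomic distance from a density ∝ d^(−α)
    truncated to the chromosome length (α = ``decay_exponent``), on a
    chromosome chosen proportional to its length; trans pairs pick two
    distinct chromosomes uniformly.  Bit-for-bit reproducible under a
    fixed seed.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if decay_exponent <= 0:
        raise ParameterError("decay_exponent must be > 0")
    if not (0.0 <= trans_fraction <= 1.0):
        raise ParameterError("trans_fraction must lie in [0, 1]")
    names = list(chrom_sizes)
    if not names:
        raise ParameterError("need at least one chromosome")
    sizes = np.array([chrom_sizes[c] for c in names], dtype=np.int64)
    rng = np.random.default_rng(seed)
    probs = sizes / sizes.sum()
    can_trans = len(names) >= 2

    for i in range(n):
        is_trans = can_trans and rng.random() < trans_fraction
        if is_trans:
            c1, c2 = rng.choice(len(names), size=2, replace=False)
            p1 = int(rng.integers(0, sizes[c1]))
            p2 = int(rng.integers(0, sizes[c2]))
            chrom1, chrom2 = names[int(c1)], names[int(c2)]
        else:
            c = int(rng.choice(len(names), p=probs))
            length = int(sizes[c])
            dmax = max(length - 1, 1)
            u = rng.random()
            alpha = decay_exponent
            if abs(alpha - 1.0) < 1e-12:
                d = np.exp(u * np.log(dmax))
            else:
                d = ((1 - u) + u * dmax ** (1 - alpha)) ** (1.0 / (1 - alpha))
            d = int(np.clip(int(d), 1, dmax))
            p1 = int(rng.integers(0, length - d))
            p2 = p1 + d
            chrom1 = chrom2 = names[c]
        s1 = "+" if rng.random() < 0.5 else "-"
        s2 = "+" if rng.random() < 0.5 else "-"
        yield ContactRecord(
            read_id=f"sim{i:07d}",
            chrom1=chrom1,
            pos1=p1,
            chrom2=chrom2,
            pos2=p2,
            strand1=s1,
            strand2=s2,
            pair_type="UU",
            weight=1.0,
        )


def random_plan(rng: np.random.Generator, max_chrom: int = 50_000) -> RearrangementPlan:
    """Draw a random rearrangement plan exercising all four edit types.

    Genomes stay small (two chromosomes, 12–``max_chrom`` bp each) so
    the exhaustive oracle sweep is cheap; edits are laid out
    non-overlapping by slicing each chromosome into disjoint windows.
    """
    sizes = {
        "chrA": int(rng.integers(12_000, max_chrom + 1)),
        "chrB": int(rng.integers(12_000, max_chrom + 1)),
    }
    edits: list[Edit] = []
    kinds = ["deletion", "insertion", "inversion", "translocation"]
    for chrom, size in sizes.items():
        n_edits = int(rng.integers(1, 5))
        # carve non-overlapping windows, one edit per window
        cut_points = np.sort(rng.choice(np.arange(1, size), size=2 * n_edits, replace=False))
        other = "chrB" if chrom == "chrA" else "chrA"
        for k in range(n_edits):
            lo, hi = int(cut_points[2 * k]), int(cut_points[2 * k + 1])
            if hi - lo < 2:
                continue
            kind = kinds[int(rng.integers(0, len(kinds)))]
            if kind == "deletion":
                edits.append(Deletion(chrom, lo, hi))
            elif kind == "insertion":
                edits.append(Insertion(chrom, lo, int(rng.integers(1, 2_000))))
            elif kind == "inversion":
                edits.append(Inversion(chrom, lo, hi))
            else:
                dest_at = int(
                    rng.choice([0, sizes[other], int(rng.integers(0, sizes[other] + 1))])
                )
                edits.append(Translocation(chrom, lo, hi, other, dest_at))
    plan = RearrangementPlan(chrom_sizes=sizes, edits=edits)
    try:
        plan.validate()
    except PlanError:
        # rare layout clash: fall back to deletions only, always valid
        plan = RearrangementPlan(
            chrom_sizes=sizes,
            edits=[e if isinstance(e, (Deletion, Insertion, Inversion)) else
                   Deletion(e.chrom, e.start, e.end) for e in edits],
        )
        plan.validate()
    return plan
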