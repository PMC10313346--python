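# Methods

## Coordinate model

All coordinates inside the engine are 0-based half-open; the pairs and
allValidPairs readers and the pairs writer perform the 1-based shift
at the file boundary, and chain files are already 0-based half-open.

A UCSC chain is a header
`chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id`
followed by data lines `size [dt dq]`. Parsing walks two cursors: each
line advances the source cursor by `size + dt` and the target cursor
by `size + dq`, yielding one ungapped block per line. The walk must
reconcile exactly with `tEnd`/`qEnd` or the chain is rejected — a
malformed chain is an error, never a silent truncation. `tStrand` is
`'+'` by the format's convention; a `'-'` source strand is rejected as
unsupported rather than guessed at.

## Point liftover

Contacts are converted per anchor at single-base resolution — a pairs
line stores one position per side, so an anchor either lifts exactly
or not at all; there is no interval straddling to arbitrate. For a
block with source interval `[t_lo, t_hi)`:

* `q_strand '+'`: `pos' = q_lo + (pos − t_lo)`
* `q_strand '-'`: `pos' = q_size − 1 − (q_lo + (pos − t_lo))`, and the
  anchor is marked inverted; an inverted anchor's read strand is
  flipped (`'.'` stays `'.'`).

Blocks live in a per-chromosome interval tree (`intervaltree`).
Distinct chains may overlap on the source axis; a covered base
resolves to the highest-scoring chain, and an exact score tie between
different chains is reported as *ambiguous* and dropped (mirroring the
classical liftOver preference for the dominant chain). `min_score`
(default 0, i.e. keep all chains — released chain files are already
net-filtered) exposes a chain-score floor; raising it can only shrink
the mappable set. Chains targeting a chromosome absent from the
user-supplied sizes table are skipped with a warning, which doubles as
the mechanism for excluding alt contigs from output.

Chain inversion swaps the two sides block-by-block: a `'+'` block
`[t_lo, t_hi) → q_lo` becomes `[q_lo, q_lo+L) → t_lo`; a `'-'` block
becomes the `'-'` block `[q_size−q_lo−L, q_size−q_lo) → t_size−t_hi`.
Inversion is an involution and, composed with the forward map, the
identity on every uniquely-mapped base — both are tested exhaustively.

## Contact pipeline

A contact survives only if **both** anchors lift uniquely onto
chromosomes present in the target sizes table. Failures are typed per
side (`unmapped_side1/2`, `both_unmapped`, `ambiguous`,
`offtarget_chrom`; unmapped takes precedence over ambiguous when both
occur) so that information loss is auditable, and the accounting
invariants — `total = lifted + Σ dropped`, total weight likewise — are
asserted at the end of every run. Per-target-chromosome counts are
lifted *anchors* (two per contact), which stays meaningful for
trans contacts.

Surviving records are canonicalized (upper-triangular under the sizes
file's chromosome order — never lexicographic), then externally
sorted: chunks of `chunk_size` records are sorted in memory, spilled
to temporary files, and k-way merged (`heapq.merge`) into the writer.
The sort key is `(chrom1, chrom2, pos1, pos2, read_id, remaining
fields)`, a total order, so output bytes are independent of the chunk
size and of the number of spills; the pipeline holds at most one chunk
in memory, which is what makes running time linear and memory flat in
the number of contacts. There is no randomness anywhere in the
pipeline: repeated runs are byte-identical.

Output is always 4DN pairs regardless of input dialect, since that is
what downstream matrix loaders consume. The header is regenerated
(magic line, `#sorted:`, `#shape:`, `#chromsize:` from the target
sizes file, `#command:`, `#columns:`) rather than propagated from the
input — input headers describe the *source* assembly and would be
wrong verbatim. `pair_type` passes through unchanged; duplicates are
not collapsed (conversion does not re-curate data). Gzip input is
detected by magic bytes, not file extension.

## Binned-matrix mode

Matrix input crosses the module boundary as a neutral bins table
(chrom, start, end) plus upper-triangular pixels (bin1, bin2, count) —
the layout of a cooler text dump — read/written as TSV. Each pixel
becomes one pseudo-contact at the floor-midpoints of its two bins with
the count as weight and `'.'` strands (strand is unknowable after
binning). The midpoint is the sole per-bin policy: a pixel whose
midpoint is unmappable is dropped whole and counted, with no weight
splitting across chain breaks and no fallback to bin edges. Midpoint
displacement is bounded by half the bin width, which is why conversion
fidelity decays mildly as input resolution coarsens; when a source bin
lies wholly inside one chain block the midpoint lift is exact and
re-binning at the same resolution reproduces the input matrix
identically (tested). Balancing weights (ICE/KR) are out of scope —
conversion operates on raw counts.

## Synthetic fixtures and the oracle

The fixtures module generates every test input. A rearrangement plan
lists non-overlapping edits on a toy genome: deletions (source bases
vanish → chain breaks), insertions (target-only sequence → the target
widens; no source base becomes unmapped — the asymmetry is inherent to
one-directional chains), inversions (minus-strand chains) and
translocations (a segment re-homed to another chromosome at a stated
breakpoint). `make_chain` derives the target genome, emits one
format-valid chain per contiguous segment (score = segment length) and
builds the oracle: an exhaustive per-base table materialized by
replaying the chain cursor walk with numpy slice writes — deliberately
independent of the interval-tree query path it validates, while
applying the same score/tie policy. Oracle genomes are capped small
(two chromosomes, ≲50 kb each) so sweeping every base of 50 random
plans takes seconds. Translocation breakpoints may not fall strictly
inside an inverted or translocated interval on the destination
chromosome (plan validation error): splitting a minus-strand segment
would complicate chain emission without adding test coverage.

The contact simulator draws cis pairs with genomic-distance density
∝ d^(−α) truncated to the chromosome (α defaults to 1.0, a generic
Hi-C-like decay; chromosome chosen proportional to length) and trans
pairs uniformly over distinct chromosome pairs with probability
`trans_fraction` (default 0.05). These are arbitrary but realistic
defaults, not estimates of any particular dataset. The simulator is
bit-for-bit reproducible under a fixed seed.

What the fixtures do *not* emulate: restriction-fragment structure,
ligation artefacts, duplicate reads, TAD/loop/compartment structure,
and real chain files' net-level filtering. Passing tests therefore
demonstrate the correctness of the coordinate arithmetic, the
accounting and the streaming machinery — not biological fidelity of
converted maps, which on real data is limited by how well the chain
file describes the two assemblies.

## Problem sizes and numerical choices

The test suite and acceptance script use 50 random plans (~3 M source
bases swept exhaustively), 10⁵ simulated pairs for end-to-end runs,
and three input sizes (10⁴/2×10⁴/4×10⁴ at fixed chunk size 2000) for
the coarse memory-flatness check via `tracemalloc`. Weights are plain
floats; all conservation checks are exact equalities (counts are
integers and the weights used in tests are exactly representable).
Degenerate inputs are defined, not special-cased: an empty chain set
maps nothing, a header-only pairs file converts to a header-only
output with zero stats, a zero-record report states 100% lifted of 0.

## Known limitations

* One anchor = one base: contacts are never split or fractionally
  assigned when a locus straddles a chain break.
* Ambiguity handling is score-based only; no reciprocal-overlap or
  synteny test, so it is optimized for intraspecies conversion.
* The `.hic`/`.cool` container formats are not parsed natively; binned
  input enters through the bins+pixels text contract (which needs two
  files, hence `--input` for bins and `--pixels` for pixels on the
  CLI).
* No parallelism, deduplication, or pairix/tabix indexing of output.
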