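# pairlift

Lift chromatin-contact coordinates between genome assemblies — without
remapping reads.

## The problem

Hi-C, Micro-C and related proximity-ligation assays produce *contacts*:
pairs of genomic loci that were spatially close in the nucleus. Each
experiment carries hundreds of millions to billions of read pairs, and
published datasets are scattered across reference assemblies (hg19,
hg38, T2T-CHM13, mm9/mm10, …). Integrating them requires one
coordinate system. Remapping raw reads to the target assembly is
accurate but takes days per dataset — and for many patient-derived
samples the raw reads are not available at all.

`pairlift` takes the second route: it converts the coordinates of the
*contacts themselves* through a UCSC chain file (the standard carrier
for assembly-to-assembly alignments). Each contact anchor is a single
base; an anchor is resolved through the chain blocks that cover it,
minus-strand chains reverse the coordinate
(`pos' = q_size − 1 − (q_start + offset)`) and flip the anchor strand,
overlaps between chains resolve to the highest chain score, and exact
score ties are dropped as ambiguous. A contact survives only if both
anchors lift uniquely onto chromosomes present in the target sizes
table; every failure is counted by reason, so
`total = lifted + Σ dropped` and total weight are conserved exactly on
every run.

Inputs: 4DN `.pairs` (plain or gzip), HiC-Pro `allValidPairs`, or a
binned sparse contact matrix (bins + upper-triangular pixels TSV, the
layout of a cooler text dump; each pixel becomes one weighted
pseudo-contact at its bin midpoints). Output is always a sorted,
upper-triangular 4DN pairs file on the target assembly, produced by an
external merge sort so memory stays bounded by the chunk size no
matter how deep the dataset is, plus a key–value conversion report and
a JSON run manifest. Conversion is intended for assemblies of the
*same* species; arbitrary chains work, but paralog-aware cross-species
mapping is out of scope.

## Worked example

The package generates its own inputs, so a complete run needs no
external data. Build a toy rearrangement (a 5 kb deletion and a 3 kb
inversion), simulate contacts on the source genome, and convert:

```bash
pairlift fixtures make-chain \
    --chrom chrA:50000 --chrom chrB:30000 \
    --deletion chrA:10000-15000 --inversion chrB:5000-8000 \
    --out-chain toy.chain --out-sizes target.sizes

printf 'chrA\t50000\nchrB\t30000\n' > source.sizes
pairlift fixtures simulate-pairs --sizes source.sizes \
    -n 2000 --seed 11 --output sim.pairs

pairlift convert --input sim.pairs --chain toy.chain \
    --out-chromsizes target.sizes --output lifted.pairs \
    --report report.tsv
```

The convert step prints the report:

```
total	2000
lifted	1833
dropped_unmapped_side1	60
dropped_unmapped_side2	29
dropped_both_unmapped	78
dropped_ambiguous	0
dropped_offtarget_chrom	0
total_weight	2000.0
lifted_weight	1833.0
dropped_weight	167.0
percent_lifted	91.6500
lifted_anchors_chrA	2134
lifted_anchors_chrB	1532
```

1833 of 2000 simulated contacts (91.65%) lift onto the rearranged
assembly; the 167 losses all touch the deleted 5 kb of chrA, split by
which side fell in it. `lifted.pairs` is a sorted 4DN pairs file whose
`#chromsize:` header matches `target.sizes` (note chrA shrank to
45 000 bp), and `lifted.pairs.manifest.json` records the command,
checksums and the same statistics.

The same operations are available as a library
(`pairlift.run_conversion`, `pairlift.lift_point`,
`pairlift.fixtures.make_chain`, …).

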