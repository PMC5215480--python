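# multilocus

Handling and analysing sequence alignments of **multiple genes** for the same
set of individuals: a container that harmonizes taxa across loci, plus the
standard first-pass analyses — concatenation, marker coding, genetic
distances, neighbor-joining trees and incongruence comparison.

## The problem

Organisms are increasingly sequenced at several loci (nuclear genes, MLST
schemes, viral genome segments). Because incomplete lineage sorting,
recombination, horizontal transfer and plain sampling noise can make
different genes support different genealogies (*phylogenetic incongruence*),
multi-gene data should first be examined locus by locus, and only then
concatenated. In practice that stumbles on bookkeeping: each locus documents
a different subset of individuals, in a different order.

`multilocus` solves the bookkeeping once. Building a `MultiLocusContainer`
enumerates every individual with at least one sequence, sorts the union of
labels alphanumerically, and pads each locus with **gap-only rows**
(`'-' * n_cols`) for its missing individuals. Afterwards all loci carry the
same individuals in the same order, so per-locus analyses are directly
comparable and loci concatenate row by row into a supermatrix.

## What it computes

* **Bookkeeping** — `n_ind` individuals, `n_seq = n_ind × n_loci` sequences
  including padding, `n_seq_miss` gap-only rows; per-locus counts of
  non-gap-only sequences.
* **Handling** — matrix-style subsetting `c[ids, loci]`, locus
  concatenation with 1-based closed partition boundaries, accessors,
  site-pattern compression.
* **Markers** — SNP extraction (a column is a SNP iff ≥ 2 distinct
  determinate states A/C/G/T occur; gaps, `N`, `?` and IUPAC ambiguity codes
  are missing) and MLST-style haplotype coding (each distinct full-length
  sequence at a locus is an allele). Codes are integers by first appearance;
  0 is the missing sentinel.
* **Distances** — with pairwise deletion (per pair, only columns where both
  rows are determinate): raw mismatch counts, the p-distance
  *p = mismatches / compared sites*, and the multiple-hit corrections

  * JC69: *d = −(3/4) ln(1 − 4p/3)*
  * K80: *d = −(1/2) ln(1 − 2P − Q) − (1/4) ln(1 − 2Q)*, with *P*, *Q* the
    transition and transversion proportions.

* **Trees** — classical neighbor joining (Saitou–Nei agglomeration,
  Studier–Keppler update), per locus or on the supermatrix; negative branch
  lengths clamped to zero and trees ladderized by default; Newick I/O.
* **Incongruence** — Robinson–Foulds symmetric difference of non-trivial
  bipartitions over the shared leaf set of two trees.
* **Visualization** — one alignment panel per locus (optionally plus the
  supermatrix), colour-coded by residue class, so missing-data patterns are
  visible at a glance.

## Worked example

```python
import multilocus as ml

# 8 individuals typed at 4 nuclear loci; per-locus coverage 5, 6, 8, 5
c = ml.worked_example_fixture(seed=1)
print(c)
```

```
=== MultiLocusContainer ===
[32 DNA sequences in 4 genes]
@n.ind: 8 individuals
@n.seq: 32 sequences in total
@n.seq.miss: 8 gap-only (missing) sequences
@labels: taxon_01 taxon_02 taxon_03 taxon_04 ...
@loci: patr_poat43 patr_poat47 patr_poat48 patr_poat49
```

32 = 8 individuals × 4 loci; the 8 gap-only sequences are the padding rows
inserted for individuals a locus did not cover. The real coverage per locus:

```python
>>> ml.count_sequences(c)
{'patr_poat43': 5, 'patr_poat47': 6, 'patr_poat48': 8, 'patr_poat49': 5}
```

Per-locus NJ trees (gap-only rows dropped first), a pooled tree from the
concatenation, and their incongruence:

```python
trees  = ml.build_trees(c)             # {'patr_poat43': <PhyloTree: 5 leaves>, ...}
pooled = ml.build_trees(c, pool=True)  # 8 leaves
for name, t in trees.items():
    print(name, ml.rf_distance(t, pooled))
```

```
patr_poat43 0
patr_poat47 0
patr_poat48 0
patr_poat49 0
```

Here every gene tree is compatible with the pooled tree (RF = 0 on the
shared leaves) — expected, since this synthetic data set evolves all four
loci on one generating tree; real multi-gene data sets typically show
non-zero RF values between loci, which is exactly what this comparison is
for.

The same workflow from a shell, one FASTA file per locus:

```sh
multilocus summary  *.fasta
multilocus concat   *.fasta --out supermatrix.fasta
multilocus snps     *.fasta --out snps.tsv
multilocus trees    *.fasta --pool
multilocus compare  *.fasta
multilocus plot     *.fasta --out overview.png
```

## Genotype export format

`export_genotypes` writes a tab-separated table (rows = individuals,
columns = markers named `locus:site` for SNPs and `locus` for haplotype
markers, missing as `NA`) plus a `.legend` sidecar mapping each integer code
back to its allele string, making the export fully invertible.

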