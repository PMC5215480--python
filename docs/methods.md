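# Methods

This note documents the model choices, conventions and numerical decisions
behind `multilocus`, and what the synthetic data generator does and does not
emulate.

## Harmonization

A multi-locus data set is a list of per-locus alignments over partially
overlapping individual sets. `build_container` enumerates every individual
with at least one sequence, sorts the union of labels, and pads each locus
with gap-only rows (`'-' * n_cols`) for absent individuals. Derived counts:
`n_ind = |labels|`, `n_seq = n_ind × n_loci`, and `n_seq_miss` = number of
(individual, locus) pairs whose row is gap-only — including rows that were
all-gap in the input, since harmonization cannot distinguish them from its
own padding.

Conventions that were genuinely open and the choices made:

* **Collation.** "Sorted alphanumerically" is implemented as plain
  case-sensitive code-point ordering. It is stable and locale-independent;
  note that it is *not* natural-numeric (`sample10` sorts before
  `sample2`). Users who need natural ordering should rename labels.
* **Gap-only.** A row is gap-only iff every character is `'-'`. Rows of all
  `N` or `?` are *not* gap-only: an ambiguity code records an observed but
  unresolved site, a gap records absence. Padding uses `'-'` exclusively.
* **Case.** Residues are uppercased on ingest; `U` is normalized to `T`
  for nucleotide data (RNA tolerance). Validation accepts the IUPAC
  ambiguity codes for nucleotides and the extended one-letter amino-acid
  codes.
* **Subsetting** (`c[ids, loci]`, index/label/boolean selectors) preserves
  canonical order, never re-sorts, never re-harmonizes, and retains loci
  that become entirely gap-only; rebuilding is an explicit separate step.
  This mirrors matrix-subsetting semantics and satisfies the composition
  law `subset(subset(c, A), B) == subset(c, A ∩ B)`.
* **Coordinates.** All user-facing column coordinates (partition
  boundaries, SNP sites) are 1-based closed intervals.
* **Metadata** tables (`ind_info`, `gene_info`) are optional and may cover a
  subset of individuals/loci; subsetting slices them to the selection.

Site-pattern compression (`compress_site_patterns`) stores each distinct
column once with an integer weight; weights sum to `n_cols` and expansion
reproduces the column multiset. It is provided as a compact representation
for downstream pattern-based methods, not used internally by the distance
code.

## File formats

FASTA parsing/writing goes through Biopython (writer wraps at 80 columns).
Phylip is accepted in *relaxed* form — whitespace-delimited names of any
length — in both sequential and interleaved layout, because the strict
10-column name field is rarely honoured in the wild; the writer emits
relaxed sequential. Clustal input is not implemented. Auto-detection treats
a leading `>` as FASTA and otherwise tries sequential then interleaved
Phylip.

Alphabet auto-detection calls a file nucleotide iff ≥ 90% of its non-gap,
non-`?` residues are A/C/G/T/U/N or IUPAC nucleotide ambiguity codes,
otherwise amino acid (the superset alphabet, hence the safe fallback — an
apparent nucleotide file containing protein-only letters also falls back).
`ensure_nucleotide` is the explicit gate in front of nucleotide-only
operations (SNP extraction, JC69/K80).

## Marker coding

Sequences are haploid: one allele per individual per marker. SNP calling
treats `-`, `?`, `N` and all other IUPAC ambiguity codes as missing rather
than expanding them — expansion would require fractional or multi-state
calls that downstream integer genotype tables cannot represent. A column is
polymorphic iff ≥ 2 distinct determinate states occur among non-missing
rows. Haplotype alleles are exact full-length string classes: sequences
differing only by `N` vs a base are distinct alleles, because collapsing
"compatible" sequences would need an arbitrary similarity rule. Allele
codes are consecutive integers from 1 in first-appearance order over the
canonical individual list; 0 is the reserved missing sentinel (rendered
`NA` in the text export).

## Distances

Pairwise deletion restricts each pair to columns where both rows are
determinate (A/C/G/T for nucleotides; the 20 standard residues for amino
acids, where only raw-count and p apply). The four models: raw mismatch
count, mismatch proportion p ("Hamming distance" is read as the proportion;
the count model is provided because the term is used both ways — `p` is the
tree-building default), JC69 and K80 as given in the README. Degenerate
pairs are reported, not guessed:

* zero compared sites → *undefined* (NaN + flag);
* JC69/K80 log argument ≤ 0 → *saturated* (NaN + flag).

Either condition poisons `nj_tree` with an explicit error; silent imputation
would bias trees invisibly.

## Neighbor joining

Classical NJ: at each step join the pair minimizing
Q(i,j) = (m−2)·d(i,j) − r_i − r_j, with branch lengths
l_i = d(i,j)/2 + (r_i − r_j)/(2(m−2)) and the Studier–Keppler update
d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2. Ties on Q resolve to the lowest
row-major index pair, so runs are bit-reproducible. The last three nodes
close a trifurcating root: trees are unrooted. Two labels yield the
degenerate single-edge tree. NJ branch lengths can be negative on
non-additive input; `build_trees` clamps them to zero afterwards (the
simplest reading of "enforcing non-negative branch lengths" — no
redistribution to adjacent edges, so path lengths may shrink slightly at
clamped edges).

`build_trees` is the default workflow: per locus, gap-only padding rows are
dropped before computing distances (they would have no shared sites with
anyone); a locus with < 3 remaining sequences is skipped with a warning. The
pooled variant concatenates all loci and keeps every individual — with the
caveat, flagged here for users, that individuals missing entire loci are
then compared on fewer sites.

Ladderization orders each node's children by descending clade size, ties by
the smallest contained leaf label; it is idempotent and changes neither
topology nor branch lengths.

Robinson–Foulds distance is computed on the induced subtrees over the
common leaf set (≥ 4 leaves required) as the symmetric difference of
non-trivial bipartitions; identical topologies give 0, the two distinct
unrooted quartets give 2. Tree containers, Newick parsing and leaf-set
restriction are delegated to scikit-bio's `TreeNode`; the Newick writer is
local so branch lengths serialize with 6 significant digits.

## Synthetic data generator

`simulate_container` evolves sequences down a generating tree under an
equal-rate (Jukes–Cantor) substitution process: along a branch of length t
(expected substitutions/site, optionally scaled by `substitution_rate`)
each site changes with probability (3/4)(1 − e^(−4t/3)), uniformly to one
of the other three bases. Without a tree, individuals sit on a star at
distance `substitution_rate` from a common ancestor. Missingness is a
per-locus presence set; absent individuals are simply not emitted, and
harmonization pads them later. All randomness flows from one integer seed;
with a target directory the generator writes per-locus FASTA and re-imports
them through the full reading path, and same-seed runs are byte-identical.

`worked_example_fixture` produces the study shape used throughout the
documentation and tests: 8 individuals, 4 loci named `patr_poat43/47/48/49`
with presence counts 5, 6, 8, 5 (one locus covers everyone), locus lengths
480/420/540/510 bp and branch lengths drawn uniformly from
[0.005, 0.05] substitutions/site — sizes and divergences typical of nuclear
loci among closely related species, giving p-distances of a few percent.
Which individuals are missing where is drawn from the seed; only the counts
are part of the contract.

What the generator does **not** emulate: rate heterogeneity across sites or
loci, transition/transversion bias, indels (gaps only ever arise from
harmonization padding), alignment error, or genuine gene-tree discordance
(all loci share one generating tree, so per-locus trees agree up to
sampling noise). Passing tests therefore demonstrate the correctness of the
bookkeeping, the estimators and the algorithms — not robustness to
real-data pathologies such as model misspecification or misalignment.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems: containers of ≤ 10 individuals × ≤ 5 loci, loci of tens to a few
hundred sites, trees of 4–8 leaves, with 100–1000 replicates per property.
These sizes already distinguish correct from incorrect implementations of
every algorithm here (NJ consistency, for instance, is checked exhaustively
against least squares at 4 leaves), and keep the whole suite at a few
seconds.

## Known limitations

* Clustal and NEXUS input are not supported.
* Only four distance models; no minimum-evolution/FastME, BIONJ, bootstrap,
  parsimony or likelihood methods — the container is designed so such tools
  can consume its per-locus alignments.
* No heterozygote handling in genotype tables (one sequence per individual
  per locus).
* Nucleotide storage is plain characters, not bit-packed; memory use is
  ~1 byte/site, fine for the intended scale (tens of loci, hundreds of
  individuals).
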