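# Methods

## Scope and model

`wgacompare` post-processes a reference-free multiple whole-genome
alignment (MAF) of annotated microbial genomes. It does not compute
alignments: Mugsy or another whole-genome aligner is assumed upstream, and
the simulator supplies a true alignment for testing. Everything downstream
— ortholog clusters, SNP calls, the core-genome tree, the reports — is a
deterministic function of the GenBank records and the MAF blocks.

## Input normalization

GenBank records are validated and minimally corrected before analysis:

* accessions longer than 16 characters are truncated to 14 characters plus
  a 2-character base-36 disambiguator, preserving uniqueness;
* locus identifiers are restricted to `[A-Za-z0-9_.-]`; disallowed
  characters become `_`, and collisions get `_2`, `_3`, … suffixes;
* pseudogene features are dropped;
* records sharing an organism name (after collapsing whitespace runs) are
  merged into one draft genome, contigs in input order.

Every change is logged as (record, rule, before, after), making the
normalization reversible by inspection and idempotent by construction.
Compound feature locations (join/complement) are collapsed to their
minimal–maximal interval with the location's strand: all downstream logic
is interval-based, so exon structure (rare in bacteria) is irrelevant here.
Coordinates are 1-based inclusive everywhere except alignment columns and
BED-like track files (0-based half-open). Empty sequences and CDSs
extending past their contig are uncorrectable and abort the run.

## Coordinate projection

MAF rows carry strand-relative 0-based starts; a reverse-strand offset k
from start s on a contig of length L maps to forward 1-based position
L − (s + k). Two normalization rules make projection a function:
within a block, a genome duplicated across rows keeps only its largest row;
across blocks, the first block in file order owns any genome position
claimed twice. The projection index built on these rules is bijective
between non-gap (block, column) pairs and genome positions, which the test
suite checks against a brute-force text walk over randomized alignments,
including reverse-strand rows.

`N` and IUPAC ambiguity codes are treated as missing bases in all allele
logic, and comparisons are case-insensitive.

## Ortholog clusters and CDS classes

A CDS's footprint is the set of canonical alignment columns its interval
projects to; coverage is footprint size over CDS length. Two CDSs from
different genomes are linked when their shared columns cover at least
`overlap_threshold` (default 0.5) of the smaller footprint — a symmetric,
scale-free criterion robust to annotation boundary drift. CDSs of the same
genome are never linked directly, so tandem paralogs only co-cluster
through a common ortholog elsewhere. Clusters are connected components;
ids follow the smallest (genome index, contig, start) of the members, so
numbering is deterministic. Raising the threshold can only remove links,
hence never merges clusters (tested).

Classes follow the span of the cluster: core = all genomes, shared = at
least two but not all, unique = one. A CDS with no aligned columns is
classified unique with an `unaligned` flag: the alignment neither supports
nor refutes its presence elsewhere, and such genes deserve follow-up
sequence searches rather than a confident call. Linking uses any-overlap
rather than mutual-best overlap; mutual-best would split legitimate
clusters whenever annotations disagree about gene boundaries, while
any-overlap errs toward merging, which the connected-component structure
makes visible in the cluster files.

## SNP calls

A SNP site is an alignment column with at least two gap-free, unambiguous
genomes carrying at least two distinct bases. Indels never produce
records, and a column where a genome is shadowed by an earlier overlapping
block treats that genome as absent, so no genome position can be reported
twice. The per-reference table keeps sites where the reference is present
and at least one other present genome differs; by symmetry of that
definition, a site reported for reference R because of genome Q is also
reported for reference Q. Unique SNPs — the innermost circular-figure ring
— are core-column sites where the reference base differs from every other
genome. VCF output indexes genotypes into REF/ALT per non-reference genome
with `.` for absent genomes; QUAL and FILTER are `.` because
alignment-derived calls carry no base-quality semantics.

## Core-genome phylogeny

Core fragments are maximal column runs within a block where every genome
is present with an unambiguous base; runs shorter than
`min_fragment_length` (default 200 columns — long enough to exclude
spurious micro-homologies, short enough to keep fragmented drafts usable;
configurable) are dropped, and fragments never span block boundaries, so
non-contiguous regions are never concatenated as if adjacent. The summary
report's core-genome length counts all core columns without the length
filter, so it is a property of the alignment alone.

The concatenated core alignment is gap-free by construction. An optional
windowed density filter can drop whole windows whose polymorphic-column
fraction exceeds a cutoff (default off): removing high-diversity windows
biases distances downward, and for tree building over a genuinely core
alignment all columns are informative, so filtering is opt-in for users
who suspect recombination or misalignment hotspots.

Distances are Jukes–Cantor, d = −(3/4)·ln(1 − (4/3)·p) from the observed
mismatch proportion p; p ≥ 0.75 means the correction is saturated and the
genomes are outside the model's range, which is reported as an error
rather than a clamped number. The tree is standard Saitou–Nei neighbor
joining: the Q-criterion is minimized at each step with ties broken by the
lowest (i, j) index pair, negative branch lengths are clamped to zero, and
the last three nodes are resolved around one internal vertex, giving an
unrooted (trifurcating-root) tree. On additive matrices NJ reproduces the
generating tree exactly; the tests assert branch-path agreement to 1e-9
and cross-check topologies against an independent NJ implementation.
FastTree can replace the built-in method (`--tree-method
external-fasttree`) when the binary is installed; the deliverable — a
Newick tree over the genome labels — is unchanged.

## Reports and tracks

GC content (percent) and GC skew (G−C)/(G+C) are computed over
non-overlapping 5 kbp windows tiling each contig, keeping the final short
window; N bases are excluded from denominators, and a window without G or C
gets skew 0 with a flag. The run summary lists per genome: contigs, total
length, CDS count and class counts, plus the core-genome length; per-genome
summaries join every CDS to its cluster members and the SNPs inside its
interval. Circular-figure rings are exported as plotter-agnostic BED-like
files (contigs sorted by size for drafts) plus a minimal matplotlib
renderer; a full-featured drawing engine is out of scope.

"Unique genome length" (run summary) is defined as bases lying in no
alignment column shared with another genome — the only reading consistent
with the core/unique CDS definitions.

## Simulator

The simulator defines the study conditions under which the pipeline's
guarantees are tested. Defaults: 4 genomes of 50 kb with 40
non-overlapping genes, 50 substitutions per star branch (200 planted
sites), 2 intergenic indels of ≤10 bp per genome, 1 whole-gene deletion
and 1 genome-specific inserted gene (600 bp) per genome — divergence of
roughly 0.1–0.4%, typical of within-species comparisons where
whole-genome alignment is the method of choice. Substitution positions
are drawn without replacement from positions present in every genome, so
each planted substitution is exactly one alignment column with one derived
allele and the truth table is exact, not expected. A guide tree with
branch lengths interpreted as substitution counts replaces the star for
tree-recovery experiments. Indels and insertions are intergenic by
default so orthology truth is unambiguous.

What the simulator does *not* emulate: rearrangements and duplications
(Mugsy's block structure from such events is exercised only via
synthetic overlapping/duplicate-row fixtures in the tests), transition/
transversion bias, rate heterogeneity, recombination, and annotation
error. Passing tests therefore demonstrate correctness of the
post-alignment computation, not robustness to aligner mistakes on real
data.

All draws flow from one `numpy` generator seeded once, in a fixed order
(ancestor, genes, deletions, indels, insertions, substitutions,
fragmentation), so outputs are byte-identical across runs of the same
config.

## Pipeline and problem sizes

Stages run serially in a fixed order; per-genome outputs are independent,
so serial execution in genome order gives the same bytes a parallel
executor would be required to produce — determinism is the contract, and
the manifest records a SHA-256 per artifact to make re-run comparisons
trivial. Any stage failure aborts with the stage name and the partial
manifest.

The test suite and the acceptance script use the simulator at the default
50 kb/4-genome scale, a 20 kb/3-genome identical-genomes null model, and
100 replicates of a 20 kb/6-leaf tree-recovery experiment — sizes chosen
so the full battery exercises every code path in well under a minute while
keeping per-branch substitution counts high enough (≥15) that tree
recovery is expected, not lucky.

## Known limitations

* Clustering quality is bounded by the input annotation: missed or split
  gene calls propagate into the class counts, as the unaligned flag only
  catches the unaligned case.
* The NJ/JC tree is a distance method; for published phylogenies users may
  prefer the FastTree hook or an external ML tool on the exported core
  alignment FASTA.
* Overlapping-block precedence (first block wins) is a convention, not a
  reconstruction of the aligner's intent; regions covered by conflicting
  blocks are resolved deterministically but arbitrarily.
* Protein-level clustering and synonymous/non-synonymous effect prediction
  are out of scope.
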