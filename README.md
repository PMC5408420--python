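# wgacompare

Reference-free comparative analysis of annotated microbial genomes from a
multiple whole-genome alignment.

Comparative studies of closely related bacteria usually start from a set of
annotated genomes (complete or draft) and ask: which genes are part of the
core genome shared by every isolate, which are shared by only some, and
which are strain-specific? Where do the isolates differ at single
nucleotides, and how are they related phylogenetically? `wgacompare`
answers these questions given two inputs:

* one or more **GenBank** files per genome (a draft genome is several
  records sharing one organism name), and
* a **MAF** multiple whole-genome alignment over those genomes, produced by
  an external reference-free aligner such as Mugsy.

From these it computes:

1. **Normalized inputs** — validated genome records, multi-FASTA sequences
   and a tab-delimited annotation map; over-long accessions and malformed
   locus identifiers are corrected deterministically, pseudogenes removed,
   and every correction logged.
2. **Ortholog clusters (COGs)** by positional conservation: two CDSs from
   different genomes are orthologous when their alignment footprints share
   at least half of the smaller footprint's columns; clusters are connected
   components of the link graph. Each CDS is classified **core** (cluster
   spans all genomes), **shared** (≥2 but not all) or **unique** (one
   genome).
3. **SNPs** from alignment columns where at least two gap-free genomes
   disagree, projected into every genome, annotated against CDSs, and
   exported as per-reference tab-delimited tables and VCF 4.2 files.
4. **A core-genome phylogeny**: maximal all-genome gap-free column runs are
   concatenated, pairwise Jukes–Cantor distances
   d = −(3/4)·ln(1 − (4/3)·p) computed, and an unrooted tree built by
   neighbor joining (Newick + PDF/SVG figure). An installed FastTree can be
   hooked in instead.
5. **Reports and tracks** — a run-level summary (contigs, lengths, CDS
   class counts, core-genome length), per-genome CDS/ortholog/SNP
   summaries, and BED-like circular-figure tracks (CDS strands, core and
   unique CDSs, unique SNPs, GC content and GC skew (G−C)/(G+C) over 5 kbp
   windows) with a minimal built-in circular renderer.

A deterministic simulator generates annotated genomes evolved from a random
ancestor along a guide tree — with planted substitutions, gene deletions,
genome-specific gene insertions and intergenic indels — together with the
true MAF and truth tables, so the whole pipeline is testable end to end
without external data.

## Worked example

Simulate four 50 kb genomes with 40 genes each, 50 substitutions per
genome, one gene deletion and one genome-specific gene insertion per
genome, then run the full pipeline on the written files:

```sh
wgacompare simulate --seed 17 --genomes 4 --length 50000 --genes 40 --out sim/
wgacompare run --genbank sim/Genome_A.gbk --genbank sim/Genome_B.gbk \
    --genbank sim/Genome_C.gbk --genbank sim/Genome_D.gbk \
    --maf sim/alignment.maf --out results/
```

which prints

```
simulated 4 genomes -> sim
pipeline complete: 65 artifacts in results/
```

`results/summary_report.tsv` then contains (for seed 17):

```
# core_genome_length_bp	46926
genome	n_contigs	total_length	unique_length	n_cds	n_core	n_shared	n_unique
Genome_A	1	49859		40	36	3	1
Genome_B	1	49962		40	36	3	1
Genome_C	1	49783		40	36	3	1
Genome_D	1	49722		40	36	3	1
```

Each genome keeps 40 CDSs: 36 ancestral genes survive in all four genomes
(core), the 4 genes deleted in exactly one genome appear as shared in the
remaining three (3 per genome), and the planted genome-specific gene is the
single unique CDS. The core genome spans 46,926 of the 50,000 ancestral
bases — the rest fall in deleted genes and small indels. `results/` also
holds `mugsyoutput.cog`/`.raw` (clusters), `snps_<genome>.tsv` and
`.vcf` (200 SNP sites, one per planted substitution), `tree.nwk` with its
PDF/SVG rendering, per-genome summaries, and the `tracks/` ring files.

The same steps are available per stage (`wgacompare normalize / cluster /
snps / phylo`) and as a library (`wgacompare.run_pipeline`,
`wgacompare.call_snps`, `wgacompare.neighbor_joining`, ...).

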