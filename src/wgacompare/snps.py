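"""SNP calling from multiple-alignment columns.

A SNP site is an alignment column where at least two gap-free, unambiguous
genomes carry different nucleotides.  Sites are reference-free; the
per-reference views derive from the same site list:

* per-reference table — rows where the reference genome is present and at
  least one other present genome carries a different base;
* unique SNPs — core columns (every genome present) where the reference base
  differs from *every* other genome, the innermost ring of the circular
  figure.

Gaps and IUPAC ambiguity codes make a genome absent at a column; indels are
never reported.  Columns a genome covers through more than one block count
once, via the projection index's first-block-wins rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .maf import AlignmentBlock, GenomePosition, ProjectionIndex, genome_names

_BASES = b"ACGT"


@dataclass
class SnpSite:
    block_id: int
    column: int
    alleles: dict[str, str]  # genome -> base, only gap-free unambiguous genomes
    positions: dict[str, GenomePosition]

    def __post_init__(self) -> None:
        assert len(self.alleles) >= 2
        assert len(set(self.alleles.values())) >= 2


def call_snps(
    blocks: Sequence[AlignmentBlock], index: ProjectionIndex | None = None
) -> list[SnpSite]:
    """All polymorphic columns, in (block, column) order."""
    if index is None:
        index = ProjectionIndex(blocks)
    sites: list[SnpSite] = []
    for block in blocks:
        if len(block.rows) < 2 or block.width == 0:
            continue
        mat = np.vstack([r.bases() for r in block.rows])  # rows x width, uint8
        present = np.isin(mat, np.frombuffer(_BASES, dtype=np.uint8))
        n_present = present.sum(axis=0)
        # distinct bases among present rows: count how many of A,C,G,T occur
        occur = np.zeros(block.width, dtype=np.int8)
        for b in _BASES:
            occur += ((mat == b) & present).any(axis=0)
        cand = np.nonzero((n_present >= 2) & (occur >= 2))[0]
        if cand.size == 0:
            continue
        row_pos = [r.positions() for r in block.rows]
        for col in cand:
            alleles: dict[str, str] = {}
            positions: dict[str, GenomePosition] = {}
            for ri, row in enumerate(block.rows):
                if not present[ri, col]:
                    continue
                p = int(row_pos[ri][col])
                if not index.owns(
                    row.genome_name, row.contig_accession, p, block.block_id, int(col)
                ):
                    continue  # shadowed by an earlier block
                alleles[row.genome_name] = chr(mat[ri, col])
                positions[row.genome_name] = GenomePosition(
                    row.genome_name, row.contig_accession, p
                )
            if len(alleles) >= 2 and len(set(alleles.values())) >= 2:
                sites.append(
                    SnpSite(
                        block_id=block.block_id,
                        column=int(col),
                        alleles=alleles,
                        positions=positions,
                    )
                )
    return sites


def _annotate_position(
    ann: pd.DataFrame, genome: str, contig: str, position: int, cogs: Mapping[tuple[str, str], int]
) -> tuple[str, str, str]:
    """(locus, product, cog_id) at a genome position; overlapping CDSs are
    pipe-joined; intergenic positions yield 'intergenic'."""
    sub = ann[
        (ann["organism"] == genome)
        & (ann["contig"] == contig)
        & (ann["start"] <= position)
        & (ann["end"] >= position)
    ]
    if sub.empty:
        return "intergenic", "", ""
    loci = list(sub["locus"])
    products = list(sub["product"])
    cog_ids = [str(cogs.get((genome, l), "")) for l in loci]
    return "|".join(loci), "|".join(products), "|".join(cog_ids)


def per_reference_table(
    snps: Sequence[SnpSite],
    annotation_map: pd.DataFrame,
    reference_genome: str,
    cog_by_locus: Mapping[tuple[str, str], int] | None = None,
    input_genomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Annotated SNP table with one genome as reference.

    One row per site where the reference is present and at least one other
    present genome differs; sorted by (contig, position).  Columns carry the
    reference contig/position/base, the comma-joined non-reference variants,
    per-genome alleles, and the CDS annotation at the reference position.
    ``input_genomes`` names the valid references explicitly; otherwise any
    genome seen in the annotation map or at a SNP site is accepted.
    """
    genomes = sorted({g for s in snps for g in s.alleles})
    known = (
        set(input_genomes)
        if input_genomes is not None
        else set(annotation_map["organism"]).union(genomes)
    )
    if reference_genome not in known:
        raise ValueError(f"unknown reference genome {reference_genome!r}")
    cogs = cog_by_locus or {}
    rows = []
    for site in snps:
        ref_base = site.alleles.get(reference_genome)
        if ref_base is None:
            continue
        others = {g: b for g, b in site.alleles.items() if g != reference_genome}
        alts = sorted({b for b in others.values() if b != ref_base})
        if not alts:
            continue
        pos = site.positions[reference_genome]
        locus, product, cog_id = _annotate_position(
            annotation_map, reference_genome, pos.contig_accession, pos.position, cogs
        )
        row = {
            "contig": pos.contig_accession,
            "position": pos.position,
            "ref_base": ref_base,
            "variants": ",".join(alts),
            "locus": locus,
            "product": product,
            "cog_id": cog_id,
            "block_id": site.block_id,
            "column": site.column,
        }
        for g in genomes:
            if g == reference_genome:
                continue
            row[f"allele:{g}"] = site.alleles.get(g, ".")
            p = site.positions.get(g)
            row[f"position:{g}"] = p.position if p else ""
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["contig", "position"], kind="mergesort").reset_index(drop=True)
    return df


def write_snp_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_vcf(
    table: pd.DataFrame,
    reference_genome: str,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Export a per-reference table as VCF 4.2.

    One sample column per non-reference genome; genotypes index into
    REF/ALT, missing (gap/ambiguous) genomes get ".".  These are
    alignment-derived calls without base-quality semantics, so QUAL and
    FILTER are ".".
    """
    sample_cols = [c for c in table.columns if c.startswith("allele:")]
    samples = [c.split(":", 1)[1] for c in sample_cols]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=wgacompare\n##reference={reference_genome}\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        elif not table.empty:
            for name in dict.fromkeys(table["contig"]):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for _, row in table.iterrows():
            alts = row["variants"].split(",")
            allele_index = {row["ref_base"]: 0}
            for k, a in enumerate(alts, start=1):
                allele_index[a] = k
            gts = []
            for g in samples:
                base = row[f"allele:{g}"]
                gts.append(str(allele_index[base]) if base in allele_index else ".")
            fh.write(
                f"{row['contig']}\t{row['position']}\t.\t{row['ref_base']}\t"
                f"{','.join(alts)}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def unique_snps(
    snps: Sequence[SnpSite], reference_genome: str, all_genomes: Sequence[str]
) -> list[SnpSite]:
    """Core-column sites where the reference base differs from every other genome."""
    want = set(all_genomes)
    out = []
    for site in snps:
        if set(site.alleles) != want:
            continue  # not a core column
        ref = site.alleles.get(reference_genome)
        if ref is None:
            continue
        if all(b != ref for g, b in site.alleles.items() if g != reference_genome):
            out.append(site)
    return out


__all__ = [
    "SnpSite",
    "call_snps",
    "per_reference_table",
    "write_snp_table",
    "write_vcf",
    "unique_snps",
    "genome_names",
]
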