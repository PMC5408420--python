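"""Deterministic simulator for annotated genomes with a known true alignment.

The simulator makes the whole pipeline testable without external data or an
external aligner.  It draws a random ancestral genome, places
non-overlapping protein-coding genes on it, and derives the input genomes
along a guide tree (a star by default) by planting:

* nucleotide substitutions (each at a globally unique ancestral position, so
  every planted substitution is exactly one polymorphic alignment column);
* whole-gene deletions;
* genome-specific gene insertions (the planted "unique" genes);
* small intergenic indels.

Because the evolutionary correspondence is known by construction, the true
multiple alignment is emitted as a MAF file alongside the GenBank records,
and a :class:`TruthSet` records the planted SNP positions projected into
every genome, the true orthology of every gene, the planted unique genes,
the guide tree, and the true core-column count.  Indels and insertions are
placed between genes so orthology truth stays unambiguous.

All randomness flows from a single integer seed through one generator, with
a fixed draw order (ancestor, genes, deletions, indels, insertions,
substitutions, fragmentation), so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genbank import CdsFeature, ContigSequence, GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Substitution counts are exact (planted), not expected values, so truth
    tables list exactly what downstream calls must recover.  With the star
    guide tree each genome receives ``substitutions_per_branch`` private
    substitutions.
    """

    seed: int = 17
    n_genomes: int = 4
    genome_length: int = 50_000
    n_genes: int = 40
    substitutions_per_branch: int = 50
    indels_per_genome: int = 2
    indel_max_len: int = 10
    n_unique_gene_insertions: int = 1
    n_gene_deletions: int = 1
    unique_gene_length: int = 600
    guide_tree: str = "star"  # "star" or a newick string with branch lengths
    # interpreted as substitution counts
    draft_fragmentation: int = 1  # contigs per genome

    def validate(self) -> None:
        if self.n_genomes < 2 or self.n_genomes > 26:
            raise ValueError("n_genomes must be in [2, 26]")
        if self.genome_length <= 0 or self.n_genes <= 0:
            raise ValueError("genome_length and n_genes must be positive")
        slot = self.genome_length // self.n_genes
        if slot < 300:
            raise ValueError(
                f"infeasible config: {self.n_genes} genes do not fit in "
                f"{self.genome_length} bp (need >= 300 bp per gene slot)"
            )
        if self.draft_fragmentation < 1:
            raise ValueError("draft_fragmentation must be >= 1")


@dataclass
class TruthSet:
    """Planted ground truth, internally consistent with the emitted files."""

    snps: pd.DataFrame  # anc_pos, genome, contig, position, base, derived
    orthology: pd.DataFrame  # gene_id, genome, locus ('deleted' when absent)
    unique_genes: pd.DataFrame  # genome, locus
    tree_newick: str
    core_column_count: int
    genome_names: list[str]

    def snp_keys(self) -> set[frozenset]:
        """One hashable key per planted SNP site: the frozen set of
        (genome, contig, position, base) tuples of gap-free genomes."""
        keys = []
        for _, grp in self.snps.groupby("anc_pos"):
            keys.append(
                frozenset(
                    (r.genome, r.contig, int(r.position), r.base)
                    for r in grp.itertuples()
                )
            )
        return set(keys)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.snps.to_csv(out_dir / "truth_snps.tsv", sep="\t", index=False)
        self.orthology.to_csv(out_dir / "truth_orthology.tsv", sep="\t", index=False)
        self.unique_genes.to_csv(out_dir / "truth_unique_genes.tsv", sep="\t", index=False)
        (out_dir / "truth_tree.nwk").write_text(self.tree_newick)
        (out_dir / "truth_core_columns.txt").write_text(str(self.core_column_count) + "\n")


@dataclass
class SimulationResult:
    genomes: list[GenomeRecord]
    truth: TruthSet
    maf_text: str
    config: SimulationConfig
    genbank_records: dict[str, list[SeqRecord]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, recs in self.genbank_records.items():
            p = out_dir / f"{name.replace(' ', '_')}.gbk"
            SeqIO.write(recs, str(p), "genbank")
            paths[name] = p
        maf = out_dir / "alignment.maf"
        maf.write_text(self.maf_text)
        paths["maf"] = maf
        self.truth.write(out_dir)
        return paths


def _genome_names(n: int) -> list[str]:
    return [f"Genome_{chr(65 + i)}" for i in range(n)]


def _place_genes(rng, length: int, n_genes: int) -> list[tuple[int, int, str]]:
    """Non-overlapping gene intervals (0-based half-open), one per equal slot,
    with intergenic padding on both sides."""
    slot = length // n_genes
    genes = []
    for i in range(n_genes):
        lo = i * slot
        max_len = min(900, slot - 120)
        glen = int(rng.integers(max(150, max_len // 2), max_len + 1))
        start = lo + int(rng.integers(40, slot - glen - 40))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        genes.append((start, start + glen, strand))
    return genes


def _branches(config: SimulationConfig, names: list[str]) -> tuple[list[tuple[frozenset, int]], str]:
    """Edges of the guide tree as (descendant leaf set, substitution count),
    plus the tree's newick text."""
    if config.guide_tree == "star":
        edges = [(frozenset([nm]), config.substitutions_per_branch) for nm in names]
        newick = "(" + ",".join(f"{nm}:1" for nm in names) + ");"
        return edges, newick
    tree = dendropy.Tree.get(data=config.guide_tree, schema="newick")
    leaves = [lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()]
    if len(leaves) != config.n_genomes:
        raise ValueError(
            f"guide tree has {len(leaves)} leaves but n_genomes={config.n_genomes}"
        )
    edges = []
    all_set = frozenset(leaves)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        desc = frozenset(
            lf.taxon.label.replace(" ", "_")
            for lf in edge.head_node.leaf_iter()
        )
        count = int(round(edge.length))
        if desc and desc != all_set and count > 0:
            edges.append((desc, count))
    return edges, config.guide_tree


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the simulator; see the module docstring for the model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    n = config.n_genomes

    ancestor = rng.integers(0, 4, size=L)
    genes = _place_genes(rng, L, config.n_genes)
    genic = np.zeros(L, dtype=bool)
    for s, e, _ in genes:
        genic[s:e] = True

    if config.guide_tree == "star":
        names = _genome_names(n)
    else:
        tree0 = dendropy.Tree.get(data=config.guide_tree, schema="newick")
        names = [lf.taxon.label.replace(" ", "_") for lf in tree0.leaf_node_iter()]
    edges, tree_newick = _branches(config, names)

    # --- deletions: whole genes, per genome -------------------------------
    deleted: dict[str, set[int]] = {nm: set() for nm in names}  # gene indices
    for nm in names:
        if config.n_gene_deletions > 0:
            picks = rng.choice(config.n_genes, size=config.n_gene_deletions, replace=False)
            deleted[nm].update(int(p) for p in picks)

    presence = {nm: np.ones(L, dtype=bool) for nm in names}
    for nm in names:
        for gi in deleted[nm]:
            s, e, _ = genes[gi]
            presence[nm][s:e] = False

    # --- small intergenic indels ------------------------------------------
    blocked = genic.copy()  # positions unavailable for further events
    for nm in names:
        placed = 0
        attempts = 0
        while placed < config.indels_per_genome and attempts < 1000:
            attempts += 1
            ilen = int(rng.integers(1, config.indel_max_len + 1))
            p = int(rng.integers(0, L - ilen))
            if blocked[p : p + ilen].any():
                continue
            blocked[p : p + ilen] = True
            presence[nm][p : p + ilen] = False  # model indels as deletions
            placed += 1

    # --- unique gene insertions -------------------------------------------
    insertions: dict[int, list[tuple[str, np.ndarray, str]]] = {}
    unique_rows = []
    for nm in names:
        for k in range(config.n_unique_gene_insertions):
            attempts = 0
            while True:
                attempts += 1
                if attempts > 1000:
                    raise ValueError("cannot place unique gene insertion intergenically")
                p = int(rng.integers(1, L - 1))
                if not blocked[p] and p not in insertions:
                    break
            seq = rng.integers(0, 4, size=config.unique_gene_length)
            locus = f"{nm}_u{k + 1:02d}"
            insertions[p] = [(nm, seq, locus)]
            unique_rows.append({"genome": nm, "locus": locus})

    # --- substitutions ------------------------------------------------------
    eligible = np.flatnonzero(
        np.logical_and.reduce([presence[nm] for nm in names])
    )
    total_subs = sum(c for _, c in edges)
    if total_subs > eligible.size:
        raise ValueError("more substitutions requested than eligible positions")
    sub_pos = rng.choice(eligible, size=total_subs, replace=False)
    sub_assign: list[tuple[int, frozenset, int]] = []  # (pos, leafset, alt code)
    cursor = 0
    for leafset, count in edges:
        for p in sub_pos[cursor : cursor + count]:
            ref = int(ancestor[p])
            alt = int((ref + rng.integers(1, 4)) % 4)
            sub_assign.append((int(p), leafset, alt))
        cursor += count
    sub_by_pos = {p: (leafset, alt) for p, leafset, alt in sub_assign}

    # --- leaf sequences over ancestral coordinates -------------------------
    leaf_base = {nm: ancestor.copy() for nm in names}
    for p, (leafset, alt) in sub_by_pos.items():
        for nm in leafset:
            leaf_base[nm][p] = alt

    # --- build the global alignment ----------------------------------------
    # fast path: no insertions and full presence -> pure substitution matrix
    has_indels = bool(insertions) or any(not presence[nm].all() for nm in names)
    code2char = np.frombuffer(b"ACGT", dtype=np.uint8)

    row_chars: dict[str, list] = {nm: [] for nm in names}
    anc2gpos = {nm: np.zeros(L, dtype=np.int64) for nm in names}
    gpos2col: dict[str, list[int]] = {nm: [] for nm in names}
    ins_features: dict[str, list[tuple[int, int, str]]] = {nm: [] for nm in names}
    counters = {nm: 0 for nm in names}

    if not has_indels:
        for nm in names:
            row_chars[nm] = [code2char[leaf_base[nm]].tobytes().decode("ascii")]
            anc2gpos[nm] = np.arange(1, L + 1, dtype=np.int64)
            gpos2col[nm] = list(range(L))
        width = L
    else:
        col = 0
        for p in range(L + 1):
            for nm_ins, seq, locus in insertions.get(p, []):
                g_start = counters[nm_ins] + 1
                for b in seq:
                    for nm in names:
                        if nm == nm_ins:
                            row_chars[nm].append(chr(code2char[b]))
                            counters[nm] += 1
                            gpos2col[nm].append(col)
                        else:
                            row_chars[nm].append("-")
                    col += 1
                ins_features[nm_ins].append((g_start, counters[nm_ins], locus))
            if p == L:
                break
            for nm in names:
                if presence[nm][p]:
                    row_chars[nm].append(chr(code2char[leaf_base[nm][p]]))
                    counters[nm] += 1
                    anc2gpos[nm][p] = counters[nm]
                    gpos2col[nm].append(col)
                else:
                    row_chars[nm].append("-")
            col += 1
        width = col

    rows = {nm: "".join(row_chars[nm]) for nm in names}
    glen = {nm: len(rows[nm].replace("-", "")) for nm in names}

    # --- contig layout ------------------------------------------------------
    # cut each genome into draft contigs at intergenic genome positions
    contig_map: dict[str, list[tuple[str, int, int]]] = {}  # (acc, gstart, gend) 1-based
    for idx, nm in enumerate(names):
        n_contigs = config.draft_fragmentation
        if n_contigs == 1:
            contig_map[nm] = [(f"{nm}_c1", 1, glen[nm])]
            continue
        # genome coords of genic bases for this genome
        genic_g = np.zeros(glen[nm] + 1, dtype=bool)
        for gi, (s, e, _) in enumerate(genes):
            if gi in deleted[nm]:
                continue
            gs, ge = int(anc2gpos[nm][s]), int(anc2gpos[nm][e - 1])
            genic_g[gs : ge + 1] = True
        for g_start, g_end, _ in ins_features[nm]:
            genic_g[g_start : g_end + 1] = True
        candidates = np.flatnonzero(~genic_g[2 : glen[nm]]) + 2  # cut before pos
        cuts = sorted(rng.choice(candidates, size=n_contigs - 1, replace=False).tolist())
        bounds = [1] + [int(c) for c in cuts] + [glen[nm] + 1]
        contig_map[nm] = [
            (f"{nm}_c{k + 1}", bounds[k], bounds[k + 1] - 1)
            for k in range(n_contigs)
        ]

    def locate(nm: str, gpos: int) -> tuple[str, int]:
        for acc, gs, ge in contig_map[nm]:
            if gs <= gpos <= ge:
                return acc, gpos - gs + 1
        raise ValueError(f"{nm}: position {gpos} outside all contigs")

    # --- genome records and GenBank ----------------------------------------
    genome_records: list[GenomeRecord] = []
    genbank_records: dict[str, list[SeqRecord]] = {}
    orth_rows = []
    for nm in names:
        seq_full = rows[nm].replace("-", "")
        contigs = [
            ContigSequence(accession=acc, sequence=seq_full[gs - 1 : ge])
            for acc, gs, ge in contig_map[nm]
        ]
        feats: list[CdsFeature] = []
        for gi, (s, e, strand) in enumerate(genes):
            locus = f"{nm}_{gi:03d}"
            if gi in deleted[nm]:
                orth_rows.append({"gene_id": f"anc{gi:03d}", "genome": nm, "locus": "deleted"})
                continue
            orth_rows.append({"gene_id": f"anc{gi:03d}", "genome": nm, "locus": locus})
            gs_, ge_ = int(anc2gpos[nm][s]), int(anc2gpos[nm][e - 1])
            acc, local_s = locate(nm, gs_)
            acc2, local_e = locate(nm, ge_)
            assert acc == acc2, "gene split across contigs"
            feats.append(
                CdsFeature(
                    locus_id=locus,
                    contig_accession=acc,
                    start=local_s,
                    end=local_e,
                    strand=strand,
                    product=f"hypothetical protein {gi:03d}",
                )
            )
        for g_start, g_end, locus in ins_features[nm]:
            acc, local_s = locate(nm, g_start)
            acc2, local_e = locate(nm, g_end)
            assert acc == acc2
            feats.append(
                CdsFeature(
                    locus_id=locus,
                    contig_accession=acc,
                    start=local_s,
                    end=local_e,
                    strand="+",
                    product="genome-specific protein",
                )
            )
        record = GenomeRecord(organism_name=nm, contigs=contigs, cds_features=feats)
        record.validate()
        genome_records.append(record)

        gb_recs = []
        for contig in record.contigs:
            rec = SeqRecord(
                Seq(contig.sequence),
                id=contig.accession,
                name=contig.accession[:16],
                description=f"{nm} simulated contig",
            )
            rec.annotations["organism"] = nm
            rec.annotations["source"] = nm
            rec.annotations["molecule_type"] = "DNA"
            for f in record.cds_features:
                if f.contig_accession != contig.accession:
                    continue
                rec.features.append(
                    SeqFeature(
                        FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1),
                        type="CDS",
                        qualifiers={"locus_tag": [f.locus_id], "product": [f.product]},
                    )
                )
            gb_recs.append(rec)
        genbank_records[nm] = gb_recs

    # --- truth SNP table -----------------------------------------------------
    snp_rows = []
    for p, (leafset, alt) in sorted(sub_by_pos.items()):
        for nm in names:
            gpos = int(anc2gpos[nm][p])
            if gpos == 0:
                continue
            acc, local = locate(nm, gpos)
            base = "ACGT"[alt] if nm in leafset else "ACGT"[int(ancestor[p])]
            snp_rows.append(
                {
                    "anc_pos": p,
                    "genome": nm,
                    "contig": acc,
                    "position": local,
                    "base": base,
                    "derived": nm in leafset,
                }
            )
    core_columns = int(np.logical_and.reduce([presence[nm] for nm in names]).sum())

    truth = TruthSet(
        snps=pd.DataFrame(snp_rows),
        orthology=pd.DataFrame(orth_rows),
        unique_genes=pd.DataFrame(unique_rows, columns=["genome", "locus"]),
        tree_newick=tree_newick,
        core_column_count=core_columns,
        genome_names=list(names),
    )

    maf_text = _write_maf_text(names, rows, gpos2col, contig_map, glen, width)
    return SimulationResult(
        genomes=genome_records,
        truth=truth,
        maf_text=maf_text,
        config=config,
        genbank_records=genbank_records,
    )


def _write_maf_text(names, rows, gpos2col, contig_map, glen, width) -> str:
    """Emit the true alignment as MAF, splitting blocks at contig boundaries."""
    breakpoints = {0, width}
    col_of = {nm: gpos2col[nm] for nm in names}
    for nm in names:
        for acc, gs, ge in contig_map[nm]:
            if gs > 1:
                breakpoints.add(col_of[nm][gs - 1])  # column of contig's first base
    cuts = sorted(breakpoints)

    # per genome: map genome position -> (contig acc, local pos, contig length)
    def locate(nm, gpos):
        for acc, gs, ge in contig_map[nm]:
            if gs <= gpos <= ge:
                return acc, gpos - gs + 1, ge - gs + 1
        raise ValueError

    # prefix counts of non-gap chars per genome for fast size computation
    import numpy as _np

    nongap = {
        nm: _np.cumsum(_np.frombuffer(rows[nm].encode(), dtype=_np.uint8) != ord("-"))
        for nm in names
    }

    out = ["##maf version=1 scoring=none"]
    for bs, be in zip(cuts[:-1], cuts[1:]):
        lines = []
        for nm in names:
            before = int(nongap[nm][bs - 1]) if bs > 0 else 0
            inside = int(nongap[nm][be - 1]) - before
            if inside == 0:
                continue
            first_gpos = before + 1
            acc, local, clen = locate(nm, first_gpos)
            text = rows[nm][bs:be]
            lines.append(
                f"s {nm}.{acc} {local - 1} {inside} + {clen} {text}"
            )
        if lines:
            out.append("")
            out.append("a score=0")
            out.extend(lines)
    return "\n".join(out) + "\n"


def fragment_to_draft(genome: GenomeRecord, n_contigs: int, seed: int) -> GenomeRecord:
    """Cut a single-contig genome into a draft of ``n_contigs`` records at
    random non-genic positions, re-coordinating every feature."""
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if n_contigs == 1:
        return genome
    if len(genome.contigs) != 1:
        raise ValueError("fragment_to_draft expects a single-contig genome")
    contig = genome.contigs[0]
    L = contig.length
    genic = np.zeros(L + 1, dtype=bool)
    for f in genome.cds_features:
        genic[f.start : f.end + 1] = True
    candidates = np.flatnonzero(~genic[2:L]) + 2
    if candidates.size < n_contigs - 1:
        raise ValueError("not enough intergenic positions to cut without splitting a gene")
    rng = np.random.default_rng(seed)
    cuts = sorted(rng.choice(candidates, size=n_contigs - 1, replace=False).tolist())
    bounds = [1] + [int(c) for c in cuts] + [L + 1]
    contigs = []
    feats: list[CdsFeature] = []
    for k in range(n_contigs):
        gs, ge = bounds[k], bounds[k + 1] - 1
        acc = f"{contig.accession}_c{k + 1}"
        contigs.append(ContigSequence(accession=acc, sequence=contig.sequence[gs - 1 : ge]))
        for f in genome.cds_features:
            if gs <= f.start and f.end <= ge:
                feats.append(
                    CdsFeature(
                        locus_id=f.locus_id,
                        contig_accession=acc,
                        start=f.start - gs + 1,
                        end=f.end - gs + 1,
                        strand=f.strand,
                        product=f.product,
                    )
                )
    out = GenomeRecord(
        organism_name=genome.organism_name, contigs=contigs, cds_features=feats
    )
    out.validate()
    return out
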