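"""Ortholog cluster (COG) detection by positional conservation.

Two CDSs from different genomes are considered orthologous when their
footprints in the whole-genome alignment overlap — i.e. they are conserved
in both nucleotide sequence (aligned) and genome location (same alignment
columns).  Clusters of orthologous genes are the connected components of the
pairwise-link graph; every CDS, aligned or not, lands in exactly one
cluster.  Cluster membership drives the core / shared / unique
classification:

* core   — the cluster spans every input genome;
* shared — the cluster spans at least two but not all genomes;
* unique — the cluster spans exactly one genome.

CDSs with no aligned columns at all are classified unique with an
``unaligned`` flag, since nothing in the alignment supports or refutes their
presence elsewhere; they deserve follow-up sequence searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .genbank import CdsFeature, GenomeRecord
from .maf import AlignmentBlock, ProjectionIndex

DEFAULT_OVERLAP_THRESHOLD = 0.5


@dataclass
class CdsFootprint:
    """The set of alignment columns a CDS occupies, with coverage fraction."""

    genome_name: str
    cds: CdsFeature
    aligned_columns: frozenset[tuple[int, int]]
    coverage_fraction: float

    @property
    def locus_id(self) -> str:
        return self.cds.locus_id

    @property
    def is_aligned(self) -> bool:
        return bool(self.aligned_columns)


@dataclass
class CogCluster:
    cog_id: int
    members: list[CdsFootprint]

    @property
    def genomes(self) -> set[str]:
        return {m.genome_name for m in self.members}

    @property
    def member_count_by_genome(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            counts[m.genome_name] = counts.get(m.genome_name, 0) + 1
        return counts


@dataclass(frozen=True)
class CdsClass:
    genome_name: str
    locus_id: str
    cds_class: str  # core | shared | unique
    unaligned_flag: bool
    cog_id: int


def compute_footprints(
    genomes: Sequence[GenomeRecord],
    blocks: Sequence[AlignmentBlock],
    index: ProjectionIndex | None = None,
) -> list[CdsFootprint]:
    """One footprint per CDS: its canonical alignment columns and the fraction
    of its length they cover."""
    if index is None:
        index = ProjectionIndex(blocks)
    out: list[CdsFootprint] = []
    for g in genomes:
        for cds in g.cds_features:
            cols = index.genome_to_columns(
                g.organism_name, cds.contig_accession, cds.start, cds.end
            )
            out.append(
                CdsFootprint(
                    genome_name=g.organism_name,
                    cds=cds,
                    aligned_columns=frozenset(cols),
                    coverage_fraction=len(cols) / cds.length,
                )
            )
    return out


def build_cogs(
    footprints: Sequence[CdsFootprint],
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    genome_order: Sequence[str] | None = None,
) -> list[CogCluster]:
    """Cluster CDSs by footprint overlap.

    Two CDSs from *different* genomes are linked iff their shared alignment
    columns cover at least ``overlap_threshold`` of the smaller footprint.
    CDSs of the same genome are never linked directly (paralog splitting) but
    may share a cluster through links to other genomes.  Clusters are the
    connected components; ids are assigned by the smallest (genome index,
    contig, start) among members so numbering is deterministic.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(footprints)))

    # candidate pairs via a coarse inverted index on column bins
    bin_index: dict[tuple[int, int], list[int]] = {}
    for i, fp in enumerate(footprints):
        for key in {(b, c >> 6) for (b, c) in fp.aligned_columns}:
            bin_index.setdefault(key, []).append(i)
    candidates: set[tuple[int, int]] = set()
    for members in bin_index.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                if footprints[i].genome_name != footprints[j].genome_name:
                    candidates.add((min(i, j), max(i, j)))

    for i, j in candidates:
        fi, fj = footprints[i], footprints[j]
        smaller = min(len(fi.aligned_columns), len(fj.aligned_columns))
        if smaller == 0:
            continue
        shared = len(fi.aligned_columns & fj.aligned_columns)
        if shared / smaller >= overlap_threshold:
            graph.add_edge(i, j)

    if genome_order is None:
        seen: list[str] = []
        for fp in footprints:
            if fp.genome_name not in seen:
                seen.append(fp.genome_name)
        genome_order = seen
    gidx = {name: k for k, name in enumerate(genome_order)}

    def sort_key(fp: CdsFootprint):
        return (gidx.get(fp.genome_name, len(gidx)), fp.cds.contig_accession,
                fp.cds.start, fp.locus_id)

    components = [sorted(comp, key=lambda i: sort_key(footprints[i]))
                  for comp in nx.connected_components(graph)]
    components.sort(key=lambda comp: sort_key(footprints[comp[0]]))
    return [
        CogCluster(cog_id=k, members=[footprints[i] for i in comp])
        for k, comp in enumerate(components, start=1)
    ]


def classify(clusters: Sequence[CogCluster], genome_count: int) -> list[CdsClass]:
    """Assign core / shared / unique per cluster span; unaligned singleton
    members carry the unaligned flag."""
    out: list[CdsClass] = []
    for cl in clusters:
        span = len(cl.genomes)
        if span >= genome_count:
            cds_class = "core"
        elif span >= 2:
            cds_class = "shared"
        else:
            cds_class = "unique"
        for m in cl.members:
            out.append(
                CdsClass(
                    genome_name=m.genome_name,
                    locus_id=m.locus_id,
                    cds_class=cds_class,
                    unaligned_flag=not m.is_aligned,
                    cog_id=cl.cog_id,
                )
            )
    return out


def classes_by_locus(classes: Sequence[CdsClass]) -> dict[tuple[str, str], CdsClass]:
    return {(c.genome_name, c.locus_id): c for c in classes}


def write_cog_files(
    clusters: Sequence[CogCluster],
    annotation_map: pd.DataFrame,
    out_dir: str | Path,
    genome_count: int | None = None,
) -> tuple[Path, Path]:
    """Write the formatted (.cog) and raw (.raw) cluster files.

    ``.cog``: one line per cluster — id, class, genome span, and member loci
    as ``genome:locus`` pairs.  ``.raw``: one line per member carrying the
    full annotation row.  Both tab-delimited with ``#`` header comments and
    byte-deterministic for fixed input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if genome_count is None:
        genome_count = annotation_map["organism"].nunique()
    classes = {
        (c.genome_name, c.locus_id): c for c in classify(clusters, genome_count)
    }
    ann = annotation_map.set_index(["organism", "locus"])

    cog_path = out_dir / "mugsyoutput.cog"
    raw_path = out_dir / "mugsyoutput.raw"
    with open(cog_path, "w") as fh:
        fh.write("#cog_id\tclass\tn_genomes\tn_members\tmembers\n")
        for cl in clusters:
            first = classes[(cl.members[0].genome_name, cl.members[0].locus_id)]
            members = ",".join(f"{m.genome_name}:{m.locus_id}" for m in cl.members)
            fh.write(
                f"{cl.cog_id}\t{first.cds_class}\t{len(cl.genomes)}\t"
                f"{len(cl.members)}\t{members}\n"
            )
    with open(raw_path, "w") as fh:
        fh.write(
            "#cog_id\tclass\torganism\tlocus\tcontig\tstart\tend\tstrand\t"
            "product\tcoverage\n"
        )
        for cl in clusters:
            for m in cl.members:
                row = ann.loc[(m.genome_name, m.locus_id)]
                cls = classes[(m.genome_name, m.locus_id)]
                fh.write(
                    f"{cl.cog_id}\t{cls.cds_class}\t{m.genome_name}\t{m.locus_id}\t"
                    f"{row['contig']}\t{row['start']}\t{row['end']}\t{row['strand']}\t"
                    f"{row['product']}\t{m.coverage_fraction:.4f}\n"
                )
    return cog_path, raw_path
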