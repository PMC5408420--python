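"""Summary reports, GC tracks, and circular-figure track data.

Two report levels mirror how comparative runs are reviewed: a run-level
``summary_report`` (one row per genome: contigs, lengths, CDS class counts,
plus the shared core-genome length and tool citations) for a quick sanity
check, and a per-genome ``summary_file`` listing every CDS with its
orthologs and the SNPs inside it for detailed follow-up.

Track data for circular genome figures is exported as plain BED-like files
(0-based half-open), one file per ring — contigs, forward/reverse CDSs,
core CDSs, unique CDSs, unique SNPs, GC content and GC skew over
non-overlapping 5 kbp windows — so any circular plotter can render them; a
minimal built-in matplotlib renderer is included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clusters import CdsClass, CogCluster
from .genbank import GenomeRecord
from .snps import SnpSite

DEFAULT_GC_WINDOW = 5000

TOOL_CITATIONS = [
    ("whole-genome alignment", "Mugsy (Angiuoli & Salzberg 2011) / NUCmer (Kurtz et al. 2004)"),
    ("ortholog clusters", "positional-conservation clustering after Mugsy-Annotator (Angiuoli et al. 2011)"),
    ("SNP calling", "multiple-alignment column scan (this package)"),
    ("core phylogeny", "concatenated core fragments after Phylomark (Sahl et al. 2012); Jukes-Cantor + neighbor joining (Saitou & Nei 1987)"),
    ("circular figure tracks", "BED-like export after Circleator (Crabtree et al. 2014)"),
]


@dataclass
class WindowValue:
    contig: str
    window_start: int  # 0-based half-open
    window_end: int
    value: float
    flagged: bool = False  # e.g. GC skew over a window with no G or C


def gc_tracks(
    genome: GenomeRecord, window: int = DEFAULT_GC_WINDOW
) -> tuple[list[WindowValue], list[WindowValue]]:
    """GC content (percent) and GC skew (G-C)/(G+C) over non-overlapping
    windows tiling each contig; the final short window is retained.  N and
    ambiguity bases are excluded from denominators; a window with no G or C
    gets skew 0 with a flag."""
    content: list[WindowValue] = []
    skew: list[WindowValue] = []
    for contig in genome.contigs:
        arr = np.frombuffer(contig.sequence.upper().encode("ascii"), dtype=np.uint8)
        for s in range(0, len(arr), window):
            e = min(s + window, len(arr))
            w = arr[s:e]
            g = int(np.count_nonzero(w == ord("G")))
            c = int(np.count_nonzero(w == ord("C")))
            a = int(np.count_nonzero(w == ord("A")))
            t = int(np.count_nonzero(w == ord("T")))
            denom = a + c + g + t
            pct = 100.0 * (g + c) / denom if denom else 0.0
            content.append(WindowValue(contig.accession, s, e, pct, denom == 0))
            if g + c == 0:
                skew.append(WindowValue(contig.accession, s, e, 0.0, True))
            else:
                skew.append(WindowValue(contig.accession, s, e, (g - c) / (g + c)))
    return content, skew


def _class_counts(classes: Sequence[CdsClass], genome_name: str) -> dict[str, int]:
    counts = {"core": 0, "shared": 0, "unique": 0}
    for c in classes:
        if c.genome_name == genome_name:
            counts[c.cds_class] += 1
    return counts


def unique_genome_length(
    genome: GenomeRecord, blocks, index
) -> int:
    """Bases of the genome lying in no alignment column shared with any other
    genome."""
    shared = 0
    for block in blocks:
        if len({r.genome_name for r in block.rows}) < 2:
            continue
        for row in block.rows:
            if row.genome_name != genome.organism_name:
                continue
            pos = row.positions()
            cols = np.nonzero(pos)[0]
            for col in cols:
                others = [
                    r
                    for r in block.rows
                    if r.genome_name != genome.organism_name and r.text[col] != "-"
                ]
                if others and index.owns(
                    row.genome_name,
                    row.contig_accession,
                    int(pos[col]),
                    block.block_id,
                    int(col),
                ):
                    shared += 1
    return genome.total_length - shared


def build_run_summary(
    genomes: Sequence[GenomeRecord],
    classes: Sequence[CdsClass],
    core_length: int,
    path: str | Path,
    unique_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Run-level tab-delimited summary: one row per genome plus the shared
    core-genome length and tool citations."""
    rows = []
    for g in genomes:
        counts = _class_counts(classes, g.organism_name)
        total = counts["core"] + counts["shared"] + counts["unique"]
        rows.append(
            {
                "genome": g.organism_name,
                "n_contigs": len(g.contigs),
                "total_length": g.total_length,
                "unique_length": (unique_lengths or {}).get(g.organism_name, ""),
                "n_cds": total,
                "n_core": counts["core"],
                "n_shared": counts["shared"],
                "n_unique": counts["unique"],
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("# comparative analysis summary report\n")
        fh.write(f"# core_genome_length_bp\t{core_length}\n")
        df.to_csv(fh, sep="\t", index=False)
        fh.write("#\n# tools and citations\n")
        for step, cite in TOOL_CITATIONS:
            fh.write(f"# {step}\t{cite}\n")
    return df


def build_genome_summary(
    genome: GenomeRecord,
    clusters: Sequence[CogCluster],
    classes: Sequence[CdsClass],
    snps: Sequence[SnpSite],
    path: str | Path,
) -> pd.DataFrame:
    """Per-genome summary: every CDS with start/stop, annotation, class,
    orthologs from the other genomes, and the SNPs falling inside it with
    the variant alleles of the orthologous genomes."""
    by_locus = {(c.genome_name, c.locus_id): c for c in classes}
    cluster_of: dict[str, CogCluster] = {}
    for cl in clusters:
        for m in cl.members:
            if m.genome_name == genome.organism_name:
                cluster_of[m.locus_id] = cl

    # SNPs indexed by (contig, position) for this genome
    snp_rows: list[tuple[str, int, SnpSite]] = []
    for site in snps:
        p = site.positions.get(genome.organism_name)
        if p is not None:
            snp_rows.append((p.contig_accession, p.position, site))

    rows = []
    contig_order = {c.accession: i for i, c in enumerate(genome.contigs)}
    for cds in sorted(
        genome.cds_features,
        key=lambda f: (contig_order[f.contig_accession], f.start),
    ):
        cl = cluster_of.get(cds.locus_id)
        orthologs = (
            ";".join(
                f"{m.genome_name}:{m.locus_id}"
                for m in cl.members
                if m.genome_name != genome.organism_name
            )
            if cl
            else ""
        )
        inside = [
            (pos, site)
            for contig, pos, site in snp_rows
            if contig == cds.contig_accession and cds.start <= pos <= cds.end
        ]
        snp_str = ";".join(
            f"{pos}:"
            + ",".join(f"{g}={b}" for g, b in sorted(site.alleles.items()))
            for pos, site in sorted(inside, key=lambda t: t[0])
        )
        cls = by_locus.get((genome.organism_name, cds.locus_id))
        rows.append(
            {
                "locus": cds.locus_id,
                "contig": cds.contig_accession,
                "start": cds.start,
                "end": cds.end,
                "strand": cds.strand,
                "product": cds.product,
                "class": cls.cds_class if cls else "",
                "cog_id": cl.cog_id if cl else "",
                "orthologs": orthologs,
                "n_snps": len(inside),
                "snps": snp_str,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def _write_bed(path: Path, rows) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def export_circular_tracks(
    genome: GenomeRecord,
    classes: Sequence[CdsClass],
    ref_unique_snps: Sequence[SnpSite],
    gc_content: Sequence[WindowValue],
    gc_skew: Sequence[WindowValue],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one BED-like file per circular-figure ring (0-based half-open).

    Rings: contigs (sorted by size for drafts), CDSs on + and - strands,
    core CDSs, unique CDSs, unique SNPs for this genome as reference, GC
    content, GC skew.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = genome.organism_name.replace(" ", "_")
    by_locus = {
        (c.genome_name, c.locus_id): c.cds_class
        for c in classes
    }
    paths: dict[str, Path] = {}

    contigs = sorted(genome.contigs, key=lambda c: -c.length)
    paths["contigs"] = out_dir / f"{name}.contigs.bed"
    _write_bed(paths["contigs"], [(c.accession, 0, c.length, c.accession) for c in contigs])

    for strand, ring in (("+", "cds_fwd"), ("-", "cds_rev")):
        paths[ring] = out_dir / f"{name}.{ring}.bed"
        _write_bed(
            paths[ring],
            [
                (f.contig_accession, f.start - 1, f.end, f.locus_id)
                for f in genome.cds_features
                if f.strand == strand
            ],
        )
    for cls, ring in (("core", "core_cds"), ("unique", "unique_cds")):
        paths[ring] = out_dir / f"{name}.{ring}.bed"
        _write_bed(
            paths[ring],
            [
                (f.contig_accession, f.start - 1, f.end, f.locus_id)
                for f in genome.cds_features
                if by_locus.get((genome.organism_name, f.locus_id)) == cls
            ],
        )

    paths["unique_snps"] = out_dir / f"{name}.unique_snps.bed"
    snp_rows = []
    for site in ref_unique_snps:
        p = site.positions[genome.organism_name]
        snp_rows.append(
            (p.contig_accession, p.position - 1, p.position, site.alleles[genome.organism_name])
        )
    _write_bed(paths["unique_snps"], sorted(snp_rows))

    for ring, track in (("gc_content", gc_content), ("gc_skew", gc_skew)):
        paths[ring] = out_dir / f"{name}.{ring}.bed"
        _write_bed(
            paths[ring],
            [(w.contig, w.window_start, w.window_end, f"{w.value:.4f}") for w in track],
        )
    return paths


def render_circular_figure(
    genome: GenomeRecord,
    classes: Sequence[CdsClass],
    ref_unique_snps: Sequence[SnpSite],
    gc_content: Sequence[WindowValue],
    gc_skew: Sequence[WindowValue],
    path_stem: str | Path,
) -> None:
    """Minimal circular rendering of the eight rings (PNG + PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    contigs = sorted(genome.contigs, key=lambda c: -c.length)
    total = sum(c.length for c in contigs)
    offsets = {}
    off = 0
    for c in contigs:
        offsets[c.accession] = off
        off += c.length

    def theta(contig: str, pos: float) -> float:
        return 2 * np.pi * (offsets[contig] + pos) / total

    fig = plt.figure(figsize=(8, 8))
    ax = fig.add_subplot(projection="polar")
    ax.set_axis_off()

    # ring radii outside-in
    def arc(contig, start, end, radius, width, color):
        t0, t1 = theta(contig, start), theta(contig, end)
        n = max(2, int((t1 - t0) * 60))
        ts = np.linspace(t0, t1, n)
        ax.fill_between(ts, radius - width, radius, color=color, linewidth=0)

    for c in contigs:
        arc(c.accession, 0, c.length, 1.00, 0.03, "black")
    by_locus = {(cl.genome_name, cl.locus_id): cl.cds_class for cl in classes}
    for f in genome.cds_features:
        r = 0.94 if f.strand == "+" else 0.88
        arc(f.contig_accession, f.start - 1, f.end, r, 0.04, "steelblue")
        cls = by_locus.get((genome.organism_name, f.locus_id))
        if cls == "core":
            arc(f.contig_accession, f.start - 1, f.end, 0.80, 0.04, "darkgreen")
        elif cls == "unique":
            arc(f.contig_accession, f.start - 1, f.end, 0.72, 0.04, "firebrick")
    for site in ref_unique_snps:
        p = site.positions[genome.organism_name]
        t = theta(p.contig_accession, p.position)
        ax.plot([t, t], [0.60, 0.64], color="purple", linewidth=0.5)
    for ring, track, color in (
        (0.52, gc_content, "gray"),
        (0.38, gc_skew, "olive"),
    ):
        vals = np.array([w.value for w in track], dtype=float)
        spread = float(vals.max() - vals.min()) if len(vals) else 0.0
        if spread > 0:
            norm = (vals - vals.min()) / spread
        else:
            norm = np.full(len(vals), 0.5)
        for w, v in zip(track, norm):
            arc(w.contig, w.window_start, w.window_end, ring, 0.10 * v + 0.001, color)
    ax.set_title(genome.organism_name)
    stem = Path(path_stem)
    for suffix in (".png", ".pdf"):
        fig.savefig(stem.with_suffix(suffix), dpi=120)
    plt.close(fig)
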