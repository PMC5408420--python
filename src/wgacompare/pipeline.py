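"""End-to-end pipeline: normalize -> cluster -> SNPs -> phylogeny -> reports.

Stages run in a fixed order on validated inputs; per-genome outputs
(per-reference SNP tables and VCFs, per-genome summaries, ring tracks) are
independent of each other and are produced serially in genome order, which
makes the run deterministic by construction — the same guarantee a parallel
executor would have to provide.  Every artifact lands in the output
directory and is listed in a JSON manifest; any stage failure aborts with
the stage name and the manifest of what was already written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import clusters as _clusters
from . import genbank as _genbank
from . import maf as _maf
from . import phylogeny as _phylo
from . import reports as _reports
from . import snps as _snps


@dataclass
class PipelineConfig:
    genbank_paths: list[str]
    maf_path: str
    out_dir: str
    overlap_threshold: float = _clusters.DEFAULT_OVERLAP_THRESHOLD
    min_fragment_length: int = _phylo.DEFAULT_MIN_FRAGMENT_LENGTH
    low_diversity_filter: bool = False
    density_window: int = 100
    max_snp_density: float = 0.5
    gc_window: int = _reports.DEFAULT_GC_WINDOW
    tree_method: str = "nj"  # nj | external-fasttree
    references: list[str] = field(default_factory=list)  # empty = all genomes
    render_figures: bool = True

    def validate(self) -> None:
        if not self.genbank_paths:
            raise ValueError("no GenBank inputs configured")
        for p in self.genbank_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"GenBank input not found: {p}")
        if not Path(self.maf_path).exists():
            raise FileNotFoundError(
                f"MAF alignment not found: {self.maf_path} "
                "(run an external whole-genome aligner such as Mugsy first)"
            )
        if self.tree_method not in ("nj", "external-fasttree"):
            raise ValueError(f"unknown tree method {self.tree_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict[str, list[str]] = {}

    def record(stage: str, *paths: Path) -> None:
        manifest.setdefault(stage, []).extend(str(p) for p in paths)

    stage = "normalize"
    try:
        raw = _genbank.read_genbank(config.genbank_paths)
        candidates, log = _genbank.validate_and_correct(raw)
        genomes = _genbank.group_by_organism(candidates)
        norm_dir = out / "normalized"
        norm_dir.mkdir(exist_ok=True)
        for g in genomes:
            p = norm_dir / f"{g.organism_name.replace(' ', '_')}.fasta"
            _genbank.write_multifasta(g, p)
            record(stage, p)
        amap = _genbank.build_annotation_map(genomes)
        _genbank.write_annotation_map(amap, norm_dir / "annotation_map.tsv")
        log.write(norm_dir / "corrections.tsv")
        record(stage, norm_dir / "annotation_map.tsv", norm_dir / "corrections.tsv")

        stage = "alignment"
        blocks = _maf.parse_maf(config.maf_path)
        index = _maf.ProjectionIndex(blocks)
        names = [g.organism_name for g in genomes]

        stage = "cluster"
        footprints = _clusters.compute_footprints(genomes, blocks, index)
        cogs = _clusters.build_cogs(
            footprints, config.overlap_threshold, genome_order=names
        )
        classes = _clusters.classify(cogs, len(genomes))
        cog_path, raw_path = _clusters.write_cog_files(cogs, amap, out, len(genomes))
        record(stage, cog_path, raw_path)

        stage = "snps"
        sites = _snps.call_snps(blocks, index)
        cog_by_locus = {(c.genome_name, c.locus_id): c.cog_id for c in classes}
        refs = config.references or names
        unique_by_ref = {}
        for ref in refs:
            table = _snps.per_reference_table(
                sites, amap, ref, cog_by_locus, input_genomes=names
            )
            safe = ref.replace(" ", "_")
            tpath = out / f"snps_{safe}.tsv"
            vpath = out / f"snps_{safe}.vcf"
            _snps.write_snp_table(table, tpath)
            ref_genome = next(g for g in genomes if g.organism_name == ref)
            _snps.write_vcf(
                table,
                ref,
                vpath,
                {c.accession: c.length for c in ref_genome.contigs},
            )
            record(stage, tpath, vpath)
            unique_by_ref[ref] = _snps.unique_snps(sites, ref, names)

        stage = "phylo"
        core_len = _phylo.core_column_count(blocks, names)
        fragments = _phylo.extract_core_fragments(
            blocks, names, config.min_fragment_length
        )
        alignment = _phylo.curate(
            fragments,
            genomes=names,
            low_diversity_filter=config.low_diversity_filter,
            window=config.density_window,
            max_snp_density=config.max_snp_density,
        )
        _phylo.write_alignment_fasta(alignment, out / "core_alignment.fasta")
        record(stage, out / "core_alignment.fasta")
        if len(names) >= 2:
            dm = _phylo.jukes_cantor_distances(alignment)
            if config.tree_method == "external-fasttree":
                tree = _phylo.run_external_fasttree(alignment)
            else:
                tree = _phylo.neighbor_joining(dm)
            figure = out / "tree" if config.render_figures else None
            _phylo.write_tree(tree, out / "tree.nwk", figure)
            record(stage, out / "tree.nwk")
            if figure is not None:
                record(stage, figure.with_suffix(".pdf"), figure.with_suffix(".svg"))

        stage = "reports"
        summary_df = _reports.build_run_summary(
            genomes, classes, core_len, out / "summary_report.tsv"
        )
        record(stage, out / "summary_report.tsv")
        for g in genomes:
            safe = g.organism_name.replace(" ", "_")
            spath = out / f"summary_{safe}.tsv"
            _reports.build_genome_summary(g, cogs, classes, sites, spath)
            record(stage, spath)
            gc_content, gc_skew = _reports.gc_tracks(g, config.gc_window)
            track_paths = _reports.export_circular_tracks(
                g,
                classes,
                unique_by_ref.get(g.organism_name, []),
                gc_content,
                gc_skew,
                out / "tracks",
            )
            record(stage, *track_paths.values())
            if config.render_figures:
                stem = out / "tracks" / f"{safe}.circular"
                _reports.render_circular_figure(
                    g,
                    classes,
                    unique_by_ref.get(g.organism_name, []),
                    gc_content,
                    gc_skew,
                    stem,
                )
                record(stage, stem.with_suffix(".png"), stem.with_suffix(".pdf"))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, manifest, exc) from exc

    full = {
        stage: {p: _sha256(Path(p)) for p in paths}
        for stage, paths in manifest.items()
    }
    (out / "manifest.json").write_text(json.dumps(full, indent=2, sort_keys=True))
    return full
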