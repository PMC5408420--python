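"""Ortholog clustering: footprints, link graph, classification, files."""

from __future__ import annotations

import itertools
from collections import Counter

import pytest

from conftest import make_block
from wgacompare import genbank as gb
from wgacompare.clusters import (
    build_cogs,
    classify,
    compute_footprints,
    write_cog_files,
)
from wgacompare.genbank import CdsFeature, ContigSequence, GenomeRecord
from wgacompare.maf import ProjectionIndex


def _genome(name: str, length: int, cds: list[tuple[str, int, int]]) -> GenomeRecord:
    return GenomeRecord(
        organism_name=name,
        contigs=[ContigSequence(accession=f"{name}_c1", sequence="A" * length)],
        cds_features=[
            CdsFeature(locus_id=l, contig_accession=f"{name}_c1", start=s, end=e, strand="+")
            for l, s, e in cds
        ],
    )


def _identical_block(names, width=100):
    return make_block(
        0, [(nm, f"{nm}_c1", 0, "+", width, "ACGT" * (width // 4)) for nm in names]
    )


def test_footprint_coverage_full_none_half():
    names = ["gA", "gB"]
    block = _identical_block(names, width=100)
    genomes = [
        _genome("gA", 200, [("full", 10, 29), ("none", 150, 169), ("half", 91, 110)]),
        _genome("gB", 100, [("b1", 10, 29)]),
    ]
    fps = compute_footprints(genomes, [block])
    by = {f.locus_id: f for f in fps}
    assert by["full"].coverage_fraction == 1.0
    assert by["none"].coverage_fraction == 0.0 and not by["none"].is_aligned
    assert by["half"].coverage_fraction == 0.5


def test_identity_genomes_one_cluster_per_gene():
    names = ["gA", "gB", "gC"]
    block = _identical_block(names, width=120)
    cds = [("x", 1, 30), ("y", 41, 70), ("z", 81, 110)]
    genomes = [
        _genome(nm, 120, [(f"{nm}_{l}", s, e) for l, s, e in cds]) for nm in names
    ]
    fps = compute_footprints(genomes, [block])
    cogs = build_cogs(fps)
    assert len(cogs) == 3
    assert all(len(c.members) == 3 and len(c.genomes) == 3 for c in cogs)
    classes = classify(cogs, 3)
    assert all(c.cds_class == "core" for c in classes)


def test_gene_deleted_in_one_genome_gives_shared_pair():
    names = ["gA", "gB", "gC"]
    block = _identical_block(names, width=120)
    genomes = [
        _genome("gA", 120, [("gA_g", 11, 40)]),
        _genome("gB", 120, [("gB_g", 11, 40)]),
        _genome("gC", 120, []),  # gene deleted
    ]
    cogs = build_cogs(compute_footprints(genomes, [block]))
    assert len(cogs) == 1 and len(cogs[0].members) == 2
    classes = classify(cogs, 3)
    assert {c.cds_class for c in classes} == {"shared"}


def test_links_match_exhaustive_pairwise_enumeration():
    """Tandem duplicates in one genome against one gene in another: the
    component must equal the brute-force link closure."""
    names = ["gA", "gB"]
    block = _identical_block(names, width=200)
    genomes = [
        _genome("gA", 200, [("a1", 1, 60), ("a2", 61, 120)]),
        _genome("gB", 200, [("b1", 31, 90)]),
    ]
    fps = compute_footprints(genomes, [block])
    cogs = build_cogs(fps, overlap_threshold=0.5)

    # brute force: all cross-genome pairs
    links = set()
    for fi, fj in itertools.combinations(fps, 2):
        if fi.genome_name == fj.genome_name:
            continue
        smaller = min(len(fi.aligned_columns), len(fj.aligned_columns))
        if smaller and len(fi.aligned_columns & fj.aligned_columns) / smaller >= 0.5:
            links.add(frozenset([fi.locus_id, fj.locus_id]))
    assert links == {frozenset(["a1", "b1"]), frozenset(["a2", "b1"])}
    # closure: one cluster holding all three, despite no direct a1-a2 link
    assert len(cogs) == 1
    assert {m.locus_id for m in cogs[0].members} == {"a1", "a2", "b1"}


def test_same_genome_cds_never_linked_directly():
    block = _identical_block(["gA"], width=100)
    genomes = [_genome("gA", 100, [("a1", 1, 50), ("a2", 26, 75)])]
    cogs = build_cogs(compute_footprints(genomes, [block]))
    assert len(cogs) == 2  # heavy overlap, same genome: stay apart


def test_unaligned_cds_is_unique_with_flag():
    block = _identical_block(["gA", "gB"], width=40)
    genomes = [_genome("gA", 200, [("lone", 101, 150)]), _genome("gB", 40, [])]
    cogs = build_cogs(compute_footprints(genomes, [block]))
    classes = classify(cogs, 2)
    (c,) = classes
    assert c.cds_class == "unique" and c.unaligned_flag


def test_raising_threshold_never_merges_clusters():
    names = ["gA", "gB"]
    block = _identical_block(names, width=200)
    genomes = [
        _genome("gA", 200, [("a1", 1, 60), ("a2", 101, 160)]),
        _genome("gB", 200, [("b1", 41, 100), ("b2", 141, 200)]),
    ]
    fps = compute_footprints(genomes, [block])
    sizes = []
    for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
        sizes.append(len(build_cogs(fps, overlap_threshold=thr)))
    assert sizes == sorted(sizes)  # clusters only split as threshold rises


def test_partition_and_per_genome_conservation(parsed_default):
    genomes, blocks, index = parsed_default
    fps = compute_footprints(genomes, blocks, index)
    names = [g.organism_name for g in genomes]
    cogs = build_cogs(fps, genome_order=names)
    total_cds = sum(len(g.cds_features) for g in genomes)
    assert sum(len(c.members) for c in cogs) == total_cds
    seen = Counter()
    for c in cogs:
        for m in c.members:
            seen[(m.genome_name, m.locus_id)] += 1
    assert all(v == 1 for v in seen.values())
    classes = classify(cogs, len(genomes))
    per_genome = Counter()
    for c in classes:
        per_genome[c.genome_name] += 1
    for g in genomes:
        assert per_genome[g.organism_name] == len(g.cds_features)


def test_planted_orthology_recovered_exactly(parsed_default, default_sim):
    """Clusters on simulator output equal the planted orthology truth."""
    genomes, blocks, index = parsed_default
    names = [g.organism_name for g in genomes]
    cogs = build_cogs(compute_footprints(genomes, blocks, index), genome_order=names)
    got = {
        frozenset((m.genome_name, m.locus_id) for m in c.members) for c in cogs
    }
    truth = default_sim.truth
    expected = set()
    for gene_id, grp in truth.orthology.groupby("gene_id"):
        members = frozenset(
            (r.genome, r.locus) for r in grp.itertuples() if r.locus != "deleted"
        )
        if members:
            expected.add(members)
    for r in truth.unique_genes.itertuples():
        expected.add(frozenset([(r.genome, r.locus)]))
    assert got == expected


def test_cog_files_deterministic_and_consistent(parsed_default, tmp_path):
    genomes, blocks, index = parsed_default
    names = [g.organism_name for g in genomes]
    cogs = build_cogs(compute_footprints(genomes, blocks, index), genome_order=names)
    amap = gb.build_annotation_map(genomes)
    p1, r1 = write_cog_files(cogs, amap, tmp_path / "a", len(genomes))
    p2, r2 = write_cog_files(cogs, amap, tmp_path / "b", len(genomes))
    assert p1.read_bytes() == p2.read_bytes()
    assert r1.read_bytes() == r2.read_bytes()
    n_records = sum(1 for line in p1.read_text().splitlines() if not line.startswith("#"))
    assert n_records == len(cogs)
    # raw rows join back to the annotation map exactly
    import pandas as pd

    raw = pd.read_csv(r1, sep="\t")
    raw.columns = [c.lstrip("#") for c in raw.columns]
    merged = raw.merge(amap, on=["organism", "locus"], suffixes=("", "_map"))
    assert len(merged) == len(raw) == len(amap)
    assert (merged["start"] == merged["start_map"]).all()
    assert (merged["end"] == merged["end_map"]).all()
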