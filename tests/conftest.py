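"""Shared fixtures: simulated datasets and hand-built toy alignments."""

from __future__ import annotations

import pytest

from wgacompare.maf import AlignmentBlock, BlockRow
from wgacompare.simulate import SimulationConfig, simulate


def make_block(block_id: int, rows: list[tuple[str, str, int, str, int, str]]) -> AlignmentBlock:
    """Rows as (genome, contig, start, strand, src_size, text)."""
    built = []
    for genome, contig, start, strand, src_size, text in rows:
        size = sum(1 for ch in text if ch != "-")
        built.append(
            BlockRow(
                genome_name=genome,
                contig_accession=contig,
                start=start,
                size=size,
                strand=strand,
                src_size=src_size,
                text=text,
            )
        )
    block = AlignmentBlock(block_id=block_id, rows=built)
    block.validate()
    return block


@pytest.fixture(scope="session")
def default_sim():
    """The standard 4-genome simulated dataset with planted substitutions,
    one gene deletion and one unique gene insertion per genome."""
    return simulate(SimulationConfig())


@pytest.fixture(scope="session")
def default_sim_dir(default_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("sim")
    paths = default_sim.write(d)
    return d, paths


@pytest.fixture(scope="session")
def identical_sim():
    """Null model: no substitutions, indels, deletions or insertions —
    all genomes identical to the ancestor."""
    return simulate(
        SimulationConfig(
            seed=3,
            n_genomes=3,
            genome_length=20_000,
            n_genes=15,
            substitutions_per_branch=0,
            indels_per_genome=0,
            n_unique_gene_insertions=0,
            n_gene_deletions=0,
        )
    )


@pytest.fixture(scope="session")
def parsed_default(default_sim_dir):
    """Simulated dataset round-tripped through files: genomes, blocks, index."""
    from wgacompare import genbank as gb
    from wgacompare import maf as M

    d, paths = default_sim_dir
    raw = gb.read_genbank([p for k, p in paths.items() if k != "maf"])
    candidates, _ = gb.validate_and_correct(raw)
    genomes = gb.group_by_organism(candidates)
    blocks = M.parse_maf(paths["maf"])
    index = M.ProjectionIndex(blocks)
    return genomes, blocks, index
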