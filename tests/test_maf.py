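"""MAF parsing and coordinate projection, with brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgacompare.maf import (
    AlignmentBlock,
    BlockRow,
    GenomePosition,
    ProjectionIndex,
    column_to_genome,
    genome_names,
    genome_to_columns,
    parse_maf,
)
from conftest import make_block

TOY_MAF = """##maf version=1

a score=10
s gA.c1 0 10 + 100 ACGTACGTAC
s gB.c1 5 10 + 100 ACGTACGTAC
s gC.c1 0 8 + 50 AC--ACGTAC

a score=3
s gA.c1 20 7 + 100 ACGTACG
s gB.c2 0 6 - 60 ACG-TAC
"""


def test_parse_toy_maf(tmp_path):
    p = tmp_path / "toy.maf"
    p.write_text(TOY_MAF)
    blocks = parse_maf(p)
    assert [b.block_id for b in blocks] == [0, 1]
    assert [b.width for b in blocks] == [10, 7]
    assert blocks[0].rows[2].size == 8
    assert blocks[1].rows[1].strand == "-"
    assert genome_names(blocks) == ["gA", "gB", "gC"]


def test_parse_counts_nongap_sizes(tmp_path):
    p = tmp_path / "t.maf"
    p.write_text("a\ns gA.c1 0 4 + 10 AC-GT\ns gB.c1 0 5 + 10 ACTGT\n")
    (block,) = parse_maf(p)
    assert block.width == 5
    assert [r.size for r in block.rows] == [4, 5]


def test_parse_empty_file(tmp_path):
    p = tmp_path / "empty.maf"
    p.write_text("")
    assert parse_maf(p) == []


def test_ragged_block_is_hard_error():
    with pytest.raises(ValueError, match="ragged"):
        make_block(0, [("gA", "c1", 0, "+", 10, "ACGT"), ("gB", "c1", 0, "+", 10, "ACG")])


def test_duplicate_genome_row_keeps_larger(tmp_path):
    p = tmp_path / "dup.maf"
    p.write_text(
        "a\ns gA.c1 0 5 + 50 ACGTT\ns gA.c2 0 3 + 50 AC--G\ns gB.c1 0 5 + 50 ACGTT\n"
    )
    (block,) = parse_maf(p)
    assert len(block.rows) == 2
    kept = block.row_for("gA")
    assert kept.contig_accession == "c1" and kept.size == 5


def test_forward_strand_projection_example():
    block = make_block(0, [("gA", "c1", 2, "+", 100, "AC-GT")])
    got = [column_to_genome(block, 0, c) for c in range(5)]
    assert [g.position if g else None for g in got] == [3, 4, None, 5, 6]


def test_reverse_strand_projection_example():
    block = make_block(0, [("gA", "c1", 0, "-", 10, "ACGT")])
    positions = [column_to_genome(block, 0, c).position for c in range(4)]
    assert positions == [10, 9, 8, 7]


def test_gap_column_maps_to_none_and_bad_row_errors():
    block = make_block(0, [("gA", "c1", 0, "+", 10, "A-C")])
    assert column_to_genome(block, 0, 1) is None
    with pytest.raises(IndexError):
        column_to_genome(block, 5, 0)


def test_genome_to_columns_within_one_block():
    block = make_block(0, [("gA", "c1", 2, "+", 100, "ACGTACGT")])
    cols = genome_to_columns([block], "gA", "c1", (3, 10))
    assert cols == [(0, c) for c in range(8)]
    assert genome_to_columns([block], "gA", "c1", (50, 60)) == []


def test_interval_spanning_two_blocks_matches_per_block_answers():
    b0 = make_block(0, [("gA", "c1", 0, "+", 100, "ACGTA")])
    b1 = make_block(1, [("gA", "c1", 5, "+", 100, "CGTAC")])
    got = genome_to_columns([b0, b1], "gA", "c1", (1, 10))
    assert got == [(0, c) for c in range(5)] + [(1, c) for c in range(5)]


def test_overlapping_blocks_first_wins():
    b0 = make_block(0, [("gA", "c1", 0, "+", 100, "ACGTA")])
    b1 = make_block(1, [("gA", "c1", 3, "+", 100, "TACGT")])  # overlaps 4,5
    idx = ProjectionIndex([b0, b1])
    assert idx.lookup("gA", "c1", 4) == (0, 3)
    assert idx.lookup("gA", "c1", 6) == (1, 2)
    assert idx.shadowed_counts[("gA", "c1")] == 2


def _brute_force_position(row: BlockRow, column: int) -> int | None:
    """Independent walk over the row text, the long way round."""
    if row.text[column] == "-":
        return None
    offset = sum(1 for ch in row.text[:column] if ch != "-")
    if row.strand == "+":
        return row.start + offset + 1
    return row.src_size - (row.start + offset)


@st.composite
def random_blocks(draw):
    """1-3 blocks over up to 3 genomes with random gaps, strands, starts."""
    n_blocks = draw(st.integers(1, 3))
    blocks = []
    for bid in range(n_blocks):
        width = draw(st.integers(1, 25))
        rows = []
        for g in range(draw(st.integers(1, 3))):
            mask = draw(
                st.lists(st.booleans(), min_size=width, max_size=width)
            )
            text = "".join("ACGT"[(i + g) % 4] if m else "-" for i, m in enumerate(mask))
            size = sum(mask)
            start = draw(st.integers(0, 30))
            strand = draw(st.sampled_from("+-"))
            rows.append((f"g{g}", "c1", start, strand, start + size + draw(st.integers(0, 10)), text))
        blocks.append(make_block(bid, rows))
    return blocks


@settings(max_examples=1000, deadline=None, derandomize=True)
@given(random_blocks())
def test_projection_agrees_with_brute_force(blocks):
    """column_to_genome matches an independent text walk, and the canonical
    index is consistent with it (first block wins on overlap)."""
    idx = ProjectionIndex(blocks)
    seen: dict[tuple[str, str, int], tuple[int, int]] = {}
    for block in blocks:
        for ri, row in enumerate(block.rows):
            count = 0
            for col in range(block.width):
                expected = _brute_force_position(row, col)
                got = column_to_genome(block, ri, col)
                if expected is None:
                    assert got is None
                else:
                    count += 1
                    assert got == GenomePosition(row.genome_name, row.contig_accession, expected)
                    key = (row.genome_name, row.contig_accession, expected)
                    seen.setdefault(key, (block.block_id, col))
            assert count == row.size  # conservation: every non-gap maps
    for (g, c, p), owner in seen.items():
        assert idx.lookup(g, c, p) == owner


@settings(max_examples=200, deadline=None, derandomize=True)
@given(random_blocks())
def test_projection_bijectivity(blocks):
    """Round trip: every non-gap (row, column) is recovered by querying the
    interval around its projected position."""
    idx = ProjectionIndex(blocks)
    for block in blocks:
        for ri, row in enumerate(block.rows):
            for col in range(block.width):
                gp = column_to_genome(block, ri, col)
                if gp is None:
                    continue
                cols = idx.genome_to_columns(
                    gp.genome_name, gp.contig_accession, gp.position, gp.position
                )
                owner = idx.lookup(gp.genome_name, gp.contig_accession, gp.position)
                assert cols == [owner]
                if owner == (block.block_id, col):
                    assert (block.block_id, col) in cols


def test_strand_consistency_reconstructs_row(parsed_default):
    """Extracting mapped forward-strand bases reproduces the gapless row text
    (simulated data is all forward strand)."""
    genomes, blocks, _ = parsed_default
    seqs = {
        (g.organism_name, c.accession): c.sequence
        for g in genomes
        for c in g.contigs
    }
    block = blocks[0]
    for row in block.rows:
        pos = row.positions()
        contig = seqs[(row.genome_name, row.contig_accession)]
        rebuilt = "".join(
            contig[p - 1] for p in pos[np.nonzero(pos)[0]]
        )
        assert rebuilt == row.text.replace("-", "").upper()
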