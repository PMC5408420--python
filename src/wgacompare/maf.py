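"""MAF whole-genome alignment model and coordinate projection.

A reference-free multiple whole-genome alignment (e.g. Mugsy output) is a
sequence of blocks; each block is a set of gapped rows over the same column
range, one row per genome region, with MAF's strand-relative 0-based start
coordinates.  Everything downstream — ortholog footprints, SNP positions,
core fragments — reduces to mapping alignment columns to 1-based
forward-strand genome positions and back, which this module provides.

MAF ``src`` fields are parsed as ``<genome>.<contig>`` on the first dot; a
name-map override is available for dialects that encode names differently.
Rows duplicating a genome within one block keep only the largest row, and
when two blocks claim the same genome position the earlier block in file
order wins, so every genome position projects to at most one (block, column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

GAP = ord("-")
_ACGT = frozenset(b"ACGT")


@dataclass
class BlockRow:
    """One gapped row of an alignment block (MAF `s` line)."""

    genome_name: str
    contig_accession: str
    start: int  # 0-based on the given strand (MAF convention)
    size: int  # aligned (non-gap) bases
    strand: str  # "+" or "-"
    src_size: int  # full contig length
    text: str  # gapped sequence

    _positions: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        nongap = sum(1 for ch in self.text if ch != "-")
        if nongap != self.size:
            raise ValueError(
                f"row {self.genome_name}.{self.contig_accession}: size {self.size} "
                f"!= non-gap count {nongap}"
            )
        if self.start + self.size > self.src_size:
            raise ValueError(
                f"row {self.genome_name}.{self.contig_accession}: start+size exceeds srcSize"
            )

    def positions(self) -> np.ndarray:
        """1-based forward-strand genome position per column; 0 where gapped.

        Reverse-strand rows follow the MAF convention: the strand-relative
        offset k at start s on a contig of length L sits at forward 1-based
        position L - (s + k).
        """
        if self._positions is None:
            arr = np.frombuffer(self.text.encode("ascii"), dtype=np.uint8)
            nongap = arr != GAP
            rank = np.cumsum(nongap) - 1  # 0-based offset on the row's strand
            if self.strand == "+":
                pos = self.start + rank + 1
            else:
                pos = self.src_size - (self.start + rank)
            pos = np.where(nongap, pos, 0)
            self._positions = pos.astype(np.int64)
        return self._positions

    def bases(self) -> np.ndarray:
        """Uppercase byte codes per column (gap retained as '-')."""
        return np.frombuffer(self.text.upper().encode("ascii"), dtype=np.uint8)


@dataclass
class AlignmentBlock:
    block_id: int
    rows: list[BlockRow]

    @property
    def width(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def validate(self) -> None:
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"block {self.block_id}: ragged row lengths {sorted(widths)}")

    def row_for(self, genome_name: str) -> BlockRow | None:
        for r in self.rows:
            if r.genome_name == genome_name:
                return r
        return None


@dataclass(frozen=True)
class GenomePosition:
    genome_name: str
    contig_accession: str
    position: int  # 1-based forward strand


def _split_src(src: str, name_map: Mapping[str, tuple[str, str]] | None) -> tuple[str, str]:
    if name_map and src in name_map:
        return name_map[src]
    if "." in src:
        genome, contig = src.split(".", 1)
        return genome, contig
    return src, src


def parse_maf(
    path: str | Path, name_map: Mapping[str, tuple[str, str]] | None = None
) -> list[AlignmentBlock]:
    """Parse a MAF file into alignment blocks, numbered in file order.

    Duplicate rows for one genome within a block (Mugsy reports duplications)
    are resolved by keeping the row with the largest aligned size.  Unknown
    line types (i/q/e) are skipped by the underlying parser.
    """
    path = Path(path)
    blocks: list[AlignmentBlock] = []
    if path.stat().st_size == 0:
        return blocks
    with open(path) as fh:
        for i, msa in enumerate(AlignIO.parse(fh, "maf")):
            rows: list[BlockRow] = []
            for rec in msa:
                genome, contig = _split_src(rec.id, name_map)
                ann = rec.annotations
                rows.append(
                    BlockRow(
                        genome_name=genome,
                        contig_accession=contig,
                        start=int(ann["start"]),
                        size=int(ann["size"]),
                        strand="+" if ann["strand"] in (1, "+") else "-",
                        src_size=int(ann["srcSize"]),
                        text=str(rec.seq),
                    )
                )
            # de-duplicate: one row per genome, largest size wins, ties by file order
            best: dict[str, BlockRow] = {}
            for r in rows:
                cur = best.get(r.genome_name)
                if cur is None or r.size > cur.size:
                    best[r.genome_name] = r
            kept = [r for r in rows if best[r.genome_name] is r]
            block = AlignmentBlock(block_id=i, rows=kept)
            block.validate()
            blocks.append(block)
    return blocks


def column_to_genome(
    block: AlignmentBlock, row_index: int, column: int
) -> GenomePosition | None:
    """Project one alignment column of one row to a genome position.

    Returns None when the row is gapped at that column.
    """
    if not 0 <= row_index < len(block.rows):
        raise IndexError(f"row index {row_index} out of range")
    if not 0 <= column < block.width:
        raise IndexError(f"column {column} out of range for width {block.width}")
    row = block.rows[row_index]
    pos = int(row.positions()[column])
    if pos == 0:
        return None
    return GenomePosition(row.genome_name, row.contig_accession, pos)


class ProjectionIndex:
    """Bidirectional map between genome positions and canonical (block, column).

    Built once over all blocks; where overlapping blocks cover the same genome
    position, the first block in file order owns it (later claims are logged
    in ``shadowed_counts``).
    """

    def __init__(self, blocks: Sequence[AlignmentBlock]):
        self.blocks = list(blocks)
        # (genome, contig) -> position(1-based) -> (block_id, column)
        self._by_pos: dict[tuple[str, str], dict[int, tuple[int, int]]] = {}
        self.shadowed_counts: dict[tuple[str, str], int] = {}
        for block in self.blocks:
            for row in block.rows:
                key = (row.genome_name, row.contig_accession)
                table = self._by_pos.setdefault(key, {})
                pos = row.positions()
                cols = np.nonzero(pos)[0]
                for col in cols:
                    p = int(pos[col])
                    if p in table:
                        self.shadowed_counts[key] = self.shadowed_counts.get(key, 0) + 1
                    else:
                        table[p] = (block.block_id, int(col))

    def lookup(self, genome: str, contig: str, position: int) -> tuple[int, int] | None:
        return self._by_pos.get((genome, contig), {}).get(position)

    def owns(self, genome: str, contig: str, position: int, block_id: int, column: int) -> bool:
        """True iff (block, column) is the canonical projection of the position."""
        return self.lookup(genome, contig, position) == (block_id, column)

    def genome_to_columns(
        self, genome: str, contig: str, start: int, end: int
    ) -> list[tuple[int, int]]:
        """Canonical (block_id, column) pairs covering a 1-based inclusive interval,
        ordered by genome position; empty where the region is unaligned."""
        table = self._by_pos.get((genome, contig), {})
        out = []
        for p in range(start, end + 1):
            hit = table.get(p)
            if hit is not None:
                out.append(hit)
        return out


def genome_to_columns(
    blocks: Sequence[AlignmentBlock],
    genome_name: str,
    contig: str,
    interval: tuple[int, int],
    index: ProjectionIndex | None = None,
) -> list[tuple[int, int]]:
    """Map a 1-based inclusive genome interval to its alignment columns."""
    if index is None:
        index = ProjectionIndex(blocks)
    return index.genome_to_columns(genome_name, contig, interval[0], interval[1])


def genome_names(blocks: Iterable[AlignmentBlock]) -> list[str]:
    seen: list[str] = []
    for b in blocks:
        for r in b.rows:
            if r.genome_name not in seen:
                seen.append(r.genome_name)
    return seen
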