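"""Core-genome phylogeny from curated concatenated alignment fragments.

The tree is built from the portion of the whole-genome alignment where every
input genome is present and unambiguous (the core genome):

1. extract maximal gap-free all-genome column runs per block (core
   fragments), dropping runs shorter than ``min_fragment_length`` —
   fragments never bridge block boundaries, so non-contiguous genomic
   regions are never concatenated as if adjacent;
2. concatenate the fragments into one curated alignment (optionally dropping
   windows with excessive SNP density);
3. compute pairwise Jukes–Cantor distances d = -(3/4)·ln(1 - (4/3)·p) from
   the observed mismatch proportion p;
4. build an unrooted tree by neighbor joining (Saitou–Nei Q-criterion, ties
   broken by the lowest index pair, negative branch lengths clamped to 0).

An external maximum-likelihood tool (FastTree) can be hooked in instead of
the built-in distance method when it is installed.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

DEFAULT_MIN_FRAGMENT_LENGTH = 200
_ACGT = frozenset("ACGT")


@dataclass
class CoreFragment:
    """A gap-free all-genome column run within one block, half-open columns."""

    block_id: int
    col_start: int
    col_end: int
    sequences: dict[str, str]  # genome -> ungapped fragment sequence

    @property
    def length(self) -> int:
        return self.col_end - self.col_start


@dataclass
class CuratedAlignment:
    genome_order: list[str]
    sequences: dict[str, str]
    fragments: list[tuple[int, int, int]]  # provenance: (block, col_start, col_end)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def matrix(self) -> np.ndarray:
        return np.vstack(
            [
                np.frombuffer(self.sequences[g].encode("ascii"), dtype=np.uint8)
                for g in self.genome_order
            ]
        )


@dataclass
class DistanceMatrix:
    genome_order: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        assert m.shape == (len(self.genome_order), len(self.genome_order))
        assert np.allclose(m, m.T) and np.all(np.diag(m) == 0) and np.all(m >= 0)


def _core_mask(block, genomes: Sequence[str]) -> np.ndarray | None:
    """Boolean mask over block columns where every genome is present with an
    unambiguous base."""
    rows = {r.genome_name: r for r in block.rows}
    if any(g not in rows for g in genomes):
        return None
    mask = np.ones(block.width, dtype=bool)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    for g in genomes:
        mask &= np.isin(rows[g].bases(), acgt)
    return mask


def core_column_count(blocks, genomes: Sequence[str]) -> int:
    """Total alignment columns where every genome is present and unambiguous —
    the core-genome length in bases."""
    total = 0
    for block in blocks:
        mask = _core_mask(block, genomes)
        if mask is not None:
            total += int(mask.sum())
    return total


def extract_core_fragments(
    blocks,
    genomes: Sequence[str],
    min_fragment_length: int = DEFAULT_MIN_FRAGMENT_LENGTH,
) -> list[CoreFragment]:
    """Maximal all-genome gap-free column runs per block, length-filtered.

    Raises if no core columns exist at all: that usually means the input
    genomes are too divergent or too fragmented for a core-genome analysis.
    """
    fragments: list[CoreFragment] = []
    any_core = False
    for block in blocks:
        mask = _core_mask(block, genomes)
        if mask is None or not mask.any():
            continue
        any_core = True
        rows = {r.genome_name: r for r in block.rows}
        # maximal runs of True
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s < min_fragment_length:
                continue
            seqs = {
                g: rows[g].text[s:e].upper() for g in genomes
            }
            fragments.append(CoreFragment(block.block_id, int(s), int(e), seqs))
    if not any_core:
        raise ValueError(
            "no core alignment columns: input genomes may be too divergent, "
            "fragmented or incompletely aligned for a core-genome phylogeny"
        )
    return fragments


def curate(
    fragments: Sequence[CoreFragment],
    genomes: Sequence[str] | None = None,
    low_diversity_filter: bool = False,
    window: int = 100,
    max_snp_density: float = 0.5,
) -> CuratedAlignment:
    """Concatenate core fragments in (block, column) order into one gap-free
    alignment; optionally drop whole windows whose polymorphic-column density
    exceeds ``max_snp_density``."""
    frags = sorted(fragments, key=lambda f: (f.block_id, f.col_start))
    if genomes is None:
        genomes = list(frags[0].sequences) if frags else []
    parts = {g: [] for g in genomes}
    prov = []
    for f in frags:
        for g in genomes:
            parts[g].append(f.sequences[g])
        prov.append((f.block_id, f.col_start, f.col_end))
    seqs = {g: "".join(parts[g]) for g in genomes}
    if low_diversity_filter and seqs and len(next(iter(seqs.values()))) > 0:
        mat = np.vstack(
            [np.frombuffer(seqs[g].encode("ascii"), dtype=np.uint8) for g in genomes]
        )
        poly = (mat != mat[0]).any(axis=0)
        keep = np.ones(mat.shape[1], dtype=bool)
        for s in range(0, mat.shape[1], window):
            e = min(s + window, mat.shape[1])
            if poly[s:e].sum() > max_snp_density * (e - s):
                keep[s:e] = False
        seqs = {
            g: bytes(mat[i, keep]).decode("ascii") for i, g in enumerate(genomes)
        }
    return CuratedAlignment(genome_order=list(genomes), sequences=seqs, fragments=prov)


def write_alignment_fasta(alignment: CuratedAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in alignment.genome_order:
            fh.write(f">{g}\n")
            seq = alignment.sequences[g]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def jukes_cantor_distances(alignment: CuratedAlignment) -> DistanceMatrix:
    """Pairwise JC69 distances from the curated alignment.

    Observed mismatch proportions p >= 0.75 saturate the correction and
    raise; a zero-length alignment raises as well.
    """
    if alignment.length == 0:
        raise ValueError("cannot compute distances from a zero-length alignment")
    mat = alignment.matrix()
    n = len(alignment.genome_order)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(mat[i] != mat[j]))
            if p >= 0.75:
                raise ValueError(
                    f"distance between {alignment.genome_order[i]} and "
                    f"{alignment.genome_order[j]} is saturated (p={p:.3f} >= 0.75)"
                )
            d[i, j] = d[j, i] = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    return DistanceMatrix(genome_order=list(alignment.genome_order), matrix=d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining (Saitou–Nei) over a distance matrix.

    Standard agglomeration on the Q-criterion with ties broken by the lowest
    (i, j) index pair; negative branch lengths are clamped to zero.  Returns
    an unrooted tree (trifurcating seed node) over the genome labels.
    """
    n = len(dm.genome_order)
    if n < 2:
        raise ValueError("neighbor joining requires at least 2 genomes")
    ns = dendropy.TaxonNamespace(dm.genome_order)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for name in dm.genome_order:
        node = dendropy.Node(taxon=ns.get_taxon(name))
        nodes.append(node)
    if n == 2:
        tree.seed_node.add_child(nodes[0])
        tree.seed_node.add_child(nodes[1])
        half = max(float(dm.matrix[0, 1]) / 2.0, 0.0)
        nodes[0].edge.length = half
        nodes[1].edge.length = half
        return tree

    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        # distances from the new node to every other active node
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            d[new_idx, k] = d[k, new_idx] = (d[i, k] + d[j, k] - dij) / 2.0
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # resolve the final three nodes around one internal vertex
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    tree.seed_node.add_child(nodes[i])
    tree.seed_node.add_child(nodes[j])
    tree.seed_node.add_child(nodes[k])
    nodes[i].edge.length = max((dij + dik - djk) / 2.0, 0.0)
    nodes[j].edge.length = max((dij + djk - dik) / 2.0, 0.0)
    nodes[k].edge.length = max((dik + djk - dij) / 2.0, 0.0)
    tree.is_rooted = False
    return tree


def run_external_fasttree(alignment: CuratedAlignment, binary: str = "fasttree") -> dendropy.Tree:
    """Optional hook: build the tree with an installed FastTree binary."""
    if shutil.which(binary) is None:
        raise RuntimeError(f"external tree tool {binary!r} not found on PATH")
    fasta = "".join(
        f">{g}\n{alignment.sequences[g]}\n" for g in alignment.genome_order
    )
    proc = subprocess.run(
        [binary, "-nt", "-quiet"],
        input=fasta,
        capture_output=True,
        text=True,
        check=True,
    )
    return dendropy.Tree.get(data=proc.stdout, schema="newick")


def write_tree(
    tree: dendropy.Tree,
    path_newick: str | Path,
    path_figure: str | Path | None = None,
) -> None:
    """Serialize to Newick; optionally render the tree as PDF and SVG
    (``path_figure`` is taken as a stem and both suffixes are written)."""
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    with open(path_newick, "w") as fh:
        fh.write(newick)
    if path_figure is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from Bio import Phylo

        handle = StringIO(newick)
        btree = Phylo.read(handle, "newick")
        fig, ax = plt.subplots(figsize=(6, 0.6 * max(4, len(tree.leaf_nodes()))))
        Phylo.draw(btree, axes=ax, do_show=False)
        stem = Path(path_figure)
        for suffix in (".pdf", ".svg"):
            fig.savefig(stem.with_suffix(suffix))
        plt.close(fig)


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unweighted RF (symmetric difference) between two trees on one label set."""
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=tree_a.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    b = dendropy.Tree.get(
        data=tree_b.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))
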