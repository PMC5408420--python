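"""Core fragments, curation, JC distances, neighbor joining, tree IO."""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np
import pytest

from conftest import make_block
from wgacompare.phylogeny import (
    CuratedAlignment,
    DistanceMatrix,
    core_column_count,
    curate,
    extract_core_fragments,
    jukes_cantor_distances,
    neighbor_joining,
    robinson_foulds,
    write_tree,
)


def _block(texts: dict[str, str], block_id=0):
    return make_block(
        block_id,
        [(nm, f"{nm}_c1", 0, "+", len(t.replace("-", "")), t) for nm, t in texts.items()],
    )


def test_single_gapless_block_one_fragment():
    names = ["g1", "g2", "g3"]
    block = _block({nm: "ACGT" * 250 for nm in names})
    frags = extract_core_fragments([block], names, min_fragment_length=200)
    assert len(frags) == 1 and frags[0].length == 1000


def test_gap_splits_run_into_two_fragments():
    n = 300
    texts = {
        "g1": "A" * (2 * n + 50),
        "g2": "A" * n + "-" * 50 + "A" * n,
    }
    block = _block(texts)
    frags = extract_core_fragments([block], ["g1", "g2"], min_fragment_length=200)
    assert [(f.col_start, f.col_end) for f in frags] == [(0, n), (n + 50, 2 * n + 50)]


def test_short_runs_dropped_by_min_length():
    texts = {"g1": "A" * 400, "g2": "A" * 150 + "-" * 10 + "A" * 240}
    block = _block(texts)
    frags = extract_core_fragments([block], ["g1", "g2"], min_fragment_length=200)
    assert [f.length for f in frags] == [240]


def test_no_core_columns_is_actionable_error():
    block = _block({"g1": "ACGT", "g2": "----AAAA"[:4]})
    with pytest.raises(ValueError, match="no core alignment columns"):
        extract_core_fragments([block], ["g1", "g2", "g3"], min_fragment_length=1)


def test_ambiguity_column_excluded_from_core():
    texts = {"g1": "AANAA", "g2": "AAAAA"}
    frags = extract_core_fragments([_block(texts)], ["g1", "g2"], min_fragment_length=1)
    assert sum(f.length for f in frags) == 4
    assert core_column_count([_block(texts)], ["g1", "g2"]) == 4


def test_curate_concatenates_in_order():
    names = ["g1", "g2"]
    b0 = _block({nm: "AAAA" for nm in names}, block_id=0)
    b1 = _block({nm: "CCCCCC" for nm in names}, block_id=1)
    frags = extract_core_fragments([b0, b1], names, min_fragment_length=1)
    aln = curate(frags, genomes=names)
    assert aln.length == 10
    assert aln.sequences["g1"] == "AAAACCCCCC"


def test_density_filter_removes_hot_windows():
    half = "A" * 100
    hot = "".join("AC"[i % 2] for i in range(100))  # 50% mismatch vs all-A
    aln_texts = {"g1": half + half, "g2": half + hot}
    frags = extract_core_fragments([_block(aln_texts)], ["g1", "g2"], min_fragment_length=1)
    aln_off = curate(frags, genomes=["g1", "g2"], low_diversity_filter=False)
    assert aln_off.length == 200
    aln_on = curate(
        frags,
        genomes=["g1", "g2"],
        low_diversity_filter=True,
        window=100,
        max_snp_density=0.4,
    )
    assert aln_on.length == 100  # the polymorphic window is dropped whole


def test_jc_distance_closed_form():
    # p = 0.25 -> d = -(3/4) ln(1 - 1/3)
    seq1 = "A" * 75 + "C" * 25
    seq2 = "A" * 100
    aln = CuratedAlignment(["g1", "g2"], {"g1": seq1, "g2": seq2}, [])
    dm = jukes_cantor_distances(aln)
    assert dm.matrix[0, 1] == pytest.approx(-0.75 * math.log(1 - 1 / 3), abs=1e-12)
    ident = CuratedAlignment(["g1", "g2"], {"g1": seq1, "g2": seq1}, [])
    assert jukes_cantor_distances(ident).matrix[0, 1] == 0.0


def test_jc_saturation_and_empty_alignment_error():
    aln = CuratedAlignment(["g1", "g2"], {"g1": "AAAA", "g2": "CCCC"}, [])
    with pytest.raises(ValueError, match="saturated"):
        jukes_cantor_distances(aln)
    empty = CuratedAlignment(["g1", "g2"], {"g1": "", "g2": ""}, [])
    with pytest.raises(ValueError, match="zero-length"):
        jukes_cantor_distances(empty)


def _tree_distance_matrix(newick: str, names: list[str]) -> np.ndarray:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    m = np.zeros((len(names), len(names)))
    for i, j in itertools.combinations(range(len(names)), 2):
        m[i, j] = m[j, i] = pdm.distance(taxa[names[i]], taxa[names[j]])
    return m


def test_nj_recovers_additive_five_leaf_tree_exactly():
    newick = "((A:2,B:3):1,(C:2,D:4):2,E:6);"
    names = list("ABCDE")
    dm = DistanceMatrix(names, _tree_distance_matrix(newick, names))
    nj = neighbor_joining(dm)
    truth = dendropy.Tree.get(data=newick, schema="newick")
    assert robinson_foulds(nj, truth) == 0
    # branch lengths: all leaf-to-leaf path lengths reproduced exactly
    pdm = nj.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in nj.taxon_namespace}
    for i, j in itertools.combinations(range(5), 2):
        assert pdm.distance(taxa[names[i]], taxa[names[j]]) == pytest.approx(
            dm.matrix[i, j], abs=1e-9
        )


def test_nj_three_taxa_closed_form():
    # ultrametric: d(A,B)=2, d(A,C)=d(B,C)=4 -> lengths 1,1,3
    m = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    nj = neighbor_joining(DistanceMatrix(list("ABC"), m))
    lengths = {
        leaf.taxon.label: leaf.edge.length for leaf in nj.leaf_node_iter()
    }
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def test_nj_invariant_to_label_order():
    newick = "((A:2,B:3):1,(C:2,D:4):2,E:6);"
    names = list("ABCDE")
    m = _tree_distance_matrix(newick, names)
    t1 = neighbor_joining(DistanceMatrix(names, m))
    perm = [4, 2, 0, 3, 1]
    names_p = [names[i] for i in perm]
    m_p = m[np.ix_(perm, perm)]
    t2 = neighbor_joining(DistanceMatrix(names_p, m_p))
    assert robinson_foulds(t1, t2) == 0


def test_nj_two_taxa_and_degenerate_inputs():
    nj = neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]])))
    assert {l.taxon.label for l in nj.leaf_node_iter()} == {"A", "B"}
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["A"], np.zeros((1, 1))))


def test_nj_matches_independent_implementation():
    """Cross-check the in-package NJ against dendropy's NJ on a noisy matrix."""
    rng = np.random.default_rng(5)
    newick = "((A:0.1,B:0.2):0.05,(C:0.12,D:0.18):0.07,(E:0.2,F:0.1):0.03);"
    names = list("ABCDEF")
    m = _tree_distance_matrix(newick, names)
    noise = rng.uniform(-0.005, 0.005, size=m.shape)
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0)
    m = np.abs(m + noise)
    mine = neighbor_joining(DistanceMatrix(names, m))

    pdm_csv = "," + ",".join(names) + "\n"
    for i, nm in enumerate(names):
        pdm_csv += nm + "," + ",".join(str(x) for x in m[i]) + "\n"
    import io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO(pdm_csv), delimiter=","
    )
    theirs = pdm.nj_tree()
    assert robinson_foulds(mine, theirs) == 0


def test_write_tree_round_trip(tmp_path):
    newick = "((A:2,B:3):1,(C:2,D:4):2,E:6);"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    out = tmp_path / "t.nwk"
    write_tree(tree, out, tmp_path / "t")
    back = dendropy.Tree.get(path=str(out), schema="newick")
    assert robinson_foulds(tree, back) == 0
    lengths_a = sorted(e.length for e in tree.preorder_edge_iter() if e.length)
    lengths_b = sorted(e.length for e in back.preorder_edge_iter() if e.length)
    assert np.allclose(lengths_a, lengths_b, atol=1e-9)
    assert (tmp_path / "t.pdf").stat().st_size > 0
    assert (tmp_path / "t.svg").stat().st_size > 0


def test_core_length_invariant_to_genome_order(parsed_default):
    _, blocks, _ = parsed_default
    names = ["Genome_A", "Genome_B", "Genome_C", "Genome_D"]
    a = core_column_count(blocks, names)
    b = core_column_count(blocks, names[::-1])
    assert a == b > 0


def test_curated_length_equals_core_columns_when_unfiltered(parsed_default):
    _, blocks, _ = parsed_default
    names = ["Genome_A", "Genome_B", "Genome_C", "Genome_D"]
    frags = extract_core_fragments(blocks, names, min_fragment_length=1)
    aln = curate(frags, genomes=names)
    assert aln.length == core_column_count(blocks, names)
    assert all(len(s) == aln.length for s in aln.sequences.values())
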