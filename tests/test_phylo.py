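"""Tajima-Nei distances, Neighbor-Joining, bootstrap, rooting, Newick."""

import io
import math

import numpy as np
import pytest

from petalsplit.phylo import (
    Clade,
    DistanceError,
    DistanceMatrix,
    PhyloTree,
    bipartitions,
    bootstrap_support,
    nj_tree,
    p_distance,
    root_with_outgroup,
    tajima_nei_distance,
    to_newick,
    write_newick,
)
from petalsplit.seqio import SequenceRecord
from petalsplit.simdata import _mutate


def _related_msa(n_taxa=6, length=400, seed=0, rate=0.06):
    rng = np.random.default_rng(seed)
    root = "".join(rng.choice(list("ACGT"), length))
    return [SequenceRecord(f"t{i}", _mutate(root, rate * (1 + i % 3), rng))
            for i in range(n_taxa)]


# ---------------------------------------------------------------------------
# Tajima-Nei
# ---------------------------------------------------------------------------

def _tn_oracle(s1, s2):
    """Independent direct evaluation of the equal-input (Tajima-Nei 1984)
    distance, written from the published formula with explicit loops."""
    nucs = "ACGT"
    used = [(a, b) for a, b in zip(s1, s2) if a in nucs and b in nucs]
    n = len(used)
    nd = sum(1 for a, b in used if a != b)
    p = nd / n
    if p == 0:
        return 0.0
    freqs = {c: 0 for c in nucs}
    for a, b in used:
        freqs[a] += 1
        freqs[b] += 1
    g = {c: freqs[c] / (2 * n) for c in nucs}
    h = 0.0
    for i in range(4):
        for j in range(i + 1, 4):
            ci, cj = nucs[i], nucs[j]
            nij = sum(1 for a, b in used
                      if (a == ci and b == cj) or (a == cj and b == ci))
            x = nij / n
            if g[ci] > 0 and g[cj] > 0:
                h += x * x / (2 * g[ci] * g[cj])
    b_f = 0.5 * (1 - sum(v * v for v in g.values()) + p * p / h)
    return -b_f * math.log(1 - p / b_f)


def test_identical_sequences_distance_zero():
    msa = [SequenceRecord("a", "ACGTACGTAC"), SequenceRecord("b", "ACGTACGTAC")]
    dm = tajima_nei_distance(msa)
    assert dm[("a", "b")] == 0.0


def test_pairwise_deletion_excludes_gapped_columns():
    msa = [SequenceRecord("a", "ACGT-ACGTA"), SequenceRecord("b", "ACGTTAC-TA")]
    dm = tajima_nei_distance(msa)
    assert dm[("a", "b")] == 0.0   # identical on the 8 shared ungapped sites


@pytest.mark.parametrize("seed", range(8))
def test_distance_matches_independent_formula_evaluation(seed):
    rng = np.random.default_rng(seed)
    s1 = "".join(rng.choice(list("ACGT"), 200))
    s2 = _mutate(s1, 0.12, rng)
    dm = tajima_nei_distance([SequenceRecord("a", s1), SequenceRecord("b", s2)])
    assert dm[("a", "b")] == pytest.approx(_tn_oracle(s1, s2), abs=1e-10)


def test_saturation_flagged_not_clamped():
    rng = np.random.default_rng(99)
    s1 = "".join(rng.choice(list("ACGT"), 300))
    s2 = "".join(rng.choice(list("ACGT"), 300))
    dm = tajima_nei_distance([SequenceRecord("a", s1), SequenceRecord("b", s2)])
    if dm.undefined[0, 1]:
        assert math.isnan(dm[("a", "b")])
        with pytest.raises(DistanceError):
            nj_tree(tajima_nei_distance(
                [SequenceRecord("a", s1), SequenceRecord("b", s2),
                 SequenceRecord("c", s1)]))


def test_matrix_symmetry_and_zero_diagonal():
    dm = tajima_nei_distance(_related_msa())
    assert np.allclose(dm.d, dm.d.T)
    assert np.allclose(np.diag(dm.d), 0.0)


def test_p_distance_for_amino_acids():
    msa = [SequenceRecord("a", "MKV-LL"), SequenceRecord("b", "MKI-LL")]
    dm = p_distance(msa)
    assert dm[("a", "b")] == pytest.approx(1 / 5)


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------

def _random_tree(rng, n_leaves):
    """Random binary topology with positive branch lengths."""
    nodes = [Clade(name=f"L{i}", branch_length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        new = Clade(children=[b, a],
                    branch_length=float(rng.uniform(0.05, 1.0)))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [new]
    return PhyloTree(Clade(children=nodes), rooted=False)


def _additive_matrix(tree):
    leaves = sorted(l.name for l in tree.root.leaves())

    def paths(clade, acc):
        if clade.is_leaf:
            return {clade.name: acc}
        out = {}
        for c in clade.children:
            out.update(paths(c, acc + [(c, c.branch_length or 0.0)]))
        return out

    # distance = sum of branch lengths on the path between two leaves
    node_paths = {}
    def collect(clade, path):
        if clade.is_leaf:
            node_paths[clade.name] = path
        for c in clade.children:
            collect(c, path + [c])
    collect(tree.root, [])
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = node_paths[leaves[i]], node_paths[leaves[j]]
            common = 0
            for a, b in zip(pi, pj):
                if a is b:
                    common += 1
                else:
                    break
            dist = sum(c.branch_length for c in pi[common:]) + \
                sum(c.branch_length for c in pj[common:])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(leaves), d, np.zeros((n, n), dtype=bool))


def test_three_taxon_closed_form():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    dm = DistanceMatrix(("A", "B", "C"), d, np.zeros((3, 3), dtype=bool))
    tree = nj_tree(dm)
    lengths = {c.name: c.branch_length for c in tree.root.children}
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(2.0)
    assert lengths["C"] == pytest.approx(3.0)


def test_four_taxon_additive_recovery():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 0, 0],
    ], dtype=float)
    d[3, 2] = d[2, 3] = 7
    d[3, 3] = 0
    dm = DistanceMatrix(("A", "B", "C", "D"), d, np.zeros((4, 4), dtype=bool))
    tree = nj_tree(dm)
    assert bipartitions(tree) == {frozenset({"C", "D"})}


@pytest.mark.parametrize("seed", range(12))
def test_nj_recovers_random_additive_trees(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 9))
    true = _random_tree(rng, n)
    dm = _additive_matrix(true)
    est = nj_tree(dm)
    assert bipartitions(est) == bipartitions(true)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_nj_topology_agrees_with_independent_library(seed):
    """Cross-check against scikit-bio's independent NJ implementation."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(seed)
    true = _random_tree(rng, 7)
    dm = _additive_matrix(true)
    ours = bipartitions(nj_tree(dm))

    sk_tree = skbio_nj(SkbioDM(dm.d, ids=list(dm.taxa)))
    taxa = frozenset(dm.taxa)
    anchor = min(taxa)
    theirs = set()
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = frozenset(taxa - side) if anchor in side else side
        if 1 < len(canon) < len(taxa) - 1:
            theirs.add(canon)
    assert ours == theirs


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _congruent_msa(n_block=40, n_const=240):
    """Alignment where every variable column supports the same nested
    topology; constant columns keep p below the saturation bound."""
    taxa = ["A", "B", "C", "D", "E", "F"]
    cols = []
    # columns supporting {A,B}, {A,B,C}, {D,E}
    for members, base, alt in (({"A", "B"}, "T", "A"),
                               ({"A", "B", "C"}, "G", "C"),
                               ({"D", "E"}, "C", "T")):
        for _ in range(n_block):
            cols.append([base if t in members else alt for t in taxa])
    for i in range(n_const):
        cols.append(["ACGT"[i % 4]] * len(taxa))
    arr = np.array(cols).T
    return [SequenceRecord(t, "".join(arr[i])) for i, t in enumerate(taxa)]


def test_single_replicate_supports_are_zero_or_hundred():
    msa = _congruent_msa()
    tree = bootstrap_support(msa, n_reps=1, seed=3)

    def supports(clade, acc):
        for c in clade.children:
            if not c.is_leaf and c.support is not None:
                acc.append(c.support)
            supports(c, acc)
        return acc

    assert set(supports(tree.root, [])) <= {0.0, 100.0}


def test_congruent_alignment_gets_full_support():
    msa = _congruent_msa()
    tree = bootstrap_support(msa, n_reps=100, seed=4)

    vals = []
    def walk(clade):
        for c in clade.children:
            if not c.is_leaf and c.support is not None:
                vals.append(c.support)
            walk(c)
    walk(tree.root)
    assert vals and all(v == 100.0 for v in vals)


def test_bootstrap_deterministic_under_seed():
    msa = _related_msa()
    t1 = bootstrap_support(msa, n_reps=30, seed=5)
    t2 = bootstrap_support(msa, n_reps=30, seed=5)
    assert to_newick(t1) == to_newick(t2)


# ---------------------------------------------------------------------------
# rooting and Newick
# ---------------------------------------------------------------------------

def test_three_taxon_rooting():
    tree = PhyloTree(Clade(children=[
        Clade("A", 1.0), Clade("B", 2.0), Clade("C", 3.0)]))
    rooted = root_with_outgroup(tree, "C")
    names = {c.name for c in rooted.root.children if c.is_leaf}
    assert names == {"C"}
    inner = next(c for c in rooted.root.children if not c.is_leaf)
    assert {l.name for l in inner.leaves()} == {"A", "B"}
    # outgroup pendant edge split at its midpoint
    out_leaf = next(c for c in rooted.root.children if c.is_leaf)
    assert out_leaf.branch_length == pytest.approx(1.5)
    assert inner.branch_length == pytest.approx(1.5)


def test_rooting_preserves_bipartitions_and_supports():
    msa = _related_msa(n_taxa=7, seed=3)
    tree = bootstrap_support(msa, n_reps=25, seed=6)
    rooted = root_with_outgroup(tree, "t0")
    assert bipartitions(rooted) == bipartitions(tree)

    def support_map(t):
        taxa = t.taxa
        anchor = min(taxa)
        out = {}
        def walk(clade):
            for c in clade.children:
                if not c.is_leaf and c.support is not None:
                    side = c.leaf_names()
                    canon = frozenset(taxa - side) if anchor in side else side
                    if 1 < len(canon) < len(taxa) - 1:
                        out[canon] = c.support
                walk(c)
        walk(t.root)
        return out

    before, after = support_map(tree), support_map(rooted)
    for split, val in before.items():
        if split in after:
            assert after[split] == val


def test_missing_outgroup_raises():
    tree = PhyloTree(Clade(children=[Clade("A", 1.0), Clade("B", 1.0),
                                     Clade("C", 1.0)]))
    with pytest.raises(KeyError):
        root_with_outgroup(tree, "missing")


def test_newick_round_trip_via_biopython(tmp_path):
    from Bio import Phylo

    msa = _related_msa(n_taxa=8, seed=4)
    tree = bootstrap_support(msa, n_reps=10, seed=7)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    parsed = Phylo.read(str(path), "newick")
    leaves = {t.name for t in parsed.get_terminals()}
    assert leaves == set(tree.taxa)
    # compare splits
    taxa = frozenset(leaves)
    anchor = min(taxa)
    theirs = set()
    for cl in parsed.get_nonterminals():
        side = frozenset(t.name for t in cl.get_terminals())
        canon = frozenset(taxa - side) if anchor in side else side
        if 1 < len(canon) < len(taxa) - 1:
            theirs.add(canon)
    assert theirs == bipartitions(tree)
    # branch lengths survive to 6 decimals
    txt = path.read_text()
    assert ":" in txt and txt.strip().endswith(";")


def test_newick_support_labels_present():
    msa = _congruent_msa()
    tree = bootstrap_support(msa, n_reps=10, seed=8)
    assert ")100:" in to_newick(tree)


def test_cyclic_tree_rejected(tmp_path):
    a = Clade("A", 1.0)
    parent = Clade(children=[a])
    a.children.append(parent)
    with pytest.raises(ValueError, match="cyclic"):
        write_newick(PhyloTree(parent), tmp_path / "c.nwk")
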