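"""Distance phylogeny: Tajima-Nei distances, Neighbor-Joining, bootstrap.

Pairwise distances use the Tajima-Nei (1984) equal-input correction,
d = -b ln(1 - p/b) with b = (1 - sum_i g_i^2 + p^2/h) / 2 and
h = sum_{i<j} x_ij^2 / (2 g_i g_j), where p is the proportion of
differing sites, g_i the pooled base frequencies and x_ij the frequencies
of unordered differing site patterns.  Alignment columns containing a gap
or ambiguity in either sequence of a pair are excluded (pairwise
deletion); complete deletion and a p-distance fallback (for amino-acid
alignments) are offered as options.  Trees are built with Saitou-Nei
Neighbor-Joining (ties broken by the lowest taxon-index pair; negative
branch lengths reported as computed), supports come from resampling
alignment columns with replacement, and rooting places the root at the
midpoint of the outgroup's pendant edge.
"""

from __future__ import annotations

import copy
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = ["Clade", "PhyloTree", "DistanceMatrix", "DistanceError",
           "tajima_nei_distance", "p_distance", "nj_tree",
           "bipartitions", "bootstrap_support", "root_with_outgroup",
           "to_newick", "write_newick"]

_NUCS = "ACGT"


class DistanceError(ValueError):
    """Undefined or saturated distances where finite ones are required."""


@dataclass
class Clade:
    """A tree node; ``branch_length`` and ``support`` describe the edge
    above this node."""

    name: str | None = None
    branch_length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class PhyloTree:
    """A phylogeny; unrooted trees have a basal multifurcation."""

    root: Clade
    rooted: bool = False
    outgroup: str | None = None

    @property
    def taxa(self) -> frozenset[str]:
        return self.root.leaf_names()

    def find(self, name: str) -> Clade | None:
        for leaf in self.root.leaves():
            if leaf.name == name:
                return leaf
        return None


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with undefined/saturated entries flagged
    (NaN in ``d``) rather than silently clamped."""

    taxa: tuple[str, ...]
    d: np.ndarray
    undefined: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.d[i, j])


def _check_msa(msa: Sequence[SequenceRecord]) -> np.ndarray:
    if len(msa) < 2:
        raise ValueError("an alignment needs at least two sequences")
    lengths = {len(r.seq) for r in msa}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    return np.array([list(r.seq.upper()) for r in msa])


def _tn_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Tajima-Nei distance for one sequence pair (pairwise deletion)."""
    valid = np.isin(a, list(_NUCS)) & np.isin(b, list(_NUCS))
    n = int(valid.sum())
    if n == 0:
        return math.nan, True
    x, y = a[valid], b[valid]
    diff = x != y
    p = float(diff.sum()) / n
    if p == 0.0:
        return 0.0, False
    g = np.array([(np.count_nonzero(x == c) + np.count_nonzero(y == c))
                  for c in _NUCS], dtype=float) / (2 * n)
    h = 0.0
    for i in range(4):
        for j in range(i + 1, 4):
            ci, cj = _NUCS[i], _NUCS[j]
            nij = np.count_nonzero((x == ci) & (y == cj)) + \
                np.count_nonzero((x == cj) & (y == ci))
            xij = nij / n
            if g[i] > 0 and g[j] > 0:
                h += xij * xij / (2.0 * g[i] * g[j])
    b_factor = 0.5 * (1.0 - float(np.sum(g * g)) + p * p / h)
    if p >= b_factor:
        return math.nan, True          # saturated
    return -b_factor * math.log(1.0 - p / b_factor), False


def tajima_nei_distance(msa: Sequence[SequenceRecord],
                        deletion: str = "pairwise") -> DistanceMatrix:
    """Tajima-Nei distance matrix of a nucleotide alignment.

    ``deletion='pairwise'`` excludes gapped/ambiguous columns per pair;
    ``'complete'`` excludes them across the whole alignment first.
    """
    arr = _check_msa(msa)
    if deletion == "complete":
        keep = np.all(np.isin(arr, list(_NUCS)), axis=0)
        arr = arr[:, keep]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = len(msa)
    d = np.zeros((n, n))
    undef = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            dij, flag = _tn_pair(arr[i], arr[j])
            d[i, j] = d[j, i] = dij
            undef[i, j] = undef[j, i] = flag
    return DistanceMatrix(tuple(r.id for r in msa), d, undef)


def p_distance(msa: Sequence[SequenceRecord],
               alphabet: str | None = None) -> DistanceMatrix:
    """Proportion-of-differing-sites distance (works for amino acids)."""
    arr = _check_msa(msa)
    gapish = np.isin(arr, list("-.?*X"))
    n = len(msa)
    d = np.zeros((n, n))
    undef = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~gapish[i] & ~gapish[j]
            m = int(valid.sum())
            if m == 0:
                d[i, j] = d[j, i] = math.nan
                undef[i, j] = undef[j, i] = True
            else:
                p = float(np.count_nonzero(arr[i][valid] != arr[j][valid])) / m
                d[i, j] = d[j, i] = p
    return DistanceMatrix(tuple(r.id for r in msa), d, undef)


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei Neighbor-Joining on a complete distance matrix.

    The Q criterion selects the pair to join; ties resolve to the lowest
    taxon-index pair.  Negative branch lengths are reported as computed
    so that additive matrices round-trip exactly.
    """
    if len(dm.taxa) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if dm.undefined.any() or np.isnan(dm.d).any():
        raise DistanceError("distance matrix contains undefined entries")
    nodes: list[Clade] = [Clade(name=t) for t in dm.taxa]
    d = dm.d.astype(float).copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        new = Clade(children=[nodes[i], nodes[j]])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.zeros((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [new]
        d = d_new
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.branch_length = 0.5 * (dab + dac - dbc)
    b.branch_length = 0.5 * (dab + dbc - dac)
    c.branch_length = 0.5 * (dac + dbc - dab)
    return PhyloTree(root=Clade(children=[a, b, c]), rooted=False)


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial splits of the tree, each canonically represented by the
    side not containing the alphabetically first taxon."""
    taxa = tree.taxa
    anchor = min(taxa)
    splits: set[frozenset[str]] = set()

    def walk(clade: Clade) -> None:
        for child in clade.children:
            side = child.leaf_names()
            if 1 < len(side) < len(taxa) - 1:
                canon = frozenset(taxa - side) if anchor in side else side
                if 1 < len(canon) < len(taxa) - 1:
                    splits.add(canon)
            walk(child)

    walk(tree.root)
    return splits


def bootstrap_support(
    msa: Sequence[SequenceRecord],
    n_reps: int,
    seed: int,
    distance_fn: Callable[[Sequence[SequenceRecord]], DistanceMatrix]
    = tajima_nei_distance,
) -> PhyloTree:
    """NJ tree of the alignment with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of an internal edge is the percentage of replicate trees
    containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(distance_fn(msa))
    arr = _check_msa(msa)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in bipartitions(tree)}
    n_cols = arr.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = [SequenceRecord(r.id, "".join(arr[i, cols]))
               for i, r in enumerate(msa)]
        rep_splits = bipartitions(nj_tree(distance_fn(rep)))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1

    taxa = tree.taxa
    anchor = min(taxa)

    def annotate(clade: Clade) -> None:
        for child in clade.children:
            if not child.is_leaf:
                side = child.leaf_names()
                canon = frozenset(taxa - side) if anchor in side else side
                if canon in counts:
                    child.support = 100.0 * counts[canon] / n_reps
            annotate(child)

    annotate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# rooting and Newick output
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup_label: str) -> PhyloTree:
    """Root the tree at the midpoint of the outgroup's pendant edge.

    Supports stay attached to the same bipartitions.
    """
    t = copy.deepcopy(tree)
    target = t.find(outgroup_label)
    if target is None:
        raise KeyError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    path = _path_to(t.root, target)
    leaf = path[-1]
    parent = path[-2]
    parent.children.remove(leaf)
    # invert the root->parent path so the outgroup's former parent becomes
    # the subroot; each inverted edge keeps its original length and support
    original = {id(c): (c.branch_length, c.support) for c in path}
    for upper, lower in zip(path[:-2][::-1], path[1:-1][::-1]):
        upper.children.remove(lower)
        lower.children.append(upper)
        upper.branch_length, upper.support = original[id(lower)]
    subroot = parent
    _suppress_unary(subroot)
    half = (leaf.branch_length or 0.0) / 2.0
    leaf.branch_length = half
    subroot.branch_length = half
    subroot.support = None
    root = Clade(children=[leaf, subroot])
    return PhyloTree(root=root, rooted=True, outgroup=outgroup_label)


def _path_to(root: Clade, target: Clade) -> list[Clade]:
    if root is target:
        return [root]
    for child in root.children:
        sub = _path_to(child, target)
        if sub:
            return [root] + sub
    return []


def _suppress_unary(clade: Clade) -> None:
    """Collapse single-child internal nodes below ``clade`` (merging branch
    lengths; the retained edge keeps the more specific support)."""
    for child in list(clade.children):
        _suppress_unary(child)
    if len(clade.children) == 1:
        only = clade.children[0]
        only.branch_length = (only.branch_length or 0.0) + \
            (clade.branch_length or 0.0)
        if only.support is None:
            only.support = clade.support
        clade.name = only.name
        clade.branch_length = only.branch_length
        clade.support = only.support
        clade.children = only.children


def _fmt_len(x: float | None) -> str:
    return "" if x is None else f":{x:.6f}"


def to_newick(tree: PhyloTree) -> str:
    """Newick string with bootstrap supports as internal node labels."""

    def render(clade: Clade) -> str:
        if clade.is_leaf:
            return f"{clade.name}{_fmt_len(clade.branch_length)}"
        inner = ",".join(render(c) for c in clade.children)
        label = "" if clade.support is None else f"{clade.support:g}"
        return f"({inner}){label}{_fmt_len(clade.branch_length)}"

    inner = ",".join(render(c) for c in tree.root.children)
    label = "" if tree.root.support is None else f"{tree.root.support:g}"
    return f"({inner}){label};"


def write_newick(tree: PhyloTree, path: str | os.PathLike) -> None:
    seen: set[int] = set()

    def check(clade: Clade) -> None:
        if id(clade) in seen:
            raise ValueError("cyclic tree structure")
        seen.add(id(clade))
        for c in clade.children:
            check(c)

    check(tree.root)
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
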