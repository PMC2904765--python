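"""Distance-based phylogenetics: Poisson/p distances, neighbor joining,
bootstrap supports and outgroup rooting.

Trees carry branch lengths in substitutions per site and per-internal-node
bootstrap supports in [0, 100].  Neighbor joining is the Saitou–Nei
Q-criterion algorithm with a declared tie-break (lowest index pair), exact
on additive matrices; negative branch-length estimates are clamped to zero
and recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .msa import MultipleAlignment, p_distance
from .seq import SequenceError


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise PhyloError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise PhyloError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise PhyloError("distances must be finite and non-negative")

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for name, row in zip(self.taxa, self.d):
            padded = name[:10].ljust(10)
            lines.append(padded + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


@dataclass
class Node:
    name: Optional[str] = None
    length: float = 0.0          # branch length to parent
    support: Optional[float] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    root: Node
    rooted: bool = False
    clamped_branches: int = 0

    @property
    def taxa(self) -> list[str]:
        return sorted(l.name for l in self.root.leaves())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the leaf set not containing the
        reference taxon (the lexicographically smallest leaf)."""
        all_taxa = set(self.taxa)
        ref = min(all_taxa)
        splits: set[frozenset] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = {l.name for l in node.leaves()}
            if ref in side:
                side = all_taxa - side
            if 1 < len(side) < len(all_taxa) - 1:
                splits.add(frozenset(side))
        return splits

    def newick(self, decimals: int = 6) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.{decimals}f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.{decimals}f}"
        inner = ",".join(fmt(c) for c in self.root.children)
        label = "" if self.root.support is None else f"{self.root.support:g}"
        return f"({inner}){label};"


def read_newick(text: str, rooted: bool = False) -> PhyloTree:
    """Parse a newick string (internal-node labels read as supports)."""
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick",
                           suppress_internal_node_taxa=True)

    def convert(dnode) -> Node:
        node = Node(
            name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
            length=dnode.edge.length or 0.0,
        )
        if dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                node.name = dnode.label
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return PhyloTree(convert(dt.seed_node), rooted=rooted)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def protein_distance(msa: MultipleAlignment, model: str = "poisson",
                     ) -> DistanceMatrix:
    """Pairwise protein distances with pairwise deletion of gap columns.

    ``p`` is the proportion of differing sites; ``poisson`` applies the
    multiple-hit correction -ln(1 - p).  A pair with p >= 1 is saturated and
    raises.
    """
    if len(msa.rows) < 3:
        raise PhyloError("need >= 3 rows for a distance matrix")
    if model not in ("p", "poisson"):
        raise PhyloError(f"unknown distance model {model!r}")
    n = len(msa.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(msa.rows[i][1], msa.rows[j][1])
            if model == "poisson":
                if p >= 1.0:
                    raise PhyloError(
                        f"saturated pair ({msa.rows[i][0]}, {msa.rows[j][0]}):"
                        f" p = {p}")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix([i for i, _ in msa.rows], d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; unrooted tree (trifurcating root node).

    Exact topology and branch lengths on additive matrices.  Tie-break: the
    pair with minimal Q and then lowest (i, j) index is joined.  Negative
    branch-length estimates are clamped to 0 and counted on the tree.
    """
    n = len(dm.taxa)
    if n < 3:
        raise PhyloError("neighbor joining needs >= 3 taxa")
    nodes: dict[int, Node] = {i: Node(name=t) for i, t in enumerate(dm.taxa)}
    d = dm.d.astype(float).copy()
    active = list(range(n))
    next_id = n
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    clamped = 0

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if (i, j) in dist else dist[(j, i)]

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                i, j = active[ii], active[jj]
                q = (r - 2) * get(i, j) - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            clamped += 1
            li = 0.0
        if lj < 0:
            clamped += 1
            lj = 0.0
        ni, nj = nodes.pop(i), nodes.pop(j)
        ni.length, nj.length = li, lj
        parent = Node(children=[ni, nj])
        nodes[next_id] = parent
        for k in active:
            if k not in (i, j):
                dist[(next_id, k)] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    children = []
    for k, lk in ((a, la), (b, lb), (c, lc)):
        if lk < 0:
            clamped += 1
            lk = 0.0
        nodes[k].length = lk
        children.append(nodes[k])
    return PhyloTree(Node(children=children), rooted=False,
                     clamped_branches=clamped)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(msa: MultipleAlignment, B: int = 1000, seed: int = 0,
                      model: str = "poisson") -> tuple[PhyloTree, int]:
    """NJ tree with bootstrap supports.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicates whose NJ tree contains each original
    bipartition.  The replicate RNG stream is derived from (seed, replicate
    index), so supports do not depend on evaluation order.  Replicates with
    a saturated pair are dropped and counted; returns (tree, n_dropped).
    """
    if B < 1:
        raise PhyloError("B must be >= 1")
    tree = neighbor_joining(protein_distance(msa, model))
    targets = tree.bipartitions()
    counts = {s: 0 for s in targets}
    used = 0
    dropped = 0
    L = msa.length
    for rep in range(B):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, L, size=L)
        rows = [(sid, "".join(row[c] for c in cols)) for sid, row in msa.rows]
        try:
            rep_tree = neighbor_joining(
                protein_distance(MultipleAlignment(rows), model))
        except PhyloError:
            dropped += 1
            continue
        used += 1
        rep_splits = rep_tree.bipartitions()
        for s in targets:
            if s in rep_splits:
                counts[s] += 1
    if used == 0:
        raise PhyloError("all bootstrap replicates dropped (saturation)")
    support_of = {s: 100.0 * counts[s] / used for s in targets}
    all_taxa = set(tree.taxa)
    ref = min(all_taxa)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = {l.name for l in node.leaves()}
        if ref in side:
            side = all_taxa - side
        key = frozenset(side)
        if key in support_of:
            node.support = support_of[key]
    return tree, dropped


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def root_by_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root on the midpoint of the outgroup's pendant edge."""
    import copy

    t = copy.deepcopy(tree)
    target = None
    parents: dict[int, Node] = {}
    for node in t.root.walk():
        for c in node.children:
            parents[id(c)] = node
        if node.is_leaf and node.name == outgroup:
            target = node
    if target is None:
        raise PhyloError(f"outgroup taxon {outgroup!r} not in tree")

    half = target.length / 2.0

    def rehang(node: Node, exclude: Node) -> Node:
        """Reverse parent links so ``node`` becomes a child-bearing subtree
        rooted away from ``exclude``."""
        kids = [c for c in node.children if c is not exclude]
        parent = parents.get(id(node))
        if parent is not None:
            flipped = rehang(parent, node)
            flipped.length = node.length
            kids.append(flipped)
        new = Node(name=node.name, support=node.support, children=kids)
        return new

    rest = rehang(parents[id(target)], target)
    rest.length = half
    out_leaf = Node(name=target.name, length=half)
    root = Node(children=[out_leaf, rest])
    return PhyloTree(root, rooted=True, clamped_branches=t.clamped_branches)


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a root bifurcation back into a trifurcation."""
    import copy

    t = copy.deepcopy(tree)
    root = t.root
    if len(root.children) != 2:
        return PhyloTree(root, rooted=False, clamped_branches=t.clamped_branches)
    a, b = root.children
    if b.is_leaf and not a.is_leaf:
        a, b = b, a
    # merge the two root edges onto one child of the non-leaf side
    if b.is_leaf:
        raise PhyloError("cannot unroot a two-leaf tree")
    b_kids = list(b.children)
    a.length = a.length + b.length
    new_root = Node(children=[a] + b_kids, support=b.support)
    return PhyloTree(new_root, rooted=False, clamped_branches=t.clamped_branches)
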