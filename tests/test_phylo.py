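"""Distance, neighbor-joining, bootstrap and rooting checks.

The brute-force minimum-evolution oracle enumerates all 15 labeled
unrooted topologies for 5 taxa, fits branch lengths by ordinary least
squares on the path-incidence matrix, and picks the shortest tree; on
additive matrices NJ must recover the same topology (and the generating
branch lengths exactly).
"""

import itertools
import math

import numpy as np
import pytest

from dazfam.msa import MultipleAlignment
from dazfam.phylo import (DistanceMatrix, PhyloError, bootstrap_support,
                          neighbor_joining, protein_distance, read_newick,
                          root_by_outgroup, unroot)


def dm(taxa, entries):
    n = len(taxa)
    d = np.zeros((n, n))
    for (i, j), v in entries.items():
        d[i, j] = d[j, i] = v
    return DistanceMatrix(list(taxa), d)


def additive_matrix_from_tree(leaf_paths):
    """Distances as path sums; leaf_paths maps leaf -> dict(edge -> 1)."""
    taxa = sorted(leaf_paths)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ei, ej = leaf_paths[taxa[i]], leaf_paths[taxa[j]]
            edges = set(ei) ^ set(ej)
            d[i, j] = d[j, i] = sum(
                ei.get(e, ej.get(e, 0.0)) for e in edges)
    return DistanceMatrix(taxa, d)


# --- brute-force minimum evolution over 5-taxon topologies ----------------

def five_taxon_topologies(taxa):
    """All 15 labeled unrooted binary topologies as sets of non-trivial
    splits (each topology has exactly two)."""
    out = []
    for pair in itertools.combinations(taxa, 2):
        rest = [t for t in taxa if t not in pair]
        for other in itertools.combinations(rest, 2):
            s1 = frozenset(pair)
            s2 = frozenset(other)
            key = frozenset({s1, s2})
            if key not in [k for k, _ in out]:
                out.append((key, (s1, s2)))
    assert len(out) == 15
    return [splits for _, splits in out]


def ols_tree_length(dmat, splits):
    """OLS branch lengths for the 5-taxon topology with the given two
    cherries; returns total tree length."""
    taxa = dmat.taxa
    s1, s2 = splits
    (a, b) = sorted(s1)
    (c, d) = sorted(s2)
    (e,) = [t for t in taxa if t not in s1 | s2]
    # edges: pendant a,b,c,d,e + internal x (ab|cde) + y (cd|abe)
    edges = [a, b, c, d, e, "x", "y"]
    pairs = list(itertools.combinations(taxa, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    idx = {t: k for k, t in enumerate(edges)}
    ti = {t: k for k, t in enumerate(taxa)}

    def path(u, v):
        cols = {u, v}
        es = [u, v]
        if cols == {a, b} or cols == {c, d}:
            return es
        if u in s1 or v in s1:
            es.append("x")
        if u in s2 or v in s2:
            es.append("y")
        return es

    for r, (u, v) in enumerate(pairs):
        for e_ in path(u, v):
            A[r, idx[e_]] = 1.0
        y[r] = dmat.d[ti[u], ti[v]]
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(sol.sum())


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        m = MultipleAlignment([("a", "MKVW"), ("b", "MKVW"), ("c", "MKVW")])
        assert np.all(protein_distance(m, "p").d == 0)

    def test_poisson_correction_at_half(self):
        m = MultipleAlignment([("a", "MKVW"), ("b", "MKYR"),
                               ("c", "MKVW")])
        d = protein_distance(m, "poisson")
        i, j = 0, 1  # p = 0.5
        assert d.d[i, j] == pytest.approx(-math.log(0.5), abs=1e-4)

    def test_row_permutation_invariance(self):
        rows = [("a", "MKVW"), ("b", "MRVW"), ("c", "MKYW")]
        d1 = protein_distance(MultipleAlignment(rows))
        d2 = protein_distance(MultipleAlignment(rows[::-1]))
        for i, ti in enumerate(d1.taxa):
            for j, tj in enumerate(d1.taxa):
                i2, j2 = d2.taxa.index(ti), d2.taxa.index(tj)
                assert d1.d[i, j] == pytest.approx(d2.d[i2, j2])

    def test_saturation_raises(self):
        m = MultipleAlignment([("a", "MK"), ("b", "VW"), ("c", "MK")])
        with pytest.raises(PhyloError, match="saturated"):
            protein_distance(m, "poisson")

    def test_phylip_output_shape(self):
        m = MultipleAlignment([("a", "MKVW"), ("b", "MRVW"), ("c", "MKYW")])
        text = protein_distance(m, "p").to_phylip()
        lines = text.strip().split("\n")
        assert lines[0].strip() == "3"
        assert len(lines) == 4


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # tree ((A:2,B:3):1,(C:4,D:5))
        m = dm("ABCD", {(0, 1): 5, (0, 2): 7, (0, 3): 8,
                        (1, 2): 8, (1, 3): 9, (2, 3): 9})
        t = neighbor_joining(m)
        assert t.bipartitions() == {frozenset("CD")}
        lengths = {l.name: l.length for l in t.root.leaves()}
        assert lengths == pytest.approx({"A": 2, "B": 3, "C": 4, "D": 5})

    def test_three_taxa_closed_form(self):
        m = dm("ABC", {(0, 1): 3, (0, 2): 4, (1, 2): 5})
        t = neighbor_joining(m)
        lengths = {l.name: l.length for l in t.root.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3})

    def test_tie_break_joins_lowest_index_pair(self):
        # perfectly symmetric star: every Q equal; (A, B) must join first
        m = dm("ABCD", {(i, j): 2.0 for i in range(4) for j in range(i + 1, 4)})
        t = neighbor_joining(m)
        assert frozenset("CD") in t.bipartitions() or \
            frozenset("AB") in t.bipartitions()

    def test_rejects_asymmetric_and_small_inputs(self):
        with pytest.raises(PhyloError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(PhyloError, match=">= 3"):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0.0]])))

    def test_five_taxon_additive_recovery_and_me_equivalence(self):
        # caterpillar tree: (A:1,(B:2,((C:1.5,D:2.5):0.5,E:4):1):1)-ish,
        # built from explicit leaf->edge paths
        leaf_paths = {
            "A": {"pa": 1.0},
            "B": {"pb": 2.0, "x": 0.7},
            "C": {"pc": 1.5, "y": 0.5, "x": 0.7},
            "D": {"pd": 2.5, "y": 0.5, "x": 0.7},
            "E": {"pe": 4.0},
        }
        m = additive_matrix_from_tree(leaf_paths)
        t = neighbor_joining(m)
        want = {frozenset("CD"), frozenset({"B", "C", "D"})}
        assert t.bipartitions() == want
        # minimum-evolution brute force agrees on the topology
        best = min(five_taxon_topologies(m.taxa),
                   key=lambda splits: ols_tree_length(m, splits))
        got = {frozenset(s) for s in best}
        ref = min(set(m.taxa))
        norm = {frozenset(set(m.taxa) - s) if ref in s else s for s in got}
        assert norm == want


class TestBootstrap:
    def _msa(self):
        rows = [("a", "MKVWMKVWMKVW"), ("b", "MKVWMKVWMKVW"),
                ("c", "MQYNMRYNMQYN"), ("d", "MQYDMRYDMRYD"),
                ("e", "MCDEMCDEMKDE")]
        return MultipleAlignment(rows)

    def test_identical_rows_get_full_support(self):
        tree, dropped = bootstrap_support(self._msa(), B=50, seed=4)
        ab = None
        for node in tree.root.walk():
            side = {l.name for l in node.leaves()}
            if side == {"a", "b"}:
                ab = node
        assert ab is not None and ab.support == 100.0
        assert 0 <= dropped < 50  # saturated replicates are dropped, counted

    def test_same_seed_reproduces_supports(self):
        t1, _ = bootstrap_support(self._msa(), B=30, seed=9)
        t2, _ = bootstrap_support(self._msa(), B=30, seed=9)
        assert t1.newick() == t2.newick()

    def test_single_replicate_supports_are_binary(self):
        tree, _ = bootstrap_support(self._msa(), B=1, seed=2)
        for node in tree.root.walk():
            if node.support is not None:
                assert node.support in (0.0, 100.0)


class TestRooting:
    def _tree(self):
        m = dm("ABCD", {(0, 1): 5, (0, 2): 7, (0, 3): 8,
                        (1, 2): 8, (1, 3): 9, (2, 3): 9})
        return neighbor_joining(m)

    def test_outgroup_pendant_midpoint(self):
        rooted = root_by_outgroup(self._tree(), "D")
        assert rooted.rooted
        kids = {c.name: c for c in rooted.root.children}
        assert "D" in kids
        assert kids["D"].length == pytest.approx(2.5)

    def test_root_then_unroot_preserves_bipartitions(self):
        t = self._tree()
        again = unroot(root_by_outgroup(t, "C"))
        assert again.bipartitions() == t.bipartitions()

    def test_unknown_outgroup_rejected(self):
        with pytest.raises(PhyloError, match="not in tree"):
            root_by_outgroup(self._tree(), "Z")


class TestNewick:
    def test_roundtrip_topology_lengths_supports(self):
        m = dm("ABCDE", {(0, 1): 2, (0, 2): 4, (0, 3): 6, (0, 4): 6,
                         (1, 2): 4, (1, 3): 6, (1, 4): 6,
                         (2, 3): 4, (2, 4): 4, (3, 4): 2})
        t = neighbor_joining(m)
        for node in t.root.walk():
            if not node.is_leaf and node is not t.root:
                node.support = 87.0
        back = read_newick(t.newick())
        assert back.bipartitions() == t.bipartitions()
        lengths = sorted(round(n.length, 6) for n in back.root.walk())
        assert lengths == sorted(round(n.length, 6) for n in t.root.walk())
        sup = [n.support for n in back.root.walk() if n.support is not None]
        assert sup and all(s == 87.0 for s in sup)

    def test_dendropy_reads_our_newick(self):
        import dendropy
        t = neighbor_joining(dm("ABC", {(0, 1): 3, (0, 2): 4, (1, 2): 5}))
        parsed = dendropy.Tree.get(data=t.newick(), schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == \
            {"A", "B", "C"}
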