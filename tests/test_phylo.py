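"""Distance models, neighbor joining (with exhaustive least-squares and
scikit-bio oracles), bootstrap support and outgroup rooting."""

import itertools
import math

import numpy as np
import pytest

from ervkit import phylo, simulate
from ervkit.phylo import AlignedSet, DistanceMatrix, Node


# ---------------------------------------------------------------------------
# helpers: random additive trees and an exhaustive least-squares oracle


def all_unrooted_topologies(names):
    """Every unrooted binary topology on the given leaves (105 for 6)."""
    trees = [Node(children=[Node(names[0]), Node(names[1]), Node(names[2])])]
    for name in names[3:]:
        nxt = []
        for tree in trees:
            n_edges = len([n for n in tree.walk() if n is not tree])
            for k in range(n_edges):
                t2 = tree.copy()
                target = [n for n in t2.walk() if n is not t2][k]
                parent = next(p for p in t2.walk() if target in p.children)
                idx = parent.children.index(target)
                parent.children[idx] = Node(children=[target, Node(name)])
                nxt.append(t2)
        trees = nxt
    return trees


def path_distances(tree, names):
    """Leaf-to-leaf path lengths from branch lengths."""
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf():
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree, [])
    n = len(names)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pi, pj = paths[names[i]], paths[names[j]]
        common = 0
        for a, b in zip(pi, pj):
            if a is b:
                common += 1
            else:
                break
        dist = sum(x.length for x in pi[common:]) + sum(x.length for x in pj[common:])
        d[i, j] = d[j, i] = dist
    return d


def ls_residual(topology, names, d):
    """Least-squares residual of fitting branch lengths to distances d."""
    edges = [n for n in topology.walk() if n is not topology]
    eidx = {id(n): k for k, n in enumerate(edges)}
    leaf_path = {}

    def walk(node, acc):
        if node is not topology:
            acc = acc + [id(node)]
        if node.is_leaf():
            leaf_path[node.name] = set(acc)
        for c in node.children:
            walk(c, acc)

    walk(topology, [])
    pairs = list(itertools.combinations(range(len(names)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([d[i, j] for i, j in pairs])
    for r, (i, j) in enumerate(pairs):
        for e in leaf_path[names[i]] ^ leaf_path[names[j]]:
            A[r, eidx[e]] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ x - y) ** 2))


def random_additive_tree(names, rng):
    tree = Node(children=[Node(names[0]), Node(names[1]), Node(names[2])])
    for name in names[3:]:
        edges = [n for n in tree.walk() if n is not tree]
        target = edges[rng.integers(len(edges))]
        parent = next(p for p in tree.walk() if target in p.children)
        idx = parent.children.index(target)
        parent.children[idx] = Node(children=[target, Node(name)])
    for n in tree.walk():
        if n is not tree:
            n.length = float(rng.uniform(0.1, 1.0))
    return tree


# ---------------------------------------------------------------------------


class TestDistances:
    def test_identical_sequences_zero_under_all_models(self):
        aln = AlignedSet(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        for model in ("p", "JC69", "K2P"):
            assert phylo.pairwise_distance(aln, model).matrix[0, 1] == 0.0

    def test_jc69_closed_form_at_p_01(self):
        aln = AlignedSet(["a", "b"], ["ACGTACGTAC", "ACGTACGTAG"])  # 1/10 mismatch
        d = phylo.pairwise_distance(aln, "JC69").matrix[0, 1]
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-5)
        assert d == pytest.approx(0.10732, abs=1e-5)

    def test_k2p_equals_independent_recomputation(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for _ in range(20):
            n = 300
            a = "".join(bases[i] for i in rng.integers(0, 4, n))
            b = "".join(
                bases[(bases.index(x) + rng.integers(0, 4)) % 4] if rng.random() < 0.3 else x
                for x in a
            )
            aln = AlignedSet(["a", "b"], [a, b])
            got = phylo.pairwise_distance(aln, "K2P").matrix[0, 1]
            P = sum((x, y) in transitions for x, y in zip(a, b)) / n
            Q = sum(x != y and (x, y) not in transitions for x, y in zip(a, b)) / n
            expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_pairwise_deletion_excludes_gap_columns(self):
        aln = AlignedSet(["a", "b"], ["AC-TACGT", "ACGTAC-T"])
        # 6 comparable columns, 0 mismatches
        assert phylo.pairwise_distance(aln, "p").matrix[0, 1] == 0.0

    def test_zero_comparable_columns_errors_with_pair(self):
        aln = AlignedSet(["x", "y", "z"], ["AC--", "--GT", "ACGT"])
        with pytest.raises(ValueError, match="'x' and 'y'"):
            phylo.pairwise_distance(aln, "p")

    def test_saturated_pair_flagged(self):
        aln = AlignedSet(["a", "b"], ["AAAAAAAAAA", "CCCCCCCCCC"])  # p = 1
        dm = phylo.pairwise_distance(aln, "JC69")
        assert math.isinf(dm.matrix[0, 1])
        assert frozenset(("a", "b")) in dm.saturated

    def test_models_agree_in_small_p_limit(self):
        n = 20_000
        a = "ACGT" * (n // 4)
        b = "ACGG" + a[4:]  # 2 mismatches: p = 1e-4
        aln = AlignedSet(["a", "b"], [a, b])
        p = phylo.pairwise_distance(aln, "p").matrix[0, 1]
        assert p <= 1e-4
        for model in ("JC69", "K2P"):
            d = phylo.pairwise_distance(aln, model).matrix[0, 1]
            assert abs(d - p) < 1e-6


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_exact(self):
        # tree ((A:1,B:2):3,C:4,D:5)
        names = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], dtype=float
        )
        tree = phylo.nj_tree(DistanceMatrix(names, d, "p"))
        assert set(phylo.bipartitions(tree)) == {frozenset({"C", "D"})}
        lengths = {n.name: n.length for n in tree.walk() if n.is_leaf()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 4, "D": 5})
        internal = [n for n in tree.walk() if not n.is_leaf() and n is not tree]
        assert len(internal) == 1 and internal[0].length == pytest.approx(3)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree = phylo.nj_tree(DistanceMatrix(["a", "b", "c"], d, "p"))
        lengths = {n.name: n.length for n in tree.children}
        assert lengths == pytest.approx({"a": 0.1, "b": 0.2, "c": 0.3})

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrices_recover_generating_tree_exactly(self, seed):
        rng = np.random.default_rng(seed)
        names = list("ABCDEF")
        true_tree = random_additive_tree(names, rng)
        d = path_distances(true_tree, names)
        nj = phylo.nj_tree(DistanceMatrix(names, d, "p"))
        assert set(phylo.bipartitions(nj)) == set(phylo.bipartitions(true_tree))
        # branch lengths exact: path distances reproduced
        assert np.allclose(path_distances(nj, names), d, atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_topology_matches_exhaustive_least_squares_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        names = list("ABCDEF")
        d = path_distances(random_additive_tree(names, rng), names)
        topos = all_unrooted_topologies(names)
        residuals = [ls_residual(t, names, d) for t in topos]
        best = topos[int(np.argmin(residuals))]
        nj = phylo.nj_tree(DistanceMatrix(names, d, "p"))
        assert set(phylo.bipartitions(nj)) == set(phylo.bipartitions(best))

    def test_agrees_with_scikit_bio_on_random_matrices(self):
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(5)
        names = list("ABCDEFG")
        for _ in range(5):
            m = rng.uniform(0.1, 1.0, size=(7, 7))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            mine = phylo.nj_tree(DistanceMatrix(names, d, "p"))
            ref = skbio_tree.nj(SkbioDM(d, names))
            ref_parts = set()
            all_names = frozenset(names)
            anchor = min(names)
            for node in ref.non_tips():
                side = frozenset(t.name for t in node.tips())
                if anchor in side:
                    side = all_names - side
                if len(side) >= 2 and len(all_names - side) >= 2:
                    ref_parts.add(side)
            assert set(phylo.bipartitions(mine)) == ref_parts

    def test_non_finite_matrix_rejected(self):
        d = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="non-finite"):
            phylo.nj_tree(DistanceMatrix(["a", "b", "c"], d, "JC69"))

    def test_negative_branch_lengths_clamped(self):
        # a decidedly non-additive matrix that forces a negative NJ estimate
        d = np.array(
            [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1.99], [1, 1, 1.99, 0]], dtype=float
        )
        tree = phylo.nj_tree(DistanceMatrix(list("ABCD"), d, "p"))
        assert all(n.length >= 0 for n in tree.walk())


def saturated_alignment():
    """Columns unambiguously supporting ((A,B),(C,D),E): every resample keeps
    both split patterns with overwhelming probability."""
    col_ab = {"A": "A", "B": "A", "C": "C", "D": "C", "E": "C"}
    col_cd = {"A": "G", "B": "G", "C": "T", "D": "T", "E": "G"}
    names = list("ABCDE")
    rows = ["".join((col_ab[n] if i % 2 else col_cd[n]) for i in range(200)) for n in names]
    return AlignedSet(names, rows)


class TestBootstrap:
    def test_saturated_signal_gives_all_100(self):
        tree = phylo.bootstrap_support(saturated_alignment(), "p", replicates=200, seed=1)
        supports = [n.support for n in tree.walk() if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_bounded_and_leaf_order_invariant(self):
        rng = np.random.default_rng(2)
        seqs = simulate.evolve_on_tree(
            "ACGT" * 100, "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05,E:0.2);", seed=3
        )
        aln1 = AlignedSet(list(seqs), list(seqs.values()))
        perm = ["C", "A", "E", "B", "D"]
        aln2 = AlignedSet(perm, [seqs[n] for n in perm])
        t1 = phylo.bootstrap_support(aln1, "p", replicates=100, seed=4)
        t2 = phylo.bootstrap_support(aln2, "p", replicates=100, seed=4)
        s1 = {p: n.support for p, n in phylo.bipartitions(t1).items()}
        s2 = {p: n.support for p, n in phylo.bipartitions(t2).items()}
        assert set(s1) == set(s2)
        assert all(0 <= v <= 100 for v in s1.values())

    def test_seed_fixed_rerun_byte_identical(self):
        aln = saturated_alignment()
        a = phylo.bootstrap_support(aln, "p", replicates=50, seed=9).to_newick()
        b = phylo.bootstrap_support(aln, "p", replicates=50, seed=9).to_newick()
        assert a == b

    def test_short_internal_branch_has_minimum_support(self):
        wins = 0
        for seed in range(20):
            seqs = simulate.evolve_on_tree(
                "ACGT" * 150,
                "((A:0.1,B:0.1):0.004,((C:0.1,D:0.1):0.15,E:0.1):0.004,F:0.1);",
                seed=seed,
            )
            aln = AlignedSet(list(seqs), list(seqs.values()))
            tree = phylo.bootstrap_support(aln, "p", replicates=100, seed=seed)
            parts = {p: n.support for p, n in phylo.bipartitions(tree).items()}
            cd = frozenset({"C", "D"})
            if cd not in parts:
                continue
            others = [v for p, v in parts.items() if p != cd]
            if not others or parts[cd] >= min(others) + 1e-9:
                wins += 1
        assert wins >= 18  # the strong C/D edge is never the weakest


class TestRooting:
    def test_single_leaf_outgroup_roots_on_pendant_edge(self):
        tree = phylo.parse_newick("((A:1,B:1):1,C:1,D:4);")
        rooted = phylo.root_on_outgroup(tree, ["D"])
        assert len(rooted.children) == 2
        og = [c for c in rooted.children if c.is_leaf() and c.name == "D"]
        assert og and og[0].length == pytest.approx(2.0)  # pendant edge halved

    def test_bipartition_set_preserved_by_rooting(self):
        aln = saturated_alignment()
        tree = phylo.bootstrap_support(aln, "p", replicates=50, seed=5)
        before = {p: n.support for p, n in phylo.bipartitions(tree).items()}
        rooted = phylo.root_on_outgroup(tree, ["E"])
        after = {p: n.support for p, n in phylo.bipartitions(rooted).items()}
        assert set(after) == set(before)
        for p in before:
            assert after[p] == before[p]

    def test_multi_leaf_outgroup_must_be_monophyletic(self):
        tree = phylo.parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        rooted = phylo.root_on_outgroup(tree, ["C", "D"])
        top = {frozenset(l.name for l in c.leaves()) for c in rooted.children}
        assert frozenset({"C", "D"}) in top
        with pytest.raises(ValueError, match="not monophyletic"):
            phylo.root_on_outgroup(tree, ["A", "C"])

    def test_simulated_outgroup_radiation_ingroup_monophyletic(self):
        ok = 0
        for seed in range(20):
            seqs = simulate.evolve_on_tree(
                "ACGT" * 200,
                "(((I1:0.05,I2:0.05):0.05,(I3:0.05,I4:0.05):0.05):0.3,(OG1:0.05,OG2:0.05):0.05);",
                seed=40 + seed,
            )
            aln = AlignedSet(list(seqs), list(seqs.values()))
            tree = phylo.nj_tree(phylo.pairwise_distance(aln, "JC69"))
            try:
                rooted = phylo.root_on_outgroup(tree, ["OG1", "OG2"])
            except ValueError:
                continue
            top = {frozenset(l.name for l in c.leaves()) for c in rooted.children}
            if frozenset({"I1", "I2", "I3", "I4"}) in top:
                ok += 1
        assert ok >= 19  # >= 95 % of replicates

    def test_unknown_outgroup_label_rejected(self):
        tree = phylo.parse_newick("((A:1,B:1):1,C:1,D:1);")
        with pytest.raises(ValueError, match="not in tree"):
            phylo.root_on_outgroup(tree, ["Z"])


class TestFlagHighSupport:
    def test_all_100_above_95_all_flagged(self):
        tree = phylo.bootstrap_support(saturated_alignment(), "p", replicates=100, seed=6)
        flagged = phylo.flag_high_support(tree, 95.0)
        assert len(flagged) == len(phylo.bipartitions(tree))

    def test_threshold_100_flags_nothing(self):
        tree = phylo.bootstrap_support(saturated_alignment(), "p", replicates=100, seed=7)
        assert phylo.flag_high_support(tree, 100.0) == []

    def test_mixed_supports_equal_direct_filter(self):
        tree = phylo.parse_newick("(((A:1,B:1)97:1,(C:1,D:1)60:1)88:1,E:1,F:1);")
        flagged = {tuple(sorted(p)) for p, _ in phylo.flag_high_support(tree, 80.0)}
        direct = {
            tuple(sorted(p))
            for p, n in phylo.bipartitions(tree).items()
            if n.support is not None and n.support > 80.0
        }
        assert flagged == direct


class TestNewick:
    def test_round_trip_with_supports_and_quotes(self):
        text = "((A:1,'odd name':2)90:0.5,C:1,D:2.5);"
        tree = phylo.parse_newick(text)
        names = tree.leaf_names()
        assert "odd name" in names
        again = phylo.parse_newick(tree.to_newick())
        assert again.leaf_names() == names

    def test_phylip_export_shape(self):
        aln = saturated_alignment()
        text = aln.to_phylip()
        header = text.splitlines()[0].split()
        assert header == ["5", "200"]
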