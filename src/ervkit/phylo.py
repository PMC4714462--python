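"""Distance-based phylogenetics: p/JC69/K2P distances, neighbor joining,
column-resampling bootstrap support, and outgroup rooting.

The tree engine is a distance/NJ implementation rather than a
maximum-likelihood search; NJ is exact on additive distance matrices, and the
bootstrap, support-flagging and outgroup-rooting machinery follows the usual
phylogram conventions (support as percent of replicates recovering each
internal bipartition; rooting by subdividing the edge that separates the
outgroup clade).  A relaxed-PHYLIP export hook is provided for users who want
to re-optimize a tree externally.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

GAP_CHARS = frozenset("-.?Nn")

_PURINES = frozenset("AGag")
_PYRIMIDINES = frozenset("CTct")


# ---------------------------------------------------------------------------
# tree structure


class Node:
    """A node of a (possibly unrooted) tree.

    Unrooted trees are stored rooted at a trifurcation.  ``support`` on an
    internal node is the bootstrap percentage of the edge above it.
    """

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name="", length=0.0, support=None, children=None):
        self.name = name
        self.length = length
        self.support = support
        self.children = children if children is not None else []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def copy(self) -> "Node":
        return Node(self.name, self.length, self.support, [c.copy() for c in self.children])

    # -- newick -------------------------------------------------------------

    def to_newick(self, _top=True) -> str:
        if self.is_leaf():
            body = _quote_name(self.name)
        else:
            inner = ",".join(c.to_newick(_top=False) for c in self.children)
            label = "" if self.support is None else f"{self.support:g}"
            body = f"({inner}){label}"
        if _top:
            return body + ";"
        return f"{body}:{_fmt_len(self.length)}"

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.to_newick()}>"


def _fmt_len(x: float) -> str:
    return f"{x:.6g}"


_NWK_RESERVED = set("();,:[]' \t\n")


def _quote_name(name: str) -> str:
    if any(c in _NWK_RESERVED for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def parse_newick(text: str) -> Node:
    """Parse a Newick string; internal labels are read as bootstrap supports
    when numeric, otherwise ignored."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    pos = 0

    def parse_node():
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character {s[pos]!r} at {pos}")
        label = _parse_label()
        if node.children:
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            node.length = float(s[start:pos])
        return node

    def _parse_label():
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
                if s[pos] == "'" and pos + 1 < len(s) and s[pos + 1] == "'":
                    out.append("'")
                    pos += 2
                elif s[pos] == "'":
                    pos += 1
                    break
                else:
                    out.append(s[pos])
                    pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in ":,();":
            pos += 1
        return s[start:pos]

    root = parse_node()
    if s[pos] != ";":
        raise ValueError(f"trailing characters after node at {pos}")
    return root


def bipartitions(tree: Node) -> dict[frozenset, "Node"]:
    """Map each internal edge of the tree to its canonical bipartition.

    The bipartition of the edge above a node is represented by the side NOT
    containing the lexicographically smallest leaf, so the encoding does not
    depend on where the unrooted tree happens to be rooted.  Trivial edges
    (pendant leaves, and the root) are excluded.
    """
    all_leaves = tree.leaf_names()
    anchor = min(all_leaves)
    out: dict[frozenset, Node] = {}

    def visit(node, is_root):
        if not is_root and not node.is_leaf():
            below = node.leaf_names()
            side = all_leaves - below if anchor in below else below
            if len(side) >= 2 and len(all_leaves - side) >= 2:
                out[frozenset(side)] = node
        for c in node.children:
            visit(c, False)

    visit(tree, True)
    return out


# ---------------------------------------------------------------------------
# alignments and distances


@dataclasses.dataclass
class AlignedSet:
    """A multiple alignment: parallel name and gapped-row lists."""

    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows are not all the same length: {sorted(lengths)}")

    def __len__(self):
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "AlignedSet":
        """Bootstrap replicate: sample columns with replacement."""
        idx = rng.integers(0, self.n_columns, size=self.n_columns)
        mat = np.array([list(r) for r in self.rows])
        return AlignedSet(list(self.names), ["".join(row) for row in mat[:, idx]])

    def to_phylip(self) -> str:
        """Relaxed PHYLIP text (hook for external ML re-optimization)."""
        lines = [f" {len(self)} {self.n_columns}"]
        lines += [f"{n}  {r}" for n, r in zip(self.names, self.rows)]
        return "\n".join(lines) + "\n"


@dataclasses.dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray
    model: str
    saturated: set = dataclasses.field(default_factory=set)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.names), len(self.names)):
            raise ValueError("matrix shape does not match names")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        self.matrix = m


def pairwise_distance(aligned: AlignedSet, model: str = "p") -> DistanceMatrix:
    """Pairwise distances under ``p``, ``JC69`` or ``K2P``.

    Columns with a gap/ambiguity in either sequence of a pair are excluded
    (pairwise deletion).  Pairs whose divergence exceeds the model's valid
    range are flagged saturated and set to ``inf``.
    """
    model = model.upper() if model.lower() != "p" else "p"
    if model not in ("p", "JC69", "K2P"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(aligned)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    d = np.zeros((n, n))
    saturated = set()
    rows = [r.upper() for r in aligned.rows]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            comp = mis = ts = 0
            for x, y in zip(a, b):
                if x in GAP_CHARS or y in GAP_CHARS:
                    continue
                comp += 1
                if x != y:
                    mis += 1
                    if (x in _PURINES) == (y in _PURINES):
                        ts += 1
            if comp == 0:
                raise ValueError(
                    f"no comparable columns between {aligned.names[i]!r} and {aligned.names[j]!r}"
                )
            p = mis / comp
            if model == "p":
                dist = p
            elif model == "JC69":
                arg = 1 - 4 * p / 3
                if arg <= 0:
                    dist = math.inf
                else:
                    dist = -0.75 * math.log(arg)
            else:  # K2P
                P = ts / comp
                Q = (mis - ts) / comp
                arg1 = 1 - 2 * P - Q
                arg2 = 1 - 2 * Q
                if arg1 <= 0 or arg2 <= 0:
                    dist = math.inf
                else:
                    dist = -0.5 * math.log(arg1 * math.sqrt(arg2))
            if math.isinf(dist):
                saturated.add(frozenset((aligned.names[i], aligned.names[j])))
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(aligned.names), d, model, saturated)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> Node:
    """Neighbor joining (Saitou–Nei, Studier–Keppler Q criterion).

    Exact (topology and branch lengths) on additive matrices.  Q-matrix ties
    are broken by the lexicographically smallest (label_i, label_j) pair,
    where a cluster's label is its alphabetically first leaf; negative branch
    lengths are clamped to zero.  Returns an unrooted tree stored as a
    trifurcation (bifurcation for 3 taxa is the trifurcating root itself).
    """
    n = len(dm.names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise ValueError("distance matrix contains non-finite entries (saturated pairs?)")
    nodes = [Node(name) for name in dm.names]
    labels = list(dm.names)  # alphabetically-first leaf per cluster, for tie-breaks
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((labels[i], labels[j])))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        u = Node(children=[nodes[i], nodes[j]])
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        # new distances, stored in slot i
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (d[i, k] + d[j, k] - d[i, j]) / 2
        nodes[i] = u
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    a, b, c = active
    # three-point formulas for the terminal trifurcation
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
    order = sorted((a, b, c), key=lambda idx: labels[idx])
    return Node(children=[nodes[idx] for idx in order])


# ---------------------------------------------------------------------------
# bootstrap and rooting


def bootstrap_support(
    aligned: AlignedSet, model: str = "p", replicates: int = 1000, seed: int = 0
) -> Node:
    """NJ tree on the full alignment with bootstrap support on internal edges.

    Columns are resampled with replacement ``replicates`` times; the support
    of each internal bipartition of the full-data tree is the percentage of
    replicate trees containing it.  Deterministic for a fixed
    (alignment, model, replicates, seed).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = nj_tree(pairwise_distance(aligned, model))
    parts = bipartitions(tree)
    counts = dict.fromkeys(parts, 0)
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        rep = aligned.resample_columns(rng)
        rep_tree = nj_tree(pairwise_distance(rep, model))
        rep_parts = set(bipartitions(rep_tree))
        for p in counts:
            if p in rep_parts:
                counts[p] += 1
    for p, node in parts.items():
        node.support = 100.0 * counts[p] / replicates
    return tree


def root_on_outgroup(tree: Node, outgroup: list[str] | set[str]) -> Node:
    """Root the tree on the edge separating the outgroup clade from the rest.

    The outgroup must be monophyletic in the unrooted tree; otherwise a
    ``ValueError`` reports the conflicting bipartition.  Supports are
    preserved on the corresponding bipartitions.
    """
    og = frozenset(outgroup)
    leaves = tree.leaf_names()
    missing = og - leaves
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")
    if og == leaves:
        raise ValueError("outgroup cannot be the whole taxon set")
    tree = tree.copy()
    if len(og) == 1:
        target = next(n for n in tree.walk() if n.is_leaf() and n.name in og)
    else:
        target = None
        for node in tree.walk():
            if node is tree:
                continue
            below = node.leaf_names()
            if below == og or below == leaves - og:
                target = node
                break
        if target is None:
            # report the best partial grouping as the conflict
            best = max(
                (n.leaf_names() for n in tree.walk() if n is not tree),
                key=lambda s: len(s & og) - len(s - og),
            )
            raise ValueError(
                f"outgroup {sorted(og)} is not monophyletic; closest clade is {sorted(best)}"
            )
    return _reroot_on_edge(tree, target, og)


def _reroot_on_edge(tree: Node, target: Node, og: frozenset) -> Node:
    """Subdivide the edge above ``target`` and root there."""
    parent_of = {}
    for node in tree.walk():
        for c in node.children:
            parent_of[id(c)] = node

    # reverse the path from target's parent up to the old root; a reversed
    # edge keeps its length and support, so the former child's values move to
    # the node that now sits below that same edge
    path = [target]
    node = target
    while id(node) in parent_of:
        node = parent_of[id(node)]
        path.append(node)
    old_len = {id(n): n.length for n in path}
    old_sup = {id(n): n.support for n in path}
    half = target.length / 2
    new_root = Node()
    upper = path[1]
    upper.children.remove(target)
    prev = upper
    # upper's new edge is the other half of target's split edge
    carried_len, carried_sup = target.length - half, old_sup[id(target)]
    for nxt in path[2:]:
        nxt.children.remove(prev)
        prev.children.append(nxt)
        prev.length, prev.support = carried_len, carried_sup
        carried_len, carried_sup = old_len[id(prev)], old_sup[id(prev)]
        prev = nxt
    prev.length, prev.support = carried_len, carried_sup
    target.length = half
    ingroup_first = og != target.leaf_names()
    new_root.children = [upper, target] if ingroup_first else [target, upper]
    # collapse a degree-2 node left at the old root position
    _suppress_unifurcations(new_root)
    return new_root


def _suppress_unifurcations(root: Node) -> None:
    for node in list(root.walk()):
        for i, c in enumerate(node.children):
            while len(c.children) == 1:
                g = c.children[0]
                g.length += c.length
                if g.support is None:
                    g.support = c.support
                node.children[i] = g
                c = g


def flag_high_support(tree: Node, threshold: float = 95.0) -> list[tuple[frozenset, float]]:
    """Internal edges with bootstrap support strictly above ``threshold`` percent."""
    out = []
    for part, node in bipartitions(tree).items():
        if node.support is not None and node.support > threshold:
            out.append((part, node.support))
    return out
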