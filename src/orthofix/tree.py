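"""Rooted trees with labeled leaves: the substrate for species and gene trees.

Trees here are rooted and ordered; all algorithms that consume them treat the
child order as irrelevant, and :func:`canonicalize` / :func:`write_newick`
impose a deterministic order (lexicographic by smallest descendant leaf label)
so that every pipeline output is byte-reproducible.

Branch lengths are parsed and retained on nodes but ignored by every
algorithm: topology corrections invalidate them, and the writer omits them by
default.
"""

from __future__ import annotations

import itertools
import re
from collections.abc import Iterable, Iterator

from .errors import NewickParseError, TreeValidationError

__all__ = [
    "Node",
    "RootedTree",
    "parse_newick",
    "write_newick",
    "lca",
    "clades",
    "clade",
    "rf_distance",
    "triplets",
    "shared_triplet_count",
    "standardize",
    "canonicalize",
]


class Node:
    """A node of a rooted tree.

    Leaves carry a mandatory unique ``label``; internal nodes may carry one
    (used e.g. to name ancestral species).
    """

    __slots__ = ("label", "parent", "children", "length")

    def __init__(self, label: str | None = None, children: Iterable["Node"] = (),
                 length: float | None = None):
        self.label = label
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = length
        for c in children:
            self.add_child(c)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach_child(self, child: "Node") -> "Node":
        self.children.remove(child)
        child.parent = None
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> Iterator["Node"]:
        return (n for n in self.preorder() if n.is_leaf)

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def ancestors(self) -> Iterator["Node"]:
        """Strict ancestors, parent first."""
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def copy(self) -> "Node":
        new = Node(self.label, length=self.length)
        for c in self.children:
            new.add_child(c.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"<leaf {self.label}>"
        return f"<node {self.label or ''} {sorted(self.leaf_labels())}>"


class RootedTree:
    """A rooted tree with uniquely labeled leaves."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        return parse_newick(text)

    def copy(self) -> "RootedTree":
        return RootedTree(self.root.copy(), validate=False)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        labels = [n.label for n in self.root.leaves()]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeValidationError("every leaf must carry a label")
        dup = [lab for lab, k in _counts(labels).items() if k > 1]
        if dup:
            raise TreeValidationError(f"duplicate leaf labels: {sorted(dup)}")
        for node in self.root.preorder():
            for c in node.children:
                if c.parent is not node:
                    raise TreeValidationError("inconsistent parent pointer")

    # -- queries -----------------------------------------------------------
    def nodes(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> Iterator[Node]:
        return self.root.leaves()

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.nodes() if not n.is_leaf)

    @property
    def is_degenerate(self) -> bool:
        """True for the single-leaf tree (allowed only as a recursion base)."""
        return self.root.is_leaf

    def find(self, label: str) -> Node:
        """Find the unique node with this label (leaf or labeled internal)."""
        for n in self.nodes():
            if n.label == label:
                return n
        raise KeyError(f"no node labeled {label!r}")

    def depths(self) -> dict[Node, int]:
        d = {self.root: 0}
        for n in self.nodes():
            if n is not self.root:
                d[n] = d[n.parent] + 1
        return d

    def newick(self, lengths: bool = False) -> str:
        return write_newick(self, lengths=lengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return _shape(self.root) == _shape(other.root)

    def __hash__(self) -> int:
        return hash(_shape(self.root))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedTree({self.newick()!r})"


def _counts(items: Iterable[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for it in items:
        out[it] = out.get(it, 0) + 1
    return out


def _shape(node: Node):
    """Order-insensitive structural key (labels of leaves, nested)."""
    if node.is_leaf:
        return node.label
    return tuple(sorted((_shape(c) for c in node.children), key=repr))


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"[^(),:;\s]+")


def parse_newick(text: str) -> RootedTree:
    """Parse a rooted Newick string.

    Internal labels and branch lengths are kept; a degree-one root (as in
    ``"(a1);"``) is contracted, so that string yields the degenerate
    single-leaf tree.  Duplicate leaf labels raise
    :class:`~orthofix.errors.TreeValidationError`; malformed input raises
    :class:`~orthofix.errors.NewickParseError` with the character offset.
    """
    s = text.strip()
    if not s:
        raise NewickParseError("empty Newick string", 0)
    pos = 0

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def parse_node() -> Node:
        nonlocal pos
        skip_ws()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node = Node()
            while True:
                node.add_child(parse_node())
                skip_ws()
                if pos >= len(s):
                    raise NewickParseError("unclosed '('", pos)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickParseError(f"expected ',' or ')', got {s[pos]!r}", pos)
            m = _LABEL_RE.match(s, pos)
            if m:
                node.label = m.group(0)
                pos = m.end()
        else:
            m = _LABEL_RE.match(s, pos)
            if not m:
                got = s[pos] if pos < len(s) else "end of input"
                raise NewickParseError(f"expected leaf label, got {got!r}", pos)
            node = Node(m.group(0))
            pos = m.end()
        skip_ws()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m2 = re.compile(r"[-+0-9.eE]+").match(s, pos)
            if not m2:
                raise NewickParseError("expected branch length after ':'", pos)
            try:
                node.length = float(m2.group(0))
            except ValueError:
                raise NewickParseError(f"bad branch length {m2.group(0)!r}", pos) from None
            pos = m2.end()
        return node

    root = parse_node()
    skip_ws()
    if pos >= len(s) or s[pos] != ";":
        raise NewickParseError("expected ';'", pos)
    if s[pos + 1:].strip():
        raise NewickParseError("trailing characters after ';'", pos + 1)
    # contract a degree-one root: "(a1);" denotes the single leaf a1
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    return RootedTree(root)


def _min_leaf(node: Node) -> str:
    return min(n.label for n in node.leaves())


def write_newick(tree: RootedTree, lengths: bool = False) -> str:
    """Serialize deterministically: children ordered by smallest leaf label."""

    def fmt(node: Node) -> str:
        lab = node.label or ""
        suffix = f":{node.length:g}" if (lengths and node.length is not None) else ""
        if node.is_leaf:
            return lab + suffix
        kids = sorted(node.children, key=_min_leaf)
        return "(" + ",".join(fmt(c) for c in kids) + ")" + lab + suffix

    return fmt(tree.root) + ";"


def canonicalize(tree: RootedTree) -> RootedTree:
    """Sort children in place by smallest descendant leaf label; returns tree."""
    for node in tree.root.postorder():
        if node.children:
            node.children.sort(key=_min_leaf)
    return tree


# ---------------------------------------------------------------------------
# Clade / LCA / triplet queries
# ---------------------------------------------------------------------------

def clade(node: Node) -> frozenset[str]:
    """The clade of a node: the set of leaf labels below it (l(x))."""
    return node.leaf_labels()


def clades(tree: RootedTree) -> frozenset[frozenset[str]]:
    """All clades of the tree, one per node (singletons and full set included)."""
    return frozenset(n.leaf_labels() for n in tree.nodes())


def clade_map(tree: RootedTree) -> dict[Node, frozenset[str]]:
    """Clade of every node, computed bottom-up in one pass."""
    out: dict[Node, frozenset[str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            out[node] = frozenset((node.label,))
        else:
            out[node] = frozenset().union(*(out[c] for c in node.children))
    return out


def lca(tree: RootedTree, labels: Iterable[str]) -> Node:
    """Lowest common ancestor of a set of leaf labels."""
    want = set(labels)
    if not want:
        raise ValueError("lca of an empty label set")
    missing = want - tree.leaf_labels
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    cmap = clade_map(tree)
    best = tree.root
    changed = True
    while changed:
        changed = False
        for c in best.children:
            if want <= cmap[c]:
                best = c
                changed = True
                break
    return best


def rf_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Robinson-Foulds distance between rooted trees on the same leaf set.

    Defined as the cardinality of the symmetric difference of the two clade
    sets; for binary trees this equals 2·c(T1,T2) where c counts clades of T1
    absent from T2.
    """
    l1, l2 = t1.leaf_labels, t2.leaf_labels
    if l1 != l2:
        only1, only2 = sorted(l1 - l2), sorted(l2 - l1)
        raise TreeValidationError(
            f"leaf sets differ: only in first {only1}, only in second {only2}")
    return len(clades(t1) ^ clades(t2))


def triplets(tree: RootedTree) -> frozenset[tuple[frozenset[str], str]]:
    """All resolved rooted triplets ((a,b),c) of a binary tree.

    Encoded as ``(frozenset({a, b}), c)``, present whenever the lca of all
    three leaves is strictly above the lca of a and b.  A binary tree on n
    leaves resolves all C(n,3) triplets.
    """
    cmap = clade_map(tree)
    all_leaves = tree.leaf_labels
    out: set[tuple[frozenset[str], str]] = set()
    for node in tree.nodes():
        if node.is_leaf:
            continue
        outside = all_leaves - cmap[node]
        for c1, c2 in itertools.combinations(node.children, 2):
            for a in cmap[c1]:
                for b in cmap[c2]:
                    pair = frozenset((a, b))
                    for c in outside:
                        out.add((pair, c))
    return frozenset(out)


def shared_triplet_count(t1: RootedTree, t2: RootedTree) -> int:
    """Number of triplets resolved identically in both trees."""
    return len(triplets(t1) & triplets(t2))


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(tree: RootedTree, extant: Iterable[str]) -> RootedTree:
    """Remove nodes with no descendant in ``extant``, then contract.

    This is the cleanup step shared by the correction algorithms: leaves not
    in ``extant`` (e.g. the species-tree skeleton copy) are deleted, internal
    nodes left with no surviving descendants disappear, non-root degree-2
    nodes are contracted and a degree-1 root is contracted.  The result's leaf
    set is exactly ``extant`` intersected with the input's leaves.
    """
    keep = set(extant)

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in keep:
                return Node(node.label, length=node.length)
            return None
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = Node(node.label, length=node.length)
        for k in kids:
            new.add_child(k)
        return new

    root = prune(tree.root)
    if root is None:
        raise TreeValidationError("standardize would produce an empty tree")
    return RootedTree(root, validate=False)
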