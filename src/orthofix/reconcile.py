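"""LCA reconciliation of gene trees with a species tree.

A reconciliation assigns to every gene-tree node g the species s(g): the
lowest common ancestor in the species tree S of the species of the extant
genes below g.  Each internal node is then labeled with an event:
speciation when s(g) differs from the species of both children, duplication
otherwise.  Orthology and paralogy of two genes are read off the event at
their lca.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .errors import TreeValidationError
from .tree import Node, RootedTree, parse_newick

__all__ = [
    "SpeciesTree",
    "GeneSpeciesMap",
    "ReconciledGeneTree",
    "reconcile",
    "SPECIATION",
    "DUPLICATION",
    "LEAF",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"
LEAF = "leaf"


class SpeciesTree:
    """A rooted binary species tree with fast ancestry queries.

    Every node is addressable by a stable identifier: its own label when
    present, otherwise the sorted comma-joined list of its descendant
    species.
    """

    def __init__(self, tree: RootedTree):
        if not tree.is_binary:
            raise TreeValidationError(
                "species tree must be binary and rooted; a trifurcating root "
                "usually indicates an unrooted Newick file")
        self.tree = tree
        self.depth: dict[Node, int] = tree.depths()
        self._leaf: dict[str, Node] = {n.label: n for n in tree.leaves()}

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return cls(parse_newick(text))

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.tree.leaf_labels

    def leaf(self, species: str) -> Node:
        try:
            return self._leaf[species]
        except KeyError:
            raise KeyError(f"species {species!r} not in species tree") from None

    def node_id(self, node: Node) -> str:
        return node.label or ",".join(sorted(node.leaf_labels()))

    def lca(self, u: Node, v: Node) -> Node:
        du, dv = self.depth[u], self.depth[v]
        while du > dv:
            u = u.parent
            du -= 1
        while dv > du:
            v = v.parent
            dv -= 1
        while u is not v:
            u, v = u.parent, v.parent
        return u

    def lca_of(self, nodes: Iterable[Node]) -> Node:
        it = iter(nodes)
        try:
            acc = next(it)
        except StopIteration:
            raise ValueError("lca of an empty node set") from None
        for n in it:
            acc = self.lca(acc, n)
        return acc

    def is_descendant(self, u: Node, v: Node, strict: bool = False) -> bool:
        """True if u lies in the subtree rooted at v."""
        if u is v:
            return not strict
        return any(a is v for a in u.ancestors())


class GeneSpeciesMap(dict):
    """Total mapping from extant gene label to species leaf label."""

    @classmethod
    def from_tsv(cls, path) -> "GeneSpeciesMap":
        out = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise TreeValidationError(
                        f"{path}:{lineno}: expected 'gene<TAB>species', got {line!r}")
                out[parts[0]] = parts[1]
        return out

    @classmethod
    def from_regex(cls, genes: Iterable[str], pattern: str) -> "GeneSpeciesMap":
        """Derive species names from leaf names via a capturing regex."""
        import re

        rx = re.compile(pattern)
        out = cls()
        for g in genes:
            m = rx.match(g)
            if not m or not m.groups():
                raise TreeValidationError(
                    f"species regex {pattern!r} does not capture from {g!r}")
            out[g] = m.group(1)
        return out

    def validate(self, gene_tree: RootedTree, species: SpeciesTree) -> None:
        for g in gene_tree.leaf_labels:
            if g not in self:
                raise TreeValidationError(f"gene leaf {g!r} has no species mapping")
            if self[g] not in species.leaf_labels:
                raise TreeValidationError(
                    f"gene {g!r} maps to {self[g]!r}, absent from the species tree")


@dataclass
class ReconciledGeneTree:
    """A gene tree with per-node species assignment s(·) and event label E(·)."""

    tree: RootedTree
    species: SpeciesTree
    gene_species: GeneSpeciesMap
    s: dict[Node, Node] = field(repr=False, default_factory=dict)
    event: dict[Node, str] = field(repr=False, default_factory=dict)

    @property
    def root(self) -> Node:
        return self.tree.root

    def species_of(self, node: Node) -> Node:
        return self.s[node]

    def event_of(self, node: Node) -> str:
        return self.event[node]

    def duplication_nodes(self) -> list[Node]:
        return [n for n in self.tree.nodes() if self.event[n] == DUPLICATION]

    def lca_event(self, g1: str, g2: str) -> str:
        from .tree import lca

        return self.event[lca(self.tree, {g1, g2})]

    def are_orthologs(self, g1: str, g2: str) -> bool:
        return self.lca_event(g1, g2) == SPECIATION

    def check(self) -> None:
        """Re-derive s(·)/E(·) and assert they match (reconcile idempotence)."""
        fresh = reconcile(self.tree, self.species, self.gene_species)
        for node in self.tree.nodes():
            assert fresh.s[node] is self.s[node], "stale species assignment"
            assert fresh.event[node] == self.event[node], "stale event label"
        # ancestor with equal species must be a duplication
        for node in self.tree.nodes():
            for anc in node.ancestors():
                if self.s[anc] is self.s[node]:
                    assert self.event[anc] == DUPLICATION


def reconcile(G: RootedTree, S: SpeciesTree, gmap: Mapping[str, str]) -> ReconciledGeneTree:
    """LCA-reconcile a gene tree with a species tree.

    Works on multifurcated intermediates as well: an internal node is a
    duplication iff its species equals the species of at least one child.
    """
    if not isinstance(gmap, GeneSpeciesMap):
        gmap = GeneSpeciesMap(gmap)
    gmap.validate(G, S)
    s: dict[Node, Node] = {}
    event: dict[Node, str] = {}
    for node in G.root.postorder():
        if node.is_leaf:
            s[node] = S.leaf(gmap[node.label])
            event[node] = LEAF
        else:
            s[node] = S.lca_of(s[c] for c in node.children)
            dup = any(s[c] is s[node] for c in node.children)
            event[node] = DUPLICATION if dup else SPECIATION
    return ReconciledGeneTree(G, S, GeneSpeciesMap(gmap), s, event)
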