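"""Gene Orthology Correction: minimal RF correction under pair constraints.

Given a reconciled gene tree G and a set P of gene pairs required to be
orthologous, the correction computes a binary tree G_P on the same leaves in
which every pair of P has a speciation lca, at minimum Robinson-Foulds
distance from G.  The key objects:

* false paralogs P_f: pairs of P whose lca in G is a duplication;
* for an ordered pair (a, b): r_{a,b} = lca_G(a, b),
  s_{a,b} = lca_S(s(a), s(b)), and the movable apex h_{a,b} — the highest
  node on the path from a to r_{a,b} whose species lies strictly below
  s_{a,b};
* the forbidden set H: strict ancestors of some h_{a,b} that are strict
  descendants of the corresponding r_{a,b}.  No P-satisfying tree can contain
  the clade of a node of H, and exactly those clades are sacrificed:
  RF(G, G_P) = 2|H|.

The corrected tree is assembled recursively: the subtrees hanging from the
highest preservable descendants of each preservable node are joined into a
maximum orthology tree by grafting them onto a copy of the species tree, so
that any two subtrees whose species are unrelated end up under a speciation.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

from .errors import ConstraintError
from .reconcile import DUPLICATION, ReconciledGeneTree, SpeciesTree, reconcile
from .results import CorrectionResult, count_duplications
from .tree import (Node, RootedTree, canonicalize, clades, rf_distance,
                   standardize)

__all__ = [
    "OrthologyConstraints",
    "GocAnalysis",
    "false_paralogs",
    "movable_apex",
    "forbidden_nodes",
    "highest_preservable_descendants",
    "max_orthology_tree",
    "analyze_goc",
    "correct_goc",
]


class OrthologyConstraints:
    """A symmetric set of unordered gene-label pairs required orthologous."""

    def __init__(self, pairs: Iterable[tuple[str, str] | frozenset]):
        self._pairs: set[frozenset[str]] = set()
        for p in pairs:
            a, b = tuple(p)
            if a == b:
                raise ConstraintError(f"pair ({a!r}, {b!r}) is not a pair of distinct genes")
            self._pairs.add(frozenset((a, b)))

    @classmethod
    def from_tsv(cls, path) -> "OrthologyConstraints":
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ConstraintError(
                        f"{path}:{lineno}: expected 'geneA<TAB>geneB', got {line!r}")
                pairs.append((parts[0], parts[1]))
        return cls(pairs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.ordered():
                if a < b:
                    fh.write(f"{a}\t{b}\n")

    def __iter__(self):
        return iter(sorted(self._pairs, key=sorted))

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self._pairs

    def __eq__(self, other) -> bool:
        if isinstance(other, OrthologyConstraints):
            return self._pairs == other._pairs
        return NotImplemented

    def ordered(self) -> list[tuple[str, str]]:
        """Both orientations of every pair, deterministically ordered."""
        out = []
        for p in self:
            a, b = sorted(p)
            out.append((a, b))
            out.append((b, a))
        return out

    def validate(self, R: ReconciledGeneTree) -> None:
        leaves = R.tree.leaf_labels
        for p in self:
            a, b = sorted(p)
            for g in (a, b):
                if g not in leaves:
                    raise ConstraintError(f"constraint gene {g!r} is not a leaf of the gene tree")
            if R.gene_species[a] == R.gene_species[b]:
                raise ConstraintError(
                    f"pair ({a!r}, {b!r}) maps to a single species "
                    f"{R.gene_species[a]!r}; same-species genes cannot be orthologs")


@dataclass
class GocAnalysis:
    """Per-instance quantities of the pair-constraint correction."""

    constraints: OrthologyConstraints
    false_paralog_pairs: OrthologyConstraints
    r: dict[tuple[str, str], Node] = field(repr=False, default_factory=dict)
    s_ab: dict[tuple[str, str], Node] = field(repr=False, default_factory=dict)
    h: dict[tuple[str, str], Node] = field(repr=False, default_factory=dict)
    forbidden: set[Node] = field(repr=False, default_factory=set)

    @property
    def forbidden_count(self) -> int:
        return len(self.forbidden)


def false_paralogs(R: ReconciledGeneTree, P: OrthologyConstraints) -> OrthologyConstraints:
    """The subset P_f of P whose lca in G is a duplication."""
    if not isinstance(P, OrthologyConstraints):
        P = OrthologyConstraints(P)
    P.validate(R)
    return OrthologyConstraints(
        p for p in P if R.lca_event(*sorted(p)) == DUPLICATION)


def _leaf_node(R: ReconciledGeneTree, label: str) -> Node:
    for n in R.tree.leaves():
        if n.label == label:
            return n
    raise KeyError(f"no gene leaf labeled {label!r}")


def _gene_lca(R: ReconciledGeneTree, a: Node, b: Node) -> Node:
    anc_a = [a, *a.ancestors()]
    in_a = set(map(id, anc_a))
    node = b
    while id(node) not in in_a:
        node = node.parent
    return node


def movable_apex(R: ReconciledGeneTree, a: str, b: str) -> Node:
    """h_{a,b}: the highest node on the path from a to r_{a,b} whose species
    lies strictly below s_{a,b} = lca_S(s(a), s(b)).

    It always exists (a itself qualifies) and is never r_{a,b}.  Species
    assignments along the path ascend in S, so the qualifying prefix of the
    path is contiguous and the apex is its top.
    """
    na, nb = _leaf_node(R, a), _leaf_node(R, b)
    r = _gene_lca(R, na, nb)
    s_ab = R.species.lca(R.s[na], R.s[nb])
    apex = None
    node = na
    while node is not r:
        if R.species.is_descendant(R.s[node], s_ab, strict=True):
            apex = node
        node = node.parent
    assert apex is not None, "leaf a must map strictly below s_{a,b}"
    return apex


def forbidden_nodes(R: ReconciledGeneTree, P_f: OrthologyConstraints) -> set[Node]:
    """H: union over ordered false-paralog pairs (a, b) of the strict
    ancestors of h_{a,b} that are strict descendants of r_{a,b}."""
    H: set[Node] = set()
    for a, b in P_f.ordered():
        na, nb = _leaf_node(R, a), _leaf_node(R, b)
        r = _gene_lca(R, na, nb)
        h = movable_apex(R, a, b)
        node = h.parent
        while node is not r:
            H.add(node)
            node = node.parent
    return H


def analyze_goc(R: ReconciledGeneTree, P: OrthologyConstraints) -> GocAnalysis:
    """Compute P_f, the per-pair r/s/h values and the forbidden set H."""
    if not isinstance(P, OrthologyConstraints):
        P = OrthologyConstraints(P)
    P.validate(R)
    pf = false_paralogs(R, P)
    ana = GocAnalysis(P, pf)
    for a, b in pf.ordered():
        na, nb = _leaf_node(R, a), _leaf_node(R, b)
        ana.r[(a, b)] = _gene_lca(R, na, nb)
        ana.s_ab[(a, b)] = R.species.lca(R.s[na], R.s[nb])
        ana.h[(a, b)] = movable_apex(R, a, b)
    ana.forbidden = forbidden_nodes(R, pf)
    return ana


def highest_preservable_descendants(R: ReconciledGeneTree, H: set[Node],
                                    x: Node) -> list[Node]:
    """Maximal nodes strictly below x that are not in H, reached through H
    nodes only.  Their clades partition the leaves of x."""
    out: list[Node] = []

    def visit(node: Node) -> None:
        if node not in H:
            out.append(node)
            return
        for c in node.children:
            visit(c)

    for c in x.children:
        visit(c)
    return out


def _min_leaf_node(node: Node) -> str:
    return min(n.label for n in node.leaves())


def max_orthology_tree(S: SpeciesTree,
                       X: Iterable[tuple[Node | RootedTree, Node]]) -> RootedTree:
    """Join subtrees so that species-unrelated pairs fall under speciations.

    ``X`` is a sequence of ``(subtree, species_node)`` pairs, the species
    node being the subtree root's assignment in S.  A full copy of S serves
    as the skeleton: each subtree is grafted (ascending order of smallest
    leaf label) on the edge immediately above the skeleton node carrying its
    species, successive grafts onto the same node stacking below earlier
    ones.  Skeleton leaves are then removed and the tree standardized.

    Every input subtree appears unchanged in the result; skeleton nodes that
    survive are speciations, and any two subtrees whose species are unrelated
    in S (neither an ancestor of the other) join under one of them.
    """
    items = []
    for sub, sp in X:
        root = sub.root if isinstance(sub, RootedTree) else sub
        items.append((root, sp))
    if not items:
        raise ValueError("max_orthology_tree requires at least one subtree")

    # skeleton copy of S; leaves unlabeled so standardize removes them even
    # if a gene happens to share a species' name
    mapping: dict[int, Node] = {}

    def cp(sn: Node) -> Node:
        c = Node(None)
        mapping[id(sn)] = c
        for k in sn.children:
            c.add_child(cp(k))
        return c

    f_root = cp(S.tree.root)
    extant: set[str] = set()
    for sub, sp in sorted(items, key=lambda t: _min_leaf_node(t[0])):
        extant.update(n.label for n in sub.leaves())
        v = mapping[id(sp)]
        graft = sub.copy()
        w = Node(None)
        if v.parent is None:
            f_root = w
        else:
            p = v.parent
            p.children[p.children.index(v)] = w
            w.parent = p
        v.parent = None
        w.add_child(graft)
        w.add_child(v)
    F = standardize(RootedTree(f_root, validate=False), extant)
    return canonicalize(F)


def correct_goc(R: ReconciledGeneTree,
                P: OrthologyConstraints | Iterable) -> CorrectionResult:
    """Solve the pair-constraint correction problem.

    Returns a corrected, re-reconciled binary tree on the same leaves in
    which every pair of P is orthologous, every preservable clade of G is
    preserved, and RF to the input equals 2|H|.
    """
    if not isinstance(P, OrthologyConstraints):
        P = OrthologyConstraints(P)
    ana = analyze_goc(R, P)
    H = ana.forbidden

    def rebuild(x: Node) -> Node:
        if x.is_leaf:
            return Node(x.label)
        parts = [(rebuild(xi), R.s[xi])
                 for xi in highest_preservable_descendants(R, H, x)]
        return max_orthology_tree(R.species, parts).root

    corrected = canonicalize(RootedTree(rebuild(R.root)))
    recon = reconcile(corrected, R.species, R.gene_species)
    rf = rf_distance(R.tree, corrected)
    lost = sorted(clades(R.tree) - clades(corrected), key=sorted)
    report = [
        {"pair": sorted(p), "satisfied": recon.are_orthologs(*sorted(p)),
         "was_false_paralog": p in ana.false_paralog_pairs}
        for p in P
    ]
    return CorrectionResult(
        corrected=recon,
        rf_to_input=rf,
        forbidden_count=len(H),
        constraint_report=report,
        lost_clades=lost,
        input_duplications=count_duplications(R),
        output_duplications=count_duplications(recon),
    )
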