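"""Clade Orthology Correction: make given clades speciation-rooted.

Given a reconciled gene tree G and a set C of clades of G whose roots are
(suspect) duplications, the correction rearranges G so that the lca of every
clade of C becomes a speciation, at minimum RF distance.

Feasibility: a solution exists iff no constrained clade maps to a leaf
species, and every two constrained clades are either leaf-disjoint or map to
different species.  Two rearrangements of a duplication node x with species
s and species children A, B are provided:

* pushing by multifurcation — replace the clade of x by a root joining the
  multifurcations of the maximal pure-A-side and pure-B-side subtrees; the
  binary resolutions of the fully pushed tree are exactly the RF-optimal
  solutions;
* pushing by tree duplication — replace the clade of x by a root joining the
  A-side restriction and B-side restriction of the subtree (each
  standardized); applied to all clades of C in any order this yields one
  specific RF-optimal solution, the one maximizing the number of triplets
  shared with G.

When C is infeasible, a heuristic pushes the constrained duplications
starting from the ones closest to the root and reports which constraints
remain unsatisfied; no optimality is claimed for it.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Sequence

from .errors import ConstraintError, InfeasibleError, ResolutionLimitError
from .oracle import enumerate_rooted_binary_trees, n_topologies
from .reconcile import (DUPLICATION, SPECIATION, ReconciledGeneTree,
                        reconcile)
from .results import CorrectionResult, count_duplications
from .tree import (Node, RootedTree, canonicalize, clade_map, clades,
                   rf_distance, standardize)

__all__ = [
    "CladeConstraints",
    "coc_feasible",
    "push_multifurcation",
    "push_tree_duplication",
    "binary_resolutions",
    "correct_coc",
]

log = logging.getLogger(__name__)


class CladeConstraints:
    """A set of leaf-label sets, each required to be the clade of a
    speciation node in the corrected tree."""

    def __init__(self, clade_sets: Iterable[Iterable[str]]):
        self._clades: set[frozenset[str]] = set()
        for c in clade_sets:
            fs = frozenset(c)
            if not fs:
                raise ConstraintError("empty clade constraint")
            self._clades.add(fs)

    @classmethod
    def from_file(cls, path) -> "CladeConstraints":
        out = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                out.append([g.strip() for g in line.split(",") if g.strip()])
        return cls(out)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(sorted(self._clades, key=lambda c: (sorted(c), len(c))))

    def __len__(self) -> int:
        return len(self._clades)

    def resolve(self, R: ReconciledGeneTree) -> dict[frozenset[str], Node]:
        """Map each constraint to the gene-tree node with exactly that clade."""
        by_clade = {cl: node for node, cl in clade_map(R.tree).items()}
        out: dict[frozenset[str], Node] = {}
        for c in self:
            if c not in by_clade:
                raise ConstraintError(
                    f"leaf set {sorted(c)} is not a clade of the gene tree")
            out[c] = by_clade[c]
        return out


def coc_feasible(R: ReconciledGeneTree,
                 C: CladeConstraints | Iterable) -> tuple[bool, list[str]]:
    """Exact feasibility test for clade constraint sets.

    Feasible iff every constrained clade maps to an internal species and
    every pair of constrained clades is leaf-disjoint or maps to two
    different species.  Returns the verdict plus human-readable violations.
    """
    if not isinstance(C, CladeConstraints):
        C = CladeConstraints(C)
    nodes = C.resolve(R)
    violations: list[str] = []
    ordered = list(C)
    for c in ordered:
        if R.s[nodes[c]].is_leaf:
            violations.append(
                f"clade {sorted(c)} maps to leaf species "
                f"{R.species.node_id(R.s[nodes[c]])!r}")
    for i, c1 in enumerate(ordered):
        for c2 in ordered[i + 1:]:
            if (c1 & c2) and R.s[nodes[c1]] is R.s[nodes[c2]]:
                violations.append(
                    f"clades {sorted(c1)} and {sorted(c2)} overlap and both map "
                    f"to species {R.species.node_id(R.s[nodes[c1]])!r}")
    return not violations, violations


def _replace_subtree(tree: RootedTree, old: Node, new: Node) -> RootedTree:
    if old.parent is None:
        return RootedTree(new, validate=False)
    p = old.parent
    p.children[p.children.index(old)] = new
    new.parent = p
    old.parent = None
    return tree


def _side_leaves(R: ReconciledGeneTree, x: Node, side: Node) -> set[str]:
    return {n.label for n in x.leaves()
            if R.species.is_descendant(R.s[n], side)}


def _check_pushable(R: ReconciledGeneTree, x: Node) -> tuple[Node, Node]:
    if R.event[x] != DUPLICATION:
        raise ConstraintError("only duplication nodes can be pushed")
    s = R.s[x]
    if s.is_leaf:
        raise ConstraintError(
            f"node maps to leaf species {R.species.node_id(s)!r}; "
            "a same-species clade cannot be rooted by a speciation")
    return s.children[0], s.children[1]


def push_multifurcation(R: ReconciledGeneTree, x: Node) -> RootedTree:
    """Replace the clade of x by a root joining the multifurcations of the
    maximal pure-A-side / pure-B-side subtrees (A, B = children of s(x)).

    The result is a (possibly multifurcated) tree whose binary resolutions
    are exactly the RF-optimal ways of making x's clade speciation-rooted.
    All clades outside x's subtree, and the pure-side clades within, are
    untouched.
    """
    A, B = _check_pushable(R, x)

    sides: dict[Node, list[Node]] = {A: [], B: []}

    def collect(node: Node) -> None:
        labs = {n.label for n in node.leaves()}
        for side in (A, B):
            if labs <= _side_leaves(R, x, side):
                sides[side].append(node.copy())
                return
        for c in node.children:
            collect(c)

    collect(x)

    def join(parts: list[Node]) -> Node:
        assert parts, "a duplication spans both sides of its species"
        if len(parts) == 1:
            return parts[0]
        return Node(None, parts)

    new = Node(None, [join(sides[A]), join(sides[B])])
    tree = R.tree.copy()
    # locate x's copy by clade
    target = {cl: n for n, cl in clade_map(tree).items()}[x.leaf_labels()]
    return canonicalize(_replace_subtree(tree, target, new))


def push_tree_duplication(R: ReconciledGeneTree, x: Node) -> ReconciledGeneTree:
    """Replace the clade of x by a speciation joining the A-side and B-side
    restrictions of x's subtree, each standardized.

    This is one particular binary resolution of the multifurcation push: the
    one that keeps the relative topology of each side intact, and with it
    every triplet that any optimal solution could keep.
    """
    A, B = _check_pushable(R, x)

    def side_copy(side: Node) -> RootedTree:
        cp = x.copy()
        cp.label = None  # the pushed node's name must not recur on both sides
        return standardize(RootedTree(cp, validate=False),
                           _side_leaves(R, x, side))

    part_a = side_copy(A)
    part_b = side_copy(B)
    new = Node(None, [part_a.root, part_b.root])
    tree = R.tree.copy()
    target = {cl: n for n, cl in clade_map(tree).items()}[x.leaf_labels()]
    out = canonicalize(_replace_subtree(tree, target, new))
    return reconcile(out, R.species, R.gene_species)


def binary_resolutions(T: RootedTree, limit: int = 10 ** 6) -> Iterator[RootedTree]:
    """All binary trees containing every clade of T, each exactly once.

    The count is the product over multifurcated nodes of (2d-3)!! for degree
    d; if it exceeds ``limit`` a :class:`ResolutionLimitError` is raised
    rather than truncating silently.
    """
    total = 1
    for node in T.nodes():
        if len(node.children) > 2:
            total *= n_topologies(len(node.children))
    if total > limit:
        raise ResolutionLimitError(
            f"{total} binary resolutions exceed the limit of {limit}")

    def resolve(node: Node) -> Iterator[Node]:
        if node.is_leaf:
            yield node.copy()
            return
        import itertools

        kid_lists = [list(resolve(c)) for c in node.children]
        for combo in itertools.product(*kid_lists):
            if len(combo) == 1:
                yield combo[0].copy()
            elif len(combo) == 2:
                yield Node(node.label, [combo[0].copy(), combo[1].copy()])
            else:
                units = {str(i): sub for i, sub in enumerate(combo)}
                for shape in enumerate_rooted_binary_trees(
                        list(units), max_leaves=max(8, len(combo))):
                    yield _substitute(shape.root, units)

    def _substitute(shape: Node, units: dict[str, Node]) -> Node:
        if shape.is_leaf:
            return units[shape.label].copy()
        return Node(None, [_substitute(c, units) for c in shape.children])

    for root in resolve(T.root):
        yield canonicalize(RootedTree(root, validate=False))


def correct_coc(R: ReconciledGeneTree, C: CladeConstraints | Iterable,
                mode: str = "strict",
                order: Sequence[frozenset[str]] | None = None) -> CorrectionResult:
    """Solve the clade-constraint correction problem.

    In ``strict`` mode the constraint set must be feasible
    (:func:`coc_feasible`); each constrained node is then pushed by tree
    duplication.  The result is independent of the push order — ``order``
    exists to let tests demonstrate that — RF-optimal, and triplet-maximal
    among the optima.

    In ``force`` mode infeasible sets are accepted: constraints are processed
    starting from the nodes closest to the root, each pushed if it is still a
    pushable duplication clade when reached; unsatisfied constraints are
    reported and no optimality is claimed.
    """
    if mode not in ("strict", "force"):
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(C, CladeConstraints):
        C = CladeConstraints(C)
    nodes = C.resolve(R)

    if mode == "strict":
        ok, violations = coc_feasible(R, C)
        if not ok:
            raise InfeasibleError(
                "no tree satisfies the clade constraints", violations)
        todo = list(C) if order is None else [frozenset(c) for c in order]
        if sorted(map(sorted, todo)) != sorted(map(sorted, C)):
            raise ConstraintError("order must be a permutation of the constraints")
    else:
        depth = R.tree.depths()
        todo = sorted(C, key=lambda c: (depth[nodes[c]], sorted(c)))

    cur = R
    pushed: list[frozenset[str]] = []
    for c in todo:
        by_clade = {cl: n for n, cl in clade_map(cur.tree).items()}
        if c not in by_clade:
            log.warning("clade %s no longer present; constraint skipped", sorted(c))
            continue
        node = by_clade[c]
        if cur.event[node] == SPECIATION:
            log.warning("clade %s already speciation-rooted; no-op", sorted(c))
            continue
        if cur.s[node].is_leaf:
            log.warning("clade %s maps to a leaf species; cannot push", sorted(c))
            continue
        cur = push_tree_duplication(cur, node)
        pushed.append(c)

    corrected = canonicalize(cur.tree)
    recon = reconcile(corrected, R.species, R.gene_species)
    out_clades = {cl: n for n, cl in clade_map(corrected).items()}
    report = [
        {"clade": sorted(c),
         "satisfied": (c in out_clades
                       and recon.event[out_clades[c]] == SPECIATION),
         "pushed": c in pushed}
        for c in C
    ]
    return CorrectionResult(
        corrected=recon,
        rf_to_input=rf_distance(R.tree, corrected),
        pushed_clades=pushed,
        constraint_report=report,
        lost_clades=sorted(clades(R.tree) - clades(corrected), key=sorted),
        input_duplications=count_duplications(R),
        output_duplications=count_duplications(recon),
    )
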