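"""Brute-force ground truth for small instances.

Exhaustive enumeration of rooted binary topologies ((2n-3)!! of them on n
leaves) plus constraint-satisfaction filters give exact minimal-RF and
maximal-shared-triplet reference answers against which the polynomial
correction algorithms are certified.  Desk-scale only: the default leaf cap
is 8.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping

from .reconcile import SPECIATION, ReconciledGeneTree, SpeciesTree, reconcile
from .tree import (Node, RootedTree, canonicalize, clade_map, rf_distance,
                   shared_triplet_count)

__all__ = [
    "n_topologies",
    "enumerate_rooted_binary_trees",
    "satisfies_pairs",
    "satisfies_clades",
    "brute_force_goc",
    "brute_force_coc",
]


def n_topologies(n: int) -> int:
    """(2n-3)!!: the number of rooted binary topologies on n labeled leaves."""
    if n < 1:
        raise ValueError("n must be positive")
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


def enumerate_rooted_binary_trees(labels: Iterable[str],
                                  max_leaves: int = 8) -> Iterator[RootedTree]:
    """Yield every rooted binary topology on the given leaf labels once.

    Leaf-insertion recursion: each n-leaf topology arises uniquely by
    inserting the largest label above one of the 2n-3 nodes of an
    (n-1)-leaf topology, so the enumeration is duplicate-free and its order
    deterministic.
    """
    labs = sorted(labels)
    if len(set(labs)) != len(labs):
        raise ValueError("duplicate labels")
    if not labs:
        raise ValueError("need at least one label")
    if len(labs) > max_leaves:
        raise ValueError(
            f"{len(labs)} leaves exceeds the enumeration cap of {max_leaves}")

    def gen(sub: list[str]) -> Iterator[Node]:
        if len(sub) == 1:
            yield Node(sub[0])
            return
        last = sub[-1]
        for t in gen(sub[:-1]):
            order = list(t.preorder())
            for i in range(len(order)):
                t2 = t.copy()
                target = list(t2.preorder())[i]
                w = Node(None)
                p = target.parent
                if p is None:
                    root = w
                else:
                    p.children[p.children.index(target)] = w
                    w.parent = p
                    root = t2
                target.parent = None
                w.add_child(Node(last))
                w.add_child(target)
                yield root if p is None else t2

    for root in gen(labs):
        yield canonicalize(RootedTree(root, validate=False))


def satisfies_pairs(T: RootedTree, S: SpeciesTree, gmap: Mapping[str, str],
                    P: Iterable) -> bool:
    """True iff every pair of P has a speciation lca in T after reconciliation."""
    R = reconcile(T, S, gmap)
    return all(R.are_orthologs(*sorted(tuple(p))) for p in P)


def satisfies_clades(T: RootedTree, S: SpeciesTree, gmap: Mapping[str, str],
                     C: Iterable[frozenset[str]]) -> bool:
    """True iff every leaf-set of C is a clade of T rooted by a speciation.

    Satisfaction requires c to remain a *clade* of the candidate tree: with
    the weaker reading (speciation lca only) a tree could satisfy two nested
    same-species constraints through one merged lca, contradicting the
    feasibility characterization.
    """
    R = reconcile(T, S, gmap)
    by_clade = {cl: nd for nd, cl in clade_map(T).items()}
    for c in C:
        node = by_clade.get(frozenset(c))
        if node is None or R.event[node] != SPECIATION:
            return False
    return True


def brute_force_goc(R: ReconciledGeneTree, P: Iterable,
                    max_leaves: int = 8) -> tuple[int, set[str]]:
    """Exact minimum RF over all P-satisfying topologies, with the full
    argmin set as canonical Newick strings."""
    best: int | None = None
    argmin: set[str] = set()
    for T in enumerate_rooted_binary_trees(R.tree.leaf_labels, max_leaves):
        if not satisfies_pairs(T, R.species, R.gene_species, P):
            continue
        d = rf_distance(R.tree, T)
        if best is None or d < best:
            best, argmin = d, {T.newick()}
        elif d == best:
            argmin.add(T.newick())
    assert best is not None, "a pair-satisfying tree always exists"
    return best, argmin


def brute_force_coc(R: ReconciledGeneTree, C: Iterable[frozenset[str]],
                    max_leaves: int = 8) -> tuple[int | None, set[str], set[str]]:
    """Exact minimum RF over all C-satisfying topologies.

    Returns ``(min_rf, argmin, triplet_max)`` where ``triplet_max`` is the
    subset of the argmin trees attaining the maximum shared-triplet count
    with the input.  An empty argmin set (min_rf None) certifies
    infeasibility.
    """
    C = [frozenset(c) for c in C]
    best: int | None = None
    argmin: set[str] = set()
    for T in enumerate_rooted_binary_trees(R.tree.leaf_labels, max_leaves):
        if not satisfies_clades(T, R.species, R.gene_species, C):
            continue
        d = rf_distance(R.tree, T)
        if best is None or d < best:
            best, argmin = d, {T.newick()}
        elif d == best:
            argmin.add(T.newick())
    if best is None:
        return None, set(), set()
    scored = {nwk: shared_triplet_count(R.tree, RootedTree.from_newick(nwk))
              for nwk in argmin}
    top = max(scored.values())
    return best, argmin, {nwk for nwk, v in scored.items() if v == top}
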