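"""Seeded instance generators: species trees, duplication-loss gene trees
with known true histories, and constraint sets for both correction problems.

The gene-tree simulator is a discrete duplication-loss process along the
species tree: every lineage entering a species-tree branch is lost with
probability ``loss_prob`` and duplicates (splits into two lineages on the
same branch, each of which may duplicate again) with probability
``dup_prob``.  Surviving leaves are named with the lowercased species label
plus an index.  All generators are pure functions of their parameters and
seed.
"""

from __future__ import annotations

import random
import string
from collections.abc import Iterable

from .reconcile import (DUPLICATION, GeneSpeciesMap, ReconciledGeneTree,
                        SpeciesTree, reconcile)
from .tree import Node, RootedTree, canonicalize

__all__ = [
    "simulate_species_tree",
    "simulate_gene_tree",
    "make_goc_instance",
    "make_coc_instance",
]


def simulate_species_tree(n_species: int, seed: int) -> SpeciesTree:
    """Uniform random rooted binary species tree on species A, B, C, ...

    Sequential random attachment: leaf i is inserted above a uniformly
    chosen node of the (i-1)-leaf tree, which samples topologies uniformly
    from the (2n-3)!! possibilities.
    """
    if not 2 <= n_species <= 26:
        raise ValueError("n_species must be between 2 and 26")
    rng = random.Random(seed)
    labels = string.ascii_uppercase[:n_species]
    root = Node(labels[0])
    for lab in labels[1:]:
        nodes = list(root.preorder())
        target = rng.choice(nodes)
        w = Node(None)
        p = target.parent
        if p is None:
            root = w
        else:
            p.children[p.children.index(target)] = w
            w.parent = p
        target.parent = None
        w.add_child(target)
        w.add_child(Node(lab))
    return SpeciesTree(canonicalize(RootedTree(root)))


def simulate_gene_tree(S: SpeciesTree, dup_prob: float = 0.2,
                       loss_prob: float = 0.1, seed: int = 0,
                       max_retries: int = 100,
                       ) -> tuple[ReconciledGeneTree, set[frozenset[str]]]:
    """Simulate a gene family along S; returns the reconciled tree and the
    clades of the *true* duplication nodes (those the simulation created and
    that survived with both copies).

    With losses, LCA reconciliation may label additional nodes as
    duplications, so the reconciled duplication set is a superset of the
    true one only in the loss-free case; the true set is returned for
    exactly that kind of comparison.  Re-draws (up to ``max_retries``) when
    fewer than two genes survive.
    """
    if not (0 <= dup_prob < 1 and 0 <= loss_prob < 1):
        raise ValueError("probabilities must be in [0, 1)")

    for attempt in range(max_retries):
        # string seeds hash via sha512, stable across processes
        rng = random.Random(f"gene:{seed}:{attempt}")
        counter: dict[str, int] = {}
        true_dups: list[Node] = []

        def on_branch(sp: Node) -> Node | None:
            if rng.random() < dup_prob:
                left = on_branch(sp)
                right = on_branch(sp)
                if left is not None and right is not None:
                    node = Node(None, [left, right])
                    true_dups.append(node)
                    return node
                return left if left is not None else right
            if sp.is_leaf:
                counter[sp.label] = counter.get(sp.label, 0) + 1
                return Node(f"{sp.label.lower()}{counter[sp.label]}")
            alive = []
            for child in sp.children:
                if rng.random() < loss_prob:
                    continue
                sub = on_branch(child)
                if sub is not None:
                    alive.append(sub)
            if not alive:
                return None
            if len(alive) == 1:
                return alive[0]
            return Node(None, alive)

        root = on_branch(S.tree.root)
        if root is None or root.is_leaf:
            continue
        tree = canonicalize(RootedTree(root))
        gmap = GeneSpeciesMap({n.label: n.label[0].upper() for n in tree.leaves()})
        R = reconcile(tree, S, gmap)
        # a recorded dup node may have been bypassed if one side died later;
        # keep only those still present in the final tree
        present = {id(n) for n in tree.nodes()}
        true_clades = {d.leaf_labels() for d in true_dups if id(d) in present}
        return R, true_clades
    raise RuntimeError(f"gene family went extinct in {max_retries} attempts")


def make_goc_instance(R: ReconciledGeneTree, k_pairs: int, seed: int):
    """Sample k cross-species leaf pairs, biased toward duplication-lca
    pairs so the instance has false paralogs whenever possible."""
    from .goc import OrthologyConstraints

    rng = random.Random(f"goc:{seed}")
    leaves = sorted(R.tree.leaf_labels)
    dup_pairs, spec_pairs = [], []
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            if R.gene_species[a] == R.gene_species[b]:
                continue
            (dup_pairs if R.lca_event(a, b) == DUPLICATION else spec_pairs).append((a, b))
    if k_pairs > len(dup_pairs) + len(spec_pairs):
        raise ValueError(
            f"k_pairs={k_pairs} exceeds the {len(dup_pairs) + len(spec_pairs)} "
            "cross-species pairs available")
    rng.shuffle(dup_pairs)
    rng.shuffle(spec_pairs)
    chosen = (dup_pairs + spec_pairs)[:k_pairs]
    return R, OrthologyConstraints(chosen)


def make_coc_instance(R: ReconciledGeneTree, k_clades: int, seed: int,
                      ensure_feasible: bool = True, max_tries: int = 500):
    """Sample k duplication-node clades as a constraint set.

    With ``ensure_feasible`` the sample is rejected until it passes the
    pairwise feasibility conditions (internal species; disjoint or
    different-species); raises if no such set is found.  Without it,
    arbitrary duplication clades are drawn, so the instance may be
    infeasible — useful for exercising the feasibility test.
    """
    from .coc import CladeConstraints, coc_feasible

    rng = random.Random(f"coc:{seed}")
    candidates = [n for n in R.tree.nodes() if R.event[n] == DUPLICATION]
    if ensure_feasible:
        candidates = [n for n in candidates if not R.s[n].is_leaf]
    if k_clades > len(candidates):
        raise ValueError(
            f"k_clades={k_clades} exceeds the {len(candidates)} candidate nodes")
    for _ in range(max_tries):
        picked = rng.sample(candidates, k_clades)
        C = CladeConstraints([n.leaf_labels() for n in picked])
        if len(C) < k_clades:
            continue
        if not ensure_feasible or coc_feasible(R, C)[0]:
            return R, C
    raise ValueError("no feasible clade set found by rejection sampling")


def write_instance(out_dir, S: SpeciesTree, R: ReconciledGeneTree,
                   P=None, C=None) -> None:
    """Write an instance as the file formats the CLI consumes."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "species.nwk").write_text(S.tree.newick() + "\n")
    (out / "gene.nwk").write_text(R.tree.newick() + "\n")
    with open(out / "map.tsv", "w") as fh:
        for g in sorted(R.tree.leaf_labels):
            fh.write(f"{g}\t{R.gene_species[g]}\n")
    if P is not None:
        P.to_tsv(out / "pairs.tsv")
    if C is not None:
        with open(out / "clades.txt", "w") as fh:
            for c in C:
                fh.write(",".join(sorted(c)) + "\n")


def iter_sized_instances(seeds: Iterable[int], n_species: int,
                         min_leaves: int, max_leaves: int,
                         dup_prob: float = 0.2, loss_prob: float = 0.1):
    """Yield (seed, reconciled tree, true duplication clades) for simulated
    families whose leaf count falls in the requested range."""
    for seed in seeds:
        S = simulate_species_tree(n_species, seed)
        try:
            R, true_dups = simulate_gene_tree(S, dup_prob, loss_prob, seed)
        except RuntimeError:
            continue
        if min_leaves <= R.tree.n_leaves <= max_leaves:
            yield seed, R, true_dups
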