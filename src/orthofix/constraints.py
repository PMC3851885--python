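"""Building orthology constraints from external evidence.

Two sources are supported:

* non-apparent duplications (NADs): duplication nodes not witnessed by any
  extant same-species gene pair across their children — the "dubious"
  duplications of curated databases, natural clade-constraint candidates;
* conserved gene order (synteny): two genes whose 3-gene neighborhoods pair
  up as orthologs are themselves required to be orthologous, the classic
  synteny argument.  Neighborhood genes are "homologous" when they belong to
  the same input gene family and "orthologous" when additionally their lca
  in that family's tree is a speciation.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable
from dataclasses import dataclass, field

from .errors import TreeValidationError
from .goc import OrthologyConstraints
from .reconcile import DUPLICATION, ReconciledGeneTree
from .tree import Node

__all__ = [
    "GeneOrder",
    "flag_non_apparent_duplications",
    "syntenic_regions",
    "synteny_status",
    "infer_orthology_constraints",
]

log = logging.getLogger(__name__)

SYNTENIC = "syntenic"
NOT_SYNTENIC = "not_syntenic"
UNDEFINED = "undefined"


@dataclass
class GeneOrder:
    """Ordered gene lists per genome (one linear order per scaffold)."""

    orders: dict[str, list[list[str]]] = field(default_factory=dict)
    _index: dict[str, tuple[str, int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for genome, scaffolds in self.orders.items():
            for si, genes in enumerate(scaffolds):
                for pos, g in enumerate(genes):
                    if g in self._index:
                        raise TreeValidationError(
                            f"gene {g!r} appears twice in the gene orders")
                    self._index[g] = (genome, si, pos)

    @classmethod
    def from_tsv(cls, path) -> "GeneOrder":
        """BED-like TSV: genome<TAB>seq<TAB>position<TAB>gene_label."""
        rows: list[tuple[str, str, float, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise TreeValidationError(
                        f"{path}:{lineno}: expected 4 tab-separated columns")
                rows.append((parts[0], parts[1], float(parts[2]), parts[3]))
        orders: dict[str, dict[str, list[tuple[float, str]]]] = {}
        for genome, seq, pos, gene in rows:
            orders.setdefault(genome, {}).setdefault(seq, []).append((pos, gene))
        built = {
            genome: [[g for _, g in sorted(scaf)] for _, scaf in sorted(seqs.items())]
            for genome, seqs in orders.items()
        }
        return cls(built)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def genome_of(self, gene: str) -> str:
        return self._index[gene][0]

    def neighbors(self, gene: str) -> tuple[str | None, str | None]:
        """Left and right adjacency of a gene; None at a scaffold end."""
        genome, si, pos = self._index[gene]
        scaffold = self.orders[genome][si]
        left = scaffold[pos - 1] if pos > 0 else None
        right = scaffold[pos + 1] if pos + 1 < len(scaffold) else None
        return left, right


def flag_non_apparent_duplications(R: ReconciledGeneTree) -> set[Node]:
    """Duplication nodes with no extant same-species pair across children."""
    out: set[Node] = set()
    for node in R.tree.nodes():
        if R.event[node] != DUPLICATION:
            continue
        species_sets = [
            {R.gene_species[leaf.label] for leaf in child.leaves()}
            for child in node.children
        ]
        witnessed = any(
            species_sets[i] & species_sets[j]
            for i in range(len(species_sets))
            for j in range(i + 1, len(species_sets))
        )
        if not witnessed:
            out.add(node)
    return out


def synteny_status(orders: GeneOrder, g1: str, g2: str,
                   homology: Callable[[str, str], bool],
                   allow_reversed: bool = True) -> str:
    """Compare the 3-gene windows centered on g1 and g2.

    ``syntenic`` when the windows pair up position-by-position under the
    homology relation (reversed orientation accepted unless disabled, since
    inversions conserve synteny); ``undefined`` when either gene sits at a
    scaffold end, so a full window does not exist.
    """
    if g1 not in orders or g2 not in orders:
        return UNDEFINED
    if orders.genome_of(g1) == orders.genome_of(g2):
        raise TreeValidationError(
            f"{g1!r} and {g2!r} are in the same genome; synteny comparison "
            "requires different genomes")
    l1, r1 = orders.neighbors(g1)
    l2, r2 = orders.neighbors(g2)
    if None in (l1, r1, l2, r2):
        return UNDEFINED
    if homology(l1, l2) and homology(r1, r2):
        return SYNTENIC
    if allow_reversed and homology(l1, r2) and homology(r1, l2):
        return SYNTENIC
    return NOT_SYNTENIC


def syntenic_regions(orders: GeneOrder, g1: str, g2: str,
                     homology: Callable[[str, str], bool],
                     allow_reversed: bool = True) -> bool:
    """Boolean form of :func:`synteny_status` (undefined counts as False)."""
    return synteny_status(orders, g1, g2, homology, allow_reversed) == SYNTENIC


def infer_orthology_constraints(orders: GeneOrder,
                                trees: Iterable[ReconciledGeneTree],
                                target: ReconciledGeneTree,
                                allow_reversed: bool = True,
                                only_false_paralogies: bool = False,
                                ) -> OrthologyConstraints:
    """Emit pairs of target-tree genes whose neighborhoods certify orthology.

    A cross-genome pair (g1, g2) of target leaves is emitted when both
    flanking pairs of their 3-gene windows are orthologous in their own
    family trees (same companion family *and* speciation lca there).  With
    ``only_false_paralogies`` pairs already orthologous in the target tree
    are dropped, leaving exactly the pairs that contradict it.
    """
    family_of: dict[str, ReconciledGeneTree] = {}
    for T in trees:
        for g in T.tree.leaf_labels:
            family_of[g] = T

    def flank_orthologous(x: str, y: str) -> bool:
        fam = family_of.get(x)
        if fam is None or family_of.get(y) is not fam:
            return False
        return fam.are_orthologs(x, y)

    leaves = sorted(target.tree.leaf_labels)
    for g in leaves:
        if g not in orders:
            log.warning("target gene %r absent from the gene orders; skipped", g)

    pairs = []
    for i, g1 in enumerate(leaves):
        for g2 in leaves[i + 1:]:
            if g1 not in orders or g2 not in orders:
                continue
            if orders.genome_of(g1) == orders.genome_of(g2):
                continue
            if not syntenic_regions(orders, g1, g2, flank_orthologous,
                                    allow_reversed):
                continue
            if only_false_paralogies and target.are_orthologs(g1, g2):
                continue
            pairs.append((g1, g2))
    return OrthologyConstraints(pairs)
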