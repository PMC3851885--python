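"""Packaged walkthrough instances for the two correction problems.

Each bundle carries a species tree, a reconciled gene tree, a constraint
set, and the facts its walkthrough establishes (movable apexes, the
forbidden set, the corrected topology), which the test suite replays.
The bundles double as regression anchors: every quantity stored here is
recomputed by the algorithms in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reconcile import GeneSpeciesMap, ReconciledGeneTree, SpeciesTree, reconcile
from .tree import RootedTree, parse_newick

__all__ = ["FixtureBundle", "load_fixture", "FIXTURE_NAMES"]


@dataclass
class FixtureBundle:
    name: str
    species_newick: str
    gene_newick: str
    gene_species: dict[str, str]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    clade_sets: list[frozenset[str]] = field(default_factory=list)
    expected_goc_newick: str | None = None
    expected_coc_newick: str | None = None
    expected_forbidden_labels: frozenset[str] | None = None
    expected_apexes: dict[tuple[str, str], str] = field(default_factory=dict)
    expected_nad_clades: list[frozenset[str]] = field(default_factory=list)
    # max-orthology sub-instance: (subtree newick, species label) pairs + result
    ortho_subtrees: list[tuple[str, str]] = field(default_factory=list)
    ortho_expected_newick: str | None = None

    def species_tree(self) -> SpeciesTree:
        return SpeciesTree.from_newick(self.species_newick)

    def gene_tree(self) -> RootedTree:
        return parse_newick(self.gene_newick)

    def reconciled(self) -> ReconciledGeneTree:
        return reconcile(self.gene_tree(), self.species_tree(),
                         GeneSpeciesMap(self.gene_species))


_FIXTURES: dict[str, FixtureBundle] = {}


def _register(bundle: FixtureBundle) -> None:
    _FIXTURES[bundle.name] = bundle


# Three species A, B, C (ancestors D = lca(A,B), E = root).  The initial tree
# has lca(a1, b1) = the duplication d with clade {b1, b2, a1, a2}, while a2
# and b2 are orthologous.  The pair-constraint optimum moves a1 only (RF 2);
# the clade-constraint optimum regroups both species' copies (RF 4).
_register(FixtureBundle(
    name="fig1",
    species_newick="((A,B)D,C)E;",
    gene_newick="(c,(b1,((b2,a2),a1)));",
    gene_species={"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c": "C"},
    pairs=[("b1", "a1")],
    clade_sets=[frozenset({"b1", "b2", "a1", "a2"})],
    expected_goc_newick="(((a1,b1),(a2,b2)),c);",
    expected_coc_newick="(((a1,a2),(b1,b2)),c);",
))

# The pair-constraint walkthrough: internal gene nodes are labeled by their
# species letter.  P = {(a1,b2), (a1,c1), (a1,c2)}; the printed facts are
# r_{a1,c2} = e3, s_{a1,c2} = E, h_{a1,c2} = d2, h_{c2,a1} = c2,
# H = {e1, e2, d1}, highest preservable descendants of the root
# {d2, c1, b3, c2}, and a corrected tree preserving every possible clade.
_register(FixtureBundle(
    name="fig2",
    species_newick="((A,B)D,C)E;",
    gene_newick="((((a1,b1)d1,b2)d2,c1)e1,(b3,c2)e2)e3;",
    gene_species={"a1": "A", "b1": "B", "b2": "B", "c1": "C",
                  "b3": "B", "c2": "C"},
    pairs=[("a1", "b2"), ("a1", "c1"), ("a1", "c2")],
    expected_goc_newick="(((a1,(b1,b2)),b3),(c1,c2));",
    expected_forbidden_labels=frozenset({"e1", "e2", "d1"}),
    expected_apexes={("a1", "c2"): "d2", ("c2", "a1"): "c2",
                     ("a1", "b2"): "a1", ("b2", "a1"): "b2"},
))

# The max-orthology sub-instance of fig2: X = the subtrees hanging from the
# highest preservable descendants of the root, joined on the species-tree
# skeleton.  Grafted subtrees appear unchanged in the result.
_register(FixtureBundle(
    name="fig3_X",
    species_newick="((A,B)D,C)E;",
    gene_newick="((((a1,b1)d1,b2)d2,c1)e1,(b3,c2)e2)e3;",
    gene_species={"a1": "A", "b1": "B", "b2": "B", "c1": "C",
                  "b3": "B", "c2": "C"},
    ortho_subtrees=[("((a1,b1),b2);", "D"), ("c1;", "C"),
                    ("b3;", "B"), ("c2;", "C")],
    ortho_expected_newick="((((a1,b1),b2),b3),(c1,c2));",
))

# The clade-push walkthrough: the duplication x roots {a1, a2, b1, b2}; the
# A-side copy drops b1, b2 and the B-side copy drops a1, a2; the two sides
# rejoin under a speciation.  x is also a non-apparent duplication (no
# species occurs on both of its sides).
_register(FixtureBundle(
    name="fig4",
    species_newick="((A,B)D,C)E;",
    gene_newick="(((a1,b1),(a2,b2))x,c);",
    gene_species={"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c": "C"},
    clade_sets=[frozenset({"a1", "a2", "b1", "b2"})],
    expected_coc_newick="(((a1,a2),(b1,b2)),c);",
    expected_nad_clades=[frozenset({"a1", "a2", "b1", "b2"})],
))

# The fish gene family example: Zebrafish (genes d*), Stickleback (s*),
# Medaka (m*), Tetraodon (t*).  Synteny requires P = {(m1,s1), (t1,d2)};
# the non-apparent duplication sits at the root of the (m1,t1,s1) subtree
# and is eliminated by the correction, which has one duplication fewer
# (3 -> 2).
_register(FixtureBundle(
    name="fig5",
    species_newick="(Z,(S,(M,T)MT)SMT)R;",
    gene_newick="(((d1,(m1,(t1,s1))x1),(s2,(m2,t2))),d2);",
    gene_species={"d1": "Z", "d2": "Z", "s1": "S", "s2": "S",
                  "m1": "M", "m2": "M", "t1": "T", "t2": "T"},
    pairs=[("m1", "s1"), ("t1", "d2")],
    expected_goc_newick="((d1,d2),(((m1,t1),s1),((m2,t2),s2)));",
    expected_nad_clades=[frozenset({"m1", "t1", "s1"})],
))

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def load_fixture(name: str) -> FixtureBundle:
    """Return the packaged instance bundle for fig1/fig2/fig3_X/fig4/fig5."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
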