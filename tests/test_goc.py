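"""Pair-constraint correction: forbidden set, max-orthology assembly,
optimality."""

import pytest

from orthofix.errors import ConstraintError
from orthofix.goc import (OrthologyConstraints, analyze_goc, correct_goc,
                          false_paralogs, forbidden_nodes,
                          highest_preservable_descendants, max_orthology_tree,
                          movable_apex)
from orthofix.reconcile import SPECIATION, reconcile
from orthofix.tree import clade_map, clades, parse_newick, rf_distance

from conftest import goc_instances


class TestFalseParalogs:
    def test_fig1_pair_is_false_paralog(self, fig1):
        R = fig1.reconciled()
        assert ("b1", "a1") in false_paralogs(R, fig1.pairs)

    def test_fig2_duplication_lca_pairs(self, fig2):
        R = fig2.reconciled()
        pf = false_paralogs(R, fig2.pairs)
        assert ("a1", "b2") in pf and ("a1", "c2") in pf
        # lca(a1, c1) = e1 joins species D and C under E: a speciation,
        # so that pair is already orthologous
        assert ("a1", "c1") not in pf

    def test_already_orthologous_pairs_yield_empty_set(self, fig1):
        R = fig1.reconciled()
        assert len(false_paralogs(R, [("a2", "b2")])) == 0

    def test_same_species_pair_rejected(self, fig1):
        with pytest.raises(ConstraintError, match="single species"):
            false_paralogs(fig1.reconciled(), [("a1", "a2")])

    def test_unknown_gene_rejected(self, fig1):
        with pytest.raises(ConstraintError, match="not a leaf"):
            false_paralogs(fig1.reconciled(), [("a1", "nope")])


class TestMovableApex:
    def test_fig2_printed_apexes(self, fig2):
        R = fig2.reconciled()
        for (a, b), label in fig2.expected_apexes.items():
            assert movable_apex(R, a, b).label == label

    def test_apex_is_leaf_when_parent_is_pair_lca(self, fig1):
        R = fig1.reconciled()
        assert movable_apex(R, "b1", "a1").label == "b1"

    @pytest.mark.parametrize("seed,R,P", goc_instances(30, 5, 4, 15),
                             ids=lambda v: str(v) if isinstance(v, int) else "")
    def test_apex_matches_linear_scan_oracle(self, seed, R, P):
        """Independent check: walk up from a, stop before the first node
        whose species is not strictly below s_{a,b}."""
        from orthofix.goc import _gene_lca, _leaf_node

        for a, b in P.ordered():
            na, nb = _leaf_node(R, a), _leaf_node(R, b)
            r = _gene_lca(R, na, nb)
            s_ab = R.species.lca(R.s[na], R.s[nb])
            node = na
            while (node.parent is not r
                   and R.species.is_descendant(R.s[node.parent], s_ab, strict=True)):
                node = node.parent
            assert movable_apex(R, a, b) is node


class TestForbiddenNodes:
    def test_fig2_forbidden_set(self, fig2):
        R = fig2.reconciled()
        pf = false_paralogs(R, fig2.pairs)
        H = forbidden_nodes(R, pf)
        assert {n.label for n in H} == fig2.expected_forbidden_labels

    def test_empty_constraints_forbid_nothing(self, fig2):
        R = fig2.reconciled()
        assert forbidden_nodes(R, OrthologyConstraints([])) == set()

    def test_root_and_leaves_always_preservable(self, fig2):
        R = fig2.reconciled()
        H = forbidden_nodes(R, false_paralogs(R, fig2.pairs))
        assert R.root not in H
        assert all(leaf not in H for leaf in R.tree.leaves())


class TestHighestPreservableDescendants:
    def test_fig2_root_partition(self, fig2):
        R = fig2.reconciled()
        H = forbidden_nodes(R, false_paralogs(R, fig2.pairs))
        got = highest_preservable_descendants(R, H, R.root)
        assert {n.label for n in got} == {"d2", "c1", "b3", "c2"}
        # their clades partition the root's leaves
        union = frozenset().union(*(n.leaf_labels() for n in got))
        assert union == R.tree.leaf_labels
        assert sum(len(n.leaf_labels()) for n in got) == len(union)

    def test_both_children_preservable(self, fig1):
        R = fig1.reconciled()
        got = highest_preservable_descendants(R, set(), R.root)
        assert got == list(R.root.children)


class TestMaxOrthologyTree:
    def test_single_subtree_unchanged(self, fig2):
        S = fig2.species_tree()
        sub = parse_newick("((a1,b1),b2);")
        F = max_orthology_tree(S, [(sub, S.tree.find("D"))])
        assert F == sub

    def test_fig3_instance(self):
        from orthofix.fixtures import load_fixture

        fx = load_fixture("fig3_X")
        S = fx.species_tree()
        X = [(parse_newick(nwk), S.tree.find(sp)) for nwk, sp in fx.ortho_subtrees]
        F = max_orthology_tree(S, X)
        assert F.newick() == fx.ortho_expected_newick
        # grafted subtrees appear unchanged
        for sub, _ in X:
            assert sub.root.leaf_labels() in clades(F)

    @pytest.mark.parametrize("seed", range(20))
    def test_unrelated_species_pairs_become_orthologs(self, seed):
        """Any two subtrees whose species are unrelated in S must join
        under a speciation, checked by reconciling the assembled tree."""
        import itertools
        import random

        from orthofix.simgen import simulate_species_tree

        S = simulate_species_tree(5, seed)
        rng = random.Random(seed)
        species = sorted(S.leaf_labels)
        X, gmap = [], {}
        for i, sp in enumerate(rng.sample(species, rng.randint(2, 5))):
            g = f"{sp.lower()}{i}"
            X.append((parse_newick(f"{g};"), S.leaf(sp)))
            gmap[g] = sp
        F = max_orthology_tree(S, X)
        R = reconcile(F, S, gmap)
        for (ga, sa), (gb, sb) in itertools.combinations(
                [(x.root.label, sp) for x, sp in X], 2):
            unrelated = not (S.is_descendant(sa, sb) or S.is_descendant(sb, sa))
            if unrelated:
                assert R.are_orthologs(ga, gb)


class TestCorrectGoc:
    def test_empty_constraints_identity(self, fig2):
        R = fig2.reconciled()
        res = correct_goc(R, [])
        assert res.rf_to_input == 0
        # topology identical; internal node names are not carried through
        # the rebuild (corrections invalidate them)
        assert res.corrected.tree == R.tree

    def test_fig2_corrected_topology(self, fig2):
        res = correct_goc(fig2.reconciled(), fig2.pairs)
        assert res.newick() == fig2.expected_goc_newick
        assert res.rf_to_input == 6 == 2 * res.forbidden_count
        assert res.all_satisfied

    def test_fig1_corrected_topology(self, fig1):
        res = correct_goc(fig1.reconciled(), fig1.pairs)
        assert res.newick() == fig1.expected_goc_newick
        assert res.rf_to_input == 2

    def test_fig5_correction_removes_the_dubious_duplication(self, fig5):
        res = correct_goc(fig5.reconciled(), fig5.pairs)
        assert res.newick() == fig5.expected_goc_newick
        assert res.all_satisfied
        assert res.output_duplications == res.input_duplications - 1

    @pytest.mark.parametrize("seed,R,P", goc_instances(40, 6, 5, 20, k_pairs=3),
                             ids=lambda v: str(v) if isinstance(v, int) else "")
    def test_rf_identity_satisfaction_and_preservation(self, seed, R, P):
        """RF(G, G_P) = 2|H|; all pairs orthologous; preservable clades kept;
        output binary on the same leaves; determinism."""
        res = correct_goc(R, P)
        assert res.rf_to_input == 2 * res.forbidden_count
        assert res.all_satisfied
        out = res.corrected.tree
        assert out.is_binary and out.leaf_labels == R.tree.leaf_labels
        ana = analyze_goc(R, P)
        preservable = {cl for nd, cl in clade_map(R.tree).items()
                       if nd not in ana.forbidden}
        assert preservable <= clades(out)
        assert rf_distance(R.tree, out) == 2 * len(
            clades(R.tree) - clades(out))
        assert correct_goc(R, P).newick() == res.newick()

    def test_recursion_soundness_on_preservable_subtree(self, fig2):
        """Correcting the subtree hanging from a preservable node gives the
        corresponding subtree of the full output."""
        R = fig2.reconciled()
        res = correct_goc(R, fig2.pairs)
        d2 = R.tree.find("d2")
        sub = reconcile(parse_newick("((a1,b1),b2);"), R.species,
                        {g: R.gene_species[g] for g in ("a1", "b1", "b2")})
        sub_res = correct_goc(sub, [("a1", "b2")])
        out_cm = {cl: nd for nd, cl in clade_map(res.corrected.tree).items()}
        node = out_cm[d2.leaf_labels()]
        from orthofix.tree import RootedTree, canonicalize

        sub_out = canonicalize(RootedTree(node.copy(), validate=False))
        assert sub_out.newick() == sub_res.newick()
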