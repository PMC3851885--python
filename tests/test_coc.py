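"""Clade-constraint correction: feasibility, pushes, resolutions,
order independence."""

import random

import pytest

from orthofix.coc import (CladeConstraints, binary_resolutions, coc_feasible,
                          correct_coc, push_multifurcation,
                          push_tree_duplication)
from orthofix.errors import (ConstraintError, InfeasibleError,
                             ResolutionLimitError)
from orthofix.reconcile import SPECIATION, SpeciesTree, reconcile
from orthofix.tree import clades, lca, parse_newick

from conftest import sized_instances


def _coc_instances(count, k_clades, ensure_feasible=True, **kw):
    from orthofix.simgen import make_coc_instance

    out = []
    for seed, R, _ in sized_instances(400, kw.pop("n_species", 6),
                                      kw.pop("min_leaves", 6),
                                      kw.pop("max_leaves", 25), **kw):
        try:
            _, C = make_coc_instance(R, k_clades, seed,
                                     ensure_feasible=ensure_feasible)
        except ValueError:
            continue
        out.append((seed, R, C))
        if len(out) >= count:
            break
    assert len(out) == count
    return out


class TestFeasibility:
    def test_leaf_species_clade_infeasible(self):
        S = SpeciesTree.from_newick("(A,B);")
        R = reconcile(parse_newick("((a1,a2),b1);"), S,
                      {"a1": "A", "a2": "A", "b1": "B"})
        ok, violations = coc_feasible(R, [{"a1", "a2"}])
        assert not ok and "leaf species" in violations[0]

    def test_nested_same_species_clades_infeasible(self, fig2):
        R = fig2.reconciled()
        # d1 = {a1,b1} and d2 = {a1,b1,b2} both map to species D
        ok, violations = coc_feasible(R, [{"a1", "b1"}, {"a1", "b1", "b2"}])
        assert not ok and "overlap" in violations[0]

    def test_empty_set_feasible(self, fig1):
        assert coc_feasible(fig1.reconciled(), []) == (True, [])

    def test_non_clade_leaf_set_rejected(self, fig1):
        with pytest.raises(ConstraintError, match="not a clade"):
            coc_feasible(fig1.reconciled(), [{"a1", "b2"}])


class TestPushMultifurcation:
    def test_pure_sided_children_imply_speciation_hence_noop(self, fig1):
        """A node whose children are pure A-side / pure B-side reconciles as
        a speciation: the push refuses it and the driver treats the
        constraint as already satisfied."""
        S = fig1.species_tree()
        R = reconcile(parse_newick("(((a1,a2),(b1,b2)),c);"), S,
                      fig1.gene_species)
        x = lca(R.tree, {"a1", "a2", "b1", "b2"})
        assert R.event[x] == SPECIATION
        with pytest.raises(ConstraintError, match="duplication"):
            push_multifurcation(R, x)
        res = correct_coc(R, [{"a1", "a2", "b1", "b2"}])
        assert res.rf_to_input == 0 and res.all_satisfied

    def test_fig1_clade_partitions_into_species_groups(self, fig1):
        R = fig1.reconciled()
        x = lca(R.tree, fig1.clade_sets[0])
        pushed = push_multifurcation(R, x)
        assert {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})} <= clades(pushed)

    def test_pushing_disjoint_clades_commutes(self):
        for seed, R, C in _coc_instances(10, 2):
            orders = [list(C), list(reversed(list(C)))]
            outs = set()
            for order in orders:
                cur = R
                for c in order:
                    node = lca(cur.tree, set(c))
                    if cur.event[node] != SPECIATION:
                        cur = reconcile(push_multifurcation(cur, node),
                                        R.species, R.gene_species)
                outs.add(cur.tree.newick())
            assert len(outs) == 1

    def test_speciation_node_rejected(self, fig1):
        R = fig1.reconciled()
        with pytest.raises(ConstraintError, match="duplication"):
            push_multifurcation(R, R.root)


class TestBinaryResolutions:
    def test_binary_input_yields_itself(self, fig1):
        t = fig1.gene_tree()
        assert [r.newick() for r in binary_resolutions(t)] == [t.newick()]

    def test_trifurcation_yields_three(self):
        got = {t.newick() for t in binary_resolutions(parse_newick("(a,b,c);"))}
        assert got == {"((a,b),c);", "((a,c),b);", "(a,(b,c));"}

    def test_all_resolutions_contain_all_input_clades(self):
        t = parse_newick("((a,b,c),(d,e,f));")
        rs = list(binary_resolutions(t))
        assert len(rs) == 9
        for r in rs:
            assert clades(t) <= clades(r)
            assert r.is_binary

    def test_limit_raises_instead_of_truncating(self):
        labs = ",".join(f"l{i}" for i in range(10))
        with pytest.raises(ResolutionLimitError):
            next(binary_resolutions(parse_newick(f"({labs});"), limit=100))


class TestPushTreeDuplication:
    def test_fig4_sides(self, fig4):
        R = fig4.reconciled()
        x = lca(R.tree, fig4.clade_sets[0])
        out = push_tree_duplication(R, x)
        assert out.tree.newick() == fig4.expected_coc_newick
        assert out.event[lca(out.tree, fig4.clade_sets[0])] == SPECIATION

    def test_same_species_cherry_rejected(self):
        S = SpeciesTree.from_newick("(A,B);")
        R = reconcile(parse_newick("((a1,a2),b1);"), S,
                      {"a1": "A", "a2": "A", "b1": "B"})
        with pytest.raises(ConstraintError, match="leaf species"):
            push_tree_duplication(R, lca(R.tree, {"a1", "a2"}))

    def test_output_is_a_binary_resolution_of_the_multifurcation_push(self):
        for seed, R, C in _coc_instances(10, 1, max_leaves=12):
            (c,) = list(C)
            x = lca(R.tree, set(c))
            out = push_tree_duplication(R, x)
            members = {t.newick() for t in binary_resolutions(
                push_multifurcation(R, x))}
            assert out.tree.newick() in members


class TestCorrectCoc:
    def test_empty_constraints_identity(self, fig1):
        res = correct_coc(fig1.reconciled(), [])
        assert res.rf_to_input == 0

    def test_fig1_coc_more_distant_than_goc(self, fig1):
        from orthofix.goc import correct_goc

        R = fig1.reconciled()
        coc_res = correct_coc(R, fig1.clade_sets)
        assert coc_res.newick() == fig1.expected_coc_newick
        assert correct_goc(R, fig1.pairs).rf_to_input < coc_res.rf_to_input

    def test_strict_mode_rejects_infeasible(self, fig2):
        with pytest.raises(InfeasibleError) as err:
            correct_coc(fig2.reconciled(),
                        [{"a1", "b1"}, {"a1", "b1", "b2"}])
        assert err.value.violations

    def test_force_mode_pushes_root_most_first_and_reports(self, fig2):
        R = fig2.reconciled()
        res = correct_coc(R, [{"a1", "b1"}, {"a1", "b1", "b2"}], mode="force")
        by_clade = {tuple(e["clade"]): e for e in res.constraint_report}
        # the root-most clade {a1,b1,b2} was pushed; pushing it destroys the
        # nested same-species clade {a1,b1}, which stays unsatisfied
        assert by_clade[("a1", "b1", "b2")]["satisfied"]
        assert not by_clade[("a1", "b1")]["satisfied"]

    def test_already_speciation_clade_is_a_noop(self, fig1):
        R = fig1.reconciled()
        res = correct_coc(R, [{"a2", "b2"}])
        assert res.rf_to_input == 0 and res.all_satisfied
        assert res.pushed_clades == []

    def test_push_order_does_not_change_output(self):
        rng = random.Random(0)
        for seed, R, C in _coc_instances(12, 2):
            base = list(C)
            outs = set()
            for _ in range(5):
                order = base[:]
                rng.shuffle(order)
                outs.add(correct_coc(R, C, order=order).newick())
            assert len(outs) == 1

    def test_rf_accounting_same_species_descendants(self):
        """rf = 2 x number of clades strictly under pushed nodes mapping to
        the pushed species."""
        for seed, R, C in _coc_instances(10, 1, max_leaves=15):
            res = correct_coc(R, C)
            (c,) = list(C)
            x = lca(R.tree, set(c))
            doomed = [n for n in x.preorder()
                      if n is not x and R.s[n] is R.s[x]]
            assert res.rf_to_input == 2 * len(doomed)
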