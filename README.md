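# orthofix

Minimal Robinson–Foulds correction of reconciled gene trees under external
orthology evidence.

## The problem

A gene tree G, reconciled with a species tree S by LCA mapping, labels every
internal node g with a species s(g) and an event E(g) ∈ {speciation,
duplication}; two genes are *orthologs* when the event at their lca is a
speciation and *paralogs* otherwise. Independent footprints of evolution —
conserved gene order above all — often assert orthologies that the tree
contradicts. `orthofix` repairs the tree instead of discarding the evidence:
it computes a binary tree on the same leaves that satisfies the evidence and
is as close as possible to the input under the (rooted, clade-based)
Robinson–Foulds distance RF(G, G′) = |clades(G) Δ clades(G′)|.

Two constraint languages are supported, and they genuinely differ:

* **Pair constraints** — a set P of gene pairs (g₁, g₂), s(g₁) ≠ s(g₂), that
  must be orthologous. For each ordered pair (a, b) with a duplication lca
  r_{a,b}, the *movable apex* h_{a,b} is the highest node on the path from a
  to r_{a,b} whose species lies strictly below s_{a,b} = lca_S(s(a), s(b)).
  The strict ancestors of h_{a,b} below r_{a,b} form the forbidden set H: no
  satisfying tree can keep their clades, and the correction loses exactly
  those, achieving the provable optimum **RF(G, G_P) = 2·|H|**. The tree is
  rebuilt recursively by grafting the subtrees hanging from the highest
  preservable descendants of each preservable node onto a copy of S (the
  *maximum orthology tree*), so every pair of subtrees with unrelated species
  joins under a speciation. A solution always exists.
* **Clade constraints** — a set C of clades of G whose roots must become
  speciations (typical input: "dubious"/non-apparent duplications). A
  solution exists iff every constrained clade maps to an internal species and
  every two constrained clades are leaf-disjoint or map to different species.
  All RF-optimal solutions are exactly the binary resolutions of the tree
  obtained by *pushing* each constrained duplication *by multifurcation*
  (splitting its subtree into its maximal pure A-side / pure B-side subtrees,
  A and B the children of s(x)); *pushing by tree duplication* (keeping each
  side's internal topology intact) picks the optimum that additionally
  maximizes the number of rooted triplets shared with G. An order-insensitive
  driver applies it to all of C, and a documented heuristic (root-closest
  first) handles infeasible sets on request.

Constraints can be supplied directly or inferred from synteny: two genes
whose 3-gene neighborhoods pair up as orthologs (same companion family,
speciation lca there) are emitted as required orthologs, and non-apparent
duplications are flagged as clade-constraint candidates.

Everything is certified against a brute-force oracle that enumerates all
(2n−3)!! rooted binary topologies on small leaf sets, plus seeded
duplication–loss simulators that generate arbitrary instances.

## Worked example

The six-gene walkthrough family (species tree `((A,B)D,C)E`), with synteny
requiring a1 orthologous to b2, c1 and c2:

```
$ orthofix goc -g gene.nwk -s species.nwk -m map.tsv -p pairs.tsv \
      -o corrected.nwk --report report.json
rf=6 satisfied=True duplications 2->3
forbidden=3
$ cat corrected.nwk
(((a1,(b1,b2)),b3),(c1,c2));
```

`forbidden=3` is |H| = |{e1, e2, d1}|: three clades of the input cannot
survive in any satisfying tree, and `rf=6 = 2·|H|` confirms that exactly
those were sacrificed — every other clade of the input is preserved.
`report.json` lists the per-pair outcome (here: `a1/b2` and `a1/c2` were
false paralogs, `a1/c1` was already orthologous) and the lost clades.
Comparing input and output directly:

```
$ orthofix compare gene.nwk corrected.nwk
rf=6 shared_triplets=9
```

Other subcommands: `orthofix coc` (clade constraints, `--force` for the
infeasible-set heuristic), `orthofix infer-constraints` (pairs from gene
orders), `orthofix simulate` (seeded instances), `orthofix verify` (oracle
certification). The same functionality is available as a library:

```python
from orthofix import load_fixture, correct_goc
fx = load_fixture("fig2")
res = correct_goc(fx.reconciled(), fx.pairs)
res.newick()          # '(((a1,(b1,b2)),b3),(c1,c2));'
res.rf_to_input       # 6
res.forbidden_count   # 3
```

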