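# Methods

## Model and conventions

All trees are rooted; gene and species trees must be binary on input
(multifurcations arise only as intermediates of the clade-constraint
characterization). Reconciliation is plain LCA mapping: s(g) is the LCA in
S of the species of g's extant descendants, and E(g) = speciation iff s(g)
differs from the species of both children. This makes the classic fact
available everywhere: if x is a strict ancestor of y with s(x) = s(y), then
x is a duplication — several correctness arguments and assertions in the
code lean on it.

The distance is the rooted, clade-based Robinson–Foulds distance: the
cardinality of the symmetric difference of the two clade sets (clades taken
per node, singletons and full set included; they cancel between trees on
the same leaves). For binary trees on a shared leaf set this equals
2·c(G,G′), where c counts clades of one tree missing from the other, and
that doubled form is what every interface reports. The CLI help states this
too. Branch lengths are parsed, ignored by all algorithms, and omitted from
outputs: a topology correction invalidates them. Unrooted Newick (spotted
as a trifurcating root) is rejected with an explanatory message; the
single-leaf tree is allowed only as a recursion base, not as tool input.

Determinism is a design requirement, not an accident: children are ordered
lexicographically by smallest descendant leaf label everywhere
(`canonicalize`/`write_newick`), subtrees are grafted in ascending order of
their smallest leaf, and clade constraints are processed in sorted order,
so identical inputs give byte-identical Newick.

## Pair constraints

Validation enforces s(g₁) ≠ s(g₂) and symmetry; pairs already orthologous
are retained (they are checked in the final report) but contribute nothing
to the forbidden set, which is computed from the false-paralog subset only,
over both orientations of each pair.

"s(h_{a,b}) is a descendant of s_{a,b}" is implemented as *strict*
descendant. The non-strict reading gives a different (wrong) apex on the
walkthrough instance, and the possibility proof of joining required
orthologs under a speciation needs the apex's species inside a proper child
subtree of s_{a,b}. Since species assignments ascend along the leaf-to-lca
path, the apex is the top of a contiguous prefix; a leaf always qualifies,
so it exists.

The maximum orthology tree keeps the full species-tree copy as its grafting
skeleton (the construction would also work without it, but the skeleton
makes the speciation guarantees direct) and removes it afterwards via
`standardize` (drop nodes with no extant descendant, contract degree-2
non-root nodes and a degree-1 root). Skeleton leaves are unlabeled in the
copy so the cleanup can never confuse a species name with a gene name.
When several grafts target the same skeleton node they stack into a
caterpillar, each new node immediately above the target and below earlier
grafts; the graft order fixed above makes the choice among RF-equivalent
optima reproducible. Internal node names of the input are not carried into
the corrected tree — the rebuild creates fresh nodes, and a corrected
topology falsifies ancestral-node identities anyway.

## Clade constraints

Satisfaction requires each constrained leaf set to be a *clade* of the
corrected tree rooted by a speciation. The weaker reading — only
E(lca(c)) = speciation — was considered and rejected: under it, two nested
same-species constraints can be "satisfied" by a single merged lca after
pushing the outer one, which would contradict the feasibility
characterization this package implements and tests. The stricter reading
makes feasibility (internal species; pairwise disjoint-or-different
species), the optimal-set characterization and triplet maximality all hold,
and the brute-force oracle confirms them exhaustively on small instances.

Pushing by tree duplication strips the pushed node's name from the two side
copies (both would otherwise inherit it), re-reconciles from scratch after
every push rather than patching s(·)/E(·) incrementally, and tolerates
constraints whose root is already a speciation as warned no-ops. A node
whose two children are already pure-sided reconciles as a speciation and is
therefore never pushable: no duplication is a push fixed point, since its
same-species child clade is always destroyed.

Constraints are supplied as leaf sets rather than node pointers so files
survive re-parsing; resolution is by exact clade match. `binary_resolutions`
is oracle machinery: it refuses (rather than truncates) beyond a
configurable yield limit, default 10⁶. The infeasible-set heuristic pushes
constrained nodes closest to the root first (ties by smallest leaf label),
skipping any that are no longer pushable when reached; it deliberately does
not push unconstrained ancestor duplications that block a constraint, and
its results are labeled heuristic with no optimality claim.

## Synteny-derived constraints

The window is the gene plus its left and right adjacencies (size 3, the
classic region definition; configurable only upward by design). Both flanks
must match; a single matching flank is deliberately not enough — the
alternative is noted but would weaken the evidence. Reversed windows count
as syntenic by default (inversions conserve synteny), with a strict flag
for same-order-only. A gene at a scaffold end has no window: the comparison
reports a distinct "undefined" status rather than plain false. Flank
"homology" is membership in the same companion family; flank "orthology"
additionally requires a speciation lca in that family's tree. Non-apparent
duplications — duplication nodes with no species shared between their
children's leaf sets — are flagged as clade-constraint candidates;
ancestral-synteny-based detection is out of scope.

## Simulators and what they do (not) show

The species-tree generator is sequential random attachment, which is
uniform over the (2n−3)!! rooted binary topologies (spot-checked against
enumeration at n = 4). The gene-tree generator is a discrete duplication–
loss process: per species-tree branch, Bernoulli loss (on entry) and
Bernoulli duplication (possibly repeated on the same branch), defaults
dup = 0.2 and loss = 0.1 — the regime used throughout validation; families
with fewer than two survivors are re-drawn from a derived seed. True
duplication events are recorded so tests can compare them with reconciled
labels: they coincide when loss = 0, and with losses only species-witnessed
true duplications are guaranteed to stay labeled.

This emulates the discrete structures the algorithms consume, not sequence
evolution: there is no rate heterogeneity, no gene conversion, no
incomplete lineage sorting, and gene-order evolution is not simulated at
all (synteny scenarios are constructed directly). Passing tests therefore
certify the combinatorial guarantees — optimality, feasibility,
order-independence — on exactly the class of instances the theory covers;
they say nothing about how often real database trees are wrong, nor about
likelihood-based validation of corrections against alignments, which
requires external data and tools and is out of scope.

Problem sizes follow the certification plan: the RF = 2|H| identity on 200
simulated instances of 5–20 genes; exhaustive cross-checks on 50 pair- and
50 + 30 clade-instances capped at 6 leaves (≤ 945 topologies each), where
the oracle's argmin sets are computed exactly; order independence on 20
two-clade instances × 5 shuffles. The packaged worked examples (fig1–fig5)
were constructed by deriving the topologies consistent with every fact
their walkthroughs establish (apexes, forbidden set, constraint sets, the
non-apparent duplication, the duplication-count drop); where those facts do
not pin the topology down completely, the bundle is the minimal instance
reproducing all of them.

## Known limitations

Only the rooted clade RF distance is optimized; a correction minimal under
RF can be large under NNI-style distances. Paralogy constraints, mixed
constraint types, duplication/loss-minimizing binary resolutions and
non-binary species trees are not supported. The oracle is desk-scale by
construction (default cap 8 leaves) — it certifies the polynomial
algorithms and never replaces them.
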