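# Methods

## Problem and model

A MAF instance is a pair of rooted binary trees T₁, T₂ with a bijection
between their leaves and a common label set 𝓛.  For A ⊆ 𝓛 and tree index
t, V_t[A] is the set of nodes of T_t lying on a path between two leaves of
A; we take the degenerate single-leaf path to be the leaf itself, so
V_t[{x}] = {x} and V_t[∅] = ∅ (this convention is what makes singleton
components occupy exactly their own leaf, matching the LP's leaf
constraints).  A set L is *compatible* when the minimal spanning subtrees
of L in the two trees are isomorphic after suppressing unary nodes;
equivalently, when every rooted triplet of L resolves to the same cherry in
both trees (in binary trees each triplet resolves uniquely, so the
implementation compares cherries, and keeps the all-triples definition as a
test oracle).  A partition 𝒫 of 𝓛 is feasible when every component is
compatible and the spanned node sets of distinct components are disjoint;
its cost is |𝒫| − 1, the number of edges deleted per tree.  With both
trees re-rooted above an extra leaf ρ, the optimum equals the rSPR
distance; `augment_with_rho` performs that augmentation and the CLI applies
it by default.

## The Red-Blue algorithm as implemented

State: a partition 𝒫 (initially {𝓛}) that never overlaps in V₂ — i.e. it
is always the leaf-set family of a forest obtained by deleting edges of T₂.
Each iteration:

1. **Lowest root of infeasibility.**  Scan T₁'s internal nodes in
   postorder and return the first node u for which one of three local
   failures holds: (a) some component's restriction to 𝓛(u) is
   incompatible; (b) two components overlap inside V₁[𝓛(u)]; (c) some
   component A leaves 𝓛(u) but every single outside leaf w makes
   (A ∩ 𝓛(u)) ∪ {w} incompatible.  Postorder guarantees the returned node
   has no qualifying descendant.  When no node qualifies the partition is
   feasible and the loop ends.  Condition (c) deliberately requires *all*
   extensions to fail; demanding only one makes the method too greedy and
   loses the factor 2.
2. **Coloring.**  B and R are the leaves below u's left and right child
   (child order as written in the Newick input), W the rest.
3. **make_rb_compatible.**  While some component A has incompatible
   A ∩ (R∪B): take the lowest T₂ node û whose leaf set meets both colors
   inside A (first qualifying node in T₂ postorder) and replace A by
   A ∩ 𝓛(û) and A ∖ 𝓛(û).
4. **make_splittable.**  While some component's color classes overlap in
   V₂: among the lowest nodes of the pairwise span intersections of the
   color classes, take the first (T₂ postorder) û for which A ∩ 𝓛(û) is
   bicolored and A ∖ 𝓛(û) retains all of A's colors, and cut there.  The
   existence of such a node is a theorem; the implementation raises an
   internal-consistency error instead of proceeding silently if the scan
   ever comes up empty.
5. **split.**  Multicolored components are replaced by their color
   classes, except a tricolored component that still holds a *compatible*
   tricolored triple (necessarily the iteration's top component), which
   undergoes a Special-Split: if every tricolored triple is compatible it
   is cut into A ∩ R and A ∖ R (two-way); otherwise it is cut around
   û₀ = lca₂(A ∩ (R∪B)) into the three color classes below û₀ plus
   A ∖ 𝓛(û₀) (four-way).  Because every red–blue pair of an
   (R∪B)-compatible component meets exactly at û₀, the triple
   {r, b, w} is compatible iff w is not a descendant of û₀; the
   implementation uses this characterization instead of enumerating
   triples.
6. **find_merge_pair.**  At most one pair of red/blue leaves that sat in
   one component at the start of the iteration but in two components now,
   such that merging their components preserves (R∪B)-feasibility.  The
   three sufficient-and-necessary situations are checked in order: (a) a
   bicolored survivor of a two-way Special-Split (merge it back with its
   red sibling); (b) two like-colored components that can *reach* a common
   T₂ node — a component reaches û if û is in its span, or lies above it
   with no covered node strictly between; (c) a red and a blue component
   reaching a common node outside both spans, with no red/blue-covered
   node between that node and lca₂ of the original component.  Merges are
   recorded but applied only after the main loop (union-find coarsening,
   order-independent); deferring them is what lets the dual keep one unit
   of objective for every recorded pair.

Top components are tracked explicitly through stages 3–4 (the remainder
A ∖ 𝓛(û) of a subdivided top component stays top), which lets the
implementation assert rather than assume the structural lemmas: only
multicolored components are subdivided, Make-Splittable preserves the
tricolored count, non-top tricolored components never hold a compatible
tricolored triple, and Special-Split fires only on top components.  All of
these, together with the refined census (one tricolored or at most two
bicolored components at iteration start) and the no-resplit property
across iterations, run as executable checks over exhaustive and random
sweeps in the test suite.

**Tie-breaking.**  Wherever the theory allows any choice, the
implementation fixes one for reproducibility: components are scanned in
order of their minimum label; candidate û nodes in order of T₂ postorder;
incomparable lowest roots of infeasibility in T₁ postorder; merge pairs
lexicographically by (min label, min label), testing conditions (a), (b),
(c) in that order.  Swapping the left/right child order of T₁ swaps the
red/blue roles; the result may differ but stays feasible and certified
(exercised in the tests).

## Dual certificate

The dual assigns y_v ≤ 0 to internal nodes of both trees and z_A = 1 to
current components.  y is decremented at lca₁(R∪B) when an iteration
starts and at every cut node û chosen in stages 3–5 (including the
four-way Special-Split's û₀); the end-of-run merges leave the dual
untouched.  Feasibility means every compatible L has load
Σ_{v ∈ V[L]∖𝓛} y_v + Σ_{A ∩ L ≠ ∅} z_A ≤ 1.  The objective
D = Σ y + |𝒫| − 1 satisfies, per iteration, 2·ΔD ≥ ΔP (ΔP counts new
components minus recorded pairs), hence finally 2D ≥ |𝒫| − 1 − |pairslist|
≥ cuts, while weak duality gives D ≤ OPT.  The implementation asserts the
arithmetic inequalities at run time; full dual feasibility is verified
only in tests (exhaustively for ≤ 9 leaves, sampled otherwise) because
enumerating compatible sets is exponential.  The accounting identities
(the component-count bookkeeping per case, and ΔD = |𝒫⁽³⁾| − |𝒫⁽²⁾| − 1 − χ
with χ the four-way indicator) are recomputed from iteration traces and
asserted across sweeps.

## LP relaxations

The enumerated LP has variables x_L ≥ 0 over all compatible sets,
Σ_{L ∋ v} x_L = 1 per leaf, Σ_{L : v ∈ V[L]} x_L ≤ 1 per internal node of
either tree, objective Σ x_L − 1; its integral restriction is the exact
set-partition ILP.  The compact formulation replaces the exponential
variable set by arc variables on the pair graph D: vertices are label
pairs (i₁ ≤ i₂) under the sorted-label order, with left arcs U₁ (first
coordinate preserved) and right arcs U₂ (second coordinate becomes first),
both descending strictly in *both* trees.  A compatible set L corresponds
to the arborescence F(L) built by recursively splitting L at the root of
its T₁-restriction and labelling each branching by the two subtree minima.
The cone of arborescence vectors is cut out by two constraint families
(U₁/U₂ out-flow balance, out-flow ≥ in-flow); leaves are covered exactly
once by arc in-flow plus a singleton variable x̄_i; and internal-node
packing is expressed by attributing to each arc (r, s) the half-open tree
path from lca_t(s) (inclusive) up to lca_t(r) (exclusive) and the
branching node lca_t(r) itself to r's root excess
y(δ⁺(r) ∩ U₁) − y(δ⁻(r)).  Under this attribution each internal node of a
spanned subtree is counted exactly once per arborescence, so the packing
constraint is the exact image of the enumerated one.  The displayed
constraint system of the source being unavailable in the extracted text,
this attribution is the package's own reconstruction; its correctness is
adjudicated empirically by the equivalence test (optima equal to 1e-6 on
every exhaustive ≤ 5-leaf instance and 200 random ≤ 8-leaf instances) and
by the cone-decomposition round-trip (greedy peeling of any feasible y
into arborescence indicators, implemented as a test utility).

Numerics: all LPs/ILPs go through scipy's HiGHS interface; optima are
compared at 1e-6, variables below 1e-7 are treated as zero.  For the
integrality-gap fixture the float optimum is upgraded to an exact rational
one by snapping the primal solution and dual multipliers to small
fractions (denominator ≤ 10⁴) and re-verifying feasibility of both and
equality of their objectives in exact arithmetic; the reported 5/4 is
therefore exact, not a float comparison.

## Exact solvers

Any feasible partition's components have pairwise-disjoint T₁ spans, so
optima are found by enumerating T₁ edge subsets of increasing size and
testing the induced leaf partition (component compatibility plus V₂
disjointness; subsets whose deletion strands a leafless piece are skipped,
as the same partition arises from fewer cuts).  This edge-enumeration
route is the default up to 9 leaves; beyond that the set-partition ILP is
used.  The two routes are cross-checked against each other on random
instances, and against the T₂-sided enumeration on small ones.

## Synthetic study conditions

The generators define the study conditions: uniform labelled topologies by
sequential random insertion (each topology arises from exactly one
insertion sequence, giving exact uniformity, verified by a multinomial
test), and SPR-perturbed pairs (prune a non-root subtree, regraft on a
uniformly chosen edge excluding the position that undoes the move), which
upper-bound the ρ-augmented optimum by the number of moves.  Sweep sizes —
the exhaustive 225-pair 4-leaf set, 500 random pairs on 6–10 leaves for
the approximation ratio, 200 random pairs up to 8 leaves for the LP
comparisons, 100 three-move SPR draws at 10 leaves — were chosen so the
exact solvers and the exhaustive dual-feasibility checks remain
enumerable at desk scale while still exercising every code path
(including four-way Special-Splits and merge conditions (a)–(c), whose
occurrence the tests assert).  Uniform random pairs are far from
ultrametric real phylogenies and carry no branch lengths or estimation
error, so passing sweeps demonstrates correctness of the combinatorics
and certificates, not robustness to reconstruction noise in real data.

The worked seven-leaf example and the two five-leaf teaching instances
were constructed to exhibit the relevant configurations (each case of a
root of infeasibility, every split variant, the compatibility/feasibility
separations) and are pinned by tests asserting each of those facts.  The
integrality-gap fixture is likewise a synthetic stand-in: an 8-leaf
instance with exact optimum 5 and rational LP optimum 4, hence OPT/LP =
5/4 exactly, found by exhaustively scanning caterpillar-first-tree
instances and frozen.  Exhaustive scans of every pair with up to 7
leaves (with and without ρ-augmentation) top out at 6/5, so 8 leaves is
where 5/4 first appears.

## Limitations

* The implementation is the straightforward polynomial one (set algebra
  over frozensets, spans recomputed on demand); the known quadratic-time
  data structures are out of scope.  Hundreds of leaves are comfortable,
  asymptotic records are not the target.
* The enumerated LP and the exact solvers are exponential by nature and
  guarded (10–12 leaves by default); the compact LP and the approximation
  scale further.
* `verify_dual_feasibility` in exhaustive mode is itself exponential and
  intended for tests; the runtime certificate checks only the objective
  inequalities, which is what the guarantee needs.
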