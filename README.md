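# rbmaf — certified maximum agreement forests for rooted binary trees

Two phylogenies reconstructed for the same species from different loci often
disagree, and a standard way to quantify the disagreement — particularly
when reticulate evolution (hybridization, recombination, horizontal gene
transfer) is suspected — is the rooted subtree-prune-and-regraft (rSPR)
distance.  Computing it is NP-hard, but it equals the optimum of the
**Maximum Agreement Forest** (MAF) problem: given rooted binary trees
T₁, T₂ on the same leaf-label set 𝓛, find a partition
𝒫 = {A₁, …, A_k} of 𝓛 such that every Aᵢ induces the same subtree in both
trees (is *compatible*) and no two parts overlap (the node sets V[Aᵢ]
spanned by their leaves are disjoint), minimizing the cost |𝒫| − 1 — the
number of edges to delete from each tree.  With the standard ρ-augmentation
(a new root with an extra leaf ρ in both trees), the MAF optimum equals the
rSPR distance.

`rbmaf` implements:

* **The Red-Blue algorithm** — a combinatorial 2-approximation.  Each
  iteration finds a lowest *root of infeasibility* u in T₁, colors the
  leaves below u's children red and blue (white elsewhere), and refines the
  current partition until it is feasible for red∪blue, via three stages
  (`make_rb_compatible`, `make_splittable`, `split`) plus a deferred
  component merge.
* **A per-run optimality certificate** by dual fitting: alongside the
  algorithm a feasible dual solution (y, z) of the problem's LP relaxation
  is maintained, whose objective D = Σ y_v + |𝒫| − 1 lower-bounds the
  optimum and always satisfies `cuts ≤ 2·D`.  Every run is therefore
  self-certifying: `OPT ≥ D ≥ cuts / 2`.
* **The LP relaxation, twice** — the exponential set-partition LP over all
  compatible sets (for small instances, by enumeration) and an equivalent
  compact formulation over an arborescence-pair graph, solvable in
  polynomial time; plus exact rational re-verification of LP optima, and
  integrality-gap computation (≤ 2 everywhere; a frozen synthetic instance
  attains exactly 5/4).
* **Exact solvers** (increasing-k edge-deletion enumeration, and the
  set-partition ILP) for ground truth on small instances, and **instance
  generators** (uniform random topologies, SPR-perturbed pairs, the
  worked-example fixtures).

## Worked example

```python
>>> from rbmaf import parse_newick, TreePair, augment_with_rho, run, exact_maf
>>> pair = TreePair(parse_newick("(((((B1,B2),(R1,R2)),W1),W2),W3);"),
...                 parse_newick("((((R1,B1),(B2,W1)),(R2,W2)),W3);"))
>>> result = run(pair)
>>> result.cuts
4
>>> sorted(sorted(c) for c in result.forest)
[['B1', 'R1'], ['B2'], ['R2'], ['W1', 'W2'], ['W3']]
>>> result.certificate.dual_objective
2
>>> exact_maf(pair).opt_cuts
2
```

The algorithm cuts this 7-leaf instance into 5 components (4 cuts) and
certifies `4 ≤ 2 × 2` from its dual solution alone, without knowing the
optimum; the exact optimum is indeed 2, so this run is tight for the
factor-2 guarantee.

The same from a shell — here with the default ρ-augmentation, so the
numbers are rSPR-distance bounds for the original pair (the augmented
instance has rSPR distance 2, and the certified run attains ratio 2
exactly):

```
$ rbmaf approx t1.nwk t2.nwk
cuts: 4
  B1	R1
  B2
  R2
  W1	W2
  W3	rho
dual lower bound: 2
certificate: cuts <= 2 x lower_bound (4 <= 4)
$ rbmaf exact t1.nwk t2.nwk
optimum cuts: 2  (method: edge_enum)
  B1	R1	W1	W2	W3	rho
  B2
  R2
$ rbmaf lp t1.nwk t2.nwk    # both relaxations, with agreement check
$ rbmaf sweep -n 4          # 225-instance exhaustive ratio/gap sweep
```

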