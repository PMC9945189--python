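"""Exact MAF solvers for ground truth on small instances.

Any feasible agreement forest has components with pairwise-disjoint T1
spans, so it arises as the leaf sets of a forest obtained by deleting edges
from T1.  The primary oracle therefore enumerates T1 edge subsets of
increasing size k = 0, 1, 2, ... and returns the first k whose induced leaf
partition is feasible (components compatible, non-overlapping in V2; the T1
side is disjoint by construction).  For larger instances the set-partition
integer program over all compatible sets (see :mod:`rbmaf.lpcompact`)
computes the same optimum; the two routes are cross-checked in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Optional

from .compat import Partition, as_partition, is_compatible
from .treeio import RootedBinaryTree, TreePair

__all__ = ["ExactResult", "exact_maf", "enumerate_all_tree_pairs", "all_topologies"]

DEFAULT_LEAF_GUARD = 12


@dataclass(frozen=True)
class ExactResult:
    opt_cuts: int
    opt_forest: Partition
    method: str  # "edge_enum" | "ilp"


def _induced_partition(t1: RootedBinaryTree, cut_nodes: frozenset[int]) -> Partition:
    """Leaf partition after deleting the parent edge of every cut node."""
    groups: dict[int, set[str]] = {}
    for lab, v in t1.node_of_label.items():
        while v not in cut_nodes and t1.parent[v] is not None:
            v = t1.parent[v]
        groups.setdefault(v, set()).add(lab)
    return as_partition(groups.values())


def _feasible_for_oracle(pair: TreePair, P: Partition, compat_cache: dict) -> bool:
    for comp in P:
        ok = compat_cache.get(comp)
        if ok is None:
            ok = compat_cache[comp] = is_compatible(pair, comp)
        if not ok:
            return False
    # overlap only needs checking in V2: the T1 spans are disjoint by
    # construction (each component is one tree of the edge-deleted forest)
    t2 = pair.t2
    seen: set[int] = set()
    for comp in P:
        span = t2.spanned_nodes(comp)
        if span & seen:
            return False
        seen |= span
    return True


def exact_maf(
    pair: TreePair,
    cap: Optional[int] = None,
    method: str = "auto",
    leaf_guard: int = DEFAULT_LEAF_GUARD,
) -> ExactResult:
    """Minimum number of cuts of a feasible agreement forest, with a witness.

    ``method="edge_enum"`` does the increasing-k enumeration over T1 edge
    subsets; ``"ilp"`` solves the set-partition integer program;
    ``"auto"`` picks edge_enum up to 9 leaves and the ILP beyond.
    """
    n = pair.n_leaves
    if n > leaf_guard:
        raise ValueError(f"{n} leaves exceeds the exact-solver guard ({leaf_guard})")
    if method == "auto":
        method = "edge_enum" if n <= 9 else "ilp"
    if method == "ilp":
        from .lpcompact import solve_lp_enumerated

        res = solve_lp_enumerated(pair, integral=True)
        forest = as_partition(
            [L for L, val in res.solution.items() if val > 0.5]
        )
        return ExactResult(opt_cuts=round(res.optimum), opt_forest=forest, method="ilp")
    if method != "edge_enum":
        raise ValueError("method must be 'auto', 'edge_enum' or 'ilp'")
    t1 = pair.t1
    edges = [v for v in t1.postorder if v != t1.root]
    max_k = len(edges) if cap is None else cap
    compat_cache: dict[frozenset[str], bool] = {}
    for k in range(max_k + 1):
        for S in combinations(edges, k):
            P = _induced_partition(t1, frozenset(S))
            if len(P) != k + 1:
                continue  # some deleted edge separated no leaves: k not minimal
            if _feasible_for_oracle(pair, P, compat_cache):
                return ExactResult(opt_cuts=k, opt_forest=P, method="edge_enum")
    raise ValueError(f"no feasible forest within cap={cap}")


# -- exhaustive instance generation ---------------------------------------


def _insert_everywhere(nested, label) -> Iterator:
    """All topologies from grafting ``label`` onto one edge of ``nested``
    (including the root edge); each result is produced exactly once."""
    yield (nested, label)
    if isinstance(nested, tuple):
        left, right = nested
        for sub in _insert_everywhere(left, label):
            yield (sub, right)
        for sub in _insert_everywhere(right, label):
            yield (left, sub)


def all_topologies(labels) -> list:
    """All (2n-3)!! labelled rooted binary topologies, as nested tuples."""
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    trees = [labels[0]]
    for lab in labels[1:]:
        trees = [t2 for t in trees for t2 in _insert_everywhere(t, lab)]
    return trees


def enumerate_all_tree_pairs(n: int, labels=None) -> Iterator[TreePair]:
    """All ordered pairs of labelled rooted binary trees on n <= 5 leaves."""
    if n > 5:
        raise ValueError("exhaustive enumeration is limited to n <= 5")
    if labels is None:
        labels = [chr(ord("a") + i) for i in range(n)]
    topos = all_topologies(labels)
    trees = [RootedBinaryTree(t) for t in topos]
    for t1 in trees:
        for t2 in trees:
            yield TreePair(t1, t2)
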