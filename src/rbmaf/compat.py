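"""Combinatorial predicates on MAF instances: cover, overlap, compatibility.

A leaf set ``L`` is *compatible* when the minimal subtrees spanning ``L`` in
the two input trees are isomorphic as leaf-labelled trees, equivalently when
every rooted triplet of ``L`` resolves to the same cherry in both trees.  A
partition of the label set is a feasible agreement forest exactly when every
component is compatible and no two components overlap (their spanned node
sets ``V[A]`` are disjoint in both trees).

The K-relative notions (``K``-compatible, ``K``-feasible, splittable) are the
local versions of these predicates that the Red-Blue algorithm works with
while an iteration focuses on the leaves below one node of T1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .treeio import LabelError, RootedBinaryTree, TreePair

__all__ = [
    "Partition",
    "Coloring",
    "triple_cherry",
    "triple_compatible",
    "is_compatible",
    "covers",
    "overlap",
    "partition_overlaps_in",
    "is_K_compatible",
    "is_splittable",
    "is_feasible",
    "is_K_feasible",
]

# A partition is simply a collection of disjoint frozensets of labels.
Partition = tuple[frozenset[str], ...]


def as_partition(components: Iterable[Iterable[str]]) -> Partition:
    """Normalize to a deterministic tuple: components sorted by min label."""
    comps = [frozenset(c) for c in components]
    if any(not c for c in comps):
        raise ValueError("empty component in partition")
    return tuple(sorted(comps, key=lambda c: min(c)))


def validate_partition(pair: TreePair, P: Iterable[frozenset[str]]) -> Partition:
    P = as_partition(P)
    union: set[str] = set()
    total = 0
    for comp in P:
        union |= comp
        total += len(comp)
    if total != len(union):
        raise ValueError("components are not pairwise disjoint")
    if union != set(pair.labels):
        raise ValueError("components do not cover the label set")
    return P


@dataclass(frozen=True)
class Coloring:
    """The red/blue/white leaf coloring of one Red-Blue iteration.

    ``R`` and ``B`` are the leaves below the right and left child of the
    chosen root of infeasibility ``u`` in T1; ``W`` is everything else.
    """

    R: frozenset[str]
    B: frozenset[str]
    W: frozenset[str]
    u: int  # node of T1

    @property
    def RB(self) -> frozenset[str]:
        return self.R | self.B

    def colors_of(self, A: Iterable[str]) -> frozenset[str]:
        """Subset of {"R","B","W"} that ``A`` intersects."""
        A = set(A)
        out = set()
        if A & self.R:
            out.add("R")
        if A & self.B:
            out.add("B")
        if A & self.W:
            out.add("W")
        return frozenset(out)

    def color_class(self, name: str) -> frozenset[str]:
        return {"R": self.R, "B": self.B, "W": self.W}[name]


# -- triplet compatibility -------------------------------------------------


def triple_cherry(tree: RootedBinaryTree, x1: str, x2: str, x3: str) -> frozenset[str]:
    """The pair among {x1,x2,x3} whose LCA lies strictly below the triple's.

    In a binary tree every 3-set of leaves resolves uniquely: exactly one
    pair has an LCA that is a proper descendant of lca(x1,x2,x3).
    """
    a, b, c = (tree.leaf_node(x) for x in (x1, x2, x3))
    ab, ac, bc = tree.lca_nodes(a, b), tree.lca_nodes(a, c), tree.lca_nodes(b, c)
    top = tree.lca_nodes(ab, c)
    if ab != top:
        return frozenset((x1, x2))
    if ac != top:
        return frozenset((x1, x3))
    if bc != top:
        return frozenset((x2, x3))
    raise AssertionError("unresolved triple in a binary tree")


def triple_compatible(pair: TreePair, x1: str, x2: str, x3: str) -> bool:
    """True iff the rooted triplet {x1,x2,x3} resolves identically in T1, T2."""
    if len({x1, x2, x3}) != 3:
        raise LabelError("triple_compatible requires three distinct labels")
    return triple_cherry(pair.t1, x1, x2, x3) == triple_cherry(pair.t2, x1, x2, x3)


def _canonical_shape(tree: RootedBinaryTree, L: frozenset[str]):
    """Canonical form of the minimal spanning subtree of L, unary nodes
    suppressed: a leaf label, or the frozenset of the two child forms."""
    if len(L) == 1:
        return next(iter(L))
    top = tree.lca(L)
    left, right = tree.children[top]
    L_left = L & tree.leaves_below(left)
    # top = lca(L) guarantees both sides are nonempty
    return frozenset((_canonical_shape(tree, L_left), _canonical_shape(tree, L - L_left)))


def is_compatible(pair: TreePair, L: Iterable[str]) -> bool:
    """True iff the minimal subtrees spanning ``L`` in T1 and T2 are isomorphic.

    Implemented by comparing canonical forms of the two restricted subtrees;
    the all-triples definition is kept as a test oracle
    (:func:`is_compatible_triples`).  Sets of size <= 2 are always compatible.
    """
    L = frozenset(L)
    unknown = L - pair.labels
    if unknown:
        raise LabelError(f"unknown labels {sorted(unknown)}")
    if len(L) <= 2:
        return True
    return _canonical_shape(pair.t1, L) == _canonical_shape(pair.t2, L)


def is_compatible_triples(pair: TreePair, L: Iterable[str]) -> bool:
    """Brute-force all-triples compatibility check (the defining condition)."""
    L = sorted(frozenset(L))
    return all(triple_compatible(pair, *t) for t in combinations(L, 3))


# -- cover / overlap -------------------------------------------------------


def covers(pair: TreePair, A: Iterable[str], v: int, tree_index: int) -> bool:
    """True iff node ``v`` of tree ``tree_index`` lies in V[A] of that tree."""
    return v in pair.tree(tree_index).spanned_nodes(A)


def overlap(
    pair: TreePair,
    A: Iterable[str],
    A2: Iterable[str],
    U: str | tuple[int, frozenset[int]] = "all",
) -> bool:
    """Do A and A2 overlap in U, i.e. is V[A] & V[A2] & U nonempty?

    ``U`` is ``"all"`` (= V1 union V2), ``"V1"``, ``"V2"``, or an explicit
    ``(tree_index, node_set)`` restriction.
    """
    if U == "all":
        return overlap(pair, A, A2, "V1") or overlap(pair, A, A2, "V2")
    if U == "V1":
        U = (1, None)
    elif U == "V2":
        U = (2, None)
    t, nodes = U
    tree = pair.tree(t)
    inter = tree.spanned_nodes(A) & tree.spanned_nodes(A2)
    if nodes is not None:
        inter &= nodes
    return bool(inter)


def partition_overlaps_in(
    pair: TreePair,
    P: Iterable[frozenset[str]],
    U: str | tuple[int, frozenset[int]] = "all",
) -> bool:
    """True iff two distinct components of P overlap in U.

    Uses a single sweep marking spanned nodes instead of the quadratic
    pairwise test.
    """
    P = list(P)
    if U == "all":
        return partition_overlaps_in(pair, P, "V1") or partition_overlaps_in(pair, P, "V2")
    if U in ("V1", "V2"):
        t, restrict = (1 if U == "V1" else 2), None
    else:
        t, restrict = U
    tree = pair.tree(t)
    seen: set[int] = set()
    for comp in P:
        span = tree.spanned_nodes(comp)
        if restrict is not None:
            span &= restrict
        if span & seen:
            return True
        seen |= span
    return False


# -- K-relative notions ----------------------------------------------------


def is_K_compatible(pair: TreePair, P: Iterable[frozenset[str]], K: Iterable[str]) -> bool:
    """Every component A has A & K compatible."""
    K = frozenset(K)
    return all(is_compatible(pair, comp & K) for comp in P)


def is_splittable(pair: TreePair, A: Iterable[str], coloring: Coloring) -> bool:
    """A's color classes A&R, A&B, A&W do not overlap pairwise in V2.

    A splittable component can be cut into its unicolored pieces by deleting
    edges of T2 only.  Unicolored (and empty) sets are vacuously splittable.
    """
    A = frozenset(A)
    classes = [A & C for C in (coloring.R, coloring.B, coloring.W) if A & C]
    if len(classes) <= 1:
        return True
    return not partition_overlaps_in(pair, classes, "V2")


def is_feasible(pair: TreePair, P: Iterable[frozenset[str]]) -> bool:
    """P is a feasible agreement forest: compatible components, no overlap."""
    P = list(P)
    return all(is_compatible(pair, comp) for comp in P) and not partition_overlaps_in(
        pair, P, "all"
    )


def is_K_feasible(pair: TreePair, P: Iterable[frozenset[str]], K: Iterable[str]) -> bool:
    """P is K-feasible: K∪{w}-compatible for every leaf w, and no two
    components overlap in V2 ∪ V1[K].  L-feasible coincides with feasible."""
    P = list(P)
    K = frozenset(K)
    for w in pair.labels:
        if not is_K_compatible(pair, P, K | {w}):
            return False
    if partition_overlaps_in(pair, P, "V2"):
        return False
    v1k = pair.t1.spanned_nodes(K)
    return not partition_overlaps_in(pair, P, (1, v1k))


def dump_spans(pair: TreePair, A: Iterable[str]) -> str:
    """Readable dump of V1[A] and V2[A] for debugging and text fixtures."""
    A = sorted(frozenset(A))
    lines = [f"A = {{{', '.join(A)}}}"]
    for t in (1, 2):
        tree = pair.tree(t)
        parts = []
        for v in sorted(tree.spanned_nodes(A), key=tree.post_index.get):
            if tree.is_leaf(v):
                parts.append(tree.leaf_label[v])
            else:
                below = ",".join(sorted(tree.leaves_below(v)))
                parts.append(f"lca({below})")
        lines.append(f"V{t}[A] = [" + "; ".join(parts) + "]")
    return "\n".join(lines)
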