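"""Rooted binary trees with leaf-label bijections, Newick IO and ancestry queries.

This module is the substrate for everything else in :mod:`rbmaf`: it holds the
two input phylogenies of a maximum-agreement-forest (MAF) instance, answers
lowest-common-ancestor (LCA) and descendant queries, and computes the node set
``V[A]`` spanned by a set of leaf labels ``A`` (all nodes lying on a path
between two leaves of ``A``), which is the geometric primitive behind the
cover/overlap predicates.

Conventions
-----------
* Trees are strictly binary: every internal node has exactly two children.
  Polytomies are rejected at parse time, never resolved.
* Leaf labels are strings; internal-node names and branch lengths in Newick
  input are accepted and discarded.
* Child order as written in the Newick string is preserved; "left" means
  first-written.  Order carries no semantics, it only makes iteration (and
  hence the algorithm's tie-breaking) deterministic.
* The reserved root label used for rho-augmentation is ``"rho"`` by default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

RHO_LABEL = "rho"

__all__ = [
    "RHO_LABEL",
    "TreeError",
    "NewickParseError",
    "ArityError",
    "LabelError",
    "RootedBinaryTree",
    "TreePair",
    "parse_newick",
    "parse_newick_pair",
    "write_newick",
    "augment_with_rho",
]


class TreeError(ValueError):
    """Base class for malformed trees or invalid queries."""


class NewickParseError(TreeError):
    """Raised when a Newick string cannot be parsed."""


class ArityError(TreeError):
    """Raised when an internal node does not have exactly two children."""


class LabelError(TreeError):
    """Raised for duplicate, missing or unknown leaf labels."""


Nested = "str | tuple"  # a label, or a 2-tuple of Nested


class RootedBinaryTree:
    """A rooted binary tree whose leaves are bijectively labelled.

    Nodes are integers ``0 .. n_nodes-1``; the root is node 0.  Construction
    precomputes depths, postorder, and per-node leaf-descendant sets, so
    ancestry queries are cheap dictionary/set operations.
    """

    __slots__ = (
        "root",
        "children",
        "parent",
        "leaf_label",
        "node_of_label",
        "depth",
        "postorder",
        "post_index",
        "_leafset",
        "labels",
    )

    def __init__(self, nested) -> None:
        self.children: list[tuple[int, ...]] = []
        self.parent: list[int | None] = []
        self.leaf_label: dict[int, str] = {}
        self._build(nested)
        self.root = 0
        self.node_of_label = {}
        for v, lab in self.leaf_label.items():
            if lab in self.node_of_label:
                raise LabelError(f"duplicate leaf label {lab!r}")
            self.node_of_label[lab] = v
        self.labels = frozenset(self.node_of_label)
        n = len(self.children)
        self.depth = [0] * n
        order: list[int] = []
        stack = [0]
        while stack:  # preorder for depths
            v = stack.pop()
            order.append(v)
            for c in self.children[v]:
                self.depth[c] = self.depth[v] + 1
                stack.append(c)
        self.postorder = order[::-1]  # reverse preorder: children before parents
        self.post_index = {v: i for i, v in enumerate(self.postorder)}
        self._leafset: list[frozenset[str]] = [frozenset()] * n
        for v in self.postorder:
            if self.is_leaf(v):
                self._leafset[v] = frozenset((self.leaf_label[v],))
            else:
                acc: frozenset[str] = frozenset()
                for c in self.children[v]:
                    acc |= self._leafset[c]
                self._leafset[v] = acc

    def _build(self, nested) -> int:
        v = len(self.children)
        self.children.append(())
        self.parent.append(None)
        if isinstance(nested, str):
            self.leaf_label[v] = nested
            return v
        if not isinstance(nested, tuple) or len(nested) != 2:
            raise ArityError(
                f"internal node with {len(nested)} children; trees must be binary"
            )
        kids = tuple(self._build(sub) for sub in nested)
        self.children[v] = kids
        for c in kids:
            self.parent[c] = v
        return v

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def internal_nodes(self) -> Iterator[int]:
        """Internal nodes in postorder (descendants before ancestors)."""
        return (v for v in self.postorder if self.children[v])

    def leaves_below(self, v: int) -> frozenset[str]:
        """The label set L(v) of leaves weakly below ``v``."""
        if not 0 <= v < self.n_nodes:
            raise TreeError(f"unknown node {v}")
        return self._leafset[v]

    def leaf_node(self, label: str) -> int:
        try:
            return self.node_of_label[label]
        except KeyError:
            raise LabelError(f"unknown leaf label {label!r}") from None

    def is_ancestor(self, u: int, v: int) -> bool:
        """True iff ``u`` is ``v`` or an ancestor of ``v`` (v <= u)."""
        while v is not None and self.depth[v] > self.depth[u]:
            v = self.parent[v]
        return v == u

    def lca_nodes(self, u: int, v: int) -> int:
        while self.depth[u] > self.depth[v]:
            u = self.parent[u]
        while self.depth[v] > self.depth[u]:
            v = self.parent[v]
        while u != v:
            u = self.parent[u]
            v = self.parent[v]
        return u

    def lca(self, labels: Iterable[str]) -> int:
        """Lowest common ancestor of a nonempty set of leaf labels."""
        it = iter(labels)
        try:
            v = self.leaf_node(next(it))
        except StopIteration:
            raise TreeError("lca of empty label set") from None
        for lab in it:
            v = self.lca_nodes(v, self.leaf_node(lab))
        return v

    def path_up(self, v: int, top: int) -> list[int]:
        """Nodes from ``v`` up to ``top`` inclusive; ``top`` must be ancestral."""
        out = [v]
        while v != top:
            v = self.parent[v]
            if v is None:
                raise TreeError("path_up: top is not an ancestor")
            out.append(v)
        return out

    def spanned_nodes(self, A: Iterable[str]) -> frozenset[int]:
        """V[A]: nodes on a path between two leaves of ``A``.

        The degenerate single-leaf path is included, so a singleton spans
        exactly its own leaf; the empty set spans nothing.
        """
        A = list(A)
        for lab in A:
            if lab not in self.node_of_label:
                raise LabelError(f"unknown leaf label {lab!r}")
        if not A:
            return frozenset()
        if len(A) == 1:
            return frozenset((self.leaf_node(A[0]),))
        top = self.lca(A)
        nodes: set[int] = set()
        for lab in A:
            v = self.leaf_node(lab)
            while v != top and v not in nodes:
                nodes.add(v)
                v = self.parent[v]
        nodes.add(top)
        return frozenset(nodes)

    # -- structure ---------------------------------------------------------

    def to_nested(self, v: int | None = None):
        v = self.root if v is None else v
        if self.is_leaf(v):
            return self.leaf_label[v]
        return tuple(self.to_nested(c) for c in self.children[v])

    def isomorphic_to(self, other: "RootedBinaryTree") -> bool:
        """Label-and-shape equality, ignoring child order."""

        def canon(tree, v):
            if tree.is_leaf(v):
                return tree.leaf_label[v]
            return frozenset(canon(tree, c) for c in tree.children[v])

        return canon(self, self.root) == canon(other, other.root)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedBinaryTree({write_newick(self)!r})"


@dataclass(frozen=True)
class TreePair:
    """A MAF instance: two rooted binary trees over the same label set."""

    t1: RootedBinaryTree
    t2: RootedBinaryTree
    rho_present: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.t1.labels != self.t2.labels:
            only1 = sorted(self.t1.labels - self.t2.labels)
            only2 = sorted(self.t2.labels - self.t1.labels)
            raise LabelError(
                f"label sets differ: only in T1 {only1}, only in T2 {only2}"
            )

    @property
    def labels(self) -> frozenset[str]:
        return self.t1.labels

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def tree(self, t: int) -> RootedBinaryTree:
        if t == 1:
            return self.t1
        if t == 2:
            return self.t2
        raise ValueError("tree index must be 1 or 2")


# -- Newick ----------------------------------------------------------------


def _dendropy_to_nested(node):
    if node.is_leaf():
        if node.taxon is None or not node.taxon.label:
            raise LabelError("unnamed leaf in Newick input")
        return node.taxon.label
    kids = node.child_nodes()
    if len(kids) != 2:
        name = (node.taxon.label if node.taxon else None) or (node.label or "<anonymous>")
        raise ArityError(
            f"internal node {name!r} has {len(kids)} children; trees must be binary"
        )
    return tuple(_dendropy_to_nested(c) for c in kids)


def parse_newick(text: str) -> RootedBinaryTree:
    """Parse a single rooted binary tree from a Newick string.

    Internal-node names and branch lengths are tolerated and discarded.
    Raises :class:`NewickParseError` on malformed input, :class:`LabelError`
    on duplicate/missing leaf names and :class:`ArityError` on polytomies.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several unrelated types
        if isinstance(exc, TreeError):
            raise
        if "Duplicate" in type(exc).__name__ or "duplicate" in str(exc).lower():
            raise LabelError(f"duplicate leaf label: {exc}") from exc
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    root = tree.seed_node
    if root.is_leaf():
        raise ArityError("a tree must have at least two leaves")
    return RootedBinaryTree(_dendropy_to_nested(root))


def parse_newick_pair(text: str) -> TreePair:
    """Parse two trees (two Newick statements) into a :class:`TreePair`."""
    chunks = [c.strip() for c in text.replace("\n", " ").split(";")]
    chunks = [c for c in chunks if c]
    if len(chunks) != 2:
        raise NewickParseError(f"expected exactly 2 trees, found {len(chunks)}")
    t1, t2 = (parse_newick(c + ";") for c in chunks)
    return TreePair(t1, t2, rho_present=RHO_LABEL in t1.labels)


_NEEDS_QUOTE = set(" (),:;[]'")


def _quote(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: RootedBinaryTree) -> str:
    """Serialize; round-trips through :func:`parse_newick` preserving order."""

    def rec(v: int) -> str:
        if tree.is_leaf(v):
            return _quote(tree.leaf_label[v])
        return "(" + ",".join(rec(c) for c in tree.children[v]) + ")"

    return rec(tree.root) + ";"


def augment_with_rho(pair: TreePair, rho_label: str = RHO_LABEL) -> TreePair:
    """Attach a new root with an extra leaf ``rho`` to both trees.

    With this augmentation the MAF optimum of the pair equals the rSPR
    distance between the original trees (the Bordewich–Semple correction);
    the new leaf pins the original roots into a common component.
    """
    if rho_label in pair.labels:
        raise LabelError(f"label {rho_label!r} already present; cannot augment again")
    t1 = RootedBinaryTree((rho_label, pair.t1.to_nested()))
    t2 = RootedBinaryTree((rho_label, pair.t2.to_nested()))
    return TreePair(t1, t2, rho_present=True)
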