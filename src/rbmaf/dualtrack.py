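"""Dual-fitting certificate maintained alongside the Red-Blue algorithm.

The exponential LP relaxation of MAF has one variable per compatible leaf
set, partition constraints on the leaves and packing constraints on internal
nodes.  Its dual assigns a value ``y_v`` to every internal node of both
trees and an indicator ``z_A`` to every leaf set; the *load* of a compatible
set L is

    load(L) = sum_{v in V[L] \\ leaves} y_v + sum_{A : A ∩ L != ∅} z_A

and the dual is feasible when every compatible set has load at most 1.  The
algorithm keeps ``z_A = 1`` exactly for the current components and only ever
decrements ``y``: by 1 at ``lca1(R∪B)`` when an iteration starts, and by 1
at every T2 node chosen to subdivide a component (the star lines, including
the four-way Special-Split).  The end-of-run merges do not touch the dual.

The dual objective ``D = sum_v y_v + |P| - 1`` is, by weak duality, a lower
bound on the MAF optimum, and the algorithm guarantees
``2 D >= |P| - 1 - |pairslist| >= cuts``, certifying the factor 2 per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Iterable, Optional, Sequence

from .compat import Partition, as_partition, is_compatible
from .treeio import TreePair

__all__ = [
    "DualSolution",
    "Certificate",
    "load",
    "verify_dual_feasibility",
    "certificate",
]


@dataclass
class DualSolution:
    """Integer dual solution: y on internal nodes, z mirroring the partition."""

    pair: TreePair
    y: dict[tuple[int, int], int]  # (tree index, node) -> value, <= 0
    z_components: Partition

    @classmethod
    def initial(cls, pair: TreePair) -> "DualSolution":
        y = {
            (t, v): 0
            for t in (1, 2)
            for v in pair.tree(t).postorder
            if not pair.tree(t).is_leaf(v)
        }
        return cls(pair=pair, y=y, z_components=(pair.labels,))

    def decrement(self, tree_index: int, v: int) -> None:
        key = (tree_index, v)
        if key not in self.y:
            raise ValueError(f"node {v} is not an internal node of T{tree_index}")
        self.y[key] -= 1

    def sync_components(self, components: Iterable[frozenset[str]]) -> None:
        self.z_components = as_partition(components)

    def objective(self) -> int:
        """D = sum(y) + |P| - 1."""
        return sum(self.y.values()) + len(self.z_components) - 1

    def copy(self) -> "DualSolution":
        return DualSolution(self.pair, dict(self.y), self.z_components)


def load(pair: TreePair, dual: DualSolution, L: Iterable[str]) -> int:
    """The dual left-hand side on a leaf set L."""
    L = frozenset(L)
    total = 0
    for t in (1, 2):
        tree = pair.tree(t)
        for v in tree.spanned_nodes(L):
            if not tree.is_leaf(v):
                total += dual.y[(t, v)]
    total += sum(1 for A in dual.z_components if A & L)
    return total


def apply_iteration_updates(dual: DualSolution, trace) -> DualSolution:
    """Replay one iteration's dual updates (standalone variant of what
    :func:`rbmaf.redblue.run` does in-line): decrement lca1(R∪B) and every
    star node, then mirror the post-Split partition in z."""
    out = dual.copy()
    out.decrement(1, trace.coloring.u)
    for v in trace.star_nodes:
        out.decrement(2, v)
    out.sync_components(trace.P3)
    return out


@dataclass(frozen=True)
class FeasibilityReport:
    feasible: bool
    checked: int
    violations: tuple[tuple[frozenset[str], int], ...]  # (set, load)


def _nonempty_subsets(labels: Sequence[str]):
    for k in range(1, len(labels) + 1):
        yield from combinations(labels, k)


def verify_dual_feasibility(
    pair: TreePair,
    dual: DualSolution,
    mode: str = "exhaustive",
    rng=None,
    samples: int = 200,
) -> FeasibilityReport:
    """Check load(L) <= 1 over compatible sets L.

    ``exhaustive`` enumerates every compatible subset (use only for small
    label sets); ``sampled`` checks a random sample plus all current
    components and all T2-subtree leaf sets.
    """
    labels = sorted(pair.labels)
    violations = []
    checked = 0
    if mode == "exhaustive":
        if len(labels) > 16:
            raise ValueError("exhaustive mode is limited to small label sets")
        candidates = _nonempty_subsets(labels)
    elif mode == "sampled":
        import numpy as np

        rng = np.random.default_rng(rng)
        cand: list[tuple[str, ...]] = [tuple(sorted(A)) for A in dual.z_components]
        t2 = pair.t2
        cand.extend(tuple(sorted(t2.leaves_below(v))) for v in t2.postorder)
        for _ in range(samples):
            k = int(rng.integers(1, len(labels) + 1))
            cand.append(tuple(sorted(rng.choice(labels, size=k, replace=False))))
        candidates = cand
    else:
        raise ValueError("mode must be 'exhaustive' or 'sampled'")
    for A in candidates:
        if not is_compatible(pair, A):
            continue
        checked += 1
        val = load(pair, dual, A)
        if val > 1:
            violations.append((frozenset(A), val))
    return FeasibilityReport(not violations, checked, tuple(violations))


@dataclass(frozen=True)
class Certificate:
    dual_objective: int
    cuts: int
    pairs: int

    @property
    def lower_bound(self) -> int:
        return self.dual_objective

    @property
    def ratio_bound(self) -> float:
        return 2.0

    def as_dict(self) -> dict:
        return {
            "dual_objective": self.dual_objective,
            "cuts": self.cuts,
            "lower_bound": self.lower_bound,
            "ratio_bound": self.ratio_bound,
        }


def certificate(
    dual: DualSolution,
    forest: Iterable[frozenset[str]],
    pairslist: Sequence[tuple[str, str]],
) -> Certificate:
    """End-of-run certificate: D from the pre-merge dual, cuts from the
    returned forest; raises if 2D >= cuts fails (it cannot, absent bugs)."""
    forest = as_partition(forest)
    D = dual.objective()
    cuts = len(forest) - 1
    if 2 * D < len(dual.z_components) - 1 - len(pairslist):
        raise AssertionError("dual certificate violated: 2D < |P|-1-|pairslist|")
    if 2 * D < cuts:
        raise AssertionError("dual certificate violated: 2D < cuts")
    return Certificate(dual_objective=D, cuts=cuts, pairs=len(pairslist))
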