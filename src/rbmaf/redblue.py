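"""The Red-Blue 2-approximation algorithm for maximum agreement forest.

The algorithm maintains a partition P of the leaf labels that never overlaps
in V2 (so it is always realizable as the leaf sets of a forest obtained by
deleting edges from T2).  Each iteration picks a *lowest root of
infeasibility* ``u`` in T1, colors the leaves red/blue/white (red = below
u's right child, blue = below its left child, white = the rest) and refines
P in three stages until it is (R∪B)-feasible:

1. ``make_rb_compatible``  – cut until every component's red∪blue part is a
   compatible set;
2. ``make_splittable``     – cut until each component's color classes are
   pairwise non-overlapping in V2;
3. ``split``               – intersect multicolored components with the
   color classes (with the Special-Split variants on the tricolored top
   component when it still holds a compatible tricolored triple).

Finally ``find_merge_pair`` records at most one pair of red/blue leaves per
iteration whose components may safely be re-merged; all merges are applied
at the very end by ``merge_components``.  The deferred merges are what makes
the dual-fitting certificate (see :mod:`rbmaf.dualtrack`) tight enough for
the factor-2 guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

from . import dualtrack
from .compat import (
    Coloring,
    Partition,
    as_partition,
    is_compatible,
    partition_overlaps_in,
    validate_partition,
)
from .treeio import LabelError, TreePair

__all__ = [
    "InternalConsistencyError",
    "IterationTrace",
    "RunResult",
    "lowest_root_of_infeasibility",
    "make_coloring",
    "classify_case",
    "make_rb_compatible",
    "make_splittable",
    "split",
    "find_merge_pair",
    "merge_components",
    "run",
]


class InternalConsistencyError(RuntimeError):
    """A structural guarantee of the algorithm failed; indicates a bug.

    Carries the partial trace list (when raised from :func:`run`) in
    ``.traces`` for debugging.
    """

    def __init__(self, message: str, traces=None):
        super().__init__(message)
        self.traces = traces


@dataclass
class SpecialSplitEvent:
    component: frozenset[str]
    kind: str  # "two_way" | "four_way"
    u_hat0: Optional[int]  # T2 node, four_way only


@dataclass
class IterationTrace:
    """Everything one iteration did, for certificates and invariant checks."""

    coloring: Coloring
    case_label: str
    star_nodes: list[int]  # T2 nodes whose y-value was decremented
    special_split_events: list[SpecialSplitEvent]
    P0: Partition
    P1: Partition
    P2: Partition
    P3: Partition
    tops_P1: tuple[frozenset[str], ...]
    tops_P2: tuple[frozenset[str], ...]
    merge_pair_found: Optional[tuple[str, str]]
    delta_D: int = 0
    delta_P: int = 0


@dataclass
class RunResult:
    forest: Partition
    cuts: int
    traces: list[IterationTrace]
    pairslist: list[tuple[str, str]]
    dual: "dualtrack.DualSolution"

    @property
    def certificate(self) -> "dualtrack.Certificate":
        return dualtrack.certificate(self.dual, self.forest, self.pairslist)


def _sorted_components(comps: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    return sorted(comps, key=lambda c: min(c))


# -- root of infeasibility -------------------------------------------------


def _is_root_of_infeasibility(pair: TreePair, P: Sequence[frozenset[str]], u: int) -> bool:
    t1 = pair.t1
    Lu = t1.leaves_below(u)
    # (a) P is not L(u)-compatible
    if any(not is_compatible(pair, comp & Lu) for comp in P):
        return True
    # (b) P overlaps in V1[L(u)]
    if partition_overlaps_in(pair, P, (1, t1.spanned_nodes(Lu))):
        return True
    # (c) some component leaves L(u) only through incompatible extensions
    for comp in P:
        inside = comp & Lu
        outside = comp - Lu
        if not inside or not outside:
            continue
        if all(not is_compatible(pair, inside | {w}) for w in outside):
            return True
    return False


def lowest_root_of_infeasibility(
    pair: TreePair, P: Iterable[frozenset[str]]
) -> Optional[int]:
    """First T1 node in postorder that is a root of infeasibility, or None.

    Postorder visits descendants first, so the returned node has no
    qualifying descendant, i.e. it is lowest.  Returns None exactly when P
    is feasible.  Requires that P does not overlap in V2.
    """
    P = validate_partition(pair, P)
    if partition_overlaps_in(pair, P, "V2"):
        raise ValueError("partition overlaps in V2; algorithm invariant broken")
    for u in pair.t1.internal_nodes():
        if _is_root_of_infeasibility(pair, P, u):
            return u
    return None


def make_coloring(pair: TreePair, u: int) -> Coloring:
    """Color leaves by u's children: left subtree blue, right subtree red."""
    t1 = pair.t1
    if t1.is_leaf(u):
        raise ValueError(f"node {u} is a leaf; the root of infeasibility is internal")
    left, right = t1.children[u]
    B = t1.leaves_below(left)
    R = t1.leaves_below(right)
    return Coloring(R=R, B=B, W=pair.labels - R - B, u=u)


def classify_case(
    pair: TreePair, P: Iterable[frozenset[str]], coloring: Coloring
) -> tuple[str, tuple[frozenset[str], ...]]:
    """Which of the three start-of-iteration configurations holds.

    case1: one tricolored component, not (R∪B)-compatible, containing a
           compatible tricolored triple;
    case2: two multicolored components, one without red, one without blue;
    case3: one tricolored, (R∪B)-compatible, no compatible tricolored triple.
    Anything else contradicts the case analysis for a lowest root of
    infeasibility and raises :class:`InternalConsistencyError`.
    """
    P = as_partition(P)
    multi = [A for A in P if len(coloring.colors_of(A)) >= 2]
    if len(multi) == 2:
        a, b = multi
        if not a & coloring.R and not b & coloring.B:
            return "case2", (a, b)
        if not b & coloring.R and not a & coloring.B:
            return "case2", (b, a)
        raise InternalConsistencyError("two multicolored components sharing a color")
    if len(multi) != 1:
        raise InternalConsistencyError(
            f"{len(multi)} multicolored components at iteration start"
        )
    A0 = multi[0]
    if len(coloring.colors_of(A0)) != 3:
        raise InternalConsistencyError("single multicolored component is not tricolored")
    if not is_compatible(pair, A0 & coloring.RB):
        if not _has_compatible_tricolored_triple(pair, A0, coloring):
            raise InternalConsistencyError(
                "case1 component lacks a compatible tricolored triple"
            )
        return "case1", (A0,)
    if _has_compatible_tricolored_triple(pair, A0, coloring):
        raise InternalConsistencyError(
            "tricolored, (R∪B)-compatible component with a compatible triple "
            "contradicts u being a root of infeasibility"
        )
    return "case3", (A0,)


def _tricolored_triple_status(
    pair: TreePair, A: frozenset[str], coloring: Coloring
) -> tuple[bool, bool]:
    """(some compatible tricolored triple, all tricolored triples compatible).

    For any red r and blue b in A, lca1(r,b) = u lies strictly below
    lca1(r,b,w) for white w, so {r,b,w} is compatible iff in T2 as well
    lca2(r,b) is strictly below lca2(r,b,w), i.e. iff w is not a descendant
    of lca2(r,b).  This avoids enumerating all triples.
    """
    R0 = A & coloring.R
    B0 = A & coloring.B
    W0 = A & coloring.W
    if not (R0 and B0 and W0):
        return False, True
    t2 = pair.t2
    has_compat = False
    all_compat = True
    lca_cache: dict[tuple[str, str], int] = {}
    for w in W0:
        wnode = t2.leaf_node(w)
        for r in R0:
            for b in B0:
                key = (r, b)
                rb = lca_cache.get(key)
                if rb is None:
                    rb = lca_cache[key] = t2.lca_nodes(t2.leaf_node(r), t2.leaf_node(b))
                if t2.is_ancestor(rb, wnode):
                    all_compat = False
                else:
                    has_compat = True
    return has_compat, all_compat


def _has_compatible_tricolored_triple(pair, A, coloring) -> bool:
    return _tricolored_triple_status(pair, A, coloring)[0]


# -- the three refinement stages -------------------------------------------


def _subdivide(comps, tops, A, part_in, part_out):
    comps.remove(A)
    comps.append(part_in)
    comps.append(part_out)
    if A in tops:
        tops.discard(A)
        tops.add(part_out)  # the remainder A \ L(û) stays the top component


def _make_rb_compatible(pair, comps, tops, coloring, stars):
    t2 = pair.t2
    RB = coloring.RB
    while True:
        bad = next(
            (A for A in _sorted_components(comps) if not is_compatible(pair, A & RB)),
            None,
        )
        if bad is None:
            return
        # lowest T2 node whose leaf set meets both colors inside `bad`;
        # postorder guarantees no qualifying descendant precedes it.
        u_hat = None
        for v in t2.postorder:
            if t2.is_leaf(v):
                continue
            below = bad & t2.leaves_below(v)
            if below & coloring.R and below & coloring.B:
                u_hat = v
                break
        if u_hat is None:
            raise InternalConsistencyError("no cut node found in make_rb_compatible")
        Lv = t2.leaves_below(u_hat)
        stars.append(u_hat)
        _subdivide(comps, tops, bad, bad & Lv, bad - Lv)


def _lowest_nodes(t2, nodes: set[int]) -> list[int]:
    """Members of ``nodes`` with no proper descendant in ``nodes``, postorder."""
    out = []
    for v in sorted(nodes, key=t2.post_index.get):
        if not any(u != v and t2.is_ancestor(v, u) for u in nodes):
            out.append(v)
    return out


def _splittable(pair, A, coloring) -> bool:
    classes = [A & coloring.color_class(c) for c in "RBW"]
    classes = [c for c in classes if c]
    if len(classes) <= 1:
        return True
    return not partition_overlaps_in(pair, classes, "V2")


def _make_splittable(pair, comps, tops, coloring, stars):
    t2 = pair.t2
    while True:
        bad = next(
            (A for A in _sorted_components(comps) if not _splittable(pair, A, coloring)),
            None,
        )
        if bad is None:
            return
        colors = coloring.colors_of(bad)
        candidates: set[int] = set()
        for c1, c2 in combinations(sorted(colors), 2):
            span1 = t2.spanned_nodes(bad & coloring.color_class(c1))
            span2 = t2.spanned_nodes(bad & coloring.color_class(c2))
            candidates.update(_lowest_nodes(t2, set(span1 & span2)))
        u_hat = None
        for v in sorted(candidates, key=t2.post_index.get):
            Lv = t2.leaves_below(v)
            inside = bad & Lv
            if len(coloring.colors_of(inside)) == 2 and coloring.colors_of(bad - Lv) == colors:
                u_hat = v
                break
        if u_hat is None:
            raise InternalConsistencyError(
                "no valid cut node for an unsplittable component"
            )
        Lv = t2.leaves_below(u_hat)
        stars.append(u_hat)
        _subdivide(comps, tops, bad, bad & Lv, bad - Lv)


def _split(pair, comps, tops, coloring, stars):
    t2 = pair.t2
    events: list[SpecialSplitEvent] = []
    out: list[frozenset[str]] = []
    for A in _sorted_components(comps):
        colors = coloring.colors_of(A)
        if len(colors) <= 1:
            out.append(A)
            continue
        has_compat = all_compat = False
        if len(colors) == 3:
            has_compat, all_compat = _tricolored_triple_status(pair, A, coloring)
        if len(colors) == 3 and has_compat:
            if A not in tops:
                raise InternalConsistencyError(
                    "Special-Split triggered on a non-top component"
                )
            if all_compat:
                out.extend((A & coloring.R, A - coloring.R))
                events.append(SpecialSplitEvent(A, "two_way", None))
            else:
                u_hat0 = t2.lca(A & coloring.RB)
                Lv = t2.leaves_below(u_hat0)
                inside = A & Lv
                parts = [
                    inside & coloring.R,
                    inside & coloring.B,
                    inside & coloring.W,
                    A - Lv,
                ]
                if not all(parts):
                    raise InternalConsistencyError(
                        "four-way Special-Split produced an empty part"
                    )
                out.extend(parts)
                stars.append(u_hat0)
                events.append(SpecialSplitEvent(A, "four_way", u_hat0))
        else:
            out.extend(A & C for C in (coloring.R, coloring.B, coloring.W) if A & C)
    comps[:] = out
    return events


# -- spec-surface wrappers (single stage on an explicit partition) ---------


def make_rb_compatible(pair, P, coloring) -> tuple[Partition, list[int]]:
    """Refine P until every component's (R∪B)-part is compatible."""
    comps = list(validate_partition(pair, P))
    tops = {A for A in comps if len(coloring.colors_of(A)) >= 2}
    stars: list[int] = []
    _make_rb_compatible(pair, comps, tops, coloring, stars)
    return as_partition(comps), stars


def make_splittable(pair, P1, coloring) -> tuple[Partition, list[int]]:
    """Refine P1 until every component is splittable."""
    comps = list(validate_partition(pair, P1))
    tops = {A for A in comps if len(coloring.colors_of(A)) >= 2}
    stars: list[int] = []
    _make_splittable(pair, comps, tops, coloring, stars)
    return as_partition(comps), stars


def split(pair, P2, coloring) -> tuple[Partition, list[SpecialSplitEvent]]:
    """Cut multicolored components into color classes (Special-Split aware).

    When called standalone (outside :func:`run`), every multicolored
    component is treated as a potential top component, since the caller
    provides no subdivision history.
    """
    comps = list(validate_partition(pair, P2))
    tops = {A for A in comps if len(coloring.colors_of(A)) >= 2}
    stars: list[int] = []
    events = _split(pair, comps, tops, coloring, stars)
    return as_partition(comps), events


# -- merging ---------------------------------------------------------------


def _reach_set(t2, comp, covered) -> frozenset[int]:
    """Nodes a component can reach: its own span, plus ancestors of its
    lca2 up to (and including) the first covered node on the way up."""
    span = t2.spanned_nodes(comp)
    reach = set(span)
    cur = t2.lca(comp)
    while True:
        nxt = t2.parent[cur]
        if nxt is None:
            break
        reach.add(nxt)
        if nxt in covered:
            break
        cur = nxt
    return frozenset(reach)


def find_merge_pair(
    pair: TreePair,
    P3: Iterable[frozenset[str]],
    coloring: Coloring,
    P0: Iterable[frozenset[str]],
    special_events: Sequence[SpecialSplitEvent] = (),
) -> Optional[tuple[str, str]]:
    """One pair of red/blue leaves whose current components can be re-merged.

    Scans each start-of-iteration component A0 that was subdivided, and
    tests the three merge conditions in order: (a) a bicolored survivor of a
    two-way Special-Split, (b) two like-colored components reaching a common
    T2 node, (c) a red and a blue component reaching a common uncovered T2
    node with a clean path up to lca2(A0).  Returns the lexicographically
    smallest (min-label, min-label) pair for the first condition that fires,
    or None.
    """
    P3 = as_partition(P3)
    P0 = as_partition(P0)
    t2 = pair.t2
    covered: set[int] = set()
    for comp in P3:
        covered |= t2.spanned_nodes(comp)

    for A0 in P0:
        Q = [C for C in P3 if C <= A0]
        if len(Q) <= 1:
            continue
        # (a) a bicolored component in Q: undo the two-way Special-Split
        bicolored = [C for C in Q if len(coloring.colors_of(C)) == 2]
        if bicolored:
            A_star = bicolored[0]
            partner = None
            for ev in special_events:
                if ev.kind == "two_way" and A_star <= ev.component:
                    partner = ev.component & coloring.R
                    break
            if partner is None:
                # standalone call without event history: find the red
                # sibling by testing the merge directly
                from .compat import is_K_feasible

                for C in sorted((C for C in Q if C <= coloring.R), key=min):
                    merged = [D for D in P3 if D not in (C, A_star)] + [C | A_star]
                    if is_K_feasible(pair, merged, coloring.RB):
                        partner = C
                        break
            if partner is None or partner not in Q:
                raise InternalConsistencyError(
                    "bicolored component after Split without a mergeable red sibling"
                )
            return (min(partner), min(A_star & coloring.RB))
        reds = [C for C in Q if C <= coloring.R]
        blues = [C for C in Q if C <= coloring.B]
        reach = {C: _reach_set(t2, C, covered) for C in reds + blues}
        # (b) two like-colored components meeting at some T2 node
        best = None
        for group in (reds, blues):
            for C, C2 in combinations(group, 2):
                if reach[C] & reach[C2]:
                    cand = tuple(sorted((min(C), min(C2))))
                    if best is None or cand < best:
                        best = cand
        if best is not None:
            return best
        # (c) a red and a blue component meeting at an uncovered node with a
        #     red/blue-free path up to lca2(A0)
        rb_cover: set[int] = set()
        for C in reds + blues:
            rb_cover |= t2.spanned_nodes(C)
        top0 = t2.lca(A0)
        for C in reds:
            for C2 in blues:
                common = (
                    (reach[C] & reach[C2])
                    - t2.spanned_nodes(C)
                    - t2.spanned_nodes(C2)
                )
                for u_hat in common:
                    if not t2.is_ancestor(top0, u_hat):
                        continue
                    path = t2.path_up(u_hat, top0)
                    if not (set(path) & rb_cover):
                        cand = tuple(sorted((min(C), min(C2))))
                        if best is None or cand < best:
                            best = cand
        if best is not None:
            return best
    return None


def merge_components(
    P_final: Iterable[frozenset[str]], pairslist: Sequence[tuple[str, str]]
) -> Partition:
    """The finest coarsening of P in which every listed pair shares a
    component; order-independent (plain union-find over components)."""
    comps = list(as_partition(P_final))
    owner: dict[str, int] = {}
    for i, comp in enumerate(comps):
        for lab in comp:
            owner[lab] = i
    parent = list(range(len(comps)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for x1, x2 in pairslist:
        if x1 not in owner or x2 not in owner:
            raise LabelError(f"merge pair ({x1!r},{x2!r}) not in the partition")
        a, b = find(owner[x1]), find(owner[x2])
        if a != b:
            parent[a] = b
    merged: dict[int, set[str]] = {}
    for i, comp in enumerate(comps):
        merged.setdefault(find(i), set()).update(comp)
    return as_partition(merged.values())


# -- the full algorithm ----------------------------------------------------


def run(pair: TreePair, check_invariants: bool = True) -> RunResult:
    """Run the Red-Blue algorithm and build its dual certificate.

    Returns the final feasible forest, the number of cuts (components minus
    one), per-iteration traces and the dual solution whose objective D
    satisfies cuts <= 2·D (checked, with the per-iteration version, when
    ``check_invariants``).
    """
    comps: list[frozenset[str]] = [pair.labels]
    dual = dualtrack.DualSolution.initial(pair)
    dual.sync_components(comps)
    traces: list[IterationTrace] = []
    pairslist: list[tuple[str, str]] = []

    iteration = 0
    while True:
        u = lowest_root_of_infeasibility(pair, comps)
        if u is None:
            break
        iteration += 1
        if iteration >= pair.n_leaves + 1:
            raise InternalConsistencyError(
                "iteration count reached the number of leaves", traces
            )
        coloring = make_coloring(pair, u)
        P0 = as_partition(comps)
        case_label, _ = classify_case(pair, P0, coloring)
        tops = {A for A in comps if len(coloring.colors_of(A)) >= 2}
        stars: list[int] = []

        _make_rb_compatible(pair, comps, tops, coloring, stars)
        P1 = as_partition(comps)
        tops_P1 = tuple(_sorted_components(tops))
        _make_splittable(pair, comps, tops, coloring, stars)
        P2 = as_partition(comps)
        tops_P2 = tuple(_sorted_components(tops))
        events = _split(pair, comps, tops, coloring, stars)
        P3 = as_partition(comps)

        merge_pair = find_merge_pair(pair, P3, coloring, P0, events)
        if merge_pair is not None:
            pairslist.append(merge_pair)

        dual.decrement(1, coloring.u)  # u = lca1(R∪B)
        for v in stars:
            dual.decrement(2, v)
        dual.sync_components(comps)

        delta_D = -(1 + len(stars)) + (len(P3) - len(P0))
        delta_P = (len(P3) - len(P0)) - (1 if merge_pair else 0)
        trace = IterationTrace(
            coloring=coloring,
            case_label=case_label,
            star_nodes=list(stars),
            special_split_events=events,
            P0=P0,
            P1=P1,
            P2=P2,
            P3=P3,
            tops_P1=tops_P1,
            tops_P2=tops_P2,
            merge_pair_found=merge_pair,
            delta_D=delta_D,
            delta_P=delta_P,
        )
        traces.append(trace)
        if check_invariants:
            if partition_overlaps_in(pair, comps, "V2"):
                raise InternalConsistencyError("partition overlaps in V2", traces)
            if 2 * delta_D < delta_P:
                raise InternalConsistencyError(
                    f"per-iteration certificate failed: 2*{delta_D} < {delta_P}", traces
                )

    pre_merge = as_partition(comps)
    forest = merge_components(pre_merge, pairslist)
    cuts = len(forest) - 1
    if check_invariants:
        D = dual.objective()
        if 2 * D < len(pre_merge) - 1 - len(pairslist):
            raise InternalConsistencyError("final dual certificate failed", traces)
    return RunResult(forest=forest, cuts=cuts, traces=traces, pairslist=pairslist, dual=dual)
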