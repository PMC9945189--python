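"""LP relaxations of MAF: the exponential set-partition LP and its compact
arborescence reformulation.

The exponential LP has a variable x_L for every compatible leaf set L,
partition constraints on leaves, packing constraints on internal nodes
(each internal node of either tree may be spanned by at most one chosen
set) and objective sum(x) - 1.  Solvable only by enumeration, so it is
restricted to small label sets.

The compact formulation encodes a compatible set L (|L| >= 2) as an
out-arborescence F(L) on the vertex set Z of label pairs (i1 <= i2): the
node (i1, i2) stands for the branching point whose two subtrees have i1 and
i2 as their minimum labels.  "Left" arcs U1 keep the first coordinate,
"right" arcs U2 chain the second coordinate into the first, and both must
descend strictly in BOTH trees -- that conjunction is exactly where
compatibility enters.  The cone generated by the arborescence indicator
vectors is cut out by flow-style constraints (out-degree balance between U1
and U2, out-flow at least in-flow), which yields a polynomial-size LP
equivalent to the exponential one.  Internal-node packing is expressed by
attributing to each arc (r, s) the tree path from lca(s) (inclusive) up to
lca(r) (exclusive), and the branching node lca(r) itself to r's root excess.

Both solvers run through scipy's HiGHS backend; a rational certification
pass (:func:`solve_lp_enumerated_exact`) turns the float solution of the
enumerated LP into an exact optimum for the integrality-gap fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse

from .compat import is_compatible
from .treeio import TreePair

__all__ = [
    "LPResult",
    "ArborGraph",
    "enumerate_compatible_sets",
    "solve_lp_enumerated",
    "solve_lp_enumerated_exact",
    "build_arbor_graph",
    "arborescence_of",
    "solve_compact_lp",
    "integrality_gap",
    "decompose_into_arborescences",
]

ENUM_CAP = 10
SOLVER_TOL = 1e-7


@dataclass
class LPResult:
    optimum: float
    solution: dict
    status: str
    model: Optional[dict] = field(default=None, repr=False)


def enumerate_compatible_sets(pair: TreePair, cap: int = ENUM_CAP) -> list[frozenset[str]]:
    """All nonempty compatible subsets of the label set, deterministic order."""
    labels = sorted(pair.labels)
    if len(labels) > cap:
        raise ValueError(
            f"{len(labels)} leaves exceeds the enumeration cap ({cap}); "
            "use the compact formulation instead"
        )
    out = []
    for k in range(1, len(labels) + 1):
        for A in combinations(labels, k):
            if is_compatible(pair, A):
                out.append(frozenset(A))
    return out


def _enumerated_model(pair: TreePair, cap: int):
    """(sets, c, A_eq, b_eq, A_ub, b_ub) of the enumerated LP."""
    sets = enumerate_compatible_sets(pair, cap)
    labels = sorted(pair.labels)
    lab_index = {lab: i for i, lab in enumerate(labels)}
    ncols = len(sets)
    A_eq = scipy.sparse.lil_matrix((len(labels), ncols))
    for j, L in enumerate(sets):
        for lab in L:
            A_eq[lab_index[lab], j] = 1.0
    rows = []
    for t in (1, 2):
        tree = pair.tree(t)
        internal = [v for v in tree.postorder if not tree.is_leaf(v)]
        node_row = {v: len(rows) + i for i, v in enumerate(internal)}
        rows.extend((t, v) for v in internal)
    A_ub = scipy.sparse.lil_matrix((len(rows), ncols))
    row_of = {key: i for i, key in enumerate(rows)}
    for j, L in enumerate(sets):
        for t in (1, 2):
            tree = pair.tree(t)
            for v in tree.spanned_nodes(L):
                if not tree.is_leaf(v):
                    A_ub[row_of[(t, v)], j] = 1.0
    c = np.ones(ncols)
    b_eq = np.ones(len(labels))
    b_ub = np.ones(len(rows))
    return sets, c, A_eq.tocsc(), b_eq, A_ub.tocsc(), b_ub


def solve_lp_enumerated(
    pair: TreePair, integral: bool = False, cap: int = ENUM_CAP + 2
) -> LPResult:
    """Optimum of the enumerated (LP), or of the set-partition ILP.

    The reported optimum is sum(x) - 1 (number of cuts); the integral
    variant equals the exact MAF optimum.
    """
    sets, c, A_eq, b_eq, A_ub, b_ub = _enumerated_model(pair, cap)
    if integral:
        constraints = [
            scipy.optimize.LinearConstraint(A_eq, b_eq, b_eq),
            scipy.optimize.LinearConstraint(A_ub, -np.inf, b_ub),
        ]
        res = scipy.optimize.milp(
            c,
            constraints=constraints,
            integrality=np.ones(len(c)),
            bounds=scipy.optimize.Bounds(0, 1),
        )
        if not res.success:
            raise RuntimeError(f"MILP solver failed: {res.message}")
        x = res.x
    else:
        res = scipy.optimize.linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, method="highs"
        )
        if not res.success:
            raise RuntimeError(f"LP solver failed: {res.message}")
        x = res.x
    solution = {L: float(v) for L, v in zip(sets, x) if v > SOLVER_TOL}
    return LPResult(optimum=float(res.fun) - 1.0, solution=solution, status="optimal")


# -- exact rational certification ------------------------------------------


def _rationalize(arr, max_den=10_000) -> list[Fraction]:
    out = []
    for v in np.atleast_1d(arr):
        f = Fraction(float(v)).limit_denominator(max_den)
        if abs(float(f) - float(v)) > 1e-6:
            raise ArithmeticError(f"cannot rationalize {v}")
        out.append(f)
    return out


def solve_lp_enumerated_exact(pair: TreePair, cap: int = ENUM_CAP + 2) -> Fraction:
    """Exact rational optimum of the enumerated LP.

    Solves with HiGHS, snaps the primal solution and the dual multipliers to
    small rationals, then verifies primal feasibility, dual feasibility and
    equality of the two objectives in exact arithmetic.  The matching pair
    of feasible solutions certifies optimality; any failure raises.
    """
    sets, c, A_eq, b_eq, A_ub, b_ub = _enumerated_model(pair, cap)
    res = scipy.optimize.linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, method="highs"
    )
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    x = _rationalize(res.x)
    lam = _rationalize(res.eqlin.marginals)
    mu = _rationalize(res.ineqlin.marginals)
    Aeq = A_eq.toarray().astype(int)
    Aub = A_ub.toarray().astype(int)
    ncols = len(x)
    if any(v < 0 for v in x):
        raise ArithmeticError("negative primal variable after rationalization")
    for i in range(Aeq.shape[0]):
        if sum(Fraction(int(Aeq[i, j])) * x[j] for j in range(ncols)) != 1:
            raise ArithmeticError("primal equality constraint violated")
    for i in range(Aub.shape[0]):
        if sum(Fraction(int(Aub[i, j])) * x[j] for j in range(ncols)) > 1:
            raise ArithmeticError("primal packing constraint violated")
    if any(m > 0 for m in mu):
        raise ArithmeticError("packing multiplier has the wrong sign")
    for j in range(ncols):
        reduced = (
            Fraction(1)
            - sum(lam[i] * int(Aeq[i, j]) for i in range(Aeq.shape[0]))
            - sum(mu[i] * int(Aub[i, j]) for i in range(Aub.shape[0]))
        )
        if reduced < 0:
            raise ArithmeticError("dual constraint violated")
    primal = sum(x) - 1
    dual = sum(lam) + sum(mu) - 1
    if primal != dual:
        raise ArithmeticError(f"primal {primal} != dual {dual}")
    return primal


# -- compact formulation ---------------------------------------------------


@dataclass
class ArborGraph:
    """The pair graph D: vertices Z (ordered label pairs), arcs U1/U2."""

    labels: list[str]  # sorted; positions are the integer leaf names
    Z: list[tuple[int, int]]  # (i1, i2) with i1 <= i2
    U1: list[tuple[tuple[int, int], tuple[int, int]]]
    U2: list[tuple[tuple[int, int], tuple[int, int]]]
    lca: dict[tuple[int, tuple[int, int]], int]  # (tree, pair-node) -> tree node

    @property
    def arcs(self):
        return self.U1 + self.U2

    def leaf_pairs(self):
        return [(i, i) for i in range(len(self.labels))]


def build_arbor_graph(pair: TreePair) -> ArborGraph:
    labels = sorted(pair.labels)
    n = len(labels)
    Z = [(i, j) for i in range(n) for j in range(i, n)]
    lca: dict[tuple[int, tuple[int, int]], int] = {}
    for t in (1, 2):
        tree = pair.tree(t)
        nodes = [tree.leaf_node(lab) for lab in labels]
        for (i, j) in Z:
            lca[(t, (i, j))] = tree.lca_nodes(nodes[i], nodes[j])
    U1, U2 = [], []
    for r in Z:
        i1, i2 = r
        if i1 == i2:
            continue  # leaf pairs have no outgoing arcs
        for s in Z:
            if s == r:
                continue
            ok = True
            for t in (1, 2):
                tree = pair.tree(t)
                lr, ls = lca[(t, r)], lca[(t, s)]
                if ls == lr or not tree.is_ancestor(lr, ls):
                    ok = False
                    break
            if not ok:
                continue
            j1, _ = s
            if j1 == i1:
                U1.append((r, s))
            elif j1 == i2:
                U2.append((r, s))
    return ArborGraph(labels=labels, Z=Z, U1=U1, U2=U2, lca=lca)


def arborescence_of(pair: TreePair, L: Iterable[str]) -> tuple[tuple, ...]:
    """F(L): the arc set of the arborescence encoding a compatible set L.

    Recursive rule: split L by the two subtrees below the root of T1[L];
    the node label is the pair of subtree minima (smaller first), with a
    left (U1) arc to the first-coordinate subtree and a right (U2) arc to
    the other.  Leaves are encoded as (i, i).  Arcs are returned as
    (kind, r, s) with kind in {1, 2}.
    """
    labels = sorted(pair.labels)
    index = {lab: i for i, lab in enumerate(labels)}
    t1 = pair.t1

    def rec(L: frozenset[str]):
        if len(L) == 1:
            i = index[next(iter(L))]
            return (i, i), ()
        top = t1.lca(L)
        left, right = t1.children[top]
        L1 = L & t1.leaves_below(left)
        L2 = L - L1
        i1, i2 = min(index[x] for x in L1), min(index[x] for x in L2)
        if i1 > i2:
            L1, L2 = L2, L1
            i1, i2 = i2, i1
        r1, arcs1 = rec(L1)
        r2, arcs2 = rec(L2)
        r = (i1, i2)
        return r, arcs1 + arcs2 + ((1, r, r1), (2, r, r2))

    _, arcs = rec(frozenset(L))
    return arcs


def _compact_model(pair: TreePair, graph: ArborGraph):
    arcs = graph.arcs
    arc_index = {(k + 1, a[0], a[1]): None for k, part in enumerate((graph.U1, graph.U2)) for a in part}
    cols: list[tuple] = []
    for a in graph.U1:
        cols.append((1, a[0], a[1]))
    for a in graph.U2:
        cols.append((2, a[0], a[1]))
    n = len(graph.labels)
    for i in range(n):
        cols.append(("xbar", i))
    col = {key: j for j, key in enumerate(cols)}
    ncols = len(cols)

    out1: dict[tuple, list] = {}
    out2: dict[tuple, list] = {}
    inc: dict[tuple, list] = {}
    for kind, part in ((1, graph.U1), (2, graph.U2)):
        for (r, s) in part:
            (out1 if kind == 1 else out2).setdefault(r, []).append(col[(kind, r, s)])
            inc.setdefault(s, []).append(col[(kind, r, s)])

    internal_pairs = [r for r in graph.Z if r[0] != r[1]]

    A_eq_rows, b_eq = [], []
    # out-degree balance at internal pair nodes
    for r in internal_pairs:
        row = np.zeros(ncols)
        for j in out1.get(r, []):
            row[j] += 1
        for j in out2.get(r, []):
            row[j] -= 1
        A_eq_rows.append(row)
        b_eq.append(0.0)
    # each leaf is covered exactly once (arc inflow at (i,i) plus singleton)
    for i in range(n):
        row = np.zeros(ncols)
        for j in inc.get((i, i), []):
            row[j] = 1
        row[col[("xbar", i)]] = 1
        A_eq_rows.append(row)
        b_eq.append(1.0)

    A_ub_rows, b_ub = [], []
    # in-flow bounded by out-flow (cone constraint)
    for r in internal_pairs:
        row = np.zeros(ncols)
        for j in inc.get(r, []):
            row[j] += 1
        for j in out1.get(r, []):
            row[j] -= 1
        A_ub_rows.append(row)
        b_ub.append(0.0)
    # internal-node occupancy in each tree
    excess_rows = {}  # r -> coefficient vector of its root excess
    for r in internal_pairs:
        row = np.zeros(ncols)
        for j in out1.get(r, []):
            row[j] += 1
        for j in inc.get(r, []):
            row[j] -= 1
        excess_rows[r] = row
    for t in (1, 2):
        tree = pair.tree(t)
        for v in tree.postorder:
            if tree.is_leaf(v):
                continue
            row = np.zeros(ncols)
            for kind, part in ((1, graph.U1), (2, graph.U2)):
                for (r, s) in part:
                    # half-open path: lca_t(s) inclusive up to lca_t(r) exclusive
                    node = graph.lca[(t, s)]
                    top = graph.lca[(t, r)]
                    while node != top:
                        if node == v:
                            row[col[(kind, r, s)]] += 1
                            break
                        node = tree.parent[node]
            for r in internal_pairs:
                if graph.lca[(t, r)] == v:
                    row += excess_rows[r]
            A_ub_rows.append(row)
            b_ub.append(1.0)

    c = np.zeros(ncols)
    for r in internal_pairs:
        c += excess_rows[r]
    for i in range(n):
        c[col[("xbar", i)]] = 1.0
    return cols, c, np.array(A_eq_rows), np.array(b_eq), np.array(A_ub_rows), np.array(b_ub)


def build_compact_lp(pair: TreePair, graph: Optional[ArborGraph] = None) -> dict:
    """The compact model as named matrices (columns, objective, equality
    and packing systems); mostly useful for inspection and debugging."""
    if graph is None:
        graph = build_arbor_graph(pair)
    cols, c, A_eq, b_eq, A_ub, b_ub = _compact_model(pair, graph)
    return {
        "columns": cols,
        "objective": c,
        "A_eq": A_eq,
        "b_eq": b_eq,
        "A_ub": A_ub,
        "b_ub": b_ub,
        "graph": graph,
    }


def solve_compact_lp(pair: TreePair) -> LPResult:
    """Optimum of the compact formulation (equals the enumerated LP)."""
    graph = build_arbor_graph(pair)
    cols, c, A_eq, b_eq, A_ub, b_ub = _compact_model(pair, graph)
    res = scipy.optimize.linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, method="highs"
    )
    if not res.success:
        raise RuntimeError(f"compact LP solver failed: {res.message}")
    solution = {key: float(v) for key, v in zip(cols, res.x) if abs(v) > SOLVER_TOL}
    return LPResult(optimum=float(res.fun) - 1.0, solution=solution, status="optimal")


def decompose_into_arborescences(graph: ArborGraph, y: dict, tol: float = 1e-9):
    """Greedy peeling of a cone-feasible y into arborescence indicators.

    Repeatedly picks a source pair node (positive out-flow, zero in-flow),
    extracts one arborescence inside the support and subtracts the largest
    feasible multiple.  Returns [(weight, arcs, leaf set)] whose weighted
    arc sum reproduces y; raises if peeling gets stuck (y not in the cone).
    """
    y = {a: v for a, v in y.items() if v > tol}

    def outflow(r, kind=None):
        return sum(
            v
            for (k, rr, ss), v in y.items()
            if rr == r and (kind is None or k == kind)
        )

    def inflow(r):
        return sum(v for (k, rr, ss), v in y.items() if ss == r)

    result = []
    while y:
        source = None
        for r in {rr for (_, rr, _) in y}:
            if inflow(r) <= tol and outflow(r) > tol:
                source = r
                break
        if source is None:
            raise ArithmeticError("peeling stuck: no source node in the support")

        arcs = []

        def grow(r):
            if r[0] == r[1]:
                return
            for kind in (1, 2):
                arc = next(
                    ((k, rr, ss) for (k, rr, ss) in y if rr == r and k == kind), None
                )
                if arc is None:
                    raise ArithmeticError("support is not closed under growth")
                arcs.append(arc)
                grow(arc[2])

        grow(source)
        eps = min(y[a] for a in arcs)
        leafset = frozenset(
            graph.labels[s[0]] for (_, _, s) in arcs if s[0] == s[1]
        )
        result.append((eps, tuple(arcs), leafset))
        for a in arcs:
            y[a] -= eps
            if y[a] <= tol:
                del y[a]
    return result


def dump_lp_text(pair: TreePair, which: str = "compact") -> str:
    """Serialize a model as CPLEX-LP-format text for debugging."""
    if which == "compact":
        graph = build_arbor_graph(pair)
        cols, c, A_eq, b_eq, A_ub, b_ub = _compact_model(pair, graph)
        names = []
        for key in cols:
            if key[0] == "xbar":
                names.append(f"xbar_{key[1]}")
            else:
                k, r, s = key
                names.append(f"y{k}_{r[0]}.{r[1]}__{s[0]}.{s[1]}")
        A_eq, A_ub = np.asarray(A_eq), np.asarray(A_ub)
    elif which == "enumerated":
        sets, c, A_eq, b_eq, A_ub, b_ub = _enumerated_model(pair, ENUM_CAP + 2)
        names = ["x_" + "_".join(sorted(L)) for L in sets]
        A_eq, A_ub = A_eq.toarray(), A_ub.toarray()
    else:
        raise ValueError("which must be 'compact' or 'enumerated'")

    def terms(row):
        return " + ".join(
            (f"{row[j]:g} {names[j]}" if row[j] != 1 else names[j])
            for j in range(len(names))
            if row[j]
        )

    lines = ["Minimize", " obj: " + terms(c) + " - 1", "Subject To"]
    for i in range(A_eq.shape[0]):
        lines.append(f" eq{i}: " + terms(A_eq[i]) + f" = {b_eq[i]:g}")
    for i in range(A_ub.shape[0]):
        lines.append(f" ub{i}: " + terms(A_ub[i]) + f" <= {b_ub[i]:g}")
    lines += ["Bounds", *(f" 0 <= {nm}" for nm in names), "End"]
    return "\n".join(lines)


def integrality_gap(pair: TreePair, method: str = "compact") -> float:
    """OPT divided by the LP optimum (1.0 when both vanish)."""
    from .oracle import exact_maf

    opt = exact_maf(pair).opt_cuts
    lp = (
        solve_compact_lp(pair).optimum
        if method == "compact"
        else solve_lp_enumerated(pair).optimum
    )
    if lp <= SOLVER_TOL:
        if opt != 0:
            raise ArithmeticError("LP optimum 0 with positive OPT")
        return 1.0
    return opt / lp
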