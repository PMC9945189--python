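"""Executable versions of the algorithm's structural guarantees.

Each checker raises AssertionError with context if a guarantee fails; the
test modules apply them across exhaustive and random instance sweeps.
"""

from itertools import combinations

from rbmaf.compat import is_feasible, partition_overlaps_in
from rbmaf.redblue import _tricolored_triple_status


def _colors(coloring, A):
    return coloring.colors_of(A)


def check_iteration(pair, trace):
    """Per-iteration guarantees: the multicolored-component census, the
    Make-Splittable bookkeeping, and the component/dual accounting
    identities that drive the certificate."""
    col = trace.coloring
    # refined census: one tricolored component xor at most two bicolored
    multi = [A for A in trace.P0 if len(_colors(col, A)) >= 2]
    tri0 = [A for A in multi if len(_colors(col, A)) == 3]
    assert multi, "an iteration must start with a multicolored component"
    if tri0:
        assert len(multi) == 1
    else:
        assert len(multi) <= 2
    # refinement chain and V2 invariant
    for earlier, later in ((trace.P0, trace.P1), (trace.P1, trace.P2), (trace.P2, trace.P3)):
        for A in later:
            assert any(A <= B for B in earlier), "stage did not refine the partition"
        assert not partition_overlaps_in(pair, later, "V2")
    # only multicolored components are subdivided
    for A in trace.P0:
        if A not in trace.P2:
            assert len(_colors(col, A)) >= 2
    # tricolored count preserved by Make-Splittable
    n_tri = lambda P: sum(1 for A in P if len(_colors(col, A)) == 3)
    assert n_tri(trace.P1) == n_tri(trace.P2)
    # non-top tricolored components hold no compatible tricolored triple
    for P, tops in ((trace.P1, trace.tops_P1), (trace.P2, trace.tops_P2)):
        for A in P:
            if len(_colors(col, A)) == 3 and A not in tops:
                assert not _tricolored_triple_status(pair, A, col)[0]
    # non-top bicolored components sit below an lca2 splitting their colors
    for A in trace.P2:
        if (
            len(_colors(col, A)) == 2
            and A not in trace.tops_P2
            and A not in trace.P0
        ):
            top = pair.t2.lca(A)
            for c in pair.t2.children[top]:
                assert len(_colors(col, A & pair.t2.leaves_below(c))) <= 1
    # white leaves above lca2(A ∩ (R∪B)) stay in a top component
    for A in trace.P0:
        if A in trace.P2:
            continue
        rb_part = A & col.RB
        below = pair.t2.leaves_below(pair.t2.lca(rb_part))
        for x in (A & col.W) - below:
            assert any(x in T for T in trace.tops_P2)
    # accounting identities behind the 2-approximation
    chi = 1 if any(ev.kind == "four_way" for ev in trace.special_split_events) else 0
    t_count = sum(
        1
        for A in trace.P2
        if len(_colors(col, A)) == 3 and A not in trace.tops_P2
    )
    d32 = len(trace.P3) - len(trace.P2)
    d20 = len(trace.P2) - len(trace.P0)
    if trace.case_label == "case1":
        assert d32 == d20 + 1 + 2 * chi + t_count
    else:
        assert chi == 0 and t_count == 0
        assert d32 == d20 + 2
    assert trace.delta_D == d32 - 1 - chi
    assert 2 * trace.delta_D >= trace.delta_P


def check_no_resplit(result):
    """Once an iteration ends, its red/blue leaves sharing a component are
    never separated again (including by the final merges)."""
    snapshots = [tr.P3 for tr in result.traces] + [result.forest]
    for i, tr in enumerate(result.traces):
        RB = tr.coloring.RB
        for A in tr.P3:
            part = A & RB
            if len(part) < 2:
                continue
            for later in snapshots[i + 1 :]:
                assert any(part <= C for C in later), "red/blue leaves were re-split"


def check_run(pair, result, opt=None):
    check_no_resplit(result)
    for tr in result.traces:
        check_iteration(pair, tr)
    assert len(result.traces) < max(pair.n_leaves, 2)
    assert is_feasible(pair, result.forest)
    D = result.dual.objective()
    assert 2 * D >= result.cuts
    if opt is not None:
        assert D <= opt
        if opt == 0:
            assert result.cuts == 0
        else:
            assert result.cuts <= 2 * opt


def spanned_oracle(tree, A):
    """Brute-force V[A]: union over leaf pairs of tree-path node sets."""
    A = list(A)
    if not A:
        return frozenset()
    if len(A) == 1:
        return frozenset((tree.leaf_node(A[0]),))
    nodes = set()
    for a, b in combinations(A, 2):
        va, vb = tree.leaf_node(a), tree.leaf_node(b)
        top = tree.lca_nodes(va, vb)
        nodes.update(tree.path_up(va, top))
        nodes.update(tree.path_up(vb, top))
    return frozenset(nodes)
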