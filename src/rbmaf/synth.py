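"""Instance generators and the worked-example fixtures.

``random_tree`` draws uniformly among labelled rooted binary topologies by
sequential leaf insertion (each topology corresponds to exactly one sequence
of insertion positions, so uniform position choices give the uniform
distribution).  ``random_spr_pair`` perturbs a random tree by k rooted
subtree-prune-and-regraft moves, which upper-bounds the rho-augmented MAF
optimum of the pair by k.

``worked_examples`` returns the small hand-checkable instances used across
the test-suite: the recurring seven-leaf red/blue/white example with the
partition states its procedures walk through, two five-leaf instances separating
the compatibility/feasibility notions, and a synthetic integrality-gap
instance whose exact OPT/LP ratio is 5/4 (found by exhaustive search over
small instances; see ``GAP_5_4_SYNTHETIC_T1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compat import as_partition
from .treeio import RootedBinaryTree, TreePair, augment_with_rho, parse_newick

__all__ = ["GenConfig", "random_tree", "random_spr_pair", "worked_examples"]


@dataclass(frozen=True)
class GenConfig:
    n_leaves: int
    seed: int
    k_spr: int = 0
    label_prefix: str = "t"

    def __post_init__(self):
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be at least 2")
        if self.k_spr < 0:
            raise ValueError("k_spr must be nonnegative")


def _random_nested(labels, rng) -> tuple:
    """Uniform labelled rooted binary topology via sequential insertion."""
    tree = labels[0]
    for lab in labels[1:]:
        positions = _count_positions(tree)
        tree = _insert_at(tree, lab, int(rng.integers(positions)))
    return tree


def _count_positions(nested) -> int:
    # one insertion position per edge, plus the root edge
    return 1 if isinstance(nested, str) else 1 + sum(map(_count_positions, nested))


def _insert_at(nested, lab, idx):
    """Insert on the idx-th edge in preorder (0 = above the current root)."""
    if idx == 0:
        return (nested, lab)
    idx -= 1
    left, right = nested
    nleft = _count_positions(left)
    if idx < nleft:
        return (_insert_at(left, lab, idx), right)
    return (left, _insert_at(right, lab, idx - nleft))


def random_tree(config: GenConfig, rng=None) -> RootedBinaryTree:
    """Uniformly random labelled rooted binary tree; a pure function of the
    config (seed included) unless an external generator is supplied."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = [f"{config.label_prefix}{i + 1}" for i in range(config.n_leaves)]
    return RootedBinaryTree(_random_nested(labels, rng))


# -- SPR moves -------------------------------------------------------------


def _all_paths(nested, path=()):
    yield path, nested
    if isinstance(nested, tuple):
        yield from _all_paths(nested[0], path + (0,))
        yield from _all_paths(nested[1], path + (1,))


def _get(nested, path):
    for i in path:
        nested = nested[i]
    return nested


def _replace(nested, path, sub):
    if not path:
        return sub
    left, right = nested
    if path[0] == 0:
        return (_replace(left, path[1:], sub), right)
    return (left, _replace(right, path[1:], sub))


def _prune(nested, path):
    """Remove the subtree at ``path``; its sibling is promoted in place.
    Returns (remainder, pruned_subtree, sibling_path_in_remainder)."""
    pruned = _get(nested, path)
    parent_path, side = path[:-1], path[-1]
    sibling = _get(nested, parent_path + (1 - side,))
    remainder = _replace(nested, parent_path, sibling)
    return remainder, pruned, parent_path


def _spr_once(nested, rng):
    """One uniformly random rooted SPR move; None if no move changes the tree."""
    prune_paths = [p for p, _ in _all_paths(nested) if p]
    rng.shuffle(prune_paths)
    for path in prune_paths:
        remainder, pruned, sibling_path = _prune(nested, path)
        if isinstance(remainder, str):
            continue  # remainder is a single leaf: regrafting cannot move anything
        # regraft targets: every edge of the remainder (path to a proper
        # subtree) plus the root edge, minus the position that undoes the prune
        targets = [p for p, _ in _all_paths(remainder)]
        targets = [p for p in targets if p != sibling_path]
        if not targets:
            continue
        tpath = targets[int(rng.integers(len(targets)))]
        target = _get(remainder, tpath)
        return _replace(remainder, tpath, (target, pruned))
    return None


def random_spr_pair(config: GenConfig) -> tuple[TreePair, int]:
    """A tree pair where T2 is T1 perturbed by up to k_spr SPR moves.

    Returns (pair, k_used); k_used < k_spr only when the tree is too small
    to admit a move.  The rho-augmented MAF optimum of the pair is at most
    k_used.
    """
    rng = np.random.default_rng(config.seed)
    labels = [f"{config.label_prefix}{i + 1}" for i in range(config.n_leaves)]
    t1_nested = _random_nested(labels, rng)
    t2_nested = t1_nested
    k_used = 0
    for _ in range(config.k_spr):
        moved = _spr_once(t2_nested, rng)
        if moved is None:
            break
        t2_nested = moved
        k_used += 1
    return (
        TreePair(RootedBinaryTree(t1_nested), RootedBinaryTree(t2_nested)),
        k_used,
    )


# -- worked-example fixtures -----------------------------------------------

# The recurring seven-leaf example: R1,R2 red, B1,B2 blue, W1,W2,W3 white
# under the coloring rooted at the node joining the blue and red cherries.
WORKED_EXAMPLE_T1 = "(((((B1,B2),(R1,R2)),W1),W2),W3);"
WORKED_EXAMPLE_T2 = "((((R1,B1),(B2,W1)),(R2,W2)),W3);"

# (R∪B)-compatible and non-overlapping, yet not (R∪B)-feasible.
NOT_RB_FEASIBLE_T1 = "(((B1,B2),R1),(W1,W2));"
NOT_RB_FEASIBLE_T2 = "(((B1,W1),(B2,W2)),R1);"

# Not L(u)-feasible although u is not a root of infeasibility
# (u is the node above {x1,x2,x3}).
SUBTLE_INFEASIBILITY_T1 = "(((x1,(x2,x3)),w1),w2);"
SUBTLE_INFEASIBILITY_T2 = "((x1,(w1,(x2,x3))),w2);"

# Synthetic integrality-gap instance (8 leaves, no rho): exact MAF optimum
# 5 while the LP relaxation attains 4, so OPT/LP = 5/4 exactly.  Found by
# exhaustively scanning caterpillar-T1 instances on 8 leaves after smaller
# exhaustive scans topped out at 6/5; the ratio is re-verified in rational
# arithmetic by the tests.
GAP_5_4_SYNTHETIC_T1 = "(((((((x0,x1),x2),x3),x4),x5),x6),x7);"
GAP_5_4_SYNTHETIC_T2 = "((((x0,x4),x3),(((x1,x5),x7),x6)),x2);"


def _pair(nw1: str, nw2: str) -> TreePair:
    return TreePair(parse_newick(nw1), parse_newick(nw2))


def worked_examples() -> dict:
    """Named instances and the partition states of the worked examples."""
    worked_pair = _pair(WORKED_EXAMPLE_T1, WORKED_EXAMPLE_T2)
    P = as_partition
    fixtures = {
        "worked_example": worked_pair,
        # the three partitions triggering conditions (a), (b), (c)
        "case_a_partition": P([{"B1", "B2", "R1", "R2", "W1", "W2", "W3"}]),
        "case_b_partition": P([{"B1"}, {"B2", "W1"}, {"R1", "R2", "W2", "W3"}]),
        "case_c_partition": P([{"R1"}, {"B1", "B2", "W1", "R2", "W2"}, {"W3"}]),
        # make_rb_compatible on {L} cuts at lca2(R1,B1)
        "rb_compat_input": P([{"B1", "B2", "R1", "R2", "W1", "W2", "W3"}]),
        "rb_compat_expected": P([{"B1", "R1"}, {"B2", "W1", "R2", "W2", "W3"}]),
        # make_splittable cuts {B1,B2,W1,R2,W2} at lca2(B2,W1)
        "splittable_input": P([{"R1"}, {"B1", "B2", "W1", "R2", "W2"}, {"W3"}]),
        "splittable_expected": P([{"R1"}, {"B2", "W1"}, {"B1", "R2", "W2"}, {"W3"}]),
        # split to singletons
        "plain_split_input": P([{"R1"}, {"B2", "W1"}, {"B1", "R2", "W2"}, {"W3"}]),
        "plain_split_expected": P(
            [{"R1"}, {"B2"}, {"W1"}, {"B1"}, {"R2"}, {"W2"}, {"W3"}]
        ),
        # four-way Special-Split replaces A = {B2,W1,R2,W2,W3} by these parts
        # (Split additionally cuts the bicolored {B1,R1} into singletons)
        "special_split_input": P([{"B1", "R1"}, {"B2", "W1", "R2", "W2", "W3"}]),
        "special_split_component": frozenset({"B2", "W1", "R2", "W2", "W3"}),
        "special_split_expected_parts": P([{"B2"}, {"R2"}, {"W1", "W2"}, {"W3"}]),
        "not_rb_feasible": _pair(NOT_RB_FEASIBLE_T1, NOT_RB_FEASIBLE_T2),
        "subtle_infeasibility": _pair(SUBTLE_INFEASIBILITY_T1, SUBTLE_INFEASIBILITY_T2),
    }
    if GAP_5_4_SYNTHETIC_T1 is not None:
        fixtures["gap_5_4"] = _pair(GAP_5_4_SYNTHETIC_T1, GAP_5_4_SYNTHETIC_T2)
    return fixtures
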