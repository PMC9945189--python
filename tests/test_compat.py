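from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_pair
from rbmaf.compat import (
    as_partition,
    covers,
    is_compatible,
    is_compatible_triples,
    is_feasible,
    is_K_compatible,
    is_K_feasible,
    is_splittable,
    overlap,
    partition_overlaps_in,
    triple_compatible,
)
from rbmaf.oracle import _induced_partition
from rbmaf.treeio import LabelError, TreePair, parse_newick


@pytest.fixture()
def abc_pair():
    return TreePair(parse_newick("((a,b),c);"), parse_newick("((a,c),b);"))


class TestTripleCompatibility:
    def test_identical_trees_all_compatible(self):
        t = parse_newick("((a,(b,c)),d);")
        pair = TreePair(t, t)
        for x, y, z in combinations(sorted(pair.labels), 3):
            assert triple_compatible(pair, x, y, z)

    def test_differing_cherry_incompatible(self, abc_pair):
        assert not triple_compatible(abc_pair, "a", "b", "c")

    def test_distinctness_required(self, abc_pair):
        with pytest.raises(LabelError):
            triple_compatible(abc_pair, "a", "a", "b")

    def test_worked_example_compatible_triples(self, worked_pair):
        assert triple_compatible(worked_pair, "R1", "R2", "W3")
        assert triple_compatible(worked_pair, "B1", "B2", "W3")


class TestIsCompatible:
    def test_small_sets_always_compatible(self, abc_pair):
        assert is_compatible(abc_pair, [])
        assert is_compatible(abc_pair, ["a"])
        assert is_compatible(abc_pair, ["a", "b"])

    def test_full_set_identical_trees(self):
        t = parse_newick("((a,(b,c)),d);")
        assert is_compatible(TreePair(t, t), {"a", "b", "c", "d"})

    def test_worked_example_case_c_witness(self, worked_pair):
        # the (c)-condition discussion at u's left child: {B1,B2} extended
        # by W2 stays compatible, while extending by W1 does not
        assert is_compatible(worked_pair, {"B1", "B2", "W2"})
        assert not is_compatible(worked_pair, {"B1", "B2", "W1"})
        # at u itself every extension of {B1,B2,R2} is incompatible
        assert not is_compatible(worked_pair, {"B1", "B2", "R2", "W1"})
        assert not is_compatible(worked_pair, {"B1", "B2", "R2", "W2"})

    @pytest.mark.parametrize("seed", range(6))
    def test_isomorphism_check_agrees_with_triples_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pair = random_pair(int(rng.integers(4, 9)), rng)
        labels = sorted(pair.labels)
        for k in range(3, len(labels) + 1):
            for A in combinations(labels, k):
                assert is_compatible(pair, A) == is_compatible_triples(pair, A)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_subsets_of_compatible_sets_are_compatible(self, seed):
        rng = np.random.default_rng(seed)
        pair = random_pair(int(rng.integers(4, 8)), rng)
        labels = sorted(pair.labels)
        compat = [
            frozenset(A)
            for k in range(3, len(labels) + 1)
            for A in combinations(labels, k)
            if is_compatible(pair, A)
        ]
        for L in compat[:50]:
            for drop in L:
                assert is_compatible(pair, L - {drop})


class TestCoverOverlap:
    def test_singleton_covers_its_leaf(self, abc_pair):
        leaf = abc_pair.t1.leaf_node("a")
        assert covers(abc_pair, {"a"}, leaf, 1)

    def test_empty_set_covers_nothing(self, abc_pair):
        assert not covers(abc_pair, set(), abc_pair.t1.root, 1)

    def test_path_covers_root(self, abc_pair):
        assert covers(abc_pair, {"a", "c"}, abc_pair.t1.root, 1)

    def test_disjoint_subtrees_do_not_overlap(self):
        t = parse_newick("((a,b),(c,d));")
        pair = TreePair(t, t)
        assert not overlap(pair, {"a", "b"}, {"c", "d"})

    def test_shared_leaf_overlaps(self, abc_pair):
        assert overlap(pair=abc_pair, A={"a", "b"}, A2={"a", "c"})

    def test_overlap_is_symmetric(self):
        rng = np.random.default_rng(3)
        pair = random_pair(6, rng)
        labels = sorted(pair.labels)
        for _ in range(30):
            A = frozenset(rng.choice(labels, size=int(rng.integers(1, 5)), replace=False))
            B = frozenset(rng.choice(labels, size=int(rng.integers(1, 5)), replace=False))
            for U in ("all", "V1", "V2"):
                assert overlap(pair, A, B, U) == overlap(pair, B, A, U)

    def test_teaching_instance_components_do_not_overlap_in_v2(self, fixtures):
        pair = fixtures["not_rb_feasible"]
        assert not overlap(pair, {"B1", "W1"}, {"B2", "W2", "R1"}, "V2")

    def test_partition_overlap_trivia(self, abc_pair):
        singles = [{x} for x in abc_pair.labels]
        assert not partition_overlaps_in(abc_pair, singles)
        assert not partition_overlaps_in(abc_pair, [abc_pair.labels])

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_deletion_partitions_never_overlap_in_v2(self, seed):
        """Deleting any edge subset of T2 yields a V2-non-overlapping
        partition; this is the invariant the algorithm maintains."""
        rng = np.random.default_rng(seed)
        pair = random_pair(7, rng)
        t2 = pair.t2
        edges = [v for v in t2.postorder if v != t2.root]
        swapped = TreePair(t2, pair.t1)  # partitions are read off t2
        for _ in range(20):
            k = int(rng.integers(0, len(edges)))
            cut = frozenset(rng.choice(edges, size=k, replace=False))
            P = _induced_partition(t2, cut)
            assert not partition_overlaps_in(swapped, P, "V1")
            assert not partition_overlaps_in(pair, P, "V2")


class TestKPredicates:
    def test_empty_K_always_compatible(self, abc_pair):
        assert is_K_compatible(abc_pair, [abc_pair.labels], [])

    def test_full_K_equals_componentwise_compatibility(self, abc_pair):
        P = [frozenset(abc_pair.labels)]
        assert is_K_compatible(abc_pair, P, abc_pair.labels) == all(
            is_compatible(abc_pair, c) for c in P
        )

    def test_first_cut_output_is_rb_compatible(self, worked_pair, worked_coloring):
        P = as_partition([{"B1", "R1"}, {"B2", "W1", "R2", "W2", "W3"}])
        assert is_K_compatible(worked_pair, P, worked_coloring.RB)

    def test_k_compatibility_preserved_under_refinement(self):
        rng = np.random.default_rng(11)
        pair = random_pair(6, rng)
        labels = sorted(pair.labels)
        K = frozenset(labels[:4])
        P = as_partition([labels[:3], labels[3:]])
        if is_K_compatible(pair, P, K):
            refined = as_partition([labels[:2], labels[2:3], labels[3:]])
            assert is_K_compatible(pair, refined, K)


class TestSplittable:
    def test_unicolored_vacuously_splittable(self, worked_pair, worked_coloring):
        assert is_splittable(worked_pair, {"W1", "W2"}, worked_coloring)

    def test_first_cut_output_already_splittable(self, worked_pair, worked_coloring):
        for comp in ({"B1", "R1"}, {"B2", "W1", "R2", "W2", "W3"}):
            assert is_splittable(worked_pair, comp, worked_coloring)

    def test_five_leaf_component_not_splittable(self, worked_pair, worked_coloring):
        assert not is_splittable(worked_pair, {"B1", "B2", "W1", "R2", "W2"}, worked_coloring)


class TestFeasibility:
    def test_singletons_always_feasible(self, abc_pair):
        assert is_feasible(abc_pair, [{x} for x in abc_pair.labels])

    def test_whole_set_feasible_iff_trees_agree(self, abc_pair):
        t = parse_newick("((a,b),c);")
        assert is_feasible(TreePair(t, t), [t.labels])
        assert not is_feasible(abc_pair, [abc_pair.labels])

    def test_L_feasible_equals_feasible(self):
        rng = np.random.default_rng(4)
        pair = random_pair(6, rng)
        labels = sorted(pair.labels)
        for P in ([{x} for x in labels], [labels[:3], labels[3:]]):
            P = as_partition(P)
            assert is_K_feasible(pair, P, pair.labels) == is_feasible(pair, P)

    def test_rb_compatible_but_not_rb_feasible_instance(self, fixtures):
        pair = fixtures["not_rb_feasible"]
        P = [pair.labels]
        K = frozenset({"R1", "B1", "B2"})
        assert is_K_compatible(pair, P, K)
        assert not partition_overlaps_in(pair, P)
        assert not is_K_feasible(pair, P, K)

    def test_not_Lu_feasible_yet_u_not_root_of_infeasibility(self, fixtures):
        pair = fixtures["subtle_infeasibility"]
        P = [pair.labels]
        K = frozenset({"x1", "x2", "x3"})
        assert is_K_compatible(pair, P, K)
        assert not is_K_feasible(pair, P, K)
        # u is nevertheless no root of infeasibility: w2 extends K compatibly
        from rbmaf.redblue import _is_root_of_infeasibility

        u = pair.t1.lca(K)
        assert pair.t1.leaves_below(u) == K
        assert not _is_root_of_infeasibility(pair, as_partition(P), u)
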