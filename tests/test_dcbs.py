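"""Candidate boundary selection: worked example, invariants, TTB baseline."""
import random

import pytest

from oracles import dcbs_oracle, depth_oracle
from hedgescope.dcbs import (Color, ancestors, label_candidates,
                             select_candidates, ttb_candidates)
from hedgescope.fixtures_synth import random_dep_tree
from hedgescope.types import DependencyTree, ScopeSpan


class TestAncestors:
    def test_worked_example_chain(self, s1):
        assert ancestors(s1.deptree, 10) == [9, 4, 3]

    def test_root_has_no_ancestors(self, s1):
        assert ancestors(s1.deptree, 3) == []

    def test_length_equals_depth_on_random_trees(self):
        for seed in range(50):
            tree = random_dep_tree(12, seed=seed, projective=bool(seed % 2))
            for v in range(1, 13):
                assert len(ancestors(tree, v)) == depth_oracle(tree, v)

    def test_out_of_range_raises(self, s1):
        with pytest.raises(IndexError):
            ancestors(s1.deptree, 99)


class TestWorkedExample:
    def test_l_candidates_are_10_and_16(self, s1):
        cs = select_candidates(s1.deptree, 10, "L",
                               punct_mask=s1.punct_mask())
        assert cs.candidates == (10, 16)

    def test_initialization_blackens_cue_and_ancestors(self, s1):
        cs = select_candidates(s1.deptree, 10, "L",
                               punct_mask=s1.punct_mask(), trace=True)
        init_black = {e.node for e in cs.trace
                      if e.phase == "init" and e.new is Color.BLACK}
        assert init_black == {3, 4, 9, 10}

    def test_node9_sweep_promotes_child_13(self, s1):
        cs = select_candidates(s1.deptree, 10, "L",
                               punct_mask=s1.punct_mask(), trace=True)
        promoted = [e.node for e in cs.trace
                    if e.phase == "sweep" and e.new is Color.BLACK
                    and e.by == 9]
        assert promoted == [13]

    def test_node9_sweep_greys_left_subtree(self, s1):
        cs = select_candidates(s1.deptree, 10, "L",
                               punct_mask=s1.punct_mask(), trace=True)
        greyed_by_9 = {e.node for e in cs.trace
                       if e.phase == "sweep" and e.new is Color.GREY
                       and e.by == 9}
        assert {5, 6, 7, 8} <= greyed_by_9

    def test_f_candidates_match_exhaustive_oracle(self, s1):
        cs = select_candidates(s1.deptree, 10, "F",
                               punct_mask=s1.punct_mask())
        oracle = dcbs_oracle(s1.deptree, 10, "F", s1.punct_mask(),
                             random.Random(1))
        assert cs.candidates == oracle == (1, 4, 5, 6, 7, 10)

    def test_single_token_sentence(self):
        tree = DependencyTree(1, {1: 0})
        for side in ("F", "L"):
            assert select_candidates(tree, 1, side).candidates == (1,)

    def test_cue_out_of_range_raises(self, s1):
        with pytest.raises(IndexError):
            select_candidates(s1.deptree, 0, "L")


class TestInvariants:
    """Cue persistence, side constraints, TTB subset, order independence."""

    @pytest.mark.parametrize("projective", [True, False])
    def test_random_tree_invariants(self, projective):
        rng = random.Random(99 + projective)
        for trial in range(500):
            n = rng.randint(1, 14)
            tree = random_dep_tree(n, seed=rng.randrange(2 ** 31),
                                   projective=projective)
            cue = rng.randint(1, n)
            for side in ("F", "L"):
                cs = select_candidates(tree, cue, side)
                assert cue in cs.candidates
                if side == "L":
                    assert all(c >= cue for c in cs.candidates)
                else:
                    assert all(c <= cue for c in cs.candidates)
                ttb = ttb_candidates(n, cue, side)
                assert set(cs.candidates) <= set(ttb.candidates)
                # order independence: shuffled worklists and the random
                # one-node-at-a-time oracle agree with the default order
                for k in range(2):
                    order = list(range(1, n + 1))
                    rng.shuffle(order)
                    alt = select_candidates(tree, cue, side,
                                            worklist_order=order)
                    assert alt.candidates == cs.candidates
                assert dcbs_oracle(tree, cue, side,
                                   rng=random.Random(trial)) == cs.candidates

    def test_projective_completeness_scope_boundaries_retained(self):
        # gold scope = interval spanned by the subtree of an ancestor of
        # the cue => both boundaries survive DCBS selection
        rng = random.Random(5)
        for _ in range(300):
            n = rng.randint(2, 14)
            tree = random_dep_tree(n, seed=rng.randrange(2 ** 31),
                                   projective=True)
            non_root = [v for v in range(1, n + 1) if tree.head[v] != 0]
            if not non_root:
                continue
            cue = rng.choice(non_root)
            anc = rng.choice(tree.ancestors(cue))
            sub = tree.subtree(anc)
            lo, hi = min(sub), max(sub)
            assert lo in select_candidates(tree, cue, "F").candidates
            assert hi in select_candidates(tree, cue, "L").candidates

    def test_punctuation_never_a_candidate(self, s1):
        cs = select_candidates(s1.deptree, 10, "L",
                               punct_mask=s1.punct_mask())
        assert 17 not in cs.candidates


class TestTTB:
    def test_l_side_definition(self):
        cs = ttb_candidates(17, 10, "L")
        assert cs.candidates == tuple(range(10, 18))
        assert len(cs) == 8

    def test_f_side_definition(self):
        assert len(ttb_candidates(17, 10, "F")) == 10


class TestLabeling:
    def test_sentence1_l_labels(self, s1):
        cs = select_candidates(s1.deptree, 10, "L",
                               punct_mask=s1.punct_mask())
        labeled, dropped = label_candidates(cs, ScopeSpan(5, 16))
        assert not dropped
        assert [(l.index, l.label) for l in labeled] == [(10, -1), (16, +1)]

    def test_missing_gold_sets_dropped_flag(self, s1):
        cs = select_candidates(s1.deptree, 10, "L",
                               punct_mask=s1.punct_mask())
        labeled, dropped = label_candidates(cs, ScopeSpan(5, 15))
        assert dropped and cs.dropped_gold
        assert all(l.label == -1 for l in labeled)

    def test_ttb_l_on_sentence1(self, s1):
        cs = ttb_candidates(17, 10, "L")
        labeled, dropped = label_candidates(cs, ScopeSpan(5, 16))
        assert not dropped
        assert sum(l.label == 1 for l in labeled) == 1
        assert sum(l.label == -1 for l in labeled) == 7
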