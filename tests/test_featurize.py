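"""Lexical vectors and phrase/dependency feature trees."""
import random

import pytest

from oracles import lca_oracle
from hedgescope.errors import AlignmentError, FeaturizationError
from hedgescope.featurize import (dependency_feature_tree,
                                  dependency_node_tree, featurize_candidate,
                                  lexical_features, phrase_feature_tree)
from hedgescope.fixtures_synth import random_dep_tree
from hedgescope.corpus_io import parse_inline, read_ptb
from hedgescope.types import DependencyTree, Sentence, Token


def feats(vec):
    return dict(item.split("=", 1) for item in vec.items)


class TestLexicalFeatures:
    def test_table_row_for_candidate_regulation(self, s1):
        d = feats(lexical_features(s1, 10, 16))
        assert d["CandidateToken(-1)"] == "hormonal"
        assert d["CandidateToken(-3)"] == "target"
        assert d["CandidateToken(1)"] == "."
        assert d["CandidateToken(2)"] == "null"
        assert d["CandidateStem(-2)"] == "for"
        assert d["CandidatePos(0)"] == "NN"
        assert d["CandidateChunk(-2)"] == "B-PP"
        assert d["HedgeToken(-3)"] == "DNA"
        assert d["HedgeStem(-2)"] == "deaminas"
        assert d["HedgeStem(-1)"] == "be"
        assert d["HedgePos(0)"] == "RB"
        assert d["HedgeChunk(3)"] == "I-NP"
        assert d["Distance"] == "6"

    def test_candidate_equal_to_cue_duplicates_windows(self, s1):
        d = feats(lexical_features(s1, 10, 10))
        assert d["Distance"] == "0"
        for what in ("Token", "Stem", "Pos", "Chunk"):
            for i in range(-3, 4):
                assert d[f"Candidate{what}({i})"] == d[f"Hedge{what}({i})"]

    def test_single_token_sentence_is_all_null_off_center(self):
        s = Sentence(tokens=[Token(1, "may", pos="MD")])
        d = feats(lexical_features(s, 1, 1))
        for i in (-3, -2, -1, 1, 2, 3):
            assert d[f"CandidateToken({i})"] == "null"
        assert d["CandidateToken(0)"] == "may"

    def test_always_exactly_57_features(self, s1):
        rng = random.Random(3)
        for _ in range(100):
            cue = rng.randint(1, 17)
            cand = rng.randint(1, 17)
            assert len(lexical_features(s1, cue, cand).items) == 57

    def test_distance_saturates_beyond_15(self):
        toks = [Token(i, f"w{i}") for i in range(1, 30)]
        s = Sentence(tokens=toks)
        assert "Distance=GT15" in lexical_features(s, 1, 29).items
        assert "Distance=15" in lexical_features(s, 1, 16).items


class TestPhraseFeatureTree:
    def test_siblings_under_one_np(self):
        pt = read_ptb("(NP (DT the) (JJ red) (NN cat))")[0]
        ft = phrase_feature_tree(pt, 1, 3)
        assert ft.label == "NP"
        assert [c.label for c in ft.children] == ["DT", "JJ", "NN"]

    def test_root_is_lca_of_kept_preterminals(self, s1):
        ft = phrase_feature_tree(s1.phrasetree, 10, 16)
        # independent check via the dependency-free leaf positions: map the
        # phrase tree to a DependencyTree-like parent table and intersect
        # ancestor paths of the kept pre-terminals
        pt = s1.phrasetree
        nodes = list(pt.root.iter_nodes())
        idx = {id(n): i + 1 for i, n in enumerate(nodes)}
        head = {idx[id(n)]: 0 for n in nodes}
        for n in nodes:
            for c in n.children:
                head[idx[id(c)]] = idx[id(n)]
        tree = DependencyTree(len(nodes), head)
        leaves = [n for n in nodes if n.is_leaf]
        keep = [9, 10, 11, 15, 16, 17]
        pre_ids = []
        for k in keep:
            leaf = leaves[k - 1]
            parent = next(n for n in nodes if leaf in n.children)
            pre_ids.append(idx[id(parent)])
        lca_node = nodes[lca_oracle(tree, pre_ids) - 1]
        assert ft.label == lca_node.label

    def test_kept_leaves_are_exactly_the_neighborhood(self, s1):
        ft = phrase_feature_tree(s1.phrasetree, 10, 16)
        leaves = [n.label for n in ft.iter_nodes() if not n.children]
        assert leaves == ["are", "potentially", "an", "hormonal",
                          "regulation", "."]

    def test_edge_candidate_shrinks_neighborhood(self):
        pt = read_ptb("(S (NP (DT the) (NN cat)) (VP (VBD sat)))")[0]
        ft = phrase_feature_tree(pt, 3, 3)
        leaves = [n.label for n in ft.iter_nodes() if not n.children]
        assert "null" not in leaves
        assert leaves == ["cat", "sat"]

    def test_is_connected_order_preserving_minor(self, s1):
        ft = phrase_feature_tree(s1.phrasetree, 9, 13)
        labels_in = [n.label for n in s1.phrasetree.root.iter_nodes()]
        for n in ft.iter_nodes():
            assert n.label in labels_in or not n.children

    def test_out_of_range_raises(self, s1):
        with pytest.raises(AlignmentError):
            phrase_feature_tree(s1.phrasetree, 10, 99)


class TestDependencyTrees:
    def test_node_tree_replaces_tokens_by_arc_labels(self):
        # "data <- indicate" with a SUB arc: node for token 1 labeled SUB
        tree = DependencyTree(2, {1: 2, 2: 0}, {1: "SUB", 2: "ROOT"})
        ft = dependency_node_tree(tree)
        assert ft.label == "ROOT"
        assert [c.label for c in ft.children] == ["SUB"]

    def test_single_node_tree(self):
        ft = dependency_node_tree(DependencyTree(1, {1: 0}))
        assert ft.label == "ROOT" and not ft.children

    def test_node_count_preserved(self, s1):
        ft = dependency_node_tree(s1.deptree)
        assert sum(1 for _ in ft.iter_nodes()) == 17

    def test_feature_tree_rooted_at_lca_label(self, s1):
        ft = dependency_feature_tree(s1.deptree, 10, 16)
        lca = lca_oracle(s1.deptree, [10, 16])
        assert lca == 9
        assert ft.label == s1.deptree.label[9]
        # cue-side chain first, then candidate-side chain to token 16
        assert len(ft.children) == 2
        assert ft.children[0].label == s1.deptree.label[10]

    def test_cue_ancestor_of_candidate_gives_single_chain(self):
        tree = DependencyTree(3, {1: 0, 2: 1, 3: 2},
                              {1: "ROOT", 2: "OBJ", 3: "NMOD"})
        ft = dependency_feature_tree(tree, 1, 3)
        assert ft.to_bracketed() == "(ROOT (OBJ NMOD))"

    def test_candidate_equal_cue_is_single_node(self, s1):
        ft = dependency_feature_tree(s1.deptree, 10, 10)
        assert not ft.children

    def test_deterministic_byte_identical(self, s1):
        a = dependency_feature_tree(s1.deptree, 10, 16).to_bracketed()
        b = dependency_feature_tree(s1.deptree, 10, 16).to_bracketed()
        assert a == b
        p1 = phrase_feature_tree(s1.phrasetree, 10, 16).to_bracketed()
        p2 = phrase_feature_tree(s1.phrasetree, 10, 16).to_bracketed()
        assert p1 == p2

    def test_lca_on_random_trees(self):
        rng = random.Random(17)
        for _ in range(100):
            n = rng.randint(2, 12)
            tree = random_dep_tree(n, seed=rng.randrange(2 ** 31))
            u, v = rng.randint(1, n), rng.randint(1, n)
            if u == v:
                continue
            ft = dependency_feature_tree(tree, u, v)
            lca = lca_oracle(tree, [u, v])
            expect = "ROOT" if tree.head[lca] == 0 else tree.label[lca]
            assert ft.label == expect


class TestFeaturizeCandidate:
    def test_missing_tree_raises_for_mode(self):
        s = parse_inline("<xscope><cue>may</cue> occur</xscope> .")
        with pytest.raises(FeaturizationError):
            featurize_candidate(s, 1, 2, "L", "dep_lexical")

    def test_instance_carries_required_views(self, s1):
        inst = featurize_candidate(s1, 10, 16, "L", "phrase_dep_lexical",
                                   label=1)
        inst.require("phrase_dep_lexical")
        assert inst.label == 1 and inst.candidate == 16
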