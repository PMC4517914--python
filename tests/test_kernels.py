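"""Tree / polynomial / composite kernels against brute-force enumeration."""
import math
import random

import numpy as np
import pytest

from oracles import brute_tree_kernel, random_feature_tree
from hedgescope.featurize import featurize_candidate
from hedgescope.kernels import (KernelParams, composite, cross_gram, delta,
                                gram_matrix, poly_kernel, tree_kernel)
from hedgescope.types import FeatureNode as N


def preterm(pos, word):
    return N(pos, (N(word),))


AB = N("A", (preterm("B", "b"), preterm("C", "c")))


class TestDelta:
    def test_equal_preterminals_give_lambda(self):
        t = preterm("NN", "regulation")
        assert delta(t, t, 0.4) == pytest.approx(0.4)

    def test_different_productions_give_zero(self):
        assert delta(preterm("NN", "a"), preterm("VB", "a"), 0.4) == 0.0

    def test_recursive_case(self):
        assert delta(AB, AB, 0.4) == pytest.approx(0.4 * 1.4 ** 2)


class TestTreeKernel:
    def test_small_tree_self_kernel(self):
        assert tree_kernel(AB, AB, 0.4) == pytest.approx(0.784 + 0.4 + 0.4)

    def test_disjoint_alphabets_give_zero(self):
        other = N("X", (preterm("Y", "y"),))
        assert tree_kernel(AB, other, 0.4) == 0.0

    def test_matches_brute_force_on_small_random_pairs(self):
        rng = random.Random(23)
        for _ in range(150):
            t1 = random_feature_tree(rng.randint(1, 7), rng)
            t2 = random_feature_tree(rng.randint(1, 7), rng)
            lam = rng.choice([0.2, 0.4, 0.7])
            assert tree_kernel(t1, t2, lam) == pytest.approx(
                brute_tree_kernel(t1, t2, lam), abs=1e-10)

    def test_symmetry_on_random_pairs(self):
        rng = random.Random(29)
        for _ in range(50):
            t1 = random_feature_tree(rng.randint(1, 9), rng)
            t2 = random_feature_tree(rng.randint(1, 9), rng)
            assert tree_kernel(t1, t2, 0.4) == pytest.approx(
                tree_kernel(t2, t1, 0.4))

    def test_monotone_in_lambda_with_common_production(self):
        vals = [tree_kernel(AB, AB, lam) for lam in (0.1, 0.3, 0.5, 0.9)]
        assert vals == sorted(vals)
        assert vals[0] < vals[-1]


class TestPolyKernel:
    def make_vec(self, s, cue, cand):
        from hedgescope.featurize import lexical_features
        return lexical_features(s, cue, cand)

    def test_identity_is_58_squared(self, s1):
        v = self.make_vec(s1, 10, 16)
        assert poly_kernel(v, v, 2) == (57 + 1) ** 2 == 3364

    def test_shared_count_formula(self, s1):
        a = self.make_vec(s1, 10, 16)
        b = self.make_vec(s1, 10, 13)
        shared = len(a.items & b.items)
        assert poly_kernel(a, b, 2) == (shared + 1) ** 2


@pytest.fixture(scope="module")
def instances(s1):
    return [featurize_candidate(s1, 10, c, "L", "phrase_dep_lexical")
            for c in (10, 13, 16)]


@pytest.fixture(scope="module")
def corpus_instances(small_corpus):
    from hedgescope.pipeline import build_side_instances
    si = build_side_instances(small_corpus[:10], "L", "dcbs",
                              "phrase_dep_lexical")
    return si.instances


class TestComposite:
    def test_gamma_zero_is_pure_polynomial(self, s1, instances):
        p = KernelParams(gamma_mix=0.0, mode="phrase_lexical")
        i, j = instances[1], instances[2]
        expect = poly_kernel(i.lexical, j.lexical, 2) / 3364
        assert composite(i, j, p) == pytest.approx(expect)

    def test_gamma_one_is_pure_normalized_tree(self, instances):
        p = KernelParams(gamma_mix=1.0, mode="phrase_lexical")
        i, j = instances[1], instances[2]
        kij = tree_kernel(i.phrase_ft, j.phrase_ft, p.lambda_decay)
        kii = tree_kernel(i.phrase_ft, i.phrase_ft, p.lambda_decay)
        kjj = tree_kernel(j.phrase_ft, j.phrase_ft, p.lambda_decay)
        assert composite(i, j, p) == pytest.approx(
            kij / math.sqrt(kii * kjj))

    def test_equal_tree_components_collapse_three_way_form(self, s1):
        # when K_phrase == K_dep the three-way mix equals the two-way mix
        inst = featurize_candidate(s1, 10, 16, "L", "phrase_dep_lexical")
        other = featurize_candidate(s1, 10, 13, "L", "phrase_dep_lexical")
        # force identical tree views
        other2 = type(other)(**{**other.__dict__,
                                "dep_ft": other.phrase_ft,
                                "phrase_ft": other.phrase_ft})
        inst2 = type(inst)(**{**inst.__dict__, "dep_ft": inst.phrase_ft})
        p3 = KernelParams(gamma_mix=0.5, mode="phrase_dep_lexical")
        p2 = KernelParams(gamma_mix=0.5, mode="phrase_lexical")
        assert composite(inst2, other2, p3) == pytest.approx(
            composite(inst2, other2, p2))

    def test_convex_combination_bounds(self, instances):
        for g in (0.0, 0.3, 0.7, 1.0):
            p = KernelParams(gamma_mix=g, mode="dep_lexical")
            i, j = instances[0], instances[2]
            kp = composite(i, j, KernelParams(gamma_mix=0.0,
                                              mode="dep_lexical"))
            kt = composite(i, j, KernelParams(gamma_mix=1.0,
                                              mode="dep_lexical"))
            val = composite(i, j, p)
            assert min(kp, kt) - 1e-12 <= val <= max(kp, kt) + 1e-12


class TestGramMatrix:
    def test_single_instance(self, s1):
        inst = featurize_candidate(s1, 10, 16, "L", "dep_lexical")
        K = gram_matrix([inst], KernelParams(mode="dep_lexical"))
        assert K.shape == (1, 1)

    def test_symmetric(self, corpus_instances):
        K = gram_matrix(corpus_instances, KernelParams())
        assert np.allclose(K, K.T, atol=1e-9)

    def test_near_psd(self, corpus_instances):
        K = gram_matrix(corpus_instances[:30], KernelParams())
        eigs = np.linalg.eigvalsh(K)
        assert eigs.min() >= -1e-8

    def test_agrees_with_pairwise_composite(self, corpus_instances):
        insts = corpus_instances[:8]
        p = KernelParams(gamma_mix=0.3)
        K = cross_gram(insts, insts, p)
        for i in range(len(insts)):
            for j in range(len(insts)):
                assert K[i, j] == pytest.approx(
                    composite(insts[i], insts[j], p), abs=1e-9)

    def test_unit_diagonal_when_normalized(self, corpus_instances):
        K = gram_matrix(corpus_instances[:10],
                        KernelParams(gamma_mix=1.0, mode="phrase_lexical"))
        # single-node trees have empty fragment sets (self-kernel 0); all
        # other diagonal entries must be exactly 1
        for i, inst in enumerate(corpus_instances[:10]):
            self_k = tree_kernel(inst.phrase_ft, inst.phrase_ft, 0.4)
            if self_k > 0:
                assert K[i, i] == pytest.approx(1.0)


def test_kernel_params_validation():
    with pytest.raises(ValueError):
        KernelParams(lambda_decay=1.5)
    with pytest.raises(ValueError):
        KernelParams(gamma_mix=-0.1)
    with pytest.raises(ValueError):
        KernelParams(degree=0)
    with pytest.raises(ValueError):
        KernelParams(mode="nope")
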