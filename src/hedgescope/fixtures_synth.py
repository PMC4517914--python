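"""Worked-example fixtures and seeded synthetic corpora.

Two hand-built sentences serve as executable worked examples:

* ``sentence1_fixture`` - "Our data indicate that the mutagenic DNA
  deaminases are potentially an important target for hormonal
  regulation ." (17 tokens, cue "potentially" at 10, scope 5..16).  The
  dependency arcs relevant to the candidate-selection walkthrough
  (ancestor chain 9-4-3 of the cue, the 8- and 13-subtrees under 9, the
  13-14-16 spine) are fixed by the published walkthrough; the remaining
  arc labels and the attributes of tokens 1..6 are plausible
  reconstructions and are flagged as such in ``Fixture.provenance``.
* ``sentence2_fixture`` - "Cells from these double mutant clones appeared
  to invade the brain , typically following fiber tracts , and sometimes
  induced the formation of trachea ." (cue "appeared" at 7, scope 1..16).
  Two tree variants exist: a ``corrected`` parse under which the L-scope
  token "tracts" (16) survives candidate selection, and a ``parse_error``
  variant in which a wrong attachment prunes it (a dropped positive).

The synthetic generator emulates the statistical shape of the task:
contiguous scopes containing the cue, projective dependency trees, and an
optional per-sentence parse-noise rate that reattaches one scope-internal
token outside the scope (the mechanism by which real parser errors drop
gold boundaries).
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Literal

from .errors import HedgescopeError
from .types import (CueAnnotation, DependencyTree, PhraseNode, PhraseTree,
                    ScopeSpan, Sentence, Token)


@dataclass
class Fixture:
    """A named worked-example sentence plus per-field provenance notes."""

    name: str
    sentence: Sentence
    provenance: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sentence 1

_S1_ROWS = [
    # surface, stem, pos, chunk           (1..6 reconstructed, 7..17 printed)
    ("Our", "our", "PRP$", "B-NP"),
    ("data", "data", "NNS", "I-NP"),
    ("indicate", "indicate", "VBP", "B-VP"),
    ("that", "that", "IN", "B-SBAR"),
    ("the", "the", "DT", "B-NP"),
    ("mutagenic", "mutagenic", "JJ", "I-NP"),
    ("DNA", "DNA", "NN", "I-NP"),
    ("deaminases", "deaminas", "NNS", "I-NP"),
    ("are", "be", "VBP", "B-VP"),
    ("potentially", "potentially", "RB", "B-ADVP"),
    ("an", "an", "DT", "B-NP"),
    ("important", "important", "JJ", "I-NP"),
    ("target", "target", "NN", "I-NP"),
    ("for", "for", "IN", "B-PP"),
    ("hormonal", "hormonal", "JJ", "B-NP"),
    ("regulation", "regulation", "NN", "I-NP"),
    (".", ".", ".", "O"),
]

_S1_HEADS = {1: 2, 2: 3, 3: 0, 4: 3, 5: 8, 6: 8, 7: 8, 8: 9, 9: 4,
             10: 9, 11: 13, 12: 13, 13: 9, 14: 13, 15: 16, 16: 14, 17: 3}

_S1_LABELS = {1: "NMOD", 2: "SUB", 3: "ROOT", 4: "VMOD", 5: "NMOD",
              6: "NMOD", 7: "NMOD", 8: "SUB", 9: "SBAR", 10: "ADV",
              11: "NMOD", 12: "NMOD", 13: "PRD", 14: "NMOD", 15: "NMOD",
              16: "PMOD", 17: "P"}

_S1_PTB = ("(S (NP (PRP$ Our) (NNS data)) "
           "(VP (VBP indicate) "
           "(SBAR (IN that) "
           "(S (NP (DT the) (JJ mutagenic) (NN DNA) (NNS deaminases)) "
           "(VP (VBP are) (ADVP (RB potentially)) "
           "(NP (NP (DT an) (JJ important) (NN target)) "
           "(PP (IN for) (NP (JJ hormonal) (NN regulation)))))))) "
           "(. .))")


def sentence1_fixture() -> Fixture:
    """The 17-token worked example with cue anchor 10 and scope (5, 16)."""
    from .corpus_io import read_ptb
    tokens = [Token(index=i, surface=s, stem=st, pos=p, chunk=c)
              for i, (s, st, p, c) in enumerate(_S1_ROWS, 1)]
    tree = DependencyTree(17, _S1_HEADS, _S1_LABELS)
    sent = Sentence(
        tokens=tokens,
        deptree=tree,
        phrasetree=read_ptb(_S1_PTB)[0],
        cues=[CueAnnotation((10,), anchor=10)],
        scopes={10: ScopeSpan(5, 16)},
        sent_id="sentence1",
    )
    return Fixture(
        name="sentence1",
        sentence=sent,
        provenance={
            "tokens[1..6]": "reconstructed",
            "tokens[7..17]": "printed lexical table",
            "arcs(ancestors of cue; 8/13 subtrees; 13-14-16 spine)":
                "fixed by the published walkthrough",
            "arc labels (except 2->3 SUB)": "reconstructed",
            "phrase tree": "reconstructed segment",
        },
    )


# ---------------------------------------------------------------------------
# Sentence 2

_S2_TEXT = ("Cells from these double mutant clones appeared to invade the "
            "brain , typically following fiber tracts , and sometimes "
            "induced the formation of trachea .")

_S2_POS = ["NNS", "IN", "DT", "JJ", "JJ", "NNS", "VBD", "TO", "VB", "DT",
           "NN", ",", "RB", "VBG", "NN", "NNS", ",", "CC", "RB", "VBD",
           "DT", "NN", "IN", "NN", "."]

# corrected parse: "tracts" heads up through "following" -> "invade"
_S2_HEADS_GOOD = {1: 7, 2: 1, 3: 6, 4: 6, 5: 6, 6: 2, 7: 0, 8: 7, 9: 8,
                  10: 11, 11: 9, 12: 9, 13: 14, 14: 9, 15: 16, 16: 14,
                  17: 7, 18: 7, 19: 20, 20: 7, 21: 22, 22: 20, 23: 22,
                  24: 23, 25: 7}

# parse error: "tracts" wrongly attached to the second conjunct "induced";
# its subtree is then eliminated during L-scope selection
_S2_HEADS_BAD = {**_S2_HEADS_GOOD, 16: 20}

_S2_LABELS = {1: "SUB", 2: "NMOD", 3: "NMOD", 4: "NMOD", 5: "NMOD",
              6: "PMOD", 7: "ROOT", 8: "VMOD", 9: "IM", 10: "NMOD",
              11: "OBJ", 12: "P", 13: "ADV", 14: "VMOD", 15: "NMOD",
              16: "OBJ", 17: "P", 18: "CC", 19: "ADV", 20: "COORD",
              21: "NMOD", 22: "OBJ", 23: "NMOD", 24: "PMOD", 25: "P"}

Variant = Literal["corrected", "parse_error"]


def sentence2_fixture(variant: Variant = "corrected") -> Fixture:
    """The dropped-positive example: cue "appeared" (7), scope (1, 16).

    ``corrected`` uses a parse under which token 16 ("tracts") is selected
    as an L-scope candidate; ``parse_error`` misattaches it so that it is
    pruned (dropped gold boundary).
    """
    if variant == "corrected":
        heads = _S2_HEADS_GOOD
    elif variant == "parse_error":
        heads = _S2_HEADS_BAD
    else:
        raise HedgescopeError(f"unknown sentence-2 variant {variant!r}")
    from .corpus_io import tokenize
    surfaces = tokenize(_S2_TEXT)
    tokens = [Token(index=i, surface=s, stem=s.lower(), pos=p,
                    chunk="O" if p in {",", "."} else "B-NP")
              for i, (s, p) in enumerate(zip(surfaces, _S2_POS), 1)]
    tree = DependencyTree(25, heads, _S2_LABELS)
    sent = Sentence(
        tokens=tokens,
        deptree=tree,
        cues=[CueAnnotation((7,), anchor=7)],
        scopes={7: ScopeSpan(1, 16)},
        sent_id=f"sentence2-{variant}",
    )
    return Fixture(
        name=f"sentence2-{variant}",
        sentence=sent,
        provenance={
            "tokens, cue, scope": "printed sentence and markup",
            "trees": ("reconstructed; constrained only by the stated "
                      "selected/dropped outcome for token 16"),
        },
    )


# ---------------------------------------------------------------------------
# Random trees

def random_dep_tree(n: int, seed: int, projective: bool = True,
                    labels: tuple[str, ...] = ("NMOD", "SUB", "OBJ", "VMOD",
                                               "PMOD", "ADV"),
                    ) -> DependencyTree:
    """A seeded random rooted tree over tokens 1..n.

    With ``projective=True`` the tree is built by recursive interval
    partition, so every subtree spans a contiguous token interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    head: dict[int, int] = {}

    if projective:
        def build(lo: int, hi: int, parent: int) -> None:
            if lo > hi:
                return
            r = rng.randint(lo, hi)
            head[r] = parent
            for a, b in ((lo, r - 1), (r + 1, hi)):
                start = a
                while start <= b:
                    end = rng.randint(start, b)
                    build(start, end, r)
                    start = end + 1
        build(1, n, 0)
    else:
        order = list(range(1, n + 1))
        rng.shuffle(order)
        head[order[0]] = 0
        for i, v in enumerate(order[1:], 1):
            head[v] = order[rng.randrange(i)]

    label = {v: (rng.choice(labels) if head[v] != 0 else "ROOT")
             for v in head}
    return DependencyTree(n, head, label)


# ---------------------------------------------------------------------------
# Synthetic corpora

_VOCAB = {
    "NN": ["gene", "protein", "cell", "pathway", "receptor", "enzyme",
           "tumor", "mutation", "domain", "signal", "tissue", "factor"],
    "VB": ["activate", "bind", "regulate", "inhibit", "encode", "express",
           "induce", "mediate"],
    "JJ": ["mutagenic", "important", "novel", "active", "distal", "human",
           "viral", "stable"],
    "RB": ["strongly", "rapidly", "directly", "partially", "typically",
           "widely"],
    "DT": ["the", "a", "this", "these"],
    "IN": ["of", "in", "for", "with", "by", "on"],
}

_CHUNK_OF_POS = {"NN": "B-NP", "VB": "B-VP", "JJ": "I-NP", "RB": "B-ADVP",
                 "DT": "B-NP", "IN": "B-PP"}

_CUE_LEXICON = [("may", "MD"), ("suggest", "VB"), ("possible", "JJ"),
                ("appeared", "VBD"), ("potentially", "RB"),
                ("indicate", "VB")]

# Clause-boundary markers flanking a scope, as in real hedged sentences
# ("indicate that <scope ...>", "<... tracts> , and"): complementizers and
# commas open a scope, punctuation and conjunctions close it.
_LEFT_MARKERS = [("that", "IN"), ("whether", "IN"), (",", ",")]
_RIGHT_MARKERS = [(",", ","), ("and", "CC"), (".", "."), (";", ":")]


@dataclass
class SynthParams:
    """Generator settings for seeded synthetic annotated corpora.

    Defaults are desk-scale study conditions: short sentences (6-14
    tokens) over a small POS-classed vocabulary so that lexical features
    are learnable, and a per-sentence parse-noise rate ``noise`` that
    reattaches one scope-internal token outside the scope subtree
    (``noise=0`` keeps trees projective with the scope equal to the
    subtree interval of the cue's parent).
    """

    n_sentences: int = 100
    min_len: int = 6
    max_len: int = 14
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise must be in [0, 1]")


def _right_branching_tree(tokens: list[Token]) -> PhraseTree:
    def build(i: int) -> PhraseNode:
        pre = PhraseNode(tokens[i].pos, (PhraseNode(tokens[i].surface),))
        if i == len(tokens) - 1:
            return PhraseNode("S", (pre,))
        return PhraseNode("S", (pre, build(i + 1)))
    return PhraseTree(build(0))


def synthetic_corpus(params: SynthParams) -> list[Sentence]:
    """Generate a fully annotated corpus, deterministic per seed.

    Per sentence: sample a projective tree, pick a non-root cue token from
    the cue lexicon, set the gold scope to the token interval spanned by
    the subtree of the cue's parent, and fill token attributes from the
    POS-classed vocabulary.  With probability ``noise`` one scope-internal
    token is reattached outside the scope (a simulated parse error which
    may drop a gold boundary from the candidate set).
    """
    rng = random.Random(params.seed)
    sentences: list[Sentence] = []
    for i in range(params.n_sentences):
        n = rng.randint(params.min_len, params.max_len)
        tree = random_dep_tree(n, seed=rng.randrange(2 ** 31), projective=True)
        non_root = [v for v in range(1, n + 1) if tree.head[v] != 0]
        cue_idx = rng.choice(non_root)
        parent = tree.head[cue_idx]
        sub = tree.subtree(parent)
        scope = ScopeSpan(min(sub), max(sub))

        tokens = []
        cue_surface, cue_pos = rng.choice(_CUE_LEXICON)
        markers: dict[int, tuple[str, str]] = {}
        if scope.first > 1:
            markers[scope.first - 1] = rng.choice(_LEFT_MARKERS)
        if scope.last < n:
            markers[scope.last + 1] = rng.choice(_RIGHT_MARKERS)
        for v in range(1, n + 1):
            if v == cue_idx:
                surface, pos = cue_surface, cue_pos
                chunk = "B-VP" if pos in {"VB", "VBD", "MD"} else \
                    _CHUNK_OF_POS.get(pos, "B-ADVP")
            elif v in markers:
                surface, pos = markers[v]
                chunk = "O" if pos in {",", ".", ":"} else "B-SBAR"
            else:
                pos = rng.choice(list(_VOCAB))
                surface = rng.choice(_VOCAB[pos])
                chunk = _CHUNK_OF_POS[pos]
            tokens.append(Token(index=v, surface=surface, stem=surface,
                                pos=pos, chunk=chunk))

        head = dict(tree.head)
        label = dict(tree.label)
        if rng.random() < params.noise:
            outside = [v for v in range(1, n + 1) if v not in scope]
            internal = [v for v in range(scope.first, scope.last + 1)
                        if v != cue_idx]
            if outside and internal:
                # bias toward the boundary tokens: that is where real
                # parser errors hurt candidate selection
                boundary = [v for v in (scope.first, scope.last)
                            if v != cue_idx]
                victim = (rng.choice(boundary)
                          if boundary and rng.random() < 0.5
                          else rng.choice(internal))
                head[victim] = rng.choice(outside)
                tree = DependencyTree(n, head, label)

        sent = Sentence(
            tokens=tokens,
            deptree=DependencyTree(n, head, label),
            phrasetree=_right_branching_tree(tokens),
            cues=[CueAnnotation((cue_idx,), anchor=cue_idx)],
            scopes={cue_idx: scope},
            sent_id=f"s{i}",
        )
        sentences.append(sent)
    return sentences
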