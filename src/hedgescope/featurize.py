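"""Feature extraction for candidate boundary instances.

Three views of a (cue, candidate) pair are built:

* a sparse binary **lexical vector**: 8 window templates
  (Candidate/Hedge x Token/Stem/Pos/Chunk) at offsets -3..3 plus a
  categorical token ``Distance`` - exactly 57 named features, with
  out-of-range window positions carrying the value ``"null"``;
* a **phrase feature tree**: the smallest connected subtree of the
  constituency parse containing the pre-terminals of the cue, the
  candidate, and their immediate neighbors, with all other leaves removed;
* a **dependency feature tree**: the arc-label path from the cue up to
  the lowest common ancestor and down to the candidate in the dependency
  node tree (the dependency tree with each token replaced by its incoming
  arc label).

The lexical vector feeds the polynomial kernel, the feature trees the
convolution tree kernel.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .errors import AlignmentError, FeaturizationError
from .types import (DependencyTree, FeatureNode, FeatureTree, PhraseNode,
                    PhraseTree, Sentence)

OFFSETS = (-3, -2, -1, 0, 1, 2, 3)
TEMPLATES = ("CandidateToken", "CandidateStem", "CandidatePos",
             "CandidateChunk", "HedgeToken", "HedgeStem", "HedgePos",
             "HedgeChunk")
NULL = "null"
DISTANCE_CAP = 15       # beyond this the categorical feature saturates

Mode = Literal["phrase_lexical", "dep_lexical", "phrase_dep_lexical"]
MODES = ("phrase_lexical", "dep_lexical", "phrase_dep_lexical")


@dataclass(frozen=True)
class LexicalVector:
    """Exactly 57 named binary features (``'Template(i)=value'`` strings)."""

    items: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.items) != len(TEMPLATES) * len(OFFSETS) + 1:
            raise FeaturizationError(
                f"lexical vector must have 57 features, got {len(self.items)}")

    def shared(self, other: "LexicalVector") -> int:
        return len(self.items & other.items)


def _attr(s: Sentence, index: int, what: str) -> str:
    if not (1 <= index <= s.n):
        return NULL
    tok = s.token(index)
    return {"Token": tok.surface, "Stem": tok.stem,
            "Pos": tok.pos, "Chunk": tok.chunk}[what]


def lexical_features(s: Sentence, cue_anchor: int, cand: int) -> LexicalVector:
    """Window + distance features for a candidate boundary token."""
    feats: set[str] = set()
    for template in TEMPLATES:
        center = cand if template.startswith("Candidate") else cue_anchor
        what = template.removeprefix("Candidate").removeprefix("Hedge")
        for i in OFFSETS:
            feats.add(f"{template}({i})={_attr(s, center + i, what)}")
    k = abs(cand - cue_anchor)
    feats.add(f"Distance={k}" if k <= DISTANCE_CAP else "Distance=GT15")
    return LexicalVector(frozenset(feats))


# ---------------------------------------------------------------------------
# Phrase feature tree

def _leaf_spans(node: PhraseNode, start: int = 1) -> dict[int, tuple[int, int]]:
    """Map id(node) -> (first, last) covered leaf index, 1-based."""
    spans: dict[int, tuple[int, int]] = {}

    def walk(nd: PhraseNode, lo: int) -> int:
        if nd.is_leaf:
            spans[id(nd)] = (lo, lo)
            return lo + 1
        cur = lo
        for c in nd.children:
            cur = walk(c, cur)
        spans[id(nd)] = (lo, cur - 1)
        return cur

    walk(node, start)
    return spans


def phrase_feature_tree(pt: PhraseTree, cue_anchor: int, cand: int,
                        ) -> FeatureTree:
    """Prune the phrase tree down to the cue/candidate neighborhood.

    Keeps the pre-terminals (and leaves) of ``{cue, cand, cue+-1, cand+-1}``
    clipped to the sentence, roots the result at their lowest common
    ancestor, and deletes every other leaf while preserving surviving
    labels and child order.
    """
    n = pt.n_leaves
    if not (1 <= cue_anchor <= n and 1 <= cand <= n):
        raise AlignmentError(
            f"cue {cue_anchor} / candidate {cand} outside 1..{n} leaves")
    keep = {i for base in (cue_anchor, cand) for i in (base - 1, base, base + 1)
            if 1 <= i <= n}
    spans = _leaf_spans(pt.root)

    def covered(nd: PhraseNode) -> set[int]:
        lo, hi = spans[id(nd)]
        return keep & set(range(lo, hi + 1))

    # descend to the lowest node still covering all kept leaves
    root = pt.root
    while True:
        kids = [c for c in root.children if covered(c)]
        if len(kids) == 1 and covered(kids[0]) == covered(root):
            root = kids[0]
        else:
            break

    def prune(nd: PhraseNode) -> Optional[FeatureNode]:
        if nd.is_leaf:
            return FeatureNode(nd.label)
        kids = tuple(p for c in nd.children
                     if covered(c) and (p := prune(c)) is not None)
        return FeatureNode(nd.label, kids)

    pruned = prune(root)
    assert pruned is not None
    return pruned


# ---------------------------------------------------------------------------
# Dependency feature trees

def dependency_node_tree(dt: DependencyTree) -> FeatureTree:
    """The dependency tree with each token replaced by its arc label.

    The root node is labeled ``ROOT``; children are ordered by token index.
    """
    def build(v: int) -> FeatureNode:
        label = "ROOT" if dt.head[v] == 0 else dt.label[v]
        return FeatureNode(label, tuple(build(c) for c in dt.children(v)))
    return build(dt.root)


def _node_label(dt: DependencyTree, v: int) -> str:
    return "ROOT" if dt.head[v] == 0 else dt.label[v]


def dependency_feature_tree(dt: DependencyTree, cue_anchor: int, cand: int,
                            ) -> FeatureTree:
    """Arc-label path cue -> LCA -> candidate as a small feature tree.

    Rooted at the LCA's label with two descending unary label chains (the
    cue-side chain first); degenerates to a single chain when one endpoint
    is an ancestor of the other, and to a single node when they coincide.
    """
    if cand == cue_anchor:
        return FeatureNode(_node_label(dt, cue_anchor))
    cue_chain = [cue_anchor] + dt.ancestors(cue_anchor)   # cue .. root
    cand_chain = [cand] + dt.ancestors(cand)
    cue_set = set(cue_chain)
    lca = next(v for v in cand_chain if v in cue_set)

    def chain_down(path_up: list[int]) -> Optional[FeatureNode]:
        """path_up = [endpoint, ..., lca]; build lca-excluded descending chain."""
        below = path_up[:path_up.index(lca)]
        node: Optional[FeatureNode] = None
        for v in below:        # endpoint first -> build bottom-up
            node = FeatureNode(_node_label(dt, v),
                               (node,) if node is not None else ())
        return node

    children = tuple(c for c in (chain_down(cue_chain), chain_down(cand_chain))
                     if c is not None)
    return FeatureNode(_node_label(dt, lca), children)


# ---------------------------------------------------------------------------
# Candidate instances

@dataclass
class CandidateInstance:
    """A featurized (cue, candidate boundary) classification instance."""

    sent_id: str
    cue_anchor: int
    candidate: int
    side: str
    lexical: LexicalVector
    phrase_ft: Optional[FeatureTree] = None
    dep_ft: Optional[FeatureTree] = None
    label: Optional[int] = None         # +1 / -1 for training instances

    def require(self, mode: Mode) -> None:
        if "phrase" in mode and self.phrase_ft is None:
            raise FeaturizationError(
                f"mode {mode} requires a phrase feature tree")
        if "dep" in mode and self.dep_ft is None:
            raise FeaturizationError(
                f"mode {mode} requires a dependency feature tree")


def featurize_candidate(s: Sentence, cue_anchor: int, cand: int, side: str,
                        mode: Mode, label: Optional[int] = None,
                        ) -> CandidateInstance:
    """Build all feature views a kernel mode needs for one candidate."""
    if mode not in MODES:
        raise FeaturizationError(f"unknown mode {mode!r}")
    phrase_ft = dep_ft = None
    if "phrase" in mode:
        if s.phrasetree is None:
            raise FeaturizationError(
                f"sentence {s.sent_id!r} has no phrase tree (mode {mode})")
        phrase_ft = phrase_feature_tree(s.phrasetree, cue_anchor, cand)
    if "dep" in mode:
        if s.deptree is None:
            raise FeaturizationError(
                f"sentence {s.sent_id!r} has no dependency tree (mode {mode})")
        dep_ft = dependency_feature_tree(s.deptree, cue_anchor, cand)
    return CandidateInstance(
        sent_id=s.sent_id, cue_anchor=cue_anchor, candidate=cand, side=side,
        lexical=lexical_features(s, cue_anchor, cand),
        phrase_ft=phrase_ft, dep_ft=dep_ft, label=label)
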