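"""Core data types shared across the package.

All token coordinates are 1-based inclusive intervals, matching the node
numbering convention used throughout the method: a scope span ``(5, 16)``
covers tokens 5..16 and always contains its hedge cue.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator, Mapping, Optional, Sequence

from .errors import AlignmentError, AnnotationError, TreeError

_CHUNK_RE = re.compile(r"^(?:(?:B|I)-[A-Z]+|O)$")
_PUNCT_POS = {".", ",", ":", "''", "``", "-LRB-", "-RRB-"}
_PUNCT_CHARS = set(".,;:?!()[]{}\"'`-")


def _looks_punct(surface: str, pos: str) -> bool:
    return pos in _PUNCT_POS or all(ch in _PUNCT_CHARS for ch in surface)


@dataclass
class Token:
    """One token with its shallow (tagger) annotation layers.

    ``stem`` is the tagger lemma, ``chunk`` a BIO shallow-phrase tag
    (``B-NP``/``I-NP``/.../``O``).  ``is_punct`` defaults from the POS tag
    and surface when not given explicitly.
    """

    index: int
    surface: str
    stem: str = ""
    pos: str = ""
    chunk: str = "O"
    is_punct: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"token index must be >= 1, got {self.index}")
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if not self.stem:
            self.stem = self.surface
        if not _CHUNK_RE.match(self.chunk):
            raise ValueError(f"bad chunk tag {self.chunk!r}")
        if self.is_punct is None:
            self.is_punct = _looks_punct(self.surface, self.pos)


@dataclass(frozen=True, order=True)
class ScopeSpan:
    """A contiguous scope as (F-scope, L-scope) token indices, inclusive."""

    first: int
    last: int

    def __post_init__(self) -> None:
        if not (1 <= self.first <= self.last):
            raise ValueError(f"invalid scope span ({self.first}, {self.last})")

    def __contains__(self, index: int) -> bool:
        return self.first <= index <= self.last

    def contains_span(self, other: "ScopeSpan") -> bool:
        return self.first <= other.first and other.last <= self.last


@dataclass(frozen=True)
class CueAnnotation:
    """A hedge cue: a contiguous token interval plus a single anchor token.

    All algorithms consume the anchor; for single-token cues (the common
    case) anchor == the one token.
    """

    token_indices: tuple[int, ...]
    anchor: int

    def __post_init__(self) -> None:
        idx = tuple(self.token_indices)
        if not idx or list(idx) != list(range(idx[0], idx[-1] + 1)):
            raise ValueError("cue token_indices must be a contiguous interval")
        if self.anchor not in idx:
            raise ValueError("cue anchor must lie inside token_indices")

    @property
    def span(self) -> ScopeSpan:
        return ScopeSpan(self.token_indices[0], self.token_indices[-1])


class DependencyTree:
    """A single-rooted dependency tree over tokens 1..n.

    ``head[v]`` is v's parent (0 for the root); ``label[v]`` the incoming
    arc label.  Supports the ancestor/subtree queries the candidate
    selection algorithm needs.
    """

    def __init__(self, n: int, head: Mapping[int, int],
                 label: Optional[Mapping[int, str]] = None) -> None:
        if n < 1:
            raise TreeError("tree must have at least one node")
        self.n = n
        self.head = {v: head[v] for v in range(1, n + 1)}
        self.label = {v: (label or {}).get(v, "DEP") for v in range(1, n + 1)}
        roots = [v for v, h in self.head.items() if h == 0]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for v, h in self.head.items():
            if h != 0 and not (1 <= h <= n):
                raise TreeError(f"node {v} has out-of-range head {h}")
        # acyclicity: walking up from every node must reach the root
        for v in range(1, n + 1):
            seen = set()
            while v != 0:
                if v in seen:
                    raise TreeError(f"cycle through node {v}")
                seen.add(v)
                v = self.head[v]

    @cached_property
    def _children(self) -> dict[int, tuple[int, ...]]:
        kids: dict[int, list[int]] = {v: [] for v in range(0, self.n + 1)}
        for v in range(1, self.n + 1):
            kids[self.head[v]].append(v)
        return {v: tuple(sorted(c)) for v, c in kids.items()}

    def children(self, v: int) -> tuple[int, ...]:
        return self._children[v]

    def parent(self, v: int) -> int:
        return self.head[v]

    def ancestors(self, v: int) -> list[int]:
        """Ancestor chain of v, nearest first, excluding v itself."""
        out = []
        v = self.head[v]
        while v != 0:
            out.append(v)
            v = self.head[v]
        return out

    def subtree(self, v: int) -> set[int]:
        """All nodes in the subtree rooted at v, including v."""
        out, stack = set(), [v]
        while stack:
            u = stack.pop()
            out.add(u)
            stack.extend(self._children[u])
        return out

    def is_projective(self) -> bool:
        return all(self._interval(v) for v in range(1, self.n + 1))

    def _interval(self, v: int) -> bool:
        sub = self.subtree(v)
        return sub == set(range(min(sub), max(sub) + 1))

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, DependencyTree)
                and self.n == other.n and self.head == other.head
                and self.label == other.label)

    def __repr__(self) -> str:
        return f"DependencyTree(n={self.n}, root={self.root})"


@dataclass(frozen=True)
class PhraseNode:
    """A node of a phrase-structure tree; leaves have no children."""

    label: str
    children: tuple["PhraseNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_preterminal(self) -> bool:
        return len(self.children) == 1 and self.children[0].is_leaf

    def leaves(self) -> list["PhraseNode"]:
        if self.is_leaf:
            return [self]
        out: list[PhraseNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def iter_nodes(self) -> Iterator["PhraseNode"]:
        yield self
        for c in self.children:
            yield from c.iter_nodes()


class PhraseTree:
    """A bracketed constituency parse whose leaves align with tokens 1..n."""

    def __init__(self, root: PhraseNode) -> None:
        self.root = root

    def leaves(self) -> list[PhraseNode]:
        return self.root.leaves()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def check_alignment(self, tokens: Sequence[Token]) -> None:
        if self.n_leaves != len(tokens):
            raise AlignmentError(
                f"phrase tree has {self.n_leaves} leaves but sentence has "
                f"{len(tokens)} tokens")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PhraseTree) and self.root == other.root


@dataclass(frozen=True)
class FeatureNode:
    """Node of an ordered labeled feature tree fed to the tree kernel."""

    label: str
    children: tuple["FeatureNode", ...] = ()

    def iter_nodes(self) -> Iterator["FeatureNode"]:
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    @property
    def production(self) -> tuple:
        return (self.label, tuple(c.label for c in self.children))

    def to_bracketed(self) -> str:
        if not self.children:
            return self.label
        inner = " ".join(c.to_bracketed() for c in self.children)
        return f"({self.label} {inner})"


# A FeatureTree is simply its root node; alias for readability.
FeatureTree = FeatureNode


@dataclass
class Sentence:
    """A fully annotated sentence: tokens, optional trees, cues and scopes.

    ``scopes`` maps each cue's anchor index to its gold scope span.
    """

    tokens: list[Token]
    deptree: Optional[DependencyTree] = None
    phrasetree: Optional[PhraseTree] = None
    cues: list[CueAnnotation] = field(default_factory=list)
    scopes: dict[int, ScopeSpan] = field(default_factory=dict)
    sent_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for pos, tok in enumerate(self.tokens, start=1):
            if tok.index != pos:
                raise AlignmentError(
                    f"token indices must be 1..n contiguous; token at "
                    f"position {pos} has index {tok.index}")
        n = len(self.tokens)
        for cue in self.cues:
            if cue.token_indices[-1] > n:
                raise AlignmentError("cue outside sentence")
            span = self.scopes.get(cue.anchor)
            if span is not None and not span.contains_span(cue.span):
                raise AnnotationError(
                    f"scope {span} does not contain its cue span {cue.span}")
        if self.deptree is not None and self.deptree.n != n:
            raise AlignmentError(
                f"dependency tree has {self.deptree.n} nodes for {n} tokens")
        if self.phrasetree is not None:
            self.phrasetree.check_alignment(self.tokens)

    @property
    def n(self) -> int:
        return len(self.tokens)

    def token(self, index: int) -> Token:
        return self.tokens[index - 1]

    def punct_mask(self) -> frozenset[int]:
        return frozenset(t.index for t in self.tokens if t.is_punct)

    def text(self) -> str:
        return " ".join(t.surface for t in self.tokens)
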