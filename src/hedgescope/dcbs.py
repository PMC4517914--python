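"""Dependency-based candidate boundary selection (DCBS).

Scope boundary classification normally treats every token on one side of
the hedge cue as a candidate (the traditional token-based scheme, TTB
here), which floods the classifier with negatives.  DCBS prunes that set
using the dependency tree: when two tokens stand in a dependency relation
they tend to fall inside the scope together, so only the token further
from the cue on the relevant side can be the boundary.

The pruning is a three-color fixpoint over tree nodes:

* WHITE  - undecided,
* BLACK  - current candidate,
* GREY   - eliminated (absorbing: a grey node is never recolored).

Initialization blackens the cue and its ancestor chain, greys punctuation,
whitens the rest.  Then, while some black node ``b`` has white children,
each white child ``c`` is compared with ``b`` by token index.  For L-scope
selection: ``c < b`` eliminates c's whole subtree; ``c > b`` promotes c to
black and demotes b to grey.  F-scope selection mirrors the comparison.
Finally, surviving black nodes on the wrong side of the cue are greyed and
the rest are the candidates.  The cue anchor is exempt from demotion so
that it is always itself a candidate.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .errors import HedgescopeError
from .types import DependencyTree, ScopeSpan

Side = Literal["F", "L"]


class Color(enum.Enum):
    WHITE = "white"
    BLACK = "black"
    GREY = "grey"


@dataclass(frozen=True)
class ColorEvent:
    """One recoloring step, for tracing/diagnostics.

    ``by`` is the black node whose child sweep caused the transition
    (None for initialization and the final wrong-side filter).
    """

    node: int
    old: Color
    new: Color
    phase: str          # "init" | "sweep" | "final"
    by: Optional[int] = None


@dataclass
class CandidateSet:
    """Sorted candidate boundary tokens for one cue and side."""

    side: Side
    cue_anchor: int
    candidates: tuple[int, ...]
    dropped_gold: bool = False
    trace: list[ColorEvent] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.cue_anchor not in self.candidates:
            raise HedgescopeError("cue anchor missing from candidate set")
        bad = [c for c in self.candidates
               if (self.side == "L" and c < self.cue_anchor)
               or (self.side == "F" and c > self.cue_anchor)]
        if bad:
            raise HedgescopeError(
                f"{self.side}-side candidates on wrong side of cue: {bad}")

    def __contains__(self, index: int) -> bool:
        return index in self.candidates

    def __len__(self) -> int:
        return len(self.candidates)


def ancestors(tree: DependencyTree, v: int) -> list[int]:
    """Ancestor chain of v (nearest first, root last, v excluded)."""
    if not (1 <= v <= tree.n):
        raise IndexError(f"node {v} out of range 1..{tree.n}")
    return tree.ancestors(v)


def _cueward(side: Side, child: int, black: int) -> bool:
    """True when the white child lies on the cue-ward (eliminate) side."""
    return child < black if side == "L" else child > black


def select_candidates(
        tree: DependencyTree,
        cue_anchor: int,
        side: Side,
        punct_mask: frozenset[int] = frozenset(),
        worklist_order: Optional[Sequence[int]] = None,
        trace: bool = False,
) -> CandidateSet:
    """Run the DCBS coloring fixpoint and return the candidate boundaries.

    ``worklist_order`` fixes the order in which eligible black nodes are
    swept (default ascending index); the final candidate set is
    order-independent, so this only matters for tracing.
    """
    if not (1 <= cue_anchor <= tree.n):
        raise IndexError(f"cue anchor {cue_anchor} out of range 1..{tree.n}")
    if side not in ("F", "L"):
        raise ValueError(f"side must be 'F' or 'L', got {side!r}")

    events: list[ColorEvent] = []
    color: dict[int, Color] = {v: Color.WHITE for v in range(1, tree.n + 1)}

    def recolor(v: int, new: Color, phase: str, by: Optional[int] = None) -> None:
        old = color[v]
        if old is new:
            return
        if old is Color.GREY:
            raise HedgescopeError(f"attempt to recolor grey node {v}")
        color[v] = new
        if trace:
            events.append(ColorEvent(v, old, new, phase, by))

    init_black = {cue_anchor, *tree.ancestors(cue_anchor)}
    for v in sorted(punct_mask):
        if v not in init_black:
            recolor(v, Color.GREY, "init")
    for v in sorted(init_black):
        recolor(v, Color.BLACK, "init")

    order = list(worklist_order) if worklist_order is not None \
        else list(range(1, tree.n + 1))

    changed = True
    while changed:
        changed = False
        for b in order:
            if color[b] is not Color.BLACK:
                continue
            whites = [c for c in tree.children(b)
                      if color[c] is Color.WHITE]
            if not whites:
                continue
            changed = True
            promoted = False
            # all comparisons in this sweep use b's index, even if b is
            # demoted part-way through
            for c in whites:
                if _cueward(side, c, b):
                    for u in sorted(tree.subtree(c)):
                        if color[u] is not Color.GREY:
                            recolor(u, Color.GREY, "sweep", by=b)
                else:
                    recolor(c, Color.BLACK, "sweep", by=b)
                    promoted = True
            if promoted and b != cue_anchor:
                recolor(b, Color.GREY, "sweep", by=b)

    for v in range(1, tree.n + 1):
        if color[v] is Color.BLACK and v != cue_anchor \
                and _cueward(side, v, cue_anchor):
            recolor(v, Color.GREY, "final")

    cands = tuple(sorted(v for v in color if color[v] is Color.BLACK))
    return CandidateSet(side=side, cue_anchor=cue_anchor, candidates=cands,
                        trace=events)


def ttb_candidates(n: int, cue_anchor: int, side: Side) -> CandidateSet:
    """Traditional token-based candidates: every token on the cue's side."""
    if not (1 <= cue_anchor <= n):
        raise IndexError(f"cue anchor {cue_anchor} out of range 1..{n}")
    if side == "F":
        cands = tuple(range(1, cue_anchor + 1))
    elif side == "L":
        cands = tuple(range(cue_anchor, n + 1))
    else:
        raise ValueError(f"side must be 'F' or 'L', got {side!r}")
    return CandidateSet(side=side, cue_anchor=cue_anchor, candidates=cands)


@dataclass(frozen=True)
class LabeledCandidate:
    index: int
    label: int          # +1 boundary, -1 not


def label_candidates(
        cands: CandidateSet, gold: ScopeSpan,
) -> tuple[list[LabeledCandidate], bool]:
    """Label candidates against the gold boundary for the set's side.

    The gold boundary (scope first token for side F, last for side L) is
    the sole positive; every other candidate is a negative.  When the gold
    boundary was pruned away, no positive is emitted and the dropped flag
    is returned true (the classifier can then never recover it: a
    structural false negative).
    """
    boundary = gold.first if cands.side == "F" else gold.last
    labeled = [LabeledCandidate(i, +1 if i == boundary else -1)
               for i in cands.candidates]
    dropped = boundary not in cands.candidates
    if dropped:
        cands.dropped_gold = True
    return labeled, dropped
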