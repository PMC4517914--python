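"""Rule-based resolution of boundary hits into one contiguous scope per cue.

The classifiers emit independent per-token F-scope and L-scope decisions;
these rules convert them into a single contiguous span that always
contains the cue:

1. one F hit and one L hit: span = (F, L);
2. one F hit, several L hits: span = (F, last L);
3. several F hits, one L hit: span = (first F, L);
4. F hits only: span runs to the last token of the sentence;
5. L hits only: span starts at the hedge cue;
6. a passive-voice hedge starts its scope at the subject of the hedge;
7. the hedge "or" spans the whole parallel structure it coordinates.

Two cases the rules leave open are closed deterministically: several hits
on both sides compose rules 2+3 (first F, last L), and no hits at all
fall back to (cue, last token) so that every cue receives exactly one
scope.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import HedgescopeError
from .types import CueAnnotation, ScopeSpan, Sentence

_SUBJECT_LABELS = {"SUB", "SBJ", "SUBJ", "NSUBJ", "NSUBJPASS"}
_AUX_STEMS = {"be", "get"}


@dataclass(frozen=True)
class BoundaryHits:
    """Sorted token indices classified as F-scope / L-scope boundaries."""

    f_hits: tuple[int, ...] = ()
    l_hits: tuple[int, ...] = ()

    def check_sides(self, cue_anchor: int) -> None:
        if any(v > cue_anchor for v in self.f_hits):
            raise HedgescopeError("F hit right of the cue")
        if any(v < cue_anchor for v in self.l_hits):
            raise HedgescopeError("L hit left of the cue")


def resolve_scope(hits: BoundaryHits, cue: CueAnnotation,
                  s: Sentence) -> ScopeSpan:
    """Apply rules 1-5 (plus the two fallbacks); total over all inputs."""
    f, l = sorted(hits.f_hits), sorted(hits.l_hits)
    n = s.n
    if f and l:
        span = (f[0], l[-1])
    elif f:
        span = (f[0], n)
    elif l:
        span = (cue.anchor, l[-1])
    else:
        span = (cue.anchor, n)
    first = min(span[0], cue.token_indices[0])
    last = max(span[1], cue.token_indices[-1])
    return ScopeSpan(first, last)


def _subtree_span(s: Sentence, v: int) -> tuple[int, int]:
    sub = s.deptree.subtree(v)
    return min(sub), max(sub)


def apply_syntactic_overrides(span: ScopeSpan, cue: CueAnnotation,
                              s: Sentence) -> ScopeSpan:
    """Rules 6-7; identity when no dependency tree is attached.

    Passive hedge (POS VBN with a be/get auxiliary on its head chain):
    the scope starts at the leftmost token of the auxiliary's subject
    subtree.  Hedge "or": the scope covers the subtree of the
    coordination head (the cue's parent), i.e. the whole parallel
    structure.
    """
    if s.deptree is None:
        return span
    tree = s.deptree
    anchor = cue.anchor
    tok = s.token(anchor)

    if tok.surface.lower() == "or":
        head = tree.head[anchor]
        coord = head if head != 0 else anchor
        lo, hi = _subtree_span(s, coord)
        return ScopeSpan(min(lo, cue.token_indices[0]),
                         max(hi, cue.token_indices[-1]))

    if tok.pos == "VBN":
        aux = next((a for a in tree.ancestors(anchor)
                    if s.token(a).stem.lower() in _AUX_STEMS), None)
        if aux is not None:
            subject = next(
                (c for c in tree.children(aux)
                 if tree.label[c].upper() in _SUBJECT_LABELS), None)
            if subject is not None:
                lo, _ = _subtree_span(s, subject)
                if lo < span.first:
                    return ScopeSpan(lo, span.last)
    return span


def resolve(hits: BoundaryHits, cue: CueAnnotation, s: Sentence,
            syntactic_overrides: bool = True,
            trim_final_punct: bool = False) -> ScopeSpan:
    """Full postprocessing: rules 1-5, then 6-7, then optional punct trim.

    ``trim_final_punct`` shrinks a span ending in sentence-final
    punctuation (rule 4 taken literally includes it; corpora following
    the BioScope convention exclude it).
    """
    span = resolve_scope(hits, cue, s)
    if syntactic_overrides:
        span = apply_syntactic_overrides(span, cue, s)
    if trim_final_punct:
        last = span.last
        while last > cue.token_indices[-1] and s.token(last).is_punct:
            last -= 1
        span = ScopeSpan(span.first, last)
    return span
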