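"""Readers and writers for the corpus formats the system consumes.

Supported formats:

* inline-tagged sentences (``<xscope>``/``<cue>`` markup around plain text),
* CoNLL-X dependency blocks (10 columns; a lenient 3/4-column mini-dialect
  is accepted for hand-written fixtures),
* Penn-bracketed phrase trees,
* 4-column tagger TSV (surface, stem, POS, BIO chunk),
* the prediction TSV emitted by the pipeline.

Every coordinate read or written is a 1-based inclusive token index.
Tokenization of inline text is whitespace splitting with terminal
punctuation (``.,;:?!``) detached as separate trailing tokens, which is
what the worked examples' token numbering assumes.
"""
from __future__ import annotations

import io
import re
from typing import Iterable, Optional, Sequence, TextIO, Union

from .errors import (AlignmentError, AnnotationError, FormatError, TreeError)
from .types import (CueAnnotation, DependencyTree, PhraseNode, PhraseTree,
                    ScopeSpan, Sentence, Token)

_TAG_RE = re.compile(r"</?\s*(?:xscope|cue)\s*>")
_TRAILING_PUNCT = set(".,;:?!")

TaggerRow = tuple[str, str, str, str]


def _as_stream(stream: Union[str, TextIO]) -> TextIO:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def tokenize(text: str) -> list[str]:
    """Whitespace-split, then detach terminal punctuation as own tokens."""
    out: list[str] = []
    for chunk in text.split():
        trailing: list[str] = []
        while len(chunk) > 1 and chunk[-1] in _TRAILING_PUNCT:
            trailing.append(chunk[-1])
            chunk = chunk[:-1]
        out.append(chunk)
        out.extend(reversed(trailing))
    return out


def parse_inline(text: str, sent_id: str = "") -> Sentence:
    """Parse one inline-tagged sentence into tokens, cues and scopes.

    Tags must be well-nested; each ``<xscope>`` must contain at least one
    cue.  Raises :class:`FormatError` on unbalanced tags and
    :class:`AnnotationError` when a cue falls outside every scope while
    scopes are present.
    """
    pos = 0
    n_tokens = 0
    tokens: list[Token] = []
    open_scopes: list[int] = []        # start token index of open xscopes
    open_cue: Optional[int] = None
    scopes: list[ScopeSpan] = []
    cues: list[CueAnnotation] = []

    def emit(segment: str) -> None:
        nonlocal n_tokens
        for surface in tokenize(segment):
            n_tokens += 1
            tokens.append(Token(index=n_tokens, surface=surface))

    for m in _TAG_RE.finditer(text):
        emit(text[pos:m.start()])
        tag = re.sub(r"\s+", "", m.group(0))
        if tag == "<xscope>":
            open_scopes.append(n_tokens + 1)
        elif tag == "</xscope>":
            if not open_scopes:
                raise FormatError("unbalanced </xscope>")
            start = open_scopes.pop()
            if n_tokens < start:
                raise FormatError("empty <xscope> element")
            scopes.append(ScopeSpan(start, n_tokens))
        elif tag == "<cue>":
            if open_cue is not None:
                raise FormatError("nested <cue> tags")
            open_cue = n_tokens + 1
        else:  # </cue>
            if open_cue is None:
                raise FormatError("unbalanced </cue>")
            if n_tokens < open_cue:
                raise FormatError("empty <cue> element")
            indices = tuple(range(open_cue, n_tokens + 1))
            cues.append(CueAnnotation(indices, anchor=indices[0]))
            open_cue = None
        pos = m.end()
    emit(text[pos:])

    if open_scopes:
        raise FormatError("unbalanced <xscope>")
    if open_cue is not None:
        raise FormatError("unbalanced <cue>")

    scope_map: dict[int, ScopeSpan] = {}
    for cue in cues:
        # innermost (smallest) scope containing the cue
        enclosing = [s for s in scopes if s.contains_span(cue.span)]
        if not enclosing:
            if scopes:
                raise AnnotationError(
                    f"cue at {cue.span} lies outside every scope")
            continue
        scope_map[cue.anchor] = min(
            enclosing, key=lambda s: s.last - s.first)
    return Sentence(tokens=tokens, cues=cues, scopes=scope_map,
                    sent_id=sent_id)


def anchor_cue(cue: CueAnnotation, tree: DependencyTree) -> CueAnnotation:
    """Re-anchor a (possibly multi-token) cue at its syntactic head.

    The anchor is the cue token whose dependency head lies outside the cue
    span; ties broken leftmost.
    """
    span = set(cue.token_indices)
    heads_out = [v for v in cue.token_indices if tree.head[v] not in span]
    anchor = min(heads_out) if heads_out else cue.token_indices[0]
    return CueAnnotation(cue.token_indices, anchor=anchor)


# ---------------------------------------------------------------------------
# CoNLL-X

def _conllx_block_to_tree(rows: list[list[str]], ordinal: int) -> DependencyTree:
    head: dict[int, int] = {}
    label: dict[int, str] = {}
    for cols in rows:
        try:
            idx = int(cols[0])
        except ValueError as exc:
            raise FormatError(
                f"sentence {ordinal}: bad token id {cols[0]!r}") from exc
        if len(cols) >= 8:
            h, rel = cols[6], cols[7]
        elif len(cols) == 4:
            h, rel = cols[2], cols[3]
        elif len(cols) == 3:
            h, rel = cols[2], "DEP"
        else:
            raise FormatError(
                f"sentence {ordinal}: row with {len(cols)} columns")
        try:
            head[idx] = int(h)
        except ValueError as exc:
            raise FormatError(
                f"sentence {ordinal}: bad head {h!r}") from exc
        label[idx] = rel
    n = len(rows)
    if sorted(head) != list(range(1, n + 1)):
        raise TreeError(f"sentence {ordinal}: token ids are not 1..{n}")
    try:
        return DependencyTree(n, head, label)
    except TreeError as exc:
        raise TreeError(f"sentence {ordinal}: {exc}") from exc


def _split_blocks(stream: TextIO) -> list[list[list[str]]]:
    blocks: list[list[list[str]]] = []
    current: list[list[str]] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
            continue
        current.append(line.split("\t") if "\t" in line else line.split())
    if current:
        blocks.append(current)
    return blocks


def read_conllx(stream: Union[str, TextIO]) -> list[DependencyTree]:
    """Read blank-line-separated CoNLL-X blocks into dependency trees."""
    return [
        _conllx_block_to_tree(rows, ordinal)
        for ordinal, rows in enumerate(_split_blocks(_as_stream(stream)), 1)
    ]


def read_conllx_with_rows(
        stream: Union[str, TextIO],
) -> list[tuple[DependencyTree, list[list[str]]]]:
    """Like :func:`read_conllx` but keeps the raw rows (for FORM/LEMMA/POS)."""
    blocks = _split_blocks(_as_stream(stream))
    return [(_conllx_block_to_tree(rows, i), rows)
            for i, rows in enumerate(blocks, 1)]


def write_conllx(stream: TextIO, sentences: Iterable[Sentence]) -> None:
    for s in sentences:
        if s.deptree is None:
            raise TreeError(f"sentence {s.sent_id!r} has no dependency tree")
        for tok in s.tokens:
            cols = [str(tok.index), tok.surface, tok.stem, tok.pos, tok.pos,
                    "_", str(s.deptree.head[tok.index]),
                    s.deptree.label[tok.index], "_", "_"]
            stream.write("\t".join(cols) + "\n")
        stream.write("\n")


def attach_conllx(sentence: Sentence, tree: DependencyTree) -> Sentence:
    if tree.n != sentence.n:
        raise AlignmentError(
            f"tree has {tree.n} nodes for {sentence.n} tokens "
            f"(sentence {sentence.sent_id!r})")
    sentence.deptree = tree
    new_cues: list[CueAnnotation] = []
    new_scopes: dict[int, ScopeSpan] = {}
    for cue in sentence.cues:
        re_anchored = anchor_cue(cue, tree)
        new_cues.append(re_anchored)
        if cue.anchor in sentence.scopes:
            new_scopes[re_anchored.anchor] = sentence.scopes[cue.anchor]
    sentence.cues = new_cues
    sentence.scopes = new_scopes
    return sentence


# ---------------------------------------------------------------------------
# Penn-bracketed phrase trees

def _tokenize_sexpr(text: str) -> list[tuple[str, int]]:
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "()":
            out.append((ch, i))
            i += 1
        elif ch.isspace():
            i += 1
        else:
            j = i
            while j < len(text) and not text[j].isspace() and text[j] not in "()":
                j += 1
            out.append((text[i:j], i))
            i = j
    return out


def read_ptb(stream: Union[str, TextIO]) -> list[PhraseTree]:
    """Read one or more Penn-bracketed trees from a stream."""
    text = _as_stream(stream).read()
    toks = _tokenize_sexpr(text)
    trees: list[PhraseTree] = []
    stack: list[tuple[str, list[PhraseNode], int]] = []
    for tok, offset in toks:
        if tok == "(":
            stack.append(("", [], offset))
        elif tok == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at offset {offset}")
            lab, kids, _ = stack.pop()
            node = PhraseNode(lab, tuple(kids))
            if stack:
                stack[-1][1].append(node)
            else:
                trees.append(PhraseTree(node))
        else:
            if not stack:
                raise FormatError(f"token outside parentheses at offset {offset}")
            lab, kids, off = stack[-1]
            if not lab and not kids:
                stack[-1] = (tok, kids, off)
            else:
                kids.append(PhraseNode(tok))
    if stack:
        raise FormatError(f"unbalanced '(' at offset {stack[-1][2]}")
    return trees


def write_ptb(tree: PhraseTree) -> str:
    def fmt(node: PhraseNode) -> str:
        if node.is_leaf:
            return node.label
        return "(" + node.label + " " + " ".join(fmt(c) for c in node.children) + ")"
    return fmt(tree.root)


# ---------------------------------------------------------------------------
# Tagger TSV

def read_tagger_tsv(stream: Union[str, TextIO]) -> list[list[TaggerRow]]:
    """Read blank-line-separated blocks of ``surface  stem  pos  chunk`` rows.

    Returns one row-list per sentence block; an empty file yields ``[]``.
    """
    blocks: list[list[TaggerRow]] = []
    current: list[TaggerRow] = []
    for line in _as_stream(stream):
        line = line.rstrip("\n")
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise FormatError(
                f"tagger row needs >= 4 tab-separated columns: {line!r}")
        current.append((cols[0], cols[1], cols[2], cols[3]))
    if current:
        blocks.append(current)
    return blocks


def apply_tagger_rows(sentence: Sentence, rows: Sequence[TaggerRow]) -> Sentence:
    """Merge one block of tagger rows into the sentence tokens by position."""
    if len(rows) != sentence.n:
        raise AlignmentError(
            f"tagger block has {len(rows)} rows for {sentence.n} tokens "
            f"(sentence {sentence.sent_id!r})")
    for tok, (surface, stem, pos, chunk) in zip(sentence.tokens, rows):
        tok.surface = surface or tok.surface
        tok.stem = stem
        tok.pos = pos
        tok.chunk = chunk
        tok.is_punct = _recompute_punct(tok)
    return sentence


def _recompute_punct(tok: Token) -> bool:
    from .types import _looks_punct
    return _looks_punct(tok.surface, tok.pos)


def write_tagger_tsv(stream: TextIO, sentences: Iterable[Sentence]) -> None:
    for s in sentences:
        for tok in s.tokens:
            stream.write(f"{tok.surface}\t{tok.stem}\t{tok.pos}\t{tok.chunk}\n")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Prediction TSV

PRED_HEADER = "sent_id\tcue_id\tfirst\tlast"

Prediction = tuple[str, str, ScopeSpan]


def write_predictions(stream: TextIO, predictions: Iterable[Prediction]) -> None:
    """Write ``sent_id  cue_id  first  last`` rows, sorted, with header."""
    stream.write(PRED_HEADER + "\n")
    for sent_id, cue_id, span in sorted(
            predictions, key=lambda p: (p[0], p[1])):
        stream.write(f"{sent_id}\t{cue_id}\t{span.first}\t{span.last}\n")


def read_predictions(stream: Union[str, TextIO]) -> list[Prediction]:
    out: list[Prediction] = []
    lines = [ln.rstrip("\n") for ln in _as_stream(stream) if ln.strip()]
    if not lines:
        return out
    if lines[0] != PRED_HEADER:
        raise FormatError("missing prediction header line")
    for ln in lines[1:]:
        cols = ln.split("\t")
        if len(cols) != 4:
            raise FormatError(f"bad prediction row: {ln!r}")
        out.append((cols[0], cols[1], ScopeSpan(int(cols[2]), int(cols[3]))))
    return out
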