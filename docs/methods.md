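# Methods

## Task and data model

A hedge cue's scope is a contiguous token span containing the cue; the
system predicts, per cue, the scope's first token (F-scope) and last
token (L-scope). All coordinates in the package are 1-based inclusive
token indices. A fully annotated sentence carries tokens with tagger
attributes (surface, lemma, POS, BIO chunk), an optional dependency tree
(single-rooted, head/label arcs), an optional phrase-structure tree
aligned leaf-for-token, cue annotations, and gold scope spans.

Inline-tagged text is tokenized by whitespace splitting with terminal
punctuation (`.,;:?!`) detached as separate trailing tokens; this is the
numbering under which the worked examples' token indices (cue
"potentially" = 10, "tracts" = 16) come out right. Multi-token cues are
anchored at the cue token whose dependency head lies outside the cue span
(leftmost on ties); every algorithm consumes the anchor.

## Candidate boundary selection

The selection algorithm colors dependency-tree nodes white (undecided),
black (candidate) or grey (eliminated; grey is absorbing):

1. **Init** — the cue anchor and its ancestor chain become black,
   punctuation becomes grey, everything else white. Punctuation is
   excluded up front because a sentence-final period attached to the root
   would otherwise always survive as the rightmost L-candidate.
2. **Fixpoint** — while some black node `b` has white children, each
   white child `c` is compared to `b` by token index. L-side: `c < b`
   greys `c`'s whole subtree; `c > b` promotes `c` to black and demotes
   `b` to grey. F-side mirrors the comparison. All children in one sweep
   are compared against `b`'s index even if `b` was demoted mid-sweep,
   and `b` is demoted only if it promoted at least one child. Every sweep
   strictly reduces the number of white nodes, so the fixpoint halts in
   at most n sweeps.
3. **Final filter** — surviving black nodes strictly on the wrong side of
   the cue (left of it for L, right for F) become grey; the sorted
   remainder is the candidate set.

Two normative choices close gaps the walkthrough leaves open. First, the
cue anchor is exempt from demotion: a cue whose own children lie on the
outward side (common for verbal cues like "appeared") would otherwise be
eliminated, and the cue must always be available as its own boundary
(scopes like "(cue, L)" exist). Second, the worklist is scanned in
ascending index order purely for convenience — the final set is
order-independent, which the test suite checks against a randomized
one-node-at-a-time oracle on 1000 random trees.

The candidate set has these properties (all asserted as tests): the cue
is always a member; L-candidates are all ≥ the cue and F-candidates ≤ it;
the set is a subset of the all-tokens baseline; and on projective trees
whose gold scope is the interval spanned by the subtree of an ancestor of
the cue, both gold boundaries always survive. A gold boundary pruned away
(on distorted parses) is a *dropped positive*: it is never shown to the
classifier and is charged as a false negative at evaluation time.

## Features

**Lexical** (polynomial kernel): for candidate and cue, the four token
attributes at window offsets −3..3 (8 templates × 7 offsets), each a
named binary feature `Template(i)=value`, out-of-range positions valued
`null`, plus a categorical distance feature `Distance=k` for
k = |cand − cue|. Distance saturates at `Distance=GT15` so the one-hot
alphabet stays bounded; the encoding (binary one-hot, 57 active features
per instance) is a package choice. `Distance` is inclusive of neither
endpoint: cue 10 → candidate 16 gives 6.

**Phrase** (tree kernel): the smallest connected subtree of the phrase
parse containing the pre-terminals of the cue, the candidate, and one
neighbor token on each side of both, with all other leaves deleted.
Surviving internal labels and child order are preserved; non-branching
chains are *not* collapsed, because the tree kernel's production matching
is label-sequence sensitive.

**Dependency** (tree kernel): in the dependency node tree (each token
replaced by its incoming arc label, root labeled `ROOT`, children ordered
by index), the path cue → lowest common ancestor → candidate, rooted at
the LCA's label with the cue-side chain as first child. Degenerate cases:
a single chain when one endpoint dominates the other, a single node when
candidate = cue. Arc labels only — no POS augmentation, and the termini
are not specially marked.

## Kernels

`Δ(n₁,n₂)` is 0 when productions (label plus ordered child-label
sequence) differ, λ when both nodes are pre-terminals of a matching
production, else `λ·Π_k (1 + Δ(ch(n₁,k), ch(n₂,k)))`. Only internal
nodes enter the double sum; bare leaves carry no production. The
implementation is memoized per node pair and grouped by production;
the test suite proves it equal to an explicit common-fragment enumerator
on exhaustively many small tree pairs.

Defaults: λ = 0.4 (the customary toolkit default for this kernel family),
polynomial degree d = 2, composite factor γ = 0.3 for the
phrase+dependency+lexical combination (the best-performing setting for
that feature set); all configurable via `KernelParams`.

Each component kernel is unit-diagonal normalized
(`K'(a,b) = K(a,b)/√(K(a,a)K(b,b))`) before mixing. Without this the
tree kernel's scale grows with tree size and γ stops meaning anything; a
single-node feature tree has an empty fragment set (self-kernel 0) and is
assigned normalized similarity 0 to everything. Gram matrices use two
fast paths that are tested to agree with the pairwise definition: sparse
one-hot matrix products for the polynomial part and deduplication by
canonical tree serialization for the tree part.

## Classifier

One soft-margin SVM per side (F, L) on the precomputed composite Gram
matrix, C = 1.0, solver tolerance 1e-4 (scikit-learn's SVC provides the
dual solver). No class weighting under dependency-based selection — the
method's point is that the ratio is already balanced; a weighting flag
would only matter for baseline comparisons. A decision value of exactly 0
is read as "not a boundary": the postprocessing rules are the designated
repair mechanism for missing boundaries, so ties resolve conservatively.

## Postprocessing

Rules for turning per-token decisions into one span per cue: (1) one F
and one L hit → (F, L); (2) one F, several L → (F, last L); (3) several
F, one L → (first F, L); (4) F hits only → span runs to the last token of
the sentence; (5) L hits only → span starts at the cue; (6) a
passive-voice hedge (POS VBN with a be/get auxiliary on its head chain)
starts its scope at the leftmost token of the auxiliary's subject subtree
(arc label SUB/NSUBJ family) — the choice of the *auxiliary's* subject
over the matrix verb's is a package decision, as is the detection
heuristic; (7) the hedge "or" spans the subtree of its coordination head.
Two uncovered cases are closed deterministically: several hits on both
sides compose rules 2+3, and no hits at all fall back to (cue, last
token) so every cue gets exactly one prediction and sentence-level
precision equals recall by construction. Rule 4 is applied literally,
including final punctuation; a `trim_final_punct` flag (default off)
implements the stricter convention that excludes it.

## Evaluation

Tag-level precision/recall/F1 score the raw classifiers per side, with
dropped positives added to the recall denominator. Sentence-level F1
scores exact (first, last) matches per cue. Instance accounting reports
selected positives, negatives, dropped counts, and the imbalance as a
"1:x" string with x rounded to one decimal. Paired two-sided Student
t-tests compare per-fold sentence-level F1 lists; degenerate inputs are
fixed deterministically (identical lists → t = 0, p = 1; constant nonzero
shift → ±∞, p = 0).

## Synthetic corpora

The generator emulates the statistical shape of hedge-scope data at desk
scale: per sentence it samples a projective dependency tree (recursive
interval partition, so every subtree spans an interval), picks a non-root
cue token from a small cue lexicon, and sets the gold scope to the token
interval spanned by the subtree of the cue's parent — contiguous and
cue-containing by construction, and consistent with the worked example
(there, the scope is exactly the subtree interval of the cue's parent).
Token attributes come from a ~44-lemma vocabulary in 6 POS classes, kept
deliberately small so the window features are learnable from a few
hundred sentences. The tokens immediately flanking the scope (outside it)
are drawn from clause-boundary marker classes — complementizers on the
left, punctuation/conjunctions on the right — mirroring how real hedged
sentences delimit scopes ("indicate **that** ⟨scope⟩",
"⟨… tracts⟩ **,** and"); without such markers the boundary is
structurally determined but lexically invisible, which real corpora are
not. Defaults: 6–14 tokens per sentence, noise 0.

A parse-noise rate ε reattaches, per sentence with probability ε, one
scope-internal token (biased toward the boundary tokens, where parser
errors actually hurt) to a head outside the scope — the mechanism that
drops gold boundaries from the candidate set. At ε = 0 the
projective-completeness property guarantees zero drops.

**What the synthetic results do and do not show.** The end-to-end check
trains on a 300-sentence corpus and scores the same corpus (in-sample):
it establishes that candidate selection, featurization, kernels, the
SVMs, resolution and scoring compose correctly and that the learning
problem the generator poses is solvable (sentence-level F1 ≈ 0.97;
held-out performance on a 200/100 split is ≈ 0.76, the gap coming from
the tiny vocabulary making degree-2 window conjunctions easy to
memorize). It says nothing about performance on real corpora, which have
richer lexica, imperfect parses, multi-token and multi-cue sentences, and
discontinuous annotation conventions the package does not model.

## Numerical and engineering choices

Problem sizes were chosen for single-CPU desk scale: property tests use
up to 1000 random trees of ≤ 14 nodes, kernel cross-checks exhaust tree
pairs of ≤ 7 nodes, and pipeline tests use 100–300-sentence corpora.
Determinism: all generator randomness flows through one seeded
`random.Random`; training is deterministic given fixed inputs and solver
tolerance; feature extraction is a pure function of its inputs (repeated
calls byte-identical). Known limitations: single-anchor treatment of
multi-token cues, no discontinuous scopes, each cue resolved
independently, and the rule-6/7 detection heuristics are syntactic
approximations.
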