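# hedgescope

Hedge (speculation) scope detection for biomedical text, built around
**dependency-based candidate boundary selection** and a **composite
tree + polynomial kernel** classifier.

## The problem

Biomedical writing hedges constantly ("the mutagenic DNA deaminases are
*potentially* an important target for hormonal regulation"). Downstream
information extraction must separate such speculation from fact, which
means finding, for each hedge cue, its *scope*: the contiguous token span
the cue governs, always containing the cue. The standard formulation
classifies tokens as the scope's first element (**F-scope**) or last
element (**L-scope**) and assembles the span from those boundary
decisions.

Taking *every* token on one side of the cue as a boundary candidate (the
traditional token-based scheme, TTB) floods the classifiers with
negatives — ratios of 1:12 to 1:18 on real corpora — and the hardest
negatives are the boundary's immediate neighbors. This package implements
a pruning method that uses the dependency tree instead: of two tokens in
a dependency relation, only the one further from the cue can plausibly be
the boundary on that side. The pruning is a three-color fixpoint
(white = undecided, black = candidate, grey = eliminated) seeded at the
cue and its ancestor chain; on real data it cuts the negative ratio to
roughly 1:3 while keeping ~95% of gold boundaries reachable.

Candidates are then classified by a soft-margin SVM over a composite
kernel

```
K_com = γ · K_tree + (1 − γ) · K_poly                    (two feature sets)
K_com = ½γ · (K_phrase + K_dep) + (1 − γ) · K_poly       (three feature sets)
```

where `K_poly(x, y) = (x·y + 1)^d` (d = 2) acts on 57 named lexical
window features and `K_tree` is the convolution tree kernel
`K(T₁,T₂) = Σ_{n₁∈N₁,n₂∈N₂} Δ(n₁,n₂)` with the usual recursion
(Δ = 0 for differing productions, Δ = λ for matching pre-terminals,
else `λ·Π_k (1 + Δ(ch(n₁,k), ch(n₂,k)))`), applied to pruned
phrase-structure subtrees and dependency arc-label paths. Seven
postprocessing rules turn the raw per-token boundary decisions into
exactly one contiguous, cue-containing scope per cue.

## Worked example

```python
from hedgescope import select_candidates, ttb_candidates, ancestors
from hedgescope.fixtures_synth import sentence1_fixture

sent = sentence1_fixture().sentence     # 17 tokens, cue "potentially" = 10
print(ancestors(sent.deptree, 10))
print(ttb_candidates(sent.n, 10, "L").candidates)
print(select_candidates(sent.deptree, 10, "L",
                        punct_mask=sent.punct_mask()).candidates)
```

prints

```
[9, 4, 3]
(10, 11, 12, 13, 14, 15, 16, 17)
(10, 16)
```

the cue's ancestor chain, the 8 baseline candidates right of the cue, and
the 2 dependency-selected candidates — which still include the gold
L-scope boundary, token 16 ("regulation"). The `examples/` directory has
one short script per capability (candidate selection, lexical features,
kernels, postprocessing, and the full synthetic-corpus pipeline); run
them as `python examples/01_candidate_selection.py` etc.

A thin CLI covers the same ground from the shell:

```bash
hedgescope synth --n 100 --seed 7 --out corpus/
hedgescope train --config run.yaml --inline corpus/inline.txt \
    --conllx corpus/corpus.conllx --tagger corpus/tagger.tsv --out run/
hedgescope predict --model run/pipeline.pkl --inline corpus/inline.txt \
    --conllx corpus/corpus.conllx --tagger corpus/tagger.tsv --out run/
```

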