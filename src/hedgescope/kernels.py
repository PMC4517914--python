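"""Convolution tree kernel, polynomial kernel, and composite kernels.

The tree kernel counts common subtree fragments of two ordered labeled
trees, each fragment weighted by lambda^(number of production nodes),
via the usual recursive Delta:

* Delta(n1, n2) = 0 when the productions (label + ordered child-label
  sequence) differ;
* Delta = lambda when both nodes are pre-terminals with equal production;
* otherwise Delta = lambda * prod_k (1 + Delta(ch(n1,k), ch(n2,k))).

Only internal nodes (nodes with children) enter the node-pair sum; bare
leaves carry no production.  The polynomial kernel over the sparse binary
lexical vectors is (x.y + 1)^d with d defaulting to 2.  The composite
kernel mixes the two with a factor gamma:

* ``phrase_lexical`` / ``dep_lexical``:
  K = gamma * K_tree + (1 - gamma) * K_poly,
* ``phrase_dep_lexical``:
  K = gamma/2 * (K_phrase + K_dep) + (1 - gamma) * K_poly.

Each component is unit-diagonal normalized before mixing (K'(a,b) =
K(a,b)/sqrt(K(a,a)K(b,b))) so that gamma weighs comparable quantities;
without it the tree kernel's scale grows with tree size and swamps the
polynomial term.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import FeaturizationError
from .featurize import MODES, CandidateInstance, LexicalVector, Mode
from .types import FeatureNode, FeatureTree


@dataclass
class KernelParams:
    """Kernel hyperparameters.

    ``lambda_decay`` (0 < lambda < 1) damps larger tree fragments; 0.4 is
    the customary tree-kernel toolkit default.  ``degree`` is the
    polynomial degree d (default 2).  ``gamma_mix`` in [0, 1] is the
    composite factor (0 = lexical only, 1 = syntactic only); 0.3 is the
    best-performing setting for the phrase_dep_lexical combination.
    """

    lambda_decay: float = 0.4
    degree: int = 2
    gamma_mix: float = 0.3
    mode: Mode = "phrase_dep_lexical"
    normalize: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_decay < 1.0):
            raise ValueError("lambda_decay must be in (0, 1)")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if not (0.0 <= self.gamma_mix <= 1.0):
            raise ValueError("gamma_mix must be in [0, 1]")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# Tree kernel

def delta(n1: FeatureNode, n2: FeatureNode, lam: float,
          _memo: Optional[dict] = None) -> float:
    """Common-subtree count rooted at the pair (n1, n2)."""
    if not n1.children or not n2.children:
        return 0.0
    if n1.production != n2.production:
        return 0.0
    if _memo is None:
        _memo = {}
    key = (id(n1), id(n2))
    if key in _memo:
        return _memo[key]
    if all(not c.children for c in n1.children):       # pre-terminal
        val = lam
    else:
        val = lam
        for c1, c2 in zip(n1.children, n2.children):
            val *= 1.0 + delta(c1, c2, lam, _memo)
    _memo[key] = val
    return val


def _internal_nodes(t: FeatureTree) -> list[FeatureNode]:
    return [n for n in t.iter_nodes() if n.children]


def tree_kernel(t1: FeatureTree, t2: FeatureTree, lam: float) -> float:
    """Sum of Delta over all internal node pairs of the two trees."""
    memo: dict = {}
    by_prod: dict[tuple, list[FeatureNode]] = {}
    for n in _internal_nodes(t2):
        by_prod.setdefault(n.production, []).append(n)
    total = 0.0
    for n1 in _internal_nodes(t1):
        for n2 in by_prod.get(n1.production, ()):
            total += delta(n1, n2, lam, memo)
    return total


# ---------------------------------------------------------------------------
# Polynomial kernel

def poly_kernel(x: LexicalVector, y: LexicalVector, d: int) -> float:
    """(x.y + 1)^d over binary named features (dot = shared-feature count)."""
    return float((x.shared(y) + 1) ** d)


# ---------------------------------------------------------------------------
# Composite kernel

def _normalized(k_ab: float, k_aa: float, k_bb: float) -> float:
    denom = k_aa * k_bb
    if denom <= 0.0:
        return 0.0
    return k_ab / math.sqrt(denom)


def _component_kernels(i1: CandidateInstance, i2: CandidateInstance,
                       p: KernelParams) -> dict[str, float]:
    i1.require(p.mode)
    i2.require(p.mode)
    comps: dict[str, float] = {
        "poly": poly_kernel(i1.lexical, i2.lexical, p.degree)}
    lam = p.lambda_decay
    if "phrase" in p.mode:
        comps["phrase"] = tree_kernel(i1.phrase_ft, i2.phrase_ft, lam)
    if "dep" in p.mode:
        comps["dep"] = tree_kernel(i1.dep_ft, i2.dep_ft, lam)
    if p.normalize:
        for name in list(comps):
            tree_a, tree_b = {
                "poly": (None, None),
                "phrase": (i1.phrase_ft, i2.phrase_ft),
                "dep": (i1.dep_ft, i2.dep_ft),
            }[name]
            if name == "poly":
                kaa = poly_kernel(i1.lexical, i1.lexical, p.degree)
                kbb = poly_kernel(i2.lexical, i2.lexical, p.degree)
            else:
                kaa = tree_kernel(tree_a, tree_a, lam)
                kbb = tree_kernel(tree_b, tree_b, lam)
            comps[name] = _normalized(comps[name], kaa, kbb)
    return comps


def composite(i1: CandidateInstance, i2: CandidateInstance,
              p: KernelParams) -> float:
    """Composite kernel value for one instance pair under ``p.mode``."""
    comps = _component_kernels(i1, i2, p)
    g = p.gamma_mix
    if p.mode == "phrase_lexical":
        syn = comps["phrase"]
    elif p.mode == "dep_lexical":
        syn = comps["dep"]
    else:
        syn = 0.5 * (comps["phrase"] + comps["dep"])
    return g * syn + (1.0 - g) * comps["poly"]


# ---------------------------------------------------------------------------
# Gram matrices (vectorized / deduplicated paths)

def _poly_gram(rows: Sequence[CandidateInstance],
               cols: Sequence[CandidateInstance],
               p: KernelParams) -> np.ndarray:
    vocab: dict[str, int] = {}
    def encode(insts: Sequence[CandidateInstance]) -> list[list[int]]:
        out = []
        for inst in insts:
            out.append([vocab.setdefault(f, len(vocab))
                        for f in inst.lexical.items])
        return out
    r_idx, c_idx = encode(rows), encode(cols)
    from scipy.sparse import csr_matrix
    def mat(idx: list[list[int]]) -> csr_matrix:
        indptr = np.cumsum([0] + [len(ix) for ix in idx])
        indices = np.concatenate([np.asarray(ix, dtype=np.int64)
                                  for ix in idx]) if idx else np.empty(0, int)
        data = np.ones(len(indices))
        return csr_matrix((data, indices, indptr),
                          shape=(len(idx), len(vocab)))
    dots = (mat(r_idx) @ mat(c_idx).T).toarray()
    K = (dots + 1.0) ** p.degree
    if p.normalize:
        nf = len(next(iter(rows)).lexical.items) if rows else 0
        self_k = float((nf + 1) ** p.degree)   # every vector has 57 features
        K /= self_k
    return K


def _tree_gram(row_trees: Sequence[FeatureTree],
               col_trees: Sequence[FeatureTree],
               p: KernelParams) -> np.ndarray:
    """Tree-kernel gram with deduplication by canonical serialization."""
    lam = p.lambda_decay
    def dedup(trees: Sequence[FeatureTree]):
        keys = [t.to_bracketed() for t in trees]
        uniq: dict[str, FeatureTree] = {}
        for k, t in zip(keys, trees):
            uniq.setdefault(k, t)
        order = list(uniq)
        pos = {k: i for i, k in enumerate(order)}
        return [uniq[k] for k in order], np.asarray([pos[k] for k in keys])
    r_uniq, r_map = dedup(row_trees)
    c_uniq, c_map = dedup(col_trees)
    U = np.empty((len(r_uniq), len(c_uniq)))
    cache: dict[tuple[str, str], float] = {}
    for a, ta in enumerate(r_uniq):
        ka = ta.to_bracketed()
        for b, tb in enumerate(c_uniq):
            kb = tb.to_bracketed()
            key = (ka, kb) if ka <= kb else (kb, ka)
            if key not in cache:
                cache[key] = tree_kernel(ta, tb, lam)
            U[a, b] = cache[key]
    if p.normalize:
        r_self = np.asarray([max(tree_kernel(t, t, lam), 0.0) for t in r_uniq])
        c_self = np.asarray([max(tree_kernel(t, t, lam), 0.0) for t in c_uniq])
        denom = np.sqrt(np.outer(r_self, c_self))
        with np.errstate(divide="ignore", invalid="ignore"):
            U = np.where(denom > 0, U / denom, 0.0)
    return U[np.ix_(r_map, c_map)]


def cross_gram(rows: Sequence[CandidateInstance],
               cols: Sequence[CandidateInstance],
               p: KernelParams) -> np.ndarray:
    """Composite kernel matrix K[i, j] = composite(rows[i], cols[j], p)."""
    if not rows or not cols:
        return np.zeros((len(rows), len(cols)))
    for inst in (*rows, *cols):
        inst.require(p.mode)
    g = p.gamma_mix
    K = (1.0 - g) * _poly_gram(rows, cols, p)
    if p.mode == "phrase_lexical":
        K += g * _tree_gram([i.phrase_ft for i in rows],
                            [i.phrase_ft for i in cols], p)
    elif p.mode == "dep_lexical":
        K += g * _tree_gram([i.dep_ft for i in rows],
                            [i.dep_ft for i in cols], p)
    else:
        K += 0.5 * g * _tree_gram([i.phrase_ft for i in rows],
                                  [i.phrase_ft for i in cols], p)
        K += 0.5 * g * _tree_gram([i.dep_ft for i in rows],
                                  [i.dep_ft for i in cols], p)
    return K


def gram_matrix(instances: Sequence[CandidateInstance],
                p: KernelParams) -> np.ndarray:
    """Symmetric composite Gram matrix over a set of instances."""
    if not instances:
        raise FeaturizationError("gram_matrix needs at least one instance")
    K = cross_gram(instances, instances, p)
    return 0.5 * (K + K.T)          # enforce exact symmetry
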