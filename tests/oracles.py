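"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by enumeration or naive recursion and
never call the code paths they are checking.
"""
from __future__ import annotations

import itertools
import random
from collections import Counter

from hedgescope.types import DependencyTree, FeatureNode


# ---------------------------------------------------------------------------
# DCBS: exhaustive nondeterministic fixpoint

def dcbs_oracle(tree: DependencyTree, cue: int, side: str,
                punct: frozenset[int] = frozenset(),
                rng: random.Random | None = None) -> tuple[int, ...]:
    """Recolor until stable, picking eligible black nodes in random order."""
    rng = rng or random.Random(0)
    WHITE, BLACK, GREY = 0, 1, 2
    color = {v: WHITE for v in range(1, tree.n + 1)}
    init_black = {cue, *tree.ancestors(cue)}
    for v in punct:
        if v not in init_black:
            color[v] = GREY
    for v in init_black:
        color[v] = BLACK

    def cueward(c, b):
        return c < b if side == "L" else c > b

    while True:
        eligible = [b for b in color
                    if color[b] == BLACK
                    and any(color[c] == WHITE for c in tree.children(b))]
        if not eligible:
            break
        b = rng.choice(eligible)
        promoted = False
        for c in tree.children(b):
            if color[c] != WHITE:
                continue
            if cueward(c, b):
                for u in tree.subtree(c):
                    color[u] = GREY
            else:
                color[c] = BLACK
                promoted = True
        if promoted and b != cue:
            color[b] = GREY
    for v in list(color):
        if color[v] == BLACK and v != cue and cueward(v, cue):
            color[v] = GREY
    return tuple(sorted(v for v in color if color[v] == BLACK))


def depth_oracle(tree: DependencyTree, v: int) -> int:
    d = 0
    while tree.head[v] != 0:
        v = tree.head[v]
        d += 1
    return d


def lca_oracle(tree: DependencyTree, nodes: list[int]) -> int:
    """Lowest common ancestor by brute-force path intersection."""
    paths = [[v] + tree.ancestors(v) for v in nodes]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    return next(v for v in paths[0] if v in common)


# ---------------------------------------------------------------------------
# Tree kernel: explicit common-fragment enumeration

def _fragments(node: FeatureNode):
    """All subtree fragments rooted at ``node`` with its production expanded.

    Yields (signature, production_node_count): at every internal child one
    may either stop (keeping just its label) or expand recursively.
    """
    child_opts = []
    for c in node.children:
        opts = [(c.label, 0)]
        if c.children:
            opts = opts + list(_fragments(c))
        child_opts.append(opts)
    for combo in itertools.product(*child_opts):
        sig = (node.label, tuple(s for s, _ in combo))
        yield sig, 1 + sum(k for _, k in combo)


def brute_tree_kernel(t1: FeatureNode, t2: FeatureNode, lam: float) -> float:
    def counts(t: FeatureNode) -> Counter:
        c: Counter = Counter()
        for n in t.iter_nodes():
            if n.children:
                for sig, nprod in _fragments(n):
                    c[(sig, nprod)] += 1
        return c
    c1, c2 = counts(t1), counts(t2)
    return sum(c1[key] * c2[key] * lam ** key[1] for key in c1 if key in c2)


def random_feature_tree(n_nodes: int, rng: random.Random,
                        labels=("A", "B", "C")) -> FeatureNode:
    """Random ordered labeled tree with exactly ``n_nodes`` nodes."""
    parents = [0] + [rng.randrange(i) for i in range(1, n_nodes)]
    kids: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for i in range(1, n_nodes):
        kids[parents[i]].append(i)
    labs = [rng.choice(labels) for _ in range(n_nodes)]

    def build(i: int) -> FeatureNode:
        return FeatureNode(labs[i], tuple(build(j) for j in kids[i]))
    return build(0)


# ---------------------------------------------------------------------------
# Paired t statistic, closed form

def paired_t_oracle(a, b):
    import math
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    return mean / math.sqrt(var / n)
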