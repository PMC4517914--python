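"""Tag-level and sentence-level scoring, instance accounting, t-tests.

Tag-level scores the raw boundary classifiers: every candidate carries a
gold label (is it the true boundary?) and a predicted label; gold
boundaries pruned away during candidate selection ("dropped positives")
were never shown to the classifier and count as false negatives in the
recall denominator.  Sentence-level scores exact span matches per cue;
because postprocessing emits exactly one span per cue, precision equals
recall there.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .errors import ProtocolError
from .types import ScopeSpan


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F1 with the underlying counts."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def tag_level(labeled: Sequence[tuple[int, int]], dropped: int = 0) -> PRF:
    """Score (gold, predicted) label pairs (+1/-1) for one side.

    ``dropped`` gold boundaries never presented to the classifier are
    added to the false negatives.
    """
    tp = sum(1 for g, p in labeled if g == 1 and p == 1)
    fp = sum(1 for g, p in labeled if g == -1 and p == 1)
    fn = sum(1 for g, p in labeled if g == 1 and p == -1) + dropped
    return PRF(tp=tp, fp=fp, fn=fn)


def sentence_level(gold: Sequence[ScopeSpan],
                   predicted: Sequence[ScopeSpan]) -> PRF:
    """Exact-span-match scoring over aligned per-cue span lists."""
    if len(gold) != len(predicted):
        raise ProtocolError(
            f"{len(predicted)} predictions for {len(gold)} gold scopes; "
            "every cue needs exactly one prediction")
    matches = sum(1 for g, p in zip(gold, predicted) if g == p)
    return PRF(tp=matches, fp=len(predicted) - matches,
               fn=len(gold) - matches)


@dataclass(frozen=True)
class InstanceStats:
    """Positive/negative candidate accounting for one side and method."""

    positives: int
    negatives: int
    dropped: int = 0

    @property
    def ratio(self) -> str:
        """Imbalance as a '1:x' string, x rounded to one decimal."""
        if self.positives == 0:
            return "1:NA"
        return f"1:{self.negatives / self.positives:.1f}"


def instance_stats(
        labeled_sets: Sequence[Sequence[tuple[int, int]]] | Sequence[Sequence],
        dropped: int = 0) -> InstanceStats:
    """Aggregate labeled candidates (one list per cue) into counts.

    Accepts lists of (index, label) pairs or of objects with a ``label``
    attribute.  ``positives`` counts the selected (emitted) positives;
    dropped gold boundaries are reported separately, mirroring the
    "996 (51 dropped)" accounting style.
    """
    pos = neg = 0
    for cands in labeled_sets:
        for item in cands:
            label = item.label if hasattr(item, "label") else item[1]
            if label == 1:
                pos += 1
            else:
                neg += 1
    return InstanceStats(positives=pos, negatives=neg, dropped=dropped)


def paired_ttest(scores_a: Sequence[float],
                 scores_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Student t-test on per-fold score lists.

    Degenerate cases are fixed deterministically: identical lists give
    (0.0, 1.0); a constant nonzero shift with zero difference variance
    gives (+-inf, 0.0).
    """
    if len(scores_a) != len(scores_b):
        raise ProtocolError("paired t-test needs equal-length score lists")
    if len(scores_a) < 2:
        raise ProtocolError("paired t-test needs at least 2 pairs")
    diffs = [a - b for a, b in zip(scores_a, scores_b)]
    if all(d == diffs[0] for d in diffs):
        if diffs[0] == 0:
            return 0.0, 1.0
        return (float("inf") if diffs[0] > 0 else float("-inf")), 0.0
    t, p = stats.ttest_rel(scores_a, scores_b)
    return float(t), float(p)
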