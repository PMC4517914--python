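"""F-scope / L-scope boundary classifiers.

Each side gets a soft-margin kernel SVM trained on the composite Gram
matrix of its labeled candidate instances (scikit-learn's SVC with a
precomputed kernel provides the dual solver).  The decision function is
sum_i coeff_i * K(train_i, x) + bias; a score of exactly 0 is treated as
"not a boundary" and left for the postprocessing rules to repair.
"""
from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import BinaryIO, Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import FeaturizationError, TrainingError
from .featurize import CandidateInstance
from .kernels import KernelParams, cross_gram, gram_matrix

MODEL_FORMAT_VERSION = 1


def fit_svm(K: np.ndarray, y: Sequence[int], C: float = 1.0,
            tol: float = 1e-4) -> SVC:
    """Fit the soft-margin dual on a precomputed Gram matrix."""
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise TrainingError("training needs both a positive and a negative")
    svc = SVC(C=C, kernel="precomputed", tol=tol)
    svc.fit(K, y)
    return svc


@dataclass
class ScopeClassifier:
    """A trained boundary classifier for one side (F or L)."""

    side: str
    params: KernelParams
    C: float
    instances: list[CandidateInstance]
    svc: SVC = field(repr=False)

    @property
    def support_coefficients(self) -> np.ndarray:
        """Per-support-vector dual coefficients (alpha_i * y_i)."""
        return self.svc.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])

    def decision_values(self, instances: Sequence[CandidateInstance],
                        ) -> np.ndarray:
        if not instances:
            return np.zeros(0)
        for inst in instances:
            inst.require(self.params.mode)
        K = cross_gram(instances, self.instances, self.params)
        return self.svc.decision_function(K)


def train(instances: Sequence[CandidateInstance], p: KernelParams,
          C: float = 1.0, side: Optional[str] = None,
          tol: float = 1e-4) -> ScopeClassifier:
    """Train one boundary classifier from labeled candidate instances."""
    instances = list(instances)
    if not instances:
        raise TrainingError("no training instances")
    labels = [i.label for i in instances]
    if any(lab not in (-1, 1) for lab in labels):
        raise TrainingError("all training instances must be labeled +1/-1")
    if side is None:
        sides = {i.side for i in instances}
        if len(sides) != 1:
            raise TrainingError(f"mixed instance sides {sides}; pass side=")
        side = sides.pop()
    K = gram_matrix(instances, p)
    svc = fit_svm(K, labels, C=C, tol=tol)
    return ScopeClassifier(side=side, params=p, C=C,
                           instances=instances, svc=svc)


def predict(model: ScopeClassifier,
            instances: Sequence[CandidateInstance],
            ) -> list[tuple[float, int]]:
    """Per-instance (score, label); label = +1 iff score > 0."""
    scores = model.decision_values(list(instances))
    return [(float(s), 1 if s > 0.0 else -1) for s in scores]


def save_model(stream: BinaryIO, model: ScopeClassifier) -> None:
    pickle.dump({"format_version": MODEL_FORMAT_VERSION, "model": model},
                stream)


def load_model(stream: BinaryIO) -> ScopeClassifier:
    payload = pickle.load(stream)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise FeaturizationError(
            f"unsupported model format {payload.get('format_version')!r}")
    return payload["model"]
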