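"""Higher-order (conjunction) feature induction from loss gradients.

Linear classifiers cannot represent interactions between features.  This
module induces candidate feature *pairs* by a three-step procedure:

1. run the trained classifier over its own training set and collect the
   misclassified documents;
2. for every unordered pair of active features in a misclassified
   document, accumulate the partial derivative of the loss with respect
   to the would-be conjunction weight, evaluated at weight zero:
   ``h'(z_d) * y_d`` (the conjunction indicator is 1 in that document);
3. keep pairs occurring in at least ``a`` misclassified documents whose
   summed derivative is at least ``b`` in absolute value (defaults
   a = 4, b = 340; ``b`` scales with corpus size and should be re-tuned
   for small corpora).

Each selected pair becomes a new binary feature ``H|i&j`` that is active
exactly when both constituents are, the vocabulary is extended, and the
classifier is retrained on the augmented vectors.  Only pairs are
considered, never triples or higher arities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .features import FeatureVocabulary
from .huber import (
    HuberModel,
    TrainSettings,
    modified_huber_grad,
    to_csr,
    train,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PairCandidate",
    "find_misclassified",
    "evaluate_pairs",
    "select_pairs",
    "augment_vectors",
    "induce_and_retrain",
]

DEFAULT_MIN_COUNT = 4
DEFAULT_MIN_DERIVATIVE = 340.0


@dataclass
class PairCandidate:
    """An unordered feature pair with its evidence across misclassified docs."""

    pair: tuple[int, int]  # 1-based feature indices, i < j
    count: int
    derivative_sum: float


def find_misclassified(
    model: HuberModel, vectors, labels: Sequence[int]
) -> np.ndarray:
    """Indices of training documents the model labels incorrectly.

    Prediction is the sign of the margin with ties (score exactly 0)
    going to the negative class.
    """
    X = to_csr(vectors, len(model.w))
    y = np.asarray(labels, dtype=float)
    margins = X @ model.w + model.theta
    pred = np.where(margins > 0.0, 1.0, -1.0)
    return np.nonzero(pred != y)[0]


def evaluate_pairs(
    model: HuberModel,
    vectors,
    labels: Sequence[int],
    misclassified: Sequence[int],
) -> list[PairCandidate]:
    """Accumulate per-pair occurrence counts and loss-derivative sums.

    For misclassified document ``d`` with margin ``z_d = y_d (w.x_d + theta)``,
    every active pair receives the contribution ``h'(z_d) * y_d``.
    """
    X = to_csr(vectors, len(model.w))
    y = np.asarray(labels, dtype=float)
    margins = X @ model.w + model.theta
    counts: dict[tuple[int, int], int] = {}
    sums: dict[tuple[int, int], float] = {}
    for d in misclassified:
        z = y[d] * margins[d]
        g = float(modified_huber_grad(z)) * y[d]
        active = (X[d].indices + 1).tolist()  # back to 1-based
        active.sort()
        for pair in combinations(active, 2):
            counts[pair] = counts.get(pair, 0) + 1
            sums[pair] = sums.get(pair, 0.0) + g
    return [
        PairCandidate(pair, counts[pair], sums[pair]) for pair in sorted(counts)
    ]


def select_pairs(
    candidates: Sequence[PairCandidate],
    min_count: int = DEFAULT_MIN_COUNT,
    min_derivative: float = DEFAULT_MIN_DERIVATIVE,
) -> list[PairCandidate]:
    """Keep pairs with count >= a and |derivative sum| >= b (inclusive)."""
    return [
        c
        for c in candidates
        if c.count >= min_count and abs(c.derivative_sum) >= min_derivative
    ]


def augment_vectors(
    vectors,
    selected: Sequence[PairCandidate],
    n_features: int,
    vocabulary: FeatureVocabulary | None = None,
) -> sp.csr_matrix:
    """Append one AND-column per selected pair; optionally extend the
    vocabulary with ``H|i&j`` entries in the same order."""
    X = to_csr(vectors, n_features).tocsc()
    cols = [X]
    for c in selected:
        i, j = c.pair
        conj = X[:, i - 1].multiply(X[:, j - 1])
        cols.append(sp.csc_matrix(conj))
        if vocabulary is not None:
            vocabulary.add_feature(f"H|{i}&{j}", doc_freq=int(conj.nnz))
    return sp.hstack(cols).tocsr()


def induce_and_retrain(
    model: HuberModel,
    vectors,
    labels: Sequence[int],
    settings: TrainSettings | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    min_derivative: float = DEFAULT_MIN_DERIVATIVE,
    vocabulary: FeatureVocabulary | None = None,
) -> tuple[HuberModel, sp.csr_matrix, list[PairCandidate]]:
    """One full induction round: misclassified -> pairs -> select ->
    augment -> retrain.  With a perfect model this is a no-op."""
    mis = find_misclassified(model, vectors, labels)
    if len(mis) == 0:
        logger.info("no misclassified documents; higher-order induction is a no-op")
        return model, to_csr(vectors, len(model.w)), []
    candidates = evaluate_pairs(model, vectors, labels, mis)
    selected = select_pairs(candidates, min_count, min_derivative)
    logger.info(
        "higher-order induction: %d misclassified docs, %d candidate pairs, %d selected",
        len(mis), len(candidates), len(selected),
    )
    if not selected:
        return model, to_csr(vectors, len(model.w)), []
    X_aug = augment_vectors(vectors, selected, len(model.w), vocabulary)
    new_model = train(X_aug, labels, settings, lam_prime=model.lam_prime)
    return new_model, X_aug, selected
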