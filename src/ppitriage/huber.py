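"""Large-margin linear classifier with the modified Huber loss.

The classifier minimizes

    C(w, theta) = sum_i h(y_i (w . X_i + theta)) + lambda ||w||^2

over binary feature vectors ``X_i`` and labels ``y_i`` in {+1, -1}, where
``h`` is the modified Huber loss (Zhang):

    h(z) = -4 z            for z < -1
    h(z) = (1 - z)^2       for -1 <= z < 1
    h(z) = 0               for z >= 1

``h`` is convex and continuously differentiable: quadratic around the
margin and linear for badly misclassified points, which keeps gradients
bounded.  The regularization weight is derived from the data:

    lambda = lambda' * <|x|>^2

with ``<|x|>`` the mean Euclidean norm of the training vectors (for
binary vectors, sqrt of the active-feature count) and ``lambda'`` a small
base rate, 0.0005 by default.

Optimization is deterministic full-batch gradient descent with a
backtracking (Armijo) line search from ``w = 0, theta = 0``; the cost is
non-increasing across iterations by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "TrainSettings",
    "HuberModel",
    "modified_huber_loss",
    "modified_huber_grad",
    "compute_lambda",
    "to_csr",
    "train",
    "score",
    "classify",
]

DEFAULT_LAMBDA_PRIME = 0.0005


@dataclass(frozen=True)
class TrainSettings:
    """Deterministic batch gradient-descent settings."""

    max_iterations: int = 1000
    initial_rate: float = 1.0
    rate_decay: float = 0.0
    tolerance: float = 1e-8
    armijo_c: float = 1e-4
    max_backtracks: int = 60
    # loss normalization: "sum" (default) or "mean" over the training set
    loss_normalization: str = "sum"
    seed: int = 0  # unused by batch descent; recorded for provenance

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.loss_normalization not in ("sum", "mean"):
            raise ValueError("loss_normalization must be 'sum' or 'mean'")


@dataclass
class HuberModel:
    """Fitted weights, threshold and regularization metadata."""

    w: np.ndarray
    theta: float
    lam: float
    lam_prime: float
    n_iterations: int = 0
    final_cost: float = float("nan")
    cost_trace: list[float] = field(default_factory=list)

    def save(self, stream: TextIO) -> None:
        stream.write(
            f"#theta={self.theta:.17g}\tlambda={self.lam:.17g}"
            f"\tlambda_prime={self.lam_prime:.17g}\tV={len(self.w)}\n"
        )
        for i, wi in enumerate(self.w, start=1):
            if wi != 0.0:
                stream.write(f"{i}\t{wi:.17g}\n")

    @classmethod
    def load(cls, stream: TextIO) -> "HuberModel":
        header = stream.readline().strip()
        if not header.startswith("#"):
            raise ValueError("model file lacks a header line")
        kv = dict(part.split("=") for part in header[1:].split("\t"))
        w = np.zeros(int(kv["V"]))
        for line in stream:
            if not line.strip():
                continue
            i, wi = line.rstrip("\n").split("\t")
            w[int(i) - 1] = float(wi)
        return cls(
            w=w,
            theta=float(kv["theta"]),
            lam=float(kv["lambda"]),
            lam_prime=float(kv["lambda_prime"]),
        )


def modified_huber_loss(z: np.ndarray | float) -> np.ndarray | float:
    """Elementwise modified Huber loss h(z)."""
    z = np.asarray(z, dtype=float)
    out = np.where(z < -1.0, -4.0 * z, np.where(z < 1.0, (1.0 - z) ** 2, 0.0))
    return out if out.ndim else float(out)


def modified_huber_grad(z: np.ndarray | float) -> np.ndarray | float:
    """Elementwise derivative h'(z): -4 below -1, 2(z-1) on [-1, 1), 0 above."""
    z = np.asarray(z, dtype=float)
    out = np.where(z < -1.0, -4.0, np.where(z < 1.0, 2.0 * (z - 1.0), 0.0))
    return out if out.ndim else float(out)


def to_csr(
    vectors: Sequence[Iterable[int]] | sp.spmatrix, n_features: int | None = None
) -> sp.csr_matrix:
    """Build a CSR indicator matrix from 1-based sparse index tuples."""
    if sp.issparse(vectors):
        return vectors.tocsr()
    rows, cols = [], []
    max_idx = 0
    seqs = [tuple(v) for v in vectors]
    for r, idx in enumerate(seqs):
        for i in idx:
            rows.append(r)
            cols.append(i - 1)
            max_idx = max(max_idx, i)
    V = n_features if n_features is not None else max_idx
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(len(seqs), V))


def compute_lambda(
    vectors: Sequence[Iterable[int]] | sp.spmatrix,
    lam_prime: float = DEFAULT_LAMBDA_PRIME,
) -> float:
    """``lambda = lambda' * <|x|>^2`` from the training vectors."""
    X = to_csr(vectors)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    mean_norm = float(norms.mean())
    if mean_norm == 0.0:
        logger.warning("all training vectors are empty; lambda = 0")
        return 0.0
    return lam_prime * mean_norm**2


def _cost_and_grad(
    X: sp.csr_matrix, y: np.ndarray, w: np.ndarray, theta: float, lam: float, scale: float
) -> tuple[float, np.ndarray, float]:
    z = y * (X @ w + theta)
    cost = scale * float(np.sum(modified_huber_loss(z))) + lam * float(w @ w)
    hp = modified_huber_grad(z) * y
    grad_w = scale * (X.T @ hp) + 2.0 * lam * w
    grad_theta = scale * float(np.sum(hp))
    return cost, grad_w, grad_theta


def train(
    vectors: Sequence[Iterable[int]] | sp.spmatrix,
    labels: Sequence[int],
    settings: TrainSettings | None = None,
    lam_prime: float = DEFAULT_LAMBDA_PRIME,
    n_features: int | None = None,
) -> HuberModel:
    """Fit the classifier by full-batch gradient descent.

    Raises ``ValueError`` on single-class input and ``RuntimeError`` if
    the line search cannot find a descent step while the gradient is
    still large (divergence).
    """
    settings = settings or TrainSettings()
    X = to_csr(vectors, n_features)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("vectors and labels differ in length")
    if X.shape[0] < 2 or len(np.unique(y)) < 2:
        raise ValueError("training requires at least two examples and both classes")

    lam = compute_lambda(X, lam_prime)
    scale = 1.0 / X.shape[0] if settings.loss_normalization == "mean" else 1.0

    w = np.zeros(X.shape[1])
    theta = 0.0
    cost, gw, gt = _cost_and_grad(X, y, w, theta, lam, scale)
    trace = [cost]
    it = 0
    for it in range(1, settings.max_iterations + 1):
        gnorm2 = float(gw @ gw) + gt * gt
        if gnorm2 == 0.0:
            break
        rate = settings.initial_rate / (1.0 + settings.rate_decay * (it - 1))
        accepted = False
        for _ in range(settings.max_backtracks):
            w_new = w - rate * gw
            theta_new = theta - rate * gt
            new_cost, gw_new, gt_new = _cost_and_grad(X, y, w_new, theta_new, lam, scale)
            if new_cost <= cost - settings.armijo_c * rate * gnorm2:
                accepted = True
                break
            rate *= 0.5
        if not accepted:
            if gnorm2 < 1e-12:
                break
            raise RuntimeError(
                f"line search failed at iteration {it} (cost {cost:.6g})"
            )
        rel_change = (cost - new_cost) / max(abs(cost), 1.0)
        w, theta, cost, gw, gt = w_new, theta_new, new_cost, gw_new, gt_new
        trace.append(cost)
        if rel_change < settings.tolerance:
            break

    logger.info("huber training: %d iterations, final cost %.6g", it, cost)
    return HuberModel(
        w=w, theta=theta, lam=lam, lam_prime=lam_prime,
        n_iterations=it, final_cost=cost, cost_trace=trace,
    )


def score(
    model: HuberModel, vector: Iterable[int] | sp.spmatrix | np.ndarray
) -> float:
    """Raw margin ``w . x + theta``; higher means more PPI-like."""
    if sp.issparse(vector):
        return float((vector @ model.w)[0] + model.theta)
    if isinstance(vector, np.ndarray):
        return float(vector @ model.w + model.theta)
    s = model.theta
    for i in vector:
        s += model.w[i - 1]
    return float(s)


def classify(model: HuberModel, vector: Iterable[int] | sp.spmatrix | np.ndarray) -> int:
    """Sign of the score; an exact 0 breaks conservatively to -1."""
    return +1 if score(model, vector) > 0.0 else -1
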