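"""Linear discriminant analysis on the selected PC scores.

Two stages: (1) a Fisher projection W (d x (C-1)) maximizing between-class
relative to within-class scatter of the training scores, and (2) a
shared-covariance Gaussian classifier in the projected space, whose per-class
linear discriminant is

    delta_c(z) = w_c' z + b_c,   w_c = Sigma_W^{-1} mu_c,
    b_c = -0.5 mu_c' Sigma_W^{-1} mu_c + log P(y=c),

with Sigma_W the pooled within-class covariance (1/(n-C) scaling) and priors
the empirical class frequencies.  Posteriors are the softmax of delta, which
is the exact class posterior under the shared-covariance Gaussian model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .io_formats import LabelVector, PredictionTable

logger = logging.getLogger(__name__)

RIDGE_SCALE = 1e-6  # ridge added to within-scatter: RIDGE_SCALE * trace / dim

UNKNOWN_LABEL = "Unknown"


@dataclass
class LDAModel:
    """Fitted projection and per-class discriminants."""

    W: np.ndarray  # d x r projection, r = min(C-1, d), unit-norm columns
    classes: np.ndarray
    class_means_lda: np.ndarray  # C x r
    sigma_w: np.ndarray  # r x r pooled within-class covariance (as inverted)
    priors: np.ndarray  # C, sums to 1
    coef: np.ndarray = field(default=None)  # type: ignore[assignment]  # C x r, rows w_c
    intercept: np.ndarray = field(default=None)  # type: ignore[assignment]  # C, b_c
    ridge: float = 0.0  # regularization actually added to sigma_w's diagonal
    scatter_ridge: float = 0.0  # regularization used for the Eq-style scatter solve


def _scatter_matrices(Z: np.ndarray, labels: LabelVector, diagonal: bool):
    grand = Z.mean(axis=0)
    d = Z.shape[1]
    S_B = np.zeros((d, d))
    S_W = np.zeros((d, d))
    for c in labels.class_set:
        Zc = Z[labels.labels == c]
        mu = Zc.mean(axis=0)
        dm = mu - grand
        S_B += len(Zc) * np.outer(dm, dm)
        R = Zc - mu
        S_W += R.T @ R
    if diagonal:
        # literal per-coordinate form: only the k-th PC contributes to entry k
        S_B = np.diag(np.diag(S_B))
        S_W = np.diag(np.diag(S_W))
    return S_B, S_W


def fit_lda_projection(
    z_train: np.ndarray, labels: LabelVector, scatter: str = "full"
) -> tuple[np.ndarray, float]:
    """Fisher projection: top C-1 generalized eigenvectors of (S_B, S_W).

    The within-scatter is ridge-regularized (``RIDGE_SCALE * trace(S_W)/d`` on
    the diagonal) before the solve; the ridge actually used is returned.
    Columns are ordered by decreasing eigenvalue, sign-fixed so the
    largest-magnitude entry is positive, and normalized to unit length.
    ``scatter='diagonal'`` uses the per-coordinate (diagonal) scatter
    matrices, which reduces the optimum to re-ranking individual coordinates.
    """
    z_train = np.asarray(z_train, dtype=float)
    n, d = z_train.shape
    C = labels.n_classes
    if C < 2:
        raise ValueError("at least two classes are required")
    counts = labels.counts()
    if counts.min() < 2:
        bad = labels.class_set[int(np.argmin(counts))]
        raise ValueError(f"class {bad!r} has fewer than 2 cells")
    r = C - 1
    if d < r:
        warnings.warn(
            f"only d={d} dimensions available for C-1={r} discriminant axes; keeping {d}",
            stacklevel=2,
        )
        r = d
    S_B, S_W = _scatter_matrices(z_train, labels, diagonal=(scatter == "diagonal"))
    ridge = RIDGE_SCALE * np.trace(S_W) / d
    S_W_reg = S_W + ridge * np.eye(d)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(S_B, S_W_reg)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            f"within-class scatter is singular even after ridge {ridge:g}"
        ) from exc
    order = np.argsort(eigvals)[::-1][:r]
    W = eigvecs[:, order]
    for j in range(W.shape[1]):
        col = W[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            col *= -1.0
        norm = np.linalg.norm(col)
        if norm > 0:
            W[:, j] = col / norm
    return W, float(ridge)


def fit_discriminants(
    z_lda_train: np.ndarray,
    labels: LabelVector,
    W: np.ndarray | None = None,
    scatter_ridge: float = 0.0,
) -> LDAModel:
    """Class means, pooled within-class covariance, priors and (w_c, b_c)."""
    Z = np.asarray(z_lda_train, dtype=float)
    n, r = Z.shape
    classes = labels.class_set
    C = len(classes)
    if n <= C:
        raise ValueError(f"need more cells than classes (n={n}, C={C}) for the 1/(n-C) scaling")
    means = np.vstack([Z[labels.labels == c].mean(axis=0) for c in classes])
    S = np.zeros((r, r))
    for ci, c in enumerate(classes):
        Rc = Z[labels.labels == c] - means[ci]
        S += Rc.T @ Rc
    sigma_w = S / (n - C)
    priors = labels.counts() / n
    ridge = 0.0
    try:
        coef = np.linalg.solve(sigma_w, means.T).T
    except np.linalg.LinAlgError:
        ridge = RIDGE_SCALE * max(np.trace(sigma_w) / r, 1.0)
        sigma_w = sigma_w + ridge * np.eye(r)
        coef = np.linalg.solve(sigma_w, means.T).T
    intercept = -0.5 * np.einsum("cr,cr->c", means, coef) + np.log(priors)
    if W is None:
        W = np.eye(r)
    return LDAModel(W, classes, means, sigma_w, priors, coef, intercept, ridge, scatter_ridge)


def decision_function(z_test: np.ndarray, model: LDAModel) -> np.ndarray:
    """Per-class discriminant values delta_c for already-selected PC scores."""
    Z = np.asarray(z_test, dtype=float)
    if Z.ndim == 1:
        Z = Z[None, :]
    if Z.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"score dimension {Z.shape[1]} does not match projection rows {model.W.shape[0]}"
        )
    z_lda = Z @ model.W
    return z_lda @ model.coef.T + model.intercept


def _softmax(delta: np.ndarray) -> np.ndarray:
    shifted = delta - delta.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def predict(z_test: np.ndarray, model: LDAModel, cell_ids: np.ndarray | None = None) -> PredictionTable:
    """Assign each cell to argmax_c delta_c; posteriors are softmax(delta).

    Exact ties go to the first class in canonical (first-appearance) order.
    """
    delta = decision_function(z_test, model)
    if cell_ids is None:
        cell_ids = np.array([f"cell_{i}" for i in range(delta.shape[0])], dtype=object)
    idx = np.argmax(delta, axis=1)  # argmax takes the first maximum: canonical tie-break
    labels = model.classes[idx]
    return PredictionTable(cell_ids, labels, _softmax(delta), model.classes, delta)


@dataclass
class ConfidenceTable:
    """Per-class mean winning posterior; NaN for classes never predicted."""

    classes: np.ndarray
    values: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"class": self.classes, "confidence": self.values})


def confidence_scores(pred: PredictionTable) -> ConfidenceTable:
    """Average the predicted-class posterior over cells assigned to each class."""
    vals = np.full(len(pred.classes), np.nan)
    for ci, c in enumerate(pred.classes):
        mask = pred.predicted_labels == c
        if mask.any():
            vals[ci] = pred.posteriors[mask, ci].mean()
    return ConfidenceTable(pred.classes, vals)


def apply_unknown_threshold(pred: PredictionTable, tau: float) -> PredictionTable:
    """Relabel cells whose maximum posterior falls below tau as "Unknown"."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    labels = pred.predicted_labels.copy()
    if len(pred):
        labels[pred.max_posterior < tau] = UNKNOWN_LABEL
    return PredictionTable(
        pred.cell_ids, labels, pred.posteriors, pred.classes, pred.decision_values
    )
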