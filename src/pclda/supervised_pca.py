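"""PCA on pooled reference+query expression with supervised PC selection.

The transductive default fits the decomposition on the concatenated
reference and query matrices (restricted to the screened gene set), so the
components capture structure shared across platforms.  Components are then
ranked not by explained variance but by the between-class / within-class
variance ratio R_k of their reference scores, mirroring the objective of the
downstream discriminant classifier.  An inductive (reference-only) fit and a
plain variance ranking are available for the ablation modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import LabelVector
from .preprocess import ExpressionMatrix


@dataclass
class JointPCAModel:
    """Fitted principal components with reference and query scores.

    ``gene_means`` (and ``gene_stds`` when standardizing) are computed over
    the cells the decomposition was fitted on — pooled cells for the joint
    fit, reference cells for the inductive fit.
    """

    gene_ids: np.ndarray
    gene_means: np.ndarray
    gene_stds: np.ndarray | None
    loadings: np.ndarray  # genes x m, orthonormal columns
    explained_variance: np.ndarray  # m, non-increasing
    scores_ref: np.ndarray  # n_ref x m
    scores_query: np.ndarray  # n_query x m
    fit_data: str  # "joint" or "ref"

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, expr: ExpressionMatrix) -> np.ndarray:
        """Project new cells (same gene order) onto the fitted components."""
        X = expr.values - self.gene_means
        if self.gene_stds is not None:
            X = X / self.gene_stds
        return X @ self.loadings


@dataclass
class PCSelection:
    """Discriminability ratios R_k and the retained component indices."""

    ratios: np.ndarray
    selected: np.ndarray | None = None  # ascending 0-based component indices
    d: int | None = None


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    # reproducibility convention: largest-magnitude loading entry positive
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]


def _fit_pca(
    ref: ExpressionMatrix,
    query: ExpressionMatrix,
    m: int | None,
    standardize: bool,
    fit_data: str,
) -> JointPCAModel:
    if not np.array_equal(ref.gene_ids, query.gene_ids):
        raise ValueError("reference and query must share an identical gene order")
    if fit_data == "joint":
        fit_X = np.vstack([ref.values, query.values])
    elif fit_data == "ref":
        fit_X = ref.values
    else:
        raise ValueError("fit_data must be 'joint' or 'ref'")
    n_fit, p = fit_X.shape
    rank_bound = min(n_fit - 1, p)
    if m is None:
        m = min(rank_bound, 500)
    if m < 1 or m > rank_bound:
        raise ValueError(f"m={m} exceeds the rank bound min(n_fit-1, p)={rank_bound}")
    means = fit_X.mean(axis=0)
    stds = None
    if standardize:
        stds = fit_X.std(axis=0, ddof=1)
        stds = np.where(stds == 0.0, 1.0, stds)
    X = fit_X - means
    if stds is not None:
        X = X / stds
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[:m].T.copy()
    scores_fit = U[:, :m] * S[:m]
    _fix_signs(loadings, scores_fit)
    explained = S[:m] ** 2 / (n_fit - 1)
    if fit_data == "joint":
        scores_ref = scores_fit[: ref.n_cells]
        scores_query = scores_fit[ref.n_cells :]
    else:
        scores_ref = scores_fit
        Xq = query.values - means
        if stds is not None:
            Xq = Xq / stds
        scores_query = Xq @ loadings
    return JointPCAModel(
        ref.gene_ids, means, stds, loadings, explained, scores_ref, scores_query, fit_data
    )


def fit_joint_pca(
    ref: ExpressionMatrix,
    query: ExpressionMatrix,
    m: int | None = None,
    standardize: bool = False,
) -> JointPCAModel:
    """Fit PCA on the pooled (reference + query) cells (transductive default).

    ``m`` defaults to min(n_pooled - 1, p, 500) components.
    """
    return _fit_pca(ref, query, m, standardize, "joint")


def fit_reference_pca(
    ref: ExpressionMatrix,
    query: ExpressionMatrix,
    m: int | None = None,
    standardize: bool = False,
) -> JointPCAModel:
    """Fit PCA on reference cells only and project the query (inductive)."""
    return _fit_pca(ref, query, m, standardize, "ref")


def discriminability_ratios(model: JointPCAModel, labels: LabelVector) -> PCSelection:
    """Between/within class variance ratio R_k of each component's reference scores.

    R_k = sum_c n_c (mu_ck - mu_k)^2  /  sum_c sum_{i in c} (z_ik - mu_ck)^2.
    A zero within-class variance yields +inf when the between term is positive
    (the component separates classes perfectly) and 0 otherwise.
    """
    Z = model.scores_ref
    if len(labels) != Z.shape[0]:
        raise ValueError("labels are not aligned to the reference scores")
    grand = Z.mean(axis=0)
    var_b = np.zeros(Z.shape[1])
    var_w = np.zeros(Z.shape[1])
    for c in labels.class_set:
        Zc = Z[labels.labels == c]
        mu_c = Zc.mean(axis=0)
        var_b += len(Zc) * (mu_c - grand) ** 2
        var_w += ((Zc - mu_c) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = var_b / var_w
    zero_w = var_w == 0.0
    ratios[zero_w & (var_b > 0.0)] = np.inf
    ratios[zero_w & (var_b == 0.0)] = 0.0
    return PCSelection(ratios)


def select_pcs(
    sel: PCSelection, d: int, model: JointPCAModel
) -> tuple[PCSelection, np.ndarray, np.ndarray]:
    """Retain the d components with the largest R_k.

    Ties are broken toward the smaller component index; the selection is
    reported (and the score columns returned) in ascending component order.
    """
    m = model.n_components
    if d < 1 or d > m:
        raise ValueError(f"d={d} must be in 1..{m}")
    order = np.argsort(-sel.ratios, kind="stable")  # stable: ties by index
    chosen = np.sort(order[:d])
    out = PCSelection(sel.ratios, chosen, d)
    return out, model.scores_ref[:, chosen], model.scores_query[:, chosen]


def select_top_variance_pcs(
    model: JointPCAModel, d: int
) -> tuple[PCSelection, np.ndarray, np.ndarray]:
    """Conventional selection: the first d components by explained variance."""
    m = model.n_components
    if d < 1 or d > m:
        raise ValueError(f"d={d} must be in 1..{m}")
    chosen = np.arange(d)
    out = PCSelection(model.explained_variance.copy(), chosen, d)
    return out, model.scores_ref[:, chosen], model.scores_query[:, chosen]
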