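"""Normalization and marker-gene screening.

Normalization is log-transformed library-size scaling to 10,000 counts per
cell: ``x' = log2(1 + 1e4 * x / libsize)``.  Screening ranks genes per cell
type by the magnitude of a one-vs-rest Welch t-score computed on the
normalized values and pools the per-type top-k sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import CountMatrix, LabelVector

logger = logging.getLogger(__name__)

SCALE_FACTOR = 1e4  # counts-per-10k normalization target


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, cells x genes."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: np.ndarray) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        cols = np.array([idx[g] for g in gene_ids], dtype=int)
        return ExpressionMatrix(self.values[:, cols], self.cell_ids, np.asarray(gene_ids, dtype=object))


@dataclass
class GeneScreenResult:
    """Per-gene per-class t-scores and, once selected, the pooled gene set."""

    t_scores: np.ndarray  # genes x classes, signed
    gene_ids: np.ndarray
    classes: np.ndarray
    selected_genes: np.ndarray | None = None
    k: int | None = None


def drop_zero_library_cells(raw: CountMatrix) -> CountMatrix:
    """Remove cells whose total count is zero (normalization is undefined)."""
    lib = raw.values.sum(axis=1)
    keep = lib > 0
    if not np.all(keep):
        dropped = raw.cell_ids[~keep]
        warnings.warn(
            f"dropping {len(dropped)} cell(s) with zero library size: "
            f"{[str(c) for c in dropped[:5]]}",
            stacklevel=2,
        )
        logger.warning("dropped %d zero-library cells", len(dropped))
        return raw.subset_cells(keep)
    return raw


def normalize_log_cpm(raw: CountMatrix) -> ExpressionMatrix:
    """Library-size normalize to 10k counts and log2(1 + .) transform.

    Every cell must have a positive library size; run
    :func:`drop_zero_library_cells` first if that is not guaranteed.
    """
    lib = raw.values.sum(axis=1)
    if np.any(lib <= 0):
        bad = raw.cell_ids[lib <= 0]
        raise ValueError(f"zero library size for cell(s): {[str(c) for c in bad[:5]]}")
    values = np.log2(1.0 + SCALE_FACTOR * raw.values / lib[:, None])
    return ExpressionMatrix(values, raw.cell_ids, raw.gene_ids)


def welch_t_scores(expr: ExpressionMatrix, labels: LabelVector) -> GeneScreenResult:
    """One-vs-rest Welch t-score per gene and class.

    T = (mean_class - mean_rest) / sqrt(var_class/n_class + var_rest/n_rest)
    with unbiased (n-1 denominator) variances.  A zero denominator yields 0
    when the numerator is zero and a sign-matched infinity otherwise, so that
    perfectly separating genes rank first.
    """
    if len(labels) != expr.n_cells:
        raise ValueError("labels are not aligned to the expression matrix")
    X = expr.values
    classes = labels.class_set
    T = np.empty((expr.n_genes, len(classes)), dtype=float)
    for ci, c in enumerate(classes):
        mask = labels.labels == c
        n_c = int(mask.sum())
        n_r = int(len(labels) - n_c)
        if n_c < 2 or n_r < 2:
            raise ValueError(
                f"class {c!r} needs at least 2 cells in and out of the class "
                f"(got {n_c} in, {n_r} out)"
            )
        xc, xr = X[mask], X[~mask]
        diff = xc.mean(axis=0) - xr.mean(axis=0)
        denom = np.sqrt(xc.var(axis=0, ddof=1) / n_c + xr.var(axis=0, ddof=1) / n_r)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / denom
        zero_den = denom == 0.0
        t[zero_den & (diff == 0.0)] = 0.0
        t[zero_den & (diff > 0.0)] = np.inf
        t[zero_den & (diff < 0.0)] = -np.inf
        T[:, ci] = t
    return GeneScreenResult(T, expr.gene_ids, classes)


def select_genes(screen: GeneScreenResult, k: int = 400) -> GeneScreenResult:
    """Pool the per-class top-k genes by |t-score| into one ordered gene set.

    Ties at the k-th rank are broken by gene order (lower index first); the
    pooled set is returned in reference gene order.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    abs_t = np.abs(screen.t_scores)
    p = abs_t.shape[0]
    keep = np.zeros(p, dtype=bool)
    for ci in range(abs_t.shape[1]):
        order = np.argsort(-abs_t[:, ci], kind="stable")  # stable: ties by gene index
        keep[order[: min(k, p)]] = True
    selected = screen.gene_ids[keep]
    return GeneScreenResult(screen.t_scores, screen.gene_ids, screen.classes, selected, k)
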