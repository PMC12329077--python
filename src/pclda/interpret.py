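"""Per-gene linear coefficients of the end-to-end decision rule.

Because screening is a mask and PCA and LDA are linear maps, each class
discriminant is an affine function of the normalized expression of the
original genes:

    delta_c(x) = beta_c' (x_G - gene_means) + b_c,
    beta_c = V_sel @ W @ w_c,

where V_sel holds the loadings of the selected components, W the Fisher
projection and w_c the class discriminant vector.  Genes outside the screened
set G carry exactly zero weight.  The sign of a coefficient gives the effect
direction (enriched vs depleted in the class) and its magnitude the effect
size on the reported expression scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lda_classifier import LDAModel
from .supervised_pca import JointPCAModel, PCSelection


@dataclass
class GeneWeightMatrix:
    """Per-gene per-class coefficients on the full (pre-screening) gene axis."""

    coefficients: np.ndarray  # p x C; zero rows outside the screened set
    gene_ids: np.ndarray  # all p genes
    classes: np.ndarray
    intercepts: np.ndarray  # per-class b_c (centering offsets are separate)
    gene_means: np.ndarray  # |G| centering offsets on the screened genes
    gene_stds: np.ndarray | None  # |G| scale, when standardized PCA was used
    selected_genes: np.ndarray  # G, reference order
    scale: str  # "log2(1+CPM/100)" or "standardized log2(1+CPM/100)"
    provenance: dict = field(default_factory=dict)  # (k, d, mode, ...) configuration

    def decision_values(self, expr_on_selected: np.ndarray) -> np.ndarray:
        """Recompute delta_c from gene space for cells x |G| normalized values."""
        X = np.asarray(expr_on_selected, dtype=float) - self.gene_means
        if self.gene_stds is not None:
            X = X / self.gene_stds
        gidx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = np.array([gidx[g] for g in self.selected_genes], dtype=int)
        return X @ self.coefficients[rows] + self.intercepts


def compose_gene_weights(
    pca: JointPCAModel | None,
    sel: PCSelection | None,
    lda: LDAModel,
    gene_set: np.ndarray,
    all_genes: np.ndarray,
    provenance: dict | None = None,
) -> GeneWeightMatrix:
    """Collapse screening mask, PCA loadings and LDA weights into gene weights.

    When the pipeline ran without a PCA stage, the loadings default to the
    identity on the screened genes.  Additive constants (centering offsets and
    b_c) are kept as a separate per-class intercept, never folded into the
    gene coefficients.
    """
    gene_set = np.asarray(gene_set, dtype=object)
    all_genes = np.asarray(all_genes, dtype=object)
    G = len(gene_set)
    if pca is None:
        V_sel = np.eye(G)
        gene_means = np.zeros(G)
        gene_stds = None
        scale = "log2(1+CPM/100)"
    else:
        if sel is None or sel.selected is None:
            raise ValueError("a PCSelection with selected components is required with a PCA model")
        if pca.loadings.shape[0] != G:
            raise ValueError(
                f"loadings cover {pca.loadings.shape[0]} genes but the gene set has {G}"
            )
        V_sel = pca.loadings[:, sel.selected]
        gene_means = pca.gene_means
        gene_stds = pca.gene_stds
        scale = (
            "standardized log2(1+CPM/100)" if pca.gene_stds is not None else "log2(1+CPM/100)"
        )
    if V_sel.shape[1] != lda.W.shape[0]:
        raise ValueError(
            f"selected components ({V_sel.shape[1]}) do not match projection rows ({lda.W.shape[0]})"
        )
    beta_G = V_sel @ lda.W @ lda.coef.T  # |G| x C
    gidx = {g: i for i, g in enumerate(all_genes)}
    coefficients = np.zeros((len(all_genes), len(lda.classes)))
    rows = np.array([gidx[g] for g in gene_set], dtype=int)
    coefficients[rows] = beta_G
    return GeneWeightMatrix(
        coefficients,
        all_genes,
        lda.classes,
        lda.intercept.copy(),
        np.asarray(gene_means, dtype=float),
        None if gene_stds is None else np.asarray(gene_stds, dtype=float),
        gene_set,
        scale,
        provenance or {},
    )


def top_genes(weights: GeneWeightMatrix, class_label: str, n: int = 100) -> pd.DataFrame:
    """Rank the screened genes of one class by absolute coefficient.

    Returns up to n rows (gene_id, coefficient, rank), descending by
    |coefficient| with ties broken by gene order; signed values are retained
    so effect direction is readable.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    matches = np.nonzero(weights.classes == class_label)[0]
    if len(matches) == 0:
        raise KeyError(f"unknown class {class_label!r}")
    ci = int(matches[0])
    gidx = {g: i for i, g in enumerate(weights.gene_ids)}
    rows = np.array([gidx[g] for g in weights.selected_genes], dtype=int)
    coefs = weights.coefficients[rows, ci]
    order = np.argsort(-np.abs(coefs), kind="stable")[: min(n, len(rows))]
    return pd.DataFrame(
        {
            "gene_id": weights.selected_genes[order],
            "class": class_label,
            "coefficient": coefs[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )


def write_gene_weights(weights: GeneWeightMatrix, path, top: int = 100) -> None:
    """TSV export: gene_id, class, coefficient, rank, top genes per class."""
    frames = [top_genes(weights, c, top) for c in weights.classes]
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# coefficient scale: {weights.scale}\n")
        for key, val in weights.provenance.items():
            fh.write(f"# {key}: {val}\n")
        out.to_csv(fh, sep="\t", index=False)
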