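"""Model/results front end over the pipeline.

`PCLDA` bundles a labeled reference, a query, and a `PipelineConfig`;
`fit()` runs the configured pipeline and returns a `PCLDAResults` carrying
the predictions, posteriors, per-class confidence scores, the fitted stage
objects and the gene-level coefficients, with a `summary()` table.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import interpret, io_formats, pipeline
from .io_formats import CountMatrix, LabelVector
from .pipeline import PipelineConfig, PipelineFit


class PCLDA:
    """Cell-type annotation model: screening + supervised PCA + LDA.

    Parameters
    ----------
    ref, ref_labels
        Labeled reference counts (cells x genes).
    query
        Query counts to annotate; shares genes with the reference by
        case-sensitive identifier intersection.
    config, **overrides
        A `PipelineConfig`, optionally with field overrides (k, d, mode, ...).
    """

    def __init__(
        self,
        ref: CountMatrix,
        ref_labels: LabelVector,
        query: CountMatrix,
        config: PipelineConfig | None = None,
        **overrides,
    ) -> None:
        self.ref = ref
        self.ref_labels = ref_labels
        self.query = query
        cfg = config or PipelineConfig()
        self.config = replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def from_files(
        cls,
        ref_path: str | Path,
        labels_path: str | Path,
        query_path: str | Path,
        format: str = "mtx_dir",
        **overrides,
    ) -> "PCLDA":
        ref = io_formats.read_count_matrix(ref_path, format)
        labels = io_formats.read_labels(labels_path, ref.cell_ids)
        query = io_formats.read_count_matrix(query_path, format)
        return cls(ref, labels, query, **overrides)

    @classmethod
    def from_dataframes(
        cls,
        ref: pd.DataFrame,
        ref_labels: pd.Series,
        query: pd.DataFrame,
        **overrides,
    ) -> "PCLDA":
        """Build from cells x genes DataFrames and a label Series aligned to ref rows."""
        ref_cm = CountMatrix(ref.to_numpy(dtype=float), ref.index.to_numpy(object), ref.columns.to_numpy(object))
        query_cm = CountMatrix(
            query.to_numpy(dtype=float), query.index.to_numpy(object), query.columns.to_numpy(object)
        )
        labels = LabelVector(ref_labels.reindex(ref.index).to_numpy(object))
        return cls(ref_cm, labels, query_cm, **overrides)

    def fit(self) -> "PCLDAResults":
        fit = pipeline.run_pclda(self.ref, self.ref_labels, self.query, self.config)
        return PCLDAResults(self, fit)


class PCLDAResults:
    """Fitted pipeline: predictions, confidence, coefficients, diagnostics."""

    def __init__(self, model: PCLDA, fit: PipelineFit) -> None:
        self.model = model
        self.fit_ = fit
        self.config = fit.config
        self.predictions = fit.predictions
        self.confidence = fit.confidence
        self.classes = fit.classes
        self._weights: interpret.GeneWeightMatrix | None = None

    # -- estimates -----------------------------------------------------------

    @property
    def predicted_labels(self) -> np.ndarray:
        return self.predictions.predicted_labels

    @property
    def posteriors(self) -> np.ndarray:
        return self.predictions.posteriors

    def gene_weights(self) -> interpret.GeneWeightMatrix:
        if self._weights is None:
            self._weights = self.fit_.gene_weights()
        return self._weights

    def top_genes(self, class_label: str, n: int = 100) -> pd.DataFrame:
        return interpret.top_genes(self.gene_weights(), class_label, n)

    def accuracy(self, truth: LabelVector, truth_cells: np.ndarray | None = None) -> pipeline.EvalReport:
        if truth_cells is not None:
            truth = pipeline.align_truth(self.predictions, truth, truth_cells)
        return pipeline.accuracy(self.predictions, truth, tau=self.config.tau)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        fit = self.fit_
        lines = [
            "PCLDA results",
            "=" * 60,
            f"mode            : {self.config.mode}",
            f"reference cells : {len(self.model.ref_labels)}",
            f"query cells     : {len(self.predictions)}",
            f"shared genes    : {len(fit.gene_ids)}",
            f"screened genes  : {len(fit.selected_genes)} (k={self.config.k} per type)",
        ]
        if fit.pca is not None:
            lines.append(
                f"PCA             : {fit.pca.fit_data} fit, {fit.pca.n_components} components, "
                f"d={len(fit.pc_selection.selected)} selected"
            )
        lines.append(f"classes         : {len(self.classes)}")
        lines.append("-" * 60)
        lines.append(f"{'class':<24}{'n predicted':>12}{'confidence':>14}")
        for ci, c in enumerate(self.classes):
            n_pred = int((self.predictions.predicted_labels == c).sum())
            conf = self.confidence.values[ci]
            conf_s = f"{conf:.4f}" if np.isfinite(conf) else "NA"
            lines.append(f"{str(c):<24}{n_pred:>12}{conf_s:>14}")
        n_unknown = int((self.predictions.predicted_labels == "Unknown").sum())
        if n_unknown:
            lines.append(f"{'Unknown':<24}{n_unknown:>12}{'-':>14}")
        return "\n".join(lines)

    def write(self, predictions_path: str | Path, confidence_path: str | Path | None = None) -> None:
        io_formats.write_predictions(self.predictions, predictions_path)
        if confidence_path is not None:
            self.confidence.to_frame().to_csv(confidence_path, sep="\t", index=False)
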