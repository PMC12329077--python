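"""Pipeline orchestration, ablation variants, cross-validation and accuracy.

The full pipeline composes the three stages: gene screening on the reference,
PCA on the pooled reference+query cells with ratio-based PC selection, and an
LDA classifier fitted on the reference scores.  Ablation modes omit or swap
individual stages:

====================  ======================================================
mode                  stages
====================  ======================================================
``full``              screening + joint PCA + ratio selection + LDA
``lda_only``          LDA on the normalized expression matrix directly
``screen_lda``        screening + LDA (no PCA)
``pca_lda``           reference-only PCA + variance selection + LDA
``topPC``             screening + joint PCA + variance selection + LDA
``refPCA``            screening + reference-only PCA + ratio selection + LDA
====================  ======================================================
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import interpret, lda_classifier, preprocess, supervised_pca
from .io_formats import CountMatrix, LabelVector, PredictionTable, intersect_genes
from .lda_classifier import UNKNOWN_LABEL, ConfidenceTable, LDAModel

logger = logging.getLogger(__name__)

MODES = ("full", "lda_only", "screen_lda", "pca_lda", "topPC", "refPCA")

#: dimensionality above which ``lda_only`` refuses to run without force
LDA_ONLY_GENE_LIMIT = 20_000

DEFAULT_GENE_GRID = (10, 50, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000)
DEFAULT_PC_GRID = (10, 50, 100, 150, 200, 250, 300, 350, 400, 450, 500)


@dataclass
class PipelineConfig:
    """Tunable parameters of one pipeline run."""

    k: int = 400  # genes kept per cell type in screening
    d: int = 200  # PCs retained for the classifier
    m_max: int = 500  # components computed before selection
    mode: str = "full"
    scatter: str = "full"  # "full" or "diagonal" scatter matrices in the LDA solve
    standardize: bool = False  # per-gene unit variance before PCA
    tau: float = 0.0  # posterior threshold for the "Unknown" label
    seed: int = 0
    force: bool = False  # allow lda_only beyond the gene limit

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.scatter not in ("full", "diagonal"):
            raise ValueError("scatter must be 'full' or 'diagonal'")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if "tau" in data:
            cfg.tau = float(data["tau"])
        return cfg


@dataclass
class PipelineFit:
    """Everything a pipeline run fitted and produced."""

    config: PipelineConfig
    predictions: PredictionTable
    confidence: ConfidenceTable
    lda: LDAModel
    classes: np.ndarray
    gene_ids: np.ndarray  # shared genes after intersection
    selected_genes: np.ndarray  # G (equals gene_ids when screening is off)
    screen: preprocess.GeneScreenResult | None = None
    pca: supervised_pca.JointPCAModel | None = None
    pc_selection: supervised_pca.PCSelection | None = None
    query_expr_selected: np.ndarray | None = None  # normalized query values on G

    def gene_weights(self) -> interpret.GeneWeightMatrix:
        """Per-gene per-class coefficients of the end-to-end decision rule."""
        return interpret.compose_gene_weights(
            self.pca,
            self.pc_selection,
            self.lda,
            self.selected_genes,
            self.gene_ids,
            provenance={
                "k": self.config.k,
                "d": self.config.d,
                "mode": self.config.mode,
                "standardize": self.config.standardize,
            },
        )


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s %.2fs", name, t1 - t0)
    return t1


def run_pclda(
    ref: CountMatrix,
    ref_labels: LabelVector,
    query: CountMatrix,
    config: PipelineConfig | None = None,
) -> PipelineFit:
    """Annotate query cells from a labeled reference in the configured mode."""
    config = config or PipelineConfig()
    if ref_labels.n_classes < 2:
        raise ValueError("pipeline stage labels: reference must contain at least 2 classes")
    t0 = time.perf_counter()

    if len(ref_labels) != ref.n_cells:
        raise ValueError("pipeline stage preprocess: labels not aligned to reference cells")
    ref, query = intersect_genes(ref, query)
    lib = ref.values.sum(axis=1)
    if np.any(lib <= 0):
        keep = lib > 0
        warnings.warn(
            f"dropping {int((~keep).sum())} reference cell(s) with zero library size",
            stacklevel=2,
        )
        ref = ref.subset_cells(keep)
        ref_labels = ref_labels.subset(keep)
    query = preprocess.drop_zero_library_cells(query)
    t0 = _stage("io", t0)

    try:
        ref_expr = preprocess.normalize_log_cpm(ref)
        query_expr = preprocess.normalize_log_cpm(query)
    except ValueError as exc:
        raise ValueError(f"pipeline stage normalize: {exc}") from exc
    t0 = _stage("normalize", t0)

    screen = None
    if config.mode in ("full", "screen_lda", "topPC", "refPCA"):
        try:
            screen = preprocess.select_genes(
                preprocess.welch_t_scores(ref_expr, ref_labels), config.k
            )
        except ValueError as exc:
            raise ValueError(f"pipeline stage screen: {exc}") from exc
        G = screen.selected_genes
        ref_expr = ref_expr.subset_genes(G)
        query_expr = query_expr.subset_genes(G)
        t0 = _stage("screen", t0)
    elif config.mode == "lda_only" and ref_expr.n_genes > LDA_ONLY_GENE_LIMIT and not config.force:
        raise ValueError(
            f"pipeline stage lda: refusing lda_only with {ref_expr.n_genes} genes "
            f"(> {LDA_ONLY_GENE_LIMIT}); use screening/PCA or set force=True"
        )
    G = ref_expr.gene_ids

    pca_model = None
    pc_sel = None
    if config.mode in ("full", "topPC", "refPCA", "pca_lda"):
        n_fit = (
            ref_expr.n_cells + query_expr.n_cells
            if config.mode in ("full", "topPC")
            else ref_expr.n_cells
        )
        m = min(n_fit - 1, ref_expr.n_genes, config.m_max)
        fit = (
            supervised_pca.fit_joint_pca
            if config.mode in ("full", "topPC")
            else supervised_pca.fit_reference_pca
        )
        try:
            pca_model = fit(ref_expr, query_expr, m=m, standardize=config.standardize)
        except ValueError as exc:
            raise ValueError(f"pipeline stage pca: {exc}") from exc
        d_eff = min(config.d, m)
        if d_eff < config.d:
            warnings.warn(
                f"d={config.d} capped at {d_eff} available components", stacklevel=2
            )
        if config.mode in ("full", "refPCA"):
            ratios = supervised_pca.discriminability_ratios(pca_model, ref_labels)
            pc_sel, z_train, z_test = supervised_pca.select_pcs(ratios, d_eff, pca_model)
        else:
            pc_sel, z_train, z_test = supervised_pca.select_top_variance_pcs(pca_model, d_eff)
        t0 = _stage("pca", t0)
    else:
        z_train = ref_expr.values
        z_test = query_expr.values

    try:
        W, scatter_ridge = lda_classifier.fit_lda_projection(
            z_train, ref_labels, scatter=config.scatter
        )
        model = lda_classifier.fit_discriminants(
            z_train @ W, ref_labels, W=W, scatter_ridge=scatter_ridge
        )
        pred = lda_classifier.predict(z_test, model, cell_ids=query_expr.cell_ids)
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise type(exc)(f"pipeline stage lda: {exc}") from exc
    if config.tau > 0.0:
        pred = lda_classifier.apply_unknown_threshold(pred, config.tau)
    conf = lda_classifier.confidence_scores(pred)
    _stage("lda", t0)

    return PipelineFit(
        config=config,
        predictions=pred,
        confidence=conf,
        lda=model,
        classes=ref_labels.class_set,
        gene_ids=ref.gene_ids,
        selected_genes=G,
        screen=screen,
        pca=pca_model,
        pc_selection=pc_sel,
        query_expr_selected=query_expr.values,
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Accuracy plus a confusion table; per-fold accuracies under CV."""

    accuracy: float
    confusion: pd.DataFrame
    n_cells: int
    n_unknown: int = 0
    n_unknown_novel: int = 0  # Unknown predictions whose truth is outside the reference classes
    per_fold: list[float] | None = None


def accuracy(pred: PredictionTable, truth: LabelVector, tau: float = 0.0) -> EvalReport:
    """Fraction of cells whose predicted label matches the ground truth.

    "Unknown" predictions count as incorrect, except that when a rejection
    threshold was active (tau > 0) and the true label is absent from the
    reference classes, the cell is excluded from the denominator and reported
    separately (the rejection was correct behaviour, not a misclassification).
    """
    if len(pred) == 0:
        raise ValueError("empty prediction table")
    if len(truth) != len(pred):
        raise ValueError("prediction and truth cover different numbers of cells")
    y_pred = pred.predicted_labels
    y_true = truth.labels
    ref_classes = set(pred.classes)
    unknown = y_pred == UNKNOWN_LABEL
    novel = np.array([t not in ref_classes for t in y_true])
    excluded = unknown & novel if tau > 0 else np.zeros(len(pred), dtype=bool)
    scored = ~excluded
    if not scored.any():
        raise ValueError("no cells left to score after excluding rejected novel cells")
    acc = float(np.mean(y_pred[scored] == y_true[scored]))
    confusion = pd.crosstab(
        pd.Series(y_true, name="truth"), pd.Series(y_pred, name="predicted")
    )
    return EvalReport(
        accuracy=acc,
        confusion=confusion,
        n_cells=int(scored.sum()),
        n_unknown=int(unknown.sum()),
        n_unknown_novel=int((unknown & novel).sum()),
    )


def align_truth(pred: PredictionTable, truth_labels: LabelVector, truth_cells: np.ndarray) -> LabelVector:
    """Reorder ground-truth labels to the prediction table's cell order."""
    mapping = dict(zip(np.asarray(truth_cells, dtype=object), truth_labels.labels))
    missing = [str(c) for c in pred.cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"cells without ground truth: {missing[:10]}")
    return LabelVector(np.array([mapping[c] for c in pred.cell_ids], dtype=object))


def cross_validate(
    data: CountMatrix,
    labels: LabelVector,
    folds: int = 5,
    config: PipelineConfig | None = None,
) -> EvalReport:
    """Stratified k-fold cross-validation of the configured pipeline.

    Folds are stratified by class and seeded from the config.  Classes with
    fewer cells than folds stay in every training fold (with a warning).
    Inside each fold the whole pipeline — screening, PCA, LDA — is re-fitted
    on the training cells, with the held-out cells playing the query role.
    """
    config = config or PipelineConfig()
    if folds < 2:
        raise ValueError("folds must be at least 2")
    rng = np.random.default_rng(config.seed)
    assignment = np.full(data.n_cells, -1, dtype=int)
    for c in labels.class_set:
        idx = np.nonzero(labels.labels == c)[0]
        if len(idx) < folds:
            warnings.warn(
                f"class {c!r} has {len(idx)} cells (< {folds} folds); kept in training only",
                stacklevel=2,
            )
            continue
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    per_fold: list[float] = []
    confusions: list[pd.DataFrame] = []
    n_correct = 0
    n_total = 0
    for f in range(folds):
        test = assignment == f
        train = ~test
        fit = run_pclda(
            data.subset_cells(train), labels.subset(train), data.subset_cells(test), config
        )
        truth = align_truth(fit.predictions, labels.subset(test), data.cell_ids[test])
        rep = accuracy(fit.predictions, truth, tau=config.tau)
        per_fold.append(rep.accuracy)
        confusions.append(rep.confusion)
        n_correct += int(round(rep.accuracy * rep.n_cells))
        n_total += rep.n_cells
    confusion = (
        pd.concat(confusions).groupby(level=0).sum() if confusions else pd.DataFrame()
    )
    return EvalReport(
        accuracy=n_correct / n_total,
        confusion=confusion,
        n_cells=n_total,
        per_fold=per_fold,
    )


def sensitivity_sweep(
    ref: CountMatrix,
    ref_labels: LabelVector,
    query: CountMatrix,
    query_labels: LabelVector,
    parameter: str = "genes",
    grid: tuple[int, ...] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Accuracy as a function of k (``parameter='genes'``) or d (``'pcs'``).

    One full pipeline run per grid point, all sharing the config seed.
    """
    config = config or PipelineConfig()
    if parameter not in ("genes", "pcs"):
        raise ValueError("parameter must be 'genes' or 'pcs'")
    if grid is None:
        grid = DEFAULT_GENE_GRID if parameter == "genes" else DEFAULT_PC_GRID
    rows = []
    for value in grid:
        cfg = replace(config, k=value) if parameter == "genes" else replace(config, d=value)
        fit = run_pclda(ref, ref_labels, query, cfg)
        truth = align_truth(fit.predictions, query_labels, query.cell_ids)
        rows.append({"parameter": parameter, "value": value,
                     "accuracy": accuracy(fit.predictions, truth, tau=cfg.tau).accuracy})
    return pd.DataFrame(rows)


def ablation_table(
    ref: CountMatrix,
    ref_labels: LabelVector,
    query: CountMatrix,
    query_labels: LabelVector,
    modes: tuple[str, ...] = ("full", "topPC", "refPCA", "screen_lda", "pca_lda"),
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Run the requested ablation modes on one reference/query pair."""
    config = config or PipelineConfig()
    rows = []
    for mode in modes:
        cfg = replace(config, mode=mode)
        fit = run_pclda(ref, ref_labels, query, cfg)
        truth = align_truth(fit.predictions, query_labels, query.cell_ids)
        rows.append({"mode": mode,
                     "accuracy": accuracy(fit.predictions, truth, tau=cfg.tau).accuracy})
    return pd.DataFrame(rows)
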