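"""Readers and writers for the matrix and label formats the pipeline touches.

Canonical in-memory orientation is cells x genes.  Matrix Market files follow
the genes-as-rows convention of the 10x/CellRanger ecosystem and are transposed
at the boundary.  No numerics live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


def _check_unique(ids: np.ndarray, axis_name: str) -> None:
    if len(np.unique(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({str(x) for x in ids if str(x) in seen or seen.add(str(x))})
        raise FormatError(f"duplicate {axis_name} identifiers: {dups[:10]}")


@dataclass
class CountMatrix:
    """Raw counts, cells x genes, with unique cell and gene identifiers."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.ndim != 2:
            raise FormatError("count matrix must be two-dimensional")
        n, p = self.values.shape
        if len(self.cell_ids) != n:
            raise FormatError(
                f"{len(self.cell_ids)} cell identifiers for {n} matrix rows"
            )
        if len(self.gene_ids) != p:
            raise FormatError(
                f"{len(self.gene_ids)} gene identifiers for {p} matrix columns"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative count at cell {self.cell_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: np.ndarray) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        cols = np.array([idx[g] for g in gene_ids], dtype=int)
        return CountMatrix(self.values[:, cols], self.cell_ids, np.asarray(gene_ids, dtype=object))

    def subset_cells(self, mask_or_index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[mask_or_index], self.cell_ids[mask_or_index], self.gene_ids)


@dataclass
class LabelVector:
    """Per-cell class labels.

    ``class_set`` is the canonical class order used everywhere downstream:
    first-appearance order of the labels.
    """

    labels: np.ndarray
    class_set: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.class_set is None:
            self.class_set = pd.unique(self.labels)
        self.class_set = np.asarray(self.class_set, dtype=object)
        known = set(self.class_set)
        bad = sorted({str(x) for x in self.labels if x not in known})
        if bad:
            raise FormatError(f"labels outside class_set: {bad[:10]}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    def counts(self) -> np.ndarray:
        return np.array([(self.labels == c).sum() for c in self.class_set], dtype=int)

    def subset(self, mask_or_index: np.ndarray) -> "LabelVector":
        return LabelVector(self.labels[mask_or_index])


@dataclass
class PredictionTable:
    """Predicted labels with per-class posterior probabilities.

    ``decision_values`` carries the raw per-class discriminant scores
    (log-posterior up to an additive constant) when the classifier provides
    them; the posterior is their softmax.
    """

    cell_ids: np.ndarray
    predicted_labels: np.ndarray
    posteriors: np.ndarray  # cells x classes, rows sum to 1
    classes: np.ndarray
    decision_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.predicted_labels = np.asarray(self.predicted_labels, dtype=object)
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        n = len(self.cell_ids)
        if self.posteriors.shape != (n, len(self.classes)):
            raise FormatError("posterior matrix shape does not match cells x classes")
        if n and (np.any(self.posteriors < -1e-12) or np.any(self.posteriors > 1 + 1e-12)):
            raise FormatError("posteriors outside [0, 1]")
        if n and np.max(np.abs(self.posteriors.sum(axis=1) - 1.0)) > 1e-9:
            raise FormatError("posterior rows must sum to 1 within 1e-9")

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def max_posterior(self) -> np.ndarray:
        return self.posteriors.max(axis=1) if len(self) else np.empty(0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.cell_ids, "predicted_label": self.predicted_labels})
        for j, c in enumerate(self.classes):
            df[str(c)] = self.posteriors[:, j] if len(self) else pd.Series(dtype=float)
        return df


# ---------------------------------------------------------------------------
# count-matrix IO


def _find_negative_mtx_line(path: Path) -> str:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("%"):
                continue
            parts = s.split()
            if len(parts) >= 3:
                try:
                    if float(parts[-1]) < 0:
                        return f"line {lineno}: {s!r}"
                except ValueError:
                    continue
    return "unknown line"


def _read_id_column(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def _locate(directory: Path, names: tuple[str, ...], what: str) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"no {what} file found in {directory} (looked for {', '.join(names)})")


def read_count_matrix(path: str | Path, format: str = "mtx_dir") -> CountMatrix:
    """Read a counts file into cells x genes orientation.

    ``mtx_dir`` expects a directory with ``matrix.mtx`` plus ``genes.tsv`` (or
    ``features.tsv``) and ``barcodes.tsv``; the Matrix Market file is genes x
    cells with 1-based triplet indices and is transposed on read.
    ``dense_tsv`` expects a delimited table with cell rows, a leading cell-id
    column and a gene-id header.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if format == "mtx_dir":
        mtx = _locate(path, ("matrix.mtx",), "matrix.mtx")
        genes_path = _locate(path, ("genes.tsv", "features.tsv", "genes.txt"), "gene list")
        cells_path = _locate(path, ("barcodes.tsv", "barcodes.txt"), "barcode list")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:  # scipy raises ValueError on malformed headers
            raise FormatError(f"malformed Matrix Market file {mtx}: {exc}") from exc
        mat = scipy.sparse.coo_matrix(mat)
        genes = _read_id_column(genes_path)
        cells = _read_id_column(cells_path)
        if mat.shape[0] != len(genes):
            raise FormatError(
                f"{mtx} declares {mat.shape[0]} genes but {genes_path.name} lists {len(genes)}"
            )
        if mat.shape[1] != len(cells):
            raise FormatError(
                f"{mtx} declares {mat.shape[1]} cells but {cells_path.name} lists {len(cells)}"
            )
        if mat.nnz and mat.data.min() < 0:
            raise FormatError(f"negative entry in {mtx} at {_find_negative_mtx_line(mtx)}")
        values = np.asarray(mat.todense()).T  # genes x cells -> cells x genes
        return CountMatrix(values, cells, genes)
    if format == "dense_tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise FormatError(f"malformed dense table {path}: {exc}") from exc
        return CountMatrix(
            df.to_numpy(dtype=float),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
        )
    raise ValueError(f"unknown format {format!r}; expected 'mtx_dir' or 'dense_tsv'")


def write_count_matrix(mat: CountMatrix, path: str | Path, format: str = "mtx_dir") -> None:
    """Inverse of :func:`read_count_matrix`; used by the simulator CLI."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(mat.values.T)  # back to genes x cells
        scipy.io.mmwrite(path / "matrix.mtx", sparse)
        pd.Series(mat.gene_ids).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(mat.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
        return
    if format == "dense_tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.DataFrame(mat.values, index=mat.cell_ids, columns=mat.gene_ids)
        df.to_csv(path, sep=sep)
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# labels


def read_labels(path: str | Path, cells: np.ndarray) -> LabelVector:
    """Read a two-column (cell_id, label) file and align it to ``cells``.

    A header row is tolerated: the first row is dropped when its cell_id field
    is not a known cell identifier.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path} must have two columns (cell_id, label)")
    cells = np.asarray(cells, dtype=object)
    known = set(cells)
    if len(df) and df.iloc[0, 0] not in known:
        df = df.iloc[1:]
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    dup = pd.Series(ids)[pd.Series(ids).duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate cell_ids in label file: {dup[:10]}")
    mapping = dict(zip(ids, df.iloc[:, 1].to_numpy(dtype=object)))
    missing = [str(c) for c in cells if c not in mapping]
    if missing:
        raise FormatError(f"cells missing from label file: {missing[:10]}")
    return LabelVector(np.array([mapping[c] for c in cells], dtype=object))


def write_labels(labels: LabelVector, cells: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"cell_id": np.asarray(cells, dtype=object), "label": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# predictions


def write_predictions(pred: PredictionTable, path: str | Path) -> None:
    """Write cell_id, predicted_label and one posterior column per class."""
    pred.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path: str | Path) -> PredictionTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    classes = np.asarray(df.columns[2:], dtype=object)
    return PredictionTable(
        df["cell_id"].to_numpy(dtype=object),
        df["predicted_label"].to_numpy(dtype=object),
        df.iloc[:, 2:].to_numpy(dtype=float) if len(df) else np.empty((0, len(classes))),
        classes,
    )


# ---------------------------------------------------------------------------
# cross-dataset gene matching


def intersect_genes(ref: CountMatrix, query: CountMatrix) -> tuple[CountMatrix, CountMatrix]:
    """Restrict both matrices to their shared genes, preserving reference order.

    Matching is case-sensitive on the identifiers.  A warning is emitted when
    the overlap covers less than half of either gene set.
    """
    query_set = set(query.gene_ids)
    shared = np.array([g for g in ref.gene_ids if g in query_set], dtype=object)
    if len(shared) == 0:
        raise FormatError("reference and query share no gene identifiers")
    for name, total in (("reference", ref.n_genes), ("query", query.n_genes)):
        if len(shared) < 0.5 * total:
            warnings.warn(
                f"gene overlap ({len(shared)}) is below 50% of the {name} gene set ({total})",
                stacklevel=2,
            )
    return ref.subset_genes(shared), query.subset_genes(shared)
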