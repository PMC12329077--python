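"""Synthetic scRNA-seq count generator with planted cell-type structure.

Counts mimic the features the annotation pipeline relies on: per-type marker
genes with a known log2 fold change, widely varying library sizes, gene-level
overdispersion, optional dropout, and an optional multiplicative per-gene
platform shift applied to the query dataset only.

The sampling model conditions on the library size: each cell draws a total
depth uniformly from ``library_size_range``, perturbs its per-gene rates with
gamma noise (fixed dispersion 0.1, giving negative-binomial-like marginal
overdispersion), and distributes the depth multinomially.  Dropout then thins
entries with independent Bernoulli zeroing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CountMatrix, LabelVector

DISPERSION = 0.1  # fixed gamma overdispersion of per-cell-gene rates


@dataclass
class SimulationSpec:
    """Parameters of one reference/query simulation.

    ``batch_shift`` is a spread s >= 1: each gene of the query draws a
    multiplicative factor s**u with u ~ Uniform(-1, 1); s = 1 disables the
    shift.  ``base_mean`` may be a scalar, a per-gene array, or None to draw
    log-normal baseline rates.
    """

    n_types: int = 5
    cells_per_type: int = 100
    n_genes: int = 2000
    markers_per_type: int = 10
    marker_effect: float = 3.0  # log2 fold change of markers in their own type
    base_mean: float | np.ndarray | None = None
    library_size_range: tuple[int, int] = (1000, 5000)
    batch_shift: float = 1.0
    dropout_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_types < 2:
            raise ValueError("invalid field n_types: need at least 2 cell types")
        if self.cells_per_type < 2:
            raise ValueError("invalid field cells_per_type: need at least 2 cells per type")
        if self.n_genes < self.n_types * self.markers_per_type:
            raise ValueError("invalid field n_genes: too few genes for disjoint marker sets")
        if self.markers_per_type < 1:
            raise ValueError("invalid field markers_per_type: must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid field library_size_range: need 0 < low <= high")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("invalid field dropout_rate: must lie in [0, 1)")
        if self.batch_shift < 1.0:
            raise ValueError("invalid field batch_shift: spread must be >= 1")
        if np.ndim(self.base_mean) == 1 and len(np.atleast_1d(self.base_mean)) != self.n_genes:
            raise ValueError("invalid field base_mean: per-gene array must have n_genes entries")


@dataclass
class SimulatedDataset:
    """Reference/query count matrices with ground-truth labels and markers."""

    ref: CountMatrix
    ref_labels: LabelVector
    query: CountMatrix
    query_labels: LabelVector
    markers: dict = field(default_factory=dict)  # type label -> marker gene ids
    batch_factors: np.ndarray | None = None

    def __iter__(self):
        return iter((self.ref, self.ref_labels, self.query, self.query_labels))


def _draw_counts(
    rng: np.random.Generator,
    rates: np.ndarray,  # cells x genes
    library_sizes: np.ndarray,
    dropout_rate: float,
) -> np.ndarray:
    n, p = rates.shape
    # gamma-perturb rates (mean 1, variance DISPERSION) for overdispersion
    shape = 1.0 / DISPERSION
    noisy = rates * rng.gamma(shape, DISPERSION, size=(n, p))
    probs = noisy / noisy.sum(axis=1, keepdims=True)
    counts = np.empty((n, p), dtype=float)
    for i in range(n):
        counts[i] = rng.multinomial(library_sizes[i], probs[i])
    if dropout_rate > 0.0:
        counts *= rng.random((n, p)) >= dropout_rate
    return counts


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Generate reference and query count matrices from one specification.

    Fully determined by ``spec.seed``; the query shares base rates and marker
    structure with the reference but gets its own cells and, when
    ``batch_shift > 1``, a per-gene multiplicative platform factor.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = spec.n_genes
    gene_ids = np.array([f"gene_{j:05d}" for j in range(p)], dtype=object)
    if spec.base_mean is None:
        base = rng.lognormal(mean=0.0, sigma=1.0, size=p)
    else:
        base = np.broadcast_to(np.asarray(spec.base_mean, dtype=float), (p,)).copy()
    if np.any(base <= 0):
        raise ValueError("invalid field base_mean: rates must be positive")

    marker_idx = rng.choice(p, size=spec.n_types * spec.markers_per_type, replace=False)
    types = [f"type_{t}" for t in range(spec.n_types)]
    markers = {
        types[t]: gene_ids[np.sort(marker_idx[t * spec.markers_per_type : (t + 1) * spec.markers_per_type])]
        for t in range(spec.n_types)
    }

    fold = 2.0**spec.marker_effect
    type_rates = np.tile(base, (spec.n_types, 1))
    for t in range(spec.n_types):
        cols = marker_idx[t * spec.markers_per_type : (t + 1) * spec.markers_per_type]
        type_rates[t, cols] *= fold

    if spec.batch_shift > 1.0:
        batch = spec.batch_shift ** rng.uniform(-1.0, 1.0, size=p)
    else:
        batch = np.ones(p)

    lo, hi = spec.library_size_range
    datasets = {}
    for name, gene_factor in (("ref", np.ones(p)), ("query", batch)):
        labels = np.repeat(types, spec.cells_per_type)
        rates = np.repeat(type_rates * gene_factor, spec.cells_per_type, axis=0)
        libs = rng.integers(lo, hi + 1, size=len(labels))
        counts = _draw_counts(rng, rates, libs, spec.dropout_rate)
        cells = np.array([f"{name}_cell_{i:05d}" for i in range(len(labels))], dtype=object)
        datasets[name] = (CountMatrix(counts, cells, gene_ids), LabelVector(labels))

    return SimulatedDataset(
        datasets["ref"][0],
        datasets["ref"][1],
        datasets["query"][0],
        datasets["query"][1],
        markers,
        batch,
    )


def low_variance_discriminant_fixture(seed: int = 0) -> SimulatedDataset:
    """A dataset whose dominant variance directions carry no class signal.

    Three blocks of genes fluctuate with strong cell-level factors that are
    independent of the class, creating high-variance PCs of pure noise, while
    a small marker block separates the two classes with a modest fold change.
    Ratio-based PC selection finds the discriminative component; variance-based
    selection with a small d picks only the noise factors.
    """
    rng = np.random.default_rng(seed)
    n_per = 40
    noise_blocks, block_size = 3, 15
    n_disc = 10
    n_bg = 60
    p = noise_blocks * block_size + n_disc + n_bg
    gene_ids = np.array([f"gene_{j:05d}" for j in range(p)], dtype=object)
    types = ["type_0", "type_1"]

    def one_dataset(name: str):
        labels = np.repeat(types, n_per)
        n = len(labels)
        rates = np.full((n, p), 5.0)
        # class-independent high-variance factors (sd 1.5 on the log2 scale)
        for b in range(noise_blocks):
            cols = slice(b * block_size, (b + 1) * block_size)
            rates[:, cols] *= 2.0 ** rng.normal(0.0, 1.5, size=n)[:, None]
        # low-variance class signal: modest fold change on a small block
        disc = slice(noise_blocks * block_size, noise_blocks * block_size + n_disc)
        rates[n_per:, disc] *= 2.0**0.8
        libs = rng.integers(2000, 4001, size=n)
        counts = _draw_counts(rng, rates, libs, dropout_rate=0.0)
        cells = np.array([f"{name}_cell_{i:05d}" for i in range(n)], dtype=object)
        return CountMatrix(counts, cells, gene_ids), LabelVector(labels)

    ref, ref_labels = one_dataset("ref")
    query, query_labels = one_dataset("query")
    markers = {"type_1": gene_ids[noise_blocks * block_size : noise_blocks * block_size + n_disc]}
    return SimulatedDataset(ref, ref_labels, query, query_labels, markers, None)
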