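"""Synthetic single-cell expression data with planted structure.

The generator emulates the statistical premise the similarity kernel is
built on: a transcriptome dominated by highly, ubiquitously expressed
genes, with cell identity carried by weak type-specific markers.  Values
are continuous and nonnegative on a log-TPM-like scale (the kernel
standardizes per cell, so absolute units do not matter).  Also provided:
the multiplicative dropout model used for robustness experiments
(each nonzero entry removed with probability 2^(-6 x)), planted regulon
tables for network-inference tests, and exactly separable instances with
known pure columns for corner-selection oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RegulonSet
from .metric import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "LabeledDataset",
    "simulate_labeled_counts",
    "apply_dropout",
    "dropout_series",
    "simulate_separable_instance",
    "plant_regulons",
]


@dataclass
class SimulationConfig:
    """Parameters of the labeled-dataset generator.

    Defaults produce five balanced types of 100 cells over 2,000 genes:
    200 universal genes with high mean expression (5.0 on the log-like
    scale), 20 exclusive markers per type adding ``marker_effect`` (2.0)
    to a low background mean (0.5), and Gaussian noise of sd 0.5 truncated
    at zero, which yields the right-skewed, zero-inflated profiles typical
    of log-scale single-cell data.
    """

    n_types: int = 5
    cells_per_type: list[int] = field(default_factory=lambda: [100] * 5)
    m_genes: int = 2000
    n_universal: int = 200
    markers_per_type: int = 20
    universal_mean: float = 5.0
    background_mean: float = 0.5
    marker_effect: float = 2.0
    noise_sd: float = 0.5
    dropout: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cells_per_type) != self.n_types:
            raise ValueError("cells_per_type length must equal n_types")
        if any(c <= 0 for c in self.cells_per_type):
            raise ValueError("cells_per_type entries must be positive")
        needed = self.n_universal + self.n_types * self.markers_per_type
        if needed > self.m_genes:
            raise ValueError(
                f"universal + marker genes ({needed}) exceed m_genes "
                f"({self.m_genes})"
            )

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_type))


@dataclass
class LabeledDataset:
    """Synthetic expression matrix with ground-truth labels and markers."""

    X: ExpressionMatrix
    labels: np.ndarray
    marker_table: dict[int, list[str]]
    universal_genes: list[str]
    regulons: RegulonSet | None = None


def simulate_labeled_counts(config: SimulationConfig) -> LabeledDataset:
    """Draw a labeled genes-by-cells matrix under the planted-type model.

    Gene layout: the first ``n_universal`` genes are universal, the next
    ``n_types * markers_per_type`` are type-exclusive markers (disjoint
    blocks), the remainder are background.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m, n = config.m_genes, config.n_cells
    labels = np.repeat(np.arange(config.n_types), config.cells_per_type)
    mean = np.full((m, n), config.background_mean)
    mean[: config.n_universal, :] = config.universal_mean
    marker_table: dict[int, list[str]] = {}
    gene_ids = [f"G{i:05d}" for i in range(m)]
    pos = config.n_universal
    for t in range(config.n_types):
        rows = slice(pos, pos + config.markers_per_type)
        mean[rows, labels == t] += config.marker_effect
        marker_table[t] = gene_ids[rows]
        pos += config.markers_per_type
    X = np.clip(mean + rng.normal(0.0, config.noise_sd, size=(m, n)), 0.0, None)
    if config.dropout:
        X = apply_dropout(X, seed=int(rng.integers(2**31)))
    cell_ids = [f"C{j:05d}" for j in range(n)]
    em = ExpressionMatrix(X, gene_ids, cell_ids)
    return LabeledDataset(
        X=em,
        labels=labels,
        marker_table=marker_table,
        universal_genes=gene_ids[: config.n_universal],
    )


def apply_dropout(X, seed: int = 0) -> np.ndarray:
    """One pass of expression-dependent dropout.

    Each nonzero entry x is independently set to zero with probability
    2^(-6 x); zeros (and very highly expressed entries, whose removal
    probability is negligible) are effectively untouched.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    if np.any(values < 0):
        raise ValueError("dropout model requires nonnegative expression")
    rng = np.random.default_rng(seed)
    p = np.exp2(-6.0 * values)
    drop = (values > 0) & (rng.random(values.shape) < p)
    out = values.copy()
    out[drop] = 0.0
    return out


def dropout_series(X, target_density: float, seed: int = 0,
                   max_passes: int = 100) -> np.ndarray:
    """Repeat dropout passes until the nonzero fraction falls to the target.

    ``target_density`` is relative to the initial nonzero count; returns
    the first matrix at or below it.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    rng = np.random.default_rng(seed)
    nnz0 = max(np.count_nonzero(values), 1)
    out = values
    for _ in range(max_passes):
        if np.count_nonzero(out) / nnz0 <= target_density:
            break
        out = apply_dropout(out, seed=int(rng.integers(2**31)))
    return out


def simulate_separable_instance(
    m: int, k: int, n: int, noise_eps: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Near-separable matrix Y = Y(:, S) H + N with known pure columns.

    k pure columns (i.i.d. standard normal, scaled to distinct norms) are
    placed at known positions; every other column is a random convex
    combination of them plus a noise column of Euclidean norm at most
    ``noise_eps``.  Returns ``(Y, true_indices, H_true)`` where ``H_true``
    is the k x n column-stochastic mixing matrix (identity block at the
    pure positions).
    """
    if k > n:
        raise ValueError("need k <= n")
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(m, k))
    W *= (1.0 + rng.random(k))  # distinct norms, no accidental ties
    true_idx = np.sort(rng.choice(n, size=k, replace=False))
    H = rng.dirichlet(np.full(k, 0.8), size=n).T  # k x n, columns sum to 1
    H[:, true_idx] = np.eye(k)
    Y = W @ H
    if noise_eps > 0:
        N = rng.normal(size=(m, n))
        N *= noise_eps * rng.random(n) / np.maximum(
            np.linalg.norm(N, axis=0), 1e-30
        )
        N[:, true_idx] = 0.0
        Y = Y + N
    return Y, true_idx, H


def plant_regulons(
    dataset: LabeledDataset,
    *,
    target_type: int = 0,
    n_targets: int = 20,
    marker_overlap: int = 15,
    n_filler_tfs: int = 100,
    targets_per_filler: int = 30,
    seed: int = 0,
) -> RegulonSet:
    """Plant a marker-enriched TF and controls into a regulon table.

    ``TF_PLANTED`` receives ``marker_overlap`` of ``target_type``'s marker
    genes plus random non-marker genes up to ``n_targets``; ``TF_RANDOM``
    gets ``n_targets`` uniformly random genes.  Filler TFs with random
    targets broaden the regulon-known gene universe so enrichment is
    evaluated against a realistic background list.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [str(g) for g in dataset.X.gene_ids]
    markers = dataset.marker_table[target_type]
    if marker_overlap > len(markers):
        raise ValueError("marker_overlap exceeds available markers")
    non_markers = [g for g in gene_ids if g not in set(markers)]
    planted = list(rng.choice(markers, size=marker_overlap, replace=False))
    planted += list(
        rng.choice(non_markers, size=n_targets - marker_overlap, replace=False)
    )
    random_targets = list(rng.choice(gene_ids, size=n_targets, replace=False))
    regulons = {"TF_PLANTED": set(planted), "TF_RANDOM": set(random_targets)}
    for f in range(n_filler_tfs):
        regulons[f"TF_FILLER{f:03d}"] = set(
            rng.choice(gene_ids, size=targets_per_filler, replace=False)
        )
    dataset.regulons = RegulonSet(regulons=regulons, provenance="planted")
    return dataset.regulons
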