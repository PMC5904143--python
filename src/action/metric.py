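"""Specificity-weighted cell-to-cell similarity kernel.

The kernel is built in three steps from a genes-by-cells expression matrix:

1. z-score each cell profile and project it onto the orthogonal complement
   of the (standardized) universal expression signature — the mean profile
   across cells — which suppresses ubiquitously expressed genes;
2. weight each gene by its expression specificity, measured as one minus a
   normalized-entropy statistic on the positive part of the adjusted
   profiles, with the specific/ubiquitous boundary located by a two-component
   Gaussian mixture over the entropy distribution;
3. form the weighted dot-product kernel ``K = Y^T Y`` with
   ``Y = diag(w) Z_perp``.

Low-level functions operate in the genes-by-cells orientation (genes in
rows).  The :class:`ACTIONKernel` estimator wraps them with the scikit-learn
convention (cells in rows) so it composes with pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "ExpressionMatrix",
    "ACTIONKernel",
    "standardize_cells",
    "universal_signature",
    "project_out_universal",
    "gene_specificity",
    "fit_entropy_threshold",
    "specificity_weights",
    "compute_kernel",
]


@dataclass
class ExpressionMatrix:
    """Labeled genes-by-cells nonnegative expression matrix.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Expression values on whatever scale the caller clusters on
        (TPM, log-TPM, ...); no internal log-transform is applied.
    gene_ids, cell_ids : sequences of str
        Unique row and column labels.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValueError(f"expression matrix must be at least 2x2, got {m}x{n}")
        if self.gene_ids.shape[0] != m:
            raise ValueError(f"{self.gene_ids.shape[0]} gene ids for {m} rows")
        if self.cell_ids.shape[0] != n:
            raise ValueError(f"{self.cell_ids.shape[0]} cell ids for {n} columns")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids in expression matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def _as_matrix(X) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(X, ExpressionMatrix):
        return X.values, X.cell_ids
    return np.asarray(X, dtype=float), None


def standardize_cells(X, cell_ids=None) -> np.ndarray:
    """z-score each cell profile (column) over its genes.

    Uses the sample (m-1 denominator) standard deviation.  Raises if any
    cell has constant expression, naming the offending cell.
    """
    X, ids = _as_matrix(X)
    if cell_ids is None:
        cell_ids = ids
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd[0] == 0)
    if bad.size:
        label = cell_ids[bad[0]] if cell_ids is not None else bad[0]
        raise ValueError(f"cell {label!r} has zero expression variance; cannot z-score")
    return (X - mu) / sd


def universal_signature(X) -> tuple[np.ndarray, np.ndarray]:
    """Mean expression over cells and its z-scored form.

    Returns ``(v, z_v)`` where ``v`` is the per-gene average across cells
    (the universal expression signature) and ``z_v`` is ``v`` standardized
    over genes.
    """
    X, _ = _as_matrix(X)
    v = X.mean(axis=1)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("universal signature is constant; cannot standardize")
    z_v = (v - v.mean()) / sd
    return v, z_v


def project_out_universal(Z: np.ndarray, z_v: np.ndarray) -> np.ndarray:
    """Project each column of Z onto the orthogonal complement of z_v."""
    Z = np.asarray(Z, dtype=float)
    z_v = np.asarray(z_v, dtype=float).ravel()
    if Z.shape[0] != z_v.shape[0]:
        raise ValueError(f"Z has {Z.shape[0]} rows but z_v has {z_v.shape[0]} entries")
    nsq = z_v @ z_v
    if nsq == 0:
        raise ValueError("universal signature has zero norm")
    return Z - np.outer(z_v, (z_v @ Z) / nsq)


def gene_specificity(Zperp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic positive projection P and normalized entropies u.

    Negative entries of ``Zperp`` are zeroed and each row rescaled to sum
    to one.  ``u[i]`` is the Shannon entropy of row i normalized by
    ``log(n_cells)`` so a gene uniformly active across cells gets u = 1 and
    a gene active in a single cell gets u = 0.  All-zero rows keep u = NaN
    (flagged; they carry no specificity signal).
    """
    Zperp = np.asarray(Zperp, dtype=float)
    pos = np.clip(Zperp, 0.0, None)
    rowsum = pos.sum(axis=1, keepdims=True)
    zero_rows = rowsum[:, 0] == 0
    P = np.divide(pos, rowsum, out=np.zeros_like(pos), where=rowsum > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    u = -plogp.sum(axis=1) / np.log(P.shape[1])
    u = np.clip(u, 0.0, 1.0)  # guard roundoff at the boundaries
    u[zero_rows] = np.nan
    return P, u


def fit_entropy_threshold(
    u: np.ndarray,
    n_cells: int | None = None,
    *,
    random_state: int | None = 0,
    n_init: int = 10,
    tol: float = 1e-6,
) -> tuple[float, np.ndarray]:
    """Locate the specific/ubiquitous boundary and derive gene weights.

    Fits a two-component Gaussian mixture (unshared variances, k-means
    initialization, ``n_init`` restarts) to the finite entropy values; the
    threshold u_hat is the equal-probability crossing point of the two
    weighted component densities, found by root bisection between the
    component means.  If the weighted densities do not cross between the
    means the midpoint of the means is used instead, with a warning.

    Returns ``(u_hat, w)`` with ``w = u_hat / u`` after clamping (see
    :func:`specificity_weights`).
    """
    u = np.asarray(u, dtype=float)
    finite = u[np.isfinite(u)]
    if finite.size < 10:
        raise ValueError(f"need at least 10 finite entropies, got {finite.size}")
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        tol=tol,
        random_state=random_state,
        init_params="kmeans",
    ).fit(finite.reshape(-1, 1))
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    wts = gmm.weights_
    lo, hi = np.argsort(means)
    if np.isclose(means[lo], means[hi]):
        warnings.warn("mixture components collapsed; using midpoint of means")
        u_hat = float(means.mean())
        return u_hat, specificity_weights(u, u_hat, n_cells=n_cells)

    def density_gap(x: float) -> float:
        return wts[lo] * norm.pdf(x, means[lo], sds[lo]) - wts[hi] * norm.pdf(
            x, means[hi], sds[hi]
        )

    a, b = float(means[lo]), float(means[hi])
    fa, fb = density_gap(a), density_gap(b)
    if fa * fb < 0:
        u_hat = float(brentq(density_gap, a, b, xtol=1e-12))
    else:
        warnings.warn(
            "component densities do not cross between the means; "
            "falling back to the midpoint"
        )
        u_hat = 0.5 * (a + b)
    return u_hat, specificity_weights(u, u_hat, n_cells=n_cells)


def specificity_weights(
    u: np.ndarray, u_hat: float, n_cells: int | None = None
) -> np.ndarray:
    """Per-gene scaling factors ``w = u_hat / u``.

    Entropies are clamped below at ``1/log(n_cells)`` (the smallest value a
    gene positive in more than zero cells can approach) so that a gene
    active in a single cell gets a large but finite weight.  Genes whose
    positive-projection row was all zero (u = NaN) get w = 1: they carry no
    specificity information, so they are neither boosted nor suppressed.
    """
    u = np.asarray(u, dtype=float)
    u_min = 1.0 / np.log(n_cells) if n_cells is not None and n_cells > np.e else 1e-3
    clamped = np.clip(u, u_min, 1.0)
    w = u_hat / clamped
    w[~np.isfinite(u)] = 1.0
    return w


def compute_kernel(Zperp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted dot-product kernel ``K = Zperp^T diag(w^2) Zperp``."""
    Zperp = np.asarray(Zperp, dtype=float)
    w = np.asarray(w, dtype=float).ravel()
    if Zperp.shape[0] != w.shape[0]:
        raise ValueError(f"{Zperp.shape[0]} genes but {w.shape[0]} weights")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be finite and positive")
    Y = Zperp * w[:, None]
    K = Y.T @ Y
    return 0.5 * (K + K.T)  # enforce exact symmetry against roundoff


class ACTIONKernel(TransformerMixin, BaseEstimator):
    """Transformer computing specificity-weighted adjusted cell profiles.

    ``fit`` learns the universal signature and gene weights from a
    cells-by-genes matrix; ``transform`` returns the weighted adjusted
    profiles ``Y^T`` (cells by genes), whose Gram matrix is the cell
    similarity kernel.  Use :meth:`kernel` for the kernel itself.

    Parameters
    ----------
    random_state : int, default 0
        Seed for the Gaussian-mixture fit locating the entropy threshold.
    gmm_n_init : int, default 10
        Number of mixture-fit restarts.

    Attributes
    ----------
    universal_signature_ : ndarray of shape (n_genes,)
        Mean expression of each gene across the training cells.
    entropies_ : ndarray of shape (n_genes,)
        Normalized entropies u in [0, 1]; NaN for genes with an all-zero
        positive-projection row.
    threshold_ : float
        Entropy value separating specific from ubiquitous genes.
    weights_ : ndarray of shape (n_genes,)
        Per-gene scaling factors w.
    kernel_ : ndarray of shape (n_cells, n_cells)
        Cell similarity kernel of the training data.
    """

    def __init__(self, random_state: int | None = 0, gmm_n_init: int = 10):
        self.random_state = random_state
        self.gmm_n_init = gmm_n_init

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        Xg = X.T  # genes x cells
        Z = standardize_cells(Xg)
        v, z_v = universal_signature(Xg)
        Zperp = project_out_universal(Z, z_v)
        P, u = gene_specificity(Zperp)
        u_hat, w = fit_entropy_threshold(
            u, Xg.shape[1], random_state=self.random_state, n_init=self.gmm_n_init
        )
        self.n_features_in_ = X.shape[1]
        self.universal_signature_ = v
        self.universal_z_ = z_v
        self.adjusted_profiles_ = Zperp
        self.entropies_ = u
        self.threshold_ = u_hat
        self.weights_ = w
        Y = Zperp * w[:, None]
        self.weighted_profiles_ = Y
        self.kernel_ = compute_kernel(Zperp, w)
        return self

    def transform(self, X) -> np.ndarray:
        """Weighted adjusted profiles of X (cells by genes)."""
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} genes, expected {self.n_features_in_}"
            )
        Z = standardize_cells(X.T)
        Zperp = project_out_universal(Z, self.universal_z_)
        return (Zperp * self.weights_[:, None]).T

    def kernel(self, X=None, Y=None) -> np.ndarray:
        """Similarity kernel between X and Y (training data if omitted)."""
        check_is_fitted(self, "kernel_")
        if X is None:
            return self.kernel_
        A = self.transform(X)
        B = A if Y is None else self.transform(Y)
        K = A @ B.T
        return 0.5 * (K + K.T) if Y is None else K
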