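"""Archetype discovery in the adjusted cell space.

Cells are modeled as near-convex combinations of a small number of extreme
profiles (archetypes), each standing for a primary transcriptional program.
Candidate pure cells are found with the successive projection algorithm
(SPA) after a minimum-volume-ellipsoid preconditioning step; the number of
archetypes is chosen automatically by growing k until newly added candidates
start crowding regions already covered (detected on an archetype similarity
graph against an Erdos-Renyi background); finally the corners are relaxed
with principal convex hull analysis (PCHA) so that archetypes become convex
combinations of several cells rather than single columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, norm
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "CandidateSet",
    "ArchetypeSimilarityGraph",
    "ArchetypalDecomposition",
    "ArchetypalAnalysis",
    "precondition_profiles",
    "spa_select",
    "detect_oversampling",
    "select_num_archetypes",
    "pcha_fit",
    "assign_dominant_archetype",
    "project_columns_to_simplex",
]


@dataclass
class CandidateSet:
    """Ordered indices of candidate pure cells selected by SPA."""

    indices: list[int]

    @property
    def k(self) -> int:
        return len(self.indices)


@dataclass
class ArchetypeSimilarityGraph:
    """Similarity graph among candidate cells used by the oversampling test."""

    nodes: list[int]
    edges: list[tuple[int, int]]
    components: list[list[int]]
    component_pvalues: list[float]
    z_threshold: float


@dataclass
class ArchetypalDecomposition:
    """Result of PCHA: Y ~ Y C H with column-stochastic C and H."""

    C: np.ndarray  # (n_cells, k)
    H: np.ndarray  # (k, n_cells)
    A: np.ndarray  # (n_features, k), A = Y C
    k: int
    objective_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Preconditioning


def _min_volume_ellipsoid_sym(
    Y: np.ndarray, tol: float = 1e-2, max_iter: int = 10_000
) -> np.ndarray:
    """Minimum-volume origin-centered ellipsoid containing {+-y_j}.

    Khachiyan's barycentric coordinate-ascent on the D-optimal design
    problem.  For a centrally symmetric point set the optimal ellipsoid is
    centered at the origin, so only the shape matrix is estimated.  Returns
    E such that the ellipsoid is {x : x^T E x <= 1}.
    """
    d, n = Y.shape
    u = np.full(n, 1.0 / n)
    YT = Y.T
    for _ in range(max_iter):
        M = (Y * u) @ YT  # sum_j u_j y_j y_j^T
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            M += 1e-12 * np.trace(M) / d * np.eye(d)
            Minv = np.linalg.inv(M)
        g = np.einsum("ij,jk,ik->i", YT, Minv, YT)
        j = int(np.argmax(g))
        kappa = g[j]
        if kappa <= d * (1.0 + tol):
            break
        step = (kappa - d) / (d * (kappa - 1.0))
        u *= 1.0 - step
        u[j] += step
    M = (Y * u) @ YT
    return np.linalg.inv(M) / d


def precondition_profiles(
    Y: np.ndarray, r: int, *, mve_tol: float = 1e-2, mve_max_iter: int = 10_000
) -> tuple[np.ndarray, dict]:
    """Reduce profiles to r dimensions and sphere them for SPA.

    Columns of ``Y`` are projected onto their top ``r`` left singular
    vectors, then linearly transformed so that the minimum-volume
    origin-centered ellipsoid of the sign-symmetrized column set becomes
    (approximately) the unit ball.  Any nonsingular transform preserves
    which columns are extreme, but this one is the standard conditioning
    step that makes greedy corner selection robust to anisotropy.

    Returns the transformed (r x n) matrix and a description of the
    transform (singular basis, ellipsoid matrix and its Cholesky factor).
    """
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    r = int(min(r, m, n))
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    pos = s > s[0] * 1e-12 if s.size else np.array([], bool)
    rank = int(pos.sum())
    if rank < r:
        warnings.warn(f"matrix rank {rank} below target dimension {r}; reducing")
        r = max(rank, 1)
    Yr = (s[:r, None] * Vt[:r])  # = U_r^T Y
    E = _min_volume_ellipsoid_sym(Yr, tol=mve_tol, max_iter=mve_max_iter)
    # x^T E x = ||L^T x||^2 with E = L L^T, so L^T maps the ellipsoid to the unit ball
    L = np.linalg.cholesky(0.5 * (E + E.T))
    Yp = L.T @ Yr
    info = {"basis": U[:, :r], "ellipsoid": E, "cholesky": L, "rank": r}
    return Yp, info


# ---------------------------------------------------------------------------
# SPA


def spa_select(Yp: np.ndarray, k: int) -> CandidateSet:
    """Greedy successive projection: pick extreme columns of Yp.

    Repeatedly selects the column of maximum Euclidean norm (ties broken by
    lowest index) and projects all columns onto the orthogonal complement
    of the pick.  Exact recovery of the generating columns is guaranteed
    for noiseless separable matrices.
    """
    R = np.array(Yp, dtype=float, copy=True)
    m, n = R.shape
    if k > n:
        raise ValueError(f"cannot select {k} columns from {n}")
    scale = np.linalg.norm(R)
    selected: list[int] = []
    for _ in range(k):
        norms = np.linalg.norm(R, axis=0)
        j = int(np.argmax(norms > norms.max() * (1 - 1e-12)))  # first near-max index
        if norms[j] <= scale * 1e-12:
            warnings.warn(
                f"residual matrix numerically zero after {len(selected)} picks; "
                f"returning fewer than {k} candidates"
            )
            break
        selected.append(j)
        q = R[:, j] / norms[j]
        R -= np.outer(q, q @ R)
    return CandidateSet(indices=selected)


# ---------------------------------------------------------------------------
# Model selection


def detect_oversampling(
    K: np.ndarray,
    candidates: CandidateSet,
    *,
    z_threshold: float = 1.96,
    alpha: float = 0.05,
) -> tuple[bool, ArchetypeSimilarityGraph]:
    """Test whether the candidate set crowds an already-covered region.

    Pairwise similarities between the candidate cells (a submatrix of the
    cell kernel) are z-scored; pairs above ``z_threshold`` become edges of
    the archetype similarity graph.  Each multi-node connected component is
    scored against an Erdos-Renyi background whose edge probability is the
    nominal upper-tail mass of the z cut (0.025 at z = 1.96) — the chance
    a pair crosses the cut when similarities really are Gaussian with no
    crowding: p-value = P(Binomial(C(c,2), p_null) >= e).  The candidate
    set is flagged as oversampled if any component is significant at
    ``alpha`` after Bonferroni correction over multi-node components.

    Requires at least 4 candidates (6 pairs) for a meaningful z-score; for
    smaller sets the test never flags.
    """
    idx = list(candidates.indices)
    k = len(idx)
    sub = np.asarray(K, dtype=float)[np.ix_(idx, idx)]
    iu = np.triu_indices(k, 1)
    sims = sub[iu]
    edges: list[tuple[int, int]] = []
    if k >= 4 and sims.size:
        sd = sims.std(ddof=1)
        z = np.zeros_like(sims) if sd == 0 else (sims - sims.mean()) / sd
        for (a, b), zv in zip(zip(*iu), z):
            if zv > z_threshold:
                edges.append((idx[a], idx[b]))
    # connected components over the candidate nodes
    parent = {v: v for v in idx}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comp_map: dict[int, list[int]] = {}
    for v in idx:
        comp_map.setdefault(find(v), []).append(v)
    components = sorted(comp_map.values(), key=lambda c: (-len(c), c))
    p_null = float(norm.sf(z_threshold))
    edge_set = {frozenset(e) for e in edges}
    pvalues: list[float] = []
    multi = [c for c in components if len(c) > 1]
    for comp in components:
        c = len(comp)
        if c < 2:
            pvalues.append(1.0)
            continue
        e = sum(
            1
            for i in range(c)
            for j in range(i + 1, c)
            if frozenset((comp[i], comp[j])) in edge_set
        )
        pvalues.append(float(binom.sf(e - 1, c * (c - 1) // 2, p_null)))
    bonferroni = max(len(multi), 1)
    flagged = any(
        p * bonferroni <= alpha
        for comp, p in zip(components, pvalues)
        if len(comp) > 1
    )
    graph = ArchetypeSimilarityGraph(
        nodes=idx,
        edges=edges,
        components=components,
        component_pvalues=pvalues,
        z_threshold=z_threshold,
    )
    return flagged, graph


def select_num_archetypes(
    Y: np.ndarray,
    K: np.ndarray,
    k_min: int = 2,
    k_max: int = 30,
    *,
    z_threshold: float = 1.96,
    alpha: float = 0.05,
    mve_tol: float = 1e-2,
) -> tuple[int, dict[int, dict]]:
    """Grow k until the candidate polytope oversamples the cell space.

    For each k from ``k_min`` upward the profiles are re-preconditioned at
    target rank k, SPA selects k candidates, and the oversampling test is
    run on their kernel submatrix.  Returns the last k before the first
    flagged k (never below ``k_min``); if no k is flagged, returns
    ``k_max`` with a warning.  The per-k diagnostics map holds each
    candidate set and similarity graph.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[1]
    k_max = min(k_max, n - 1)
    if not 2 <= k_min < k_max + 1:
        raise ValueError(f"need 2 <= k_min <= k_max, got {k_min}, {k_max}")
    # the SVD basis is shared across k: compute once at the largest rank
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    r_full = min(k_max, (s > s[0] * 1e-12).sum()) if s.size else 1
    Yred = s[:r_full, None] * Vt[:r_full]
    diagnostics: dict[int, dict] = {}
    for k in range(k_min, k_max + 1):
        r = min(k, r_full)
        E = _min_volume_ellipsoid_sym(Yred[:r], tol=mve_tol)
        L = np.linalg.cholesky(0.5 * (E + E.T))
        cands = spa_select(L.T @ Yred[:r], k)
        flagged, graph = detect_oversampling(
            K, cands, z_threshold=z_threshold, alpha=alpha
        )
        diagnostics[k] = {"candidates": cands, "graph": graph, "flagged": flagged}
        if flagged:
            return max(k - 1, k_min), diagnostics
    warnings.warn(
        f"no oversampling detected up to k_max={k_max}; returning k_max"
    )
    return k_max, diagnostics


# ---------------------------------------------------------------------------
# PCHA


def project_columns_to_simplex(V: np.ndarray, radius: float = 1.0) -> np.ndarray:
    """Euclidean projection of each column onto the probability simplex."""
    V = np.asarray(V, dtype=float)
    k = V.shape[0]
    U = np.sort(V, axis=0)[::-1]
    css = np.cumsum(U, axis=0) - radius
    ind = np.arange(1, k + 1)[:, None]
    cond = U - css / ind > 0
    rho = k - 1 - np.argmax(cond[::-1], axis=0)
    theta = css[rho, np.arange(V.shape[1])] / (rho + 1.0)
    return np.clip(V - theta, 0.0, None)


def _pcha_objective(G: np.ndarray, C: np.ndarray, H: np.ndarray, trG: float) -> float:
    # ||Y - YCH||_F^2 expressed through the Gram matrix G = Y^T Y
    GC = G @ C
    CtGC = C.T @ GC
    return float(trG - 2.0 * np.einsum("ij,ji->", GC, H)
                 + np.einsum("ij,ik,kj->", H, CtGC, H))


def pcha_fit(
    Y: np.ndarray,
    init: CandidateSet | list[int],
    k: int | None = None,
    delta: float = 0.0,
    *,
    max_iter: int = 200,
    rel_tol: float = 1e-6,
) -> ArchetypalDecomposition:
    """Principal convex hull analysis by alternating projected gradient.

    Minimizes ``||Y - Y C H||_F^2`` over entrywise-nonnegative C (n x k)
    and H (k x n) with unit column sums, starting from C = indicator of the
    SPA candidate columns and H = the corresponding simplex projection.
    Step sizes adapt multiplicatively (doubled after an accepted step,
    halved otherwise), and a step is accepted only if the objective does
    not increase, so the objective trace is non-increasing by construction.

    ``delta`` relaxes the corner constraint by letting column sums of C
    range over [1 - delta, 1 + delta], allowing archetypes slightly outside
    the convex hull of the data.
    """
    Y = np.asarray(Y, dtype=float)
    idx = init.indices if isinstance(init, CandidateSet) else list(init)
    if k is None:
        k = len(idx)
    if len(idx) != k:
        raise ValueError(f"init provides {len(idx)} indices for k={k}")
    n = Y.shape[1]
    G = Y.T @ Y  # Gram matrix; the objective depends on Y only through it
    trG = float(np.trace(G))
    scale = trG if trG > 0 else 1.0

    C = np.zeros((n, k))
    C[idx, np.arange(k)] = 1.0

    def proj_C(V):
        if delta <= 0:
            return project_columns_to_simplex(V)
        P1 = project_columns_to_simplex(V)
        sums = np.clip(np.maximum(V, 0).sum(axis=0), 1.0 - delta, 1.0 + delta)
        return P1 * sums

    def update_H(C):
        # solve for H given C by projected gradient to a fixed point
        AtA = C.T @ G @ C
        AtY = C.T @ G
        lip = max(np.linalg.norm(AtA, 2), 1e-12)
        H = project_columns_to_simplex(np.linalg.lstsq(AtA + 1e-10 * np.eye(k), AtY, rcond=None)[0])
        for _ in range(50):
            grad = AtA @ H - AtY
            Hn = project_columns_to_simplex(H - grad / lip)
            if np.abs(Hn - H).max() < 1e-12:
                H = Hn
                break
            H = Hn
        return H

    H = update_H(C)
    obj = _pcha_objective(G, C, H, trG)
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite PCHA objective at initialization")
    trace = [obj]
    mu_C = 1.0
    mu_H = 1.0
    for _ in range(max_iter):
        # --- C update (projected gradient with backtracking)
        HHt = H @ H.T
        GYHt = G @ H.T  # gradient pieces: dJ/dC = 2 (G C HHt - G H^T)
        grad_C = 2.0 * (G @ (C @ HHt) - GYHt)
        gnorm = max(np.abs(grad_C).max(), 1e-30)
        accepted = False
        for _ in range(25):
            Cn = proj_C(C - mu_C * grad_C / gnorm)
            new_obj = _pcha_objective(G, Cn, H, trG)
            if new_obj <= obj * (1 + 1e-15):
                accepted = True
                break
            mu_C *= 0.5
        if accepted and new_obj < obj:
            C, obj = Cn, new_obj
            mu_C *= 2.0
        # --- H update
        CtGC = C.T @ G @ C
        CtG = C.T @ G
        grad_H = 2.0 * (CtGC @ H - CtG)
        gnorm = max(np.abs(grad_H).max(), 1e-30)
        accepted = False
        for _ in range(25):
            Hn = project_columns_to_simplex(H - mu_H * grad_H / gnorm)
            new_obj = _pcha_objective(G, C, Hn, trG)
            if new_obj <= obj * (1 + 1e-15):
                accepted = True
                break
            mu_H *= 0.5
        if accepted and new_obj < obj:
            H, obj = Hn, new_obj
            mu_H *= 2.0
        if not np.isfinite(obj):
            raise FloatingPointError("non-finite PCHA objective")
        trace.append(obj)
        if trace[-2] - trace[-1] <= rel_tol * max(abs(trace[-2]), 1e-12 * scale):
            break
    # report the trace on the Frobenius-norm scale of the residual
    fro_trace = [float(np.sqrt(max(t, 0.0))) for t in trace]
    return ArchetypalDecomposition(
        C=C, H=H, A=Y @ C, k=k, objective_trace=fro_trace
    )


def assign_dominant_archetype(H: np.ndarray) -> np.ndarray:
    """Label each cell with its highest-weight archetype (ties: lowest index)."""
    H = np.asarray(H, dtype=float)
    return np.argmax(H, axis=0)


# ---------------------------------------------------------------------------
# Estimator


class ArchetypalAnalysis(BaseEstimator):
    """Archetypal decomposition of cell profiles with automatic order selection.

    Fits ``Y ~ Y C H`` on a cells-by-features matrix (typically the output
    of :class:`~action.metric.ACTIONKernel.transform`): candidate extreme
    cells are found by preconditioned SPA, the number of archetypes is
    chosen by the oversampling test unless ``n_archetypes`` is given, and
    PCHA relaxes the corners.

    Parameters
    ----------
    n_archetypes : int or None
        Fixed number of archetypes; None selects it automatically.
    k_min, k_max : int
        Search range for the automatic selection (k_max is clipped to
        n_cells - 1).
    delta : float
        PCHA corner-relaxation radius; 0 keeps archetypes inside the
        convex hull of the cells.
    z_threshold, alpha : float
        Oversampling-test parameters: the similarity z-score cut and the
        Erdos-Renyi component significance level.

    Attributes
    ----------
    n_archetypes_ : int
        Chosen number of archetypes.
    archetypes_ : ndarray of shape (n_archetypes_, n_features)
        Archetype profiles, rows in the same feature space as the input.
    C_ : ndarray of shape (n_cells, n_archetypes_)
        Column-stochastic cell loadings composing each archetype.
    H_ : ndarray of shape (n_archetypes_, n_cells)
        Column-stochastic convex coefficients of each cell on the
        archetypes.
    labels_ : ndarray of shape (n_cells,)
        Dominant archetype of each training cell.
    objective_trace_ : list of float
        PCHA residual norm per iteration (non-increasing).
    selection_diagnostics_ : dict
        Per-k candidate sets, similarity graphs and flags from the
        automatic selection (empty when n_archetypes is fixed).
    """

    def __init__(
        self,
        n_archetypes: int | None = None,
        k_min: int = 2,
        k_max: int = 30,
        delta: float = 0.0,
        z_threshold: float = 1.96,
        alpha: float = 0.05,
        max_iter: int = 200,
        tol: float = 1e-6,
        random_state: int | None = 0,
    ):
        self.n_archetypes = n_archetypes
        self.k_min = k_min
        self.k_max = k_max
        self.delta = delta
        self.z_threshold = z_threshold
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        Y = X.T  # features x cells
        check_random_state(self.random_state)  # validates the seed
        K = Y.T @ Y
        if self.n_archetypes is None:
            k_star, diag = select_num_archetypes(
                Y,
                K,
                k_min=self.k_min,
                k_max=self.k_max,
                z_threshold=self.z_threshold,
                alpha=self.alpha,
            )
            self.selection_diagnostics_ = diag
        else:
            k_star = int(self.n_archetypes)
            self.selection_diagnostics_ = {}
        Yp, _ = precondition_profiles(Y, k_star)
        cands = spa_select(Yp, k_star)
        decomp = pcha_fit(
            Y, cands, k=len(cands.indices), delta=self.delta,
            max_iter=self.max_iter, rel_tol=self.tol,
        )
        self.n_features_in_ = X.shape[1]
        self.n_archetypes_ = decomp.k
        self.candidates_ = cands
        self.C_ = decomp.C
        self.H_ = decomp.H
        self.archetypes_ = decomp.A.T
        self.objective_trace_ = decomp.objective_trace
        self.labels_ = assign_dominant_archetype(decomp.H)
        return self

    def transform(self, X) -> np.ndarray:
        """Convex coefficients of cells on the fitted archetypes."""
        check_is_fitted(self, "archetypes_")
        X = check_array(X, dtype=float)
        A = self.archetypes_.T  # features x k
        k = A.shape[1]
        AtA = A.T @ A
        AtY = A.T @ X.T
        lip = max(np.linalg.norm(AtA, 2), 1e-12)
        H = project_columns_to_simplex(
            np.linalg.lstsq(AtA + 1e-10 * np.eye(k), AtY, rcond=None)[0]
        )
        for _ in range(500):
            Hn = project_columns_to_simplex(H - (AtA @ H - AtY) / lip)
            if np.abs(Hn - H).max() < 1e-10:
                H = Hn
                break
            H = Hn
        return H.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.H_.T

    def predict(self, X) -> np.ndarray:
        """Dominant archetype of each cell in X."""
        return assign_dominant_archetype(self.transform(X).T)
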