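"""Archetype-specific transcriptional regulatory network inference.

Each archetype is first orthogonalized against the positive parts of all
other archetypes; the residual expression ranks genes by how specific they
are to that archetype.  For every transcription factor (TF) with annotated
target genes (a regulon), the placement of its targets in the ranked list
is scored with the minimum-hypergeometric (mHG) statistic: the best
hypergeometric enrichment tail over all prefix cuts of the list.  The mHG
score is not itself a p-value (it is optimized over cuts), so an exact
p-value is computed by a lattice-path dynamic program over all arrangements
of the targets in the list.  Significant TFs, together with their targets
above the optimal cut, form the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .io import RegulonSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "RegulatoryNetwork",
    "orthogonalize_archetype",
    "residual_expression",
    "rank_genes",
    "mhg_score",
    "mhg_pvalue_dp",
    "build_trn",
]


@dataclass
class EnrichmentResult:
    """mHG enrichment of one TF's targets in one ranked gene list."""

    tf: str
    r: int  # targets present in the ranking
    m: int  # ranking length
    mhg_score: float
    l_best: int
    p_value: float
    selected_targets: list[str] = field(default_factory=list)


@dataclass
class RegulatoryNetwork:
    """Per-archetype TF -> target edges with enrichment statistics."""

    alpha: float
    edges: dict[int, list[tuple[str, str, float]]]  # archetype -> (TF, TG, p)
    enrichments: dict[int, list[EnrichmentResult]]

    def significant_tfs(self, archetype: int) -> list[str]:
        return sorted({tf for tf, _, _ in self.edges.get(archetype, [])})


def orthogonalize_archetype(A: np.ndarray, i: int) -> np.ndarray:
    """Residual of archetype i against the positive parts of the others.

    Negative entries of the archetype matrix are zeroed, and column i is
    replaced by the residual of its least-squares projection onto the span
    of the remaining columns.  The projection uses the pseudoinverse, so
    rank-deficient archetype sets (e.g. duplicated archetypes) are handled:
    a column lying in the span of the others gets a zero residual.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("need an m x k archetype matrix with k >= 2")
    Apos = np.clip(A, 0.0, None)
    a_i = Apos[:, i]
    others = np.delete(Apos, i, axis=1)
    coef, *_ = np.linalg.lstsq(others, a_i, rcond=None)
    return a_i - others @ coef


def residual_expression(A: np.ndarray) -> np.ndarray:
    """Residual expression matrix: column i orthogonalized against the rest."""
    A = np.asarray(A, dtype=float)
    return np.column_stack(
        [orthogonalize_archetype(A, i) for i in range(A.shape[1])]
    )


def rank_genes(residuals: np.ndarray, gene_ids) -> list[str]:
    """Genes sorted by descending residual; ties broken lexicographically."""
    residuals = np.asarray(residuals, dtype=float).ravel()
    if not np.all(np.isfinite(residuals)):
        raise ValueError("residual expressions must be finite")
    gene_ids = [str(g) for g in gene_ids]
    if len(gene_ids) != residuals.size:
        raise ValueError("gene_ids length does not match residual vector")
    order = sorted(range(len(gene_ids)), key=lambda j: (-residuals[j], gene_ids[j]))
    return [gene_ids[j] for j in order]


def _dp_survival_py(tails: np.ndarray, score: float, m: int, r: int) -> float:
    # Each arrangement of r targets in m slots is a monotone lattice path;
    # R(l, b) = A(l, b) / C(l, b) with A = #surviving prefixes.  The pure
    # recurrence A(l,b) = A(l-1,b) + A(l-1,b-1) becomes, after dividing by
    # C(l, b): R(l,b) = ((l-b)/l) R(l-1,b) + (b/l) R(l-1,b-1), which keeps
    # every entry in [0, 1] — no over/underflow rescaling needed.
    R = np.zeros(r + 1)
    R[0] = 1.0
    Rn = np.zeros(r + 1)
    for l in range(1, m + 1):
        b_hi = min(l, r)
        for b in range(b_hi, -1, -1):
            if tails[l - 1, b] <= score:
                Rn[b] = 0.0  # path attains the observed score here
            else:
                v = R[b] * (l - b) / l
                if b >= 1:
                    v += R[b - 1] * b / l
                Rn[b] = v
        for b in range(b_hi + 1, r + 1):
            Rn[b] = 0.0
        b_lo = r - (m - l)  # need enough remaining slots for the rest
        for b in range(0, min(b_lo, r + 1)):
            Rn[b] = 0.0
        R, Rn = Rn, R
    return float(R[r])


try:  # compiled DP kernel; the plain-Python version is the reference path
    from numba import njit

    _dp_survival = njit(cache=False)(_dp_survival_py)
except ImportError:  # pragma: no cover
    _dp_survival = _dp_survival_py


@lru_cache(maxsize=64)
def _hypergeom_tail_grid(m: int, r: int) -> np.ndarray:
    """Upper tails P(X >= b | m, r, l) for l = 1..m (rows), b = 0..r (cols).

    Computed from log-binomials with a reverse cumulative sum.  Both the
    score and its DP p-value read tails from this grid, so the blocked-cell
    comparison in the DP is exactly consistent with the observed score.
    Cached per (m, r) since every regulon of the same size on the same
    universe shares the grid.
    """
    bs = np.arange(r + 1)
    log_c_r = gammaln(r + 1) - gammaln(bs + 1) - gammaln(r - bs + 1)
    ls = np.arange(1, m + 1)[:, None]
    lb = ls - bs[None, :]
    valid = (lb >= 0) & (lb <= m - r)
    lb_safe = np.where(valid, lb, 0)
    log_pmf = (
        log_c_r[None, :]
        + gammaln(m - r + 1) - gammaln(lb_safe + 1) - gammaln(m - r - lb_safe + 1)
        - (gammaln(m + 1) - gammaln(ls + 1) - gammaln(m - ls + 1))
    )
    pmf = np.where(valid, np.exp(log_pmf), 0.0)
    tails = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    return np.minimum(tails, 1.0)


def mhg_score(membership) -> tuple[float, int]:
    """Minimum hypergeometric tail over all prefix cuts of a ranked list.

    ``membership`` is the binary indicator (in ranked order) of which
    positions are targets.  For each cut length l the hypergeometric upper
    tail P(X >= k_l) is computed, with k_l the number of targets in the
    top l, population m = len(membership) and r = total targets; the score
    is the minimum over l = 1..m and ``l_best`` the smallest minimizer.
    With no targets the score is 1 at cut 0.
    """
    lam = np.asarray(membership, dtype=int).ravel()
    m = lam.size
    r = int(lam.sum())
    if r == 0:
        return 1.0, 0
    k_l = np.cumsum(lam)
    grid = _hypergeom_tail_grid(m, r)
    tails = grid[np.arange(m), k_l]
    j = int(np.argmin(tails))
    return float(tails[j]), int(j + 1)


def mhg_pvalue_dp(score: float, m: int, r: int) -> float:
    """Exact p-value of an observed mHG score by dynamic programming.

    Over the uniform distribution on all C(m, r) arrangements of r targets
    among m list positions, computes the probability that the mHG score is
    <= the observed ``score``.  Each arrangement is a monotone lattice path
    from (0, 0) to (m, r); a path attains the score iff it touches a cell
    (l, b) whose hypergeometric tail P(X >= b) <= score.  The DP propagates
    the reaching probability R(l, b) = P(b targets in first l | path avoids
    all blocked cells so far) directly on the probability scale,
    R(l, b) = (1 - b'/l) R(l-1, b) + (b/l) ... using the hypergeometric
    path weights, which keeps every entry in [0, 1] (no over/underflow
    rescaling needed).
    """
    if not 0 <= r <= m:
        raise ValueError(f"need 0 <= r <= m, got r={r}, m={m}")
    if r == 0:
        return 1.0
    if not 0 < score <= 1:
        raise ValueError("score must be in (0, 1]")
    tails = _hypergeom_tail_grid(m, r)
    surv = _dp_survival(tails, float(score), m, r)
    return float(min(1.0, max(0.0, 1.0 - surv)))


def tf_enrichment(
    ranked_genes: list[str], targets: set[str], tf: str = ""
) -> EnrichmentResult:
    """mHG enrichment of a target set in a ranked gene list."""
    lam = np.fromiter((g in targets for g in ranked_genes), dtype=int)
    score, l_best = mhg_score(lam)
    m = len(ranked_genes)
    r = int(lam.sum())
    p = mhg_pvalue_dp(score, m, r) if r else 1.0
    selected = [g for g in ranked_genes[:l_best] if g in targets]
    return EnrichmentResult(
        tf=tf, r=r, m=m, mhg_score=score, l_best=l_best, p_value=p,
        selected_targets=selected,
    )


def build_trn(
    Aperp: np.ndarray,
    gene_ids,
    regulons: RegulonSet,
    alpha: float = 0.05,
) -> RegulatoryNetwork:
    """Infer a TF -> target network for every archetype.

    The gene universe is the intersection of the ranked genes with the
    genes known to the regulon table (as TF or target); m and r are
    recomputed per TF on that universe, so list length is comparable
    across regulons.  A TF is significant when its exact mHG p-value is at
    most ``alpha``; its edges go to the targets ranked above the optimal
    cut.  TFs with no targets in the universe are skipped (logged).
    """
    Aperp = np.asarray(Aperp, dtype=float)
    gene_ids = [str(g) for g in gene_ids]
    known = regulons.known_genes()
    universe = [g for g in gene_ids if g in known]
    uni_set = set(universe)
    if not universe:
        raise ValueError("no overlap between ranked genes and regulon genes")
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    edges: dict[int, list[tuple[str, str, float]]] = {}
    enrichments: dict[int, list[EnrichmentResult]] = {}
    for arch in range(Aperp.shape[1]):
        resid = Aperp[:, arch]
        ranked_all = rank_genes(resid, gene_ids)
        ranked = [g for g in ranked_all if g in uni_set]
        arch_edges: list[tuple[str, str, float]] = []
        arch_enr: list[EnrichmentResult] = []
        for tf in sorted(regulons.regulons):
            targets = regulons.regulons[tf] & uni_set
            if not targets:
                logger.info("TF %s has no targets in the gene universe; skipped", tf)
                continue
            res = tf_enrichment(ranked, targets, tf=tf)
            arch_enr.append(res)
            if res.p_value <= alpha:
                arch_edges.extend((tf, tg, res.p_value) for tg in res.selected_targets)
        edges[arch] = arch_edges
        enrichments[arch] = arch_enr
    _ = gene_pos  # positions retained for future marker-table export
    return RegulatoryNetwork(alpha=alpha, edges=edges, enrichments=enrichments)
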