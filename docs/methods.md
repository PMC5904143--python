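# Methods

## Similarity kernel

Each cell profile (column of the genes-by-cells matrix **X**) is z-scored
over its genes with the sample (m−1) standard deviation; the universal
signature — the per-gene mean over cells — is z-scored the same way. The
kernel is computed on whatever expression scale the caller supplies (TPM,
log-TPM, …); no internal log transform is applied, so users should pass
the scale they would cluster on. A cell with constant expression cannot be
z-scored and is reported by id as an error rather than silently dropped.

Gene specificity uses the normalized entropy of the positive part of the
adjusted profiles, row-normalized to a stochastic matrix **P**. Entropies
are normalized by log(n_cells) so that a gene uniformly active across
cells attains u = 1 and a gene active in a single cell u = 0; natural
logarithms are used throughout (the base cancels). Rows of **P** that are
entirely zero (genes with no positive adjusted expression) carry no
specificity signal; they are flagged (u = NaN) and receive weight w = 1.

The specific/ubiquitous boundary û is the equal-probability crossing of a
two-component Gaussian mixture fitted to the entropy distribution:
scikit-learn's EM with unshared variances, k-means initialization, 10
restarts, tolerance 1e−6, and a fixed seed; the crossing is found by
Brent's root bisection of the weighted density difference between the two
component means. If the densities do not cross in that interval (possible
when one component swallows the other), the midpoint of the means is used
and a warning raised. Whether the mixture should share a variance is not
determined by the data model; unshared variances were chosen as the more
flexible default.

Weights are w = û/u after clamping u below at 1/log(n_cells) — the scale
of the smallest achievable nonzero entropy — so a gene positive in a
single cell gets a large but finite boost; without the clamp one gene
could dominate the kernel. The kernel K = Yᵀ Y with Y = diag(w) Z⊥ is
symmetrized exactly (0.5 (K + Kᵀ)) to remove floating-point asymmetry.

## Archetype discovery

**Preconditioning.** Profiles are reduced to r = k dimensions by truncated
SVD and transformed so the minimum-volume origin-centered ellipsoid of the
sign-symmetrized columns becomes the unit ball. The ellipsoid is computed
with Khachiyan's barycentric coordinate-ascent (tolerance 1e−2, at most
10,000 iterations) and the transform is the transposed Cholesky factor of
the ellipsoid matrix. Any nonsingular transform preserves which columns
are extreme; this one equalizes directions so greedy selection is not
biased toward high-variance axes. When the matrix rank is below the
requested dimension the target rank is reduced with a warning.

**SPA.** Greedy successive projection: pick the column of maximum norm
(ties to the lowest index, for run-to-run determinism), deflate by
projecting all columns onto its orthogonal complement, repeat. On
noiseless separable data this provably recovers the generating columns;
the test suite checks exact recovery on planted instances.

**Choosing k.** For each k from k_min = 2 upward, SPA candidates are
selected at preconditioning rank k and their pairwise kernel similarities
(a submatrix of the cell kernel — identical values, no recomputation) are
z-scored. Pairs above z = 1.96 form the archetype similarity graph. Each
multi-node connected component is tested against an Erdős–Rényi
background: with p₀ = P(Z > 1.96) ≈ 0.025 as the null edge probability —
the chance a pair crosses the cut when candidate similarities are
homogeneous Gaussian — a component with c nodes and e edges gets p-value
P(Binomial(C(c,2), p₀) ≥ e), Bonferroni-corrected over multi-node
components at α = 0.05. The nominal tail mass, rather than the observed
edge density, is used as the null probability because conditioning the
null on the observed edges makes a first duplicated corner (one edge in a
2-node component) unsurprising by construction and the search then
systematically overshoots. The selection returns the last k before the
first flagged k; if nothing is flagged up to k_max (default
min(30, n−1)), k_max is returned with a warning. The test needs at least
4 candidates (6 pairs) to z-score; smaller sets never flag, and
zero-variance similarity sets give all-zero z-scores (no edges).

**PCHA.** Alternating projected-gradient minimization of ‖Y − YCH‖_F,
implemented on the Gram matrix Yᵀ Y so cost is independent of the number
of genes. C starts as the indicator of the SPA candidates; steps are
normalized by the max gradient entry, columns are projected onto the
probability simplex (Euclidean projection), and a step is kept only when
the objective does not increase — step sizes double after success and
halve after failure. The objective trace is therefore non-increasing by
construction; convergence is declared at relative decrease < 1e−6 or 200
iterations. The corner-relaxation radius δ (allowing C column sums in
[1−δ, 1+δ], i.e. archetypes slightly outside the data hull) defaults to 0
and is exposed as a parameter. Cells are labeled by their dominant
archetype (argmax of their H column, ties to the lowest index).

## Regulatory network inference

Archetype profiles are clipped to their positive parts; archetype i is
orthogonalized against the span of the other positive columns by a
least-squares residual (equivalently the Moore–Penrose pseudoinverse), so
rank-deficient archetype sets — e.g. duplicated archetypes — yield a zero
residual instead of a failed matrix inverse. Genes are ranked by
descending residual with lexicographic tie-breaks for reproducibility.

The gene universe for enrichment is the intersection of the ranked genes
with the genes known to the regulon table (TFs and targets); list length
m and target count r are recomputed per TF on that universe so scores are
comparable across regulons. The mHG score is the minimum over all prefix
cuts l = 1..m of the hypergeometric upper tail; all cuts are candidates
(no top-fraction restriction). Its exact p-value is the probability, over
the uniform distribution on all C(m, r) placements of the targets, of
attaining an equal or better score. Arrangements are monotone lattice
paths from (0,0) to (m,r); the dynamic program propagates the surviving
path fraction R(l,b) = A(l,b)/C(l,b), which obeys
R(l,b) = ((l−b)/l)·R(l−1,b) + (b/l)·R(l−1,b−1) and stays in [0,1], so no
overflow rescaling is needed (path *counts* would overflow doubles near
m ≈ 1000). Both the score and the DP read hypergeometric tails from one
shared log-gamma table, so the DP's blocked-cell comparison is bitwise
consistent with the observed score. The inner recurrence is JIT-compiled
with numba, with an identical pure-Python fallback.

TFs are kept at raw p ≤ α (default 0.05; a strict 1e−3 level is exposed
for high-confidence networks); Benjamini–Hochberg correction is
deliberately not the default since the thresholds are defined on raw
p-values, but the full per-TF enrichment table is returned so any
correction can be applied downstream. Regulon activation/repression modes
are carried as edge attributes but do not enter scoring. Edges run from
each significant TF to its targets ranked above that TF's optimal cut.

## Synthetic data

The generator emulates the premise the kernel is designed for: 2,000
genes × 500 cells (five types × 100) by default, with 200 universal genes
at mean 5.0 on a log-TPM-like scale, disjoint blocks of 20 exclusive
markers per type at background 0.5 plus effect 2.0 in their own type, and
Gaussian noise of sd 0.5 truncated at zero (right-skewed, zero-inflated
continuous values). Counts, library sizes and batch effects are not
modeled — the kernel standardizes per cell, so absolute scale is
irrelevant — which means passing tests demonstrate recovery of planted
mean-shift structure, not robustness to the full noise anatomy of real
scRNA-seq. Dropout is modeled as in robustness experiments on real data:
each nonzero entry is removed with probability 2^(−6x) per pass, and
passes repeat until a target fraction of the original nonzeros remains.
Separable instances for corner-recovery oracles place k random pure
columns at known positions and mix the rest convexly (Dirichlet(0.8))
with bounded column-wise noise. Planted regulon tables give one TF a
configurable overlap with a chosen type's markers (default 15 of 20
targets), a control TF random targets, and 100 filler TFs of 30 random
targets each so the enrichment universe is a realistically broad gene
list rather than just the planted sets.

## Evaluation

Kernel k-means assigns points by the kernel-expressed centroid distance
d(i,c) = K_ii − 2·mean_{j∈c} K_ij + mean_{j,l∈c} K_jl, with random
initial assignments, 100 restarts by default (best inertia kept), and a
documented empty-cluster rule: the point farthest from its current
centroid is moved into an emptied cluster. ARI and NMI come from
scikit-learn (NMI with the arithmetic-mean normalization, the common
default); the F-score is the pairwise variant — harmonic mean of
precision and recall over co-clustered sample pairs — computed from the
contingency table, chosen over B-cubed alternatives for simplicity and
labeled as such.

## Problem sizes

The bundled studies run at desk scale: five-type recovery uses 500 cells
× 2,000 genes over 10 seeds; rare-type sensitivity uses 1,000 cells with
the rare fraction swept over 1–5% (10 replicates each, smallest fraction
recovered in ≥ 5/10 reported); dropout robustness uses repeated removal
passes down to 50% retained nonzeros; mHG exactness is checked against
complete enumeration for all list lengths up to 10. These sizes were
chosen so the planted effects match the generator defaults above while
each study completes in minutes on one CPU.

## Known limitations

- The oversampling test needs k ≥ 4 candidates; datasets with 2–3 true
  types rely on the k_min boundary rather than the statistical test.
- The entropy threshold assumes a bimodal entropy distribution; on data
  without a ubiquitous/specific split the mixture components collapse and
  the midpoint fallback (with warning) governs the weights.
- PCHA converges to a local optimum; initialization from SPA candidates
  is what makes the planted-simplex recovery reliable.
- The DP p-value is exact but O(m·r) per TF; regulon tables with many
  thousands of targets per TF on very long rankings will be slow.
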