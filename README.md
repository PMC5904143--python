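# action-sc

Archetypal analysis of single-cell transcriptomes: a cell-to-cell
similarity kernel that suppresses universally expressed genes and boosts
cell-type-specific ones, archetype discovery with automatic selection of
the number of archetypes, and archetype-specific transcriptional
regulatory network (TRN) inference from TF regulons.

## The problem

Single-cell RNA-seq profiles are dominated by housekeeping genes that are
highly expressed in every cell, while the genes that actually distinguish
cell types are weakly expressed. Generic similarity measures (correlation,
Euclidean distance) are driven by the former and blur the latter. This
package is for computational biologists who want to (i) measure cell
similarity on the type-specific signal, (ii) decompose a cell population
into a small number of extreme transcriptional programs ("archetypes")
with a principled choice of how many, and (iii) ask which transcription
factors plausibly drive each program.

## The model

Let **X** ∈ ℝ^{m×n} be a genes-by-cells expression matrix with columns
**x**_i. Each profile is z-scored to **z**_i; the universal signature
**v** = mean_i **x**_i is z-scored to **z**_v; and each profile is
projected onto the orthogonal complement of **z**_v:

    z_i⊥ = (I − z_v z_vᵀ / ‖z_v‖²) z_i

Gene specificity is measured by the normalized entropy u(i) of the i-th
row of the row-stochastic positive part **P** of **Z**⊥: a gene active
uniformly across cells has u = 1, a gene active in one cell has u = 0. A
two-Gaussian mixture over {u(i)} locates the boundary û between specific
and ubiquitous genes, and genes are rescaled by w_i = û/u(i) (> 1 for
specific genes, < 1 for ubiquitous ones). The similarity kernel is the
weighted dot product

    K = (Z⊥)ᵀ diag(w²) Z⊥ = Yᵀ Y,   Y = diag(w) Z⊥.

Cells are then modeled as near-convex combinations of k extreme profiles:
**Y** ≈ **Y C H** with column-stochastic **C** (n×k) and **H** (k×n), so
archetypes **A** = **YC** are convex combinations of cells and each cell's
column of **H** gives its convex weights on the archetypes. Candidate
corners come from the successive projection algorithm (SPA) after a
minimum-volume-ellipsoid preconditioning; k is grown until newly added
candidates crowd an already-covered region (z-scored candidate
similarities > 1.96 build a graph whose dense components are tested
against an Erdős–Rényi background); the corners are then relaxed by
principal convex hull analysis (PCHA).

For each archetype, the positive part of its profile is orthogonalized
against the other archetypes' positive parts; the residual expression
ranks genes by archetype specificity. A transcription factor's regulon is
scored on that ranking with the minimum-hypergeometric (mHG) statistic —
the best hypergeometric enrichment tail over all prefix cuts — and its
exact p-value is computed by a lattice-path dynamic program over all
arrangements of the targets. Significant TFs with their above-cut targets
form the per-archetype TRN.

## Worked example

```python
from action import (ACTIONKernel, ArchetypalAnalysis, SimulationConfig,
                    simulate_labeled_counts, clustering_scores, build_trn,
                    residual_expression)
from action.simulate import plant_regulons

ds = simulate_labeled_counts(SimulationConfig(seed=0))   # 5 types, 500 cells
regulons = plant_regulons(ds, target_type=0, seed=0)

kern = ACTIONKernel(random_state=0).fit(ds.X.values.T)   # cells x genes
print(f"entropy threshold u_hat = {kern.threshold_:.3f}")
print(f"genes boosted (w > 1): {(kern.weights_ > 1).sum()}")

aa = ArchetypalAnalysis(k_max=12, random_state=0).fit(kern.weighted_profiles_.T)
print(f"selected k* = {aa.n_archetypes_} archetypes")
scores = clustering_scores(aa.labels_, ds.labels)
print(f"ARI = {scores['ari']:.3f}, NMI = {scores['nmi']:.3f}, F = {scores['fscore']:.3f}")

net = build_trn(residual_expression(aa.archetypes_.T), ds.X.gene_ids,
                regulons, alpha=1e-3)
for arch in sorted(net.edges):
    tfs = net.significant_tfs(arch)
    if tfs:
        p = min(p for _, _, p in net.edges[arch])
        print(f"archetype {arch}: significant TFs {tfs} (min p = {p:.2e})")
```

Output:

```
entropy threshold u_hat = 0.799
genes boosted (w > 1): 100
selected k* = 5 archetypes
ARI = 1.000, NMI = 1.000, F = 1.000
archetype 3: significant TFs ['TF_PLANTED'] (min p = 4.44e-15)
```

The five planted cell types are recovered as five archetypes
(ARI/NMI/F = 1 against the planted labels), the 100 planted marker genes
(20 per type) are exactly the genes the entropy weighting boosts, and the
TF whose targets were planted among one type's markers is the only
regulator called significant — on the archetype representing that type —
while the random-target control TF is not.

The same pipeline is available from the shell:

```sh
action simulate --preset fivetype --seed 0 --out-prefix sim_
action kernel --input sim_X.tsv --output K.h5 --export-weights w.tsv
action decompose --kernel-input K.h5 --kmax 12 --output decomp.h5 --labels-output pred.csv
action trn --decomp decomp.h5 --input sim_X.tsv --regulons sim_regulons.tsv --out-prefix trn_
action evaluate --kernel K.h5 --k 5 --truth sim_labels.csv
```

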