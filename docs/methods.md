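# Methods

## Linear mixture model and estimation

Bulk expression is modeled as `Y ≈ X P` on linear scale (TPM/intensity
like). The signature `X` is built from sorted-cell reference profiles in
three steps: replicate columns are averaged per cell type; genes are
restricted to the (sorted) intersection with the bulk gene space; a gene
becomes a marker of type *k* iff its pseudocounted expression exceeds
that of **every** other type by more than the fold-change threshold
(default 1.5). Qualifying genes are ranked by enrichment over the
strongest competitor — the most selective deterministic ranking — with
lexicographic gene-id tie-breaks, and truncated to 200 per type.
Requiring enrichment over all other types makes marker lists disjoint by
construction. The rule is applied on linear-scale values with a
pseudocount of 1.0 to stabilize zero denominators; enrichment is
one-sided (genes depleted 1.5-fold are not markers), matching the usual
construction of a signature from type-enriched genes.

Each sample column is fitted independently by minimizing

    ‖y − X p‖₂² + λ [ (1−α)/2 ‖p‖₂² + α ‖p‖₁ ],   λ = 1, α = 0.05.

The data term carries no 1/(2n) factor. scikit-learn's coordinate
descent minimizes `(1/2n)‖y − Xw‖² + a·l1·‖w‖₁ + (a/2)(1−l1)‖w‖²`, so the
adapter passes `a = λ/(2N)` and `l1 = α` for `N` genes, which makes the
two objectives proportional and hence the minimizers identical. The
mapping is verified in the tests against (i) the closed-form ridge
solution `(XᵀX + (λ/2)I)⁻¹Xᵀy` obtained by differentiating the objective
at α = 0, and (ii) an independent proximal-gradient solver of the exact
objective; `λ = 0` falls back to ordinary least squares. No intercept
and no predictor standardization are fitted by default — the objective
contains neither — but both are exposed as configuration flags, as is an
optional `log2(x+1)` input transform and non-negative clipping.
Estimates are reported as unconstrained scores; no sum-to-one
renormalization is applied, because every downstream step consumes
z-scores, which are invariant to per-cell-type affine rescaling.

## Z-scoring conventions

`zscore_vs_control` standardizes each cell type within a control group:
`z = (value − mean(controls)) / sd(controls)` with ddof = 1; controls are
transformed with their own group's statistics, so each control block has
exactly zero mean. Groups need at least 2 controls and non-zero SD; both
violations are hard errors naming the offending (cell type, group).
`zscore_between_samples` standardizes each feature across a compared
sample set (ddof = 1); Pearson correlations are invariant under it, which
the tests assert numerically. ddof = 1 was chosen for both (the
convention of small-n toxicogenomics panels); the choice only rescales z
values uniformly.

## Compound stratification

Compounds are screened by peak ALT ≥ 65 IU/l over treated samples within
24 h (maximum over doses and times). Per retained compound, the
trafficking fingerprint is the mean over treated replicates of the
control-z-scored estimate for each of Mon, Neu, CD4T, CD8T at 3, 6, 9,
24 h (16 features). Replicates are aggregated by the mean. A
transcriptome variant uses per-gene `log(x+1)` condition means z-scored
across compounds.

Six 2-D candidate embeddings are computed (LLE, metric MDS, spectral
embedding, PCA, t-SNE, UMAP) with small-sample safeguards: t-SNE
perplexity `min(5, ⌊(n−1)/3⌋)`, neighbor counts `min(15, n−1)`, LLE
neighbors `min(5, n−2)`; a method that fails at the given n is dropped
with a warning. The candidates are combined by a spectral
meta-visualization step: for each point, every candidate's distance
vector to the other points is L2-normalized; the leading eigenvector of
the candidates' Gram (concordance) matrix — taken entrywise absolute and
normalized to sum 1, with a degenerate leading eigenvalue falling back to
uniform weights — weighs the candidates, and the weighted sum of
normalized distance rows forms the point's meta-distance row. The matrix
is symmetrized (`(m_ij + m_ji)/2`) with an exactly zero diagonal.
Consequences asserted in tests: the weights lie on the simplex, the
matrix is a valid dissimilarity, duplicated candidates share weight
uniformly and add nothing (the K-copies meta-distance equals the
single-candidate one exactly), a majority of concordant candidates
outweighs a dissident one, and the result is invariant to rigid motions
of any candidate. Because each row is unit-normalized per point, the
symmetrized matrix is rank-faithful to a single candidate only through
this normalization, not against raw distances — the relevant identity is
the one asserted.

The meta-distance is clustered agglomeratively with average linkage
(Ward is not applicable to a precomputed non-Euclidean dissimilarity;
linkage is configurable). Labels are renumbered by increasing cluster
size, ties broken by the lexicographically first member, so numbering is
stable across runs. The 2-D consensus layout (metric MDS of the
meta-distance with a fixed seed) is cosmetic and never used for
clustering. Per-cluster time courses are summarized as mean ± 1.96·SE
over all member samples per time; a single-sample cell reports its mean
with the CI flagged undefined rather than fabricated.

## ssGSEA and discriminative terms

Genes are ranked by expression descending (lexicographic tie-breaks);
the gene at position *i* of *N* gets rank value `r_i = N − i + 1` and, if
it belongs to the set, weight `r_i^τ` (τ = 0.75 by default). The
enrichment score is `ES = Σ_i [P_in(i) − P_out(i)]` with `P_in` the
weighted in-set cumulative fraction and `P_out` the uniform out-of-set
cumulative fraction, optionally divided by `N`. The variant (rank-value
weights, exponent, sum-of-differences running statistic, optional
normalization) is fixed here for determinism and is fully
config-exposed; scores are rank-based and therefore invariant under
strictly monotone transforms, which is property-tested, and the τ = 0
limit is cross-checked against a brute-force cumulative oracle. Sets are
intersected with the expression genes and dropped below 3 present genes.

Cluster characterization tests, per (cluster, set), the cluster's sample
scores against all other clustered samples with a two-sided Mann-Whitney
U (robust at small n; a Welch t-test is available), Bonferroni-corrected
across sets within each cluster contrast (Holm and BH available);
direction is the sign of the median difference. A constant score vector
short-circuits to p = 1.

## Synthetic data: what it emulates, and what it does not

`simulate_reference` draws a shared log-normal baseline per gene
(meanlog 3, sdlog 1), multiplies each planted marker by its fold change
(default 5) in its target type only, and applies multiplicative
log-normal noise — so at zero noise the marker enrichment ratio is exact.
`simulate_mixture` is the forward model `Y = XP` with multiplicative
log-normal noise (default SD 0.1, ~10% CV, typical of expression data).

`simulate_study` emulates a 16-compound, 4-time-point (3/6/9/24 h)
liver panel with matched vehicle controls: 1200 genes, 60 markers per
type, 3 treated replicates per condition and 8 shared controls per time
point. Control composition is an uneven, neutrophil-heavy simplex point
(Mon .15, Neu .35, CD4T .15, CD8T .10, NK .10, B .15) so control
z-scoring is exercised against a non-trivial baseline. Per-sample true
proportions add Gaussian replicate jitter (SD 0.04 per cell type, i.e.
10–40% CV — the order of inter-animal variability seen in flow
cytometry) and, for treated samples, a cluster archetype scaled by
`effect_scale` in units of that jitter SD, then clip and renormalize to
the simplex. The four archetypes are qualitatively distinct trafficking
narratives: early neutrophil influx, delayed monocyte accumulation, a
pan-immune response, and a late T-lymphocyte shift. Eight controls per
time point reflect that a multi-arm panel carries several vehicle groups
per sacrifice time; with only 3 controls the z denominators are so noisy
(χ²₂) that single features occasionally inflate several-fold even for
ground-truth inputs. ALT is drawn at 100–300 IU/l for every treated
sample and 15–45 for controls, so the ALT ≥ 65 screen passes all treated
compounds by construction (including at zero effect, letting clustering
robustness be tested independently of the screen); hematology analytes
carry baseline noise only. `simulate_gene_sets` plants discriminative
sets by sampling from the markers of the cell types a target cluster's
archetype moves, with the remainder drawn uniformly from the gene
universe.

What the generator does not emulate: probe-level microarray artifacts,
batch effects, compound-specific transcriptional programs beyond the
mixture signal, dose structure (a single dose group is generated),
liver-resident subpopulations whose profiles differ from circulating
cells, and correlated marker noise across cell types. Passing recovery
tests therefore show the estimator and pipeline are correct under the
linear mixture model with realistic noise magnitudes — not that real
liver NK/B-cell estimates are accurate, a limitation the validation
analysis of sorted-cell data also observed in the real setting.

## Problem sizes and numerical choices

Tests and the acceptance script use these sizes: 20 random 50×6
instances for solver-oracle comparisons; a 2000-gene / 100-marker
reference with 30 Dirichlet(1) mixtures for noisy recovery; 20 seeds at
effect scale 3 plus smaller grids (6–8 seeds) at 1.5/0.75/0 for
planted-cluster recovery; 200 gene sets of size 50 for term detection.
Elastic-net tolerance is 1e-6 with 10 000 iterations. Mean ARI is
expected to saturate at 1.0 at the top of the effect grid, so the
degradation check asserts non-increasing means with a strict end-to-end
decrease. Ties in marker ranking and ssGSEA ranking are broken
lexicographically; degenerate inputs (zero control SD, constant
features, empty gene intersections, sets equal to the universe) are hard
errors rather than silent NaNs.
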