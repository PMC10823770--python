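# immucast

Immune-cell deconvolution of bulk rat liver transcriptomes and
stratification of hepatotoxic compounds by the immune-cell trafficking
they induce.

Drug-induced liver injury is accompanied by time-dependent influx and
efflux of immune populations (monocytes, neutrophils, CD4/CD8 T cells, NK
cells, B cells). Measuring those directly requires flow cytometry of
perfused tissue, but a bulk expression profile already carries the
mixture signal. This package estimates per-sample immune-cell scores from
bulk transcriptomes with a sorted-cell signature matrix, z-scores them
against matched vehicle controls, and clusters compounds by their
trafficking time courses — the workflow a toxicogenomics group would run
over an Open TG-GATEs-style compound panel. A synthetic-data module
reproduces the study design (sorted-cell references with planted markers,
mixtures with known proportions, a multi-compound time course with
planted cluster structure), so the entire pipeline is testable end to end
without any external download.

## Model

Bulk expression is treated as a linear mixture `Y ≈ X P`, with `Y ∈
R^{N×M}` the bulk matrix over `N` marker genes and `M` samples, `X ∈
R^{N×K}` the signature matrix of `K` sorted cell types, and `P ∈ R^{K×M}`
the cell scores. `X` contains genes enriched more than 1.5-fold in one
cell type over **every** other type (up to 200 per type, ranked by
enrichment over the strongest competitor). Each sample column is
estimated by elastic-net regression

    p̂ = argmin_p ‖y − X p‖₂² + λ [ (1−α)/2 ‖p‖₂² + α ‖p‖₁ ],  λ = 1, α = 0.05,

solved by coordinate descent with the penalty rescaled exactly to this
objective (no intercept, no standardization). Downstream analysis uses
z-scores against matched vehicle controls. Compound stratification builds
a 16-dimensional trafficking fingerprint per compound (Mon/Neu/CD4T/CD8T
× 3/6/9/24 h), embeds it with six reduction methods (LLE, MDS, spectral
embedding, PCA, t-SNE, UMAP) and combines the candidates by spectral
meta-visualization: per compound, candidate distance profiles are
weighted by the leading eigenvector of their concordance matrix and
summed into a meta-distance that is hierarchically clustered. Clusters
are characterized by rank-weighted running-sum ssGSEA (τ = 0.75) and
Mann-Whitney tests with Bonferroni correction.

## Worked example

The numbered drivers under `analysis/` run the full study on simulated
data (each is `argparse`-driven; run them in order from the repository
root):

```
$ python analysis/01_simulate_study.py --seed 7
simulated 1200 genes x 224 samples (192 treated, 32 control)
16 compounds in 4 planted clusters at effect scale 3.0; planted gene set(s): ['planted_c2_1']

$ python analysis/02_build_signature.py
signature: 360 marker genes x 6 cell types

$ python analysis/03_estimate_scores.py
estimated 6 cell types x 224 samples (lambda=1.0, alpha=0.05)
control-z-scored table written; max |z| = 8.25

$ python analysis/04_validate_concordance.py
         pearson_r  slope  intercept  n_points
Mon          0.963  0.963        0.0        68
Neu          0.960  0.960       -0.0        68
CD4T         0.952  0.952        0.0        68
CD8T         0.963  0.963        0.0        68
NK           0.947  0.947        0.0        68
B            0.828  0.828       -0.0        68

$ python analysis/05_stratify_compounds.py --seed 7
16 compounds pass the ALT >= 65 screen
cluster sizes: {1: 4, 2: 4, 3: 4, 4: 4}

$ python analysis/06_enrichment_terms.py
  cluster 3: top term planted_c2_1 (up, adjusted p = 2.00e-09)
```

Reading: the per-cell-type Pearson r (0.83–0.96) is the concordance
between estimated scores and the known simulated fractions after
per-condition medians and z-scoring between conditions — the analogue of
validating estimates against flow cytometry. The four recovered clusters
match the planted archetypes exactly (compounds were assigned round-robin),
and the planted gene set is the top discriminative term of its target
cluster.

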