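"""End-to-end convenience wrappers over the library modules.

These chain the standard route — signature construction from the
reference, elastic-net estimation of cell scores, control z-scoring,
trafficking-feature assembly, embedding ensemble, meta-visualization and
hierarchical clustering — so drivers and tests run the whole analysis
with one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datasets import SyntheticStudy
from .deconv import ElasticNetConfig, ScoreMatrix, fit_proportions, zscore_vs_control
from .signature import build_signature, intersect_genes, select_markers
from .stratify import (
    ClusterAssignment,
    MetaDistance,
    assemble_trafficking_features,
    embed_candidates,
    filter_compounds_by_alt,
    hierarchical_cluster,
    meta_combine,
)

__all__ = ["StratificationResult", "estimate_scores", "stratify_study"]


@dataclass
class StratificationResult:
    signature: pd.DataFrame
    scores: ScoreMatrix
    z_scores: ScoreMatrix
    features: pd.DataFrame
    meta_distance: MetaDistance
    assignment: ClusterAssignment


def estimate_scores(
    expression: pd.DataFrame,
    reference: pd.DataFrame,
    cfg: ElasticNetConfig = ElasticNetConfig(),
    fc_threshold: float = 1.5,
    max_genes: int = 200,
) -> tuple[pd.DataFrame, ScoreMatrix]:
    """Signature from the reference, then elastic-net scores for the bulk."""
    ref, bulk = intersect_genes(reference, expression)
    markers = select_markers(ref, fc_threshold=fc_threshold, max_genes=max_genes)
    X = build_signature(ref, markers)
    Y = bulk.loc[X.index]
    return X, fit_proportions(Y, X, cfg)


def stratify_study(
    study: SyntheticStudy,
    n_clusters: int = 4,
    seed: int = 0,
    alt_threshold: float = 65.0,
    cfg: ElasticNetConfig = ElasticNetConfig(),
) -> StratificationResult:
    """Full trafficking stratification of a compound study."""
    X, scores = estimate_scores(study.expression, study.reference, cfg)
    z = zscore_vs_control(scores, study.metadata)
    compounds = filter_compounds_by_alt(study.metadata, threshold=alt_threshold)
    feats = assemble_trafficking_features(z, study.metadata, compounds=compounds)
    emb = embed_candidates(feats, seed=seed)
    md = meta_combine(emb)
    assignment = hierarchical_cluster(md, n_clusters=n_clusters)
    return StratificationResult(
        signature=X,
        scores=scores,
        z_scores=z,
        features=feats,
        meta_distance=md,
        assignment=assignment,
    )
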