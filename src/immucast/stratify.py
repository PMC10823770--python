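"""Compound stratification by immune-cell trafficking.

The trafficking response of each compound is summarized as a z-score
feature vector (cell type x sampling time), embedded in 2-D by six
dimensionality-reduction methods (LLE, MDS, spectral embedding, PCA,
t-SNE, UMAP), and the candidate embeddings are combined by a spectral
meta-visualization step into a single meta-distance matrix that is then
hierarchically clustered.

Meta-visualization weights each candidate per point by how concordant its
local distance profile is with the other candidates: for point *i* the
unit-normalized distance vectors of all candidates form a Gram matrix
whose leading eigenvector (made non-negative, normalized to sum 1) gives
the candidate weights, and the meta-distance row of *i* is the weighted
sum of the candidates' normalized distance rows, finally symmetrized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .datasets import DEFAULT_TIMES_H, TRAFFICKING_CELLS
from .deconv import ScoreMatrix

__all__ = [
    "EmbeddingSet",
    "MetaDistance",
    "ClusterAssignment",
    "filter_compounds_by_alt",
    "assemble_trafficking_features",
    "assemble_transcriptome_features",
    "embed_candidates",
    "meta_combine",
    "hierarchical_cluster",
    "summarize_time_course",
    "consensus_mds",
]


@dataclass
class EmbeddingSet:
    """Named 2-D candidate embeddings over a common point order."""

    point_ids: list[str]
    method_names: list[str]
    coords: list[np.ndarray]  # each n x 2
    seed: int = 0


@dataclass
class MetaDistance:
    """Combined compound x compound dissimilarity with per-point weights."""

    matrix: pd.DataFrame  # n x n symmetric, zero diagonal
    weights: pd.DataFrame  # n x K, rows sum to 1


@dataclass
class ClusterAssignment:
    """Compound -> cluster label (1..n_clusters) plus the linkage record."""

    labels: dict[str, int]
    linkage: np.ndarray = field(repr=False, default=None)
    method: str = "average"

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")


def filter_compounds_by_alt(
    meta: pd.DataFrame, threshold: float = 65.0, max_time_h: float = 24.0
) -> list[str]:
    """Compounds whose maximum ALT over treated samples within
    ``max_time_h`` reaches the hepatotoxicity screen threshold."""
    if "alt" not in meta.columns or meta["alt"].isna().all():
        raise ValueError("metadata carries no ALT values")
    treated = meta[~meta["is_control"] & (meta["time_h"] <= max_time_h)]
    peak = treated.groupby("compound")["alt"].max()
    return sorted(peak.index[peak >= threshold])


def assemble_trafficking_features(
    z_scores: ScoreMatrix,
    meta: pd.DataFrame,
    cell_types: Sequence[str] = TRAFFICKING_CELLS,
    times_h: Sequence[float] = DEFAULT_TIMES_H,
    compounds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per compound of control-z-scored trafficking features.

    Feature ``<cell>@<t>h`` is the mean over treated replicates of the
    z-scored estimate for that cell type at that time.
    """
    if z_scores.scale_tag != "zscore_vs_control":
        raise ValueError(
            "trafficking features require control-z-scored estimates "
            f"(got scale_tag={z_scores.scale_tag!r})"
        )
    data = z_scores.data
    sub = meta.loc[list(data.columns)]
    treated = sub[~sub["is_control"]]
    if compounds is None:
        compounds = sorted(treated["compound"].unique())
    rows = {}
    gaps = []
    for compound in compounds:
        feats = {}
        for t in times_h:
            mask = (treated["compound"] == compound) & (
                treated["time_h"] == float(t)
            )
            samples = list(treated.index[mask])
            if not samples:
                gaps.append((compound, t))
                continue
            for cell in cell_types:
                feats[f"{cell}@{t:g}h"] = data.loc[cell, samples].mean()
        rows[compound] = feats
    if gaps:
        raise ValueError(f"missing (compound, time) conditions: {gaps}")
    table = pd.DataFrame.from_dict(rows, orient="index")
    order = [f"{c}@{t:g}h" for c in cell_types for t in times_h]
    return table[order]


def assemble_transcriptome_features(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    times_h: Sequence[float] = DEFAULT_TIMES_H,
    compounds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-compound log-expression features, z-scored across compounds.

    Feature ``<gene>@<t>h`` is the mean over treated replicates of
    ``log(x + 1)`` expression; each feature column is then z-scored
    between compounds. Zero-variance features are dropped with a warning.
    """
    sub = meta.loc[list(expr.columns)]
    treated = sub[~sub["is_control"]]
    if compounds is None:
        compounds = sorted(treated["compound"].unique())
    blocks = []
    for t in times_h:
        rows = []
        for compound in compounds:
            mask = (treated["compound"] == compound) & (
                treated["time_h"] == float(t)
            )
            samples = list(treated.index[mask])
            if not samples:
                raise ValueError(f"missing condition ({compound}, {t})")
            rows.append(np.log1p(expr[samples]).mean(axis=1).to_numpy())
        block = pd.DataFrame(
            rows,
            index=list(compounds),
            columns=[f"{g}@{t:g}h" for g in expr.index],
        )
        blocks.append(block)
    table = pd.concat(blocks, axis=1)
    sd = table.std(axis=0, ddof=1)
    dead = sd[sd == 0]
    if len(dead):
        warnings.warn(
            f"dropping {len(dead)} constant feature(s)", stacklevel=2
        )
        table = table.drop(columns=list(dead.index))
        sd = sd.drop(index=list(dead.index))
    return (table - table.mean(axis=0)) / sd


def embed_candidates(feats: pd.DataFrame, seed: int = 0) -> EmbeddingSet:
    """Project the feature table to 2-D with six reduction methods.

    Methods: locally linear embedding, metric MDS, spectral embedding,
    PCA, t-SNE and UMAP, each with small-sample safeguards on its
    neighborhood size. A method that fails on the given n is dropped with
    a warning.
    """
    n = feats.shape[0]
    if n < 6:
        raise ValueError("need at least 6 points to embed")
    X = feats.to_numpy(dtype=float)
    n_neighbors = min(15, n - 1)
    perplexity = max(1, min(5, (n - 1) // 3))
    lle_neighbors = max(2, min(5, n - 2))

    from sklearn.decomposition import PCA
    from sklearn.manifold import (
        MDS,
        TSNE,
        LocallyLinearEmbedding,
        SpectralEmbedding,
    )

    def _umap(data):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from umap import UMAP

            return UMAP(
                n_components=2,
                n_neighbors=n_neighbors,
                random_state=seed,
                min_dist=0.1,
            ).fit_transform(data)

    builders = {
        "lle": lambda d: LocallyLinearEmbedding(
            n_components=2, n_neighbors=lle_neighbors, random_state=seed
        ).fit_transform(d),
        "mds": lambda d: MDS(
            n_components=2, random_state=seed, normalized_stress=False
        ).fit_transform(d),
        "spectral": lambda d: SpectralEmbedding(
            n_components=2,
            n_neighbors=n_neighbors,
            random_state=seed,
            affinity="nearest_neighbors",
        ).fit_transform(d),
        "pca": lambda d: PCA(n_components=2, random_state=seed).fit_transform(d),
        "tsne": lambda d: TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
        ).fit_transform(d),
        "umap": _umap,
    }
    names, coords = [], []
    for name, build in builders.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                emb = np.asarray(build(X), dtype=float)
            if not np.isfinite(emb).all():
                raise ValueError("non-finite coordinates")
        except Exception as exc:  # pragma: no cover - small-n fallback
            warnings.warn(f"embedding {name!r} dropped: {exc}", stacklevel=2)
            continue
        names.append(name)
        coords.append(emb)
    if not names:
        raise ValueError("every embedding method failed")
    return EmbeddingSet(
        point_ids=list(feats.index), method_names=names, coords=coords, seed=seed
    )


def meta_combine(emb: EmbeddingSet) -> MetaDistance:
    """Combine candidate embeddings into one meta-distance matrix.

    Per point i: the candidates' distance vectors to all other points are
    L2-normalized; their Gram matrix's leading eigenvector (absolute
    values, renormalized to sum 1; degenerate leading eigenvalue ->
    uniform) weights the candidates; the weighted sum of normalized
    distance rows is the meta-distance row. The result is symmetrized and
    has an exactly zero diagonal.
    """
    n = len(emb.point_ids)
    K = len(emb.method_names)
    if K < 1:
        raise ValueError("need at least one candidate embedding")
    dists = np.stack(
        [squareform(pdist(c)) for c in emb.coords]
    )  # K x n x n
    meta_rows = np.zeros((n, n))
    weights = np.zeros((n, K))
    for i in range(n):
        rows = dists[:, i, :]  # K x n (includes zero self-distance)
        norms = np.linalg.norm(rows, axis=1)
        valid = norms > 0
        if not valid.any():
            raise ValueError(f"point {emb.point_ids[i]!r} is isolated in "
                             "every candidate")
        if not valid.all():
            warnings.warn(
                f"candidate(s) {[emb.method_names[k] for k in np.where(~valid)[0]]}"
                f" degenerate at point {emb.point_ids[i]!r}; excluded there",
                stacklevel=2,
            )
        idx = np.where(valid)[0]
        unit = rows[idx] / norms[idx, None]
        gram = unit @ unit.T
        evals, evecs = np.linalg.eigh(gram)
        if len(evals) > 1 and abs(evals[-1] - evals[-2]) < 1e-12:
            w = np.full(len(idx), 1.0 / len(idx))
        else:
            w = np.abs(evecs[:, -1])
            w = w / w.sum()
        weights[i, idx] = w
        meta_rows[i] = w @ unit
    matrix = (meta_rows + meta_rows.T) / 2
    np.fill_diagonal(matrix, 0.0)
    return MetaDistance(
        matrix=pd.DataFrame(matrix, index=emb.point_ids, columns=emb.point_ids),
        weights=pd.DataFrame(
            weights, index=emb.point_ids, columns=emb.method_names
        ),
    )


def hierarchical_cluster(
    md: MetaDistance, n_clusters: int = 4, linkage: str = "average"
) -> ClusterAssignment:
    """Agglomerative clustering of the precomputed meta-distance.

    Labels are renumbered 1..n_clusters by increasing cluster size, ties
    broken by the lexicographically first member, so the numbering is
    stable across runs.
    """
    ids = list(md.matrix.index)
    n = len(ids)
    if not 2 <= n_clusters <= n:
        raise ValueError(f"n_clusters must lie in [2, {n}]")
    condensed = squareform(md.matrix.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for cid, name in zip(raw, ids):
        groups.setdefault(int(cid), []).append(name)
    order = sorted(
        groups, key=lambda c: (len(groups[c]), sorted(groups[c])[0])
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = {name: relabel[int(cid)] for cid, name in zip(raw, ids)}
    return ClusterAssignment(labels=labels, linkage=Z, method=linkage)


def summarize_time_course(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    assignment: ClusterAssignment,
    feature_axis: str = "rows",
) -> pd.DataFrame:
    """Per-cluster mean and 95% CI of each feature at each time point.

    ``values`` is features x samples (e.g. control-z-scored estimates or
    hematology analytes). The CI is mean +/- 1.96 SE over all samples of
    the cluster's compounds at that time; a single-sample cell reports the
    mean with the CI flagged undefined (NaN bounds, ``ci_defined=False``).
    """
    if feature_axis != "rows":
        values = values.T
    sub = meta.loc[list(values.columns)]
    treated = sub[~sub["is_control"]]
    rows = []
    for cluster in sorted(set(assignment.labels.values())):
        members = [c for c, k in assignment.labels.items() if k == cluster]
        for t in sorted(treated["time_h"].unique()):
            mask = treated["compound"].isin(members) & (treated["time_h"] == t)
            samples = list(treated.index[mask])
            for feature in values.index:
                vals = values.loc[feature, samples].to_numpy(dtype=float)
                n = len(vals)
                mean = float(np.mean(vals)) if n else np.nan
                if n >= 2:
                    se = float(np.std(vals, ddof=1)) / np.sqrt(n)
                    lo, hi = mean - 1.96 * se, mean + 1.96 * se
                    defined = True
                else:
                    lo = hi = np.nan
                    defined = False
                rows.append(
                    {
                        "cluster": cluster,
                        "feature": feature,
                        "time_h": t,
                        "mean": mean,
                        "ci_low": lo,
                        "ci_high": hi,
                        "n": n,
                        "ci_defined": defined,
                    }
                )
    return pd.DataFrame(rows)


def consensus_mds(md: MetaDistance, seed: int = 0) -> pd.DataFrame:
    """Cosmetic 2-D consensus layout of the meta-distance (metric MDS)."""
    from sklearn.manifold import MDS

    coords = MDS(
        n_components=2,
        dissimilarity="precomputed",
        random_state=seed,
        normalized_stress=False,
    ).fit_transform(md.matrix.to_numpy())
    return pd.DataFrame(coords, index=md.matrix.index, columns=["x", "y"])
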