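"""Single-sample gene-set enrichment (ssGSEA) and cluster-discriminative
term detection.

The ssGSEA variant is a rank-weighted running sum: genes are ranked by
expression (descending, ties broken lexicographically by gene id), the
gene at position i receives rank value r_i = N - i + 1 and, if it belongs
to the set, weight r_i^tau. The enrichment score is the sum over all
positions of the difference between the weighted in-set cumulative
fraction and the uniform out-of-set cumulative fraction; optionally
divided by N. Scores are rank-based, hence invariant under strictly
monotone transforms of the expression values.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stratify import ClusterAssignment

__all__ = ["ssgsea_score", "score_table", "discriminative_terms"]


def _ranked_genes(values: pd.Series) -> pd.Index:
    order = sorted(values.index, key=lambda g: (-values[g], g))
    return pd.Index(order)


def ssgsea_score(
    expr_sample: pd.Series,
    gene_set: Sequence[str],
    tau: float = 0.75,
    normalize: bool = True,
) -> float:
    """Enrichment score of one gene set in one expression profile."""
    in_set = set(gene_set) & set(expr_sample.index)
    if not in_set:
        raise ValueError("no gene of the set is present in the profile")
    if len(in_set) == len(expr_sample):
        raise ValueError("gene set equals the universe; complement is empty")
    ranked = _ranked_genes(expr_sample)
    return _es_from_ranking(
        np.fromiter((g in in_set for g in ranked), bool, len(ranked)),
        tau,
        normalize,
    )


def _es_from_ranking(mask: np.ndarray, tau: float, normalize: bool) -> float:
    N = len(mask)
    r = np.arange(N, 0, -1, dtype=float)  # N, N-1, ..., 1
    w = np.where(mask, r**tau, 0.0)
    p_in = np.cumsum(w) / w.sum()
    n_out = N - mask.sum()
    p_out = np.cumsum(~mask) / n_out
    es = float(np.sum(p_in - p_out))
    return es / N if normalize else es


def score_table(
    expr: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    tau: float = 0.75,
    normalize: bool = True,
    min_size: int = 3,
) -> pd.DataFrame:
    """ssGSEA scores for every (sample, gene set) pair.

    Sets are intersected with the expression genes; sets falling below
    ``min_size`` present genes are dropped with a warning. Returns a
    samples x sets DataFrame.
    """
    genes = set(expr.index)
    usable: dict[str, set[str]] = {}
    for name, members in sets.items():
        present = set(members) & genes
        if len(present) < min_size:
            warnings.warn(
                f"gene set {name!r} has {len(present)} gene(s) present "
                f"(< {min_size}); dropped",
                stacklevel=2,
            )
            continue
        if len(present) == len(genes):
            warnings.warn(f"gene set {name!r} equals the universe; dropped",
                          stacklevel=2)
            continue
        usable[name] = present
    if not usable:
        raise ValueError("no usable gene set after size filtering")
    out = pd.DataFrame(
        index=list(expr.columns), columns=list(usable), dtype=float
    )
    for sample in expr.columns:
        ranked = _ranked_genes(expr[sample])
        position = {g: i for i, g in enumerate(ranked)}
        N = len(ranked)
        for name, members in usable.items():
            mask = np.zeros(N, dtype=bool)
            mask[[position[g] for g in members]] = True
            out.loc[sample, name] = _es_from_ranking(mask, tau, normalize)
    return out


def discriminative_terms(
    scores: pd.DataFrame,
    assignment: ClusterAssignment,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "mannwhitney",
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Gene sets whose enrichment separates one cluster from the rest.

    For every (cluster, set) pair a two-sided test compares the scores of
    the cluster's samples against all other clustered samples, with a
    conservative multiplicity correction across all sets within the
    cluster contrast. Direction is the sign of the median difference.
    Rows are sorted by adjusted p within each cluster.
    """
    sub = meta.loc[[s for s in scores.index if s in meta.index]]
    labels = pd.Series(
        {
            s: assignment.labels.get(sub.loc[s, "compound"])
            for s in sub.index
            if not sub.loc[s, "is_control"]
        }
    ).dropna()
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters with scored samples")
    frames = []
    for cluster in clusters:
        in_samples = labels.index[labels == cluster]
        out_samples = labels.index[labels != cluster]
        if len(in_samples) < 2:
            warnings.warn(
                f"cluster {cluster} has < 2 scored samples; contrast skipped",
                stacklevel=2,
            )
            continue
        rows = []
        for name in scores.columns:
            a = scores.loc[in_samples, name].to_numpy(dtype=float)
            b = scores.loc[out_samples, name].to_numpy(dtype=float)
            if np.ptp(np.concatenate([a, b])) == 0:
                p = 1.0
            elif test == "mannwhitney":
                p = float(
                    stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                )
            elif test == "ttest":
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            direction = "up" if np.median(a) >= np.median(b) else "down"
            rows.append(
                {
                    "set_name": name,
                    "cluster": int(cluster),
                    "raw_p": p,
                    "direction": direction,
                }
            )
        frame = pd.DataFrame(rows)
        frame["adjusted_p"] = multipletests(
            frame["raw_p"], method=correction
        )[1]
        frame = frame.sort_values(
            ["adjusted_p", "raw_p", "set_name"]
        ).reset_index(drop=True)
        frame["significant"] = frame["adjusted_p"] < alpha
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out[
        ["set_name", "cluster", "raw_p", "adjusted_p", "direction", "significant"]
    ]
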