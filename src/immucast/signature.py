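"""Signature-matrix construction from sorted-cell reference profiles.

A gene is a marker of cell type *k* when its (pseudocounted) expression in
*k* exceeds its expression in every other type by more than a fold-change
threshold; per type, qualifying genes are ranked by their enrichment over
the strongest competitor and truncated to a maximum count. The signature
matrix X stacks the marker rows of all cell types, on linear scale, and is
the design matrix of the deconvolution regression.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "collapse_replicates",
    "intersect_genes",
    "select_markers",
    "build_signature",
]


def collapse_replicates(
    ref_raw: pd.DataFrame, cell_type_of_sample: Mapping[str, str]
) -> pd.DataFrame:
    """Average sorted-cell replicate columns into one profile per cell type.

    ``cell_type_of_sample`` maps every column of ``ref_raw`` to its cell
    type; an unlabeled column is an error. Cell-type order follows first
    appearance among the columns.
    """
    unlabeled = [s for s in ref_raw.columns if s not in cell_type_of_sample]
    if unlabeled:
        raise ValueError(f"samples without a cell-type label: {unlabeled}")
    order: list[str] = []
    for s in ref_raw.columns:
        ct = cell_type_of_sample[s]
        if ct not in order:
            order.append(ct)
    grouped = ref_raw.T.groupby(
        [cell_type_of_sample[s] for s in ref_raw.columns], sort=False
    ).mean()
    return grouped.T[order]


def intersect_genes(
    ref: pd.DataFrame, mixture: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict reference and bulk matrices to their common genes,
    sorted, in identical order."""
    common = sorted(set(ref.index) & set(mixture.index))
    if not common:
        raise ValueError("reference and mixture share no genes")
    return ref.loc[common], mixture.loc[common]


def select_markers(
    ref: pd.DataFrame,
    fc_threshold: float = 1.5,
    max_genes: int = 200,
    pseudocount: float = 1.0,
) -> dict[str, list[tuple[str, float]]]:
    """Select per-type marker genes by the fold-change rule.

    A gene qualifies for type *k* iff
    ``(expr_k + pc) / (expr_j + pc) > fc_threshold`` for every other type
    *j* — equivalently its ratio against the strongest competitor
    (max over the other types) exceeds the threshold. Qualifying genes are
    ranked by that ratio, descending (ties broken by gene id), and at most
    ``max_genes`` are retained per type. Requiring enrichment over *every*
    other type makes the per-type lists disjoint.
    """
    if ref.shape[1] < 2:
        raise ValueError("need at least two cell types")
    vals = ref.to_numpy(dtype=float) + pseudocount
    if (vals <= 0).any():
        raise ValueError("expression + pseudocount must be positive")
    markers: dict[str, list[tuple[str, float]]] = {}
    for k, cell in enumerate(ref.columns):
        others = np.delete(vals, k, axis=1)
        ratio = vals[:, k] / others.max(axis=1)
        qualifies = ratio > fc_threshold
        picked = pd.DataFrame(
            {"gene": ref.index[qualifies], "ratio": ratio[qualifies]}
        ).sort_values(["ratio", "gene"], ascending=[False, True])
        picked = picked.head(max_genes)
        if picked.empty:
            warnings.warn(
                f"no marker gene qualifies for cell type {cell!r}",
                stacklevel=2,
            )
        markers[cell] = list(zip(picked["gene"], picked["ratio"]))
    return markers


def build_signature(
    ref: pd.DataFrame, markers: Mapping[str, list[tuple[str, float]]]
) -> pd.DataFrame:
    """Assemble the marker-gene x cell-type signature matrix X.

    Rows concatenate the per-type marker lists in cell-type order; values
    are copied from the reference on linear scale.
    """
    genes: list[str] = []
    for cell in ref.columns:
        genes.extend(g for g, _ in markers.get(cell, []))
    if not genes:
        raise ValueError("all marker lists are empty; cannot build signature")
    return ref.loc[genes]
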