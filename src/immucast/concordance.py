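"""Concordance between estimated cell scores and measured cell fractions.

Mirrors the validation protocol: replicate values are summarized per
experimental condition by the median, both sides are z-scored between the
compared points, and agreement per cell type is reported as the Pearson
correlation plus an ordinary least-squares line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .deconv import zscore_between_samples

__all__ = ["aggregate_condition_medians", "concordance"]


def aggregate_condition_medians(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    by: tuple[str, ...] = ("compound", "dose_group", "time_h"),
) -> pd.DataFrame:
    """Median of each feature over the replicates of every condition.

    ``values`` is features x samples; columns are grouped by the ``by``
    metadata keys. Output columns are labelled ``compound|dose|time``.
    """
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing[:5]}")
    sub = meta.loc[list(values.columns), list(by)]
    keys = sub.astype(str).agg("|".join, axis=1)
    out = values.T.groupby(keys.values, sort=True).median().T
    return out


def concordance(
    estimated: pd.DataFrame,
    measured: pd.DataFrame,
    zscore: bool = True,
) -> pd.DataFrame:
    """Per-feature Pearson r and OLS fit of estimated on measured.

    Both tables are features x points with identical labels; with
    ``zscore`` (default) each side is first z-scored between the compared
    points, which leaves Pearson r unchanged and puts the regression on a
    common scale. Requires >= 3 paired points per feature.
    """
    if list(estimated.index) != list(measured.index) or list(
        estimated.columns
    ) != list(measured.columns):
        raise ValueError("estimated and measured must share labels")
    if estimated.shape[1] < 3:
        raise ValueError("need at least 3 paired points")
    if zscore:
        estimated = zscore_between_samples(estimated)
        measured = zscore_between_samples(measured)
    rows = []
    for feature in estimated.index:
        x = measured.loc[feature].to_numpy(dtype=float)
        y = estimated.loc[feature].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero variance for feature {feature!r}")
        fit = stats.linregress(x, y)
        rows.append(
            {
                "feature": feature,
                "pearson_r": fit.rvalue,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "n_points": len(x),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
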