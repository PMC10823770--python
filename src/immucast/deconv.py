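"""Elastic-net deconvolution of bulk expression and z-score transforms.

Each bulk sample column ``y`` is regressed on the signature matrix ``X``
by minimizing, per sample,

    ||y - X p||_2^2 + lam * [ (1 - alpha)/2 * ||p||_2^2 + alpha * ||p||_1 ]

with defaults ``lam = 1`` and ``alpha = 0.05``. The data term carries no
1/(2n) factor; scikit-learn's coordinate descent parametrization divides
the data term by 2n, so its penalty is rescaled exactly
(``alpha_sklearn = lam / (2 N)``, ``l1_ratio = alpha`` for N genes).
Estimates are reported as unconstrained cell scores — downstream analysis
uses only z-scored values, so no simplex renormalization is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

__all__ = [
    "ElasticNetConfig",
    "ScoreMatrix",
    "fit_proportions",
    "zscore_vs_control",
    "zscore_between_samples",
]


@dataclass(frozen=True)
class ElasticNetConfig:
    """Penalty configuration; the defaults reproduce the published setting."""

    lam: float = 1.0
    alpha: float = 0.05
    fit_intercept: bool = False
    nonneg_clip: bool = False
    max_iter: int = 10000
    tol: float = 1e-6
    log2_input: bool = False  # sensitivity option: log2(x+1) both Y and X

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class ScoreMatrix:
    """Cell-type x sample score matrix with its scale recorded."""

    data: pd.DataFrame
    scale_tag: str = "raw"

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def objective(
    X: np.ndarray, y: np.ndarray, p: np.ndarray, lam: float, alpha: float
) -> float:
    """The per-sample elastic-net objective, exactly as fitted."""
    r = y - X @ p
    return float(
        r @ r
        + lam * ((1 - alpha) / 2 * (p @ p) + alpha * np.abs(p).sum())
    )


def fit_proportions(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    cfg: ElasticNetConfig = ElasticNetConfig(),
) -> ScoreMatrix:
    """Estimate cell scores P for every sample column of ``Y``.

    ``Y`` must be restricted to the signature's marker genes in the same
    row order. Columns are solved independently; ``lam = 0`` falls back to
    ordinary least squares.
    """
    if list(Y.index) != list(X.index):
        raise ValueError("Y and X must share identical gene rows (same order)")
    Xv = X.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    if cfg.log2_input:
        Xv = np.log2(Xv + 1)
        Yv = np.log2(Yv + 1)
    n_genes = Xv.shape[0]
    if cfg.lam == 0:
        coef, *_ = np.linalg.lstsq(
            np.column_stack([Xv, np.ones(n_genes)]) if cfg.fit_intercept else Xv,
            Yv,
            rcond=None,
        )
        P = coef[: Xv.shape[1]]
    else:
        model = ElasticNet(
            alpha=cfg.lam / (2 * n_genes),
            l1_ratio=cfg.alpha,
            fit_intercept=cfg.fit_intercept,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
        )
        with warnings.catch_warnings():
            # l1_ratio=0 (pure ridge) is a supported limit of the same objective
            warnings.filterwarnings(
                "ignore", message=".*l1_ratio.*", category=UserWarning
            )
            model.fit(Xv, Yv)
        # coef_ is (n_targets, n_features) for 2-D y
        P = np.asarray(model.coef_).reshape(Yv.shape[1], Xv.shape[1]).T
    if cfg.nonneg_clip:
        P = np.clip(P, 0.0, None)
    data = pd.DataFrame(P, index=X.columns, columns=Y.columns)
    return ScoreMatrix(data=data, scale_tag="raw")


def _group_of(meta: pd.DataFrame) -> pd.Series:
    return meta["control_group_key"].astype(str)


def zscore_vs_control(scores: ScoreMatrix, meta: pd.DataFrame) -> ScoreMatrix:
    """Z-score every sample against its matched vehicle-control group.

    For each cell type and control group, ``z = (value - mean(controls)) /
    sd(controls)`` with ddof=1; control samples are transformed with their
    own group's statistics. Requires >= 2 controls per group and non-zero
    control SD.
    """
    data = scores.data
    missing = [s for s in data.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing[:5]}")
    sub = meta.loc[list(data.columns)]
    groups = _group_of(sub)
    out = pd.DataFrame(
        np.nan, index=data.index, columns=data.columns, dtype=float
    )
    for key, samples in groups.groupby(groups).groups.items():
        ctrl = [s for s in samples if sub.loc[s, "is_control"]]
        if len(ctrl) < 2:
            raise ValueError(
                f"control group {key!r} has {len(ctrl)} control sample(s); "
                "need at least 2"
            )
        mu = data[ctrl].mean(axis=1)
        sd = data[ctrl].std(axis=1, ddof=1)
        zero = sd[sd == 0]
        if len(zero):
            raise ValueError(
                f"zero control SD for {list(zero.index)} in group {key!r}"
            )
        cols = list(samples)
        out[cols] = data[cols].sub(mu, axis=0).div(sd, axis=0)
    return ScoreMatrix(data=out, scale_tag="zscore_vs_control")


def zscore_between_samples(
    values: pd.DataFrame, samples: list[str] | None = None
) -> pd.DataFrame:
    """Z-score each feature row across a set of compared samples (ddof=1)."""
    sub = values if samples is None else values[list(samples)]
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-score between samples")
    sd = sub.std(axis=1, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero variance for features {list(zero.index)[:5]}")
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
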