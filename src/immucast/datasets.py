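"""Synthetic reference profiles, bulk mixtures and a toxicogenomics-style
compound study with planted immune-trafficking clusters.

The generators emulate the structure of a sorted-immune-cell reference
(marker genes enriched in one cell type), bulk mixtures that follow the
linear model Y = X P with multiplicative log-normal noise, and a
multi-compound, multi-time-point liver study with matched vehicle controls,
ALT values and a planted cluster structure over trafficking responses.
Everything is seed-deterministic so downstream recovery is testable
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "TRAFFICKING_CELLS",
    "DEFAULT_TIMES_H",
    "SyntheticTruth",
    "SyntheticStudy",
    "simulate_reference",
    "simulate_mixture",
    "simulate_study",
    "simulate_gene_sets",
]

#: The six immune populations the reference is sorted into.
CELL_TYPES = ("Mon", "Neu", "CD4T", "CD8T", "NK", "B")

#: Populations used as trafficking features downstream.
TRAFFICKING_CELLS = ("Mon", "Neu", "CD4T", "CD8T")

DEFAULT_TIMES_H = (3.0, 6.0, 9.0, 24.0)

# Resting-liver composition used as the control baseline: neutrophil-heavy
# and deliberately uneven so control z-scoring is exercised against a
# non-trivial simplex point.
BASELINE_PROPORTIONS = {
    "Mon": 0.15,
    "Neu": 0.35,
    "CD4T": 0.15,
    "CD8T": 0.10,
    "NK": 0.10,
    "B": 0.15,
}

# Trafficking archetypes for the four planted clusters: rows are the
# trafficking cell types, columns the four sampling times. Entries are
# effect sizes in units of the control proportion SD (scaled by
# ``effect_scale`` at study time). The patterns are qualitatively distinct:
# early neutrophil influx, delayed monocyte accumulation, a pan-immune
# response, and a weak late lymphocyte shift.
_ARCHETYPES = {
    # early neutrophil influx, resolving by 24 h
    0: np.array(
        [
            [0.0, 0.0, 0.0, 0.0],  # Mon
            [1.0, 1.0, 0.5, 0.0],  # Neu
            [0.0, 0.0, 0.0, 0.0],  # CD4T
            [0.0, 0.0, 0.0, 0.0],  # CD8T
        ]
    ),
    # delayed monocyte accumulation
    1: np.array(
        [
            [0.0, 1.0, 1.0, 1.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    ),
    # pan-immune response across the whole time course
    2: np.array(
        [
            [1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, 1.0],
        ]
    ),
    # late T-lymphocyte shift
    3: np.array(
        [
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 1.0],
            [0.0, 0.0, 1.0, 1.0],
        ]
    ),
}


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside a simulated dataset."""

    true_proportions: pd.DataFrame | None = None  # cell types x samples
    true_markers: dict[str, list[str]] = field(default_factory=dict)
    true_cluster: dict[str, int] = field(default_factory=dict)
    effect_profiles: dict[int, pd.DataFrame] = field(default_factory=dict)
    shifted_genes: dict[int, list[str]] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    """A simulated multi-compound liver time-course study."""

    expression: pd.DataFrame  # genes x samples, linear scale
    metadata: pd.DataFrame  # indexed by sample id
    reference: pd.DataFrame  # genes x cell types, noiseless profiles
    truth: SyntheticTruth


def _lognormal_factor(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    if sd == 0:
        return np.ones(shape)
    return np.exp(rng.normal(0.0, sd, size=shape))


def simulate_reference(
    n_cell_types: int = 6,
    n_genes: int = 2000,
    markers_per_type: int = 100,
    marker_fc: float = 5.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    baseline_meanlog: float = 3.0,
    baseline_sdlog: float = 1.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate sorted-cell reference profiles with planted markers.

    Each gene has a log-normal baseline shared across cell types; each
    marker gene is multiplied by ``marker_fc`` in its target type only, and
    multiplicative log-normal noise of SD ``noise_sd`` is applied. With
    ``noise_sd=0`` a planted marker's target/other expression ratio equals
    ``marker_fc`` exactly.
    """
    if marker_fc <= 1:
        raise ValueError("marker_fc must exceed 1: markers must be enriched")
    if markers_per_type * n_cell_types > n_genes:
        raise ValueError("markers_per_type * n_cell_types exceeds n_genes")
    rng = np.random.default_rng(seed)
    cells = (
        list(CELL_TYPES[:n_cell_types])
        if n_cell_types <= len(CELL_TYPES)
        else [f"C{i + 1}" for i in range(n_cell_types)]
    )
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    baseline = rng.lognormal(baseline_meanlog, baseline_sdlog, size=n_genes)
    values = np.tile(baseline[:, None], (1, n_cell_types))
    markers: dict[str, list[str]] = {}
    for k, cell in enumerate(cells):
        rows = slice(k * markers_per_type, (k + 1) * markers_per_type)
        values[rows, k] *= marker_fc
        markers[cell] = genes[rows]
    values *= _lognormal_factor(rng, noise_sd, values.shape)
    ref = pd.DataFrame(values, index=genes, columns=cells)
    return ref, SyntheticTruth(true_markers=markers)


def simulate_mixture(
    reference: pd.DataFrame,
    proportions: pd.DataFrame,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Mix reference profiles into bulk samples: ``Y = X P`` with
    multiplicative log-normal noise.

    ``proportions`` is cell types x samples with non-negative columns
    summing to 1.
    """
    if list(proportions.index) != list(reference.columns):
        raise ValueError(
            "cell types of proportions do not match reference columns"
        )
    P = proportions.to_numpy(dtype=float)
    if (P < 0).any():
        raise ValueError("proportions must be non-negative")
    if not np.allclose(P.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("proportion columns must sum to 1")
    rng = np.random.default_rng(seed)
    Y = reference.to_numpy() @ P
    Y *= _lognormal_factor(rng, noise_sd, Y.shape)
    return pd.DataFrame(Y, index=reference.index, columns=proportions.columns)


def _archetype(cluster: int, n_clusters: int, times_h: Sequence[float]) -> pd.DataFrame:
    n_times = len(times_h)
    if cluster in _ARCHETYPES and n_times == 4:
        mat = _ARCHETYPES[cluster]
    else:
        # procedurally distinct pattern for non-default designs
        rng = np.random.default_rng(7_000_000 + cluster)
        mat = rng.choice([0.0, 0.5, 1.0], size=(len(TRAFFICKING_CELLS), n_times))
        mat[cluster % len(TRAFFICKING_CELLS), :] = 1.0
    return pd.DataFrame(
        mat[:, :n_times], index=list(TRAFFICKING_CELLS), columns=list(times_h)
    )


def simulate_study(
    n_compounds: int = 16,
    n_clusters: int = 4,
    times_h: Sequence[float] = DEFAULT_TIMES_H,
    n_replicates: int = 3,
    effect_scale: float = 3.0,
    seed: int = 0,
    n_genes: int = 1200,
    markers_per_type: int = 60,
    marker_fc: float = 5.0,
    mixture_noise_sd: float = 0.1,
    prop_noise_sd: float = 0.04,
    n_control_replicates: int = 8,
) -> SyntheticStudy:
    """Simulate a multi-compound liver time-course with planted clusters.

    Compounds are assigned round-robin to ``n_clusters`` trafficking
    archetypes. Per treated sample, true proportions are the control
    baseline plus Gaussian replicate jitter (SD ``prop_noise_sd``) plus the
    cluster archetype scaled by ``effect_scale`` (in control-SD units),
    clipped and renormalized to the simplex. Bulk expression follows
    :func:`simulate_mixture`. Matched vehicle controls exist at every time
    point; ALT is drawn above the hepatotoxicity screen threshold for every
    treated sample and at baseline for controls, and hematology analytes
    carry baseline noise only.
    """
    if n_clusters > n_compounds:
        raise ValueError("n_clusters cannot exceed n_compounds")
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    rng = np.random.default_rng(seed)
    reference, ref_truth = simulate_reference(
        n_cell_types=len(CELL_TYPES),
        n_genes=n_genes,
        markers_per_type=markers_per_type,
        marker_fc=marker_fc,
        noise_sd=0.0,
        seed=rng.integers(2**31),
    )
    cells = list(reference.columns)
    baseline = np.array([BASELINE_PROPORTIONS[c] for c in cells])
    compounds = [f"cmpd{i + 1:02d}" for i in range(n_compounds)]
    true_cluster = {c: i % n_clusters for i, c in enumerate(compounds)}
    effect_profiles = {
        k: _archetype(k, n_clusters, times_h) for k in range(n_clusters)
    }

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    prop_cols: list[np.ndarray] = []

    def _draw_proportions(effect: np.ndarray) -> np.ndarray:
        p = baseline + rng.normal(0.0, prop_noise_sd, size=len(cells)) + effect
        p = np.clip(p, 0.005, None)
        return p / p.sum()

    hem_analytes = ("TBIL", "PLT", "RBC", "LYM")

    def _meta_row(compound, time, rep, is_control, key, alt):
        row = {
            "compound": compound,
            "dose_group": "high",
            "time_h": float(time),
            "replicate": rep,
            "is_control": is_control,
            "control_group_key": key,
            "alt": alt,
        }
        for an in hem_analytes:
            row[f"hem_{an}"] = rng.normal(0.0, 1.0)
        return row

    for time in times_h:
        key = f"ctrl_{time:g}h"
        for rep in range(1, n_control_replicates + 1):
            sid = f"ctrl_t{time:g}_r{rep}"
            sample_ids.append(sid)
            prop_cols.append(_draw_proportions(np.zeros(len(cells))))
            meta_rows.append(
                _meta_row("vehicle", time, rep, True, key, rng.uniform(15, 45))
            )
    for compound in compounds:
        arch = effect_profiles[true_cluster[compound]]
        for time in times_h:
            effect = np.zeros(len(cells))
            for cell in TRAFFICKING_CELLS:
                effect[cells.index(cell)] = (
                    effect_scale * prop_noise_sd * arch.loc[cell, float(time)]
                )
            for rep in range(1, n_replicates + 1):
                sid = f"{compound}_t{time:g}_r{rep}"
                sample_ids.append(sid)
                prop_cols.append(_draw_proportions(effect))
                meta_rows.append(
                    _meta_row(
                        compound,
                        time,
                        rep,
                        False,
                        f"ctrl_{time:g}h",
                        rng.uniform(100, 300),
                    )
                )

    proportions = pd.DataFrame(
        np.column_stack(prop_cols), index=cells, columns=sample_ids
    )
    expression = simulate_mixture(
        reference, proportions, noise_sd=mixture_noise_sd, seed=rng.integers(2**31)
    )
    metadata = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))

    shifted: dict[int, list[str]] = {}
    for k, arch in effect_profiles.items():
        affected = [c for c in TRAFFICKING_CELLS if arch.loc[c].abs().sum() > 0]
        genes: list[str] = []
        for c in affected:
            genes.extend(ref_truth.true_markers[c])
        shifted[k] = sorted(genes)

    truth = SyntheticTruth(
        true_proportions=proportions,
        true_markers=ref_truth.true_markers,
        true_cluster=true_cluster,
        effect_profiles=effect_profiles,
        shifted_genes=shifted,
    )
    return SyntheticStudy(expression, metadata, reference, truth)


def simulate_gene_sets(
    study: SyntheticStudy,
    n_sets: int = 200,
    set_size: int = 50,
    n_discriminative: int = 1,
    target_cluster: int = 0,
    seed: int = 0,
) -> tuple[dict[str, list[str]], list[str]]:
    """Build a gene-set collection over a study's gene universe.

    ``n_discriminative`` sets are sampled from the genes whose expression is
    shifted in the target cluster's compounds (the markers of the cell
    types that cluster's archetype moves); the remaining sets are uniform
    draws from the whole universe. Returns the collection and the names of
    the planted sets.
    """
    universe = list(study.expression.index)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    pool = study.truth.shifted_genes.get(target_cluster, [])
    if n_discriminative > 0 and len(pool) < set_size:
        raise ValueError(
            f"cluster {target_cluster} has only {len(pool)} shifted genes, "
            f"fewer than set_size={set_size}"
        )
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    planted: list[str] = []
    for i in range(n_discriminative):
        name = f"planted_c{target_cluster}_{i + 1}"
        sets[name] = sorted(rng.choice(pool, size=set_size, replace=False))
        planted.append(name)
    for i in range(n_sets - n_discriminative):
        sets[f"random_{i + 1:03d}"] = sorted(
            rng.choice(universe, size=set_size, replace=False)
        )
    return sets, planted
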