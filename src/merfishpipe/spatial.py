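"""Spatial statistics: proximity enrichment, gene-set scores, distance curves.

Proximity between cell populations A and B is quantified as the mean number
of B cells within 30 um of each A cell (mu_true). Its null distribution is
built by jittering every B cell independently by Uniform(-100, 100) um in x
and y and recounting, 1000 times. The statistic is summarized as::

    enrichment = log2(mu_true / mu_background)
    Z = (mu_true - mu_background) / sigma_background
    P = 2 * (1 - Phi(|Z|))

with Benjamini-Hochberg FDR across all evaluated ordered pairs.

Gene-set activation/inflammation scores subtract the mean of an
expression-bin-matched random background pool from the mean Z-scored
expression of the set. Activation as a function of distance to a reference
cell type is summarized on a 0-80 um grid with a sliding 30-um window and
the curve mean subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProximityResult",
    "proximity_enrichment",
    "proximity_enrichment_pairs",
    "gene_set_score",
    "ActivationCurve",
    "score_vs_distance",
    "neighbor_score_correlation",
]


@dataclass
class ProximityResult:
    type_a: str
    type_b: str
    mu_true: float
    mu_background: float
    sigma_background: float
    enrichment: float
    z: float
    p: float
    fdr_p: float = np.nan


def _mean_neighbors(xy_a: np.ndarray, xy_b: np.ndarray, radius: float) -> float:
    """Mean over A cells of the number of B cells within ``radius``."""
    pairs = cKDTree(xy_a).count_neighbors(cKDTree(xy_b), radius)
    return pairs / len(xy_a)


def proximity_enrichment(
    xy_a: np.ndarray,
    xy_b: np.ndarray,
    radius_um: float = 30.0,
    jitter_um: float = 100.0,
    n_rand: int = 1000,
    seed: int = 0,
    type_a: str = "A",
    type_b: str = "B",
) -> ProximityResult:
    """Jittered-null proximity enrichment of B around A (one ordered pair).

    Only B positions are jittered; A stays fixed, so (A, B) and (B, A) are
    distinct statistics. A zero null standard deviation leaves Z and P as
    NaN (flagged, not raised).
    """
    xy_a = np.asarray(xy_a, dtype=float)
    xy_b = np.asarray(xy_b, dtype=float)
    if len(xy_a) == 0 or len(xy_b) == 0:
        raise ValueError("both cell sets must be non-empty")
    rng = np.random.default_rng(seed)
    mu_true = _mean_neighbors(xy_a, xy_b, radius_um)
    null = np.empty(n_rand)
    for r in range(n_rand):
        jitter = rng.uniform(-jitter_um, jitter_um, size=xy_b.shape)
        null[r] = _mean_neighbors(xy_a, xy_b + jitter, radius_um)
    mu_bg = float(null.mean())
    sigma_bg = float(null.std(ddof=0))
    enrichment = float(np.log2(mu_true / mu_bg)) if mu_true > 0 and mu_bg > 0 else np.nan
    if sigma_bg == 0:
        warnings.warn(f"zero null variance for pair ({type_a}, {type_b})")
        z = p = np.nan
    else:
        z = (mu_true - mu_bg) / sigma_bg
        p = float(2.0 * (1.0 - stats.norm.cdf(abs(z))))
    return ProximityResult(
        type_a=type_a,
        type_b=type_b,
        mu_true=float(mu_true),
        mu_background=mu_bg,
        sigma_background=sigma_bg,
        enrichment=enrichment,
        z=float(z) if np.isfinite(z) else np.nan,
        p=p if isinstance(p, float) else np.nan,
    )


def proximity_enrichment_pairs(
    obs: pd.DataFrame,
    type_col: str = "cell_type",
    pairs: list[tuple[str, str]] | None = None,
    radius_um: float = 30.0,
    jitter_um: float = 100.0,
    n_rand: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Proximity enrichment for every ordered pair of cell types, with FDR.

    ``obs`` needs ``x_um``, ``y_um`` and the type column; all cells are
    assumed to come from one section (call per section and combine
    otherwise). Returns one row per ordered pair.
    """
    types = sorted(pd.unique(obs[type_col]))
    if pairs is None:
        pairs = [(a, b) for a in types for b in types if a != b]
    xy = {t: obs.loc[obs[type_col] == t, ["x_um", "y_um"]].to_numpy(dtype=float) for t in types}
    results = []
    for i, (a, b) in enumerate(pairs):
        results.append(
            proximity_enrichment(
                xy[a], xy[b], radius_um, jitter_um, n_rand, seed=seed + i, type_a=a, type_b=b
            )
        )
    out = pd.DataFrame([vars(r) for r in results])
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr_p"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def gene_set_score(
    z_expr: pd.DataFrame,
    gene_set: list[str],
    n_ctrl: int = 50,
    n_bins: int = 25,
    seed: int = 0,
) -> pd.Series:
    """Per-cell gene-set score against a bin-matched random background.

    Genes are ranked by mean expression and cut into ``n_bins`` equal-size
    bins; for each set gene, ``n_ctrl`` control genes are drawn (seeded,
    without replacement where possible) from the same bin, excluding set
    members. The score is the mean expression of the set minus the mean of
    the pooled controls, per cell.
    """
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    missing = [g for g in gene_set if g not in z_expr.columns]
    if missing:
        raise KeyError(f"genes absent from the matrix: {missing}")
    rng = np.random.default_rng(seed)
    gene_means = z_expr.mean(axis=0)
    n_bins = min(n_bins, max(1, len(gene_means) // 2))
    bins = pd.qcut(gene_means.rank(method="first"), q=n_bins, labels=False)
    in_set = set(gene_set)
    controls: list[str] = []
    for g in gene_set:
        pool = [
            c for c in gene_means.index[bins == bins[g]] if c not in in_set
        ]
        if not pool:
            pool = [c for c in gene_means.index if c not in in_set]
        take = min(n_ctrl, len(pool))
        controls.extend(rng.choice(pool, size=take, replace=False))
    ctrl_mean = z_expr[controls].mean(axis=1) if controls else 0.0
    return (z_expr[list(gene_set)].mean(axis=1) - ctrl_mean).rename("score")


@dataclass
class ActivationCurve:
    """Mean-subtracted sliding-window score-vs-distance curve."""

    grid_um: np.ndarray  # 0..max_dist inclusive, 1-um steps
    mean_score: np.ndarray  # after mean subtraction
    sem: np.ndarray
    n_cells: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    subtracted_constant: float = np.nan


def score_vs_distance(
    scores: pd.Series,
    scored_obs: pd.DataFrame,
    reference_obs: pd.DataFrame,
    max_dist_um: float = 80.0,
    window_um: float = 30.0,
    step_um: float = 1.0,
) -> ActivationCurve:
    """Average score as a function of distance to the nearest reference cell.

    Per section, each scored cell's distance to the nearest reference-type
    cell is found; cells farther than ``max_dist_um`` are dropped. The mean
    (and sd/sqrt(n) SEM) of contributing scores is evaluated on a grid of
    ``step_um`` steps using a sliding window of width ``window_um`` clipped
    to [0, max_dist]; the unweighted grid mean is subtracted and reported as
    ``subtracted_constant``.
    """
    dists, vals = [], []
    for section, grp in scored_obs.groupby("section"):
        ref = reference_obs[reference_obs["section"] == section]
        if ref.empty:
            continue
        tree = cKDTree(ref[["x_um", "y_um"]].to_numpy(dtype=float))
        d, _ = tree.query(grp[["x_um", "y_um"]].to_numpy(dtype=float))
        keep = d <= max_dist_um
        dists.append(d[keep])
        vals.append(scores.loc[grp.index[keep]].to_numpy(dtype=float))
    grid = np.arange(0.0, max_dist_um + step_um / 2, step_um)
    if not dists or sum(len(d) for d in dists) == 0:
        warnings.warn("no scored cell within range of a reference cell")
        empty = np.full(len(grid), np.nan)
        return ActivationCurve(grid, empty, empty.copy(), np.zeros(len(grid), dtype=int))
    d = np.concatenate(dists)
    v = np.concatenate(vals)
    half = window_um / 2.0
    mean = np.empty(len(grid))
    sem = np.empty(len(grid))
    n = np.empty(len(grid), dtype=int)
    for i, g in enumerate(grid):
        lo, hi = max(g - half, 0.0), min(g + half, max_dist_um)
        mask = (d >= lo) & (d <= hi)
        n[i] = int(mask.sum())
        if n[i] == 0:
            mean[i] = sem[i] = np.nan
            continue
        mean[i] = v[mask].mean()
        sem[i] = v[mask].std(ddof=0) / np.sqrt(n[i])
    constant = float(np.nanmean(mean))
    return ActivationCurve(grid, mean - constant, sem, n, subtracted_constant=constant)


def neighbor_score_correlation(
    scores_a: pd.Series,
    obs_a: pd.DataFrame,
    scores_b: pd.Series,
    obs_b: pd.DataFrame,
    radius_um: float = 30.0,
) -> tuple[float, pd.DataFrame]:
    """Pearson R between A-cell scores and mean scores of their B neighbors.

    Per section, every A cell with at least one B cell within ``radius_um``
    contributes the pair (its own score, mean score of those B neighbors).
    Returns (R, pairs); R is NaN with fewer than 3 pairs or a constant side.
    """
    rows = []
    for section, grp in obs_a.groupby("section"):
        sub_b = obs_b[obs_b["section"] == section]
        if sub_b.empty:
            continue
        tree = cKDTree(sub_b[["x_um", "y_um"]].to_numpy(dtype=float))
        neigh = tree.query_ball_point(grp[["x_um", "y_um"]].to_numpy(dtype=float), r=radius_um)
        b_scores = scores_b.loc[sub_b.index].to_numpy(dtype=float)
        for cell_id, idxs in zip(grp.index, neigh):
            if idxs:
                rows.append((cell_id, scores_a.loc[cell_id], float(b_scores[idxs].mean())))
    pairs = pd.DataFrame(rows, columns=["cell_id", "score_a", "mean_score_b"])
    if len(pairs) < 3:
        return np.nan, pairs
    a = pairs["score_a"].to_numpy(dtype=float)
    b = pairs["mean_score_b"].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan, pairs
    return float(stats.pearsonr(a, b)[0]), pairs
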