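"""Quality control and normalization for snRNA-seq and MERFISH cell tables.

snRNA-seq filter: cells with fewer than 2,500 UMIs or fewer than 1,000
detected genes are removed, then genes detected in fewer than 3 cells.

MERFISH filter cascade, in order: optional doublet removal (pluggable
scorer), cells with fewer than 20 molecules or fewer than 5 detected genes
removed, volume bounds (volume below 100 um^3 or above 3x the median volume
of the cells surviving the count filter), then a two-sided 2% quantile trim
on total volume-normalized expression.

Normalization: counts are divided by cell volume, rescaled so each cell's
(pre-log) expression sums to 250, log-transformed (natural log of x+1), and
Z-scored per gene.

The two decoding runs of a dual-panel experiment are reconciled by mutual
nearest-neighbor matching of nucleus centroids within 5 um.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .celltable import CellTable

__all__ = [
    "qc_snrnaseq",
    "match_nuclei",
    "qc_merfish",
    "normalize_expression",
]

DoubletScorer = Callable[[pd.DataFrame], np.ndarray]  # counts -> boolean is-doublet


def qc_snrnaseq(
    counts: pd.DataFrame,
    min_umi: int = 2500,
    min_genes: int = 1000,
    min_cells_per_gene: int = 3,
    doublet_scorer: DoubletScorer | None = None,
) -> pd.DataFrame:
    """Filter an snRNA-seq count matrix (cells x genes).

    Cells with ``< min_umi`` total counts or ``< min_genes`` detected genes
    are removed first, then genes detected in ``< min_cells_per_gene``
    surviving cells. Doublet removal, when a scorer is supplied, runs before
    everything else.
    """
    if doublet_scorer is not None:
        is_doublet = np.asarray(doublet_scorer(counts), dtype=bool)
        counts = counts.loc[~is_doublet]
    umis = counts.sum(axis=1)
    genes_per_cell = (counts > 0).sum(axis=1)
    counts = counts.loc[(umis >= min_umi) & (genes_per_cell >= min_genes)]
    cells_per_gene = (counts > 0).sum(axis=0)
    counts = counts.loc[:, cells_per_gene >= min_cells_per_gene]
    if counts.empty:
        warnings.warn("snRNA-seq QC removed every cell or gene")
    return counts


def match_nuclei(
    centroids_run1: pd.DataFrame,
    centroids_run2: pd.DataFrame,
    max_dist_um: float = 5.0,
) -> tuple[pd.DataFrame, list, list]:
    """Mutual-nearest-neighbor matching of nuclei between two decoding runs.

    Both inputs are DataFrames indexed by nucleus id with columns ``x_um``
    and ``y_um``. A pair ``(a, b)`` is kept iff ``b`` is ``a``'s nearest
    nucleus in run 2, ``a`` is ``b``'s nearest in run 1, and their distance
    is at most ``max_dist_um``. Returns ``(pairs, dropped_run1,
    dropped_run2)`` where ``pairs`` has columns ``id_run1, id_run2,
    dist_um``. Ties at identical coordinates resolve to the lowest index,
    which is deterministic.
    """
    xy1 = centroids_run1[["x_um", "y_um"]].to_numpy(dtype=float)
    xy2 = centroids_run2[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy1) == 0 or len(xy2) == 0:
        empty = pd.DataFrame(columns=["id_run1", "id_run2", "dist_um"])
        return empty, list(centroids_run1.index), list(centroids_run2.index)
    d12, nn12 = cKDTree(xy2).query(xy1)
    d21, nn21 = cKDTree(xy1).query(xy2)
    rows = []
    matched1, matched2 = set(), set()
    for i in range(len(xy1)):
        j = int(nn12[i])
        if int(nn21[j]) == i and d12[i] <= max_dist_um:
            rows.append((centroids_run1.index[i], centroids_run2.index[j], float(d12[i])))
            matched1.add(i)
            matched2.add(j)
    pairs = pd.DataFrame(rows, columns=["id_run1", "id_run2", "dist_um"])
    dropped1 = [centroids_run1.index[i] for i in range(len(xy1)) if i not in matched1]
    dropped2 = [centroids_run2.index[j] for j in range(len(xy2)) if j not in matched2]
    return pairs, dropped1, dropped2


def concat_matched_counts(
    pairs: pd.DataFrame, counts_run1: pd.DataFrame, counts_run2: pd.DataFrame
) -> pd.DataFrame:
    """Concatenate the per-gene counts of matched nuclei from the two runs."""
    left = counts_run1.loc[pairs["id_run1"]].reset_index(drop=True)
    right = counts_run2.loc[pairs["id_run2"]].reset_index(drop=True)
    out = pd.concat([left, right], axis=1)
    out.index = pd.Index(pairs["id_run1"].to_numpy(), name="cell_id")
    return out


def qc_merfish(
    table: CellTable,
    min_counts: int = 20,
    min_genes: int = 5,
    min_volume_um3: float = 100.0,
    max_volume_median_factor: float = 3.0,
    trim_quantile: float = 0.02,
    doublet_scorer: DoubletScorer | None = None,
    exclude_genes: tuple[str, ...] = (),
) -> CellTable:
    """Apply the MERFISH cell-filter cascade in its stated order.

    ``exclude_genes`` supports dropping genes read out on a compromised bit
    before any cell filtering. The volume median for the upper bound is
    computed on the cells surviving the counts/genes filter. The final trim
    removes cells whose total volume-normalized expression falls strictly
    below the ``trim_quantile`` or strictly above the ``1 - trim_quantile``
    quantile; cells exactly at a boundary are kept.
    """
    if exclude_genes:
        keep = [g for g in table.counts.columns if g not in set(exclude_genes)]
        table = CellTable(counts=table.counts[keep], obs=table.obs)
    if doublet_scorer is not None:
        is_doublet = np.asarray(doublet_scorer(table.counts), dtype=bool)
        table = table.subset(~is_doublet)

    total = table.counts.sum(axis=1)
    n_genes = (table.counts > 0).sum(axis=1)
    table = table.subset((total >= min_counts) & (n_genes >= min_genes))

    vol = table.obs["volume_um3"]
    median_vol = float(vol.median()) if len(vol) else np.nan
    table = table.subset(
        (vol >= min_volume_um3) & (vol <= max_volume_median_factor * median_vol)
    )

    norm_total = (table.counts.div(table.obs["volume_um3"], axis=0)).sum(axis=1)
    lo = norm_total.quantile(trim_quantile)
    hi = norm_total.quantile(1.0 - trim_quantile)
    table = table.subset((norm_total >= lo) & (norm_total <= hi))

    if table.n_cells == 0:
        raise ValueError("MERFISH QC removed every cell")
    return table


def normalize_expression(table: CellTable, target_sum: float = 250.0) -> CellTable:
    """Volume-normalize, rescale to ``target_sum`` per cell, log, Z-score.

    Adds three layers to a copy of the table: ``norm_expr`` (counts divided
    by volume, each cell rescaled to sum to ``target_sum``), ``log_expr``
    (log1p of ``norm_expr``), and ``z_expr`` (``log_expr`` Z-scored per gene
    across cells; constant genes map to 0).
    """
    out = table.copy()
    per_volume = out.counts.div(out.obs["volume_um3"], axis=0)
    totals = per_volume.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cell with zero total expression; run QC first")
    out.norm_expr = per_volume.mul(target_sum / totals, axis=0)
    out.log_expr = np.log1p(out.norm_expr)
    mean = out.log_expr.mean(axis=0)
    sd = out.log_expr.std(axis=0, ddof=0)
    sd = sd.replace(0.0, np.nan)
    out.z_expr = out.log_expr.sub(mean, axis=1).div(sd, axis=1).fillna(0.0)
    return out
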