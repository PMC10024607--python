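"""Per-cell container shared by all pipeline stages.

A :class:`CellTable` bundles the raw molecule counts of an imaging-based
spatial transcriptomics experiment with per-cell metadata (spatial centroid
in micrometers, nucleus volume in cubic micrometers, age / condition /
section labels) and, after normalization, up to three derived expression
layers:

``norm_expr``
    counts divided by cell volume, rescaled so each cell sums to 250.
``log_expr``
    natural log of ``norm_expr + 1``.
``z_expr``
    ``log_expr`` Z-scored per gene across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: obs columns that every MERFISH-style cell table is expected to carry.
SPATIAL_COLUMNS = ("x_um", "y_um", "volume_um3")


@dataclass
class CellTable:
    """Cells-by-genes counts plus per-cell metadata and expression layers."""

    counts: pd.DataFrame
    obs: pd.DataFrame
    norm_expr: pd.DataFrame | None = None
    log_expr: pd.DataFrame | None = None
    z_expr: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.obs.index):
            raise ValueError("counts and obs must share the same cell index")

    # -- basic introspection -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def genes(self) -> pd.Index:
        return self.counts.columns

    @property
    def xy(self) -> np.ndarray:
        """Cell centroids as an (n_cells, 2) float array in micrometers."""
        return self.obs[["x_um", "y_um"]].to_numpy(dtype=float)

    # -- manipulation --------------------------------------------------------
    def subset(self, mask) -> "CellTable":
        """Return a new table restricted to cells selected by ``mask``.

        ``mask`` may be a boolean array aligned to the cell index or a list
        of cell ids. Layers are sliced consistently.
        """

        def _take(df: pd.DataFrame | None) -> pd.DataFrame | None:
            return None if df is None else df.loc[mask_ids]

        if isinstance(mask, (pd.Series, np.ndarray, list)) and np.asarray(mask).dtype == bool:
            mask_ids = self.counts.index[np.asarray(mask)]
        else:
            mask_ids = pd.Index(mask)
        return CellTable(
            counts=self.counts.loc[mask_ids],
            obs=self.obs.loc[mask_ids],
            norm_expr=_take(self.norm_expr),
            log_expr=_take(self.log_expr),
            z_expr=_take(self.z_expr),
        )

    def copy(self) -> "CellTable":
        return CellTable(
            counts=self.counts.copy(),
            obs=self.obs.copy(),
            norm_expr=None if self.norm_expr is None else self.norm_expr.copy(),
            log_expr=None if self.log_expr is None else self.log_expr.copy(),
            z_expr=None if self.z_expr is None else self.z_expr.copy(),
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (optional dependency)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.to_numpy(dtype=float),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=self.counts.columns),
        )
        for name in ("norm_expr", "log_expr", "z_expr"):
            layer = getattr(self, name)
            if layer is not None:
                adata.layers[name] = layer.to_numpy(dtype=float)
        return adata
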