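"""Spatial-domain segmentation from neighborhood cell-type composition.

Each cell is summarized by the counts of every cell cluster within a 100-um
radius of it (excluding itself, never crossing section boundaries). PCA
followed by seeded k-means with k=20 over-segments the tissue; a
user-supplied merge map (guided by an average-linkage hierarchy of the
k-means centers) collapses the raw spatial clusters into named anatomical
domains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "neighborhood_composition",
    "segment_domains",
    "merge_domains",
    "DomainSegmentation",
]


def neighborhood_composition(
    obs: pd.DataFrame,
    cluster_col: str = "cluster",
    radius_um: float = 100.0,
) -> pd.DataFrame:
    """Cells-by-clusters neighbor counts within ``radius_um``.

    ``obs`` needs ``x_um``, ``y_um``, ``section`` and the cluster column;
    rows with missing cluster labels are an error. Entry (i, c) counts the
    cells of cluster c within Euclidean distance ``radius_um`` of cell i in
    the same section, excluding cell i itself.
    """
    if obs[cluster_col].isna().any():
        raise ValueError("all cells must carry a cluster label")
    clusters = sorted(pd.unique(obs[cluster_col]))
    cluster_idx = {c: i for i, c in enumerate(clusters)}
    comp = np.zeros((len(obs), len(clusters)), dtype=np.int64)
    pos = {cid: i for i, cid in enumerate(obs.index)}
    for _, grp in obs.groupby("section"):
        xy = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        labels = grp[cluster_col].map(cluster_idx).to_numpy()
        rows = [pos[cid] for cid in grp.index]
        tree = cKDTree(xy)
        neighbor_lists = tree.query_ball_point(xy, r=radius_um)
        for local_i, neighbors in enumerate(neighbor_lists):
            for local_j in neighbors:
                if local_j == local_i:
                    continue
                comp[rows[local_i], labels[local_j]] += 1
    return pd.DataFrame(comp, index=obs.index, columns=clusters)


@dataclass
class DomainSegmentation:
    """Raw spatial-cluster labels plus the objects needed to merge them."""

    labels: pd.Series
    pc_coords: np.ndarray
    kmeans_centers: np.ndarray
    inertia: float
    degenerate: bool = False

    def center_hierarchy(self) -> np.ndarray:
        """Average-linkage hierarchy over k-means centers (scipy linkage matrix)."""
        return linkage(self.kmeans_centers, method="average")


def segment_domains(
    composition: pd.DataFrame,
    k: int = 20,
    n_pcs: int | None = None,
    seed: int = 0,
    n_init: int = 10,
) -> DomainSegmentation:
    """PCA + seeded k-means segmentation of the composition matrix."""
    if len(composition) < k:
        raise ValueError(f"{len(composition)} cells cannot support k={k} clusters")
    X = composition.to_numpy(dtype=float)
    degenerate = bool(np.allclose(X, X[0]))
    if degenerate:
        warnings.warn("all composition rows identical; segmentation is degenerate")
    if n_pcs is None:
        n_pcs = min(20, composition.shape[1] - 1) or 1
    n_pcs = max(1, min(n_pcs, min(X.shape)))
    coords = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(coords)
    return DomainSegmentation(
        labels=pd.Series(km.labels_, index=composition.index, name="spatial_cluster"),
        pc_coords=coords,
        kmeans_centers=km.cluster_centers_,
        inertia=float(km.inertia_),
        degenerate=degenerate,
    )


def merge_domains(raw_labels: pd.Series, merge_map: dict) -> pd.Series:
    """Deterministically relabel raw spatial clusters into final domains.

    ``merge_map`` must cover every label present in ``raw_labels``; extra
    entries (e.g. for empty raw clusters) are tolerated.
    """
    present = set(pd.unique(raw_labels))
    missing = present - set(merge_map)
    if missing:
        raise KeyError(f"merge map does not cover raw labels {sorted(missing)}")
    return raw_labels.map(merge_map).rename("domain")
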