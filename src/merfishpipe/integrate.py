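"""Joint embedding of MERFISH and snRNA-seq, imputation, and label transfer.

The two modalities are restricted to the shared gene panel, Z-scored,
concatenated, and reduced by PCA. A pluggable aligner then removes
modality-specific structure from the principal-component coordinates; the
built-in default matches per-modality centroids per PC, which removes any
constant modality offset exactly. Genome-wide profiles are imputed onto
imaged cells by averaging the full expression profiles of their 10 nearest
sequenced neighbors in the first 30 aligned PCs. Labels are transferred to
new (e.g. LPS-treated) cells with a seeded multilayer-perceptron classifier
on the first 25 joint PCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

__all__ = [
    "JointEmbedding",
    "centroid_aligner",
    "joint_embed",
    "impute_expression",
    "validate_imputation_bins",
    "validate_imputation_celltype_region",
    "transfer_labels",
]

#: aligner contract: (coords, modality labels) -> adjusted coords, same shape,
#: same row order; must reduce the distance between modality centroids.
Aligner = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class JointEmbedding:
    """PC coordinates of both modalities plus per-cell tags."""

    coordinates: pd.DataFrame  # cells x PCs
    modality: pd.Series  # "merfish" | "snrnaseq"
    batch: pd.Series

    @property
    def n_pcs(self) -> int:
        return self.coordinates.shape[1]

    def cells(self, modality: str) -> pd.Index:
        return self.coordinates.index[self.modality == modality]


def centroid_aligner(coords: np.ndarray, modality: np.ndarray) -> np.ndarray:
    """Shift each modality so its centroid lands on the global centroid."""
    out = coords.copy()
    global_mean = coords.mean(axis=0)
    for mod in np.unique(modality):
        mask = modality == mod
        out[mask] += global_mean - coords[mask].mean(axis=0)
    return out


def joint_embed(
    expr_merfish: pd.DataFrame,
    expr_snrna: pd.DataFrame,
    n_pcs: int = 50,
    aligner: Aligner | None = centroid_aligner,
    batch_merfish: pd.Series | None = None,
    batch_snrna: pd.Series | None = None,
    seed: int = 0,
) -> JointEmbedding:
    """PCA of the concatenated Z-scored panel matrices, then alignment.

    Both matrices must cover exactly the same (panel) genes. ``n_pcs`` is
    capped at the achievable rank.
    """
    if list(expr_merfish.columns) != list(expr_snrna.columns):
        raise ValueError("modalities must share an identical gene panel")
    joint = pd.concat([expr_merfish, expr_snrna])
    modality = np.array(
        ["merfish"] * len(expr_merfish) + ["snrnaseq"] * len(expr_snrna)
    )
    n_pcs = min(n_pcs, min(joint.shape))
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(joint.to_numpy(dtype=float))
    if aligner is not None:
        coords = aligner(coords, modality)
    index = joint.index
    batch = pd.concat(
        [
            batch_merfish if batch_merfish is not None else pd.Series("merfish", index=expr_merfish.index),
            batch_snrna if batch_snrna is not None else pd.Series("snrnaseq", index=expr_snrna.index),
        ]
    )
    return JointEmbedding(
        coordinates=pd.DataFrame(coords, index=index, columns=[f"pc{i + 1}" for i in range(n_pcs)]),
        modality=pd.Series(modality, index=index),
        batch=batch,
    )


def impute_expression(
    embedding: JointEmbedding,
    snrna_profiles: pd.DataFrame,
    k: int = 10,
    n_pcs: int = 30,
) -> pd.DataFrame:
    """kNN-average imputation of full profiles onto MERFISH cells.

    For every MERFISH cell, the ``k`` nearest snRNA-seq cells by Euclidean
    distance in the first ``n_pcs`` embedding coordinates are found and
    their ``snrna_profiles`` rows (any gene universe) averaged without
    weights.
    """
    merfish_ids = embedding.cells("merfish")
    snrna_ids = embedding.cells("snrnaseq")
    if len(snrna_ids) == 0:
        raise ValueError("embedding contains no snRNA-seq cells")
    if len(snrna_ids) < k:
        warnings.warn(f"only {len(snrna_ids)} snRNA-seq cells available; using all")
        k = len(snrna_ids)
    n_pcs = min(n_pcs, embedding.n_pcs)
    ref = embedding.coordinates.loc[snrna_ids].iloc[:, :n_pcs].to_numpy()
    query = embedding.coordinates.loc[merfish_ids].iloc[:, :n_pcs].to_numpy()
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    _, idx = nn.kneighbors(query)
    profiles = snrna_profiles.loc[snrna_ids].to_numpy(dtype=float)
    imputed = profiles[idx].mean(axis=1)
    return pd.DataFrame(imputed, index=merfish_ids, columns=snrna_profiles.columns)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def validate_imputation_bins(
    measured: pd.DataFrame,
    imputed: pd.DataFrame,
    obs: pd.DataFrame,
    bin_um: float = 150.0,
) -> pd.Series:
    """Per-gene Pearson r between measured and imputed spatial bin means.

    Cells are assigned to half-open square bins of side ``bin_um`` anchored
    at each section's bounding-box lower-left corner; a bin's value is the
    mean over its cells; empty bins are excluded. Genes shared by both
    matrices are correlated across all (section, bin) combinations.
    """
    genes = [g for g in measured.columns if g in set(imputed.columns)]
    keys = []
    for section, grp in obs.groupby("section"):
        x0, y0 = grp["x_um"].min(), grp["y_um"].min()
        bx = np.floor((grp["x_um"] - x0) / bin_um).astype(int)
        by = np.floor((grp["y_um"] - y0) / bin_um).astype(int)
        keys.append(pd.Series(list(zip([section] * len(grp), bx, by)), index=grp.index))
    bin_key = pd.concat(keys).loc[measured.index]
    meas_bins = measured[genes].groupby(bin_key.to_numpy()).mean()
    imp_bins = imputed[genes].groupby(bin_key.to_numpy()).mean()
    if len(meas_bins) < 2:
        return pd.Series(np.nan, index=genes)
    return pd.Series(
        {g: _pearson(meas_bins[g].to_numpy(), imp_bins[g].to_numpy()) for g in genes}
    )


def validate_imputation_celltype_region(
    measured: pd.DataFrame,
    imputed: pd.DataFrame,
    type_labels: pd.Series,
    region_labels: pd.Series,
) -> pd.DataFrame:
    """Pearson r across genes of mean profiles per (cell type, region).

    Returns a type x region DataFrame; strata with no cells, or with
    constant mean profiles, are NA.
    """
    genes = [g for g in measured.columns if g in set(imputed.columns)]
    types = sorted(pd.unique(type_labels))
    regions = sorted(pd.unique(region_labels))
    out = pd.DataFrame(np.nan, index=types, columns=regions)
    for t in types:
        for r in regions:
            mask = ((type_labels == t) & (region_labels == r)).to_numpy()
            if mask.sum() == 0:
                continue
            m = measured.loc[mask, genes].mean(axis=0).to_numpy()
            i = imputed.loc[mask, genes].mean(axis=0).to_numpy()
            out.loc[t, r] = _pearson(m, i)
    return out


def transfer_labels(
    reference_coords: pd.DataFrame,
    reference_labels: pd.Series,
    query_coords: pd.DataFrame,
    n_pcs: int = 25,
    classifier=None,
    seed: int = 0,
) -> pd.Series:
    """Supervised label transfer on joint PC coordinates.

    Default classifier is a seeded feed-forward network (one hidden layer of
    64 units); any scikit-learn style estimator may be supplied. Classes
    with fewer than 5 reference cells trigger a warning.
    """
    n_pcs = min(n_pcs, reference_coords.shape[1], query_coords.shape[1])
    small = reference_labels.value_counts()
    for cls, n in small.items():
        if n < 5:
            warnings.warn(f"reference class {cls!r} has only {n} cells")
    if classifier is None:
        classifier = MLPClassifier(
            hidden_layer_sizes=(64,), max_iter=1000, random_state=seed
        )
    X = reference_coords.iloc[:, :n_pcs].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        classifier.fit(X, reference_labels.to_numpy())
    preds = classifier.predict(query_coords.iloc[:, :n_pcs].to_numpy())
    return pd.Series(preds, index=query_coords.index, name="predicted_label")
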