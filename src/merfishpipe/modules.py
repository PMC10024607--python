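"""Gene-module discovery from a low-rank gene-gene correlation proxy.

The gene-gene relationship matrix is the rank-50 reconstruction of the
gene-space dot product: with the SVD ``X = U S V^T`` of the Z-scored
cells-by-genes expression matrix, the gene representation is ``G = V_k S_k``
and the correlation proxy ``G G^T`` (equal to ``X^T X`` when k reaches the
rank). The proxy is Z-scored over its off-diagonal entries and entries with
Z below 0.1 are zeroed. Genes are embedded in 2-D (deterministic spectral
embedding by default, UMAP pluggable) and clustered with DBSCAN; candidate
modules are kept only if their mean intra-module correlation beats a
1000-fold label-permutation null at FDR < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "lowrank_gene_correlation",
    "sparsify_zscore",
    "embed_cluster_genes",
    "test_modules",
    "GeneModuleSet",
    "find_gene_modules",
]


def lowrank_gene_correlation(expr: pd.DataFrame, n_sv: int = 50) -> pd.DataFrame:
    """Rank-``n_sv`` gene-gene dot-product matrix from Z-scored expression."""
    X = expr.to_numpy(dtype=float)
    max_rank = min(X.shape)
    if n_sv > max_rank:
        warnings.warn(f"n_sv={n_sv} exceeds matrix rank; capped at {max_rank}")
        n_sv = max_rank
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    G = vt[:n_sv].T * s[:n_sv]
    corr = G @ G.T
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(corr, index=expr.columns, columns=expr.columns)


def sparsify_zscore(corr: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Z-score over off-diagonal entries; zero everything with Z < threshold.

    The threshold is applied literally, so negative Z entries are zeroed
    too. The diagonal is zeroed as well (self-similarity carries no module
    information). A constant input yields an all-zero matrix with a warning.
    """
    M = corr.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("input must be square and symmetric")
    off = ~np.eye(M.shape[0], dtype=bool)
    mu, sd = M[off].mean(), M[off].std(ddof=0)
    if sd == 0:
        warnings.warn("constant correlation matrix; sparsified result is all zero")
        return pd.DataFrame(np.zeros_like(M), index=corr.index, columns=corr.columns)
    Z = (M - mu) / sd
    Z[Z < threshold] = 0.0
    np.fill_diagonal(Z, 0.0)
    return pd.DataFrame(Z, index=corr.index, columns=corr.columns)


def _spectral_embedding(affinity: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Deterministic spectral embedding of a non-negative affinity matrix.

    Coordinates are the leading eigenvectors of the affinity itself scaled
    by sqrt(eigenvalue). Dense blocks land along distinct axes while genes
    with no retained affinity collapse at the origin (they form a spurious
    dense candidate there, which the permutation test removes). Laplacian
    embeddings are unsuitable here: the sparsified graph is typically highly
    disconnected and two Laplacian eigenvectors cannot separate many
    components. Signs are fixed so each vector's largest-magnitude entry is
    positive.
    """
    A = np.maximum(affinity, 0.0)
    vals, vecs = linalg.eigh(A)
    order = np.argsort(vals)[::-1][:n_components]
    emb = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    for j in range(emb.shape[1]):
        k = np.argmax(np.abs(emb[:, j]))
        if emb[k, j] < 0:
            emb[:, j] = -emb[:, j]
    return emb


def _dbscan_eps(embedding: np.ndarray, min_samples: int) -> float:
    """Default DBSCAN radius: 5% of the embedding's bounding-box diagonal.

    Module blocks collapse to tight clusters separated by a large fraction
    of the embedding extent, while k-NN-distance knee rules are thrown off
    by the many exactly-coincident zero-affinity genes; an extent fraction
    is scale-free and robust to both. The permutation test downstream
    removes any spurious dense candidate this over-captures.
    """
    span = embedding.max(axis=0) - embedding.min(axis=0)
    diag = float(np.linalg.norm(span))
    if diag == 0:
        return 1e-6
    return 0.05 * diag


def embed_cluster_genes(
    sparse_corr: pd.DataFrame,
    seed: int = 0,
    embedding: str = "spectral",
    eps: float | None = None,
    min_samples: int = 5,
) -> dict[int, list[str]]:
    """2-D embedding of gene rows followed by DBSCAN into candidate modules.

    ``embedding`` is ``"spectral"`` (deterministic, default) or ``"umap"``.
    DBSCAN's ``eps`` defaults to the knee of the ``min_samples``-NN distance
    curve. Noise genes are left unassigned; module ids are re-indexed from 0.
    """
    if sparse_corr.shape[0] < 10:
        raise ValueError("need at least 10 genes to detect modules")
    A = sparse_corr.to_numpy(dtype=float)
    if embedding == "spectral":
        emb = _spectral_embedding(A)
    elif embedding == "umap":
        import umap

        emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(A)
    else:
        raise ValueError(f"unknown embedding {embedding!r}")
    if eps is None:
        eps = _dbscan_eps(emb, min_samples)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(emb)
    genes = np.asarray(sparse_corr.index)
    modules: dict[int, list[str]] = {}
    for new_id, lab in enumerate(sorted(set(labels) - {-1})):
        modules[new_id] = sorted(genes[labels == lab])
    return modules


@dataclass
class GeneModuleSet:
    """Significant gene modules with permutation statistics."""

    modules: dict[int, list[str]]
    mean_intra_corr: dict[int, float]
    perm_p: dict[int, float]
    fdr_p: dict[int, float]
    unassigned: list[str] = field(default_factory=list)


def _mean_intra(corr: np.ndarray, idx: np.ndarray) -> float:
    block = corr[np.ix_(idx, idx)]
    n = len(idx)
    return float((block.sum() - np.trace(block)) / (n * (n - 1)))


def test_modules(
    corr: pd.DataFrame,
    modules: dict[int, list[str]],
    n_perm: int = 1000,
    fdr_threshold: float = 0.1,
    seed: int = 0,
) -> GeneModuleSet:
    """Permutation test of candidate modules; keep those with FDR < 0.1.

    For each module the observed mean intra-module correlation is compared
    with the same statistic under ``n_perm`` random permutations of the
    module labels over all genes; ``p = (1 + #null >= obs) / (1 + n_perm)``,
    then BH-FDR across modules. Singleton modules are skipped.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    M = corr.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(corr.index)}
    tested = {m: gl for m, gl in modules.items() if len(gl) >= 2}
    obs = {m: _mean_intra(M, np.array([gene_pos[g] for g in gl])) for m, gl in tested.items()}

    all_genes = np.arange(len(corr.index))
    sizes = {m: len(gl) for m, gl in tested.items()}
    exceed = {m: 0 for m in tested}
    for _ in range(n_perm):
        perm = rng.permutation(all_genes)
        start = 0
        for m in tested:
            idx = perm[start : start + sizes[m]]
            start += sizes[m]
            if _mean_intra(M, idx) >= obs[m]:
                exceed[m] += 1
    pvals = {m: (1 + exceed[m]) / (1 + n_perm) for m in tested}
    mods = list(tested)
    fdr = (
        dict(zip(mods, multipletests([pvals[m] for m in mods], method="fdr_bh")[1]))
        if mods
        else {}
    )
    kept = {m: tested[m] for m in mods if fdr[m] < fdr_threshold}
    assigned = {g for gl in kept.values() for g in gl}
    return GeneModuleSet(
        modules=kept,
        mean_intra_corr={m: obs[m] for m in kept},
        perm_p={m: pvals[m] for m in kept},
        fdr_p={m: fdr[m] for m in kept},
        unassigned=sorted(set(corr.index) - assigned),
    )


def find_gene_modules(
    expr: pd.DataFrame,
    n_sv: int = 50,
    z_threshold: float = 0.1,
    n_perm: int = 1000,
    fdr_threshold: float = 0.1,
    seed: int = 0,
    embedding: str = "spectral",
    min_samples: int = 5,
) -> GeneModuleSet:
    """End-to-end module discovery from a Z-scored expression matrix."""
    corr = lowrank_gene_correlation(expr, n_sv=n_sv)
    sparse = sparsify_zscore(corr, threshold=z_threshold)
    candidates = embed_cluster_genes(
        sparse, seed=seed, embedding=embedding, min_samples=min_samples
    )
    return test_modules(
        corr, candidates, n_perm=n_perm, fdr_threshold=fdr_threshold, seed=seed
    )
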