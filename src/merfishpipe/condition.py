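"""Condition response: OLS differential expression and up-regulation classes.

Per gene, within one cell type, the Z-scored expression is modeled as
``y ~ C(condition) + intercept`` by ordinary least squares with the control
condition (-LPS, or juvenile for the age contrast) as the reference level.
The full model is compared with the intercept-only null by an F-test
(1 numerator df), and p-values are BH-FDR corrected across genes. The
coefficient of a two-group OLS is the difference of group means, which the
implementation exploits in closed form.

A gene is called up-regulated for a contrast iff its coefficient's Z-score
(standardized across genes within the cell type) exceeds 2 and its FDR
falls below 1e-4; the two contrasts combine into the categories
``both / lps / age / neither``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["condition_de_ols", "classify_genes", "condition_de_table"]


def condition_de_ols(
    expr: pd.DataFrame,
    condition_labels: pd.Series,
    reference: str,
) -> pd.DataFrame:
    """Two-group OLS DE for every gene; returns coef, p, fdr_p.

    ``expr`` is cells x genes (normalized, log-transformed, Z-scored
    values); ``condition_labels`` must contain exactly two levels including
    ``reference``. ``coef`` is the non-reference minus reference group mean.
    Degenerate genes (either group constant-free, i.e. fewer than 2 cells in
    a group) yield NA rather than crashing.
    """
    levels = pd.unique(condition_labels)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two condition levels, got {list(levels)}")
    if reference not in set(levels):
        raise ValueError(f"reference level {reference!r} not present")
    treat = (condition_labels != reference).to_numpy()
    X = expr.to_numpy(dtype=float)
    n1, n0 = int(treat.sum()), int((~treat).sum())
    n = n1 + n0
    if n1 < 2 or n0 < 2:
        coef = np.full(X.shape[1], np.nan)
        pvals = np.full(X.shape[1], np.nan)
    else:
        mean1 = X[treat].mean(axis=0)
        mean0 = X[~treat].mean(axis=0)
        coef = mean1 - mean0
        # pooled residual variance of the two-group OLS fit
        rss = ((X[treat] - mean1) ** 2).sum(axis=0) + ((X[~treat] - mean0) ** 2).sum(axis=0)
        sigma2 = rss / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = coef**2 / (sigma2 * (1.0 / n1 + 1.0 / n0))
        pvals = stats.f.sf(f, 1, n - 2)
        pvals = np.where(np.isfinite(pvals), pvals, np.nan)
    out = pd.DataFrame({"gene": expr.columns, "coef": coef, "p": pvals})
    ok = out["p"].notna()
    out["fdr_p"] = np.nan
    if ok.any():
        out.loc[ok, "fdr_p"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def _zscore_finite(values: np.ndarray) -> np.ndarray:
    finite = np.isfinite(values)
    mu = values[finite].mean() if finite.any() else np.nan
    sd = values[finite].std(ddof=0) if finite.any() else np.nan
    if not np.isfinite(sd) or sd == 0:
        return np.full_like(values, np.nan)
    return (values - mu) / sd


def condition_de_table(
    expr: pd.DataFrame,
    lps_labels: pd.Series,
    age_labels: pd.Series,
    cell_type_labels: pd.Series,
    lps_reference: str = "-LPS",
    age_reference: str = "juvenile",
) -> pd.DataFrame:
    """Both contrasts per cell type, with per-type coefficient Z-scores.

    The LPS contrast uses cells of the reference age only (both conditions);
    the age contrast uses untreated (reference-condition) cells only,
    mirroring how the two comparisons partition a crossed design. Returns a
    ConditionDETable with columns ``gene, cell_type, coef_lps, coef_age,
    p_lps, p_age, fdr_p_lps, fdr_p_age, z_lps, z_age``.
    """
    frames = []
    for ctype in sorted(pd.unique(cell_type_labels)):
        in_type = (cell_type_labels == ctype).to_numpy()
        lps_cells = in_type & (age_labels == age_reference).to_numpy()
        age_cells = in_type & (lps_labels == lps_reference).to_numpy()
        de_lps = condition_de_ols(expr.loc[lps_cells], lps_labels.loc[lps_cells], lps_reference)
        de_age = condition_de_ols(expr.loc[age_cells], age_labels.loc[age_cells], age_reference)
        merged = de_lps.merge(de_age, on="gene", suffixes=("_lps", "_age"))
        merged.insert(1, "cell_type", ctype)
        merged["z_lps"] = _zscore_finite(merged["coef_lps"].to_numpy(dtype=float))
        merged["z_age"] = _zscore_finite(merged["coef_age"].to_numpy(dtype=float))
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


def classify_genes(
    table: pd.DataFrame, z_threshold: float = 2.0, p_threshold: float = 1e-4
) -> pd.DataFrame:
    """Assign each (gene, cell type) row to both / lps / age / neither.

    Significance for a contrast requires a coefficient Z-score strictly
    above ``z_threshold`` and FDR strictly below ``p_threshold``. The four
    categories are exhaustive and mutually exclusive.
    """
    out = table.copy()
    sig_lps = (out["z_lps"] > z_threshold) & (out["fdr_p_lps"] < p_threshold)
    sig_age = (out["z_age"] > z_threshold) & (out["fdr_p_age"] < p_threshold)
    sig_lps = sig_lps.fillna(False)
    sig_age = sig_age.fillna(False)
    category = np.where(
        sig_lps & sig_age, "both", np.where(sig_lps, "lps", np.where(sig_age, "age", "neither"))
    )
    out["category"] = category
    return out
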