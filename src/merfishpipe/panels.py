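"""Gene-panel selection: age differential expression and cell-type markers.

Age DE fits, per gene and per cell population, a negative-binomial GLM with
log link on raw UMI counts::

    y_i ~ C(age) + log10(total_counts) + intercept

with the juvenile age as the reference level, against a reduced model
without the age term. A likelihood-ratio test (1 df chi-square) gives the
p-value; Benjamini-Hochberg FDR is applied across all genes in all
populations. The per-gene dispersion is estimated once by maximum
likelihood (method-of-moments fallback) and held fixed in both fits so the
test compares nested mean models.

The aging panel takes, among genes with FDR-adjusted p below 1e-6 and age
coefficient above 1.5, the top 5 per major cell type and top 2 per fine
cluster, sorted by coefficient.

Markers are found one-vs-rest by t-test with four acceptance criteria:
expressed in at least 40% of the population, FDR below 0.05, mean expression
at least 2-fold higher than outside, and expressed fraction at least 3x the
outside fraction. The marker panel greedily covers every population with at
least two markers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "age_de_nbglm",
    "select_aging_panel",
    "find_markers",
    "select_marker_panel",
]

_ALPHA_MIN, _ALPHA_MAX = 1e-6, 10.0


def _estimate_alpha(y: np.ndarray, X_reduced: np.ndarray) -> float:
    """Per-gene NB dispersion alpha (Var = mu + alpha*mu^2) by ML, MoM fallback."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.NegativeBinomial(y, X_reduced).fit(disp=0, maxiter=100)
        alpha = float(fit.params[-1])
        if not np.isfinite(alpha) or alpha <= 0:
            raise ValueError
    except Exception:
        mu = float(y.mean())
        var = float(y.var(ddof=1)) if len(y) > 1 else mu
        alpha = (var - mu) / mu**2 if mu > 0 else _ALPHA_MIN
    return float(np.clip(alpha, _ALPHA_MIN, _ALPHA_MAX))


def age_de_nbglm(
    counts: pd.DataFrame,
    age_labels: pd.Series,
    cluster_labels: pd.Series,
    total_counts: pd.Series | None = None,
    reference_age: str = "juvenile",
) -> pd.DataFrame:
    """NB-GLM age differential expression per gene per population.

    Returns a DETable DataFrame with columns ``gene, cluster, coef_age,
    lrt_p, fdr_p``. Genes identically zero within a population are excluded
    from that population's table; non-converging fits yield NA with a
    warning and are excluded from FDR.
    """
    ages = pd.unique(age_labels)
    if len(ages) != 2:
        raise ValueError(f"expected exactly two age levels, got {list(ages)}")
    if reference_age not in set(ages):
        raise ValueError(f"reference age {reference_age!r} not present")
    if total_counts is None:
        total_counts = counts.sum(axis=1)

    rows = []
    for cluster in sorted(pd.unique(cluster_labels)):
        in_cluster = (cluster_labels == cluster).to_numpy()
        sub = counts.loc[in_cluster]
        age_ind = (age_labels.loc[in_cluster] != reference_age).to_numpy(dtype=float)
        log_tc = np.log10(total_counts.loc[in_cluster].to_numpy(dtype=float))
        X_full = np.column_stack([np.ones(len(sub)), age_ind, log_tc])
        X_red = np.column_stack([np.ones(len(sub)), log_tc])
        for gene in sub.columns:
            y = sub[gene].to_numpy(dtype=float)
            if y.sum() == 0:
                continue
            alpha = _estimate_alpha(y, X_red)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    family = sm.families.NegativeBinomial(alpha=alpha)
                    full = sm.GLM(y, X_full, family=family).fit()
                    red = sm.GLM(y, X_red, family=family).fit()
                lrt = max(2.0 * (full.llf - red.llf), 0.0)
                p = float(stats.chi2.sf(lrt, df=1))
                coef = float(full.params[1])
                if not np.isfinite(coef) or not np.isfinite(p):
                    raise ValueError
            except Exception:
                warnings.warn(f"NB GLM did not converge for {gene!r} in {cluster!r}")
                coef, p = np.nan, np.nan
            rows.append((gene, cluster, coef, p))

    table = pd.DataFrame(rows, columns=["gene", "cluster", "coef_age", "lrt_p"])
    table["fdr_p"] = np.nan
    ok = table["lrt_p"].notna()
    if ok.any():
        table.loc[ok, "fdr_p"] = multipletests(table.loc[ok, "lrt_p"], method="fdr_bh")[1]
    return table


def select_aging_panel(
    de_major: pd.DataFrame,
    de_cluster: pd.DataFrame | None = None,
    n_per_major: int = 5,
    n_per_cluster: int = 2,
    coef_min: float = 1.5,
    fdr_max: float = 1e-6,
) -> list[str]:
    """Union of top age-upregulated genes per major type and per cluster.

    Only genes with ``fdr_p < fdr_max`` and ``coef_age > coef_min`` are
    eligible; within each population they are ranked by decreasing
    coefficient with lexicographic gene-name tie-breaking.
    """

    def _top(de: pd.DataFrame, n: int) -> set[str]:
        chosen: set[str] = set()
        passing = de[(de["fdr_p"] < fdr_max) & (de["coef_age"] > coef_min)]
        for _, grp in passing.groupby("cluster"):
            ranked = grp.sort_values(["coef_age", "gene"], ascending=[False, True])
            chosen.update(ranked["gene"].head(n))
        return chosen

    panel = _top(de_major, n_per_major)
    if de_cluster is not None:
        panel |= _top(de_cluster, n_per_cluster)
    return sorted(panel)


def find_markers(
    expr: pd.DataFrame,
    labels: pd.Series,
    min_frac_in: float = 0.4,
    fdr_max: float = 0.05,
    min_fold_change: float = 2.0,
    min_frac_ratio: float = 3.0,
    top_n: int = 15,
) -> pd.DataFrame:
    """One-vs-rest marker detection on a normalized expression matrix.

    ``expr`` holds linear-scale normalized expression; t-tests run on
    ``log1p(expr)``; fractions and fold changes use the linear values.
    Returns MarkerRecords as a DataFrame with columns ``gene, population,
    frac_in, frac_out, fold_change, fdr_p``, keeping per population the top
    ``top_n`` passing markers by fold change.
    """
    populations = sorted(pd.unique(labels))
    if len(populations) < 2:
        raise ValueError("need at least two populations for one-vs-rest markers")
    logx = np.log1p(expr.to_numpy(dtype=float))
    X = expr.to_numpy(dtype=float)
    records = []
    for pop in populations:
        mask = (labels == pop).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"population {pop!r} has <2 cells; skipped")
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(logx[mask], logx[~mask], equal_var=False)
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        frac_in = (X[mask] > 0).mean(axis=0)
        frac_out = (X[~mask] > 0).mean(axis=0)
        mean_in = X[mask].mean(axis=0)
        mean_out = X[~mask].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(mean_out > 0, mean_in / mean_out, np.inf)
            frac_ratio = np.where(frac_out > 0, frac_in / frac_out, np.inf)
        keep = (
            (frac_in >= min_frac_in)
            & (fdr < fdr_max)
            & (fc >= min_fold_change)
            & (frac_ratio >= min_frac_ratio)
        )
        pop_df = pd.DataFrame(
            {
                "gene": expr.columns[keep],
                "population": pop,
                "frac_in": frac_in[keep],
                "frac_out": frac_out[keep],
                "fold_change": fc[keep],
                "fdr_p": fdr[keep],
            }
        ).sort_values(["fold_change", "gene"], ascending=[False, True])
        records.append(pop_df.head(top_n))
    if not records:
        return pd.DataFrame(
            columns=["gene", "population", "frac_in", "frac_out", "fold_change", "fdr_p"]
        )
    return pd.concat(records, ignore_index=True)


def select_marker_panel(markers: pd.DataFrame, min_per_population: int = 2) -> list[str]:
    """Greedy marker panel covering every population with >= 2 genes.

    Populations are visited in sorted order; within a population candidate
    markers are taken by decreasing fold change. A gene already in the panel
    counts toward every population it marks.
    """
    panel: set[str] = set()
    for pop in sorted(pd.unique(markers["population"])) if len(markers) else []:
        pop_markers = markers[markers["population"] == pop].sort_values(
            ["fold_change", "gene"], ascending=[False, True]
        )
        n_covered = len(panel & set(pop_markers["gene"]))
        for gene in pop_markers["gene"]:
            if n_covered >= min_per_population:
                break
            if gene not in panel:
                panel.add(gene)
                n_covered += 1
        if n_covered < min_per_population:
            warnings.warn(
                f"population {pop!r} has only {n_covered} candidate markers"
            )
    return sorted(panel)
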