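"""Covariate selection against top principal components and weighted
least-squares residualization of expression.

Covariates are judged by their association with the top PCs of expression
(Pearson correlation for continuous covariates, one-way ANOVA for
categorical ones), Bonferroni-adjusted across PCs.  Collinear covariates are
handled greedily: the strongest covariate is regressed out of the
expression matrix, PCs are recomputed, and the test repeats until nothing
is significant — so a covariate that only mirrors an already-removed one is
never selected twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleTable
from .preprocess import PCAResult, pca_scores


@dataclass
class CovariateSelection:
    selected: list[str]
    association_log: list[pd.DataFrame] = field(default_factory=list)
    iterations: list[dict] = field(default_factory=list)


@dataclass
class ResidualMatrix:
    residuals: pd.DataFrame  # genes x samples
    design_terms: list[str]
    weighted: bool


def _is_numeric(series: pd.Series) -> bool:
    return series.dtype.kind in "ifu" and series.nunique() > 2


def design_matrix(sample_table: SampleTable | pd.DataFrame,
                  covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates; categorical covariates expanded to
    treatment-coded indicators (first level by sorted order is reference)."""
    df = sample_table.frame if isinstance(sample_table, SampleTable) else sample_table
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cov in covariates:
        series = df[cov]
        if series.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values; no imputation is done")
        if _is_numeric(series):
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(map(str, series.unique()))
            for level in levels[1:]:
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
    x = np.column_stack(cols)
    return x, names


def associate_covariates(pca: PCAResult, sample_table: SampleTable,
                         candidates: list[str], alpha: float = 0.05) -> pd.DataFrame:
    """p-value per (covariate, PC) plus each covariate's minimum
    Bonferroni-adjusted p across the PCs tested.

    Continuous covariates use a Pearson correlation test; categorical ones a
    one-way ANOVA of PC scores on levels.  Constant covariates are excluded
    with a warning.
    """
    df = sample_table.frame
    scores = pca.scores.to_numpy()
    n_pcs = scores.shape[1]
    rows = {}
    for cov in candidates:
        series = df[cov]
        if series.nunique() <= 1:
            warnings.warn(f"covariate {cov!r} is constant; excluded")
            continue
        pvals = np.ones(n_pcs)
        for j in range(n_pcs):
            pc = scores[:, j]
            if _is_numeric(series):
                _, pvals[j] = stats.pearsonr(series.to_numpy(dtype=float), pc)
            else:
                groups = [pc[(series == lev).to_numpy()] for lev in series.unique()]
                groups = [g for g in groups if len(g) > 0]
                with np.errstate(invalid="ignore"):
                    _, pvals[j] = stats.f_oneway(*groups)
                if not np.isfinite(pvals[j]):
                    pvals[j] = 1.0
        rows[cov] = pvals
    table = pd.DataFrame(rows, index=[f"PC{j + 1}" for j in range(n_pcs)]).T
    table["min_p_bonferroni"] = np.minimum(table.min(axis=1) * n_pcs, 1.0)
    return table


def residualize(expr: pd.DataFrame, sample_table: SampleTable | pd.DataFrame,
                covariates: list[str],
                weights: pd.DataFrame | None = None) -> ResidualMatrix:
    """Per-gene (weighted) least squares of expression on the covariate design;
    returns the residuals.  With weights, each gene is fit by WLS with its own
    per-observation weights."""
    x, names = design_matrix(sample_table, covariates)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"design with terms {names} is rank deficient")
    y = expr.to_numpy()
    if weights is None:
        # one hat matrix for all genes
        beta = np.linalg.solve(x.T @ x, x.T @ y.T)
        resid = y - (x @ beta).T
    else:
        w = weights.loc[expr.index, expr.columns].to_numpy()
        resid = np.empty_like(y)
        for g in range(y.shape[0]):
            xw = x * w[g][:, None]
            beta = np.linalg.solve(x.T @ xw, xw.T @ y[g])
            resid[g] = y[g] - x @ beta
    return ResidualMatrix(
        residuals=pd.DataFrame(resid, index=expr.index, columns=expr.columns),
        design_terms=names, weighted=weights is not None)


def select_covariates_sequential(
    expr: pd.DataFrame, sample_table: SampleTable, candidates: list[str],
    alpha: float = 0.05, max_iter: int = 10, n_pcs: int = 20,
    recompute_pcs: bool = True,
) -> CovariateSelection:
    """Greedy forward covariate selection: at each step, test all remaining
    candidates against the top PCs of the current residual matrix, add the
    one with the smallest Bonferroni-adjusted p if below ``alpha``, regress
    it out, and repeat.  Ties break lexicographically on covariate name."""
    selected: list[str] = []
    selection = CovariateSelection(selected=selected)
    pca = pca_scores(expr, n_components=n_pcs)
    for it in range(max_iter):
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        table = associate_covariates(pca, sample_table, remaining, alpha=alpha)
        selection.association_log.append(table)
        if table.empty:
            break
        adj = table["min_p_bonferroni"].sort_index()  # lexicographic tie-break
        best = adj.idxmin()
        best_p = float(adj.loc[best])
        selection.iterations.append({"iteration": it, "best": best, "p": best_p})
        if best_p >= alpha:
            break
        x, names = design_matrix(sample_table, selected + [best])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            selection.iterations[-1]["note"] = "rank deficient; stopped"
            break
        selected.append(best)
        if recompute_pcs:
            current = residualize(expr, sample_table, selected).residuals
            pca = pca_scores(current, n_components=n_pcs)
    return selection
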