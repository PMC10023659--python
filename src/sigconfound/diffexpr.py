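"""Per-gene two-group contrasts with optional empirical-Bayes variance
moderation, Benjamini-Hochberg adjustment, and cross-dataset t-statistic
concordance over one-to-one orthologs.

The contrast fit is a per-gene (weighted) least-squares regression of
expression on a two-level group indicator.  With moderation on, residual
variances are shrunk toward a common prior fitted by matching moments of
log residual variances to a scaled inverse-chi-square (equivalently scaled
F) prior, and the t-test degrees of freedom grow by the prior's; this is
the standard moderated-t construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import OrthologyMap, SampleTable


@dataclass
class DEResult:
    """Per-gene effect (log2 fold change), t, p and BH q for one contrast."""

    table: pd.DataFrame  # index gene; columns beta, se, t, df, p, q, mean_expression
    contrast: tuple[str, str, str]  # (column, test level, reference level)

    @property
    def betas(self) -> pd.Series:
        return self.table["beta"]

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p"]


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene residual variances.

    Fits the scaled inverse-chi-square prior (d0, s0^2) by matching the mean
    and variance of log(s2), then returns posterior variances
    ``(d0*s0^2 + df*s2) / (d0 + df)`` along with d0 and s0^2.  d0 may be inf
    (all variances pooled) when the observed spread is no wider than the
    sampling spread.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        d0 = 2 * _trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s02 = np.exp(emean)
        post = np.full_like(s2, s02)
    post[~ok] = s02 * (d0 / (d0 + df)) if np.isfinite(d0) else s02
    return post, float(d0), float(s02)


def fit_contrast(expr: pd.DataFrame, sample_table: SampleTable,
                 contrast: tuple[str, str, str],
                 weights: pd.DataFrame | None = None,
                 moderation: bool = True) -> DEResult:
    """Per-gene (weighted) least squares of expression on a two-level group
    indicator; two-sided p from the t distribution.

    ``contrast = (column, test_level, reference_level)``: beta is the mean
    difference test - reference on the (log2) expression scale.  Genes with
    zero residual variance get p = 0 when beta != 0 and p = 1 when beta = 0,
    and are flagged in the ``zero_variance`` column.
    """
    col, lev_test, lev_ref = contrast
    labels = sample_table.frame[col].astype(str)
    keep = labels.isin([lev_test, lev_ref]).to_numpy()
    n_test = int((labels == lev_test).sum())
    n_ref = int((labels == lev_ref).sum())
    if n_test < 2 or n_ref < 2:
        raise ValueError(
            f"contrast {contrast} needs >= 2 samples per level "
            f"(got {lev_test}: {n_test}, {lev_ref}: {n_ref})")
    sample_ids = list(sample_table.frame["sample_id"][keep])
    y = expr[sample_ids].to_numpy()
    g = (labels[keep] == lev_test).to_numpy(dtype=float)
    x = np.column_stack([np.ones(g.size), g])
    n = g.size
    df_resid = n - 2

    if weights is None:
        xtx_inv = np.linalg.inv(x.T @ x)
        beta_all = (xtx_inv @ (x.T @ y.T))  # 2 x genes
        fitted = (x @ beta_all).T
        resid = y - fitted
        s2 = (resid ** 2).sum(axis=1) / df_resid
        c = xtx_inv[1, 1]
        beta = beta_all[1]
        unit_var = np.full(y.shape[0], c)
    else:
        w = weights.loc[expr.index, sample_ids].to_numpy()
        beta = np.empty(y.shape[0])
        s2 = np.empty(y.shape[0])
        unit_var = np.empty(y.shape[0])
        for gi in range(y.shape[0]):
            xw = x * w[gi][:, None]
            xtx_inv = np.linalg.inv(x.T @ xw)
            b = xtx_inv @ (xw.T @ y[gi])
            r = y[gi] - x @ b
            beta[gi] = b[1]
            s2[gi] = (w[gi] * r ** 2).sum() / df_resid
            unit_var[gi] = xtx_inv[1, 1]

    # numerically-exact fits: squash roundoff-level residual variance and betas
    scale = np.maximum(np.abs(y).max(axis=1), 1.0)
    s2 = np.where(s2 < (1e-10 * scale) ** 2, 0.0, s2)
    beta = np.where(np.abs(beta) < 1e-10 * scale, 0.0, beta)

    if moderation:
        s2_post, d0, _ = moderate_variances(s2, df_resid)
        df_total = df_resid + d0 if np.isfinite(d0) else np.inf
    else:
        s2_post, df_total = s2, float(df_resid)

    se = np.sqrt(s2_post * unit_var)
    zero_var = s2_post <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, beta / np.where(se > 0, se, np.nan))
    if np.isfinite(df_total):
        p = 2 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2 * stats.norm.sf(np.abs(t))
    # zero-residual-variance convention: certain effect or certain null
    p = np.where(zero_var & (beta != 0), 0.0, p)
    p = np.where(zero_var & (beta == 0), 1.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var & (beta != 0), np.sign(beta) * np.inf, t)

    table = pd.DataFrame({
        "beta": beta, "se": se, "t": t,
        "df": np.full(y.shape[0], df_total),
        "p": p, "q": adjust_bh(p),
        "mean_expression": y.mean(axis=1),
        "zero_variance": zero_var,
    }, index=expr.index)
    return DEResult(table=table, contrast=contrast)


def subgroup_contrasts(expr: pd.DataFrame, sample_table: SampleTable,
                       column: str = "tox_group", reference: str = "none",
                       reference_diagnosis: str = "control",
                       weights: pd.DataFrame | None = None,
                       moderation: bool = True) -> dict[str, DEResult]:
    """One contrast per non-reference level found in ``column`` (each
    toxicology subgroup vs controls), with BH within each contrast."""
    levels = [l for l in sample_table.frame[column].astype(str).unique() if l != reference]
    out = {}
    for level in sorted(levels):
        out[level] = fit_contrast(expr, sample_table, (column, level, reference),
                                  weights=weights, moderation=moderation)
    return out


def cross_concordance(de_a: DEResult, de_b: DEResult,
                      orthology: OrthologyMap) -> tuple[float, float, int]:
    """Pearson r and Spearman rho of t-statistics over ortholog-matched genes."""
    a2b = orthology.a_to_b
    genes_a = [g for g in de_a.table.index if g in a2b and a2b[g] in de_b.table.index]
    if len(genes_a) < 3:
        raise ValueError(f"only {len(genes_a)} ortholog-matched genes; need >= 3")
    t_a = de_a.table.loc[genes_a, "t"].to_numpy()
    t_b = de_b.table.loc[[a2b[g] for g in genes_a], "t"].to_numpy()
    r = stats.pearsonr(t_a, t_b)[0]
    rho = stats.spearmanr(t_a, t_b)[0]
    return float(r), float(rho), len(genes_a)
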