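"""Gene filtering, TMM normalization, logCPM, precision weights, PCA and
sample-outlier detection.

The defaults mirror the analysis presets: genes kept at CPM > 1 in >= 50% of
samples (human preset) or in >= 3 samples (macaque preset); trimmed mean of
M-values (TMM) scale factors with the standard 30% / 5% trims; logCPM with a
0.5 pseudocount; PCA on gene-centered logCPM; outliers flagged at |z| > 5 on
at least two of the top 20 components (single pass, no re-fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix


@dataclass
class NormalizedExpression:
    """logCPM (log2 units) with the TMM factors and library sizes behind it."""

    logcpm: pd.DataFrame  # genes x samples
    tmm_factors: np.ndarray
    library_sizes: np.ndarray
    prior_count: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.logcpm.to_numpy())):
            raise ValueError("logCPM contains non-finite values")


@dataclass
class PCAResult:
    scores: pd.DataFrame      # samples x K
    loadings: pd.DataFrame    # genes x K
    explained_variance: np.ndarray  # fractions, non-increasing


def filter_genes(counts: CountMatrix, cpm_threshold: float = 1.0,
                 min_fraction: float | None = None,
                 min_samples: int | None = None) -> CountMatrix:
    """Keep genes with CPM > threshold (raw library sizes, no pseudocount) in
    at least ``min_fraction`` of samples or ``min_samples`` samples."""
    if (min_fraction is None) == (min_samples is None):
        raise ValueError("give exactly one of min_fraction / min_samples")
    lib = counts.library_sizes.astype(float)
    if np.any(lib <= 0):
        raise ValueError("samples with zero library size")
    cpm = counts.counts / lib[None, :] * 1e6
    n_pass = (cpm > cpm_threshold).sum(axis=1)
    if min_fraction is not None:
        required = int(np.ceil(min_fraction * counts.shape[1] - 1e-12))
    else:
        required = int(min_samples)
    keep = n_pass >= required
    if not keep.any():
        raise ValueError(
            f"all genes filtered at CPM > {cpm_threshold} in >= {required} samples; "
            "lower the threshold")
    return counts.subset_genes(keep)


def tmm_factors(counts: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05,
                ref_sample: str | None = None) -> np.ndarray:
    """TMM normalization factors (Robinson & Oshlack's trimmed mean of
    M-values): doubly-trimmed, precision-weighted mean of gene-wise log
    expression ratios against a reference sample, rescaled to geometric mean 1.

    The reference defaults to the sample whose 75th CPM percentile is closest
    to the mean of those percentiles across samples.
    """
    y = counts.counts.astype(float)
    lib = y.sum(axis=0)
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    f75 = np.quantile(y / lib[None, :], 0.75, axis=0)
    if ref_sample is None:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref = counts.sample_ids.index(ref_sample)

    factors = np.empty(counts.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for s in range(counts.shape[1]):
        ys, ns = y[:, s], lib[s]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(
                f"sample {counts.sample_ids[s]!r} shares no nonzero genes with the reference")
        ps, pr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        if np.max(np.abs(m)) < 1e-6:
            factors[s] = 1.0
            continue
        # double trim by rank, as in the published procedure
        n = m.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm, ra = rankdata(m), rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            factors[s] = 1.0
            continue
        factors[s] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(counts: CountMatrix, factors: np.ndarray | None = None,
            prior_count: float = 0.5) -> NormalizedExpression:
    """logCPM on TMM-effective library sizes:
    ``log2((count + prior) / (lib*factor + 2*prior) * 1e6)``."""
    lib = counts.library_sizes.astype(float)
    if factors is None:
        factors = tmm_factors(counts)
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("TMM factors must be positive")
    eff = lib * factors
    vals = np.log2((counts.counts + prior_count) / (eff + 2 * prior_count)[None, :] * 1e6)
    logcpm = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)
    return NormalizedExpression(logcpm, factors, lib.astype(np.int64), prior_count)


def pca_scores(expr: NormalizedExpression | pd.DataFrame, n_components: int = 20) -> PCAResult:
    """PCA of samples on gene-centered (not scaled) expression.

    Each component is oriented so its largest-magnitude gene loading is
    positive, making signs deterministic.
    """
    mat = expr.logcpm if isinstance(expr, NormalizedExpression) else expr
    x = mat.to_numpy().T  # samples x genes
    n, p = x.shape
    xc = x - x.mean(axis=0, keepdims=True)
    total_var = np.sum(xc ** 2)
    if total_var <= 0:
        raise ValueError("constant expression matrix: PCA undefined")
    k = min(n_components, n - 1, p)
    if k < n_components:
        warnings.warn(f"truncating PCA to {k} components (n={n}, p={p})")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|loading| positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=mat.columns, columns=cols),
        loadings=pd.DataFrame(vt.T, index=mat.index, columns=cols),
        explained_variance=s ** 2 / total_var,
    )


def detect_outliers(pca: PCAResult, sd_threshold: float = 5.0,
                    min_pcs: int = 2, top_k: int = 20) -> list[str]:
    """Samples whose standardized PC score exceeds ``sd_threshold`` SDs in
    ``min_pcs`` or more of the first ``top_k`` components.  Single pass."""
    scores = pca.scores.iloc[:, :top_k].to_numpy()
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.abs((scores - scores.mean(axis=0)) / sd)
    n_extreme = (z > sd_threshold).sum(axis=1)
    return [s for s, n in zip(pca.scores.index, n_extreme) if n >= min_pcs]


def voom_weights(counts: CountMatrix, factors: np.ndarray,
                 design: np.ndarray, span: float = 0.5,
                 prior_count: float = 0.5) -> pd.DataFrame:
    """Per-observation precision weights from the logCPM mean-variance trend.

    Per-gene linear models on logCPM give residual standard deviations; a
    lowess of sqrt(residual SD) on average log2 count is inverted at each
    observation's fitted log-count, and the weight is the predicted standard
    deviation to the power -4 (inverse predicted variance of logCPM).
    """
    if counts.shape[0] < 10:
        raise ValueError("voom trend unestimable with < 10 genes")
    design = np.asarray(design, dtype=float)
    n, k = design.shape
    if np.linalg.matrix_rank(design) < k:
        raise ValueError("design is rank deficient")
    lib = counts.library_sizes.astype(float) * np.asarray(factors, dtype=float)
    y = np.log2((counts.counts + prior_count) / (lib + 2 * prior_count)[None, :] * 1e6)

    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    fitted = (design @ coef).T  # genes x samples
    resid = y - fitted
    df_resid = n - k
    s2 = (resid ** 2).sum(axis=1) / df_resid
    sy = np.sqrt(np.sqrt(s2))  # quarter-root variance = sqrt of residual SD
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1)) - np.log2(1e6)

    ok = s2 > 0
    trend = lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # per-observation fitted log2 count, constant extrapolation beyond the trend
    lam = fitted + (np.log2(lib + 1) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(lam, tx, ty)
    w = np.clip(pred_sqrt_sd, 1e-6, None) ** -4.0
    w = np.clip(w, 1e-6, 1e6)
    return pd.DataFrame(w, index=counts.gene_ids, columns=counts.sample_ids)
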