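"""Per-sample disease-expression-signature score and non-parametric group
comparisons.

The signature aggregates differential expression per sample: each sample's
covariate-corrected logCPM residual vector is projected (dot product) onto
the case-control log fold changes over all genes with nominal p below a
threshold (default 0.05).  A higher score means expression deviating from
the cohort mean in the disease direction.  Group comparisons follow a
Shapiro-Wilk normality gate into Mann-Whitney U (two groups),
Kruskal-Wallis (several groups) and Dunn post-hoc tests with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult, adjust_bh


@dataclass
class SignatureScores:
    scores: pd.Series  # per sample
    n_genes_used: int
    beta_source: str


def signature_scores(residuals: pd.DataFrame,
                     de_result: DEResult | None = None,
                     external_betas: pd.DataFrame | None = None,
                     p_threshold: float = 0.05) -> SignatureScores:
    """score_s = sum over genes with p < threshold of residual[g, s] * beta_g.

    Betas come either from an internal contrast (:class:`DEResult`) or an
    external table with columns ``beta`` and ``p`` indexed by gene id
    (supports externally derived fold changes).
    """
    if (de_result is None) == (external_betas is None):
        raise ValueError("give exactly one of de_result / external_betas")
    if de_result is not None:
        table = de_result.table
        source = f"contrast {de_result.contrast}"
    else:
        table = external_betas
        source = "external betas"
        if not {"beta", "p"} <= set(table.columns):
            raise ValueError("external beta table needs columns 'beta' and 'p'")
    shared = residuals.index.intersection(table.index)
    table = table.loc[shared]
    passing = table.index[table["p"] < p_threshold]
    if len(passing) == 0:
        raise ValueError(
            f"no genes pass p < {p_threshold} among {len(shared)} shared genes")
    scores = residuals.loc[passing].T @ table.loc[passing, "beta"]
    return SignatureScores(scores=scores, n_genes_used=len(passing), beta_source=source)


def normality_gate(values) -> dict:
    """Shapiro-Wilk test; downstream comparisons go non-parametric when
    p < 0.05 (the branch this analysis takes)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk defined for 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant values: normality test undefined")
    stat, p = stats.shapiro(x)
    return {"shapiro_w": float(stat), "shapiro_p": float(p), "parametric_ok": p >= 0.05}


def _groups_to_arrays(values, groups) -> tuple[list[str], list[np.ndarray]]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(map(str, pd.unique(groups)))
    return names, [values[groups.astype(str) == g] for g in names]


def kruskal_wallis(values, groups) -> dict:
    """Kruskal-Wallis H with tie correction; all-tied data reports H = 0,
    p = 1 by convention."""
    names, arrays = _groups_to_arrays(values, groups)
    if len(names) < 2 or any(len(a) < 1 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    flat = np.concatenate(arrays)
    if flat.size < 3:
        raise ValueError("need total n >= 3")
    if np.ptp(flat) == 0:
        return {"test": "kruskal", "groups": names, "statistic": 0.0, "p": 1.0}
    stat, p = stats.kruskal(*arrays)
    return {"test": "kruskal", "groups": names, "statistic": float(stat), "p": float(p)}


def mann_whitney(x, y, exact_below: int = 20) -> dict:
    """Mann-Whitney U: exact enumeration when both groups are small
    (n <= ``exact_below``) and tie-free, else the normal approximation with
    tie and continuity corrections."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= exact_below and y.size <= exact_below and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    medx, medy = float(np.median(x)), float(np.median(y))
    return {"test": "mwu", "statistic": float(res.statistic), "p": float(res.pvalue),
            "method": method,
            "direction": "x>y" if medx > medy else ("x<y" if medx < medy else "x=y")}


def dunn_posthoc(values, groups, adjust: str = "bh") -> pd.DataFrame:
    """Dunn's post-hoc pairwise z tests on joint ranks after Kruskal-Wallis.

    z_ij = (meanrank_i - meanrank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided p; BH
    across all pairs (Bonferroni if ``adjust='bonferroni'``).
    """
    names, arrays = _groups_to_arrays(values, groups)
    if len(names) < 3:
        raise ValueError("Dunn post-hoc needs >= 3 groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    flat = np.concatenate(arrays)
    n_tot = flat.size
    ranks = stats.rankdata(flat)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + len(a)].mean())
        sizes.append(len(a))
        start += len(a)
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_tot - 1))
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term

    rows = []
    for i, j in combinations(range(len(names)), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var) if var > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_i": names[i], "group_j": names[j],
                     "z": float(z), "p": float(p)})
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["q"] = adjust_bh(out["p"].to_numpy())
    elif adjust == "bonferroni":
        out["q"] = np.minimum(out["p"] * len(out), 1.0)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def group_test_report(scores: pd.Series, sample_table, group_col: str = "tox_group",
                      diagnosis_col: str = "diagnosis") -> pd.DataFrame:
    """The full comparison battery for signature scores: normality gate,
    Kruskal-Wallis over all groups, Kruskal-Wallis within case subgroups,
    Mann-Whitney case vs control, and Dunn post-hoc over all groups."""
    df = sample_table.frame.loc[scores.index]
    vals = scores.to_numpy(dtype=float)
    groups = np.where(df[diagnosis_col] == "control", "control", df[group_col].astype(str))
    case_mask = (df[diagnosis_col] == "case").to_numpy()
    rows = []
    gate = normality_gate(vals)
    rows.append({"test": "shapiro", "groups": "all", "statistic": gate["shapiro_w"],
                 "p": gate["shapiro_p"]})
    kw_all = kruskal_wallis(vals, groups)
    rows.append({"test": "kruskal_all", "groups": "|".join(kw_all["groups"]),
                 "statistic": kw_all["statistic"], "p": kw_all["p"]})
    if np.unique(groups[case_mask]).size >= 2:
        kw_case = kruskal_wallis(vals[case_mask], groups[case_mask])
        rows.append({"test": "kruskal_within_cases", "groups": "|".join(kw_case["groups"]),
                     "statistic": kw_case["statistic"], "p": kw_case["p"]})
    mwu = mann_whitney(vals[case_mask], vals[~case_mask])
    rows.append({"test": "mwu_case_vs_control", "groups": "case|control",
                 "statistic": mwu["statistic"], "p": mwu["p"]})
    report = pd.DataFrame(rows)
    if np.unique(groups).size >= 3:
        dunn = dunn_posthoc(vals, groups)
        dunn.insert(0, "test", "dunn")
        report = pd.concat([report, dunn.rename(
            columns={"z": "statistic", "group_i": "groups"})], ignore_index=True)
    return report
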