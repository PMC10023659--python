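"""Reference-based cell-type deconvolution of bulk expression.

The estimator is deliberately transparent ("Bisque-like"): per-type CPM
profiles are averaged from a labeled single-cell/nucleus reference (after
configurable cluster merging and dropping), each bulk sample's CPM vector is
decomposed by non-negative least squares on the profile matrix and
renormalized to the unit simplex, and — when samples assayed in both bulk
and reference are available — a gene-wise linear moment matching of the bulk
distribution to the reference-composite distribution is applied first, the
same device the reference-based design uses to de-bias platform differences.
Group comparisons of proportions reuse the non-parametric battery
(Kruskal-Wallis, Mann-Whitney) with BH across cell types per test family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .diffexpr import adjust_bh
from .io import CountMatrix, SampleTable
from .signature import kruskal_wallis, mann_whitney


@dataclass
class CellTypeReference:
    """Cell x gene counts with a label per cell, plus merge/drop config."""

    counts: np.ndarray           # cells x genes
    gene_ids: list[str]
    cell_types: list[str]
    donor_ids: list[str] | None = None
    merge_map: dict[str, str] = field(default_factory=dict)   # old label -> new label
    drop_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.cell_types), len(self.gene_ids)):
            raise ValueError("reference counts shape does not match labels/genes")


@dataclass
class ProportionEstimates:
    proportions: pd.DataFrame  # samples x cell types, rows on the simplex
    residual_norm: pd.Series   # per-sample NNLS residual norm


def build_reference_profiles(reference: CellTypeReference) -> pd.DataFrame:
    """Cell-type x gene CPM profiles: apply merge_map, then drop_list, then
    average the CPM-normalized profile over cells of each (merged) type."""
    merged = [reference.merge_map.get(t, t) for t in reference.cell_types]
    dropped_sources = {t for t in reference.drop_list}
    for old, new in reference.merge_map.items():
        if old in dropped_sources and new not in dropped_sources:
            raise ValueError(f"merge target {new!r} mixes dropped type {old!r}")
    keep_types = sorted({t for t, raw in zip(merged, reference.cell_types)
                         if raw not in dropped_sources and t not in dropped_sources})
    if len(keep_types) < 2:
        raise ValueError("need >= 2 cell types after merge/drop")
    rows = {}
    for t in keep_types:
        mask = np.array([m == t and raw not in dropped_sources
                         for m, raw in zip(merged, reference.cell_types)])
        mean_counts = reference.counts[mask].mean(axis=0)
        total = mean_counts.sum()
        if total <= 0:
            raise ValueError(f"cell type {t!r} has all-zero mean profile")
        rows[t] = mean_counts / total * 1e6
    return pd.DataFrame(rows, index=reference.gene_ids).T


def _cpm(values: np.ndarray) -> np.ndarray:
    totals = values.sum(axis=0, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("all-zero bulk sample")
    return values / totals * 1e6


def estimate_proportions(bulk: CountMatrix | pd.DataFrame, profiles: pd.DataFrame,
                         overlap_bulk: pd.DataFrame | None = None,
                         overlap_reference: pd.DataFrame | None = None,
                         ) -> ProportionEstimates:
    """NNLS of each bulk CPM vector on the cell-type profiles, renormalized to
    the simplex.

    ``overlap_bulk`` / ``overlap_reference`` are genes x samples matrices for
    samples assayed on both platforms; when given, each gene's bulk values are
    shifted and scaled so their overlap-sample mean and SD match the
    reference-composite values before the NNLS (gene-wise moment matching).
    """
    if isinstance(bulk, CountMatrix):
        bulk_df = bulk.to_frame().astype(float)
    else:
        bulk_df = bulk.astype(float)
    genes = bulk_df.index.intersection(profiles.columns)
    if len(genes) < 10:
        raise ValueError(f"only {len(genes)} genes shared between bulk and reference")
    if profiles.shape[0] < 2:
        raise ValueError("need >= 2 cell-type profiles")
    x = _cpm(bulk_df.loc[genes].to_numpy())

    if overlap_bulk is not None:
        if overlap_reference is None:
            raise ValueError("overlap_reference required with overlap_bulk")
        shared = [s for s in overlap_bulk.columns if s in overlap_reference.columns]
        ob = _cpm(overlap_bulk.loc[genes, shared].to_numpy().astype(float))
        orf = _cpm(overlap_reference.loc[genes, shared].to_numpy().astype(float))
        mu_b, sd_b = ob.mean(axis=1), ob.std(axis=1)
        mu_r, sd_r = orf.mean(axis=1), orf.std(axis=1)
        scale = np.where(sd_b > 0, sd_r / np.where(sd_b > 0, sd_b, 1.0), 1.0)
        x = (x - mu_b[:, None]) * scale[:, None] + mu_r[:, None]
        x = np.clip(x, 0.0, None)

    a = profiles[genes].to_numpy().T  # genes x types
    props = np.zeros((x.shape[1], a.shape[1]))
    resid = np.zeros(x.shape[1])
    for s in range(x.shape[1]):
        coef, rnorm = nnls(a, x[:, s])
        total = coef.sum()
        if total <= 0:
            raise ValueError(f"NNLS returned all-zero coefficients for sample {s}")
        props[s] = coef / total
        resid[s] = rnorm
    sample_ids = list(bulk_df.columns)
    return ProportionEstimates(
        proportions=pd.DataFrame(props, index=sample_ids, columns=profiles.index),
        residual_norm=pd.Series(resid, index=sample_ids))


def compare_proportions(props: ProportionEstimates | pd.DataFrame,
                        sample_table: SampleTable,
                        group_col: str = "tox_group",
                        diagnosis_col: str = "diagnosis") -> pd.DataFrame:
    """Per cell type: Kruskal-Wallis over all groups, Kruskal-Wallis within
    case subgroups, Mann-Whitney case vs control; BH across cell types within
    each test family."""
    table = props.proportions if isinstance(props, ProportionEstimates) else props
    meta = sample_table.frame.loc[table.index]
    groups = np.where(meta[diagnosis_col] == "control", "control",
                      meta[group_col].astype(str))
    case_mask = (meta[diagnosis_col] == "case").to_numpy()
    rows = []
    for ct in table.columns:
        vals = table[ct].to_numpy(dtype=float)
        kw = kruskal_wallis(vals, groups)
        rows.append({"cell_type": ct, "test": "kruskal_all",
                     "statistic": kw["statistic"], "p": kw["p"]})
        if np.unique(groups[case_mask]).size >= 2:
            kw_c = kruskal_wallis(vals[case_mask], groups[case_mask])
            rows.append({"cell_type": ct, "test": "kruskal_within_cases",
                         "statistic": kw_c["statistic"], "p": kw_c["p"]})
        if case_mask.any() and (~case_mask).any():
            mwu = mann_whitney(vals[case_mask], vals[~case_mask])
            rows.append({"cell_type": ct, "test": "mwu_case_vs_control",
                         "statistic": mwu["statistic"], "p": mwu["p"]})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for fam, sub in out.groupby("test"):
        out.loc[sub.index, "q"] = adjust_bh(sub["p"].to_numpy())
    return out
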