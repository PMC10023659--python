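"""Two-dataset signed consensus co-expression networks.

Pipeline: signed adjacency a_ij = ((1 + cor_ij)/2)^beta with soft power 12,
topological overlap (TOM), quantile scaling of the second dataset's TOM to
the first, element-wise minimum (the consensus), average-linkage clustering
of 1 - consensus with a simplified two-level percentile tree cut, module
eigengenes (first PC of standardized member expression, sign-oriented),
consensus merging at eigengene correlation > 1 - mergeCutHeight in both
datasets, a kME >= 0.3 membership filter in both datasets, eigengene ~
condition association, and convergent/divergent classification of module
condition effects across the two datasets.

The tree cut is a deliberate simplification of dynamic hybrid cutting: the
dendrogram is cut at the 99th percentile of merge heights, and any resulting
cluster larger than three times the minimum module size is re-cut at its own
99th-percentile height (two levels of splitting in total).  The published
module parameters (minimum size 30, merge cut 0.25, minimum kME 0.3) are
honored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diffexpr import adjust_bh
from .io import SampleTable


@dataclass
class Network:
    adjacency: np.ndarray
    tom: np.ndarray | None
    beta_power: int
    gene_ids: list[str]


@dataclass
class ModuleAssignment:
    labels: pd.Series            # gene -> "M1".../"unassigned"
    kme_a: pd.DataFrame | None   # gene x module signed correlations
    kme_b: pd.DataFrame | None

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels[self.labels != "unassigned"].value_counts()


@dataclass
class EigengeneSet:
    eigengenes: pd.DataFrame     # modules x samples, unit variance
    explained: dict[str, float]  # PC1 variance fraction per module


def signed_adjacency(expr: pd.DataFrame, beta_power: int = 12) -> Network:
    """a_ij = ((1 + pearson(x_i, x_j)) / 2)^beta; diagonal 1."""
    x = expr.to_numpy()
    if x.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(expr.index, sd) if s == 0]
        raise ValueError(f"constant genes (undefined correlation): {bad[:10]}")
    cor = np.corrcoef(x)
    adj = ((1.0 + cor) / 2.0) ** beta_power
    np.fill_diagonal(adj, 1.0)
    return Network(adjacency=adj, tom=None, beta_power=beta_power, gene_ids=list(expr.index))


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    connectivities k excluding the diagonal and shared-neighbor sums over
    u != i, j; TOM_ii = 1."""
    a = np.asarray(adjacency, dtype=float)
    a_nd = a.copy()
    np.fill_diagonal(a_nd, 0.0)
    k = a_nd.sum(axis=1)
    shared = a_nd @ a_nd  # includes u = i or j only via zeroed diagonal -> excluded
    num = shared + a_nd
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a_nd
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def consensus_tom(tom_a: np.ndarray, tom_b: np.ndarray,
                  scale_quantile: float = 0.95) -> np.ndarray:
    """Scale tom_b so its ``scale_quantile`` of off-diagonal entries matches
    tom_a's, then take the element-wise minimum, clipped to [0, 1]."""
    if tom_a.shape != tom_b.shape:
        raise ValueError("TOM matrices must share the gene universe and order")
    off = ~np.eye(tom_a.shape[0], dtype=bool)
    qa = np.quantile(tom_a[off], scale_quantile)
    qb = np.quantile(tom_b[off], scale_quantile)
    scaled_b = tom_b * (qa / qb) if qb > 0 else tom_b
    cons = np.clip(np.minimum(tom_a, scaled_b), 0.0, 1.0)
    np.fill_diagonal(cons, 1.0)
    return cons


def _tree_cut(tom: np.ndarray, min_size: int, cohesion_ratio: float = 1.5) -> np.ndarray:
    """Recursive binary splitting of the average-linkage dendrogram of
    1 - TOM, the simplified stand-in for dynamic hybrid cutting.

    Each cluster is split in two; pieces smaller than the merge floor are
    peeled off (their genes may be rescued later by the kME stage).  A split
    is accepted only when it runs along a real cluster boundary: at least one
    piece must be markedly more cohesive internally than across the split
    (mean within-piece TOM > ``cohesion_ratio`` x mean cross-piece TOM) AND
    the cross-piece similarity must sit near the matrix-wide background level
    — the latter stops the recursion from shaving the high-connectivity core
    off a coherent module, the former stops it inside homogeneous background.
    """
    dissim = 1.0 - tom
    final: list[np.ndarray] = []
    min_piece = max(10, min_size // 3)  # fragments this small go to the kME rescue
    off = ~np.eye(tom.shape[0], dtype=bool)
    background_level = float(np.median(tom[off]))
    cross_cap = max(10.0 * background_level, 1e-12)

    def split(idx: np.ndarray) -> None:
        if len(idx) < 2 * min_piece:
            final.append(idx)
            return
        z = linkage(squareform(dissim[np.ix_(idx, idx)], checks=False), method="average")
        lab = fcluster(z, 2, criterion="maxclust")
        p1, p2 = idx[lab == 1], idx[lab == 2]
        if min(len(p1), len(p2)) == 0:
            final.append(idx)
            return

        def within(p: np.ndarray) -> float:
            if len(p) < 2:
                return 0.0
            m = tom[np.ix_(p, p)]
            return float(m[~np.eye(len(p), dtype=bool)].mean())

        cross = float(tom[np.ix_(p1, p2)].mean())
        separated = max(within(p1), within(p2)) > cohesion_ratio * max(cross, 1e-12)
        if not (separated and cross <= cross_cap):
            final.append(idx)
            return
        if min(len(p1), len(p2)) < min_piece:
            small, big = (p1, p2) if len(p1) < len(p2) else (p2, p1)
            final.append(small)
            split(big)
        else:
            split(p1)
            split(p2)

    split(np.arange(tom.shape[0]))
    out = np.zeros(tom.shape[0], dtype=int)
    for i, members in enumerate(final, 1):
        out[members] = i
    return out


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> EigengeneSet:
    """First principal component of each module's gene-standardized
    expression, scaled to unit variance and oriented so the mean correlation
    with member genes is non-negative.  Single-gene modules use the gene's
    standardized profile."""
    modules = [m for m in labels.unique() if m != "unassigned"]
    rows, explained = {}, {}
    for m in sorted(modules, key=str):
        genes = labels.index[labels == m]
        x = expr.loc[genes].to_numpy()
        sd = x.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        if len(genes) == 1:
            eig = z[0]
            explained[m] = 1.0
        else:
            u, s, vt = np.linalg.svd(z.T, full_matrices=False)
            eig = u[:, 0] * s[0]
            explained[m] = float(s[0] ** 2 / np.sum(s ** 2))
        eig = eig / eig.std(ddof=1)
        cors = np.array([stats.pearsonr(z[i], eig)[0] for i in range(z.shape[0])])
        if cors.mean() < 0:
            eig = -eig
        rows[m] = eig
    eigs = pd.DataFrame(rows, index=expr.columns).T
    return EigengeneSet(eigengenes=eigs, explained=explained)


def _kme(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Signed correlation of every gene with every module eigengene."""
    x = expr.to_numpy()
    xz = (x - x.mean(axis=1, keepdims=True))
    xn = np.sqrt((xz ** 2).sum(axis=1))
    e = eigengenes.to_numpy()
    ez = e - e.mean(axis=1, keepdims=True)
    en = np.sqrt((ez ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        kme = (xz @ ez.T) / np.outer(xn, en)
    return pd.DataFrame(np.nan_to_num(kme), index=expr.index, columns=eigengenes.index)


def detect_modules(cons_tom: np.ndarray, expr_a: pd.DataFrame, expr_b: pd.DataFrame,
                   min_size: int = 30, merge_cut: float = 0.25,
                   min_kme: float = 0.3) -> ModuleAssignment:
    """Consensus module detection on 1 - consensus TOM.

    Clusters below ``min_size`` go to "unassigned"; module pairs whose
    eigengenes correlate above 1 - ``merge_cut`` in BOTH datasets are merged
    iteratively; genes whose signed kME to their own module falls below
    ``min_kme`` in either dataset are unassigned; surviving modules are
    relabeled "M1", "M2", ... by decreasing size.
    """
    genes = list(expr_a.index)
    if cons_tom.shape[0] != len(genes):
        raise ValueError("consensus TOM does not match expression gene count")
    raw = _tree_cut(cons_tom, min_size)
    labels = pd.Series([f"c{v}" for v in raw], index=genes)
    # fragments below the merge floor go straight to "unassigned" (the kME
    # rescue can reclaim their genes); larger fragments — including halves of
    # over-split modules — enter eigengene merging before any size pruning
    merge_floor = max(10, min_size // 3)
    sizes = labels.value_counts()
    labels[labels.map(sizes) < merge_floor] = "unassigned"
    if (labels == "unassigned").all():
        import warnings
        warnings.warn("no module of minimum size survives; all genes unassigned")
        return ModuleAssignment(labels=labels, kme_a=None, kme_b=None)

    # iterative consensus merging: closest pair first, both datasets must agree
    def _eig(mod: str) -> tuple[np.ndarray, np.ndarray]:
        sub = labels.index[labels == mod]
        ea = module_eigengenes(expr_a.loc[sub], labels.loc[sub]).eigengenes.loc[mod]
        eb = module_eigengenes(expr_b.loc[sub], labels.loc[sub]).eigengenes.loc[mod]
        return ea.to_numpy(), eb.to_numpy()

    eigs = {m: _eig(m) for m in set(labels) - {"unassigned"}}
    while len(eigs) >= 2:
        mods = sorted(eigs)
        best, best_cor = None, 1.0 - merge_cut
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                ca = stats.pearsonr(eigs[mods[i]][0], eigs[mods[j]][0])[0]
                cb = stats.pearsonr(eigs[mods[i]][1], eigs[mods[j]][1])[0]
                consensus_cor = min(ca, cb)
                if consensus_cor > best_cor:
                    best, best_cor = (mods[i], mods[j]), consensus_cor
        if best is None:
            break
        labels[labels == best[1]] = best[0]
        del eigs[best[1]]
        eigs[best[0]] = _eig(best[0])

    # only merged clusters reaching the minimum module size survive
    sizes = labels.value_counts()
    labels[(labels != "unassigned") & (labels.map(sizes) < min_size)] = "unassigned"
    if (labels == "unassigned").all():
        import warnings
        warnings.warn("no module of minimum size survives; all genes unassigned")
        return ModuleAssignment(labels=labels, kme_a=None, kme_b=None)

    # kME stage: rescue unassigned genes whose consensus kME (minimum over the
    # two datasets) clears the bar for some module, then drop members that
    # fall below it in either dataset
    eig_a = module_eigengenes(expr_a, labels).eigengenes
    eig_b = module_eigengenes(expr_b, labels).eigengenes
    kme_a = _kme(expr_a, eig_a)
    kme_b = _kme(expr_b, eig_b)
    kme_cons = np.minimum(kme_a, kme_b)
    for g in labels.index[labels == "unassigned"]:
        best = kme_cons.loc[g].idxmax()
        if kme_cons.loc[g, best] >= min_kme:
            labels[g] = best
    for g in labels.index[labels != "unassigned"]:
        m = labels[g]
        if kme_a.loc[g, m] < min_kme or kme_b.loc[g, m] < min_kme:
            labels[g] = "unassigned"
    sizes = labels[labels != "unassigned"].value_counts()
    sizes = sizes[sizes >= min_size]
    rename = {old: f"M{i + 1}" for i, old in enumerate(sizes.index)}
    labels = labels.map(lambda v: rename.get(v, "unassigned"))
    if (labels == "unassigned").all():
        return ModuleAssignment(labels=labels, kme_a=None, kme_b=None)
    eig_a = module_eigengenes(expr_a, labels).eigengenes
    eig_b = module_eigengenes(expr_b, labels).eigengenes
    return ModuleAssignment(labels=labels, kme_a=_kme(expr_a, eig_a), kme_b=_kme(expr_b, eig_b))


def eigengene_association(eigengenes: pd.DataFrame, sample_table: SampleTable,
                          condition: str, reference: str | None = None) -> pd.DataFrame:
    """OLS of each module eigengene on each non-reference condition level
    (vs the reference level): two-sided t and p per coefficient, BH across
    modules within each level."""
    labels = sample_table.frame.loc[eigengenes.columns, condition].astype(str)
    levels = sorted(labels.unique())
    if reference is None:
        reference = "control" if "control" in levels else (
            "placebo" if "placebo" in levels else levels[0])
    rows = []
    for level in [l for l in levels if l != reference]:
        keep = labels.isin([level, reference]).to_numpy()
        if (labels == level).sum() < 2 or (labels == reference).sum() < 2:
            raise ValueError(f"level {level!r} or {reference!r} has < 2 samples")
        g = (labels[keep] == level).to_numpy(dtype=float)
        x = np.column_stack([np.ones(g.size), g])
        xtx_inv = np.linalg.inv(x.T @ x)
        df_resid = g.size - 2
        for m in eigengenes.index:
            y = eigengenes.loc[m].to_numpy()[keep]
            b = xtx_inv @ (x.T @ y)
            resid = y - x @ b
            s2 = (resid ** 2).sum() / df_resid
            se = np.sqrt(max(s2, 0.0) * xtx_inv[1, 1])
            if se > 0:
                t = b[1] / se
                p = 2 * stats.t.sf(abs(t), df_resid)
            else:  # noiseless eigengene = indicator
                t = np.sign(b[1]) * np.inf if b[1] != 0 else 0.0
                p = 0.0 if b[1] != 0 else 1.0
            rows.append({"module": m, "level": level, "reference": reference,
                         "beta": float(b[1]), "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = np.concatenate([
        adjust_bh(sub["p"].to_numpy()) for _, sub in out.groupby("level", sort=True)
    ]) if len(out) else []
    return out


def classify_convergence(assoc_a: pd.DataFrame, assoc_b: pd.DataFrame,
                         t_threshold: float = 2.0) -> pd.DataFrame:
    """Per module x (condition_a level, condition_b level): convergent when
    both |t| >= threshold with equal signs, divergent with opposite signs,
    otherwise indeterminate."""
    mods_a, mods_b = set(assoc_a["module"]), set(assoc_b["module"])
    if mods_a != mods_b:
        raise ValueError("association tables cover different module sets")
    rows = []
    for _, ra in assoc_a.iterrows():
        for _, rb in assoc_b[assoc_b["module"] == ra["module"]].iterrows():
            ta, tb = ra["t"], rb["t"]
            if abs(ta) >= t_threshold and abs(tb) >= t_threshold:
                cls = "convergent" if np.sign(ta) == np.sign(tb) else "divergent"
            else:
                cls = "indeterminate"
            rows.append({"module": ra["module"], "level_a": ra["level"],
                         "level_b": rb["level"], "t_a": ta, "t_b": tb,
                         "p_a": ra["p"], "p_b": rb["p"], "classification": cls})
    return pd.DataFrame(rows)
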