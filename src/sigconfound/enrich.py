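"""Fisher's exact test enrichment of gene lists against gene-set collections
and against a prioritized (GWAS-derived) gene list.

All tests condition on a declared background (all expressed genes; for
module enrichment, further restricted to one-to-one orthologs).  Two-sided p
comes from summing hypergeometric probabilities no larger than the observed
table's.  Sets overlapping the list in fewer than ``min_hits`` genes
(default 4, i.e. excluding <=3-hit terms) are removed before BH adjustment,
which runs within each gene list across its surviving sets.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh
from .io import GeneSetCollection


def fisher_enrichment(gene_list: Iterable[str], gene_set: Iterable[str],
                      background: Iterable[str]) -> dict:
    """One 2x2 Fisher's exact test of list membership vs set membership.

    Odds-ratio conventions: b*c = 0 with a*d > 0 gives +inf; a*d = 0 gives 0.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    lst = set(gene_list) & bg
    gs = set(gene_set) & bg
    a = len(lst & gs)
    b = len(lst - gs)
    c = len(gs - lst)
    d = len(bg) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if a * d == 0:
        odds = 0.0
    elif b * c == 0:
        odds = np.inf
    else:
        odds = (a * d) / (b * c)
    return {"a": a, "b": b, "c": c, "d": d, "n_hits": a,
            "odds_ratio": odds, "p": float(p)}


def enrich_collection(gene_lists: Mapping[str, Iterable[str]],
                      collection: GeneSetCollection,
                      background: Iterable[str],
                      min_hits: int = 4) -> pd.DataFrame:
    """Fisher's exact test of every (gene list, gene set) pair; sets with
    fewer than ``min_hits`` list hits are excluded before BH, which is applied
    within each gene list."""
    bg = set(background)
    frames = []
    for list_name, genes in gene_lists.items():
        rows = []
        for set_name, members in collection.sets.items():
            res = fisher_enrichment(genes, members, bg)
            if res["n_hits"] < min_hits:
                continue
            res.update({"gene_list": list_name, "gene_set": set_name})
            rows.append(res)
        if rows:
            sub = pd.DataFrame(rows)
            sub["q"] = adjust_bh(sub["p"].to_numpy())
            frames.append(sub)
    if not frames:
        import warnings
        warnings.warn("no gene set survives the minimum-hits filter")
        return pd.DataFrame(columns=["gene_list", "gene_set", "a", "b", "c", "d",
                                     "n_hits", "odds_ratio", "p", "q"])
    out = pd.concat(frames, ignore_index=True)
    cols = ["gene_list", "gene_set", "a", "b", "c", "d", "n_hits", "odds_ratio", "p", "q"]
    return out[cols]


def gwas_overlap(module_genes: Mapping[str, Iterable[str]],
                 prioritized_genes: Iterable[str],
                 background: Iterable[str]) -> pd.DataFrame:
    """Per-module Fisher's exact test of overlap with a prioritized gene list
    (e.g. GWAS fine-mapped genes), BH across modules."""
    prioritized = list(prioritized_genes)
    if not prioritized:
        raise ValueError("empty prioritized gene list")
    rows = []
    for module, genes in module_genes.items():
        res = fisher_enrichment(genes, prioritized, background)
        res["module"] = module
        rows.append(res)
    out = pd.DataFrame(rows)
    out["q"] = adjust_bh(out["p"].to_numpy())
    return out[["module", "a", "b", "c", "d", "n_hits", "odds_ratio", "p", "q"]]
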