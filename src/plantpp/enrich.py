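"""Profile-correlation co-evolution ranking and hypergeometric enrichment.

``profile_correlation`` ranks every gene by the Pearson correlation of its
NPP row with a designated anchor gene (Pearson is appropriate on Z-scored
profiles, whose correlation coefficients are close to normally
distributed) and returns the top percentile as the anchor's co-evolved
set.  ``hypergeom_enrich`` tests a gene set for over-represented flat
annotation terms with the upper-tail hypergeometric test and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "profile_correlation",
    "hypergeom_enrich",
    "read_annotations",
]


@dataclass
class CorrelationResult:
    """Per-gene Pearson correlation with one anchor gene's profile."""

    anchor: str
    r: pd.Series            # indexed by gene, includes the anchor (r = 1)
    top_set: list[str]      # top-fraction co-evolved genes, anchor excluded
    fraction: float

    def table(self) -> pd.DataFrame:
        others = self.r.drop(self.anchor)
        ranked = others.sort_index().sort_values(ascending=False, kind="stable")
        return pd.DataFrame({
            "r": ranked,
            "rank": np.arange(1, len(ranked) + 1),
            "in_top_set": [g in set(self.top_set) for g in ranked.index],
        })


def profile_correlation(
    npp_values: pd.DataFrame,
    anchor: str,
    fraction: float = 0.01,
) -> CorrelationResult:
    """Correlate every gene's profile with the anchor gene's profile.

    Requires at least 3 species columns and a non-constant anchor row.
    The top set holds ``floor(fraction * (n_genes - 1))`` genes (minimum
    1), ranked by r descending with lexicographic tie-break; genes with
    constant profiles get r = NaN and never enter the top set.
    """
    if anchor not in npp_values.index:
        raise KeyError(f"anchor gene {anchor!r} not in the matrix")
    if npp_values.shape[1] < 3:
        raise ValueError("profile correlation needs at least 3 species columns")
    X = npp_values.to_numpy(dtype=float)
    a = npp_values.loc[anchor].to_numpy(dtype=float)
    a_c = a - a.mean()
    a_ss = float(a_c @ a_c)
    if a_ss == 0.0:
        raise ValueError(f"anchor gene {anchor!r} has a constant profile")
    X_c = X - X.mean(axis=1, keepdims=True)
    row_ss = (X_c ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X_c @ a_c) / np.sqrt(row_ss * a_ss)
    r = pd.Series(r, index=npp_values.index, name="r")
    r[anchor] = 1.0

    others = r.drop(anchor).dropna()
    ranked = others.sort_index().sort_values(ascending=False, kind="stable")
    n_top = max(1, math.floor(fraction * (len(npp_values) - 1)))
    top_set = list(ranked.index[:n_top])
    return CorrelationResult(anchor=anchor, r=r, top_set=top_set, fraction=fraction)


def read_annotations(path: str | Path) -> dict[str, list[str]]:
    """Read a flat gene_id<TAB>term_id annotation file (multi-row per gene)."""
    table = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    out: dict[str, list[str]] = {}
    for gene, sub in table.groupby("gene", sort=False):
        out[gene] = list(dict.fromkeys(sub["term"]))
    return out


def hypergeom_enrich(
    query: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    For a term annotated to K of the N universe genes, with k of the n
    query genes carrying it, p = P(X >= k) under sampling n genes without
    replacement.  All terms present in the universe are tested and
    adjusted together by Benjamini-Hochberg; rows are sorted by p (term id
    breaks ties).  The universe defaults to all annotated genes.
    """
    if universe is None:
        universe = list(annotations)
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query_set = {g for g in query if g in universe_set}
    if not query_set:
        raise ValueError("query is empty after restriction to the universe")

    term_genes: dict[str, set[str]] = {}
    for gene in universe_set:
        for term in annotations.get(gene, ()):  # genes may lack annotations
            term_genes.setdefault(term, set()).add(gene)
    if not term_genes:
        raise ValueError("no annotated terms in the universe")

    N = len(universe_set)
    n = len(query_set)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        K = len(members)
        k = len(members & query_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "pvalue"])
    out["p_adj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out = out.sort_values(["pvalue", "term"], kind="stable").reset_index(drop=True)
    return out
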