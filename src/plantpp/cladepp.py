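"""Clade-wise co-evolution detection with Ward clustering and the MRS.

Genes that function together tend to be conserved or lost together, and
the signal is often local to one branch of the species tree.  Following
the CladePP strategy, NPP rows are clustered hierarchically (Ward's
minimum-variance criterion, Euclidean distance) once over all species
("ALL") and once per clade with enough species, the dendrograms are cut
into flat clusters at a multi-resolution grid of cluster counts, and each
gene is scored by the maximal ratio score (MRS): the highest query-gene
purity of any sufficiently large cluster containing it, maximized over
clades and cut levels.  MRS lies in [0, 1]; values near 1 mean the gene
tracks the query set's evolutionary trajectory in at least one clade.

The exact cluster-purity statistic is a reconstruction: the published
description fixes the name and the [0, 1] range but not the formula.  The
score used here for gene g in cluster C against query set Q is
``|C ∩ Q \\ {g}| / |C \\ {g}|`` for ``|C| >= min_cluster_size`` (else 0),
the simplest statistic with the stated range and "similarity to the query
genes" semantics.  See docs/methods.md.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage

__all__ = [
    "ALL_CLADE",
    "DEFAULT_CUT_GRID",
    "CladeMap",
    "QuerySet",
    "CladePP",
    "CladePPResults",
    "cluster_clade",
    "cut_grid",
    "mrs_scores",
    "select_candidates",
]

ALL_CLADE = "ALL"
DEFAULT_CUT_GRID = (10, 20, 50, 100, 200, 500)
#: Clades need more than this many species minus one (i.e. >= 10) to be
#: clustered separately.
CLADE_MIN_SPECIES = 10


class CladeMap:
    """Species -> clade assignment plus the pseudo-clade ``ALL``.

    Only clades with at least ``min_species`` members are clustered on
    their own; the ``ALL`` pseudo-clade (every species) is always
    eligible.
    """

    def __init__(self, mapping: Mapping[str, str], min_species: int = CLADE_MIN_SPECIES):
        if not mapping:
            raise ValueError("clade map is empty")
        self.mapping = dict(mapping)
        self.min_species = int(min_species)

    @classmethod
    def from_tsv(cls, path: str | Path, min_species: int = CLADE_MIN_SPECIES) -> "CladeMap":
        table = pd.read_csv(path, sep="\t", header=None, names=["species", "clade"],
                            dtype=str)
        return cls(dict(zip(table["species"], table["clade"])), min_species)

    @property
    def species(self) -> list[str]:
        return list(self.mapping)

    @property
    def clades(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def species_of(self, clade: str) -> list[str]:
        if clade == ALL_CLADE:
            return self.species
        return [s for s, c in self.mapping.items() if c == clade]

    @property
    def eligible_clades(self) -> list[str]:
        """``ALL`` first, then clades with >= min_species species."""
        sizes = pd.Series(self.mapping).value_counts()
        eligible = sorted(c for c in sizes.index if sizes[c] >= self.min_species)
        return [ALL_CLADE] + eligible


class QuerySet:
    """Gold-standard gene ids anchoring the co-evolution search."""

    def __init__(self, genes: Iterable[str], universe: Iterable[str] | None = None):
        genes = list(dict.fromkeys(genes))
        if not genes:
            raise ValueError("query set is empty")
        self.requested = genes
        if universe is not None:
            universe = set(universe)
            missing = [g for g in genes if g not in universe]
            if missing:
                warnings.warn(
                    f"{len(missing)} query gene(s) absent from the matrix "
                    f"and dropped: {missing[:5]}", stacklevel=2,
                )
            genes = [g for g in genes if g in universe]
            if not genes:
                raise ValueError("no query gene is present in the matrix")
        self.genes = genes

    @classmethod
    def from_file(cls, path: str | Path,
                  universe: Iterable[str] | None = None) -> "QuerySet":
        ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(ids, universe)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def cluster_clade(values: pd.DataFrame, species_subset: Sequence[str]) -> np.ndarray:
    """Ward-linkage dendrogram of gene rows restricted to a species subset.

    Returns the scipy linkage matrix (Euclidean distance, Ward criterion);
    deterministic given the input.
    """
    species_subset = list(species_subset)
    if not species_subset:
        raise ValueError("species subset is empty")
    if values.shape[0] < 2:
        raise ValueError("clustering needs at least 2 genes")
    sub = values[species_subset].to_numpy()
    return linkage(sub, method="ward")


def cut_grid(
    dendrogram: np.ndarray,
    n_genes: int,
    grid: Sequence[int] = DEFAULT_CUT_GRID,
) -> dict[int, np.ndarray]:
    """Flat cluster assignments at every cluster count k in the grid.

    The grid is intersected with [2, n_genes - 1]; each assignment is a
    partition of the genes into exactly k clusters.
    """
    ks = sorted(k for k in set(grid) if 2 <= k <= n_genes - 1)
    if not ks:
        raise ValueError("cut grid empty after intersection with [2, n_genes-1]")
    cuts = cut_tree(dendrogram, n_clusters=ks)
    return {k: cuts[:, i] for i, k in enumerate(ks)}


def _ratio_vector(labels: np.ndarray, is_query: np.ndarray,
                  min_cluster_size: int) -> np.ndarray:
    """Query-purity ratio for every gene under one flat assignment."""
    sizes = np.bincount(labels)
    q_counts = np.bincount(labels, weights=is_query)
    size_g = sizes[labels].astype(float)
    q_g = q_counts[labels] - is_query
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = q_g / (size_g - 1.0)
    ratio[size_g < min_cluster_size] = 0.0
    ratio[size_g <= 1] = 0.0
    return ratio


def mrs_scores(
    assignments: Mapping[str, Mapping[int, np.ndarray]],
    gene_ids: Sequence[str],
    query: QuerySet | Iterable[str],
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Maximal ratio score per gene over all clades and cut levels.

    ``assignments`` maps clade -> {k -> flat labels over ``gene_ids``}.
    Returns a table indexed by gene with columns ``mrs``, ``best_clade``,
    ``best_cut``, ``is_query`` and one ``ratio_<clade>`` column per clade
    (the clade-wise maximum).  Ties are resolved toward the first clade in
    mapping order and the smallest cut level.
    """
    if not assignments:
        raise ValueError("no clade assignments given")
    query_genes = set(query.genes if isinstance(query, QuerySet) else query)
    gene_ids = list(gene_ids)
    is_query = np.array([g in query_genes for g in gene_ids], dtype=float)
    if is_query.sum() == 0:
        raise ValueError("query set does not intersect the gene set")

    n = len(gene_ids)
    mrs = np.zeros(n)
    best_clade = np.array([""] * n, dtype=object)
    best_cut = np.zeros(n, dtype=int)
    clade_best: dict[str, np.ndarray] = {}
    for clade, cuts in assignments.items():
        cmax = np.zeros(n)
        for k in sorted(cuts):
            labels = np.asarray(cuts[k]).ravel()
            if labels.shape[0] != n:
                raise ValueError(f"assignment for clade {clade!r} k={k} has wrong length")
            ratio = _ratio_vector(labels, is_query, min_cluster_size)
            better = ratio > mrs
            mrs[better] = ratio[better]
            best_clade[better] = clade
            best_cut[better] = k
            cmax = np.maximum(cmax, ratio)
        clade_best[clade] = cmax

    out = pd.DataFrame({
        "mrs": mrs,
        "best_clade": best_clade,
        "best_cut": best_cut,
        "is_query": is_query.astype(bool),
    }, index=pd.Index(gene_ids, name="gene"))
    for clade, cmax in clade_best.items():
        out[f"ratio_{clade}"] = cmax
    return out


def select_candidates(
    mrs_table: pd.DataFrame,
    fraction: float = 0.01,
    query: Iterable[str] = (),
) -> pd.DataFrame:
    """Top-fraction genes by MRS, the co-evolution candidates.

    Genes are ranked by MRS descending with lexicographic gene-id
    tie-break; query genes keep their rank but are excluded from the
    returned list.  The list holds the top ``floor(fraction * n_genes)``
    non-query genes (minimum 1).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    query = set(query)
    ranked = mrs_table.sort_index().sort_values("mrs", ascending=False, kind="stable")
    ranked = ranked.assign(rank=np.arange(1, len(ranked) + 1))
    n_cand = max(1, math.floor(fraction * len(ranked)))
    non_query = ranked.loc[[g not in query for g in ranked.index]]
    return non_query.head(n_cand)


class CladePP:
    """Co-evolution screening model over an NPP matrix.

    Parameters
    ----------
    npp
        NPP values (genes x species DataFrame) or an ``NPPMatrix``.
    clade_map
        ``CladeMap`` or plain species -> clade mapping.
    query
        Gold-standard gene ids (``QuerySet``, iterable, or path handled by
        ``QuerySet.from_file`` upstream).
    grid, min_cluster_size, top_fraction
        Cut-level grid, smallest cluster allowed to score, and candidate
        fraction (defaults 10..500, 3, 1%).
    """

    def __init__(
        self,
        npp,
        clade_map: CladeMap | Mapping[str, str],
        query: QuerySet | Iterable[str],
        grid: Sequence[int] = DEFAULT_CUT_GRID,
        min_cluster_size: int = 3,
        top_fraction: float = 0.01,
    ):
        self.values: pd.DataFrame = getattr(npp, "values", npp)
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("npp must be a DataFrame or NPPMatrix")
        if not isinstance(clade_map, CladeMap):
            clade_map = CladeMap(clade_map)
        self.clade_map = clade_map
        if not isinstance(query, QuerySet):
            query = QuerySet(query, universe=self.values.index)
        else:
            query = QuerySet(query.genes, universe=self.values.index)
        self.query = query
        self.grid = tuple(grid)
        self.min_cluster_size = int(min_cluster_size)
        self.top_fraction = float(top_fraction)

    def fit(self) -> "CladePPResults":
        """Cluster every eligible clade, cut, and score all genes."""
        known = set(self.values.columns)
        assignments: dict[str, dict[int, np.ndarray]] = {}
        dendrograms: dict[str, np.ndarray] = {}
        for clade in self.clade_map.eligible_clades:
            subset = [s for s in self.clade_map.species_of(clade) if s in known]
            if not subset:
                warnings.warn(f"clade {clade!r} has no species in the matrix; skipped",
                              stacklevel=2)
                continue
            Z = cluster_clade(self.values, subset)
            dendrograms[clade] = Z
            assignments[clade] = cut_grid(Z, self.values.shape[0], self.grid)
        table = mrs_scores(assignments, list(self.values.index), self.query,
                           self.min_cluster_size)
        return CladePPResults(self, table, dendrograms)


@dataclass
class CladePPResults:
    """Fitted co-evolution screen: MRS table, candidates, dendrograms."""

    model: CladePP
    mrs_table: pd.DataFrame
    dendrograms: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def candidates(self, fraction: float | None = None) -> pd.DataFrame:
        if fraction is None:
            fraction = self.model.top_fraction
        return select_candidates(self.mrs_table, fraction, self.model.query.genes)

    def summary(self, top: int = 10) -> str:
        cand = self.candidates()
        lines = [
            "CladePP co-evolution screen",
            "===========================",
            f"genes scored:      {len(self.mrs_table)}",
            f"query genes used:  {len(self.model.query)}",
            f"clades clustered:  {', '.join(self.dendrograms)}",
            f"cut grid:          {list(self.model.grid)}",
            f"candidates (top {self.model.top_fraction:.1%}): {len(cand)}",
            "",
            f"top {min(top, len(cand))} candidates:",
            cand.head(top)[["mrs", "best_clade", "best_cut", "rank"]].to_string(),
        ]
        return "\n".join(lines)

    def to_tsv(self, mrs_path: str | Path, candidates_path: str | Path | None = None) -> None:
        self.mrs_table.to_csv(mrs_path, sep="\t")
        if candidates_path is not None:
            self.candidates().to_csv(candidates_path, sep="\t")
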