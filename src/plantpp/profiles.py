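"""Normalized phylogenetic profile (NPP) matrices from best-hit bit-scores.

A phylogenetic profile records, for each gene of a reference proteome, the
best BLASTP/DIAMOND bit-score against every other proteome in a species
panel.  Raw bit-scores are length-dependent, so each row is normalized by
the gene's self-alignment score (LPP = BS / BS_self); species differ in
phylogenetic distance from the reference, so each column is then Z-scored
(NPP).  Genes whose profiles are uninformative are removed first:

1. proteins shorter than ``MIN_LENGTH`` (40 aa) are dropped;
2. proteins whose self-alignment score is <= ``MIN_SELF_SCORE`` (80 bits)
   are dropped;
3. every score below the noise floor ``SCORE_FLOOR`` (24.6 bits, the
   bit-score of an E-value of 0.05) — including absent hits — is set to
   the floor;
4. proteins with a score above the floor in fewer than
   ``MIN_OTHER_SPECIES`` (5) non-reference proteomes are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "MIN_LENGTH",
    "MIN_SELF_SCORE",
    "SCORE_FLOOR",
    "MIN_OTHER_SPECIES",
    "BitScoreMatrix",
    "NPPMatrix",
    "read_proteome_lengths",
    "read_hit_table",
    "read_combined_hits",
    "best_hit_matrix",
    "filter_and_floor",
    "normalize_lpp",
    "zscore_columns",
    "build_npp",
    "write_npp_tsv",
    "read_npp_tsv",
]

MIN_LENGTH = 40
MIN_SELF_SCORE = 80.0
SCORE_FLOOR = 24.6
MIN_OTHER_SPECIES = 5

#: BLAST tabular (outfmt 6) column names.
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class BitScoreMatrix:
    """Genes x species best-hit bit-scores plus per-gene self-scores.

    ``scores`` holds NaN for species where a gene has no hit (absent hits
    are encoded by omission in BLAST tabular output).  ``lengths`` may be
    None when no proteome FASTA was supplied.
    """

    scores: pd.DataFrame
    self_scores: pd.Series
    lengths: pd.Series | None = None
    filter_report: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.scores.columns)

    def copy(self) -> "BitScoreMatrix":
        return BitScoreMatrix(
            self.scores.copy(),
            self.self_scores.copy(),
            None if self.lengths is None else self.lengths.copy(),
            None if self.filter_report is None else self.filter_report.copy(),
        )


@dataclass
class NPPMatrix:
    """Column-standardized profile matrix.

    ``values[i, j]`` is the Z-score of gene i's normalized bit-score in
    species j; ``column_stats`` stores the per-species mean ``mu`` and
    sample standard deviation ``sigma`` used for the transform.  Columns
    with zero spread are set to all-zeros and listed in ``degenerate``.
    """

    values: pd.DataFrame
    column_stats: pd.DataFrame
    degenerate: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.columns)


def read_proteome_lengths(fasta: str | Path) -> dict[str, int]:
    """Map each FASTA record id to its residue count.

    Raises ``ValueError`` naming the id on duplicate headers; an empty
    file yields an empty map.
    """
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(fasta), "fasta"):
        if record.id in lengths:
            raise ValueError(f"duplicate FASTA id: {record.id!r}")
        lengths[record.id] = len(record.seq)
    return lengths


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Parse a BLAST/DIAMOND tabular hit file.

    Accepts plain outfmt-6 (12 columns), a minimal 3-column layout
    (qseqid, sseqid, bitscore) or a combined file with one extra leading
    species column (13 columns).  The dialect is auto-detected from the
    column count.  Returns columns ``species`` (may be absent), ``qseqid``,
    ``sseqid``, ``bitscore``.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["qseqid", "sseqid", "bitscore"])
    ncol = raw.shape[1]
    if ncol == 12:
        out = raw.iloc[:, [0, 1, 11]].copy()
        out.columns = ["qseqid", "sseqid", "bitscore"]
    elif ncol == 13:
        out = raw.iloc[:, [0, 1, 2, 12]].copy()
        out.columns = ["species", "qseqid", "sseqid", "bitscore"]
    elif ncol == 3:
        out = raw.copy()
        out.columns = ["qseqid", "sseqid", "bitscore"]
    else:
        raise ValueError(
            f"{path}: expected 3, 12 or 13 tab-separated columns, found {ncol}"
        )
    scores = pd.to_numeric(out["bitscore"], errors="coerce")
    if scores.isna().any():
        bad = int(scores.index[scores.isna()][0]) + 1
        raise ValueError(f"{path}: malformed bit-score on line {bad}")
    out["bitscore"] = scores.astype(float)
    return out


def read_combined_hits(path: str | Path) -> dict[str, pd.DataFrame]:
    """Split a combined hit file (leading species column) per species."""
    table = read_hit_table(path)
    if "species" not in table.columns:
        raise ValueError(f"{path}: no species column; not a combined hit file")
    return {sp: df.drop(columns="species") for sp, df in table.groupby("species")}


def best_hit_matrix(
    hit_files: Mapping[str, str | Path],
    reference: str,
    gene_ids: Sequence[str] | None = None,
    species_ids: Sequence[str] | None = None,
) -> BitScoreMatrix:
    """Assemble the best-hit bit-score matrix from per-species hit files.

    Parameters
    ----------
    hit_files
        Mapping species id -> tabular hit file.  Must contain ``reference``;
        self alignments there (``qseqid == sseqid``) provide the per-gene
        self-scores.  The reference species is not a matrix column.
    gene_ids, species_ids
        Optional explicit row/column orders.  Defaults: sorted union of
        query ids across files / sorted non-reference species.

    Entry (i, j) is the maximum bit-score of gene i among its hits in
    proteome j; genes with no hit in a proteome are NaN (absent).
    """
    if reference not in hit_files:
        raise ValueError(f"reference species {reference!r} has no hit file")
    tables: dict[str, pd.DataFrame] = {}
    for sp, path in hit_files.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"hit file for species {sp!r} missing: {path}")
        tables[sp] = read_hit_table(path)

    if species_ids is None:
        species_ids = sorted(sp for sp in hit_files if sp != reference)
    if gene_ids is None:
        seen: set[str] = set()
        for tab in tables.values():
            seen.update(tab["qseqid"])
        gene_ids = sorted(seen)

    scores = pd.DataFrame(np.nan, index=list(gene_ids), columns=list(species_ids))
    for sp in species_ids:
        best = tables[sp].groupby("qseqid")["bitscore"].max()
        best = best.reindex(scores.index)
        scores[sp] = best

    ref = tables[reference]
    self_rows = ref[ref["qseqid"] == ref["sseqid"]]
    self_scores = (
        self_rows.groupby("qseqid")["bitscore"].max().reindex(scores.index)
    )
    self_scores.name = "self_score"
    return BitScoreMatrix(scores=scores, self_scores=self_scores)


def filter_and_floor(
    matrix: BitScoreMatrix,
    min_length: int = MIN_LENGTH,
    min_self_score: float = MIN_SELF_SCORE,
    floor: float = SCORE_FLOOR,
    min_other_species: int = MIN_OTHER_SPECIES,
) -> BitScoreMatrix:
    """Apply the four profile filters in order and floor the matrix.

    1. drop genes shorter than ``min_length`` residues (skipped when the
       matrix carries no lengths);
    2. drop genes with self-score <= ``min_self_score`` (or missing);
    3. set every score < ``floor`` and every absent entry to ``floor``;
    4. drop genes with a score > ``floor`` in fewer than
       ``min_other_species`` non-reference proteomes.

    The returned matrix carries a ``filter_report`` table
    (gene, rule_removed_by).  Idempotent; may return an empty matrix.
    """
    report: list[tuple[str, str]] = []
    m = matrix.copy()

    if m.lengths is not None:
        short = m.lengths.reindex(m.scores.index).fillna(0) < min_length
        report += [(g, "min_length") for g in m.scores.index[short]]
        m.scores = m.scores.loc[~short.values]

    self_scores = m.self_scores.reindex(m.scores.index)
    weak = ~(self_scores > min_self_score)  # NaN self-score also fails
    report += [(g, "self_score") for g in m.scores.index[weak.values]]
    m.scores = m.scores.loc[~weak.values]

    m.scores = m.scores.fillna(floor).clip(lower=floor)

    support = (m.scores > floor).sum(axis=1)
    sparse = support < min_other_species
    report += [(g, "min_other_species") for g in m.scores.index[sparse.values]]
    m.scores = m.scores.loc[~sparse.values]

    m.self_scores = matrix.self_scores.reindex(m.scores.index)
    if matrix.lengths is not None:
        m.lengths = matrix.lengths.reindex(m.scores.index)
    m.filter_report = pd.DataFrame(report, columns=["gene", "rule_removed_by"])
    return m


def normalize_lpp(matrix: BitScoreMatrix) -> pd.DataFrame:
    """Divide each row by the gene's self-alignment score (LPP matrix)."""
    self_scores = matrix.self_scores.reindex(matrix.scores.index)
    bad = self_scores.isna() | (self_scores <= 0)
    if bad.any():
        gene = matrix.scores.index[bad.values][0]
        raise ValueError(f"gene {gene!r} has zero or missing self-score")
    return matrix.scores.div(self_scores, axis=0)


def zscore_columns(lpp: pd.DataFrame) -> NPPMatrix:
    """Z-score each species column of the LPP matrix (sample sd, n-1).

    Degenerate columns (zero spread) become all-zeros and are flagged with
    a warning rather than removed, so column indices stay aligned with the
    clade map.  A single-row matrix is an error (sd undefined).
    """
    if lpp.shape[0] < 2:
        raise ValueError("Z-scoring needs at least 2 retained genes")
    mu = lpp.mean(axis=0)
    sigma = lpp.std(axis=0, ddof=1)
    degenerate = list(sigma.index[sigma == 0.0])
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} constant column(s) set to zero: {degenerate[:5]}",
            stacklevel=2,
        )
    safe_sigma = sigma.replace(0.0, 1.0)
    values = lpp.sub(mu, axis=1).div(safe_sigma, axis=1)
    values[degenerate] = 0.0
    stats = pd.DataFrame({"mu": mu, "sigma": sigma})
    return NPPMatrix(values=values, column_stats=stats, degenerate=degenerate)


def build_npp(
    hit_files: Mapping[str, str | Path],
    reference: str,
    fasta: str | Path | None = None,
    species_ids: Sequence[str] | None = None,
    min_length: int = MIN_LENGTH,
    min_self_score: float = MIN_SELF_SCORE,
    floor: float = SCORE_FLOOR,
    min_other_species: int = MIN_OTHER_SPECIES,
) -> tuple[NPPMatrix, BitScoreMatrix]:
    """Full BS -> LPP -> NPP pipeline from files.

    When ``fasta`` is given its record ids define the gene universe and the
    length filter is active.  Returns the NPP matrix and the filtered
    bit-score matrix (whose ``filter_report`` audits the removals).
    """
    gene_ids = None
    lengths = None
    if fasta is not None:
        length_map = read_proteome_lengths(fasta)
        gene_ids = sorted(length_map)
        lengths = pd.Series(length_map, name="length")
    bs = best_hit_matrix(hit_files, reference, gene_ids=gene_ids, species_ids=species_ids)
    bs.lengths = lengths
    filtered = filter_and_floor(
        bs,
        min_length=min_length,
        min_self_score=min_self_score,
        floor=floor,
        min_other_species=min_other_species,
    )
    npp = zscore_columns(normalize_lpp(filtered))
    return npp, filtered


def write_npp_tsv(npp: NPPMatrix, path: str | Path) -> None:
    """Write the NPP values as TSV (gzip when the name ends in .gz)."""
    npp.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_npp_tsv(path: str | Path) -> NPPMatrix:
    """Read an NPP values TSV; column stats are recomputed descriptively."""
    values = pd.read_csv(path, sep="\t", index_col="gene")
    stats = pd.DataFrame({"mu": values.mean(axis=0), "sigma": values.std(axis=0, ddof=1)})
    degenerate = [c for c in values.columns if values[c].nunique() <= 1]
    return NPPMatrix(values=values, column_stats=stats, degenerate=degenerate)
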