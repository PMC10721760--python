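"""Clade-structured synthetic bit-score data with planted co-evolving modules.

The generator emulates the statistical structure a phylogenetic-profiling
pipeline exploits: functionally related genes are conserved (or lost) in
tandem across genome panels, and that conservation is clade-blocked — a
module of co-evolving genes shares one latent conservation level per clade,
with independent species-level noise on top.  Background genes draw their
own independent clade profiles.  Latent conservation in [0, 1] is mapped
affinely onto bit-scores between the 24.6-bit noise floor and each gene's
self-alignment score, and a configurable fraction of hits is deleted to
emulate missing best hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import SCORE_FLOOR, OUTFMT6_COLUMNS, BitScoreMatrix

__all__ = ["SimulationSpec", "SyntheticDataset", "simulate_dataset", "write_fixtures"]

#: Species id used for the reference proteome's self-alignment hit file.
REFERENCE_SPECIES = "REF"


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the benchmark condition used throughout: 2,000 genes
    over 4 clades of 12 species, one 20-gene co-evolving module of signal
    strength 0.9, moderate species-level noise and 5% missing hits.

    ``modules`` is a sequence of (module_size, signal_strength) pairs;
    signal 1 means module rows share the latent profile exactly, 0 means
    module membership adds nothing over background noise.
    """

    n_genes: int = 2000
    clade_sizes: tuple[int, ...] = (12, 12, 12, 12)
    modules: tuple[tuple[int, float], ...] = ((20, 0.9),)
    background_noise_sd: float = 0.25
    missing_rate: float = 0.05
    self_score_range: tuple[float, float] = (200.0, 1000.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.clade_sizes or any(s < 1 for s in self.clade_sizes):
            raise ValueError("clade_sizes must all be >= 1")
        total_module = sum(size for size, _ in self.modules)
        if total_module > self.n_genes:
            raise ValueError("modules: total module size exceeds n_genes")
        for size, signal in self.modules:
            if size < 1:
                raise ValueError("modules: module_size must be >= 1")
            if not 0.0 <= signal <= 1.0:
                raise ValueError("modules: signal_strength must be in [0, 1]")
        if self.background_noise_sd <= 0:
            raise ValueError("background_noise_sd must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.self_score_range
        if not (lo > 80 and hi > 80 and hi >= lo):
            raise ValueError("self_score_range bounds must be > 80 and ordered")


@dataclass
class SyntheticDataset:
    """A simulated bit-score panel with ground truth.

    ``module_labels`` maps each gene to ``"M1"``, ``"M2"``, ... or
    ``"background"``; ``ml_labels`` marks module genes as the positive
    class for the classification stage.  ``annotations`` assigns each gene
    flat terms, with one term per module shared by all its members so the
    enrichment stage has a recoverable signal.
    """

    spec: SimulationSpec
    bitscore_matrix: BitScoreMatrix
    clade_map: dict[str, str]
    module_labels: pd.Series
    ml_labels: pd.Series
    annotations: dict[str, list[str]] = field(default_factory=dict)
    latent: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.bitscore_matrix.gene_ids)

    @property
    def species_ids(self) -> list[str]:
        return list(self.bitscore_matrix.species_ids)

    def module_genes(self, module: str = "M1") -> list[str]:
        return list(self.module_labels.index[self.module_labels == module])

    def query_genes(self, module: str = "M1", n: int | None = None) -> list[str]:
        """First ``n`` genes of a module (default: half), the query set."""
        genes = self.module_genes(module)
        if n is None:
            n = max(1, len(genes) // 2)
        return genes[:n]


def simulate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Draw one dataset; the seed fully determines the output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    clade_names = [f"clade{i + 1}" for i in range(len(spec.clade_sizes))]
    species: list[str] = []
    clade_map: dict[str, str] = {}
    clade_cols: dict[str, slice] = {}
    start = 0
    for name, size in zip(clade_names, spec.clade_sizes):
        ids = [f"sp_{name}_{k + 1:02d}" for k in range(size)]
        species += ids
        clade_map.update({s: name for s in ids})
        clade_cols[name] = slice(start, start + size)
        start += size
    n_species = len(species)

    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    module_labels = pd.Series("background", index=genes, name="module")
    row = 0
    module_rows: list[tuple[str, slice, float]] = []
    for m, (size, signal) in enumerate(spec.modules):
        label = f"M{m + 1}"
        module_labels.iloc[row:row + size] = label
        module_rows.append((label, slice(row, row + size), signal))
        row += size

    latent = np.empty((spec.n_genes, n_species))
    # Background genes: each draws its own clade-mean profile.
    bg_means = rng.uniform(0.05, 0.95, size=(spec.n_genes, len(spec.clade_sizes)))
    for c, name in enumerate(clade_names):
        cols = clade_cols[name]
        width = cols.stop - cols.start
        latent[:, cols] = bg_means[:, [c]] + rng.normal(
            0.0, spec.background_noise_sd, size=(spec.n_genes, width)
        )
    # Module genes: one shared clade-mean profile per module; noise shrinks
    # with signal strength.
    for label, rows, signal in module_rows:
        shared = rng.uniform(0.05, 0.95, size=len(spec.clade_sizes))
        n_rows = rows.stop - rows.start
        for c, name in enumerate(clade_names):
            cols = clade_cols[name]
            width = cols.stop - cols.start
            latent[rows, cols] = shared[c] + rng.normal(
                0.0, spec.background_noise_sd * (1.0 - signal), size=(n_rows, width)
            )
    latent = np.clip(latent, 0.0, 1.0)

    self_scores = pd.Series(
        rng.uniform(*spec.self_score_range, size=spec.n_genes),
        index=genes, name="self_score",
    )
    scores = SCORE_FLOOR + latent * (self_scores.to_numpy()[:, None] - SCORE_FLOOR)
    if spec.missing_rate > 0:
        missing = rng.random(scores.shape) < spec.missing_rate
        scores = np.where(missing, np.nan, scores)
    scores_df = pd.DataFrame(scores, index=genes, columns=species)

    lengths = pd.Series(
        rng.integers(60, 500, size=spec.n_genes), index=genes, name="length"
    )
    matrix = BitScoreMatrix(scores=scores_df, self_scores=self_scores, lengths=lengths)

    ml_labels = (module_labels != "background").astype(int)
    ml_labels.name = "label"

    background_terms = [f"TERM_R{j + 1:02d}" for j in range(20)]
    annotations: dict[str, list[str]] = {}
    n_terms = rng.integers(1, 4, size=spec.n_genes)
    for i, g in enumerate(genes):
        picks = rng.choice(len(background_terms), size=n_terms[i], replace=False)
        terms = [background_terms[p] for p in sorted(picks)]
        label = module_labels.iloc[i]
        if label != "background":
            terms = [f"TERM_{label}"] + terms
        annotations[g] = terms

    return SyntheticDataset(
        spec=spec,
        bitscore_matrix=matrix,
        clade_map=clade_map,
        module_labels=module_labels,
        ml_labels=ml_labels,
        annotations=annotations,
        latent=pd.DataFrame(latent, index=genes, columns=species),
    )


def _hit_rows(genes: Sequence[str], species: str, scores: pd.Series,
              lengths: pd.Series) -> pd.DataFrame:
    """Outfmt-6 rows for the present hits of one target proteome."""
    present = scores.dropna()
    n = len(present)
    ln = lengths.reindex(present.index).to_numpy()
    return pd.DataFrame({
        "qseqid": present.index,
        "sseqid": [f"{species}|{g}" for g in present.index],
        "pident": np.full(n, 50.0),
        "length": ln,
        "mismatch": np.zeros(n, dtype=int),
        "gapopen": np.zeros(n, dtype=int),
        "qstart": np.ones(n, dtype=int),
        "qend": ln,
        "sstart": np.ones(n, dtype=int),
        "send": ln,
        "evalue": np.full(n, 1e-10),
        "bitscore": present.to_numpy(),
    }, columns=OUTFMT6_COLUMNS)


def write_fixtures(
    dataset: SyntheticDataset,
    directory: str | Path,
    lengths: Mapping[str, int] | None = None,
) -> dict[str, Path]:
    """Serialize a dataset to the on-disk formats the pipeline reads.

    Emits a dummy-sequence FASTA, one outfmt-6 hit file per target species
    plus a reference self-alignment file, the clade-map TSV, the query
    list and the flat annotation TSV.  ``lengths`` overrides per-gene
    sequence lengths (e.g. to exercise the 40-aa filter).  Returns a
    manifest of paths keyed by role (hit files keyed by species id).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hits_dir = directory / "hits"
    hits_dir.mkdir(exist_ok=True)
    matrix = dataset.bitscore_matrix
    eff_lengths = matrix.lengths.copy()
    if lengths:
        for g, val in lengths.items():
            eff_lengths[g] = val

    manifest: dict[str, Path] = {}

    fasta_path = directory / "proteome.fasta"
    with open(fasta_path, "w") as fh:
        for g in matrix.gene_ids:
            seq = ("MAKTSEQVLR" * (int(eff_lengths[g]) // 10 + 1))[: int(eff_lengths[g])]
            fh.write(f">{g}\n{seq}\n")
    manifest["fasta"] = fasta_path

    fmt = dict(sep="\t", header=False, index=False, float_format="%.17g")
    for sp in matrix.species_ids:
        rows = _hit_rows(matrix.gene_ids, sp, matrix.scores[sp], eff_lengths)
        path = hits_dir / f"{sp}.tsv"
        rows.to_csv(path, **fmt)
        manifest[f"hits:{sp}"] = path

    ref = matrix.self_scores.dropna()
    ln = eff_lengths.reindex(ref.index).to_numpy()
    ref_rows = pd.DataFrame({
        "qseqid": ref.index, "sseqid": ref.index,
        "pident": np.full(len(ref), 100.0), "length": ln,
        "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": ln,
        "sstart": 1, "send": ln, "evalue": 0.0,
        "bitscore": ref.to_numpy(),
    }, columns=OUTFMT6_COLUMNS)
    ref_path = hits_dir / f"{REFERENCE_SPECIES}.tsv"
    ref_rows.to_csv(ref_path, **fmt)
    manifest[f"hits:{REFERENCE_SPECIES}"] = ref_path

    clade_path = directory / "clades.tsv"
    pd.Series(dataset.clade_map, name="clade").rename_axis("species").to_csv(
        clade_path, sep="\t", header=False
    )
    manifest["clades"] = clade_path

    query_path = directory / "query.txt"
    query: list[str] = []
    for label in sorted(set(dataset.module_labels) - {"background"}):
        query += dataset.query_genes(label)
    query_path.write_text("".join(f"{g}\n" for g in query))
    manifest["query"] = query_path

    annot_path = directory / "annotations.tsv"
    with open(annot_path, "w") as fh:
        for g in matrix.gene_ids:
            for term in dataset.annotations.get(g, []):
                fh.write(f"{g}\t{term}\n")
    manifest["annotations"] = annot_path

    return manifest
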