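"""Expression z-score matrices, phenotype labels, and seed-gene selection.

Inputs are cBioPortal-style gene x sample matrices of expression
z-scores (each gene standardised across the cohort). A sample's seed
genes are its top-N most extreme genes by z-score: highest for the
upregulated direction, lowest for the downregulated direction. The
seed-count sweep reruns the whole clustering for several candidate N and
reports the cophenetic correlation of each dendrogram, the diagnostic
used to choose N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError
from .interactome import Interactome

logger = logging.getLogger(__name__)

_GENE_HEADERS = ("hugo_symbol", "gene")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of expression z-scores.

    ``data`` is a pandas DataFrame indexed by gene symbol with one
    column per sample ID; missing measurements are NaN (never silently
    zero). Gene and sample identifiers are unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene symbols")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def sample_scores(self, sample: str) -> pd.Series:
        if sample not in self.data.columns:
            raise LookupError(f"unknown sample {sample!r}")
        return self.data[sample]


@dataclass
class PhenotypeLabels:
    """Two-group sample assignment: sample ID -> group tag in {1, 2}."""

    assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g for g in self.assignment.values() if g not in (1, 2)}
        if bad:
            raise ValueError(f"group tags must be 1 or 2, got {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.assignment)

    def group(self, sample: str) -> int:
        return self.assignment[sample]

    def members(self, group: int) -> set[str]:
        return {s for s, g in self.assignment.items() if g == group}

    def require_two_groups(self) -> None:
        if not self.members(1) or not self.members(2):
            raise ValueError("both phenotype groups must be non-empty")


@dataclass
class SeedSet:
    """Ordered seed genes for one sample (selection rank order)."""

    sample: str
    direction: str  # "up" or "down"
    n_requested: int
    genes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate seed genes")
        if len(self.genes) > self.n_requested:
            raise ValueError("more genes than requested")


def read_zscore_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a z-score TSV: gene-symbol column first (header
    ``Hugo_Symbol`` or ``gene``), one column per sample, cells numeric
    or ``NA``. A cBioPortal ``Entrez_Gene_Id`` second column is ignored
    if present.

    Duplicate gene rows collapse by keeping the row with the fewest
    missing cells (ties: first occurrence, warning logged). Duplicate
    sample columns are an input-format error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0].strip().lower() not in _GENE_HEADERS:
        raise InputFormatError(
            f"{path}: first column header must be 'Hugo_Symbol' or 'gene', "
            f"got {header[0]!r}" if header else f"{path}: empty file"
        )
    sample_cols = header[1:]
    if sample_cols and sample_cols[0].strip().lower() == "entrez_gene_id":
        sample_cols = sample_cols[1:]
    if len(set(sample_cols)) != len(sample_cols):
        dupes = sorted({c for c in sample_cols if sample_cols.count(c) > 1})
        raise InputFormatError(f"{path}: duplicate sample column(s) {dupes}")

    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={header[0]: str})
    df = df.set_index(header[0])
    if "Entrez_Gene_Id" in df.columns:
        df = df.drop(columns=["Entrez_Gene_Id"])
    df.index.name = "gene"
    df = df.astype(float)

    if df.index.has_duplicates:
        n_missing = df.isna().sum(axis=1)
        # stable sort keeps first occurrence among equal missing counts
        order = n_missing.groupby(level=0).transform("min")
        keep = df[n_missing == order]
        keep = keep[~keep.index.duplicated(keep="first")]
        logger.warning(
            "%s: collapsed %d duplicate gene row(s)", path, len(df) - len(keep)
        )
        df = keep.loc[[g for g in dict.fromkeys(df.index)]]
    if not np.isfinite(df.fillna(0.0).to_numpy()).all():
        raise InputFormatError(f"{path}: non-finite z-score value")
    return ExpressionMatrix(df)


def read_phenotype(path: str | Path) -> PhenotypeLabels:
    """Read a two-column phenotype TSV: ``sample_id<TAB>group`` with
    group in {1, 2}."""
    assignment: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise InputFormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            sample, raw = fields[0].strip(), fields[1].strip()
            if lineno == 1 and raw.lower() in ("group", "phenotype"):
                continue
            try:
                group = int(raw)
            except ValueError:
                raise InputFormatError(
                    f"{path}: line {lineno}: group must be 1 or 2, got {raw!r}"
                ) from None
            if group not in (1, 2):
                raise InputFormatError(
                    f"{path}: line {lineno}: group must be 1 or 2, got {group}"
                )
            if sample in assignment:
                raise InputFormatError(
                    f"{path}: line {lineno}: duplicate sample {sample!r}"
                )
            assignment[sample] = group
    return PhenotypeLabels(assignment)


def write_zscore_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.data.copy()
    df.index.name = "Hugo_Symbol"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")


def write_phenotype_tsv(labels: PhenotypeLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in labels.assignment.items():
            fh.write(f"{sample}\t{group}\n")


def select_seeds(
    expr: ExpressionMatrix, sample: str, n: int, direction: str = "up"
) -> SeedSet:
    """Select the sample's top-``n`` seed genes by z-score.

    direction="up" ranks genes by z descending (most upregulated first),
    "down" by z ascending. Genes with missing values are excluded before
    ranking; ties on z break toward the lexicographically smaller
    symbol. Returns fewer than ``n`` genes (with a warning) if the
    sample has fewer scored genes.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    scores = expr.sample_scores(sample).dropna()
    sign = -1.0 if direction == "up" else 1.0
    ranked = sorted(scores.items(), key=lambda kv: (sign * kv[1], kv[0]))
    genes = [g for g, _ in ranked[:n]]
    if len(genes) < n:
        logger.warning(
            "sample %s: only %d scored gene(s) available for n=%d",
            sample,
            len(genes),
            n,
        )
    return SeedSet(sample=sample, direction=direction, n_requested=n, genes=genes)


def seed_count_sweep(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    interactome: Interactome,
    candidate_ns: Sequence[int],
    direction: str = "up",
    max_path_length: int = 2,
    connector_mode: str = "best",
    jaccard_mode: str = "nodes",
) -> pd.DataFrame:
    """Cophenetic-correlation sweep over candidate seed counts.

    For each N the full front half of the pipeline is run (seed
    selection -> sample networks -> Jaccard distances -> UPGMA) and the
    cophenetic correlation between the distance matrix and the
    dendrogram is recorded. A high, stable coefficient across N
    indicates the dendrogram structure is insensitive to the exact seed
    count. One row per N, in input order.
    """
    from .cluster import cophenetic_correlation, pairwise_distances, upgma
    from .networks import build_sample_network

    if not candidate_ns:
        raise ValueError("candidate_ns must be non-empty")
    if any(n < 1 for n in candidate_ns):
        raise ValueError("all candidate seed counts must be >= 1")
    samples = [s for s in expr.samples if s in labels.assignment]
    rows = []
    for n in candidate_ns:
        graphs = [
            build_sample_network(
                select_seeds(expr, s, n, direction),
                interactome,
                max_path_length=max_path_length,
                connector_mode=connector_mode,
            )
            for s in samples
        ]
        dist = pairwise_distances(graphs, mode=jaccard_mode)
        dendro = upgma(dist)
        rows.append({"n": n, "cophenetic_correlation": cophenetic_correlation(dist, dendro)})
    return pd.DataFrame(rows)
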