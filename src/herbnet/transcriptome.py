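"""Transcriptome validation stage: DEG filtering, connectivity-score
screening, and enrichment of the resulting gene lists.

Differential-expression tables arrive already preprocessed (background
correction and normalization happen upstream); this module only applies
the significance thresholds — |log2 fold-change| >= 1.0 with the boundary
included, adjusted p < 0.05 with the boundary excluded — and screens
externally provided connectivity-map similarity scores at an inclusive
cutoff of 80. Similarity scores are consumed, never computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .enrichment import EnrichmentRecord, GeneSetLibrary, ora

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityRecord",
    "load_deg_table",
    "load_similarity_table",
    "deg_filter",
    "similarity_filter",
    "deg_enrich",
]


@dataclass(frozen=True)
class SimilarityRecord:
    compound: str
    score: float


def load_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a (gene, log2fc, padj) TSV into a one-row-per-gene DataFrame."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    required = {"gene", "log2fc", "padj"}
    if not required <= set(df.columns):
        raise ValueError(f"DEG table must have columns {sorted(required)}")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate genes in DEG table: {dups}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError("adjusted p-values must lie in [0, 1]")
    return df[["gene", "log2fc", "padj"]]


def load_similarity_table(path: str | Path) -> list[SimilarityRecord]:
    """Read a (compound, score) TSV of externally provided similarity scores."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    return [SimilarityRecord(str(r.compound), float(r.score)) for r in df.itertuples()]


def deg_filter(
    table: pd.DataFrame, lfc_min: float = 1.0, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Split significant genes into (upregulated, downregulated) lists.

    up: log2fc >= +lfc_min and padj < alpha; down: log2fc <= -lfc_min and
    padj < alpha. The fold-change boundary is included, the p boundary is
    not. The two lists are disjoint and each sorted by gene ID.
    """
    sig = table["padj"] < alpha
    up = sorted(table.loc[sig & (table["log2fc"] >= lfc_min), "gene"])
    down = sorted(table.loc[sig & (table["log2fc"] <= -lfc_min), "gene"])
    logger.info("deg_filter: %d up, %d down of %d genes", len(up), len(down), len(table))
    return up, down


def similarity_filter(
    records: Iterable[SimilarityRecord], cutoff: float = 80.0
) -> list[SimilarityRecord]:
    """Records with summary score >= cutoff (inclusive), sorted descending."""
    kept = [r for r in records if r.score >= cutoff]
    return sorted(kept, key=lambda r: (-r.score, r.compound))


def deg_enrich(
    genes: Sequence[str],
    library: GeneSetLibrary,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Over-representation of a DEG list (up, down, or their union) against
    a gene-set library; delegates to :func:`herbnet.enrichment.ora`."""
    return ora(genes, library, universe, alpha=alpha)
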