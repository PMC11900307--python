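"""Over-representation analysis against GMT gene-set libraries.

Per term the raw p-value is the hypergeometric upper tail of the
query/term overlap; p-values are Benjamini-Hochberg adjusted across the
library's tested terms. The ranking metric is the combined score
``-ln(p) * z``, where z is the overlap's deviation from its hypergeometric
null expectation in standard-deviation units (positive for
over-representation). The z-score uses the exact hypergeometric mean and
variance — a deterministic, reproducible background rather than one based
on precomputed random gene-list rankings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .scoring import hypergeom_upper

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetLibrary",
    "EnrichmentRecord",
    "read_gmt",
    "ora",
    "bh_adjust",
    "combined_score",
]


@dataclass
class GeneSetLibrary:
    """Named collection of terms, each a (description, gene set) pair."""

    name: str
    terms: dict[str, tuple[str, set[str]]] = field(default_factory=dict)

    def filter_terms(self, blocklist: Iterable[str]) -> "GeneSetLibrary":
        """Drop terms whose ID or description contains a blocklisted token
        (case-insensitive); used to exclude e.g. disease-named terms."""
        tokens = [b.lower() for b in blocklist]
        kept = {
            t: v for t, v in self.terms.items()
            if not any(tok in t.lower() or tok in v[0].lower() for tok in tokens)
        }
        return GeneSetLibrary(name=self.name, terms=kept)


@dataclass
class EnrichmentRecord:
    term: str
    description: str
    overlap_k: int
    term_n: int
    p_raw: float
    p_adjusted: float
    z_score: float
    combined: float
    genes: tuple[str, ...]


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT file: term, description, then member genes, tab-separated.

    Duplicate genes within a line collapse; lines with no genes are
    rejected with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    lib = GeneSetLibrary(name=path.stem)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split("\t")]
            if len(cells) < 3 or not any(cells[2:]):
                logger.warning("%s:%d: term %r has no genes, skipped",
                               path, lineno, cells[0] if cells else "")
                continue
            term, desc = cells[0], cells[1]
            genes = {g for g in cells[2:] if g}
            lib.terms[term] = (desc, genes)
    return lib


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving on
    the input index; every output lies in [p, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def combined_score(p: float, z: float) -> float:
    """Enrichment ranking metric ``-ln(p) * z``; z is positive when the
    overlap exceeds its null expectation."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    return -math.log(p) * z


def _hypergeom_z(k: int, n: int, K: int, N: int) -> float:
    """Exact z-score of the overlap under the hypergeometric null."""
    mean = n * K / N
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1) if N > 1 else 0.0
    if var <= 0.0:
        return 0.0
    return (k - mean) / math.sqrt(var)


def ora(
    query: Iterable[str],
    library: GeneSetLibrary,
    universe: Iterable[str],
    alpha: float = 0.05,
    use_adjusted_for_combined: bool = False,
) -> list[EnrichmentRecord]:
    """Per-term over-representation of ``query`` against ``library``.

    Query genes outside the universe are dropped with a warning; term gene
    sets are restricted to the universe. Records are sorted by combined
    score descending (ties by term ID). ``alpha`` is carried for callers
    that threshold on adjusted p; no records are dropped here.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    off = query - universe
    if off:
        logger.warning("%d query genes outside the universe dropped", len(off))
        query &= universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")

    N, n = len(universe), len(query)
    terms = sorted(library.terms)
    raws, infos = [], []
    for t in terms:
        desc, genes = library.terms[t]
        term_in = genes & universe
        K = len(term_in)
        overlap = sorted(query & term_in)
        k = len(overlap)
        p_raw = hypergeom_upper(k, n, K, N) if K > 0 else 1.0
        z = _hypergeom_z(k, n, K, N) if K > 0 else 0.0
        raws.append(p_raw)
        infos.append((t, desc, k, K, z, overlap))

    adj = bh_adjust(raws)
    records = []
    for (t, desc, k, K, z, overlap), p_raw, p_adj in zip(infos, raws, adj):
        p_for_combined = p_adj if use_adjusted_for_combined else p_raw
        records.append(EnrichmentRecord(
            term=t, description=desc, overlap_k=k, term_n=K,
            p_raw=p_raw, p_adjusted=float(p_adj), z_score=z,
            combined=combined_score(p_for_combined, z),
            genes=tuple(overlap),
        ))
    records.sort(key=lambda rec: (-rec.combined, rec.term))
    return records
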