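"""Herb and compound prioritization against a disease profile.

Each retained herb gets a diffusion profile from its compound-target seed
set; the ranking statistic is the correlation of that profile with the
disease profile over the full node vector (proteins and functions).
Alongside the correlation, an overlap test reports how many of the herb's
targets fall inside the disease gene set, with a hypergeometric upper-tail
p-value and a fold enrichment (observed overlap fraction over the fraction
expected under random draws from the protein universe).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .catalog import (
    DiseaseGeneSet,
    HerbCatalog,
    compound_seed,
    disease_seed,
    herb_seed,
    pathway_count,
    top_targets,
)
from .diffusion import DiffusionProfile, RWRParams, batch_profiles, diffusion_profile, transition_matrix
from .msnet import MultiscaleNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PrioritizationRecord",
    "correlation_score",
    "hypergeom_upper",
    "fold_enrichment",
    "prioritize",
    "prioritize_compounds",
]


@dataclass
class PrioritizationRecord:
    """One ranked entity: correlation score plus overlap statistics.

    ``overlap_k`` of the entity's ``overlap_n`` targets fall in the disease
    set (size ``disease_K``) drawn from a universe of ``universe_N``
    proteins; ``significant`` flags ``p_value < alpha``.
    """

    entity: str
    correlation: float
    overlap_k: int
    overlap_n: int
    disease_K: int
    universe_N: int
    p_value: float
    enrichment: float
    significant: bool
    rank: int = 0


def correlation_score(
    profile_a: DiffusionProfile,
    profile_b: DiffusionProfile,
    method: str = "pearson",
) -> float:
    """Correlation of two diffusion profiles over the shared node index."""
    if profile_a.nodes != profile_b.nodes:
        raise ValueError("profiles are not over the same node index")
    a, b = profile_a.values, profile_b.values
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("degenerate profile: zero variance")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), via log-space sf.

    ``k`` overlapping out of ``n`` drawn, ``K`` marked in a universe of
    ``N``.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(math.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): observed overlap fraction over the expected fraction."""
    if n <= 0 or K <= 0:
        raise ValueError("n and K must be positive")
    return (k / n) * (N / K)


def _overlap_record(
    entity: str,
    corr: float,
    targets: set[str],
    disease_on: set[str],
    N: int,
    alpha: float,
) -> PrioritizationRecord:
    n = len(targets)
    K = len(disease_on)
    k = len(targets & disease_on)
    p = hypergeom_upper(k, n, K, N)
    enr = fold_enrichment(k, n, K, N) if n > 0 and K > 0 else 0.0
    return PrioritizationRecord(
        entity=entity, correlation=corr, overlap_k=k, overlap_n=n,
        disease_K=K, universe_N=N, p_value=p, enrichment=enr,
        # alpha = 1 disables the overlap flag (p can equal 1 exactly at k=0)
        significant=p < alpha or alpha >= 1.0,
    )


def prioritize(
    catalog: HerbCatalog,
    disease: DiseaseGeneSet,
    network: MultiscaleNetwork,
    params: RWRParams | None = None,
    method: str = "pearson",
    alpha: float = 0.05,
    universe_N: int | None = None,
    overlap_from_top_n: int | None = None,
) -> list[PrioritizationRecord]:
    """Rank every herb in the catalog against the disease.

    Sorted by correlation score descending, ties broken by herb ID.
    Records failing the overlap test at ``alpha`` stay in the ranking with
    ``significant=False``. With ``overlap_from_top_n`` the overlap
    denominator is capped to the herb's top-n targets by compound count
    instead of its full on-network target set.
    """
    params = params or RWRParams()
    N = universe_N if universe_N is not None else len(network.proteins)
    disease_on = disease.genes & network.proteins
    d_seed = disease_seed(disease, network)
    herbs = sorted(catalog.herbs)
    seeds = [herb_seed(catalog, h, network) for h in herbs]
    profiles = batch_profiles(network, [d_seed] + seeds, params)
    d_profile, herb_profiles = profiles[0], profiles[1:]

    records = []
    for h, seed, prof in zip(herbs, seeds, herb_profiles):
        if overlap_from_top_n is not None:
            counts = pathway_count(catalog, h)
            cand = set(top_targets(counts, overlap_from_top_n))
            targets = cand & network.proteins
        else:
            targets = set(seed.genes)
        corr = correlation_score(prof, d_profile, method)
        records.append(_overlap_record(h, corr, targets, disease_on, N, alpha))
    records.sort(key=lambda rec: (-rec.correlation, rec.entity))
    for i, rec in enumerate(records, start=1):
        rec.rank = i
    return records


def prioritize_compounds(
    catalog: HerbCatalog,
    herb: str,
    disease: DiseaseGeneSet,
    network: MultiscaleNetwork,
    params: RWRParams | None = None,
    method: str = "pearson",
    alpha: float = 0.05,
    universe_N: int | None = None,
    top_m: int = 5,
) -> list[PrioritizationRecord]:
    """Rank a herb's compounds against the disease; return the top ``top_m``.

    Each compound is seeded by its own targets. Compounds with no
    on-network target are skipped with a warning.
    """
    if herb not in catalog.herbs:
        raise KeyError(f"unknown herb {herb!r}")
    params = params or RWRParams()
    N = universe_N if universe_N is not None else len(network.proteins)
    disease_on = disease.genes & network.proteins
    d_profile = diffusion_profile(network, disease_seed(disease, network), params)
    mats = transition_matrix(network, params)

    records = []
    for c in sorted(catalog.compounds_of[herb]):
        try:
            seed = compound_seed(catalog, c, network)
        except ValueError:
            logger.warning("compound %s skipped: no on-network targets", c)
            continue
        prof = diffusion_profile(network, seed, params, _matrices=mats)
        corr = correlation_score(prof, d_profile, method)
        records.append(_overlap_record(c, corr, set(seed.genes), disease_on, N, alpha))
    records.sort(key=lambda rec: (-rec.correlation, rec.entity))
    for i, rec in enumerate(records, start=1):
        rec.rank = i
    return records[:top_m]
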