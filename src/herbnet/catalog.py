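"""Herb-compound-target catalog: loading, curation filters, seed derivation.

Herb-compound and compound-target tables come in as two-column TSVs (herb
name / PubChem-CID-like compound ID, and compound ID / Entrez-like gene ID).
All identifiers are opaque strings; any ID harmonization happens upstream
via a user-supplied mapping file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._tsv import iter_tsv_rows
from .msnet import MultiscaleNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "HerbCatalog",
    "SeedSet",
    "DiseaseGeneSet",
    "load_herb_compound",
    "load_compound_target",
    "load_catalog",
    "filter_herbs",
    "pathway_count",
    "top_targets",
    "herb_seed",
    "load_disease_genes",
    "cotarget_summary",
]


@dataclass
class HerbCatalog:
    """Herb -> compound -> target mapping.

    ``compounds_of`` maps each herb to its compound IDs; ``targets_of`` maps
    compound IDs to target gene sets. A compound referenced by a herb but
    absent from ``targets_of`` is "untargeted"; a compound with targets but
    no herb is an orphan (retained, flagged in :meth:`orphan_compounds`).
    """

    compounds_of: dict[str, set[str]] = field(default_factory=dict)
    targets_of: dict[str, set[str]] = field(default_factory=dict)

    @property
    def herbs(self) -> set[str]:
        return set(self.compounds_of)

    @property
    def compounds(self) -> set[str]:
        out = set(self.targets_of)
        for cs in self.compounds_of.values():
            out |= cs
        return out

    def untargeted_compounds(self, herb: str) -> set[str]:
        return {c for c in self.compounds_of[herb] if not self.targets_of.get(c)}

    def targeted_compounds(self, herb: str) -> set[str]:
        return {c for c in self.compounds_of[herb] if self.targets_of.get(c)}

    def orphan_compounds(self) -> set[str]:
        referenced = set()
        for cs in self.compounds_of.values():
            referenced |= cs
        return set(self.targets_of) - referenced

    def herb_targets(self, herb: str) -> set[str]:
        """Union of the herb's compound target sets."""
        if herb not in self.compounds_of:
            raise KeyError(f"unknown herb {herb!r}")
        out: set[str] = set()
        for c in self.compounds_of[herb]:
            out |= self.targets_of.get(c, set())
        return out

    def n_associations(self) -> int:
        return sum(len(cs) for cs in self.compounds_of.values())

    def to_dict(self) -> dict:
        """JSON-ready snapshot with sorted members."""
        return {
            "herbs": {h: sorted(cs) for h, cs in sorted(self.compounds_of.items())},
            "compound_targets": {c: sorted(ts) for c, ts in sorted(self.targets_of.items())},
        }


@dataclass
class SeedSet:
    """Restart support for a diffusion profile.

    ``genes`` is an ordered, duplicate-free tuple; ``weights`` (optional)
    are nonnegative restart weights summing to 1, uniform when omitted.
    """

    entity: str
    genes: tuple[str, ...]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("seed genes contain duplicates")
        if not self.genes:
            raise ValueError(f"seed set for {self.entity!r} is empty")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.genes),):
                raise ValueError("weights length mismatch")
            if (w < 0).any():
                raise ValueError("negative seed weight")
            if abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("seed weights must sum to 1")
            self.weights = w

    def weight_map(self) -> dict[str, float]:
        if self.weights is None:
            u = 1.0 / len(self.genes)
            return {g: u for g in self.genes}
        return dict(zip(self.genes, self.weights))


@dataclass
class DiseaseGeneSet:
    """Curated disease-gene association records: (gene, source, association type)."""

    disease: str
    records: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return {g for g, _, _ in self.records}


def _apply_mapping(token: str, mapping: Mapping[str, str] | None) -> str:
    return mapping.get(token, token) if mapping else token


def load_id_mapping(path: str | Path) -> dict[str, str]:
    """Two-column old-ID -> new-ID table applied before loading."""
    return {row[0]: row[1] for _, row in iter_tsv_rows(path, min_columns=2)}


def load_herb_compound(
    path: str | Path, id_mapping: Mapping[str, str] | None = None
) -> HerbCatalog:
    """Read a herb/compound TSV into a catalog fragment (no targets yet).

    Duplicate rows collapse; rows with empty fields are rejected with their
    line number; an empty file raises ``ValueError("no associations")``.
    """
    catalog = HerbCatalog()
    for _, row in iter_tsv_rows(path, min_columns=2):
        herb, compound = row[0], _apply_mapping(row[1], id_mapping)
        catalog.compounds_of.setdefault(herb, set()).add(compound)
    if not catalog.compounds_of:
        raise ValueError(f"no associations in {path}")
    logger.info(
        "loaded %d herbs, %d unique herb-compound pairs from %s",
        len(catalog.compounds_of), catalog.n_associations(), path,
    )
    return catalog


def load_compound_target(
    path: str | Path, id_mapping: Mapping[str, str] | None = None
) -> dict[str, set[str]]:
    """Read a compound/target TSV into a compound -> gene-set map."""
    targets: dict[str, set[str]] = {}
    for _, row in iter_tsv_rows(path, min_columns=2):
        compound, gene = row[0], _apply_mapping(row[1], id_mapping)
        targets.setdefault(compound, set()).add(gene)
    logger.info("loaded targets for %d compounds from %s", len(targets), path)
    return targets


def load_catalog(
    herb_compound_path: str | Path,
    compound_target_path: str | Path,
    id_mapping: Mapping[str, str] | None = None,
) -> HerbCatalog:
    """Assemble a full catalog from the two tables; orphan compounds are kept."""
    catalog = load_herb_compound(herb_compound_path, id_mapping)
    catalog.targets_of = load_compound_target(compound_target_path, id_mapping)
    orphans = catalog.orphan_compounds()
    if orphans:
        logger.warning("%d compounds have targets but no herb (kept as orphans)", len(orphans))
    return catalog


def filter_herbs(catalog: HerbCatalog, min_components: int = 3) -> HerbCatalog:
    """Drop herbs with fewer than ``min_components`` target-linked compounds.

    Only compounds with at least one known target count toward the
    threshold; untargeted compounds neither help nor hurt. Idempotent.
    """
    if min_components < 1:
        raise ValueError("min_components must be >= 1")
    kept = {
        h: set(cs)
        for h, cs in catalog.compounds_of.items()
        if len(catalog.targeted_compounds(h)) >= min_components
    }
    removed = sorted(set(catalog.compounds_of) - set(kept))
    if removed:
        logger.info("filter_herbs removed %d herbs: %s", len(removed), ", ".join(removed))
    return HerbCatalog(compounds_of=kept, targets_of=dict(catalog.targets_of))


def pathway_count(catalog: HerbCatalog, herb: str) -> dict[str, int]:
    """Per-target count of the herb's compounds hitting it.

    A target hit by several of the herb's compounds accumulates one count
    per compound; every reported value is >= 1.
    """
    if herb not in catalog.compounds_of:
        raise KeyError(f"unknown herb {herb!r}")
    counts: dict[str, int] = {}
    for c in catalog.compounds_of[herb]:
        for t in catalog.targets_of.get(c, set()):
            counts[t] = counts.get(t, 0) + 1
    return counts


def top_targets(counts: Mapping[str, int], n: int = 50) -> list[str]:
    """Top-``n`` targets by compound count, ties broken by gene ID ascending."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(counts, key=lambda g: (-counts[g], g))
    return ranked[:n]


def herb_seed(
    catalog: HerbCatalog, herb: str, network: MultiscaleNetwork
) -> SeedSet:
    """Uniform-weight seed over the herb's on-network compound targets."""
    targets = catalog.herb_targets(herb)
    on = sorted(targets & network.proteins)
    dropped = sorted(targets - network.proteins)
    if dropped:
        logger.info("herb %s: %d targets off-network dropped", herb, len(dropped))
    if not on:
        raise ValueError(f"herb {herb!r} has no on-network targets")
    return SeedSet(entity=herb, genes=tuple(on))


def compound_seed(
    catalog: HerbCatalog, compound: str, network: MultiscaleNetwork
) -> SeedSet:
    """Uniform-weight seed over a compound's on-network targets."""
    targets = catalog.targets_of.get(compound, set())
    on = sorted(targets & network.proteins)
    if not on:
        raise ValueError(f"compound {compound!r} has no on-network targets")
    return SeedSet(entity=compound, genes=tuple(on))


def disease_seed(disease: DiseaseGeneSet, network: MultiscaleNetwork) -> SeedSet:
    """Uniform-weight seed over the disease's on-network genes."""
    on = sorted(disease.genes & network.proteins)
    if not on:
        raise ValueError(f"disease {disease.disease!r} has no on-network genes")
    return SeedSet(entity=disease.disease, genes=tuple(on))


def load_disease_genes(
    path: str | Path,
    disease: str = "disease",
    excluded_association_types: Iterable[str] = (),
    excluded_evidence: Iterable[str] = (),
) -> DiseaseGeneSet:
    """Read a disease gene list with optional ``source`` / ``association_type`` columns.

    Records whose source tag is in ``excluded_evidence`` or whose
    association-type tag is in ``excluded_association_types`` are dropped
    (e.g. associations from animal-model homology, from literature mining
    alone, or labeled therapeutic). Files with a bare gene column keep
    everything.
    """
    excl_assoc = {t.lower() for t in excluded_association_types}
    excl_evid = {t.lower() for t in excluded_evidence}
    records: list[tuple[str, str, str]] = []
    n_before = 0
    for _, row in iter_tsv_rows(path, min_columns=1):
        gene = row[0]
        source = row[1] if len(row) > 1 else ""
        assoc = row[2] if len(row) > 2 else ""
        n_before += 1
        if source.lower() in excl_evid or assoc.lower() in excl_assoc:
            continue
        records.append((gene, source, assoc))
    logger.info("disease gene records: %d before filtering, %d after", n_before, len(records))
    if n_before and not records:
        logger.warning("all %d disease gene records excluded by curation filters", n_before)
    return DiseaseGeneSet(disease=disease, records=records)


def cotarget_summary(
    catalog: HerbCatalog,
    herbs: Sequence[str] | None = None,
    min_herbs: int = 1,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Herb-target edge table and per-target distinct-herb counts.

    Edges are herb-level: a target reached through several compounds of the
    same herb contributes one edge. Returns ``(edges, counts)`` where
    ``counts`` keeps only targets co-targeted by at least ``min_herbs``
    distinct herbs.
    """
    herb_list = sorted(catalog.herbs) if herbs is None else list(herbs)
    if not herb_list:
        raise ValueError("cotarget_summary needs at least one herb")
    edges: list[tuple[str, str]] = []
    counts: dict[str, int] = {}
    for h in herb_list:
        for t in sorted(catalog.herb_targets(h)):
            edges.append((h, t))
            counts[t] = counts.get(t, 0) + 1
    counts = {t: c for t, c in counts.items() if c >= min_herbs}
    return edges, counts
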