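"""Deterministic output writers: ranking tables, enrichment tables,
synthetic fixture directories, and run manifests.

All table formatting lives here, never in the core operations. Numeric
columns are written with 4 significant digits in TSV and at full precision
in JSON, and every writer emits rows in a deterministic order so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .catalog import DiseaseGeneSet, HerbCatalog
from .enrichment import EnrichmentRecord
from .msnet import MultiscaleNetwork
from .scoring import PrioritizationRecord

__all__ = [
    "write_prioritization",
    "write_enrichment",
    "write_cotarget_edges",
    "write_fixture_dir",
    "write_manifest",
]


def _sig4(x: float) -> str:
    return f"{x:.4g}"


def write_prioritization(
    records: Sequence[PrioritizationRecord], tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Ranked-herb table: entity, correlation, overlap "k/n", p, enrichment."""
    with Path(tsv_path).open("w") as fh:
        fh.write("rank\tentity\tcorrelation_score\toverlap\tp_value\tenrichment\tsignificant\n")
        for rec in records:
            fh.write(
                f"{rec.rank}\t{rec.entity}\t{_sig4(rec.correlation)}\t"
                f"{rec.overlap_k}/{rec.overlap_n}\t{_sig4(rec.p_value)}\t"
                f"{_sig4(rec.enrichment)}\t{str(rec.significant).lower()}\n"
            )
    if json_path is not None:
        payload = [
            {
                "rank": rec.rank, "entity": rec.entity,
                "correlation_score": rec.correlation,
                "overlap_k": rec.overlap_k, "overlap_n": rec.overlap_n,
                "disease_K": rec.disease_K, "universe_N": rec.universe_N,
                "p_value": rec.p_value, "enrichment": rec.enrichment,
                "significant": rec.significant,
            }
            for rec in records
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def write_enrichment(records: Sequence[EnrichmentRecord], path: str | Path) -> None:
    """Enrichment table: term, overlap "k/n", adjusted p, combined score, genes."""
    with Path(path).open("w") as fh:
        fh.write("term\tdescription\toverlap\tadjusted_p\tcombined_score\ttargets\n")
        for rec in records:
            fh.write(
                f"{rec.term}\t{rec.description}\t{rec.overlap_k}/{rec.term_n}\t"
                f"{_sig4(rec.p_adjusted)}\t{_sig4(rec.combined)}\t"
                f"{';'.join(rec.genes)}\n"
            )


def write_cotarget_edges(
    edges: Iterable[tuple[str, str]], counts: Mapping[str, int], path: str | Path
) -> None:
    """Herb-target edge table with per-target distinct-herb counts."""
    with Path(path).open("w") as fh:
        fh.write("herb\ttarget\tn_herbs_on_target\n")
        for herb, target in sorted(edges):
            fh.write(f"{herb}\t{target}\t{counts.get(target, 0)}\n")


def _write_pairs(path: Path, header: tuple[str, str], pairs: Iterable[tuple[str, str]]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def write_fixture_dir(
    out_dir: str | Path,
    network: MultiscaleNetwork,
    catalog: HerbCatalog,
    disease: DiseaseGeneSet,
    gmt: Mapping[str, set[str]] | None = None,
    deg_table=None,
    ground_truth: Mapping | None = None,
) -> dict[str, Path]:
    """Materialize a complete input directory in the TSV/GMT dialects the
    loaders read. Returns the map of written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["pp"] = out / "pp.tsv"
    _write_pairs(paths["pp"], ("node_1", "node_2"), network.pp_edges)
    paths["pf"] = out / "pf.tsv"
    _write_pairs(paths["pf"], ("protein", "function"), network.pf_edges)
    paths["ff"] = out / "ff.tsv"
    _write_pairs(paths["ff"], ("child", "parent"), network.ff_edges)

    paths["herb_compound"] = out / "herb_compound.tsv"
    _write_pairs(
        paths["herb_compound"], ("herb", "compound"),
        ((h, c) for h, cs in catalog.compounds_of.items() for c in cs),
    )
    paths["compound_target"] = out / "compound_target.tsv"
    _write_pairs(
        paths["compound_target"], ("compound", "gene"),
        ((c, t) for c, ts in catalog.targets_of.items() for t in ts),
    )

    paths["disease_genes"] = out / "disease_genes.tsv"
    with paths["disease_genes"].open("w") as fh:
        fh.write("gene\tsource\tassociation_type\n")
        for g, src, assoc in sorted(disease.records):
            fh.write(f"{g}\t{src}\t{assoc}\n")

    if gmt is not None:
        paths["gmt"] = out / "library.gmt"
        with paths["gmt"].open("w") as fh:
            for term in sorted(gmt):
                genes = "\t".join(sorted(gmt[term]))
                fh.write(f"{term}\tsynthetic term\t{genes}\n")

    if deg_table is not None:
        paths["deg"] = out / "deg_table.tsv"
        deg_table.to_csv(paths["deg"], sep="\t", index=False)

    if ground_truth is not None:
        paths["ground_truth"] = out / "ground_truth.json"
        paths["ground_truth"].write_text(json.dumps(dict(ground_truth), indent=2, sort_keys=True) + "\n")
    return paths


def write_manifest(out_path: str | Path, config: Mapping, inputs: Iterable[str | Path]) -> None:
    """Run manifest: canonical config hash plus input-file checksums."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    checksums = {}
    for p in sorted(str(x) for x in inputs):
        path = Path(p)
        if path.exists():
            checksums[p] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": json.loads(canonical),
        "input_sha256": checksums,
    }
    Path(out_path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
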