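"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates, at desk scale, everything the pipeline consumes:

* a connected scale-free protein-protein layer (preferential attachment,
  matching the heavy-tailed degree distributions of physical interactomes;
  an Erdos-Renyi option exists for ablation),
* a layered function hierarchy with child -> parent edges and Poisson
  protein annotations,
* a planted disease module — a connected protein subset with elevated
  internal wiring,
* a herb catalog in which one planted "effective" herb draws its compound
  targets from the disease module and its graph neighborhood with
  probability ``p_in`` while decoy herbs draw essentially uniformly
  (``p_bg``), giving a recoverable ground truth,
* a DEG table with null genes (log2fc ~ Normal(0, 0.3), uniform adjusted
  p) and spiked genes at a fixed effect size with small p.

All randomness flows from a single config seed through named substreams
(network / disease / catalog / deg), so each component regenerates
independently.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import DiseaseGeneSet, HerbCatalog, SeedSet, disease_seed
from .diffusion import RWRParams
from .msnet import MultiscaleNetwork
from . import scoring
from .mechanism import extract_mechanism
from .diffusion import diffusion_profile

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "generate_network",
    "plant_disease",
    "generate_catalog",
    "generate_deg_table",
    "generate_gmt",
    "benchmark_run",
]

_SUBSTREAMS = {"network": 0, "disease": 1, "catalog": 2, "deg": 3}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic benchmark; defaults are the standard
    planted-herb recovery conditions."""

    n_proteins: int = 200
    pp_attachment: int = 3          # preferential-attachment edges per new node
    pp_model: str = "ba"            # "ba" scale-free | "er" Erdos-Renyi ablation
    n_functions: int = 40
    hierarchy_depth: int = 3
    annotations_per_protein: float = 1.0   # Poisson mean of pf annotations
    disease_module_size: int = 15
    disease_wiring: float = 0.3     # extra internal edge probability
    n_herbs: int = 20               # one planted + (n_herbs - 1) decoys
    compounds_per_herb: int = 5
    targets_per_compound: int = 4
    p_in: float = 0.8               # planted-herb target lands in module/neighborhood
    p_bg: float = 0.05              # decoy-herb equivalent
    deg_n_genes: int = 1000
    deg_n_spiked: int = 50
    deg_effect: float = 2.0
    deg_null_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_proteins, self.pp_attachment, self.n_functions,
                  self.hierarchy_depth, self.disease_module_size, self.n_herbs,
                  self.compounds_per_herb, self.targets_per_compound,
                  self.deg_n_genes, self.deg_n_spiked)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for p in (self.p_in, self.p_bg, self.disease_wiring):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    def rng(self, substream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_SUBSTREAMS[substream],))
        )


def _protein_name(i: int) -> str:
    return f"P{i:04d}"


def _function_name(i: int) -> str:
    return f"F{i:04d}"


def generate_network(config: SyntheticConfig) -> MultiscaleNetwork:
    """Three-layer synthetic multiscale network, deterministic given the seed.

    The pp layer is a connected Barabasi-Albert graph (or G(n, p) matched
    in expected degree when ``pp_model='er'``); functions sit on
    ``hierarchy_depth`` levels with each non-top function wired to 1-2
    parents on the level above (depth 1 means no hierarchy edges);
    annotations per protein are Poisson.
    """
    rng = config.rng("network")
    n = config.n_proteins
    if config.pp_model == "ba":
        g = nx.barabasi_albert_graph(n, min(config.pp_attachment, n - 1), seed=int(rng.integers(2**31)))
    elif config.pp_model == "er":
        p = min(1.0, 2 * config.pp_attachment / (n - 1)) if n > 1 else 0.0
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        # stitch components so every protein can be reached
        comps = [sorted(c) for c in nx.connected_components(g)]
        for a, b in zip(comps, comps[1:]):
            g.add_edge(a[0], b[0])
    else:
        raise ValueError(f"unknown pp_model {config.pp_model!r}")

    net = MultiscaleNetwork()
    net.proteins = {_protein_name(i) for i in range(n)}
    for u, v in g.edges():
        net.add_pp_edge(_protein_name(u), _protein_name(v))

    # layered function hierarchy: level sizes as even as possible
    depth = config.hierarchy_depth
    nf = config.n_functions
    base, extra = divmod(nf, depth)
    levels: list[list[str]] = []
    idx = 0
    for lv in range(depth):
        size = base + (1 if lv < extra else 0)
        levels.append([_function_name(i) for i in range(idx, idx + size)])
        idx += size
    net.functions = {f for lvl in levels for f in lvl}
    for lower, upper in zip(levels, levels[1:]):
        if not upper:
            continue
        for child in lower:
            n_parents = int(rng.integers(1, 3))
            for parent in rng.choice(upper, size=min(n_parents, len(upper)), replace=False):
                net.add_ff_edge(child, str(parent))

    all_funcs = sorted(net.functions)
    for i in range(n):
        k = rng.poisson(config.annotations_per_protein)
        if k == 0 or not all_funcs:
            continue
        for f in rng.choice(all_funcs, size=min(k, len(all_funcs)), replace=False):
            net.add_pf_edge(_protein_name(i), str(f))
    return net


def plant_disease(
    network: MultiscaleNetwork, config: SyntheticConfig
) -> DiseaseGeneSet:
    """Plant a connected disease module and densify its internal wiring.

    Grows a connected protein subset of ``disease_module_size`` by seeded
    BFS-with-random-frontier, then adds each missing internal edge with
    probability ``disease_wiring`` (mutating the network in place).
    """
    rng = config.rng("disease")
    proteins = sorted(network.proteins)
    start = str(rng.choice(proteins))
    module = [start]
    in_module = {start}
    frontier = sorted(network.neighbors(start)["protein"])
    while len(module) < config.disease_module_size and frontier:
        nxt = str(rng.choice(sorted(frontier)))
        frontier = sorted(set(frontier) - {nxt})
        if nxt in in_module:
            continue
        module.append(nxt)
        in_module.add(nxt)
        frontier = sorted((set(frontier) | network.neighbors(nxt)["protein"]) - in_module)
    if len(module) < config.disease_module_size:
        logger.warning("disease module truncated to %d proteins", len(module))
    for i, u in enumerate(module):
        for v in module[i + 1:]:
            if v not in network.neighbors(u)["protein"] and rng.random() < config.disease_wiring:
                network.add_pp_edge(u, v)
    records = [(g, "synthetic-curated", "causal") for g in sorted(module)]
    return DiseaseGeneSet(disease="synthetic-disease", records=records)


def _proximal_draw(
    rng: np.random.Generator, network: MultiscaleNetwork, module: list[str]
) -> str:
    """One target inside or adjacent to the module: pick a module gene
    uniformly, then keep it or step to one of its pp neighbors (50/50).

    Stepping from a sampled module gene, rather than pooling every
    neighbor of every module gene, keeps the draw concentrated near the
    module even when hubs make the pooled one-hop neighborhood span much
    of a scale-free graph.
    """
    g = str(rng.choice(module))
    if rng.random() < 0.5:
        return g
    nbrs = sorted(network.neighbors(g)["protein"])
    return str(rng.choice(nbrs)) if nbrs else g


def generate_catalog(
    network: MultiscaleNetwork,
    disease: DiseaseGeneSet,
    config: SyntheticConfig,
) -> tuple[HerbCatalog, str]:
    """Herb catalog with one planted proximal herb among decoys.

    Every target draw lands in the disease module or its pp neighborhood
    with probability ``p_in`` (planted herb) or ``p_bg`` (decoys), and is
    uniform over all proteins otherwise. Returns (catalog, planted herb
    ID).
    """
    rng = config.rng("catalog")
    proteins = sorted(network.proteins)
    module = sorted(disease.genes)
    catalog = HerbCatalog()
    planted = "HERB_000"
    cid = 0
    for h in range(config.n_herbs):
        herb = f"HERB_{h:03d}"
        p_hit = config.p_in if herb == planted else config.p_bg
        compounds = set()
        for _ in range(config.compounds_per_herb):
            compound = f"CID{cid:06d}"
            cid += 1
            targets = set()
            while len(targets) < config.targets_per_compound:
                if rng.random() < p_hit:
                    targets.add(_proximal_draw(rng, network, module))
                else:
                    targets.add(str(rng.choice(proteins)))
            catalog.targets_of[compound] = targets
            compounds.add(compound)
        catalog.compounds_of[herb] = compounds
    return catalog, planted


def generate_deg_table(config: SyntheticConfig) -> tuple[pd.DataFrame, set[str]]:
    """DEG table of null plus spiked genes; returns (table, spiked gene set).

    Null genes: log2fc ~ Normal(0, deg_null_sd), padj ~ Uniform(0, 1).
    Spiked genes: |log2fc| = deg_effect + |Normal(0, deg_null_sd)| with
    random sign, padj ~ Uniform(0, 0.005) (well under the 0.01 the spike
    definition requires).
    """
    rng = config.rng("deg")
    n, ns = config.deg_n_genes, config.deg_n_spiked
    if ns > n:
        raise ValueError("more spiked genes than genes")
    genes = [f"G{i:05d}" for i in range(n)]
    spiked = set(str(g) for g in rng.choice(genes, size=ns, replace=False))
    rows = []
    for g in genes:
        if g in spiked:
            lfc = float(rng.choice([-1.0, 1.0]) * (config.deg_effect + abs(rng.normal(0, config.deg_null_sd))))
            padj = float(rng.uniform(0, 0.005))
        else:
            lfc = float(rng.normal(0, config.deg_null_sd))
            padj = float(rng.uniform(0, 1))
        rows.append((g, lfc, padj))
    return pd.DataFrame(rows, columns=["gene", "log2fc", "padj"]), spiked


def generate_gmt(network: MultiscaleNetwork, config: SyntheticConfig,
                 n_terms: int = 10, term_size: int = 15) -> dict[str, set[str]]:
    """Small gene-set library drawn from the network's proteins, for
    exercising the enrichment stage on synthetic runs."""
    rng = config.rng("catalog")
    proteins = sorted(network.proteins)
    return {
        f"TERM_{i:02d}": {str(g) for g in rng.choice(proteins, size=min(term_size, len(proteins)), replace=False)}
        for i in range(n_terms)
    }


def benchmark_run(
    config: SyntheticConfig, params: RWRParams | None = None, k: int = 20
) -> dict:
    """Generate -> prioritize -> mechanism, end to end; report ground truth
    recovery for the planted herb."""
    t0 = time.perf_counter()
    params = params or RWRParams()
    network = generate_network(config)
    disease = plant_disease(network, config)
    catalog, planted = generate_catalog(network, disease, config)
    records = scoring.prioritize(catalog, disease, network, params)
    rank = next(rec.rank for rec in records if rec.entity == planted)

    top = scoring.prioritize_compounds(catalog, planted, disease, network, params, top_m=1)
    compound = top[0].entity
    c_targets = catalog.targets_of[compound] & network.proteins
    c_seed_profile = diffusion_profile(
        network, SeedSet(compound, tuple(sorted(c_targets))), params
    )
    d_profile = diffusion_profile(network, disease_seed(disease, network), params)
    mech = extract_mechanism(
        c_seed_profile, d_profile, network, c_targets, disease.genes, k=k
    )
    module_in_mech = bool(disease.genes & mech.nodes)
    return {
        "planted_herb": planted,
        "planted_rank": rank,
        "top1": rank == 1,
        "n_herbs": config.n_herbs,
        "mechanism_contains_disease_protein": module_in_mech,
        "runtime_s": time.perf_counter() - t0,
    }
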