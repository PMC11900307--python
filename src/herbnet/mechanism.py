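"""Mechanism subnetwork extraction: compound -> targets -> disease, through
the top-k most-visited proteins and biological functions.

The candidate node set joins the top-k nodes of the compound's and the
disease's diffusion profiles with the compound's targets and the disease's
on-network genes. Induced multiscale edges connect them, plus anchor edges
from the compound node to each retained target and from the disease node to
each disease gene. Compound targets not linked (by direct network
adjacency, or optionally within two hops) to any disease-side or top-k node
are excluded. The top-ranked node of each profile is flagged critical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .diffusion import DiffusionProfile
from .msnet import MultiscaleNetwork, NodeClass, subnetwork as induce

logger = logging.getLogger(__name__)

__all__ = [
    "MechanismSubnetwork",
    "top_k_nodes",
    "extract_mechanism",
    "export_subnetwork",
    "read_graphml_subnetwork",
]

# role priority when a node qualifies for several
_ROLE_ORDER = [
    "compound", "disease", "compound-target", "disease-protein",
    "biological-function", "intermediate-protein",
]


@dataclass
class MechanismSubnetwork:
    """Role-tagged induced graph linking a compound to a disease.

    ``roles`` maps node -> one of {compound, disease, compound-target,
    disease-protein, intermediate-protein, biological-function};
    ``edges`` holds (source, target, layer) with layer in
    {compound-target, pp, pf, ff, disease-protein}; ``critical`` holds the
    top-ranked node of each profile; ``ranks`` the 1-based profile ranks of
    top-k members.
    """

    compound: str
    disease: str
    roles: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    critical: set[str] = field(default_factory=set)
    ranks: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.roles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MechanismSubnetwork):
            return NotImplemented
        return (
            self.compound == other.compound
            and self.disease == other.disease
            and self.roles == other.roles
            and self.edges == other.edges
            and self.critical == other.critical
            and self.ranks == other.ranks
        )


def top_k_nodes(
    profile: DiffusionProfile, k: int = 20, exclude: set[str] = frozenset()
) -> list[str]:
    """k highest-probability nodes excluding ``exclude``; ties by node ID.

    ``k`` defaults to 20, large enough to capture the bulk of the
    high-visitation nodes on networks of practical size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return profile.top_nodes(k, exclude=set(exclude))


def extract_mechanism(
    compound_profile: DiffusionProfile,
    disease_profile: DiffusionProfile,
    network: MultiscaleNetwork,
    compound_targets: set[str],
    disease_genes: set[str],
    k: int = 20,
    exclude_seeds: bool = True,
    two_hop_linkage: bool = False,
) -> MechanismSubnetwork:
    """Build the mechanism subnetwork for one compound-disease pair.

    Seeds are excluded from their own top-k list by default so the list
    names influenced nodes rather than inputs. The unlinked-target
    exclusion is a fixpoint of repeated removal and does not depend on
    processing order (the reference set — disease-side and top-k nodes —
    is never itself removed).
    """
    if compound_profile.nodes != disease_profile.nodes:
        raise ValueError("profiles are not on the same network")
    compound = compound_profile.entity
    disease = disease_profile.entity
    if compound == disease:
        raise ValueError("compound and disease profiles must have distinct entity labels")
    targets_on = set(compound_targets) & network.nodes
    disease_on = set(disease_genes) & network.nodes

    top_c = top_k_nodes(
        compound_profile, k, exclude=targets_on if exclude_seeds else set()
    )
    top_d = top_k_nodes(
        disease_profile, k, exclude=disease_on if exclude_seeds else set()
    )
    candidates = set(top_c) | set(top_d) | targets_on | disease_on
    if not candidates & network.nodes:
        raise ValueError("no candidate node lies on the network")

    # linkage reference: disease-side nodes plus both top-k lists
    reference = (set(top_d) | disease_on | set(top_c)) & network.nodes

    def linked(t: str) -> bool:
        nb = network.neighbors(t)
        one_hop = nb["protein"] | nb["function_up"] | nb["function_down"]
        if one_hop & (reference - {t}):
            return True
        if two_hop_linkage:
            for m in one_hop:
                nb2 = network.neighbors(m)
                two_hop = nb2["protein"] | nb2["function_up"] | nb2["function_down"]
                if two_hop & (reference - {t}):
                    return True
        return False

    dropped = {t for t in targets_on if t not in reference and not linked(t)}
    if dropped:
        logger.info("excluded %d unlinked compound targets: %s",
                    len(dropped), ", ".join(sorted(dropped)))
    retained = candidates - dropped

    sub = induce(network, retained)
    mech = MechanismSubnetwork(compound=compound, disease=disease)
    for n in sorted(retained):
        if n in targets_on - dropped:
            role = "compound-target"
        elif n in disease_on:
            role = "disease-protein"
        elif network.node_class(n) is NodeClass.FUNCTION:
            role = "biological-function"
        else:
            role = "intermediate-protein"
        mech.roles[n] = role
    mech.roles[compound] = "compound"
    mech.roles[disease] = "disease"

    for u, v in sub.pp_edges:
        mech.edges.add((u, v, "pp"))
    for p, f in sub.pf_edges:
        mech.edges.add((p, f, "pf"))
    for c, pa in sub.ff_edges:
        mech.edges.add((c, pa, "ff"))
    for t in sorted(targets_on - dropped):
        mech.edges.add((compound, t, "compound-target"))
    for g in sorted(disease_on & retained):
        mech.edges.add((disease, g, "disease-protein"))

    if top_c:
        mech.critical.add(top_c[0])
    if top_d:
        mech.critical.add(top_d[0])
    for rank, n in enumerate(top_c, start=1):
        if n in retained:
            mech.ranks.setdefault(n, rank)
    for rank, n in enumerate(top_d, start=1):
        if n in retained:
            mech.ranks[n] = min(mech.ranks.get(n, rank), rank)
    return mech


def _to_networkx(mech: MechanismSubnetwork) -> nx.MultiDiGraph:
    # multigraph: an anchor edge may run parallel to an induced edge
    g = nx.MultiDiGraph(compound=mech.compound, disease=mech.disease)
    for n in sorted(mech.roles):
        g.add_node(
            n,
            role=mech.roles[n],
            critical=n in mech.critical,
            rank=mech.ranks.get(n, 0),
        )
    for u, v, layer in sorted(mech.edges):
        g.add_edge(u, v, layer=layer)
    return g


def export_subnetwork(
    mech: MechanismSubnetwork, path: str | Path, fmt: str = "graphml"
) -> None:
    """Serialize with role/layer tags; ``fmt`` in {graphml, cytoscape-json, tsv}."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_to_networkx(mech), str(path))
    elif fmt == "cytoscape-json":
        data = nx.cytoscape_data(_to_networkx(mech))
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    elif fmt == "tsv":
        with path.open("w") as fh:
            fh.write("source\ttarget\tlayer\trole_source\trole_target\n")
            for u, v, layer in sorted(mech.edges):
                fh.write(f"{u}\t{v}\t{layer}\t{mech.roles[u]}\t{mech.roles[v]}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_graphml_subnetwork(path: str | Path) -> MechanismSubnetwork:
    """Inverse of the GraphML writer; round-trips to an equal subnetwork."""
    g = nx.read_graphml(str(path))
    mech = MechanismSubnetwork(
        compound=g.graph["compound"], disease=g.graph["disease"]
    )
    for n, data in g.nodes(data=True):
        mech.roles[n] = data["role"]
        if data.get("critical"):
            mech.critical.add(n)
        if data.get("rank"):
            mech.ranks[n] = int(data["rank"])
    for u, v, data in g.edges(data=True):
        mech.edges.add((u, v, data["layer"]))
    return mech
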