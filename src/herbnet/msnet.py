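"""Multiscale network: protein-protein, protein-function, function-hierarchy layers.

The network joins a physical protein-protein interaction layer, a layer of
experimentally supported protein -> biological-function annotations, and a
hierarchy of biological functions. Protein and function nodes are disjoint;
pp and pf edges are undirected, while hierarchy (ff) edges are stored
child -> parent so a walker can distinguish upward from downward moves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from ._tsv import iter_tsv_rows

logger = logging.getLogger(__name__)

__all__ = [
    "NodeClass",
    "MultiscaleNetwork",
    "NetworkValidationError",
    "load_network",
    "validate",
    "subnetwork",
    "write_graphml",
]


class NodeClass(Enum):
    """Class of a network node; every node carries exactly one."""

    PROTEIN = "protein"
    FUNCTION = "function"


class NetworkValidationError(ValueError):
    """Raised when the three layers are mutually inconsistent."""


def _canon(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class MultiscaleNetwork:
    """Typed heterogeneous graph over protein and biological-function nodes.

    Parameters
    ----------
    proteins, functions
        Disjoint node sets.
    pp_edges
        Undirected protein-protein pairs, stored canonically (sorted tuple).
    pf_edges
        Undirected protein-function annotation pairs ``(protein, function)``.
    ff_edges
        Directed hierarchy pairs ``(child_function, parent_function)``.
    """

    proteins: set[str] = field(default_factory=set)
    functions: set[str] = field(default_factory=set)
    pp_edges: set[tuple[str, str]] = field(default_factory=set)
    pf_edges: set[tuple[str, str]] = field(default_factory=set)
    ff_edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._adjacency: dict[str, dict[str, set[str]]] | None = None
        self._node_list: tuple[str, ...] | None = None

    # -- node bookkeeping ---------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return self.proteins | self.functions

    def node_class(self, node: str) -> NodeClass:
        if node in self.proteins:
            return NodeClass.PROTEIN
        if node in self.functions:
            return NodeClass.FUNCTION
        raise KeyError(f"unknown node {node!r}")

    @property
    def node_list(self) -> tuple[str, ...]:
        """Deterministic node order: sorted proteins, then sorted functions."""
        if self._node_list is None:
            self._node_list = tuple(sorted(self.proteins)) + tuple(sorted(self.functions))
        return self._node_list

    @property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.node_list)}

    # -- adjacency partitioned by neighbor class ----------------------------

    def _build_adjacency(self) -> dict[str, dict[str, set[str]]]:
        adj: dict[str, dict[str, set[str]]] = {
            n: {"protein": set(), "function_up": set(), "function_down": set()}
            for n in self.nodes
        }
        for u, v in self.pp_edges:
            adj[u]["protein"].add(v)
            adj[v]["protein"].add(u)
        for p, f in self.pf_edges:
            # from a protein, an annotated function is an "up" move into the
            # function layer; from the function the protein is a plain
            # protein neighbor
            adj[p]["function_up"].add(f)
            adj[f]["protein"].add(p)
        for child, parent in self.ff_edges:
            adj[child]["function_up"].add(parent)
            adj[parent]["function_down"].add(child)
        return adj

    def neighbors(self, node: str) -> dict[str, set[str]]:
        """Neighbors of ``node`` partitioned as protein / function_up / function_down."""
        if self._adjacency is None:
            self._adjacency = self._build_adjacency()
        return self._adjacency[node]

    def degree(self, node: str) -> int:
        nb = self.neighbors(node)
        return len(nb["protein"]) + len(nb["function_up"]) + len(nb["function_down"])

    def _invalidate(self) -> None:
        self._adjacency = None
        self._node_list = None

    # -- mutation (used by the synthetic generator) -------------------------

    def add_pp_edge(self, u: str, v: str) -> None:
        if u == v:
            raise NetworkValidationError(f"pp self-loop {u!r}")
        self.proteins.update((u, v))
        self.pp_edges.add(_canon(u, v))
        self._invalidate()

    def add_pf_edge(self, protein: str, function: str) -> None:
        if protein == function:
            raise NetworkValidationError(f"pf self-loop {protein!r}")
        self.proteins.add(protein)
        self.functions.add(function)
        self.pf_edges.add((protein, function))
        self._invalidate()

    def add_ff_edge(self, child: str, parent: str) -> None:
        self.functions.update((child, parent))
        self.ff_edges.add((child, parent))
        self._invalidate()

    # -- conversion ---------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        """Directed view with ``kind`` node attributes and ``layer`` edge attributes.

        Undirected pp/pf edges appear once in canonical orientation with
        ``directed='false'``; hierarchy edges keep child -> parent direction.
        """
        g = nx.DiGraph()
        for p in sorted(self.proteins):
            g.add_node(p, kind=NodeClass.PROTEIN.value)
        for f in sorted(self.functions):
            g.add_node(f, kind=NodeClass.FUNCTION.value)
        for u, v in sorted(self.pp_edges):
            g.add_edge(u, v, layer="pp", directed="false")
        for p, f in sorted(self.pf_edges):
            g.add_edge(p, f, layer="pf", directed="false")
        for c, pa in sorted(self.ff_edges):
            g.add_edge(c, pa, layer="ff", directed="true")
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiscaleNetwork):
            return NotImplemented
        return (
            self.proteins == other.proteins
            and self.functions == other.functions
            and self.pp_edges == other.pp_edges
            and self.pf_edges == other.pf_edges
            and self.ff_edges == other.ff_edges
        )


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    for lineno, row in iter_tsv_rows(path, min_columns=2):
        pairs.append((row[0], row[1]))
    return pairs


def load_network(
    pp_path: str | Path,
    pf_path: str | Path,
    ff_path: str | Path | None = None,
) -> MultiscaleNetwork:
    """Read the three tab-separated edge layers into a :class:`MultiscaleNetwork`.

    Each file needs two node-ID columns; extra columns are ignored. Duplicate
    rows collapse to one edge, pp/pf self-loops are dropped with a warning,
    and reciprocal hierarchy edges (A->B together with B->A) are collapsed
    keeping the lexicographically smaller child. A pf "function" endpoint
    that also occurs in the protein layer raises :class:`NetworkValidationError`.
    """
    net = MultiscaleNetwork()

    for u, v in _read_pairs(pp_path):
        if u == v:
            logger.warning("dropping pp self-loop %r", u)
            continue
        net.proteins.update((u, v))
        net.pp_edges.add(_canon(u, v))

    pf_pairs = _read_pairs(pf_path)
    conflicts = sorted({f for _, f in pf_pairs if f in net.proteins})
    if conflicts:
        raise NetworkValidationError(
            "class conflict: function endpoints also present in the protein "
            f"layer: {', '.join(conflicts)}"
        )
    for p, f in pf_pairs:
        if p == f:
            logger.warning("dropping pf self-loop %r", p)
            continue
        net.proteins.add(p)
        net.functions.add(f)
        net.pf_edges.add((p, f))

    if ff_path is not None:
        for c, pa in _read_pairs(ff_path):
            if c == pa:
                logger.warning("dropping ff self-loop %r", c)
                continue
            if {c, pa} & net.proteins:
                raise NetworkValidationError(
                    f"class conflict: hierarchy edge ({c!r}, {pa!r}) touches the protein layer"
                )
            if (pa, c) in net.ff_edges:
                logger.warning("reciprocal hierarchy edges %r<->%r collapsed", c, pa)
                if (c, pa) > (pa, c):
                    continue
                net.ff_edges.discard((pa, c))
            net.functions.update((c, pa))
            net.ff_edges.add((c, pa))

    net._invalidate()
    logger.info(
        "loaded multiscale network: %d proteins, %d functions, |pp|=%d |pf|=%d |ff|=%d",
        len(net.proteins), len(net.functions),
        len(net.pp_edges), len(net.pf_edges), len(net.ff_edges),
    )
    return net


def validate(network: MultiscaleNetwork) -> dict:
    """Consistency report: layer counts, isolated nodes, class-consistency verdict.

    Never mutates the network.
    """
    isolated = sorted(n for n in network.nodes if network.degree(n) == 0)
    class_ok = not (network.proteins & network.functions)
    edges_ok = all(
        u in network.proteins and v in network.proteins for u, v in network.pp_edges
    ) and all(
        p in network.proteins and f in network.functions for p, f in network.pf_edges
    ) and all(
        c in network.functions and pa in network.functions for c, pa in network.ff_edges
    )
    # recount the adjacency index against the edge sets
    nb_total = sum(network.degree(n) for n in network.nodes)
    expected = 2 * (len(network.pp_edges) + len(network.pf_edges) + len(network.ff_edges))
    return {
        "n_proteins": len(network.proteins),
        "n_functions": len(network.functions),
        "n_pp": len(network.pp_edges),
        "n_pf": len(network.pf_edges),
        "n_ff": len(network.ff_edges),
        "isolated_nodes": isolated,
        "class_consistent": class_ok and edges_ok,
        "adjacency_consistent": nb_total == expected,
    }


def subnetwork(network: MultiscaleNetwork, nodes: Iterable[str]) -> MultiscaleNetwork:
    """Induced subgraph on ``nodes``, preserving layer labels."""
    keep = set(nodes) & network.nodes
    return MultiscaleNetwork(
        proteins=keep & network.proteins,
        functions=keep & network.functions,
        pp_edges={e for e in network.pp_edges if e[0] in keep and e[1] in keep},
        pf_edges={e for e in network.pf_edges if e[0] in keep and e[1] in keep},
        ff_edges={e for e in network.ff_edges if e[0] in keep and e[1] in keep},
    )


def write_graphml(network: MultiscaleNetwork, path: str | Path,
                  labels: Mapping[str, str] | None = None) -> None:
    """Export to GraphML, optionally attaching display labels."""
    g = network.to_networkx()
    if labels:
        for n, lab in labels.items():
            if n in g:
                g.nodes[n]["label"] = lab
    nx.write_graphml(g, str(path))
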