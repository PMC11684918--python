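"""Transkingdom network container and Cytoscape-style export.

A :class:`TranskingdomNetwork` is a simple undirected graph whose nodes are
ASVs, genes or metabolic phenotypes (each tagged with its fold-change sign
between the treated and untreated groups) and whose edges carry the pooled
Spearman correlation that survived the sign-consistency / significance /
causality filters.

Export writes three plain-text files: a SIF edge list plus node- and
edge-attribute TSVs, ready for Cytoscape or any graph tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["NetworkNode", "NetworkEdge", "TranskingdomNetwork", "write_network", "read_node_attributes"]

NODE_KINDS = ("ASV", "gene", "phenotype")


@dataclass(frozen=True)
class NetworkNode:
    id: str
    kind: str  # one of NODE_KINDS
    fc_sign: int  # +1 / -1, treated vs untreated fold-change direction
    mean_abundance: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.fc_sign not in (-1, 1):
            raise ValueError(f"fc_sign must be +/-1, got {self.fc_sign}")


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    rho_pooled: float
    p_pooled: float
    rho_sign_exp1: int
    rho_sign_exp2: int

    def key(self) -> tuple[str, str]:
        return (self.node_a, self.node_b) if self.node_a <= self.node_b else (self.node_b, self.node_a)


@dataclass
class TranskingdomNetwork:
    nodes: dict[str, NetworkNode] = field(default_factory=dict)
    edges: dict[tuple[str, str], NetworkEdge] = field(default_factory=dict)

    def add_node(self, node: NetworkNode) -> None:
        self.nodes[node.id] = node

    def add_edge(self, edge: NetworkEdge) -> None:
        if edge.node_a == edge.node_b:
            raise ValueError(f"self-edge on {edge.node_a!r}")
        for end in (edge.node_a, edge.node_b):
            if end not in self.nodes:
                raise ValueError(f"edge endpoint {end!r} is not a node")
        self.edges[edge.key()] = edge

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes_of_kind(self, *kinds: str) -> list[str]:
        return [n.id for n in self.nodes.values() if n.kind in kinds]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes.values():
            g.add_node(node.id, kind=node.kind, fc_sign=node.fc_sign, mean_abundance=node.mean_abundance)
        for (a, b), e in self.edges.items():
            g.add_edge(a, b, rho=e.rho_pooled, p=e.p_pooled)
        return g

    def main_component(self) -> set[str]:
        """Largest connected component; ties broken by lexicographically
        smallest member. An edgeless network yields a single-node component."""
        g = self.to_networkx()
        if g.number_of_nodes() == 0:
            return set()
        comps = [set(c) for c in nx.connected_components(g)]
        return max(comps, key=lambda c: (len(c), [-ord(ch) for ch in min(c)]))


def write_network(
    net: TranskingdomNetwork,
    prefix: str | Path,
    topology: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write ``<prefix>.sif``, ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv``.

    ``topology``, if given, is a frame indexed by node id with columns
    ``degree`` and ``bibc``; otherwise degree is computed from the edge set
    and BiBC left empty.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sif_path = prefix.with_suffix(".sif")
    nodes_path = prefix.parent / (prefix.name + ".nodes.tsv")
    edges_path = prefix.parent / (prefix.name + ".edges.tsv")

    with open(sif_path, "w") as fh:
        for (a, b), e in sorted(net.edges.items()):
            rel = "pos" if e.rho_pooled >= 0 else "neg"
            fh.write(f"{a}\t{rel}\t{b}\n")

    g = net.to_networkx()
    rows = []
    for nid in sorted(net.nodes):
        node = net.nodes[nid]
        deg = g.degree(nid)
        bibc = math.nan
        if topology is not None and nid in topology.index:
            deg = int(topology.at[nid, "degree"])
            bibc = float(topology.at[nid, "bibc"])
        rows.append(
            {
                "node_id": nid,
                "kind": node.kind,
                "fc_sign": node.fc_sign,
                "mean_abundance": node.mean_abundance,
                "degree": deg,
                "bibc": bibc,
            }
        )
    pd.DataFrame(
        rows, columns=["node_id", "kind", "fc_sign", "mean_abundance", "degree", "bibc"]
    ).to_csv(nodes_path, sep="\t", index=False)

    erows = [
        {
            "node_a": a,
            "node_b": b,
            "rho": e.rho_pooled,
            "p": e.p_pooled,
            "rho_sign_exp1": e.rho_sign_exp1,
            "rho_sign_exp2": e.rho_sign_exp2,
        }
        for (a, b), e in sorted(net.edges.items())
    ]
    pd.DataFrame(erows, columns=["node_a", "node_b", "rho", "p", "rho_sign_exp1", "rho_sign_exp2"]).to_csv(
        edges_path, sep="\t", index=False
    )
    return {"sif": sif_path, "nodes": nodes_path, "edges": edges_path}


def read_node_attributes(path: str | Path) -> pd.DataFrame:
    """Read back a node-attribute TSV written by :func:`write_network`."""
    return pd.read_csv(path, sep="\t", index_col="node_id")
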