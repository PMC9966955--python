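"""First-neighbor protein–protein interaction subnetworks.

Starting from an undirected interactome (a generic two-column edge list, or
the BioGRID tab3 dialect filtered to physical interactions), the pipeline
takes the significant proteins as seeds, adds every interactor adjacent to a
seed (the first neighbors), and keeps *all* interactome edges among that
node set — the induced subgraph, so neighbor–neighbor edges are retained.
Hubs are ranked by degree within the subnetwork. Gene-symbol matching is
case-insensitive (symbols are upper-cased on ingest); no synonym resolution
is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "Subnetwork",
    "read_edge_list",
    "first_neighbor_network",
    "hub_degrees",
    "export_network",
    "read_graphml",
]

logger = logging.getLogger(__name__)


@dataclass
class Subnetwork:
    """Seeds plus first neighbors with the induced interactome edges."""

    seeds: set[str]
    neighbors: set[str]
    graph: nx.Graph
    seed_regulation: dict[str, str] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def summary(self) -> dict[str, int]:
        return {
            "n_edges": self.n_edges,
            "n_seeds_found": len(self.seeds & self.nodes),
            "n_neighbors": len(self.neighbors),
        }


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def read_edge_list(path: str | Path, dialect: str = "tsv") -> nx.Graph:
    """Read an undirected interactome.

    ``tsv``: whitespace/tab-separated two-column edge list (extra columns
    ignored, ``#`` comment lines skipped). ``biogrid_tab3``: the official
    BioGRID tab3 TSV; uses the two official-symbol columns and keeps only
    rows whose Experimental System Type is ``physical``. Duplicate and
    reversed edges are collapsed; self-loops are dropped with a logged count.
    """
    g = nx.Graph()
    self_loops = 0
    if dialect == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: edge line needs >= 2 columns")
                a, b = _norm(parts[0]), _norm(parts[1])
                if a == b:
                    self_loops += 1
                    continue
                g.add_edge(a, b)
    elif dialect == "biogrid_tab3":
        df = pd.read_csv(path, sep="\t", dtype=str)
        sym_a = "Official Symbol Interactor A"
        sym_b = "Official Symbol Interactor B"
        sys_type = "Experimental System Type"
        missing = {sym_a, sym_b} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing BioGRID tab3 columns {sorted(missing)}")
        if sys_type in df.columns:
            df = df[df[sys_type].str.lower() == "physical"]
        for a, b in zip(df[sym_a], df[sym_b]):
            a, b = _norm(a), _norm(b)
            if a == b:
                self_loops += 1
                continue
            g.add_edge(a, b)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if self_loops:
        logger.info("read_edge_list: dropped %d self-loop rows", self_loops)
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def first_neighbor_network(
    graph: nx.Graph,
    seeds: set[str],
    seed_regulation: Mapping[str, str] | None = None,
) -> Subnetwork:
    """Induced subgraph on the seeds and every node adjacent to a seed.

    Seeds absent from the interactome are retained as isolated nodes so the
    output always contains every query protein.
    """
    if not seeds:
        raise ValueError("seeds must be non-empty")
    seeds = {_norm(s) for s in seeds}
    regulation = {_norm(k): v for k, v in (seed_regulation or {}).items()}

    neighbors: set[str] = set()
    for s in seeds & set(graph.nodes):
        neighbors.update(graph.neighbors(s))
    neighbors -= seeds

    nodeset = seeds | neighbors
    sub = nx.Graph(graph.subgraph(nodeset & set(graph.nodes)))
    sub.add_nodes_from(seeds)  # isolated seeds kept
    for n in sub.nodes:
        sub.nodes[n]["is_seed"] = n in seeds
        sub.nodes[n]["regulation"] = regulation.get(n, "")
    return Subnetwork(seeds=seeds, neighbors=neighbors, graph=sub,
                      seed_regulation=regulation)


def hub_degrees(subnetwork: Subnetwork) -> list[tuple[str, int, bool, str]]:
    """(node, degree, is_seed, regulation), degree-descending, ties lexicographic."""
    rows = [
        (n, subnetwork.graph.degree(n), n in subnetwork.seeds,
         subnetwork.seed_regulation.get(n, ""))
        for n in subnetwork.graph.nodes
    ]
    return sorted(rows, key=lambda r: (-r[1], r[0]))


def export_network(subnetwork: Subnetwork, path: str | Path, format: str = "sif") -> None:
    """Write the subnetwork for external visualization.

    ``sif``: one ``A pp B`` line per edge, isolated nodes as bare lines.
    ``graphml``: full graph with is_seed / regulation node attributes.
    """
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            written = set()
            for a, b in sorted(tuple(sorted(e)) for e in subnetwork.graph.edges):
                fh.write(f"{a} pp {b}\n")
                written.update((a, b))
            for n in sorted(set(subnetwork.graph.nodes) - written):
                fh.write(f"{n}\n")
    elif format == "graphml":
        nx.write_graphml(subnetwork.graph, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_graphml(path: str | Path) -> Subnetwork:
    """Re-import a GraphML export as a Subnetwork (round-trip of export_network)."""
    g = nx.read_graphml(path)
    g = nx.Graph(g)
    seeds = {n for n, d in g.nodes(data=True) if d.get("is_seed")}
    regulation = {n: d["regulation"] for n, d in g.nodes(data=True)
                  if d.get("regulation") and d.get("is_seed")}
    return Subnetwork(seeds=seeds, neighbors=set(g.nodes) - seeds, graph=g,
                      seed_regulation=regulation)
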