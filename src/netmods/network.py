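"""Reference protein–protein interaction (PPI) network.

The search substrate for dense module search is an undirected simple graph
whose nodes are uppercase gene symbols.  Edges carry no direction and no
confidence weight; self-loops and duplicate pairs are dropped at load time.
Interactome flat files (HPRD-style two-column edge lists, SIF) are the
expected on-disk formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "PPINetwork",
    "LoadReport",
    "load_network",
    "neighborhood",
    "merge_modules",
    "write_sif",
    "write_edge_list",
    "write_graphml",
]


@dataclass
class LoadReport:
    """Bookkeeping from :func:`load_network`."""

    n_rows: int = 0
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_rows} rows read, "
            f"{self.n_duplicates_dropped} duplicate edges dropped, "
            f"{self.n_self_loops_dropped} self-loops dropped"
        )


class PPINetwork:
    """Undirected simple graph over uppercase gene symbols.

    Thin wrapper around :class:`networkx.Graph` that enforces the type
    invariants (no self-loops, unique unordered edges, endpoints in the
    node set) and exposes the accessors the search modules need.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = graph if graph is not None else nx.Graph()
        loops = list(nx.selfloop_edges(self._g))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_edges(
        cls, pairs: Iterable[tuple[str, str]], report: LoadReport | None = None
    ) -> "PPINetwork":
        """Build a network from gene-symbol pairs.

        Symbols are uppercased; self-loops are dropped and duplicate
        unordered pairs collapsed, with counts recorded in *report*.
        """
        g = nx.Graph()
        rep = report if report is not None else LoadReport()
        for a, b in pairs:
            rep.n_rows += 1
            a, b = str(a).strip().upper(), str(b).strip().upper()
            if a == b:
                rep.n_self_loops_dropped += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                rep.n_duplicates_dropped += 1
                continue
            g.add_edge(a, b)
        return cls(g)

    # -- accessors ------------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self._g.edges}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, gene: str) -> bool:
        return self._g.has_node(gene)

    def neighbors(self, gene: str) -> set[str]:
        return set(self._g.neighbors(gene))

    def degree(self, gene: str) -> int:
        return self._g.degree(gene)

    def adjacency(self) -> dict[str, set[str]]:
        """Plain dict-of-sets adjacency (fast repeated BFS)."""
        return {n: set(nbrs) for n, nbrs in self._g.adjacency()}

    def induced(self, genes: Iterable[str]) -> "PPINetwork":
        genes = set(genes)
        missing = genes - self.nodes
        if missing:
            raise KeyError(f"genes not in network: {sorted(missing)[:5]}")
        return PPINetwork(nx.Graph(self._g.subgraph(genes)))

    def restricted_to(self, genes: Iterable[str]) -> "PPINetwork":
        """Induced subgraph on ``nodes ∩ genes`` (no error on extras)."""
        keep = self.nodes & set(genes)
        return PPINetwork(nx.Graph(self._g.subgraph(keep)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"PPINetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def load_network(path: str | Path, format: str = "edge_list") -> tuple[PPINetwork, LoadReport]:
    """Load a PPI network from *path*.

    Parameters
    ----------
    path:
        Text file.  ``edge_list``: two or more tab-separated columns, the
        first two being interacting gene symbols (extra columns, e.g. HPRD
        accession numbers, are ignored).  ``sif``: ``source<tab>relation<tab>
        target [target ...]``; a one-field row declares an isolated node.
    format:
        ``"edge_list"`` or ``"sif"``.

    Returns
    -------
    (PPINetwork, LoadReport)
    """
    path = Path(path)
    if format not in ("edge_list", "sif"):
        raise ValueError(f"unknown format: {format!r}")
    text = path.read_text()
    lines = text.splitlines()
    if not any(ln.strip() for ln in lines):
        raise ValueError(f"{path}: empty network file")

    pairs: list[tuple[str, str]] = []
    isolated: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if format == "edge_list":
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 fields, got {len(fields)}")
            pairs.append((fields[0], fields[1]))
        else:  # sif
            if len(fields) == 1:
                isolated.append(fields[0].strip().upper())
            elif len(fields) == 2:
                raise ValueError(
                    f"{path}:{lineno}: SIF row with a relation but no target"
                )
            else:
                src = fields[0]
                for tgt in fields[2:]:
                    pairs.append((src, tgt))
    report = LoadReport()
    net = PPINetwork.from_edges(pairs, report)
    for n in isolated:
        net.graph.add_node(n)
    return net, report


def neighborhood(net: PPINetwork, genes: Iterable[str], d: int) -> set[str]:
    """Genes within shortest-path distance ``d`` of any member of *genes*.

    Returns nodes **outside** *genes* reachable in at most *d* hops; this is
    the candidate pool a module may recruit from during greedy expansion.
    """
    genes = set(genes)
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    unknown = genes - net.nodes
    if unknown:
        raise KeyError(f"genes not in network: {sorted(unknown)[:5]}")
    return neighborhood_adj(net.adjacency(), genes, d)


def neighborhood_adj(adj: dict[str, set[str]], genes: set[str], d: int) -> set[str]:
    """Multi-source BFS variant of :func:`neighborhood` on a dict adjacency."""
    seen = set(genes)
    frontier = set(genes)
    out: set[str] = set()
    for _ in range(d):
        nxt: set[str] = set()
        for u in frontier:
            nxt |= adj[u]
        nxt -= seen
        if not nxt:
            break
        out |= nxt
        seen |= nxt
        frontier = nxt
    return out


def merge_modules(net: PPINetwork, modules: Sequence[Iterable[str]]) -> PPINetwork:
    """Induced subgraph on the union of module gene sets."""
    if len(modules) == 0:
        raise ValueError("merge_modules requires at least one module")
    union: set[str] = set()
    for m in modules:
        union |= set(m)
    return net.induced(union)


# -- export ------------------------------------------------------------


def write_sif(net: PPINetwork, path: str | Path, relation: str = "pp") -> None:
    """Write SIF (Cytoscape-compatible); isolated nodes as bare rows."""
    path = Path(path)
    with path.open("w") as fh:
        covered: set[str] = set()
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
            covered |= {a, b}
        for n in sorted(net.nodes - covered):
            fh.write(f"{n}\n")


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")
        isolated = net.nodes - {g for e in net.edges for g in e}
        if isolated:
            warnings.warn(
                f"{len(isolated)} isolated nodes not representable in edge list",
                stacklevel=2,
            )


def write_graphml(net: PPINetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))
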