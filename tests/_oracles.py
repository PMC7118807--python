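"""Independent brute-force oracles used to cross-check the fast paths.

Everything here recomputes from scratch with networkx primitives and no
caching, deliberately sharing no code with the package's search
implementation.
"""

from __future__ import annotations

import math

import networkx as nx


def naive_neighborhood(graph: nx.Graph, genes: set[str], d: int) -> set[str]:
    """Distance-d neighborhood by per-node shortest-path queries."""
    out = set()
    for node in graph.nodes:
        if node in genes:
            continue
        for m in genes:
            try:
                if nx.shortest_path_length(graph, node, m) <= d:
                    out.add(node)
                    break
            except nx.NetworkXNoPath:
                continue
    return out


def naive_score(graph: nx.Graph, z: dict[str, float], genes: list[str]) -> float:
    return sum(z[g] for g in genes) / math.sqrt(len(genes))


def naive_greedy(
    graph: nx.Graph, z: dict[str, float], seed: str, d: int, r: float
) -> list[str]:
    """Step-by-step greedy simulator: recompute everything each iteration.

    Best-first single-gene recruitment; candidate ties break to the
    lexicographically smallest gene; accept only if the new score beats
    z_m*(1+r) (additive form z_m + |z_m|*r when z_m <= 0).
    """
    genes = [seed]
    while True:
        z_m = naive_score(graph, z, genes)
        best_gene, best_score = None, -math.inf
        for g in sorted(naive_neighborhood(graph, set(genes), d)):
            s = naive_score(graph, z, genes + [g])
            if s > best_score:
                best_gene, best_score = g, s
        if best_gene is None:
            return genes
        bound = z_m * (1 + r) if z_m > 0 else z_m + abs(z_m) * r
        if best_score <= bound:
            return genes
        genes.append(best_gene)


def naive_greedy_from_set(
    graph: nx.Graph, z: dict[str, float], start: list[str], d: int, r: float
) -> list[str]:
    """Greedy expansion started from an explicit gene list (e.g. an edge)."""
    genes = list(start)
    while True:
        z_m = naive_score(graph, z, genes)
        best_gene, best_score = None, -math.inf
        for g in sorted(naive_neighborhood(graph, set(genes), d)):
            s = naive_score(graph, z, genes + [g])
            if s > best_score:
                best_gene, best_score = g, s
        if best_gene is None:
            return genes
        bound = z_m * (1 + r) if z_m > 0 else z_m + abs(z_m) * r
        if best_score <= bound:
            return genes
        genes.append(best_gene)
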