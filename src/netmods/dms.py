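"""Node-weighted greedy dense module search.

Every scored gene in the network seeds a module.  A module grows by
best-first recruitment: among all genes within distance ``d`` of the current
members, the candidate giving the highest new module score is admitted only
if it improves the score by more than the factor ``(1 + r)``; the module is
final when the best candidate fails that test.  The module score is

    Z_m = Σ zᵢ / √k

over the k member z-scores, and module ranking uses the run-normalized
score Z_n = (Z_m − mean) / sd (population sd over all modules of the run).

The multiplicative acceptance rule is ill-posed when Z_m ≤ 0; there the rule
becomes ``Z_{m+1} > Z_m + |Z_m|·r``, which coincides with the multiplicative
rule for positive scores and still demands strict improvement at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .network import PPINetwork, merge_modules, neighborhood_adj
from .scoring import GeneScoreTable

__all__ = [
    "Module",
    "ModuleSet",
    "module_score",
    "dense_module_search",
    "expand_from_seed",
    "normalize_scores",
    "top_k_subnetwork",
    "check_local_maximality",
    "accepts",
]


def module_score(zs: Sequence[float]) -> float:
    """Z_m = Σz / √k for the k member z-scores."""
    k = len(zs)
    if k == 0:
        raise ValueError("module_score requires at least one z-score")
    return float(sum(zs) / math.sqrt(k))


def accepts(current: float, candidate: float, r: float) -> bool:
    """Greedy acceptance rule: candidate score must beat Z_m × (1 + r).

    For non-positive Z_m the equivalent additive form Z_m + |Z_m|·r is used
    (the multiplicative form would invert the inequality's sense).
    """
    if current > 0:
        return candidate > current * (1.0 + r)
    return candidate > current + abs(current) * r


@dataclass
class Module:
    """A module grown from one seed gene.

    ``genes`` preserves insertion order (seed first); ``z_m`` is the raw
    module score and ``z_n`` the run-normalized score, absent until
    :func:`normalize_scores`.  Members are connected in the d-step sense:
    each recruit lies within distance d of an earlier member on the search
    network.  For d >= 2 the induced subgraph may omit linker genes and
    need not itself be connected.
    """

    seed: str
    genes: list[str]
    z_m: float
    z_n: float | None = None

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class ModuleSet:
    modules: list[Module]
    d: int
    r: float
    score_mean: float | None = None
    score_sd: float | None = None

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "module_id": i + 1,
                "seed": m.seed,
                "z_m": m.z_m,
                "z_n": m.z_n if m.z_n is not None else float("nan"),
                "size": m.size,
                "genes": ",".join(m.genes),
            }
            for i, m in enumerate(self.modules)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _search_substrate(
    net: PPINetwork, scores: GeneScoreTable, strict: bool = False
) -> tuple[dict[str, set[str]], dict[str, float]]:
    """Adjacency and node weights restricted to scored network genes.

    Network genes without a score are excluded from the substrate (the
    search needs a weight for every node it may recruit); scored genes
    absent from the network are simply never reachable.
    """
    z = scores.z
    if strict:
        missing = net.nodes - z.keys()
        if missing:
            raise KeyError(f"network genes without a score: {sorted(missing)[:5]}")
    keep = net.nodes & z.keys()
    sub = net.restricted_to(keep)
    return sub.adjacency(), {g: z[g] for g in keep}


def expand_from_seed(
    adj: dict[str, set[str]],
    z: dict[str, float],
    seed: str,
    d: int = 2,
    r: float = 0.1,
    max_iter: int = 1000,
) -> Module:
    """Grow one module from *seed* by best-first greedy recruitment."""
    genes = [seed]
    members = {seed}
    zsum = z[seed]
    zm = zsum  # k = 1
    for _ in range(max_iter):
        candidates = neighborhood_adj(adj, members, d)
        if not candidates:
            break
        sqrt_k1 = math.sqrt(len(genes) + 1)
        best_gene: str | None = None
        best_score = -math.inf
        for g in sorted(candidates):  # lexicographic tie-break: first max wins
            s = (zsum + z[g]) / sqrt_k1
            if s > best_score:
                best_score, best_gene = s, g
        if not accepts(zm, best_score, r):
            break
        genes.append(best_gene)
        members.add(best_gene)
        zsum += z[best_gene]
        zm = best_score
    else:
        warnings.warn(
            f"module from seed {seed} hit max_iter={max_iter} before convergence",
            stacklevel=2,
        )
    return Module(seed=seed, genes=genes, z_m=zm)


def dense_module_search(
    net: PPINetwork,
    scores: GeneScoreTable,
    d: int = 2,
    r: float = 0.1,
    max_iter: int = 1000,
    seeds: Iterable[str] | None = None,
) -> ModuleSet:
    """Run the greedy search from every scored gene (or the given seeds).

    Deterministic: seeds are processed in sorted order and candidate ties
    break lexicographically, so identical inputs give identical output.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if r < 0:
        raise ValueError("r must be >= 0")
    adj, z = _search_substrate(net, scores)
    if seeds is None:
        seed_list = sorted(adj)
    else:
        seed_list = sorted(set(seeds))
        unknown = [s for s in seed_list if s not in adj]
        if unknown:
            raise KeyError(
                f"seed genes missing from the scored network substrate: {unknown[:5]}"
            )
    modules = [expand_from_seed(adj, z, s, d=d, r=r, max_iter=max_iter) for s in seed_list]
    return ModuleSet(modules=modules, d=d, r=r)


def normalize_scores(ms: ModuleSet) -> ModuleSet:
    """Standardize raw module scores: Z_n = (Z_m − mean) / sd (population sd)."""
    if len(ms) < 2:
        raise ValueError("normalization requires at least 2 modules")
    zm = np.array([m.z_m for m in ms.modules], dtype=float)
    mean = float(zm.mean())
    sd = float(zm.std(ddof=0))
    if sd == 0.0:
        raise ValueError("all module scores identical; sd is zero")
    modules = [replace(m, z_n=float((m.z_m - mean) / sd)) for m in ms.modules]
    return ModuleSet(
        modules=modules, d=ms.d, r=ms.r, score_mean=mean, score_sd=sd
    )


class SubnetworkResult(NamedTuple):
    network: PPINetwork
    gene_report: pd.DataFrame
    nominal_fraction: float


def top_k_subnetwork(
    ms: ModuleSet,
    net: PPINetwork,
    scores: GeneScoreTable,
    k: int = 50,
) -> SubnetworkResult:
    """Union of the k best modules by Z_n, with a per-gene report.

    Ties in Z_n break lexicographically by seed gene.  The report lists each
    subnetwork gene's p, z, the number of top-k modules containing it, and a
    nominal-significance flag (p < 0.05); ``nominal_fraction`` is the share
    of subnetwork genes with p < 0.05.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if any(m.z_n is None for m in ms.modules):
        ms = normalize_scores(ms)
    if k > len(ms):
        warnings.warn(
            f"k={k} exceeds the number of modules ({len(ms)}); using all modules",
            stacklevel=2,
        )
        k = len(ms)
    ranked = sorted(ms.modules, key=lambda m: (-m.z_n, m.seed))
    top = ranked[:k]
    subnet = merge_modules(net, [m.gene_set for m in top])
    counts: dict[str, int] = {}
    for m in top:
        for g in m.gene_set:
            counts[g] = counts.get(g, 0) + 1
    p, z = scores.p, scores.z
    rows = []
    for g in sorted(subnet.nodes):
        pg = p.get(g, float("nan"))
        rows.append(
            {
                "gene": g,
                "p": pg,
                "z": z.get(g, float("nan")),
                "n_modules": counts.get(g, 0),
                "nominal": bool(pg < 0.05),
            }
        )
    report = pd.DataFrame(rows)
    frac = float(report["nominal"].mean()) if len(report) else 0.0
    return SubnetworkResult(network=subnet, gene_report=report, nominal_fraction=frac)


def check_local_maximality(
    net: PPINetwork,
    scores: GeneScoreTable,
    module: Module,
    d: int,
    r: float,
) -> bool:
    """Post-hoc certificate: no neighborhood gene passes the acceptance rule.

    Recomputed naively (fresh BFS, fresh scores) so it is independent of any
    caching inside the search.
    """
    adj, z = _search_substrate(net, scores)
    members = set(module.genes)
    zm = module_score([z[g] for g in module.genes])
    if not math.isclose(zm, module.z_m, rel_tol=0, abs_tol=1e-9):
        return False
    for g in sorted(neighborhood_adj(adj, members, d)):
        cand = module_score([z[x] for x in module.genes] + [z[g]])
        if accepts(zm, cand, r):
            return False
    return True
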