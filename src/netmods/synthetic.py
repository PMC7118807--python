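"""Synthetic study data with planted signal for end-to-end testing.

Real inputs to this pipeline — GWAS summary statistics, an interactome and
a case/control expression matrix — are typically controlled-access.  This
module generates stand-ins with known ground truth so every stage can be
exercised and parameter recovery measured:

* a connected preferential-attachment network whose heavy-tailed degree
  distribution mimics a curated interactome;
* two gene-score datasets (discovery and evaluation) that share one planted
  connected module: planted genes draw z ~ N(node_effect, noise_sd)
  independently in each dataset, background genes z ~ N(0, 1), emulating
  two cohorts that share causal genes but not noise;
* a case/control expression matrix in which the planted genes are
  equicorrelated at ``r_case`` within cases and ``r_control`` within
  controls (edge signal), optionally with a mean shift in cases.

What this deliberately does not model: linkage disequilibrium, allele
frequencies, genotyping platforms, probe-level artifacts beyond a thin
probe-splitting wrapper, or expression covariance outside the planted set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coexpr import ExpressionMatrix
from .network import PPINetwork
from .scoring import GeneScoreTable, P_CEIL, P_FLOOR

__all__ = [
    "SyntheticTruth",
    "generate_network",
    "generate_dual_gwas",
    "generate_expression",
    "split_to_probes",
    "generate_gene_sets",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset; suffices to regenerate it."""

    planted_genes: list[str]
    node_effect: float
    edge_effect: float
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def generate_network(n: int, attach: int = 3, seed: int = 0) -> PPINetwork:
    """Connected preferential-attachment graph over genes G0001…G{n}.

    Construction: a complete clique on ``attach + 1`` founder nodes, then
    each new node attaches to ``attach`` distinct existing nodes chosen with
    probability proportional to current degree.  Edge count is therefore
    exactly C(attach+1, 2) + attach · (n − attach − 1) and the graph is
    connected by construction.  Deterministic given *seed*.
    """
    if attach < 1:
        raise ValueError("attach must be >= 1")
    if n < attach + 1:
        raise ValueError(f"need n >= attach + 1, got n={n}, attach={attach}")
    rng = np.random.default_rng(seed)
    g = nx.complete_graph(attach + 1)
    degrees = np.zeros(n)
    degrees[: attach + 1] = attach
    for new in range(attach + 1, n):
        targets: set[int] = set()
        while len(targets) < attach:
            probs = degrees[:new] / degrees[:new].sum()
            pick = int(rng.choice(new, p=probs))
            targets.add(pick)
        for t in targets:
            g.add_edge(new, t)
            degrees[t] += 1
        degrees[new] = attach
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in range(n)})
    return PPINetwork(g)


def _random_walk_plant(net: PPINetwork, size: int, rng: np.random.Generator) -> list[str]:
    """Connected planted gene set grown by a random walk from a random start."""
    nodes = sorted(net.nodes)
    adj = net.adjacency()
    start = nodes[rng.integers(len(nodes))]
    planted = [start]
    members = {start}
    current = start
    stalled = 0
    while len(planted) < size:
        nbrs = sorted(adj[current])
        current = nbrs[rng.integers(len(nbrs))]
        if current not in members:
            members.add(current)
            planted.append(current)
            stalled = 0
        else:
            stalled += 1
            if stalled > 50 * size:  # jump to escape a trapping region
                current = planted[rng.integers(len(planted))]
                stalled = 0
    return planted


def generate_dual_gwas(
    net: PPINetwork,
    plant_size: int,
    node_effect: float,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[GeneScoreTable, GeneScoreTable, SyntheticTruth]:
    """Two gene-score datasets sharing one planted connected module.

    Planted genes draw z ~ N(node_effect, noise_sd) independently in each
    dataset; background genes draw z ~ N(0, 1).  p = 1 − Φ(z).  The shared
    planted set with independent per-dataset noise is what makes
    dual-dataset consistency selection meaningful.
    """
    if plant_size < 2:
        raise ValueError("plant_size must be >= 2")
    if plant_size > net.n_nodes:
        raise ValueError(
            f"plant_size {plant_size} exceeds network size {net.n_nodes}"
        )
    rng = np.random.default_rng(seed)
    planted = _random_walk_plant(net, plant_size, rng)
    planted_set = set(planted)
    genes = sorted(net.nodes)
    tables = []
    for _ in range(2):
        z = rng.standard_normal(len(genes))
        for i, g in enumerate(genes):
            if g in planted_set:
                z[i] = node_effect + noise_sd * rng.standard_normal()
        p = np.clip(stats.norm.sf(z), P_FLOOR, P_CEIL)
        tables.append(GeneScoreTable.from_pvalues(pd.Series(p, index=pd.Index(genes))))
    truth = SyntheticTruth(
        planted_genes=sorted(planted),
        node_effect=node_effect,
        edge_effect=0.0,
        seed=seed,
        params={"plant_size": plant_size, "noise_sd": noise_sd, "n": net.n_nodes},
    )
    return tables[0], tables[1], truth


def generate_expression(
    net: PPINetwork,
    truth: SyntheticTruth,
    n_case: int = 7,
    n_control: int = 6,
    r_case: float = 0.8,
    r_control: float = 0.0,
    de_shift: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Case/control expression with a planted co-expression shift.

    Planted genes are drawn from an equicorrelated multivariate normal
    (pairwise correlation ``r_case`` within cases, ``r_control`` within
    controls); background genes are independent N(0, 1).  ``de_shift`` adds
    a log2-scale mean shift to planted genes in cases.  The default 7
    cases / 6 controls matches a small clinical expression study; the
    Fisher-z edge weighting needs at least 4 samples per condition.
    """
    if n_case < 4 or n_control < 4:
        raise ValueError("need >= 4 samples per condition")
    planted = [g for g in truth.planted_genes if net.has_node(g)]
    k = len(planted)
    for r in (r_case, r_control):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1, got {r}")
        if k > 1 and r < -1.0 / (k - 1):
            raise ValueError(
                f"equicorrelation {r} is not positive definite for {k} genes"
            )
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes)
    samples = [f"CASE{i+1:02d}" for i in range(n_case)] + [
        f"CTRL{i+1:02d}" for i in range(n_control)
    ]
    condition = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples
    )
    values = pd.DataFrame(
        rng.standard_normal((len(genes), len(samples))), index=genes, columns=samples
    )
    pidx = [genes.index(g) for g in planted]
    for r, cols in ((r_case, range(n_case)), (r_control, range(n_case, n_case + n_control))):
        cov = np.full((k, k), r) + (1.0 - r) * np.eye(k)
        chol = np.linalg.cholesky(cov)
        draws = chol @ rng.standard_normal((k, len(list(cols))))
        values.iloc[pidx, list(cols)] = draws
    if de_shift:
        values.iloc[pidx, : n_case] += de_shift
    mat = ExpressionMatrix(values=values, condition=condition)
    truth.edge_effect = r_case - r_control
    truth.params.update(
        {
            "n_case": n_case,
            "n_control": n_control,
            "r_case": r_case,
            "r_control": r_control,
            "de_shift": de_shift,
            "expression_seed": seed,
        }
    )
    return mat


def split_to_probes(
    mat: ExpressionMatrix,
    seed: int = 0,
    max_probes: int = 3,
    probe_sd: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expand each gene row into 1–``max_probes`` probe rows.

    Each probe is the gene profile plus an independent N(0, probe_sd) offset
    per entry; averaging a gene's probes recovers the gene profile up to
    that noise.  Exists to exercise probe collapsing.
    """
    rng = np.random.default_rng(seed)
    rows, probe_map = [], {}
    index = []
    for g in mat.genes:
        n_probes = int(rng.integers(1, max_probes + 1))
        base = mat.values.loc[g].to_numpy(float)
        for j in range(n_probes):
            pid = f"{g}_at{j + 1}"
            probe_map[pid] = g
            rows.append(base + probe_sd * rng.standard_normal(base.size))
            index.append(pid)
    probe_df = pd.DataFrame(rows, index=index, columns=mat.samples)
    return probe_df, probe_map


def generate_gene_sets(
    net: PPINetwork,
    truth: SyntheticTruth,
    n_sets: int = 20,
    size_range: tuple[int, int] = (10, 60),
    seed: int = 0,
) -> dict[str, tuple[str, frozenset[str]]]:
    """Random gene sets plus one set built around the planted module.

    Set ``PLANTED`` contains the planted genes padded with random background
    genes to the minimum size, so enrichment of recovered genes against the
    collection has a known positive control.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes)
    lo, hi = size_range
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    planted = list(truth.planted_genes)
    pad = [g for g in genes if g not in set(planted)]
    rng.shuffle(pad)
    planted_set = planted + pad[: max(0, lo - len(planted))]
    sets["PLANTED"] = ("planted module plus padding", frozenset(planted_set))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"RAND{i + 1:03d}"] = (
            f"random set {i + 1}",
            frozenset(genes[j] for j in members),
        )
    return sets
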