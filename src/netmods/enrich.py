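"""Over-representation analysis of module genes against GMT collections.

Standard hypergeometric enrichment: for a query gene list and a named gene
set, the p-value is the upper tail P(X ≥ overlap) of a hypergeometric draw
with population |universe|, success count |set ∩ universe| and draw count
|query ∩ universe|.  Sets are filtered by universe-restricted size before
testing and the Bonferroni correction runs over the tested sets only.
A redundancy-reduction step clusters significant sets by Jaccard similarity
(affinity propagation, with a greedy fallback) and flags one exemplar per
cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "enrich",
    "reduce_redundancy",
    "summarize_overlap",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, tuple[str, frozenset[str]]]  # id -> (description, members)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(g.upper() for g in self.universe)
        self.sets = {
            sid: (desc, frozenset(g.upper() for g in members))
            for sid, (desc, members) in self.sets.items()
        }

    def restricted(self, sid: str) -> frozenset[str]:
        """Members of *sid* inside the universe."""
        return self.sets[sid][1] & self.universe

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set id, description, tab-separated member genes).

    When *universe* is omitted, the union of all set members is used as the
    background; pass the scored-gene list to test against the genes the
    analysis could actually have selected.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT row needs id, description, >=1 gene")
        sid, desc, members = fields[0], fields[1], fields[2:]
        sets[sid] = (desc, frozenset(m.upper() for m in members if m))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    if universe is None:
        uni: frozenset[str] = frozenset().union(*(m for _, m in sets.values()))
    else:
        uni = frozenset(g.upper() for g in universe)
    return GeneSetCollection(sets=sets, universe=uni)


def enrich(
    query: Iterable[str],
    coll: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of *query* in each collection set.

    Sets whose universe-restricted size falls outside [min_size, max_size]
    are excluded before testing (and from the Bonferroni denominator).
    Returns rows sorted by p with columns set_id, set_name, pathway_size,
    overlap, p, p_adj, significant.
    """
    if not coll.universe:
        raise ValueError("empty universe")
    q = frozenset(g.upper() for g in query) & coll.universe
    if not q:
        raise ValueError("query has no genes in the universe")
    M, N = len(coll.universe), len(q)
    rows = []
    for sid, (desc, _) in coll.sets.items():
        members = coll.restricted(sid)
        K = len(members)
        if K < min_size or K > max_size:
            continue
        ov = len(members & q)
        # upper tail P(X >= ov); sf(ov-1) to include the observed count
        p = float(stats.hypergeom.sf(ov - 1, M, K, N))
        rows.append(
            {
                "set_id": sid,
                "set_name": desc,
                "pathway_size": K,
                "overlap": ov,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows, columns=["set_id", "set_name", "pathway_size", "overlap", "p"]
    )
    n_tested = len(df)
    if n_tested:
        df["p_adj"] = np.minimum(1.0, df["p"] * n_tested)
        df["significant"] = df["p_adj"] <= alpha
        df = df.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def _jaccard_matrix(sets: Sequence[frozenset[str]]) -> np.ndarray:
    n = len(sets)
    sim = np.eye(n)
    for i, j in combinations(range(n), 2):
        union = len(sets[i] | sets[j])
        sim[i, j] = sim[j, i] = len(sets[i] & sets[j]) / union if union else 0.0
    return sim


def _greedy_clusters(sim: np.ndarray, order: np.ndarray, cut: float = 0.5) -> np.ndarray:
    """Best-p-first fallback: attach each set to the first exemplar with
    Jaccard >= *cut*, else open a new cluster."""
    labels = np.full(len(order), -1)
    exemplars: list[int] = []
    for idx in order:
        for c, ex in enumerate(exemplars):
            if sim[idx, ex] >= cut:
                labels[idx] = c
                break
        else:
            labels[idx] = len(exemplars)
            exemplars.append(idx)
    return labels


def reduce_redundancy(
    rows: pd.DataFrame,
    coll: GeneSetCollection,
    damping: float = 0.9,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Cluster significant enrichment rows by gene-set Jaccard similarity.

    Affinity propagation (damping 0.9, preference = median similarity) on
    the universe-restricted member sets; if it fails to converge the greedy
    best-p-first clustering at Jaccard ≥ 0.5 is used instead.  All rows are
    preserved; significant rows gain a ``cluster`` id and one ``exemplar``
    flag per cluster (the lowest-p member).
    """
    out = rows.copy()
    out["cluster"] = -1
    out["exemplar"] = False
    sig_idx = out.index[out.get("significant", pd.Series(False, index=out.index))]
    if len(sig_idx) == 0:
        return out
    if len(sig_idx) == 1:
        out.loc[sig_idx, "cluster"] = 0
        out.loc[sig_idx, "exemplar"] = True
        return out
    members = [coll.restricted(out.loc[i, "set_id"]) for i in sig_idx]
    sim = _jaccard_matrix(members)
    labels = None
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap = AffinityPropagation(
                affinity="precomputed",
                damping=damping,
                max_iter=max_iter,
                preference=float(np.median(sim)),
                random_state=0,
            ).fit(sim)
            if ap.labels_ is not None and (ap.labels_ >= 0).all():
                labels = ap.labels_
        except ConvergenceWarning:
            labels = None
    if labels is None:
        order = np.argsort(out.loc[sig_idx, "p"].to_numpy(), kind="mergesort")
        labels = _greedy_clusters(sim, order)
    out.loc[sig_idx, "cluster"] = labels
    for c in np.unique(labels):
        cluster_rows = [i for i, lab in zip(sig_idx, labels) if lab == c]
        best = min(cluster_rows, key=lambda i: (out.loc[i, "p"], out.loc[i, "set_id"]))
        out.loc[best, "exemplar"] = True
    return out


def summarize_overlap(named_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Venn-partition counts for 2–3 named gene sets.

    Returns one row per non-empty membership pattern (e.g. genes only in A,
    genes in A and B but not C, ...) plus one ``total`` row per set.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("summarize_overlap takes 2 or 3 sets")
    sets = {n: frozenset(g.upper() for g in named_sets[n]) for n in names}
    rows = []
    for mask in range(1, 2 ** len(names)):
        inside = [n for i, n in enumerate(names) if mask >> i & 1]
        outside = [n for n in names if n not in inside]
        region = frozenset.intersection(*(sets[n] for n in inside))
        for n in outside:
            region -= sets[n]
        rows.append(
            {
                "region": "&".join(inside),
                "kind": "exclusive",
                "count": len(region),
            }
        )
    for n in names:
        rows.append({"region": n, "kind": "total", "count": len(sets[n])})
    return pd.DataFrame(rows, columns=["region", "kind", "count"])
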