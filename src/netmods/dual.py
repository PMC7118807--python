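"""Discovery/evaluation module selection across two GWAS datasets.

Modules found in a discovery dataset are re-scored with a second,
independent evaluation dataset; modules scoring highly in both are called
consistent.  This guards against modules driven by dataset-specific noise:
a true disease module should carry signal in both cohorts.  The procedure
is one-directional by default (discovery → evaluation); the reverse
direction can be run explicitly by swapping the datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dms import Module, ModuleSet, module_score
from .scoring import GeneScoreTable

__all__ = [
    "DualScoredModule",
    "evaluate_modules",
    "select_consistent",
    "score_correlation",
]


@dataclass
class DualScoredModule:
    module: Module
    z_m_disc: float
    z_n_disc: float
    z_m_eval: float
    z_n_eval: float | None = None


def evaluate_modules(
    ms: ModuleSet,
    eval_scores: GeneScoreTable,
    strict: bool = True,
) -> list[DualScoredModule]:
    """Re-score discovery modules with evaluation-dataset z-scores.

    ``z_m_eval`` applies the module-score formula to the same gene set using
    evaluation z-scores; ``z_n_eval`` standardizes those raw scores across
    all evaluated modules (population sd).  In strict mode a module gene
    missing from the evaluation table raises; in lenient mode the module is
    dropped with a warning.
    """
    if any(m.z_n is None for m in ms.modules):
        raise ValueError("discovery modules must be normalized first (z_n missing)")
    z_eval = eval_scores.z
    dual: list[DualScoredModule] = []
    for m in ms.modules:
        missing = [g for g in m.genes if g not in z_eval]
        if missing:
            if strict:
                raise KeyError(
                    f"module seeded at {m.seed} has genes absent from the "
                    f"evaluation scores: {missing[:5]}"
                )
            warnings.warn(
                f"dropping module seeded at {m.seed}: "
                f"{len(missing)} genes lack evaluation scores",
                stacklevel=2,
            )
            continue
        zme = module_score([z_eval[g] for g in m.genes])
        dual.append(
            DualScoredModule(module=m, z_m_disc=m.z_m, z_n_disc=m.z_n, z_m_eval=zme)
        )
    if not dual:
        return dual
    zs = np.array([d.z_m_eval for d in dual], dtype=float)
    sd = float(zs.std(ddof=0))
    if sd == 0.0:
        raise ValueError("evaluation module scores are all identical; cannot normalize")
    mean = float(zs.mean())
    for dm in dual:
        dm.z_n_eval = float((dm.z_m_eval - mean) / sd)
    return dual


@dataclass
class ConsistentSelection:
    modules: ModuleSet
    gene_report: pd.DataFrame
    nominal_fraction_disc: float


def select_consistent(
    dual: Sequence[DualScoredModule],
    disc_scores: GeneScoreTable | None = None,
    eval_scores: GeneScoreTable | None = None,
    disc_quantile: float = 0.99,
    eval_threshold: float = 1.64,
) -> ConsistentSelection:
    """Keep modules significant in both datasets.

    A module passes when its discovery Z_n is at or above the
    *disc_quantile* quantile of the discovery Z_n distribution (default: top
    1%) **and** its evaluation Z_n is at least *eval_threshold* (default
    1.64, the one-sided normal 0.05 cut).  Returns the selected modules plus
    a per-gene report over their union: p in each dataset, the number of
    selected modules containing the gene, and the fraction of union genes
    nominally significant (p < 0.05) in the discovery set.
    """
    if len(dual) == 0:
        raise ValueError("no dual-scored modules supplied")
    zn_disc = np.array([d.z_n_disc for d in dual], dtype=float)
    cut = float(np.quantile(zn_disc, disc_quantile))
    kept = [
        d
        for d in dual
        if d.z_n_disc >= cut and d.z_n_eval is not None and d.z_n_eval >= eval_threshold
    ]
    if not kept:
        warnings.warn("no module passed both consistency thresholds", stacklevel=2)
    src = dual[0].module
    counts: dict[str, int] = {}
    for d in kept:
        for g in d.module.gene_set:
            counts[g] = counts.get(g, 0) + 1
    p_disc = disc_scores.p if disc_scores is not None else {}
    p_eval = eval_scores.p if eval_scores is not None else {}
    rows = [
        {
            "gene": g,
            "p_disc": p_disc.get(g, float("nan")),
            "p_eval": p_eval.get(g, float("nan")),
            "n_modules": n,
        }
        for g, n in sorted(counts.items())
    ]
    report = pd.DataFrame(rows, columns=["gene", "p_disc", "p_eval", "n_modules"])
    if len(report) and disc_scores is not None:
        frac = float((report["p_disc"] < 0.05).mean())
    else:
        frac = 0.0
    # d/r metadata is inherited from whichever search produced the modules
    ms = ModuleSet(modules=[d.module for d in kept], d=0, r=0.0)
    return ConsistentSelection(modules=ms, gene_report=report, nominal_fraction_disc=frac)


def score_correlation(dual: Sequence[DualScoredModule]) -> float:
    """Pearson correlation of raw module scores across the two datasets.

    A positive correlation indicates the discovery modules carry replicable
    signal in the evaluation cohort; its absence is a reason to swap (or
    distrust) the discovery/evaluation roles.
    """
    if len(dual) < 3:
        raise ValueError("score correlation requires at least 3 modules")
    x = np.array([d.z_m_disc for d in dual], dtype=float)
    y = np.array([d.z_m_eval for d in dual], dtype=float)
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("zero variance in module scores; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)
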