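"""Case/control expression handling and differential co-expression weights.

The edge weight for the edge-weighted search measures how strongly the
co-expression of an interacting gene pair changes between case and control
samples: Pearson correlations are computed within each condition, mapped
through Fisher's z-transform, and their difference standardized by the
usual two-sample Fisher-z standard error

    z_raw = (atanh(r_case) − atanh(r_control)) / sqrt(1/(n_case−3) + 1/(n_control−3)).

Because a correlation gain and a correlation loss are equally interesting,
the search consumes w = |z_raw| standardized across edges (mean 0, sd 1)
and shifted so min w = 0, i.e. non-negative weights.

Expression values are assumed to be normalized log2-scale intensities;
probe-level matrices are collapsed to genes by averaging a gene's probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .network import PPINetwork

__all__ = [
    "ExpressionMatrix",
    "EdgeWeightTable",
    "read_expression",
    "collapse_probes",
    "differential_expression",
    "edge_weight",
    "fisher_z_difference",
]

CONDITIONS = ("case", "control")
R_CLIP = 0.999999


@dataclass
class ExpressionMatrix:
    """Gene × sample log2-scale expression with case/control labels."""

    values: pd.DataFrame  # index genes, columns sample ids
    condition: pd.Series  # sample id -> "case" | "control"

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).str.upper()
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()[:5]
            raise ValueError(f"duplicate gene symbols: {dupes}")
        self.condition = self.condition.reindex(self.values.columns)
        if self.condition.isna().any():
            missing = self.condition[self.condition.isna()].index.tolist()[:5]
            raise ValueError(f"samples without condition label: {missing}")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return list(self.condition[self.condition == condition].index)

    def n_of(self, condition: str) -> int:
        return int((self.condition == condition).sum())

    def submatrix(self, condition: str) -> pd.DataFrame:
        return self.values[self.samples_of(condition)]

    def check_scale(self, band: float = 2.0) -> bool:
        """Warn if per-sample medians spread more than *band* log2 units.

        A wide spread suggests the matrix was not normalized upstream.
        """
        med = self.values.median(axis=0)
        spread = float(med.max() - med.min())
        if spread > band:
            warnings.warn(
                f"per-sample medians spread {spread:.2f} log2 units (> {band}); "
                "expression may not be normalized",
                stacklevel=2,
            )
            return False
        return True

    def to_tsv(self, path: str | Path, condition_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)
        if condition_path is not None:
            self.condition.rename("condition").rename_axis("sample").reset_index().to_csv(
                condition_path, sep="\t", index=False
            )


def read_expression(path: str | Path, condition_path: str | Path) -> ExpressionMatrix:
    """Load expression TSV (first column gene id) + sample-condition TSV."""
    values = pd.read_csv(path, sep="\t")
    values = values.set_index(values.columns[0])
    values.index.name = None
    cond = pd.read_csv(condition_path, sep="\t")
    condition = pd.Series(
        cond.iloc[:, 1].astype(str).values, index=cond.iloc[:, 0].astype(str)
    )
    return ExpressionMatrix(values=values, condition=condition)


def collapse_probes(
    probe_values: pd.DataFrame,
    probe_map: Mapping[str, str],
    condition: pd.Series,
) -> ExpressionMatrix:
    """Average a gene's probe rows into one gene row.

    Probes absent from *probe_map* are dropped (count logged via warning).
    """
    mapped = [p for p in probe_values.index if p in probe_map]
    n_unmapped = len(probe_values) - len(mapped)
    if n_unmapped:
        warnings.warn(f"dropping {n_unmapped} unmapped probes", stacklevel=2)
    if not mapped:
        raise ValueError("no probe maps to a gene; nothing to collapse")
    sub = probe_values.loc[mapped]
    genes = pd.Index([str(probe_map[p]).upper() for p in mapped], name="gene")
    collapsed = sub.groupby(genes).mean()
    return ExpressionMatrix(values=collapsed, condition=condition)


def differential_expression(mat: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene log2 fold change and Welch-test p-value (case vs control).

    log2FC is the difference of condition means on the log2-scale matrix.
    Flags: ``de`` for p < 0.05, ``two_fold`` for |log2FC| > 1 (strict).
    """
    for c in CONDITIONS:
        if mat.n_of(c) < 2:
            raise ValueError(f"need >= 2 {c} samples for differential expression")
    case = mat.submatrix("case").to_numpy(float)
    ctrl = mat.submatrix("control").to_numpy(float)
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).pvalue
    df = pd.DataFrame(
        {
            "gene": mat.genes,
            "log2fc": log2fc,
            "p": p,
            "de": p < 0.05,
            "two_fold": np.abs(log2fc) > 1.0,
        }
    )
    return df


def fisher_z_difference(
    r_case: float | np.ndarray,
    r_control: float | np.ndarray,
    n_case: int,
    n_control: int,
):
    """Fisher z statistic for the difference of two Pearson correlations."""
    if n_case - 3 <= 0 or n_control - 3 <= 0:
        raise ValueError("Fisher z test needs more than 3 samples per condition")
    rc = np.clip(np.asarray(r_case, dtype=float), -R_CLIP, R_CLIP)
    rk = np.clip(np.asarray(r_control, dtype=float), -R_CLIP, R_CLIP)
    se = np.sqrt(1.0 / (n_case - 3) + 1.0 / (n_control - 3))
    out = (np.arctanh(rc) - np.arctanh(rk)) / se
    if np.isscalar(r_case) and np.isscalar(r_control):
        return float(out)
    return out


class EdgeWeightTable:
    """Per-edge differential co-expression weights.

    Backed by a DataFrame with columns gene_a, gene_b, r_case, r_control,
    z_raw, w (gene_a < gene_b lexicographically).
    """

    COLUMNS = ("gene_a", "gene_b", "r_case", "r_control", "z_raw", "w")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"edge weight table missing columns: {sorted(missing)}")
        self.df = df[list(self.COLUMNS)].reset_index(drop=True)
        self._wmap: dict[frozenset[str], float] | None = None

    @property
    def w(self) -> dict[frozenset[str], float]:
        if self._wmap is None:
            self._wmap = {
                frozenset((a, b)): float(w)
                for a, b, w in zip(self.df["gene_a"], self.df["gene_b"], self.df["w"])
            }
        return self._wmap

    @property
    def edges(self) -> set[frozenset[str]]:
        return set(self.w)

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EdgeWeightTable":
        return cls(pd.read_csv(path, sep="\t"))


def edge_weight(mat: ExpressionMatrix, net: PPINetwork) -> EdgeWeightTable:
    """Differential co-expression weight for every network edge in *mat*.

    Edges whose endpoints are both expressed get within-condition Pearson
    correlations, the Fisher-z difference statistic ``z_raw``, and the
    non-negative search weight ``w`` (standardized |z_raw|, min shifted to
    0).  Edges touching a zero-variance gene are dropped with a warning;
    edges with an endpoint missing from the matrix are skipped.
    """
    n_case, n_ctrl = mat.n_of("case"), mat.n_of("control")
    for c, n in (("case", n_case), ("control", n_ctrl)):
        if n < 4:
            raise ValueError(f"need >= 4 {c} samples for edge weights, got {n}")
    genes = [g for g in mat.genes if net.has_node(g)]
    gene_idx = {g: i for i, g in enumerate(genes)}
    edges = sorted(
        (min(a, b), max(a, b))
        for e in net.edges
        for a, b in [tuple(e)]
        if a in gene_idx and b in gene_idx
    )
    if not edges:
        raise ValueError("no network edge has both endpoints in the expression matrix")

    case = mat.submatrix("case").loc[genes].to_numpy(float)
    ctrl = mat.submatrix("control").loc[genes].to_numpy(float)
    var_case = case.var(axis=1)
    var_ctrl = ctrl.var(axis=1)
    degenerate = {
        genes[i] for i in range(len(genes)) if var_case[i] == 0 or var_ctrl[i] == 0
    }
    if degenerate:
        warnings.warn(
            f"dropping edges touching {len(degenerate)} zero-variance genes",
            stacklevel=2,
        )
        edges = [(a, b) for a, b in edges if a not in degenerate and b not in degenerate]
        if not edges:
            raise ValueError("all edges touch zero-variance genes")

    rc_mat = np.corrcoef(case)
    rk_mat = np.corrcoef(ctrl)
    ia = np.array([gene_idx[a] for a, _ in edges])
    ib = np.array([gene_idx[b] for _, b in edges])
    r_case = rc_mat[ia, ib]
    r_control = rk_mat[ia, ib]
    z_raw = fisher_z_difference(r_case, r_control, n_case, n_ctrl)
    absz = np.abs(z_raw)
    sd = absz.std(ddof=0)
    if sd == 0.0:
        w = np.zeros_like(absz)
    else:
        w = (absz - absz.mean()) / sd
        w = w - w.min()
    df = pd.DataFrame(
        {
            "gene_a": [a for a, _ in edges],
            "gene_b": [b for _, b in edges],
            "r_case": r_case,
            "r_control": r_control,
            "z_raw": z_raw,
            "w": w,
        }
    )
    return EdgeWeightTable(df)
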