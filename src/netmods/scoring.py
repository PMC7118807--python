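"""Gene-level association scores from SNP-level GWAS p-values.

SNPs are assigned to a gene when they fall in the gene body or within a
symmetric flanking window (default 50 kb on each side).  Per-gene p-values
are obtained from the mapped SNP p-values with a simple combiner (Šidák on
the minimum, or Fisher's method) and transformed to z-scores with the
inverse normal transform z = Φ⁻¹(1 − p), so small p-values become large
positive node weights.  An extreme-signal capping step floors outlier
p-values so a handful of genome-wide-significant genes cannot dominate every
module found by the greedy search.

The combiners here are deliberately simple stand-ins for LD-aware gene
tests: they ignore linkage disequilibrium between SNPs.  When gene-level
p-values from an LD-aware tool are available, load them directly with
:func:`read_gene_scores` / :meth:`GeneScoreTable.from_pvalues`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneScoreTable",
    "read_snp_associations",
    "read_gene_annotations",
    "read_gene_scores",
    "map_snps_to_genes",
    "combine_snp_pvalues",
    "pvalue_to_z",
    "z_to_pvalue",
    "cap_extreme_genes",
    "bonferroni_threshold",
]

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


def _clip_p(p):
    return np.clip(p, P_FLOOR, P_CEIL)


def pvalue_to_z(p):
    """Inverse normal transform z = Φ⁻¹(1 − p); strictly decreasing in p.

    Accepts a scalar or array with every element in the open interval (0,1).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("p-values must lie strictly in (0, 1)")
    z = stats.norm.isf(arr)
    return float(z) if np.isscalar(p) else z


def z_to_pvalue(z):
    """Upper-tail p = 1 − Φ(z); inverse of :func:`pvalue_to_z`."""
    p = stats.norm.sf(np.asarray(z, dtype=float))
    return float(p) if np.isscalar(z) else p


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Per-gene genome-wide significance bound alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    return alpha / n_genes


class GeneScoreTable:
    """Per-gene association scores: p-value, z-score, SNP count, cap flag.

    Backed by a DataFrame indexed by gene symbol with columns
    ``p``, ``z``, ``n_snps``, ``capped``.  The invariant
    ``z == Φ⁻¹(1 − p)`` holds for every row.
    """

    COLUMNS = ("p", "z", "n_snps", "capped")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()[:5]
            raise ValueError(f"duplicate genes in score table: {dupes}")
        p = df["p"].to_numpy(float)
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("gene p-values must lie strictly in (0, 1)")
        self.df = df[list(self.COLUMNS)].copy()
        self._zmap: dict[str, float] | None = None

    @classmethod
    def from_pvalues(
        cls,
        pvalues: Mapping[str, float] | pd.Series,
        n_snps: Mapping[str, int] | pd.Series | None = None,
    ) -> "GeneScoreTable":
        s = pd.Series(dict(pvalues)) if not isinstance(pvalues, pd.Series) else pvalues
        p = _clip_p(s.to_numpy(float))
        df = pd.DataFrame(
            {
                "p": p,
                "z": stats.norm.isf(p),
                "n_snps": 0,
                "capped": False,
            },
            index=s.index.str.upper(),
        )
        if n_snps is not None:
            ns = pd.Series(dict(n_snps)) if not isinstance(n_snps, pd.Series) else n_snps
            ns.index = ns.index.str.upper()
            df["n_snps"] = ns.reindex(df.index).fillna(0).astype(int)
        return cls(df)

    # -- accessors ------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene: str) -> bool:
        return gene in self.df.index

    @property
    def z(self) -> dict[str, float]:
        """Gene → z-score mapping (cached; this is the search's node weight)."""
        if self._zmap is None:
            self._zmap = self.df["z"].to_dict()
        return self._zmap

    @property
    def p(self) -> dict[str, float]:
        return self.df["p"].to_dict()

    # -- i/o ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneScoreTable":
        df = pd.read_csv(path, sep="\t")
        df["gene"] = df["gene"].str.upper()
        df = df.set_index("gene")
        df.index.name = None
        if "z" not in df.columns:
            df["z"] = stats.norm.isf(_clip_p(df["p"].to_numpy(float)))
        if "n_snps" not in df.columns:
            df["n_snps"] = 0
        if "capped" not in df.columns:
            df["capped"] = False
        df["capped"] = df["capped"].astype(bool)
        return cls(df)


def read_gene_scores(path: str | Path) -> GeneScoreTable:
    """Load precomputed gene-level scores (TSV with ``gene`` and ``p``)."""
    return GeneScoreTable.from_tsv(path)


def read_snp_associations(
    path: str | Path, colmap: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read SNP association results: TSV with header (snp, chrom, pos, p).

    *colmap* renames source columns, e.g. ``{"SNP": "snp", "CHR": "chrom",
    "BP": "pos", "P": "p"}`` for plink association output.
    """
    df = pd.read_csv(path, sep="\t")
    if colmap:
        df = df.rename(columns=dict(colmap))
    required = {"snp", "chrom", "pos", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    df = df[["snp", "chrom", "pos", "p"]].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        raise ValueError("SNP positions must be >= 1 (1-based)")
    p = df["p"].to_numpy(float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("SNP p-values must lie in (0, 1]")
    return df


def read_gene_annotations(path: str | Path, zero_based: bool = False) -> pd.DataFrame:
    """Read gene annotations: TSV (chrom, start, end, gene, strand).

    Coordinates are 1-based inclusive by default; pass ``zero_based=True``
    for 0-based half-open BED input (converted on load).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "strand"],
        comment="#",
    )
    df["chrom"] = df["chrom"].astype(str)
    df["gene"] = df["gene"].astype(str).str.upper()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if zero_based:
        df["start"] = df["start"] + 1  # half-open end becomes inclusive as-is
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]]["gene"].tolist()[:5]
        raise ValueError(f"start > end for genes: {bad}")
    return df


def map_snps_to_genes(
    snps: pd.DataFrame, annot: pd.DataFrame, flank: int = 50_000
) -> dict[str, pd.DataFrame]:
    """Assign SNPs to genes within the gene body ± *flank* bp.

    A SNP maps to gene g iff the chromosome matches and
    ``start − flank <= pos <= end + flank`` (boundaries inclusive).  A SNP
    may map to several genes; genes with no mapped SNP are absent from the
    result.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    mapping: dict[str, pd.DataFrame] = {}
    if len(snps) == 0 or len(annot) == 0:
        return mapping
    by_chrom = {
        chrom: grp.sort_values("pos").reset_index(drop=True)
        for chrom, grp in snps.groupby("chrom")
    }
    for row in annot.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, row.start - flank, side="left")
        hi = np.searchsorted(pos, row.end + flank, side="right")
        if hi > lo:
            mapping[row.gene] = grp.iloc[lo:hi].reset_index(drop=True)
    return mapping


def combine_snp_pvalues(
    mapping: Mapping[str, pd.DataFrame], method: str = "sidak_min"
) -> GeneScoreTable:
    """Collapse mapped SNP p-values to one gene-level p-value.

    ``sidak_min``: p = 1 − (1 − min pᵢ)^m, the Šidák-corrected minimum over
    the m mapped SNPs.  ``fisher``: X = −2 Σ ln pᵢ referred to χ² with 2m
    degrees of freedom.  Both ignore LD between SNPs (see module docstring).
    Results are clipped to [1e−300, 1 − 1e−16] before the z transform.
    """
    if method not in ("sidak_min", "fisher"):
        raise ValueError(f"unknown combination method: {method!r}")
    pvals: dict[str, float] = {}
    n_snps: dict[str, int] = {}
    for gene, snp_df in mapping.items():
        p = np.asarray(snp_df["p"], dtype=float)
        if p.size == 0:
            raise ValueError(f"gene {gene} has an empty SNP list")
        m = p.size
        if method == "sidak_min":
            combined = 1.0 - (1.0 - p.min()) ** m
        else:
            x = -2.0 * np.sum(np.log(p))
            combined = stats.chi2.sf(x, df=2 * m)
        pvals[gene] = float(_clip_p(combined))
        n_snps[gene] = int(m)
    return GeneScoreTable.from_pvalues(pvals, n_snps)


def cap_extreme_genes(
    table: GeneScoreTable,
    strategy: str = "floor_to_min_remaining",
    threshold: float | None = None,
) -> GeneScoreTable:
    """Tame genome-wide-significant outlier genes before module search.

    Genes with p below *threshold* (default: the Bonferroni bound
    0.05 / number of scored genes) either have their p-value floored to the
    smallest p among the remaining genes (``floor_to_min_remaining``, the
    default) or are removed (``drop``).  Without this step a single extreme
    gene tends to appear in nearly every module.  Floored rows are flagged
    ``capped`` and their z-scores recomputed.
    """
    if strategy not in ("floor_to_min_remaining", "drop"):
        raise ValueError(f"unknown capping strategy: {strategy!r}")
    if threshold is None:
        threshold = bonferroni_threshold(len(table))
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    df = table.df.copy()
    below = df["p"] < threshold
    if not below.any():
        return GeneScoreTable(df)
    if strategy == "drop":
        return GeneScoreTable(df.loc[~below])
    remaining = df.loc[~below, "p"]
    if remaining.empty:
        raise ValueError("all genes fall below the capping threshold; floor undefined")
    floor = float(remaining.min())
    df.loc[below, "p"] = floor
    df.loc[below, "capped"] = True
    df.loc[below, "z"] = stats.norm.isf(floor)
    return GeneScoreTable(df)
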