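"""Stage orchestration with config, seeding, and a provenance manifest.

Stages (dependency order): ``score`` → ``dms`` → ``dual`` → ``ew`` →
``enrich``.  Each stage reads only files, writes only its own outputs, and
records them in a JSON manifest with input checksums, the effective
parameters and the package version, so identical inputs and seeds reproduce
identical outputs.  All randomness flows from one top-level seed, expanded
per stage by hashing the stage name, so rerunning a single stage is stable.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .coexpr import edge_weight, differential_expression, read_expression
from .dms import dense_module_search, normalize_scores, top_k_subnetwork
from .dual import evaluate_modules, select_consistent, score_correlation
from .enrich import enrich as _enrich, read_gmt, reduce_redundancy
from .ewdms import (
    auto_lambda,
    ew_dense_module_search,
    modules_to_tsv,
    permutation_significance,
)
from .network import load_network, write_graphml, write_sif
from .scoring import (
    cap_extreme_genes,
    combine_snp_pvalues,
    map_snps_to_genes,
    read_gene_annotations,
    read_gene_scores,
    read_snp_associations,
)

STAGES = ("score", "dms", "dual", "ew", "enrich")

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "STAGES"]


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run.

    Unset paths disable the stages that need them; every parameter has a
    recorded default and the effective config is serialized next to the
    outputs.
    """

    out_dir: str = "netmods_out"
    network: str | None = None
    network_format: str = "edge_list"
    snps: str | None = None
    annotations: str | None = None
    gene_scores: str | None = None       # precomputed discovery gene p-values
    gene_scores_eval: str | None = None  # evaluation dataset
    expression: str | None = None
    conditions: str | None = None
    gmt: str | None = None
    combine_method: str = "sidak_min"
    flank: int = 50_000
    cap_strategy: str = "floor_to_min_remaining"
    d: int = 2
    r: float = 0.1
    top_k: int = 50
    disc_quantile: float = 0.99
    eval_z: float = 1.64
    lam: float = 0.5
    auto_lam: bool = False
    max_size: int = 10
    n_perm: int = 1000
    p_perm_cut: float = 0.05
    min_set_size: int = 10
    max_set_size: int = 500
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat ``key = value`` config file; '#' starts a comment."""
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        defaults = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for key, value in asdict(self).items():
                if value is None:  # unset paths: omit, keep the default
                    continue
                fh.write(f"{key} = {value}\n")


def stage_seed(base: int, stage: str) -> int:
    """Per-stage seed: base mixed with a stage-name hash, kept below 2^31."""
    return (int(base) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages: Iterable[str] | None = None) -> dict:
    """Run the selected stages in dependency order; return the manifest."""
    selected = list(stages) if stages is not None else list(STAGES)
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    selected = [s for s in STAGES if s in selected]

    # upfront validation: every selected stage's inputs must exist
    needed: dict[str, list[str | None]] = {
        "score": [config.network, config.snps or config.gene_scores],
        "dms": [config.network],
        "dual": [config.network, config.gene_scores_eval],
        "ew": [config.network, config.expression, config.conditions],
        "enrich": [config.network, config.gmt],
    }
    for stage in selected:
        for item in needed[stage]:
            if item is None:
                raise FileNotFoundError(f"stage {stage!r}: required input not configured")
            if not Path(item).exists():
                raise FileNotFoundError(f"stage {stage!r}: missing input {item}")
    if "score" in selected and config.snps and not config.annotations:
        raise FileNotFoundError("SNP input requires gene annotations")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.txt")
    manifest: dict = {"version": __version__, "stages": {}, "inputs": {}, "params": asdict(config)}
    for p in [config.network, config.snps, config.annotations, config.gene_scores,
              config.gene_scores_eval, config.expression, config.conditions, config.gmt]:
        if p and Path(p).exists():
            manifest["inputs"][p] = _sha256(Path(p))

    net, _ = load_network(config.network, format=config.network_format)
    scores = None
    modules = None
    selection_genes: list[str] | None = None
    ew_genes: list[str] | None = None

    def _record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(f): _sha256(f) for f in files},
            "seed": stage_seed(config.seed, stage),
        }

    if "score" in selected or {"dms", "dual", "ew", "enrich"} & set(selected):
        if config.gene_scores:
            scores = read_gene_scores(config.gene_scores)
        else:
            snps = read_snp_associations(config.snps)
            annot = read_gene_annotations(config.annotations)
            mapping = map_snps_to_genes(snps, annot, flank=config.flank)
            scores = combine_snp_pvalues(mapping, method=config.combine_method)
        scores = cap_extreme_genes(scores, strategy=config.cap_strategy)
        if "score" in selected:
            f = out / "gene_scores.tsv"
            scores.to_tsv(f)
            _record("score", [f])

    if "dms" in selected or "dual" in selected:
        ms = normalize_scores(
            dense_module_search(net, scores, d=config.d, r=config.r)
        )
        modules = ms
        if "dms" in selected:
            f_mod = out / "modules.tsv"
            ms.to_tsv(f_mod)
            result = top_k_subnetwork(ms, net, scores, k=config.top_k)
            f_sif = out / "subnetwork.sif"
            f_gml = out / "subnetwork.graphml"
            f_rep = out / "subnetwork_genes.tsv"
            write_sif(result.network, f_sif)
            write_graphml(result.network, f_gml)
            result.gene_report.to_csv(f_rep, sep="\t", index=False)
            _record("dms", [f_mod, f_sif, f_gml, f_rep])

    if "dual" in selected:
        eval_scores = cap_extreme_genes(
            read_gene_scores(config.gene_scores_eval), strategy=config.cap_strategy
        )
        dual = evaluate_modules(modules, eval_scores, strict=False)
        sel = select_consistent(
            dual,
            disc_scores=scores,
            eval_scores=eval_scores,
            disc_quantile=config.disc_quantile,
            eval_threshold=config.eval_z,
        )
        selection_genes = list(sel.gene_report["gene"])
        f_dual = out / "dual_modules.tsv"
        pd.DataFrame(
            [
                {
                    "seed": d.module.seed,
                    "size": d.module.size,
                    "z_m_disc": d.z_m_disc,
                    "z_n_disc": d.z_n_disc,
                    "z_m_eval": d.z_m_eval,
                    "z_n_eval": d.z_n_eval,
                    "genes": ",".join(d.module.genes),
                }
                for d in dual
            ]
        ).to_csv(f_dual, sep="\t", index=False)
        f_genes = out / "consistent_genes.tsv"
        sel.gene_report.to_csv(f_genes, sep="\t", index=False)
        f_corr = out / "dual_correlation.txt"
        try:
            corr = score_correlation(dual)
            f_corr.write_text(f"pearson_r\t{corr:.6f}\n")
        except ValueError:
            f_corr.write_text("pearson_r\tNA\n")
        _record("dual", [f_dual, f_genes, f_corr])

    if "ew" in selected:
        mat = read_expression(config.expression, config.conditions)
        mat.check_scale()
        ewt = edge_weight(mat, net)
        f_ew = out / "edge_weights.tsv"
        ewt.to_tsv(f_ew)
        f_de = out / "differential_expression.tsv"
        differential_expression(mat).to_csv(f_de, sep="\t", index=False)
        lam = auto_lambda(scores, ewt) if config.auto_lam else config.lam
        ew_modules = ew_dense_module_search(
            net, scores, ewt, lam=lam, d=config.d, r=config.r, max_size=config.max_size
        )
        ew_modules = permutation_significance(
            ew_modules,
            net,
            scores,
            ewt,
            lam=lam,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "ew"),
        )
        f_mod = out / "ew_modules.tsv"
        modules_to_tsv(ew_modules, f_mod)
        ew_genes = sorted(
            {g for m in ew_modules if m.p_perm < config.p_perm_cut for g in m.genes}
        )
        f_genes = out / "ew_genes.tsv"
        pd.DataFrame({"gene": ew_genes}).to_csv(f_genes, sep="\t", index=False)
        manifest["stages"]["ew"] = {
            "outputs": {str(f): _sha256(f) for f in [f_ew, f_de, f_mod, f_genes]},
            "seed": stage_seed(config.seed, "ew"),
            "lambda": lam,
        }

    if "enrich" in selected:
        coll = read_gmt(config.gmt, universe=scores.genes)
        query = ew_genes if ew_genes else selection_genes
        if not query:
            # fall back to the top-k subnetwork genes from a fresh search
            ms = modules or normalize_scores(
                dense_module_search(net, scores, d=config.d, r=config.r)
            )
            query = sorted(top_k_subnetwork(ms, net, scores, k=config.top_k).network.nodes)
        rows = _enrich(
            query,
            coll,
            min_size=config.min_set_size,
            max_size=config.max_set_size,
            alpha=config.alpha,
        )
        rows = reduce_redundancy(rows, coll)
        f = out / "enrichment.tsv"
        rows.to_csv(f, sep="\t", index=False)
        _record("enrich", [f])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
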