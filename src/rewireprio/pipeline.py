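"""End-to-end per-stage pipeline and run manifest.

For each developmental stage: MV screen -> candidate genes -> per-condition
GCC matrices -> rewiring network -> HMRF posteriors -> top-k list; then the
stage-wise top lists are stacked into a multilayer network with overlap and
layer statistics.  Every artifact is a plain TSV (plus GEXF for graphs) so
stages are independently inspectable and testable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gcc import GCCConfig, build_wgdcn, export_network, gcc_by_condition
from .hmrf import HMRFConfig, discrimination_ability, icm_fit, rank_genes
from .io import (
    ExpressionMatrix,
    binary_response,
    deg_table,
    load_expression,
    load_metadata,
    partition_stages,
    stage_submatrix,
    validate_metadata,
)
from .multilayer import (
    assemble_multilayer,
    jaccard_overlap,
    layer_stats_table,
    layer_subnetwork,
)
from .mv import filter_candidates, mv_screen_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full pipeline configuration with the method's default parameters."""

    expr: str = ""
    meta: str = ""
    outdir: str = "rewireprio_out"
    orientation: str = "genes_by_samples"
    log2_transform: bool = False
    impute_missing: bool = False
    weeks_per_stage: int = 3
    first_week: int = 3
    stages: list | None = None          # None = all stages in the partition
    k_perms: int = 5000
    alpha: float = 0.01
    rho: float = 0.5
    r0: float = 0.9
    delta: float = 0.95
    tau1: float = 0.01
    tau2: float = 0.01
    h_quantile: float = 0.90
    init_alpha: float = 0.005
    mu_bar: float = 2.0
    a: float = 1.0
    g: float = 1.0
    d: float = 1.0
    max_sweeps: int = 100
    top_k: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        return cls(**raw)

    def gcc_config(self) -> GCCConfig:
        return GCCConfig(rho=self.rho, r0=self.r0, delta=self.delta)

    def hmrf_config(self) -> HMRFConfig:
        return HMRFConfig(
            tau1=self.tau1, tau2=self.tau2, delta=self.delta,
            h_quantile=self.h_quantile, init_alpha=self.init_alpha,
            filter_alpha=self.alpha, mu_bar=self.mu_bar, a=self.a, g=self.g,
            d=self.d, max_sweeps=self.max_sweeps,
        )


def run_stage(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    cfg: PipelineConfig,
    stage: int,
    outdir: Path | None = None,
):
    """Run screening, network construction and prioritization for one stage.

    Returns a dict with the per-stage artifacts (mv table, candidate list,
    network, HMRF state, ranking) and summary counts.
    """
    y = binary_response(meta, expr.sample_ids)
    mv_res = mv_screen_matrix(
        expr.values, y, expr.gene_ids,
        k_perms=cfg.k_perms, alpha=cfg.alpha, seed=cfg.seed + stage,
    )
    candidates = filter_candidates(mv_res, cfg.alpha)
    if not candidates:
        raise RuntimeError(f"stage {stage}: MV screen retained no candidate genes")
    sub = expr.subset_genes(candidates)
    gcc_t, gcc_c = gcc_by_condition(sub, y, cfg.gcc_config())
    net = build_wgdcn(gcc_t, gcc_c, candidates, cfg.gcc_config(), stage=stage)
    p_mv = mv_res.set_index("gene_id").loc[candidates, "p_mv"].to_numpy()
    state = icm_fit(net, p_mv, cfg.hmrf_config(), gene_ids=candidates, k_perms=cfg.k_perms)
    ranking = rank_genes(state, top_k=len(candidates))
    degs = deg_table(expr, meta)
    result = {
        "stage": stage,
        "n_samples": expr.n_samples,
        "mv": mv_res,
        "candidates": candidates,
        "network": net,
        "state": state,
        "ranking": ranking,
        "deg": degs,
        "top_genes": ranking.head(cfg.top_k)["gene_id"].tolist(),
        "discrimination_mv": discrimination_ability(p_mv),
        "discrimination_hmrf": discrimination_ability(state.posterior),
    }
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        mv_res.to_csv(outdir / f"stage{stage}_mv.tsv", sep="\t", index=False)
        export_network(net, outdir / f"stage{stage}_wgdcn.tsv", fmt="edgelist")
        export_network(net, outdir / f"stage{stage}_wgdcn.gexf", fmt="gexf")
        ranking.to_csv(outdir / f"stage{stage}_ranking.tsv", sep="\t", index=False)
        degs.to_csv(outdir / f"stage{stage}_deg.tsv", sep="\t", index=False)
    return result


def run_pipeline(cfg: PipelineConfig, expr: ExpressionMatrix | None = None,
                 meta: pd.DataFrame | None = None) -> dict:
    """Run all requested stages plus the multilayer summary.

    ``expr``/``meta`` may be passed in-memory; otherwise they are loaded
    from the configured paths.  Writes per-stage TSVs, multilayer outputs
    and a run manifest under ``cfg.outdir``; returns the in-memory results.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if expr is None:
        expr = load_expression(cfg.expr, orientation=cfg.orientation,
                               impute_missing=cfg.impute_missing,
                               log2_transform=cfg.log2_transform)
    if meta is None:
        meta = load_metadata(cfg.meta)
    meta = validate_metadata(meta, expr)
    part = partition_stages(meta, cfg.weeks_per_stage, cfg.first_week)
    stage_ids = cfg.stages if cfg.stages else part.stage_indices
    results = {}
    for stage in stage_ids:
        sub_expr, sub_meta = stage_submatrix(expr, meta, part, stage)
        try:
            results[stage] = run_stage(sub_expr, sub_meta, cfg, stage, outdir=outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    summary: dict = {}
    if len(results) >= 2:
        layers = [
            (s, layer_subnetwork(r["network"], r["top_genes"]))
            for s, r in sorted(results.items())
        ]
        mln = assemble_multilayer(layers)
        stats = layer_stats_table(mln)
        overlap = jaccard_overlap([r["top_genes"] for _, r in sorted(results.items())])
        stats.to_csv(outdir / "layer_stats.tsv", sep="\t", index=False)
        pd.DataFrame(
            overlap,
            index=[f"stage{s}" for s in sorted(results)],
            columns=[f"stage{s}" for s in sorted(results)],
        ).to_csv(outdir / "overlap.tsv", sep="\t")
        import networkx as nx

        nx.write_gexf(mln.to_networkx(), outdir / "multilayer.gexf")
        summary["multilayer"] = mln
        summary["layer_stats"] = stats
        summary["overlap"] = overlap

    manifest = {
        "package": "rewireprio",
        "version": __version__,
        "numpy": np.__version__,
        "config": dataclasses.asdict(cfg),
        "stages": {
            str(s): {
                "n_samples": int(r["n_samples"]),
                "n_genes_screened": int(r["mv"].shape[0]),
                "n_candidates": len(r["candidates"]),
                "n_edges": r["network"].number_of_edges(),
                "h": r["state"].h,
                "n_sweeps": r["state"].n_sweeps,
                "converged": bool(r["state"].converged),
                "discrimination_mv": r["discrimination_mv"],
                "discrimination_hmrf": r["discrimination_hmrf"],
                "top_genes": r["top_genes"],
            }
            for s, r in results.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %d stage(s), outputs in %s", len(results), outdir)
    return {"stages": results, **summary, "manifest": manifest}
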