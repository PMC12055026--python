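"""Configuration-driven orchestration of the full gradient pipeline.

Stages (in order): ``simulate`` -> ``msn`` -> ``gradients`` -> ``stats``
-> ``graph`` -> ``cognition`` -> ``pls``.  Each stage reads its inputs
from the run directory and writes its artifacts back there, so stages
can be re-run individually; a stage whose inputs are missing aborts with
the name of the stage that must run first.  A single master seed
deterministically derives every stage seed, and a YAML manifest with
per-artifact SHA-256 hashes makes reruns auditable: the same
configuration and seed reproduce every artifact bit for bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import cognition as cog
from . import gradients as grad
from . import graph as gph
from . import io
from . import msn as msn_mod
from . import stats as st
from . import synthetic as syn
from . import transcriptomics as tx

__all__ = ["RunConfig", "StageError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "msn", "gradients", "stats", "graph", "cognition", "pls")


class StageError(RuntimeError):
    """A pipeline stage failed or its inputs are missing."""


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # synthetic cohort
    n_regions: int = 400
    n_ad: int = 60
    n_nc: int = 60
    n_sites: int = 2
    effect_sd: float = 0.5
    site_offset_sd: float = 0.1
    profile_amplitude: float = 2.5
    # synthetic expression
    n_genes: int = 2000
    n_planted: int = 50
    planted_corr: float = 0.9
    # synthetic cognition (weights over Von Economo classes; class means
    # are standardized across subjects before coupling)
    cognition_coupling: dict[str, float] = Field(
        default_factory=lambda: {"Asso1": 1.0, "Prim_sens": -0.5}
    )
    cognition_noise_sd: float = 1.0
    # gradients
    density: float = 0.10
    n_components: int = 10
    alpha: float = 0.5
    diffusion_time: float = 0.0
    # group statistics
    covariates: tuple[str, ...] = ("age", "sex", "education")
    # graph topology
    graph_density: float = 0.10
    graph_binarize: bool = False
    # prediction
    svr_n_outer: int = 5
    svr_n_inner: int = 5
    svr_c_grid: tuple[float, ...] = cog.DEFAULT_C_GRID
    svr_eps_grid: tuple[float, ...] = cog.DEFAULT_EPS_GRID
    svr_n_perm: int = 1000
    # transcriptomics
    pls_n_perm: int = 10000
    pls_n_boot: int = 10000
    gene_q_threshold: float = 0.001
    # control
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        unknown = [s for s in v if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid stages are {list(STAGES)}")
        return v


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([master, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _require(out: Path, stage: str, filename: str, producer: str) -> Path:
    path = out / filename
    if not path.exists():
        raise StageError(
            f"stage '{stage}' requires {filename}; run the '{producer}' stage first"
        )
    return path


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    rng = np.random.default_rng(_stage_seed(cfg.seed, "simulate"))
    effect_map = rng.normal(0.0, cfg.effect_sd, cfg.n_regions)
    site_offsets = rng.normal(0.0, cfg.site_offset_sd, (cfg.n_sites, 5))
    spec = syn.CohortSpec(
        n_regions=cfg.n_regions,
        n_per_group=(cfg.n_ad, cfg.n_nc),
        n_sites=cfg.n_sites,
        effect_map=effect_map,
        site_offsets=site_offsets,
        profile_amplitude=cfg.profile_amplitude,
        seed=int(rng.integers(0, 2**31)),
    )
    cohort = syn.generate_cohort(spec)
    io.write_cohort(cohort, out)
    atlas = syn.generate_atlas(cfg.n_regions)
    io.write_tsv(atlas, out / "atlas.tsv")
    io.write_tsv(
        pd.DataFrame({"region_id": cohort.region_ids, "effect": effect_map}),
        out / "effect_map.tsv",
    )


def _stage_msn(cfg: RunConfig, out: Path) -> None:
    features = io.read_array(_require(out, "msn", "features.npy", "simulate"))
    msns = msn_mod.msn_stack(features)
    io.write_array(msns, out / "msns.npy")
    meta = io.read_tsv(out / "metadata.tsv")
    strength = np.stack([msn_mod.regional_strength(m) for m in msns])
    frame = pd.DataFrame(
        strength,
        index=meta["subject_id"],
        columns=[f"region_{i + 1:04d}" for i in range(cfg.n_regions)],
    )
    io.write_tsv(frame.reset_index(), out / "strength.tsv")


def _stage_gradients(cfg: RunConfig, out: Path) -> None:
    msns = io.read_array(_require(out, "gradients", "msns.npy", "msn"))
    meta = io.read_tsv(out / "metadata.tsv")
    aligned, template = grad.cohort_gradients(
        msns,
        density=cfg.density,
        k=cfg.n_components,
        alpha=cfg.alpha,
        t=cfg.diffusion_time,
    )
    comps = np.stack([g.components for g in aligned])
    io.write_array(comps, out / "gradients.npy")
    io.write_array(template.components, out / "template.npy")
    regions = [f"region_{i + 1:04d}" for i in range(cfg.n_regions)]
    g1 = pd.DataFrame(comps[:, :, 0], index=meta["subject_id"], columns=regions)
    io.write_tsv(g1.reset_index(), out / "gradient1.tsv")
    lam = pd.DataFrame(
        np.stack([g.lambdas for g in aligned]),
        index=meta["subject_id"],
        columns=[f"lambda_{j + 1}" for j in range(cfg.n_components)],
    )
    io.write_tsv(lam.reset_index(), out / "lambdas.tsv")
    gm = pd.DataFrame(
        [vars(grad.gradient_global_metrics(g)) for g in aligned],
        index=meta["subject_id"],
    )
    io.write_tsv(gm.reset_index(), out / "gradient_global_metrics.tsv")


def _stage_stats(cfg: RunConfig, out: Path) -> None:
    _require(out, "stats", "gradient1.tsv", "gradients")
    g1 = io.read_tsv(out / "gradient1.tsv", index_col="subject_id")
    meta = io.read_tsv(out / "metadata.tsv")
    atlas = io.read_tsv(out / "atlas.tsv")
    values = st.combat_harmonize(g1.to_numpy(), meta, covariates=("group",) + tuple(cfg.covariates))
    harmonized = pd.DataFrame(values, index=g1.index, columns=g1.columns)
    io.write_tsv(harmonized.reset_index(), out / "gradient1_harmonized.tsv")
    stat_map = st.glm_contrast(harmonized, meta, covariates=tuple(cfg.covariates))
    io.write_tsv(
        stat_map.rename_axis("region_id").reset_index(), out / "stat_map.tsv"
    )
    is_ad = meta["group"].to_numpy() == "AD"
    d, p = st.ks_compare(
        harmonized.loc[is_ad].to_numpy().ravel(),
        harmonized.loc[~is_ad].to_numpy().ravel(),
    )
    io.write_tsv(pd.DataFrame({"D": [d], "p": [p]}), out / "ks_global.tsv")
    for level, name in (("class", "class_summary"), ("network", "network_summary")):
        lc = st.label_contrast(
            harmonized, meta, atlas, level=level, covariates=tuple(cfg.covariates)
        )
        summary = lc.glm.join(lc.ks, lsuffix="_glm", rsuffix="_ks")
        io.write_tsv(summary.rename_axis("label").reset_index(), out / f"{name}.tsv")
        if level == "class":
            io.write_tsv(
                lc.means.set_axis(g1.index).reset_index(), out / "class_means.tsv"
            )


def _stage_graph(cfg: RunConfig, out: Path) -> None:
    msns = io.read_array(_require(out, "graph", "msns.npy", "msn"))
    meta = io.read_tsv(out / "metadata.tsv")
    topo = gph.topology_metrics(
        msns, density=cfg.graph_density, binarize=cfg.graph_binarize
    )
    topo.insert(0, "subject_id", meta["subject_id"])
    io.write_tsv(topo, out / "topology.tsv")
    contrasts = st.glm_contrast(
        topo[["clustering_coefficient", "avg_path_length"]],
        meta,
        covariates=tuple(cfg.covariates),
    )
    io.write_tsv(
        contrasts.rename_axis("metric").reset_index(), out / "topology_contrast.tsv"
    )
    gm = io.read_tsv(_require(out, "graph", "gradient_global_metrics.tsv", "gradients"))
    is_ad = meta["group"].to_numpy() == "AD"
    rows = []
    for metric in ("clustering_coefficient", "avg_path_length"):
        r, p = gph.topology_gradient_correlation(
            topo.loc[is_ad, metric].to_numpy(),
            gm.loc[is_ad, "explained_ratio_1"].to_numpy(),
        )
        rows.append({"metric": metric, "against": "explained_ratio_1", "r": r, "p": p})
    io.write_tsv(pd.DataFrame(rows), out / "topology_gradient_corr.tsv")


def _stage_cognition(cfg: RunConfig, out: Path) -> None:
    _require(out, "cognition", "class_means.tsv", "stats")
    class_means = io.read_tsv(out / "class_means.tsv", index_col="subject_id")
    meta = io.read_tsv(out / "metadata.tsv")
    seed = _stage_seed(cfg.seed, "cognition")
    standardized = (class_means - class_means.mean()) / class_means.std(ddof=1)
    scores, weights = syn.generate_cognition(
        standardized, cfg.cognition_coupling, cfg.cognition_noise_sd, seed=seed
    )
    io.write_tsv(scores.reset_index(), out / "cognition.tsv")
    io.write_tsv(
        weights.rename("weight").rename_axis("class").reset_index(),
        out / "cognition_weights.tsv",
    )

    is_ad = meta["group"].to_numpy() == "AD"
    covs = meta.loc[is_ad, list(cfg.covariates)].to_numpy(dtype=float)
    rows = []
    for klass in class_means.columns:
        for score in scores.columns:
            r, p = cog.partial_correlation(
                class_means.loc[class_means.index[is_ad], klass].to_numpy(),
                scores.loc[scores.index[is_ad], score].to_numpy(),
                covs,
            )
            rows.append({"class": klass, "score": score, "r": r, "p": p})
    pc = pd.DataFrame(rows)
    pc["q"] = st.bh_fdr(pc["p"].to_numpy())
    io.write_tsv(pc, out / "partial_correlations.tsv")

    g1 = io.read_tsv(
        _require(out, "cognition", "gradient1.tsv", "gradients"),
        index_col="subject_id",
    )
    strength = io.read_tsv(
        _require(out, "cognition", "strength.tsv", "msn"), index_col="subject_id"
    )
    report = cog.compare_feature_sets(
        g1.loc[is_ad].to_numpy(),
        strength.loc[is_ad].to_numpy(),
        scores.loc[scores.index[is_ad]],
        n_perm=cfg.svr_n_perm,
        seed=seed + 1,
        n_outer=cfg.svr_n_outer,
        n_inner=cfg.svr_n_inner,
        c_grid=tuple(cfg.svr_c_grid),
        eps_grid=tuple(cfg.svr_eps_grid),
    )
    io.write_tsv(report, out / "prediction_report.tsv")


def _stage_pls(cfg: RunConfig, out: Path) -> None:
    _require(out, "pls", "stat_map.tsv", "stats")
    stat_map = io.read_tsv(out / "stat_map.tsv", index_col="region_id")
    seed = _stage_seed(cfg.seed, "pls")
    # expression is planted against the realized group-difference t-map so
    # the transcriptomic association has a recoverable ground truth
    expr = syn.generate_expression(
        stat_map["t"].to_numpy(),
        n_genes=cfg.n_genes,
        n_planted=cfg.n_planted,
        planted_corr=cfg.planted_corr,
        seed=seed,
    )
    io.write_tsv(expr.expression.reset_index(), out / "expression.tsv")
    io.write_tsv(
        pd.DataFrame({"gene_id": expr.planted_genes}), out / "planted_genes.tsv"
    )
    expression = expr.expression
    result, plus, minus = tx.pls_association(
        expression,
        stat_map["t"].to_numpy(),
        n_perm=cfg.pls_n_perm,
        n_boot=cfg.pls_n_boot,
        q_threshold=cfg.gene_q_threshold,
        seed=seed,
    )
    genes = pd.DataFrame(
        {
            "gene_id": result.gene_weights.index,
            "weight": result.gene_weights.to_numpy(),
            "z": result.gene_z.to_numpy(),
            "p": result.gene_p.to_numpy(),
            "q": result.gene_q.to_numpy(),
        }
    )
    genes["set"] = "ns"
    genes.loc[genes["gene_id"].isin(plus), "set"] = "+"
    genes.loc[genes["gene_id"].isin(minus), "set"] = "-"
    io.write_tsv(genes, out / "pls_genes.tsv")
    io.write_tsv(
        pd.DataFrame(
            {
                "var_explained": [result.var_explained],
                "perm_p_var": [result.perm_p_var],
                "corr_scores_t": [result.corr_scores_t],
                "perm_p_corr": [result.perm_p_corr],
                "n_genes_plus": [len(plus)],
                "n_genes_minus": [len(minus)],
            }
        ),
        out / "pls_summary.tsv",
    )
    io.write_tsv(
        pd.DataFrame(
            {
                "region_id": stat_map.index,
                "pls1_score": result.pls1_scores,
                "t": stat_map["t"].to_numpy(),
            }
        ),
        out / "pls_scores.tsv",
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "msn": _stage_msn,
    "gradients": _stage_gradients,
    "stats": _stage_stats,
    "graph": _stage_graph,
    "cognition": _stage_cognition,
    "pls": _stage_pls,
}


def run_pipeline(config: RunConfig | dict, out_dir: Path | str) -> dict:
    """Execute the configured stages into ``out_dir``; returns the manifest."""
    cfg = config if isinstance(config, RunConfig) else RunConfig(**config)
    unknown = [s for s in cfg.stages if s not in STAGES]
    if unknown:
        raise StageError(f"unknown stage(s): {unknown}; valid stages are {list(STAGES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in cfg.stages]
    for stage in ordered:
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage context
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
    payload = {
        "config": cfg.model_dump(mode="json"),
        "seed": cfg.seed,
        "stage_seeds": {s: _stage_seed(cfg.seed, s) for s in ordered},
        "stages_run": list(ordered),
    }
    io.write_manifest(out, payload)
    return io.read_manifest(out)
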