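"""Plain-files pipeline orchestration with a run manifest.

Stages run in dependency order (simulate/ingest -> validate -> batch-adjust
-> classify -> fitness -> GLM+lfdr -> subset -> EMD -> knockoffs -> GP
model); each stage writes re-loadable TSV outputs tagged with the package
version and config hash, and the manifest records outputs, parameters,
seeds and wall-clock per stage.  The manifest is written even when a stage
fails; downstream stages are then skipped.  With ``resume=True`` stages
whose outputs already exist are not recomputed.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .batch_adjust import batch_adjust
from .config import RunConfig
from .counts_io import (CountMatrix, SampleDesign, drop_all_zero_genes,
                        read_count_table, validate_dataset, write_count_table)
from .emd_synergy import condition_distances, synergy_rank
from .fitness_calls import classify_genes, fitness_defect, subset_for_selection
from .glm_lfdr import call_lfdr, fit_nb_glm
from .gp_coessentiality import estimate_T, gibbs_fit, summarize_components
from .knockoff_select import select_predictors
from .simdata import TruthConfig, default_design, simulate_experiment

log = logging.getLogger(__name__)


def _meta_line(cfg: RunConfig) -> str:
    return f"# tnhomeo {__version__} config={cfg.config_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_line(cfg))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute the configured stages and return the manifest dict."""
    cfg = config
    out = Path(cfg.paths.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config_hash": cfg.config_hash(),
                      "config": cfg.model_dump(), "stages": {}}
    mpath = out / "manifest.json"

    def record(stage: str, status: str, outputs: list[str], t0: float,
               error: str | None = None) -> None:
        manifest["stages"][stage] = {
            "status": status, "outputs": outputs,
            "seconds": round(time.time() - t0, 3)}
        if error:
            manifest["stages"][stage]["error"] = error
        mpath.write_text(json.dumps(manifest, indent=2, default=str))

    def fresh(*paths: Path) -> bool:
        return resume and all(p.exists() for p in paths)

    try:
        data = _stage_inputs(cfg, out, record, fresh)
        counts_total, counts_unique, design = data
    except Exception as exc:
        record("inputs", "failed", [], time.time(), _err(exc))
        return manifest

    ct, cu = counts_total, counts_unique
    if cfg.stages.batch_adjust:
        t0 = time.time()
        p_t, p_u = out / "adjusted_total.tsv", out / "adjusted_unique.tsv"
        try:
            if fresh(p_t, p_u):
                ct = read_count_table(p_t, "total")
                cu = read_count_table(p_u, "unique")
                record("batch_adjust", "resumed", [str(p_t), str(p_u)], t0)
            else:
                ct, _ = batch_adjust(counts_total, design)
                cu, _ = batch_adjust(counts_unique, design)
                for c, p in ((ct, p_t), (cu, p_u)):
                    with open(p, "w") as fh:
                        fh.write(_meta_line(cfg))
                        c.to_frame().to_csv(fh, sep="\t")
                record("batch_adjust", "ok", [str(p_t), str(p_u)], t0)
        except Exception as exc:
            record("batch_adjust", "failed", [], t0, _err(exc))
            return manifest

    calls = None
    if cfg.stages.classify:
        t0 = time.time()
        p = out / "fitness_calls.tsv"
        try:
            calls = classify_genes(cu, design, tau_ess=cfg.tau_ess,
                                   rho_fc=cfg.rho_fc)
            _write_tsv(calls.table, p, cfg, index=False)
            record("classify", "ok", [str(p)], t0)
        except Exception as exc:
            record("classify", "failed", [], t0, _err(exc))
            return manifest

    fitness = None
    if cfg.stages.fitness:
        t0 = time.time()
        p = out / "fitness_values.tsv"
        try:
            fitness = fitness_defect(cu, design)
            _write_tsv(fitness.per_condition, p, cfg)
            record("fitness", "ok", [str(p)], t0)
        except Exception as exc:
            record("fitness", "failed", [], t0, _err(exc))
            return manifest

    glm_calls = None
    if cfg.stages.glm:
        t0 = time.time()
        p_c, p_l = out / "glm_coefficients.tsv", out / "glm_lfdr_calls.tsv"
        try:
            fits = fit_nb_glm(cu, design, n_lambda=cfg.glm_n_lambda)
            _write_tsv(fits.coef_table(), p_c, cfg)
            parts = []
            for fam in ("e|g", "s|e|g"):
                res = call_lfdr(fits, family=fam, lfdr_cut=cfg.lfdr_cut)
                parts.append(res.table.assign(family=fam, pi0=res.pi0))
            glm_calls = pd.concat(parts, ignore_index=True)
            _write_tsv(glm_calls, p_l, cfg, index=False)
            record("glm", "ok", [str(p_c), str(p_l)], t0)
        except Exception as exc:
            record("glm", "failed", [], t0, _err(exc))
            return manifest

    retained: dict[str, list[str]] = {}
    if calls is not None:
        retained = subset_for_selection(calls, glm_calls)
        p = out / "retained_genes.tsv"
        _write_tsv(pd.DataFrame(
            [(s, g) for s, gl in retained.items() for g in gl],
            columns=["strain", "locus_tag"]), p, cfg, index=False)

    if cfg.stages.emd and retained:
        t0 = time.time()
        outputs = []
        try:
            for strain, genes in retained.items():
                if not genes:
                    continue
                for channel, cm in (("total", ct), ("unique", cu)):
                    S = condition_distances(cm, design, strain, genes)
                    ranked = synergy_rank(S)
                    p = out / f"emd_{strain}_{channel}.tsv"
                    _write_tsv(ranked, p, cfg, index=False)
                    outputs.append(str(p))
                    _bubble_plot(ranked, out / f"emd_{strain}_{channel}.png",
                                 strain, channel)
            record("emd", "ok", outputs, t0)
        except Exception as exc:
            record("emd", "failed", outputs, t0, _err(exc))
            return manifest

    if cfg.stages.knockoff and retained and fitness is not None:
        t0 = time.time()
        outputs = []
        try:
            for strain, genes in retained.items():
                if len(genes) < 2:
                    continue
                run = select_predictors(fitness, design, strain, genes,
                                        q=cfg.q, seed=cfg.seeds.knockoff)
                p = out / f"knockoff_{strain}.tsv"
                _write_tsv(pd.DataFrame(
                    {"W": run.W,
                     "selected": [g in run.selected for g in run.W.index]}),
                    p, cfg)
                outputs.append(str(p))
            record("knockoff", "ok", outputs, t0)
        except Exception as exc:
            record("knockoff", "failed", outputs, t0, _err(exc))
            return manifest

    if cfg.stages.gpmodel and retained:
        t0 = time.time()
        outputs = []
        try:
            for strain, genes in retained.items():
                if not genes:
                    continue
                mask = design.table["strain"] == strain
                sub = design.subset(mask)
                cu_s = cu.reorder_samples(sub.sample_ids).subset_genes(genes)
                T = estimate_T(cu_s, tau_ess=cfg.tau_ess,
                               seed=cfg.seeds.gpmodel)
                samples = gibbs_fit(cu_s, sub, T, K=cfg.K, eps0=cfg.eps0,
                                    a=cfg.a, iters=cfg.mcmc.iters,
                                    burnin=cfg.mcmc.burnin,
                                    thin=cfg.mcmc.thin,
                                    seed=cfg.seeds.gpmodel)
                summ = summarize_components(samples)
                p1 = out / f"gp_loadings_{strain}.tsv"
                p2 = out / f"gp_hmean_{strain}.tsv"
                p3 = out / f"gp_trace_{strain}.tsv"
                _write_tsv(summ["loadings"], p1, cfg)
                _write_tsv(summ["h_mean"], p2, cfg)
                _write_tsv(pd.DataFrame(
                    {"sweep": np.arange(len(samples.loglik_trace)),
                     "loglik": samples.loglik_trace}).assign(
                        ess=float(samples.ess_info["ess"].iloc[0])),
                    p3, cfg, index=False)
                _loadings_heatmap(summ["loadings"],
                                  out / f"gp_loadings_{strain}.png", strain)
                outputs += [str(p1), str(p2), str(p3)]
            record("gpmodel", "ok", outputs, t0)
        except Exception as exc:
            record("gpmodel", "failed", outputs, t0, _err(exc))
            return manifest

    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_inputs(cfg: RunConfig, out: Path, record, fresh):
    t0 = time.time()
    if cfg.simulate is not None:
        sc = cfg.simulate
        design = default_design(strains=tuple(sc.strains),
                                stresses=tuple(sc.stresses),
                                levels=tuple(sc.levels),
                                n_reps=sc.n_reps, n_batches=sc.n_batches)
        tc = TruthConfig(L=sc.L, K_true=sc.K_true, fractions=sc.fractions,
                         baseline_mu=sc.baseline_mu,
                         essential_mu=sc.essential_mu,
                         dispersion_range=tuple(sc.dispersion_range),
                         p_unique=sc.p_unique, batch_sigma=sc.batch_sigma,
                         stress_cluster_map={
                             int(k): v for k, v in
                             (sc.stress_cluster_map or {}).items()}
                         if sc.stress_cluster_map else None)
        ct, cu, design, truth = simulate_experiment(design, tc,
                                                    seed=cfg.seeds.simulate)
        write_count_table(ct, out / "sim_counts_total.tsv")
        write_count_table(cu, out / "sim_counts_unique.tsv")
        design.write(out / "sim_design.tsv")
        truth.gene_class.to_csv(out / "sim_truth_classes.tsv", sep="\t",
                                index=False)
        record("simulate", "ok", [str(out / "sim_counts_total.tsv"),
                                  str(out / "sim_counts_unique.tsv"),
                                  str(out / "sim_design.tsv")], t0)
    else:
        if not (cfg.paths.counts_total and cfg.paths.counts_unique
                and cfg.paths.design):
            raise ValueError("either a simulate: block or input paths for "
                             "counts_total, counts_unique and design are "
                             "required")
        ct = read_count_table(cfg.paths.counts_total, "total")
        cu = read_count_table(cfg.paths.counts_unique, "unique")
        design = SampleDesign.read(cfg.paths.design)
        record("ingest", "ok", [], t0)
    t0 = time.time()
    issues = validate_dataset(ct, cu, design)
    (out / "validation.json").write_text(json.dumps(issues, indent=2))
    if cfg.drop_all_zero:
        ct, cu, dropped = drop_all_zero_genes(ct, cu)
        if dropped:
            log.info("dropped %d all-zero genes", len(dropped))
    record("validate", "ok", [str(out / "validation.json")], t0)
    return ct, cu, design


def _bubble_plot(ranked: pd.DataFrame, path: Path, strain: str,
                 channel: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, max(3, 0.3 * len(ranked))))
    emd = ranked["emd"].to_numpy()
    size = 30 + 270 * emd / max(emd.max(), 1e-12)
    colors = ranked["tier"].map({"low": "#7fbf7f", "moderate": "#ffbf00",
                                 "high": "#d62728"})
    ax.scatter(emd, np.arange(len(ranked)), s=size, c=colors, alpha=0.8)
    ax.set_yticks(np.arange(len(ranked)))
    ax.set_yticklabels(ranked["pair"])
    ax.invert_yaxis()
    ax.set_xlabel("EMD")
    ax.set_title(f"{strain} ({channel} counts)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _loadings_heatmap(loadings: pd.DataFrame, path: Path,
                      strain: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(1 + 0.8 * loadings.shape[1],
                                    1 + 0.4 * loadings.shape[0]))
    im = ax.imshow(loadings.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0, vmax=1)
    ax.set_xticks(range(loadings.shape[1]),
                  labels=loadings.columns, rotation=45, ha="right")
    ax.set_yticks(range(loadings.shape[0]), labels=loadings.index)
    ax.set_title(f"{strain}: condition loadings")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _err(exc: Exception) -> str:
    return "".join(traceback.format_exception_only(type(exc), exc)).strip() \
        + "\n" + traceback.format_exc(limit=3)
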