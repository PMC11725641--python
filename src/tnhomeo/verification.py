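"""Verification experiments: planted-truth simulations for every stage.

Each function builds its own synthetic inputs from an explicit seed, runs
one pipeline component, and returns the measured quantities (errors, false
discovery proportions, power, recovery accuracy).  The test suite asserts
on these numbers and ``scripts/acceptance.py`` reports them; both recompute
everything from scratch at run time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize
from scipy.special import gammaln

from .counts_io import SampleDesign, build_design_matrix
from .emd_synergy import emd_1d
from .glm_lfdr import fit_gene, lfdr_from_z
from .gp_coessentiality import (GibbsSampler, ThresholdMatrix, _autocorr_ess,
                                gibbs_fit)
from .knockoff_select import knockoff_filter, make_knockoffs
from .simdata import TruthConfig, default_design, simulate_experiment, \
    simulate_gp_counts
from .batch_adjust import batch_adjust, estimate_batch_model


# ------------------------------------------------------------ NB-GLM oracle

def _nb_negloglik(params, y, X, phi):
    eta = params[0] + X @ params[1:]
    mu = np.exp(np.clip(eta, -30, 30))
    ll = (gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
          + phi * np.log(phi / (phi + mu)) + y * np.log(mu / (phi + mu)))
    return -ll.sum()


def glm_oracle_error(seed: int) -> dict:
    """Max |MLE - brute-force optimizer| over 5 two-group toy genes."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(1, 5):
        rows.append({"sample_id": f"c{j}", "strain": "wt",
                     "stress": "control", "level": "none", "replicate": j,
                     "batch": "b1"})
        rows.append({"sample_id": f"h{j}", "strain": "wt", "stress": "heat",
                     "level": "low", "replicate": j, "batch": "b1"})
    design = SampleDesign(pd.DataFrame(rows))
    X = build_design_matrix(design, coding="full")
    ctrl = (design.table["stress"] == "control").to_numpy()
    phi = 50.0
    worst = 0.0
    for mu_c, mu_h in [(50, 20), (10, 80), (30, 30), (5, 40), (100, 12)]:
        y = np.empty(8)
        y[ctrl] = rng.poisson(mu_c, 4)
        y[~ctrl] = rng.poisson(mu_h, 4)
        fit = fit_gene(y, X, phi=phi, lam=0.0)
        kept = [c for c in X.columns if abs(fit.beta[c]) > 0]
        res = minimize(_nb_negloglik, np.zeros(1 + len(kept)),
                       args=(y, X[kept].to_numpy(), phi),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        ours = np.r_[fit.beta["const"], [fit.beta[c] for c in kept]]
        worst = max(worst, float(np.abs(ours - res.x).max()))
    return {"max_abs_diff": worst, "n": 5}


# ------------------------------------------------------------ lfdr checks

def lfdr_null_calibration(seed: int, reps: int = 20, n_z: int = 5000) -> dict:
    """Call rate on pure N(0,1) z-values at lfdr <= 0.2, averaged."""
    ss = np.random.SeedSequence(seed).spawn(reps)
    rates = []
    for s in ss:
        z = np.random.default_rng(s).normal(0, 1, n_z)
        lfdr, *_ = lfdr_from_z(z)
        rates.append(np.mean(lfdr <= 0.2))
    return {"call_rate_pct": 100.0 * float(np.mean(rates)), "n": reps}


def lfdr_mixed_performance(seed: int, reps: int = 20) -> dict:
    """Realized FDP and power on 10% +/-4-shifted z-values, averaged."""
    ss = np.random.SeedSequence(seed + 1).spawn(reps)
    fdps, powers = [], []
    for s in ss:
        rng = np.random.default_rng(s)
        z = np.r_[rng.normal(0, 1, 4500), rng.normal(4, 1, 250),
                  rng.normal(-4, 1, 250)]
        truth = np.r_[np.zeros(4500), np.ones(500)]
        lfdr, *_ = lfdr_from_z(z)
        calls = lfdr <= 0.2
        fdps.append(np.sum(calls & (truth == 0)) / max(calls.sum(), 1))
        powers.append(np.sum(calls & (truth == 1)) / 500)
    return {"fdp": float(np.mean(fdps)), "power": float(np.mean(powers)),
            "n": reps}


# ------------------------------------------------------------ knockoffs

def knockoff_fdr_power(seed: int, reps: int = 50, n: int = 36, r: int = 200,
                       k_true: int = 10, q: float = 0.1) -> dict:
    """Mean realized FDP and power of the model-Y knockoff filter.

    Each replicate plants ``k_true`` discriminative genes with a 2-SD
    class-mean shift (one stress class per gene, round-robin) among
    ``r`` standardized Gaussian fitness features over ``n`` samples in
    three stress classes.
    """
    classes = np.repeat(["heat", "oxidative", "canavanine"], n // 3)
    cls_idx = {"heat": 0, "oxidative": 1, "canavanine": 2}
    ss = np.random.SeedSequence(seed + 2).spawn(reps)
    fdps, powers = [], []
    for i, s in enumerate(ss):
        rng = np.random.default_rng(s)
        Y = rng.standard_normal((n, r))
        for j in range(k_true):
            mu = np.zeros(3)
            mu[j % 3] = 2.0
            Y[:, j] += np.array([mu[cls_idx[c]] for c in classes])
        Y = (Y - Y.mean(0)) / Y.std(0)
        Ydf = pd.DataFrame(Y, columns=[f"g{j}" for j in range(r)])
        Yt = make_knockoffs(Ydf, seed=int(rng.integers(2 ** 31)))
        run = knockoff_filter(classes, Ydf, Yt, q=q)
        sel = set(run.selected)
        tp = len([g for g in sel if int(g[1:]) < k_true])
        fdps.append((len(sel) - tp) / max(len(sel), 1))
        powers.append(tp / k_true)
    fdps = np.asarray(fdps)
    return {"mean_fdp": float(fdps.mean()), "mean_power":
            float(np.mean(powers)),
            "fdp_mc_se": float(fdps.std(ddof=1) / np.sqrt(reps)), "n": reps}


def knockoff_null_fdr(seed: int, reps: int = 50, n: int = 36,
                      r: int = 200, q: float = 0.1) -> dict:
    """Mean FDP on pure-noise features (all selections are false)."""
    classes = np.repeat(["heat", "oxidative", "canavanine"], n // 3)
    ss = np.random.SeedSequence(seed + 3).spawn(reps)
    fdps = []
    for s in ss:
        rng = np.random.default_rng(s)
        Y = rng.standard_normal((n, r))
        Y = (Y - Y.mean(0)) / Y.std(0)
        Ydf = pd.DataFrame(Y, columns=[f"g{j}" for j in range(r)])
        Yt = make_knockoffs(Ydf, seed=int(rng.integers(2 ** 31)))
        run = knockoff_filter(classes, Ydf, Yt, q=q)
        fdps.append(1.0 if run.selected else 0.0)
    fdps = np.asarray(fdps)
    return {"mean_fdp": float(fdps.mean()),
            "fdp_mc_se": float(fdps.std(ddof=1) / np.sqrt(reps)), "n": reps}


# ------------------------------------------------------------ EMD oracle

def _lp_transport(P: np.ndarray, Q: np.ndarray) -> float:
    m, n = len(P), len(Q)
    cost = np.abs(np.subtract.outer(P, Q)).ravel()
    A_eq = np.zeros((m + n, m * n))
    for i in range(m):
        A_eq[i, i * n:(i + 1) * n] = 1
    for j in range(n):
        A_eq[m + j, j::n] = 1
    b_eq = np.r_[np.full(m, 1 / m), np.full(n, 1 / n)]
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, method="highs")
    if not res.success:
        raise RuntimeError("LP transport oracle failed")
    return float(res.fun)


def emd_oracle_error(seed: int, trials: int = 1000) -> dict:
    """Max |emd_1d - LP min-cost transport| over random small instances."""
    rng = np.random.default_rng(seed + 4)
    worst = 0.0
    for _ in range(trials):
        P = rng.uniform(0, 50, rng.integers(2, 8))
        Q = rng.uniform(0, 50, rng.integers(2, 10))
        worst = max(worst, abs(emd_1d(P, Q) - _lp_transport(P, Q)))
    return {"max_abs_err": worst, "n": trials}


# ------------------------------------------------------------ GP model

def gp_recovery_accuracy(seed: int, L: int = 200, n_reps: int = 4,
                         iters: int = 500) -> dict:
    """Elementwise accuracy of posterior H on planted K=2 block data
    (6 conditions x n_reps replicates), best component permutation."""
    rows = []
    for e in ("heat", "oxidative"):
        for s in ("low", "medium", "high"):
            for j in range(1, n_reps + 1):
                rows.append({"sample_id": f"{e}_{s}_r{j}", "strain": "wt",
                             "stress": e, "level": s, "replicate": j,
                             "batch": "b1"})
    d = SampleDesign(pd.DataFrame(rows))
    K = 2
    H = np.zeros((K, L), int)
    H[0, :int(0.3 * L)] = 1
    H[1, int(0.3 * L):int(0.6 * L)] = 1
    T = np.column_stack([np.full(L, 1.0), np.full(L, 60.0)])
    theta = np.array([[0.9, 0.1] if r.startswith("heat") else [0.1, 0.9]
                      for r in d.sample_ids])
    y = simulate_gp_counts(H, theta, T, d, seed=seed + 5)
    Tm = ThresholdMatrix(y.genes, T, np.full((L, 2), .5), np.ones((L, 2)),
                         np.zeros(L, bool))
    out = gibbs_fit(y, d, Tm, K=K, iters=iters, burnin=iters // 2, thin=2,
                    seed=seed + 6)
    from itertools import permutations
    acc = max(np.mean((out.h_mean[list(p)] > 0.5) == H)
              for p in permutations(range(K)))
    return {"h_accuracy_pct": 100.0 * float(acc), "n": L}


def gp_geweke_zscores(seed: int, n_draw: int = 6000) -> dict:
    """Joint-distribution ("getting it right") check on a tiny instance.

    Marginal statistics of (parameters, data) drawn forward from the prior
    are compared with the same statistics along a successive-conditional
    chain (Gibbs sweep then data redraw); agreement within Monte-Carlo
    error validates every conditional of the sampler.  The successive
    chain runs 10x ``n_draw`` sweeps: the hyperparameter chains mix slowly
    in the prior-predictive regime and shorter chains make the
    autocorrelation-adjusted standard errors unreliable.
    """
    L, K, I, J = 10, 2, 3, 2
    cond = np.repeat(np.arange(I), J)
    T = np.column_stack([np.full(L, 1.0), np.full(L, 5.0)])

    def stats(smp, Y):
        s = smp.state
        return [np.log(s.rho0), np.log(s.tau), s.H.mean(),
                np.log1p(Y).mean()]

    rng = np.random.default_rng(seed + 7)
    smp = GibbsSampler(np.zeros((L, I * J), int), cond, T, K=K, eps0=1.0,
                       a=0.3, rng=rng, init="prior")
    fwd = []
    for _ in range(n_draw):
        smp.state = smp.sample_prior_state()
        Y = smp.sample_data(smp.state)
        fwd.append(stats(smp, Y))
    fwd = np.array(fwd)

    rng2 = np.random.default_rng(seed + 8)
    smp2 = GibbsSampler(np.zeros((L, I * J), int), cond, T, K=K, eps0=1.0,
                        a=0.3, rng=rng2, init="prior")
    Y = smp2.sample_data(smp2.state)
    succ = []
    n_succ = 10 * n_draw
    for _ in range(n_succ):
        smp2.Y = Y.astype(np.int64)
        smp2.sweep()
        Y = smp2.sample_data(smp2.state)
        succ.append(stats(smp2, Y))
    succ = np.array(succ[n_succ // 6:])

    zs = []
    for j in range(fwd.shape[1]):
        essv = max(_autocorr_ess(succ[:, j]), 2.0)
        se = np.sqrt(fwd[:, j].var() / len(fwd) + succ[:, j].var() / essv)
        zs.append((fwd[:, j].mean() - succ[:, j].mean()) / max(se, 1e-12))
    return {"max_abs_z": float(np.abs(zs).max()), "n": n_draw}


# ------------------------------------------------------------ batch model

def batch_recovery(seed: int, L: int = 500) -> dict:
    """Recovery and removal of a planted 2x batch shift over L genes."""
    d = default_design(strains=("wt",), stresses=("heat",), levels=("low",),
                       n_reps=8, n_batches=2)
    cfg = TruthConfig(L=L, fractions={}, baseline_sigma=0.2,
                      batch_log_fc={"b1": 1.0, "b2": 2.0},
                      dispersion_range=(5.0, 5.0))
    _, cu, design, _ = simulate_experiment(d, cfg, seed=seed + 9)
    model = estimate_batch_model(cu, design)
    gamma_diff = float((model.gamma["b2"] - model.gamma["b1"]).mean())
    adjusted, _ = batch_adjust(cu, design)
    b = design.table.set_index("sample_id")["batch"]
    adf = adjusted.to_frame()
    m1 = adf[b[b == "b1"].index.tolist()].to_numpy().mean()
    m2 = adf[b[b == "b2"].index.tolist()].to_numpy().mean()
    return {"gamma_abs_error": abs(gamma_diff - np.log(2)),
            "residual_mean_diff_pct": 100.0 * abs(m1 - m2) / m1, "n": L}


# ------------------------------------------------------------ end to end

def pipeline_end_to_end(seed: int, outdir, L: int = 500) -> dict:
    """Full pipeline on the default simulation fixture.

    Plants conditionally essential gene clusters so that heat and oxidative
    stress share essential genes while canavanine has its own set; measures
    the recall of planted conditionally essential calls and whether the
    top-ranked EMD pair separates canavanine from the shared cluster.
    """
    from .config import RunConfig
    from .pipeline import run_pipeline
    cfg = RunConfig(**{
        "paths": {"outdir": str(outdir)},
        "simulate": {"L": L, "K_true": 3, "n_reps": 4, "n_batches": 2,
                     "dispersion_range": [2.0, 8.0],
                     "stress_cluster_map": {0: ["heat", "oxidative"],
                                            1: ["heat", "oxidative"],
                                            2: ["canavanine"]}},
        "seeds": {"simulate": seed + 10, "knockoff": seed + 11,
                  "gpmodel": seed + 12},
        "mcmc": {"iters": 300, "burnin": 150, "thin": 3},
        "K": 6, "glm_n_lambda": 6})
    manifest = run_pipeline(cfg)
    statuses = {s: v["status"] for s, v in manifest["stages"].items()}
    ok = all(v == "ok" for v in statuses.values())

    outdir = str(outdir)
    truth = pd.read_csv(f"{outdir}/sim_truth_classes.tsv", sep="\t")
    calls = pd.read_csv(f"{outdir}/fitness_calls.tsv", sep="\t", skiprows=1)
    planted = truth[truth["gene_class"] == "cond_essential"][
        ["locus_tag", "strain", "stress", "level"]]
    merged = planted.merge(calls, on=["locus_tag", "strain", "stress",
                                      "level"], suffixes=("_true", ""))
    recall = float((merged["gene_class"] == "cond_essential").mean())

    emd = pd.read_csv(f"{outdir}/emd_wt_unique.tsv", sep="\t", skiprows=1)
    top = emd.iloc[0]
    split = ("canavanine" in top["condition_a"]) != (
        "canavanine" in top["condition_b"])
    return {"all_stages_ok": ok, "cond_essential_recall_pct": 100.0 * recall,
            "top_emd_pair_is_planted_dissimilar": bool(split),
            "n": L, "statuses": statuses}
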