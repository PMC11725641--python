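"""Synthetic Tn-seq experiments with the structure the pipeline assumes.

The generator emulates the study layout — several genetic backgrounds, three
proteotoxic stresses at three levels plus an unstressed control, replicated
in quadruplicate across multiple batches — and plants known gene classes
(essential, conditionally essential / beneficial / detrimental, neutral)
with cluster structure, so every downstream stage can be tested against a
known truth.  Counts follow a negative binomial law whose log-mean is the
nested design linear predictor plus a per-(batch, gene) log factor; the
unique-site channel is a binomial thinning of the total channel, which
preserves the unique <= total ordering by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import (CONTROL_LEVEL, CONTROL_STRESS, CountMatrix,
                        SampleDesign, build_design_matrix)

GENE_CLASSES = ("essential", "cond_essential", "cond_beneficial",
                "cond_detrimental", "neutral")

DEFAULT_FRACTIONS = {"essential": 0.05, "cond_essential": 0.05,
                     "cond_beneficial": 0.03, "cond_detrimental": 0.03}


@dataclass
class TruthConfig:
    """Planted-truth parameters for :func:`simulate_experiment`.

    Defaults mirror the study conditions: ~4,000 loci would be full scale,
    but ``L`` is set by the caller; quadruplicate replication and the
    strain/stress grid come from the design sheet.  ``baseline_mu`` is the
    total-channel mean of a neutral gene under control; ``essential_mu`` the
    total-channel mean in the essential regime; effects are on the log scale.
    """

    L: int = 4000
    K_true: int = 3
    fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    baseline_mu: float = 80.0
    baseline_sigma: float = 0.3
    essential_mu: float = 1.0
    beta_beneficial: float = -1.6
    beta_detrimental: float = 1.6
    level_gradient: dict = field(
        default_factory=lambda: {"low": 0.0, "medium": 0.25, "high": 0.5})
    dispersion_range: tuple = (0.1, 10.0)
    p_unique: float = 0.6
    batch_sigma: float = 0.15
    batch_log_fc: dict | None = None
    stress_cluster_map: dict | None = None


@dataclass
class SimTruth:
    """Ground truth behind one simulated experiment."""

    genes: list[str]
    gene_class: pd.DataFrame          # long: locus_tag, strain, stress, level, class
    true_beta: pd.DataFrame           # genes x design-term columns (log scale)
    baseline_log_mu: np.ndarray       # per gene, total channel, control regime
    dispersion: np.ndarray            # per gene, Var = mu + mu^2/phi
    batch_log_factors: pd.DataFrame   # genes x batch, centered per gene
    H_true: np.ndarray                # K_true x L cluster membership (0/1)
    cluster_of_gene: np.ndarray       # -1 for genes outside any cluster

    def classes_for(self, strain: str, stress: str, level: str) -> pd.Series:
        m = ((self.gene_class["strain"] == strain)
             & (self.gene_class["stress"] == stress)
             & (self.gene_class["level"] == level))
        sub = self.gene_class[m].set_index("locus_tag")["gene_class"]
        return sub.reindex(self.genes)


def default_design(strains=("wt", "dlon", "dclpA", "dclpB", "dnaKJ-NI"),
                   stresses=("heat", "oxidative", "canavanine"),
                   levels=("low", "medium", "high"),
                   n_reps: int = 4, n_batches: int = 2) -> SampleDesign:
    """The study grid: per strain, 1 control + stresses x levels, replicated.

    Replicates are spread across batches round-robin so batches stay
    balanced within each condition.
    """
    rows = []
    for g in strains:
        conds = [(CONTROL_STRESS, CONTROL_LEVEL)]
        conds += [(e, s) for e in stresses for s in levels]
        for e, s in conds:
            for j in range(1, n_reps + 1):
                b = f"b{(j - 1) % n_batches + 1}"
                rows.append({"sample_id": f"{g}_{e}_{s}_r{j}",
                             "strain": g, "stress": e, "level": s,
                             "replicate": j, "batch": b})
    return SampleDesign(pd.DataFrame(rows))


def _assign_classes(cfg: TruthConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic class counts: round(frac * L) genes per class, placed
    by a seeded permutation.  Returns (class label per gene, cluster id)."""
    fr = dict(cfg.fractions)
    unknown = set(fr) - set(GENE_CLASSES)
    if unknown:
        raise ValueError(f"unknown gene classes in fractions: {sorted(unknown)}")
    if any(not 0 <= v <= 1 for v in fr.values()) or sum(fr.values()) > 1 + 1e-12:
        raise ValueError("class fractions must lie in [0,1] and sum to <= 1")
    counts = {c: int(round(fr.get(c, 0.0) * cfg.L)) for c in GENE_CLASSES
              if c != "neutral"}
    if sum(counts.values()) > cfg.L:
        raise ValueError("class fractions leave no room for neutral genes")
    order = rng.permutation(cfg.L)
    labels = np.array(["neutral"] * cfg.L, dtype=object)
    pos = 0
    for c in ("essential", "cond_essential", "cond_beneficial",
              "cond_detrimental"):
        labels[order[pos:pos + counts.get(c, 0)]] = c
        pos += counts.get(c, 0)
    cluster = np.full(cfg.L, -1, dtype=int)
    ce = np.flatnonzero(labels == "cond_essential")
    for r, gidx in enumerate(ce):
        cluster[gidx] = r % max(cfg.K_true, 1)
    return labels, cluster


def simulate_experiment(design: SampleDesign, truth_config: TruthConfig,
                        seed: int) -> tuple[CountMatrix, CountMatrix,
                                            SampleDesign, SimTruth]:
    """Draw a full two-channel Tn-seq experiment with planted gene classes.

    Conditionally essential genes are organized into ``K_true`` clusters;
    cluster ``k`` is essential under the stresses ``stress_cluster_map[k]``
    (default: stress ``k mod n_stresses``) in every strain.  Conditionally
    beneficial/detrimental genes get a log effect on their target stress,
    growing with stress level via ``level_gradient``.  Returns
    ``(counts_total, counts_unique, design, truth)``.
    """
    cfg = truth_config
    if cfg.L < 10:
        raise ValueError("L must be >= 10")
    design.require_controls()
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:05d}" for i in range(cfg.L)]
    labels, cluster = _assign_classes(cfg, rng)

    log_mu0 = np.log(cfg.baseline_mu) + rng.normal(0, cfg.baseline_sigma, cfg.L)
    log_mu0[labels == "essential"] = np.log(cfg.essential_mu)
    lo, hi = cfg.dispersion_range
    phi = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.L))

    stresses = design.stresses()
    if not stresses:
        cluster_map = {}
    else:
        cluster_map = cfg.stress_cluster_map or {
            k: [stresses[k % len(stresses)]] for k in range(cfg.K_true)}
    # target stress for beneficial/detrimental genes, round-robin
    target_stress = np.array([""] * cfg.L, dtype=object)
    if stresses:
        for c in ("cond_beneficial", "cond_detrimental"):
            idx = np.flatnonzero(labels == c)
            for r, gidx in enumerate(idx):
                target_stress[gidx] = stresses[r % len(stresses)]

    X = build_design_matrix(design, coding="full")
    beta_arr = np.zeros((cfg.L, X.shape[1]))
    colpos = {c: i for i, c in enumerate(X.columns)}
    beta_ess = np.log(cfg.essential_mu) - log_mu0  # drives mean to essential_mu
    is_ce = labels == "cond_essential"
    base_eff = np.where(labels == "cond_beneficial", cfg.beta_beneficial,
                        np.where(labels == "cond_detrimental",
                                 cfg.beta_detrimental, 0.0))
    for g in design.strains:
        for e in design.stresses(g):
            col_e = colpos.get(f"e|g[{g}:{e}]")
            if col_e is None:
                continue
            ce_hit = is_ce & np.array(
                [e in cluster_map.get(c, []) for c in cluster])
            bd_hit = (base_eff != 0) & (target_stress == e)
            beta_arr[ce_hit, col_e] = beta_ess[ce_hit]
            beta_arr[bd_hit, col_e] = base_eff[bd_hit]
            for s, grad in cfg.level_gradient.items():
                col_s = colpos.get(f"s|e|g[{g}:{e}:{s}]")
                if col_s is None or grad == 0.0:
                    continue
                beta_arr[bd_hit, col_s] = grad * base_eff[bd_hit]
    beta = pd.DataFrame(beta_arr, index=genes, columns=X.columns)

    batches = design.batches
    if cfg.batch_log_fc is not None:
        raw = np.zeros((cfg.L, len(batches)))
        for bi, b in enumerate(batches):
            raw[:, bi] = np.log(cfg.batch_log_fc.get(b, 1.0))
    else:
        raw = rng.normal(0, cfg.batch_sigma, (cfg.L, len(batches)))
    batch_log = raw - raw.mean(axis=1, keepdims=True)  # geometric mean 1
    batch_df = pd.DataFrame(batch_log, index=genes, columns=batches)

    # strain columns carry no planted effect: backgrounds differ only through
    # their conditional responses, so control means are shared
    eta = (log_mu0[:, None]
           + beta.to_numpy() @ X.to_numpy().T)
    batch_idx = np.array([batches.index(b) for b in design.table["batch"]])
    eta = eta + batch_log[:, batch_idx]
    mu = np.exp(eta)

    # NB with Var = mu + mu^2/phi: numpy's (n, p) with n=phi, p=phi/(phi+mu);
    # large phi approaches the Poisson limit
    phi_col = np.clip(phi, 1e-6, 1e12)[:, None]
    total = rng.negative_binomial(phi_col, phi_col / (phi_col + mu))
    unique = rng.binomial(total, cfg.p_unique)

    sample_ids = design.sample_ids
    counts_total = CountMatrix(genes, sample_ids, total, "total")
    counts_unique = CountMatrix(genes, sample_ids, unique, "unique")

    rows = []
    levels_by = design.table.groupby(["strain", "stress"])["level"].unique()
    for g in design.strains:
        for e in [CONTROL_STRESS] + design.stresses(g):
            for s in levels_by.loc[(g, e)]:
                for gidx, tag in enumerate(genes):
                    lab = labels[gidx]
                    if lab == "essential":
                        cls = "essential"
                    elif e == CONTROL_STRESS:
                        cls = "neutral"
                    elif lab == "cond_essential" and e in cluster_map.get(
                            cluster[gidx], []):
                        cls = "cond_essential"
                    elif lab in ("cond_beneficial", "cond_detrimental") \
                            and target_stress[gidx] == e:
                        cls = lab
                    else:
                        cls = "neutral"
                    rows.append((tag, g, e, s, cls))
    gene_class = pd.DataFrame(
        rows, columns=["locus_tag", "strain", "stress", "level", "gene_class"])

    H_true = np.zeros((max(cfg.K_true, 1), cfg.L), dtype=int)
    for gidx in np.flatnonzero(cluster >= 0):
        H_true[cluster[gidx], gidx] = 1

    truth = SimTruth(genes=genes, gene_class=gene_class, true_beta=beta,
                     baseline_log_mu=log_mu0, dispersion=phi,
                     batch_log_factors=batch_df, H_true=H_true,
                     cluster_of_gene=cluster)
    return counts_total, counts_unique, design, truth


def simulate_gp_counts(H_true: np.ndarray, theta_true: np.ndarray,
                       T_true: np.ndarray, design: SampleDesign,
                       seed: int) -> CountMatrix:
    """Draw unique-site counts from the Gamma-Poisson essentiality model.

    ``H_true`` is K x L binary (1 = essential in that component), ``T_true``
    is L x 2 with column 0 the essential-regime mean and column 1 the
    nonessential mean, and ``theta_true`` holds component propensities per
    sample, shape (N, K) with N = number of design rows.  Counts are Poisson
    with rate sum_k theta[n, k] * phi[l, k] where phi picks the T column by
    membership.
    """
    H = np.asarray(H_true, dtype=int)
    T = np.asarray(T_true, dtype=float)
    theta = np.asarray(theta_true, dtype=float)
    K, L = H.shape
    if T.shape != (L, 2):
        raise ValueError(f"T_true must be {L} x 2, got {T.shape}")
    if np.any(T[:, 0] >= T[:, 1]):
        raise ValueError("essential column of T must be < nonessential column")
    if theta.ndim != 2 or theta.shape[1] != K:
        raise ValueError(
            f"theta_true has {theta.shape[-1] if theta.ndim == 2 else '?'} "
            f"components but H_true has K={K}")
    if np.any(theta < 0):
        raise ValueError("theta_true must be non-negative")
    N = len(design.sample_ids)
    if theta.shape[0] != N:
        raise ValueError(f"theta_true has {theta.shape[0]} rows for {N} samples")
    rng = np.random.default_rng(seed)
    phi = np.where(H.T == 1, T[:, [0]], T[:, [1]])  # L x K
    rate = phi @ theta.T                            # L x N
    counts = rng.poisson(rate)
    genes = [f"gene{i + 1:05d}" for i in range(L)]
    return CountMatrix(genes, design.sample_ids, counts, "unique")
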