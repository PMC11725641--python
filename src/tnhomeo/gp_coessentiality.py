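"""Hierarchical Gamma-Poisson model of shared conditional essentiality.

Unique insertion counts y_ijl (condition i, replicate j, gene l) are modeled
as a sum over K latent components ("networks" of co-essential genes):

    y_ijl ~ Pois(sum_k theta_ijk * phi_lk),      phi_lk = T[l, 0] if h_lk = 1
                                                 else T[l, 1],

where the L x 2 matrix T holds each gene's expected count in the essential
(column 0) and nonessential (column 1) regime, and H = (h_lk) in {0,1}^{KxL}
marks which genes are essential in which component.  The component
propensities follow a deep Gamma chain with a shrinkage prior on the number
of active components:

    rho0, tau ~ Gamma(eps0, eps0)
    theta''_k ~ Gamma(rho0 / K, tau)         per component
    theta'_ik ~ Gamma(theta''_k, 1)          per (condition, component)
    theta_ijk ~ Gamma(theta'_ik, 1)          per (condition, replicate,
                                             component)
    h_lk ~ Bernoulli(a_l)                    prior essentiality probability

Inference is a fully conjugate Gibbs sampler built by augment-and-
marginalize: counts are allocated to components multinomially, evidence is
propagated up the Gamma chain with Chinese-restaurant-table (CRT) auxiliary
counts and the marginalized negative-binomial representation, and H is
updated from the allocated counts by a Bernoulli log-odds step.  The
Gamma(rho0/K, tau) shape shrinks superfluous components toward zero mass,
realizing the nonparametric intent at a finite truncation K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.mixture import GaussianMixture

from .counts_io import CountMatrix, SampleDesign

log = logging.getLogger(__name__)

ESSENTIAL_MEAN_CAP = 10.0  # upper bound on the essential-regime mean


# ------------------------------------------------------------- T estimation

@dataclass
class ThresholdMatrix:
    """Per-gene expected counts in the essential / nonessential regime."""

    genes: list[str]
    T: np.ndarray            # L x 2, column 0 essential < column 1 nonessential
    weights: np.ndarray      # L x 2 mixture weights
    variances: np.ndarray    # L x 2 mixture variances
    fallback: np.ndarray     # bool per gene: EM collapsed, heuristic used


def estimate_T(counts_unique: CountMatrix, genes: list[str] | None = None,
               tau_ess: float = 3.0, seed: int = 0,
               eps: float = 0.1) -> ThresholdMatrix:
    """Two-component Gaussian mixture per gene on unique counts.

    The smaller-mean component is the essential regime; its mean is clamped
    to at most 10.  Genes where EM collapses (a component goes empty or the
    counts are constant) take a fallback: essential mean = min(counts) + eps,
    nonessential mean = mean of counts above ``tau_ess`` (floored above the
    essential mean).
    """
    if genes is not None:
        counts_unique = counts_unique.subset_genes(list(genes))
    Y = counts_unique.values.astype(float)
    L, N = Y.shape
    if N < 6:
        raise ValueError(f"need >= 6 observations per gene, have {N}")
    T = np.zeros((L, 2))
    wts = np.full((L, 2), 0.5)
    var = np.ones((L, 2))
    fb = np.zeros(L, dtype=bool)
    for li in range(L):
        y = Y[li]
        means = None
        if np.ptp(y) > 0:
            gm = GaussianMixture(n_components=2, random_state=seed,
                                 n_init=2, reg_covar=1e-3)
            try:
                gm.fit(y.reshape(-1, 1))
                resp = gm.predict(y.reshape(-1, 1))
                if len(np.unique(resp)) == 2:
                    order = np.argsort(gm.means_.ravel())
                    means = gm.means_.ravel()[order]
                    wts[li] = gm.weights_[order]
                    var[li] = gm.covariances_.ravel()[order]
            except Exception:
                means = None
        if means is None:
            fb[li] = True
            hi_part = y[y > tau_ess]
            hi = float(hi_part.mean()) if len(hi_part) else float(
                max(y.mean(), tau_ess + 1.0))
            means = np.array([float(y.min()) + eps, hi])
        ess = float(np.clip(means[0], eps, ESSENTIAL_MEAN_CAP))
        non = float(max(means[1], ess + eps, eps))
        if ess >= non:
            ess = non / 2.0
        T[li] = (ess, non)
    if fb.any():
        log.info("estimate_T: fallback path for %d/%d genes", int(fb.sum()), L)
    return ThresholdMatrix(counts_unique.genes, T, wts, var, fb)


# ------------------------------------------------------------- Gibbs sampler

@dataclass
class GPState:
    """One draw of the latent state."""

    H: np.ndarray          # K x L binary
    theta: np.ndarray      # N x K  (theta_ijk, one row per sample)
    theta_p: np.ndarray    # I x K  (theta'_ik, per condition)
    theta_pp: np.ndarray   # K      (theta''_k)
    rho0: float
    tau: float


@dataclass
class GPSamples:
    """Thinned post-burnin posterior draws plus posterior summaries."""

    states: list[GPState]
    h_mean: np.ndarray             # K x L inclusion probabilities
    theta_mean: np.ndarray         # N x K
    genes: list[str]
    conditions: list[str]
    cond_of_sample: np.ndarray
    loglik_trace: np.ndarray
    ess_info: pd.DataFrame = field(default_factory=pd.DataFrame)


class GibbsSampler:
    """CRT-augmented Gibbs sampler for the Gamma-Poisson hierarchy.

    ``cond_of_sample`` maps each of the N samples (condition x replicate) to
    its condition index i; ``a`` is the prior essentiality probability,
    scalar or per gene.
    """

    def __init__(self, Y: np.ndarray, cond_of_sample: np.ndarray,
                 T: np.ndarray, K: int, eps0: float = 0.1,
                 a: float | np.ndarray = 0.1,
                 rng: np.random.Generator | None = None,
                 init: str = "data"):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.Y = np.asarray(Y, dtype=np.int64)          # L x N
        self.L, self.N = self.Y.shape
        self.cond = np.asarray(cond_of_sample, dtype=int)
        self.I = int(self.cond.max()) + 1
        self.J = np.bincount(self.cond, minlength=self.I).astype(float)
        self.T = np.asarray(T, dtype=float)
        self.K = K
        self.eps0 = float(eps0)
        self.a = np.broadcast_to(np.asarray(a, dtype=float), (self.L,)).copy()
        if np.any((self.a < 0) | (self.a > 1)):
            raise ValueError("prior essentiality a must lie in [0, 1]")
        self.rng = rng or np.random.default_rng(0)
        self.state = self.sample_prior_state()
        if init == "data":
            self._init_from_data()
        elif init != "prior":
            raise ValueError(f"unknown init {init!r}")

    def _init_from_data(self) -> None:
        """Break the merged-mode symmetry before sampling.

        H is initialized by k-means clustering of the per-gene binary
        essentiality pattern across conditions (mean count below the
        geometric midpoint of the gene's two T regimes), and theta is
        warmed with a few allocation/theta-only sweeps while H is held
        fixed.  Purely an initialization: the stationary distribution is
        untouched."""
        M = np.zeros((self.L, self.I))
        for i in range(self.I):
            M[:, i] = self.Y[:, self.cond == i].mean(axis=1)
        midpoint = np.sqrt(self.T[:, 0] * self.T[:, 1])
        E = (M <= midpoint[:, None]).astype(float)
        hit = E.any(axis=1) & (self.a > 0)
        H = np.zeros((self.K, self.L), dtype=np.int8)
        idx = np.flatnonzero(hit)
        if len(idx):
            k_eff = int(min(self.K, len(idx)))
            if k_eff == 1:
                H[0, idx] = 1
            else:
                from sklearn.cluster import KMeans
                km = KMeans(n_clusters=k_eff, n_init=3,
                            random_state=int(self.rng.integers(2 ** 31)))
                lab = km.fit_predict(E[idx])
                for k in range(k_eff):
                    H[k, idx[lab == k]] = 1
        self.state.H = H
        for _ in range(3):
            self.sweep(update_H=False)

    # -- prior / data simulation (also used by joint-distribution checks)

    def sample_prior_state(self) -> GPState:
        r = self.rng
        rho0 = float(r.gamma(self.eps0, 1.0 / self.eps0))
        tau = float(r.gamma(self.eps0, 1.0 / self.eps0))
        tpp = r.gamma(max(rho0 / self.K, 1e-6), 1.0 / tau, self.K)
        tpp = np.maximum(tpp, 1e-12)
        tp = r.gamma(np.maximum(tpp[None, :], 1e-12), 1.0,
                     (self.I, self.K))
        tp = np.maximum(tp, 1e-12)
        th = r.gamma(np.maximum(tp[self.cond], 1e-12), 1.0)
        th = np.maximum(th, 1e-12)
        H = (r.random((self.K, self.L)) < self.a[None, :]).astype(np.int8)
        return GPState(H, th, tp, tpp, rho0, tau)

    def sample_data(self, state: GPState) -> np.ndarray:
        phi = self.phi_of(state.H)                       # L x K
        rate = phi @ state.theta.T                       # L x N
        return self.rng.poisson(rate)

    def phi_of(self, H: np.ndarray) -> np.ndarray:
        return np.where(H.T == 1, self.T[:, [0]], self.T[:, [1]])

    # -- sampler internals

    def _crt(self, m: np.ndarray, r_par: np.ndarray) -> np.ndarray:
        """Chinese-restaurant-table counts, elementwise over flat arrays."""
        m = np.asarray(m).ravel()
        r_par = np.asarray(r_par, dtype=float).ravel()
        out = np.zeros(m.shape, dtype=np.int64)
        for idx in range(len(m)):
            mi = int(m[idx])
            if mi == 0:
                continue
            ri = max(r_par[idx], 1e-12)
            probs = ri / (ri + np.arange(mi))
            out[idx] = int(np.sum(self.rng.random(mi) < probs))
        return out

    def _allocate(self, state: GPState, phi: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Multinomial allocation of y_nl over components.

        Returns (m_nk = counts per sample/component,
                 A_lk = counts per gene/component); the chain of binomials
        conserves the totals exactly."""
        L, N, K = self.L, self.N, self.K
        w = phi[:, None, :] * state.theta[None, :, :]    # L x N x K
        w_sum = w.sum(axis=2)
        remaining = self.Y.astype(np.int64).copy()
        m_nk = np.zeros((N, K), dtype=np.int64)
        A_lk = np.zeros((L, K), dtype=np.int64)
        rest = w_sum.copy()
        for k in range(K - 1):
            p = np.divide(w[:, :, k], np.maximum(rest, 1e-300),
                          out=np.zeros((L, N)), where=rest > 0)
            p = np.clip(p, 0.0, 1.0)
            yk = self.rng.binomial(remaining, p)
            remaining -= yk
            rest -= w[:, :, k]
            m_nk[:, k] = yk.sum(axis=0)
            A_lk[:, k] = yk.sum(axis=1)
        m_nk[:, K - 1] = remaining.sum(axis=0)
        A_lk[:, K - 1] = remaining.sum(axis=1)
        return m_nk, A_lk

    def sweep(self, update_H: bool = True) -> None:
        """One full Gibbs sweep over all latent variables.

        Order: collapsed Bernoulli update of H (marginalizing allocations),
        multinomial allocation, upward CRT pass (marginalizing the theta
        levels with their current shape parameters), then downward
        conjugate sampling of rho0, tau, theta'', theta', theta."""
        s = self.state
        r = self.rng
        if update_H:
            self._update_H(s)
        phi = self.phi_of(s.H)                           # L x K
        m_nk, A_lk = self._allocate(s, phi)
        Phi = phi.sum(axis=0)                            # K

        # upward: CRT counts with the current (pre-update) shapes
        t_nk = self._crt(m_nk, np.broadcast_to(s.theta_p[self.cond],
                                               m_nk.shape)).reshape(m_nk.shape)
        t_ik = np.zeros((self.I, self.K), dtype=np.int64)
        np.add.at(t_ik, self.cond, t_nk)
        tp_ik = self._crt(t_ik, np.broadcast_to(s.theta_pp[None, :],
                                                t_ik.shape)).reshape(
            t_ik.shape)
        tpp_k = self._crt(tp_ik.sum(axis=0),
                          np.full(self.K, s.rho0 / self.K))
        q1 = np.log1p(Phi)                               # K
        q2 = np.log1p(self.J[:, None] * q1[None, :])     # I x K
        Q_k = q2.sum(axis=0)
        q3 = np.log1p(Q_k / s.tau)

        # downward: conjugate draws top to bottom
        s.rho0 = float(max(r.gamma(self.eps0 + tpp_k.sum(),
                                   1.0 / (self.eps0 + q3.sum() / self.K)),
                           1e-8))
        shape_pp = np.maximum(s.rho0 / self.K + tp_ik.sum(axis=0), 1e-12)
        s.theta_pp = np.maximum(r.gamma(shape_pp, 1.0 / (s.tau + Q_k)), 1e-12)
        s.tau = float(max(r.gamma(self.eps0 + s.rho0,
                                  1.0 / (self.eps0 + s.theta_pp.sum())),
                          1e-8))
        rate_p = 1.0 + self.J[:, None] * q1[None, :]
        shape_p = np.maximum(s.theta_pp[None, :] + t_ik, 1e-12)
        s.theta_p = np.maximum(r.gamma(shape_p, 1.0 / rate_p), 1e-12)
        shape = np.maximum(s.theta_p[self.cond] + m_nk, 1e-12)
        s.theta = np.maximum(r.gamma(shape, 1.0 / (1.0 + Phi)[None, :]),
                             1e-12)

    def _update_H(self, s: GPState) -> None:
        """Collapsed Bernoulli update of h_lk, marginalizing allocations.

        Run before the allocation step of the sweep, so no allocation
        variables persist across the flip; the conditional compares the
        Poisson likelihood of the observed totals under rate
        base + theta_k * T[l, regime] for the two regimes."""
        r = self.rng
        with np.errstate(divide="ignore"):
            log_prior = np.log(self.a) - np.log1p(
                -np.clip(self.a, 0, 1 - 1e-12))
        log_prior = np.where(self.a <= 0, -np.inf,
                             np.where(self.a >= 1, np.inf, log_prior))
        phi = self.phi_of(s.H)                           # L x K
        rate = phi @ s.theta.T                           # L x N
        for k in range(self.K):
            base = rate - np.outer(phi[:, k], s.theta[:, k])
            base = np.maximum(base, 0.0)
            r1 = np.maximum(base + np.outer(self.T[:, 0], s.theta[:, k]),
                            1e-300)
            r0 = np.maximum(base + np.outer(self.T[:, 1], s.theta[:, k]),
                            1e-300)
            dll = np.sum(self.Y * (np.log(r1) - np.log(r0)) - (r1 - r0),
                         axis=1)
            logodds = np.clip(log_prior + dll, -700, 700)
            p_ess = np.where(np.isneginf(logodds), 0.0,
                             np.where(np.isposinf(logodds), 1.0,
                                      1.0 / (1.0 + np.exp(-logodds))))
            h_new = (r.random(self.L) < p_ess).astype(np.int8)
            changed = h_new != s.H[k]
            if changed.any():
                s.H[k] = h_new
                phi_new = np.where(h_new == 1, self.T[:, 0], self.T[:, 1])
                rate += np.outer(phi_new - phi[:, k], s.theta[:, k])
                phi[:, k] = phi_new

    def loglik(self) -> float:
        phi = self.phi_of(self.state.H)
        rate = np.maximum(phi @ self.state.theta.T, 1e-300)
        from scipy.special import gammaln
        return float(np.sum(self.Y * np.log(rate) - rate
                            - gammaln(self.Y + 1)))


def _condition_index(design: SampleDesign) -> tuple[np.ndarray, list[str]]:
    t = design.table
    labels = (t["strain"] + "/" + t["stress"] + "/" + t["level"]).tolist()
    uniq = list(dict.fromkeys(labels))
    idx = np.array([uniq.index(x) for x in labels])
    return idx, uniq


def gibbs_fit(counts_unique: CountMatrix, design: SampleDesign,
              T: ThresholdMatrix, K: int = 20, eps0: float = 0.1,
              a: float | np.ndarray = 0.1, iters: int = 2000,
              burnin: int = 1000, thin: int = 5,
              seed: int = 0) -> GPSamples:
    """Run the Gibbs sampler and return thinned post-burnin draws.

    ``counts_unique`` must be restricted to the retained genes and aligned
    with ``T``; conditions are the distinct (strain, stress, level) cells of
    the design and replicates the samples within each.
    """
    counts_unique = counts_unique.reorder_samples(design.sample_ids)
    if counts_unique.genes != T.genes:
        counts_unique = counts_unique.subset_genes(T.genes)
    cond_idx, cond_labels = _condition_index(design)
    rng = np.random.default_rng(seed)
    smp = GibbsSampler(counts_unique.values, cond_idx, T.T, K=K, eps0=eps0,
                       a=a, rng=rng)
    states: list[GPState] = []
    ll_trace = np.empty(iters)
    for it in range(iters):
        smp.sweep()
        ll_trace[it] = smp.loglik()
        if it >= burnin and (it - burnin) % thin == 0:
            s = smp.state
            states.append(GPState(s.H.copy(), s.theta.copy(),
                                  s.theta_p.copy(), s.theta_pp.copy(),
                                  s.rho0, s.tau))
    if not states:
        raise ValueError("no retained samples; increase iters beyond burnin")
    h_mean = np.mean([st.H for st in states], axis=0)
    theta_mean = np.mean([st.theta for st in states], axis=0)
    post_ll = ll_trace[burnin:]
    ess = _autocorr_ess(post_ll)
    info = pd.DataFrame({"statistic": ["loglik"],
                         "ess": [ess], "n_kept": [len(states)]})
    return GPSamples(states, h_mean, theta_mean, counts_unique.genes,
                     cond_labels, cond_idx, ll_trace, info)


def _autocorr_ess(x: np.ndarray) -> float:
    """Effective sample size via Geweke's initial-positive-sequence rule:
    sum autocorrelations in lag pairs until a pair sum goes non-positive."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.std(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1)
                                                      * x.var())
    s = acf[0]
    for t in range(1, (n - 1) // 2):
        pair = acf[2 * t - 1] + acf[2 * t]
        if pair <= 0:
            break
        s += 2.0 * pair
    return float(n / max(s, 1.0))


def align_components(samples: GPSamples) -> GPSamples:
    """Resolve label switching by matching each draw's components to the
    first retained draw on H agreement (Hungarian assignment)."""
    if not samples.states:
        return samples
    ref = samples.states[0].H
    K = ref.shape[0]
    aligned = []
    for st in samples.states:
        agree = (ref[:, None, :] == st.H[None, :, :]).sum(axis=2)
        _, perm = linear_sum_assignment(-agree)
        aligned.append(GPState(st.H[perm], st.theta[:, perm],
                               st.theta_p[:, perm], st.theta_pp[perm],
                               st.rho0, st.tau))
    h_mean = np.mean([st.H for st in aligned], axis=0)
    theta_mean = np.mean([st.theta for st in aligned], axis=0)
    return GPSamples(aligned, h_mean, theta_mean, samples.genes,
                     samples.conditions, samples.cond_of_sample,
                     samples.loglik_trace, samples.ess_info)


def summarize_components(samples: GPSamples, include_prob: float = 0.5,
                         merge_jaccard: float = 0.5) -> dict:
    """Per-condition loadings and per-component essential-gene lists.

    Loadings are posterior-mean theta averaged over replicates within each
    condition, normalized per condition to sum to 1 for display; components
    are ordered by total loading.  A finite truncation leaves the atoms
    exchangeable, so the chain can split one gene network across several
    components with the same essential-gene set; components whose gene sets
    overlap with Jaccard >= ``merge_jaccard`` are therefore merged (their
    loadings summed, h averaged weighted by loading) and the merge is
    logged.  Components with no gene at inclusion probability >=
    ``include_prob`` are reported as empty, not dropped, and never merged.
    """
    samples = align_components(samples)
    if len(samples.states) < 50:
        log.warning("summarize_components: only %d retained draws",
                    len(samples.states))
    I = len(samples.conditions)
    K = samples.h_mean.shape[0]
    theta_cond = np.zeros((I, K))
    for i in range(I):
        theta_cond[i] = samples.theta_mean[samples.cond_of_sample == i].mean(
            axis=0)
    tot = theta_cond.sum(axis=1, keepdims=True)
    loadings = theta_cond / np.maximum(tot, 1e-300)
    order = np.argsort(-loadings.sum(axis=0), kind="mergesort")
    loadings = loadings[:, order]
    h_mean = samples.h_mean[order]
    sets = [frozenset(np.flatnonzero(h_mean[k] >= include_prob))
            for k in range(K)]

    kept: list[int] = []
    merged_into: dict[int, int] = {}
    for k in range(K):
        target = None
        if sets[k]:
            for k0 in kept:
                if not sets[k0]:
                    continue
                jac = len(sets[k] & sets[k0]) / len(sets[k] | sets[k0])
                if jac >= merge_jaccard:
                    target = k0
                    break
        if target is None:
            kept.append(k)
        else:
            merged_into[k] = target
    if merged_into:
        log.info("summarize_components: merged %d duplicated component(s) "
                 "by gene-set overlap", len(merged_into))
    L_out = np.zeros((I, len(kept)))
    H_out = np.zeros((len(kept), h_mean.shape[1]))
    W_out = np.zeros(len(kept))
    for pos, k0 in enumerate(kept):
        members = [k0] + [k for k, t in merged_into.items() if t == k0]
        w = np.maximum(loadings[:, members].sum(axis=0), 1e-300)
        L_out[:, pos] = loadings[:, members].sum(axis=1)
        H_out[pos] = (h_mean[members] * w[:, None]).sum(axis=0) / w.sum()
        W_out[pos] = w.sum()
    order2 = np.argsort(-W_out, kind="mergesort")
    L_out = L_out[:, order2]
    H_out = H_out[order2]
    comp_genes = []
    for k in range(len(kept)):
        idx = np.flatnonzero(H_out[k] >= include_prob)
        comp_genes.append([samples.genes[i] for i in idx])
    names = [f"component_{k + 1}" for k in range(len(kept))]
    return {"loadings": pd.DataFrame(L_out, index=samples.conditions,
                                     columns=names),
            "h_mean": pd.DataFrame(H_out, columns=samples.genes,
                                   index=names),
            "essential_genes": dict(zip(names, comp_genes)),
            "n_merged": len(merged_into)}
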