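"""Model-Y knockoff selection of perturbation-predictor genes.

The roles of condition label and fitness profile are swapped: each sample's
label X_i is the proteotoxic stress class, and its r-dimensional fitness
vector Y_i (one entry per retained gene) becomes the feature matrix of a
multinomial-logistic model.  Second-order Gaussian knockoff copies of the
fitness features are built from a shrinkage-estimated covariance, an L1
multinomial-logistic path is fit on [Y, Y~], and the knockoff+ threshold on
the per-gene statistics W controls the FDR of the selected gene set at the
target level q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, eigh
from sklearn.covariance import LedoitWolf
from sklearn.linear_model import LogisticRegression

from .counts_io import SampleDesign
from .fitness_calls import FitnessMatrix

log = logging.getLogger(__name__)

DEFAULT_Q = 0.1


def build_swap_dataset(fitness: FitnessMatrix, design: SampleDesign,
                       strain: str, genes: list[str]
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """One row per stressed sample of the strain: label = stress class,
    features = standardized fitness values of the retained genes.

    Constant-variance genes are dropped with a log entry; kept columns have
    mean 0 and SD 1.
    """
    t = design.table
    rows = t[(t["strain"] == strain) & (t["stress"] != "control")]
    counts = rows["stress"].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"stress classes with < 2 samples for strain "
                         f"{strain!r}: {sorted(small.index)}")
    ids = rows["sample_id"].tolist()
    Y = fitness.per_sample.loc[genes, ids].T  # samples x genes
    sd = Y.std(axis=0, ddof=0)
    const = sd[sd <= 1e-12].index.tolist()
    if const:
        log.info("build_swap_dataset: dropping %d constant gene(s): %s",
                 len(const), const[:5])
        Y = Y.drop(columns=const)
        sd = sd.drop(const)
    Y = (Y - Y.mean(axis=0)) / sd
    X = rows["stress"].to_numpy()
    return X, Y


def _equicorrelated_s(Sigma: np.ndarray) -> np.ndarray:
    lam_min = float(eigh(Sigma, eigvals_only=True,
                         subset_by_index=[0, 0])[0])
    return np.full(Sigma.shape[0], min(1.0, 2.0 * lam_min))


def _sdp_s(Sigma: np.ndarray, n_pass: int = 2) -> np.ndarray:
    """Coordinate-ascent approximation to the SDP rule: maximize sum(s)
    subject to 2*Sigma - diag(s) >= 0 and 0 <= s <= diag(Sigma)."""
    r = Sigma.shape[0]
    s = _equicorrelated_s(Sigma).copy()

    def feasible(sv: np.ndarray) -> bool:
        M = 2.0 * Sigma - np.diag(sv)
        return float(eigh(M, eigvals_only=True,
                          subset_by_index=[0, 0])[0]) >= 1e-10
    for _ in range(n_pass):
        for j in range(r):
            lo, hi = s[j], float(min(1.0, 2.0 * Sigma[j, j]))
            for _ in range(20):
                mid = 0.5 * (lo + hi)
                trial = s.copy()
                trial[j] = mid
                if feasible(trial):
                    lo = mid
                else:
                    hi = mid
            s[j] = lo
    return s


def make_knockoffs(Y: pd.DataFrame | np.ndarray,
                   method: str = "equicorrelated",
                   seed: int = 0,
                   cov: np.ndarray | None = None) -> pd.DataFrame:
    """Second-order Gaussian knockoff copy of the feature matrix.

    Mean and covariance are estimated with Ledoit-Wolf shrinkage (required
    whenever r >= n), unless a known feature covariance is supplied via
    ``cov``; the cross-covariance target is Sigma - diag(s) with ``s`` from
    the equicorrelated rule (default) or an SDP approximation.
    Deterministic under ``seed``.
    """
    cols = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    Ym = np.asarray(Y, dtype=float)
    n, r = Ym.shape
    if n < 2:
        raise ValueError("need at least 2 rows to build knockoffs")
    mu = Ym.mean(axis=0)
    Sigma = LedoitWolf().fit(Ym).covariance_ if cov is None \
        else np.asarray(cov, dtype=float)
    corr = np.corrcoef(Ym, rowvar=False)
    dup = np.argwhere(np.triu(np.abs(corr) > 1 - 1e-10, k=1))
    if len(dup):
        log.info("make_knockoffs: %d near-duplicate column pair(s) handled "
                 "by shrinkage (first: %s)", len(dup), tuple(dup[0]))
    lam_min = float(eigh(Sigma, eigvals_only=True,
                         subset_by_index=[0, 0])[0])
    if lam_min <= 1e-10:
        raise ValueError(
            "shrunk covariance is not positive definite; increase shrinkage "
            "(more samples, or drop collinear features)")
    if method == "equicorrelated":
        s = _equicorrelated_s(Sigma)
    elif method == "sdp":
        s = _sdp_s(Sigma)
    else:
        raise ValueError(f"unknown knockoff method {method!r}")
    s = 0.999 * s  # keep the conditional covariance strictly PD
    D = np.diag(s)
    Sinv_D = np.linalg.solve(Sigma, D)
    cond_mean = mu + (Ym - mu) @ (np.eye(r) - Sinv_D)
    cond_cov = 2.0 * D - D @ Sinv_D
    cond_cov = 0.5 * (cond_cov + cond_cov.T)
    w, V = np.linalg.eigh(cond_cov)
    w = np.clip(w, 1e-12, None)
    C = V @ np.diag(np.sqrt(w))
    rng = np.random.default_rng(seed)
    Yt = cond_mean + rng.standard_normal((n, r)) @ C.T
    if cols is not None:
        return pd.DataFrame(Yt, columns=cols,
                            index=Y.index if isinstance(Y, pd.DataFrame)
                            else None)
    return pd.DataFrame(Yt)


@dataclass
class KnockoffRun:
    """Result of one knockoff-filter selection."""

    genes: list[str]
    W: pd.Series
    threshold: float
    selected: list[str]
    q: float
    statistic: str = "bic_coef_diff"
    lambda_selected: float | None = None
    details: dict = field(default_factory=dict)


def knockoff_threshold(W: np.ndarray, q: float) -> float:
    """Knockoff+ threshold: min t with (1 + #{W <= -t}) / #{W >= t} <= q."""
    if q >= 1.0:
        pos = W[W > 0]
        return float(pos.min()) if len(pos) else np.inf
    cand = np.sort(np.abs(W[W != 0]))
    for t in cand:
        ratio = (1.0 + np.sum(W <= -t)) / max(1, np.sum(W >= t))
        if ratio <= q:
            return float(t)
    return np.inf


def _l1_multinomial_path(X_labels: np.ndarray, F: np.ndarray,
                         n_lambda: int = 12, seed: int = 0):
    """L1 multinomial-logistic path; returns (lambdas, coef arrays)."""
    n = len(X_labels)
    Cs = np.geomspace(1e-2, 1e2, n_lambda)  # C = 1/(n*lambda) in sklearn
    clf = LogisticRegression(l1_ratio=1.0, solver="saga", C=Cs[0],
                             max_iter=3000, tol=1e-5, warm_start=True,
                             random_state=seed)
    path = []
    for C in Cs:
        clf.C = C
        clf.fit(F, X_labels)
        ll = -_log_loss_total(clf, F, X_labels)
        df = int(np.sum(np.abs(clf.coef_) > 1e-8))
        bic = -2.0 * ll + df * np.log(n)
        path.append((1.0 / (n * C), clf.coef_.copy(), bic))
    return path


def _log_loss_total(clf, F, labels) -> float:
    P = clf.predict_proba(F)
    idx = {c: i for i, c in enumerate(clf.classes_)}
    rows = np.arange(len(labels))
    cols = np.array([idx[c] for c in labels])
    return float(-np.sum(np.log(np.maximum(P[rows, cols], 1e-300))))


def _anova_f(M: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    from scipy.stats import f_oneway
    return f_oneway(*[M[g] for g in groups], axis=0).statistic


def knockoff_filter(X_labels: np.ndarray, Y: pd.DataFrame,
                    Ytilde: pd.DataFrame, q: float = DEFAULT_Q,
                    statistic: str = "anova_diff",
                    seed: int = 0) -> KnockoffRun:
    """Apply the knockoff filter to the swapped (label ~ fitness) model.

    Any statistic here is antisymmetric under swapping a feature with its
    knockoff, which is what the knockoff+ threshold needs for FDR control.

    ``statistic="anova_diff"`` (default): W_l = F_l - F~_l, the one-way
    ANOVA F of the feature across stress classes minus that of its
    knockoff.  A marginal statistic is the package default because at
    desk-scale n (~36 samples) sparse multinomial paths suffer from a
    discreteness pathology: the knockoff+ threshold needs at least
    ceil(1/q) candidate features, and planted genes with near-duplicate
    class profiles are conditionally redundant, so lasso-based W leaves too
    few candidates and the selection collapses to empty.

    ``statistic="bic_coef_diff"``: W_l = max_class |beta_l| - max_class
    |beta~_l| at the BIC-selected penalty on the L1 multinomial path
    (restricted to path points dense enough that knockoff+ can fire).
    ``statistic="entry_lambda"``: signed difference of the largest penalty
    at which each feature (or its knockoff) first enters the path.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    genes = list(Y.columns)
    F = np.column_stack([np.asarray(Y, dtype=float),
                         np.asarray(Ytilde, dtype=float)])
    r = len(genes)
    if statistic == "anova_diff":
        labels = np.asarray(X_labels)
        groups = [labels == c for c in np.unique(labels)]
        f_all = _anova_f(F, groups)
        W = f_all[:r] - f_all[r:]
        thr = knockoff_threshold(W, q)
        Ws = pd.Series(W, index=genes)
        selected = [g for g, w in Ws.items() if w >= thr and w > 0]
        return KnockoffRun(genes, Ws, thr, selected, q, statistic, None)
    path = _l1_multinomial_path(X_labels, F, seed=seed)
    if statistic == "bic_coef_diff":
        # the knockoff+ threshold cannot fire with fewer than ceil(1/q)
        # candidate features, so restrict BIC to path points dense enough
        # to make discoveries possible (symmetric in [Y, Ytilde], hence
        # exchangeability and FDR control are untouched)
        min_active = int(np.ceil(1.0 / q))
        dense = [p for p in path
                 if np.sum(np.max(np.abs(p[1]), axis=0) > 1e-8) >= min_active]
        pool = dense if dense else path
        lam_sel, coef, _ = min(pool, key=lambda p: p[2])
        mag = np.max(np.abs(coef), axis=0)
        W = mag[:r] - mag[r:]
    elif statistic == "entry_lambda":
        lam_sel = None
        entry = np.zeros(2 * r)
        for lam, coef, _ in sorted(path, key=lambda p: -p[0]):
            active = np.max(np.abs(coef), axis=0) > 1e-8
            newly = active & (entry == 0)
            entry[newly] = lam
        W = np.where(entry[:r] >= entry[r:],
                     entry[:r], -entry[r:])
        W[(entry[:r] == 0) & (entry[r:] == 0)] = 0.0
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    thr = knockoff_threshold(W, q)
    Ws = pd.Series(W, index=genes)
    selected = [g for g, w in Ws.items() if w >= thr and w > 0]
    return KnockoffRun(genes, Ws, thr, selected, q, statistic, lam_sel)


def select_predictors(fitness: FitnessMatrix, design: SampleDesign,
                      strain: str, genes: list[str], q: float = DEFAULT_Q,
                      method: str = "equicorrelated",
                      seed: int = 0) -> KnockoffRun:
    """End-to-end model-Y knockoff selection for one strain."""
    X, Y = build_swap_dataset(fitness, design, strain, genes)
    Yt = make_knockoffs(Y, method=method, seed=seed)
    return knockoff_filter(X, Y, Yt, q=q, seed=seed)


def overlap_table(runs: dict[str, KnockoffRun]) -> pd.DataFrame:
    """Strain x gene membership table of selected predictors (UpSet-style)."""
    all_genes = sorted({g for r in runs.values() for g in r.selected})
    return pd.DataFrame({s: [g in r.selected for g in all_genes]
                         for s, r in runs.items()},
                        index=all_genes)
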