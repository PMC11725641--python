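"""Per-gene regularized negative-binomial GLM and local-FDR calling.

For each gene l the unique-count vector y across samples follows
NB(mu, phi_l) with Var = mu + mu^2/phi_l and

    log mu = beta0 + x_g beta_g + x_e|g beta_e|g + x_s|e|g beta_s|e|g,

the nested genotype -> stress -> level indicator design.  Fitting proceeds
gene by gene: (1) dispersion by method of moments refined by maximizing the
Cox-Reid adjusted profile likelihood; (2) an L1-penalized fit by iteratively
reweighted least squares with coordinate descent over a decreasing lambda
path (the intercept is never penalized); (3) the lambda minimizing BIC on
the path is selected; (4) the selected support is refit unpenalized to give
debiased coefficients and Wald z-values.

Calling pools z-values of one coefficient family (stress-within-strain or
level-within-stress) across genes, estimates the marginal density f(z) by
Lindsey's method (a Poisson polynomial fit to histogram counts), the
empirical null N(mu0, sigma0) and null fraction pi0 by central matching,
and reports lfdr(z) = pi0 f0(z) / f(z) capped at 1.  A gene is called
detrimental when lfdr <= cut and z > 0 (insertions enriched: losing the
gene helps under the condition) and beneficial when lfdr <= cut and z < 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm

from .counts_io import CountMatrix, SampleDesign, build_design_matrix

log = logging.getLogger(__name__)

_MAX_PHI = 1e8
DEFAULT_LFDR_CUT = 0.2
MIN_POOL = 200  # below this the theoretical null is used and logged


# ---------------------------------------------------------------- fitting

@dataclass
class GlmGeneFit:
    """Fit summary for one gene."""

    locus_tag: str
    beta: pd.Series            # includes "const"; zeros off the support
    z: pd.Series               # Wald z per design coefficient
    phi: float
    lambda_selected: float
    converged: bool = True


@dataclass
class GlmResults:
    fits: list[GlmGeneFit]
    design_columns: list[str] = field(default_factory=list)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({f.locus_tag: f.beta for f in self.fits}).T

    def z_table(self) -> pd.DataFrame:
        return pd.DataFrame({f.locus_tag: f.z for f in self.fits}).T

    @property
    def converged(self) -> list[GlmGeneFit]:
        return [f for f in self.fits if f.converged]


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-10)
    return float(np.sum(gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
                        + phi * np.log(phi / (phi + mu))
                        + y * np.log(mu / (phi + mu))))


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Greedy earliest-first selection of a linearly independent column set."""
    keep: list[int] = []
    basis = np.zeros((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col.astype(float)
        nrm = np.linalg.norm(resid)
        if nrm > tol * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.column_stack([basis, resid / nrm])
    return keep


def estimate_dispersion(y: np.ndarray, X: np.ndarray) -> float:
    """Per-gene phi: method of moments, then adjusted profile likelihood.

    The Cox-Reid adjustment -0.5 log|X'WX| corrects the profile likelihood
    for estimating the mean parameters.
    """
    Xc = sm.add_constant(X, has_constant="add")
    keep = _independent_columns(Xc)
    Xc = Xc[:, keep]
    try:
        pois = sm.GLM(y, Xc, family=sm.families.Poisson()).fit()
        mu = pois.mu
    except Exception:
        mu = np.full_like(y, max(float(np.mean(y)), 1e-3), dtype=float)
    resid = float(np.sum((y - mu) ** 2) - np.sum(mu))
    phi0 = _MAX_PHI if resid <= 0 else float(
        np.clip(np.sum(mu ** 2) / resid, 1e-3, _MAX_PHI))
    if phi0 >= _MAX_PHI:
        return _MAX_PHI

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        try:
            fit = sm.GLM(y, Xc, family=sm.families.NegativeBinomial(
                alpha=1.0 / phi)).fit(maxiter=25)
            mu_l = fit.mu
        except Exception:
            mu_l = mu
        ll = _nb_loglik(y, mu_l, phi)
        W = mu_l / (1.0 + mu_l / phi)
        XtWX = Xc.T @ (Xc * W[:, None])
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            logdet = 0.0
        return -(ll - 0.5 * logdet)

    res = minimize_scalar(neg_apl,
                          bounds=(np.log(phi0) - 4, np.log(phi0) + 4),
                          method="bounded",
                          options={"xatol": 1e-2})
    return float(np.clip(np.exp(res.x), 1e-3, _MAX_PHI))


def _refit_support(y: np.ndarray, X: pd.DataFrame, support: list[str],
                   phi: float) -> tuple[pd.Series, pd.Series, float, bool]:
    """Unpenalized NB refit on a coefficient support (plus intercept).

    Aliased columns are dropped earliest-first (strain before stress before
    level, by design-matrix block order); dropped columns keep beta = 0 and
    z = 0.  Returns (beta, z, loglik, converged)."""
    cols = [c for c in X.columns if c in support]
    Xs = np.column_stack([np.ones(len(y))] +
                         [X[c].to_numpy() for c in cols])
    keep = _independent_columns(Xs)
    names = ["const"] + cols
    kept_names = [names[i] for i in keep]
    beta = pd.Series(0.0, index=["const"] + list(X.columns))
    z = pd.Series(0.0, index=list(X.columns))
    try:
        fit = sm.GLM(y, Xs[:, keep], family=sm.families.NegativeBinomial(
            alpha=1.0 / phi)).fit(maxiter=100)
        ok = bool(fit.converged)
        for name, b, se in zip(kept_names, fit.params, fit.bse):
            beta[name] = b
            if name != "const":
                z[name] = b / se if se > 0 else 0.0
        ll = _nb_loglik(y, fit.mu, phi)
    except Exception:
        return beta, z, -np.inf, False
    return beta, z, ll, ok


def _lambda_path(y: np.ndarray, X: np.ndarray, n_lambda: int) -> np.ndarray:
    # score at the intercept-only model bounds the entry point of each column
    ybar = max(float(np.mean(y)), 1e-6)
    score = np.abs(X.T @ (y - ybar)) / len(y)
    lam_max = max(float(score.max()), 1e-3) * 1.1
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambda)


def fit_gene(y: np.ndarray, X: pd.DataFrame, phi: float | None = None,
             lam: float | str = "bic", n_lambda: int = 8,
             z_families: tuple = ("e|g[", "s|e|g["),
             locus_tag: str = "") -> GlmGeneFit:
    """Full fitting recipe for one gene (see module docstring)."""
    y = np.asarray(y, dtype=float)
    if phi is None:
        phi = estimate_dispersion(y, X.to_numpy())
    if np.all(y == y[0]):
        # constant counts: intercept-only model at any penalty
        beta = pd.Series(0.0, index=["const"] + list(X.columns))
        beta["const"] = np.log(max(y[0], 1e-10)) if y[0] > 0 else -np.inf
        z = pd.Series(0.0, index=list(X.columns))
        return GlmGeneFit(locus_tag, beta, z, phi, 0.0, True)

    fam = sm.families.NegativeBinomial(alpha=1.0 / phi)
    n = len(y)
    if lam == "bic":
        path = _lambda_path(y, X.to_numpy(), n_lambda)
    elif float(lam) == 0.0:
        path = None
    else:
        path = np.array([float(lam)])

    if path is None:
        supports = [list(X.columns)]
    else:
        supports = []
        seen = set()
        lam_of_support: dict[tuple, float] = {}
        penalty_weight = np.r_[0.0, np.ones(X.shape[1])]  # free intercept
        Xc = sm.add_constant(X.to_numpy(), has_constant="add")
        start = None
        for lam_k in path:
            try:
                with warnings.catch_warnings():
                    # the penalized solution only proposes a support; the
                    # support is refit unpenalized, so loose convergence of
                    # the coordinate descent is acceptable
                    warnings.simplefilter("ignore")
                    reg = sm.GLM(y, Xc, family=fam).fit_regularized(
                        method="elastic_net", alpha=lam_k * penalty_weight,
                        L1_wt=1.0, start_params=start, maxiter=100)
                start = np.asarray(reg.params)
            except Exception:
                continue
            sup = tuple(c for c, b in zip(X.columns, np.asarray(reg.params)[1:])
                        if abs(b) > 1e-8)
            if sup not in seen:
                seen.add(sup)
                supports.append(list(sup))
                lam_of_support[sup] = float(lam_k)
        if not supports:
            supports = [[]]
            lam_of_support[()] = float(path[0])

    best = None
    for sup in supports:
        beta, z, ll, ok = _refit_support(y, X, sup, phi)
        df = 1 + len(sup)
        bic = -2.0 * ll + df * np.log(n)
        if np.isfinite(ll) and (best is None or bic < best[0]):
            best = (bic, sup, beta, z, ok)
    if best is None:  # every refit failed
        beta = pd.Series(0.0, index=["const"] + list(X.columns))
        beta["const"] = np.log(max(float(np.mean(y)), 1e-10))
        return GlmGeneFit(locus_tag, beta,
                          pd.Series(0.0, index=list(X.columns)), phi, np.nan,
                          False)
    _, sup, beta, z, ok = best
    lam_sel = 0.0 if path is None else lam_of_support.get(tuple(sup), 0.0)

    # z-values for family coefficients outside the selected support: refit
    # support + that single coefficient so every pooled z is a Wald z
    if path is not None:
        for c in X.columns:
            if c in sup or not any(c.startswith(f) for f in z_families):
                continue
            _, z1, ll1, _ = _refit_support(y, X, sup + [c], phi)
            if np.isfinite(ll1):
                z[c] = z1[c]
    return GlmGeneFit(locus_tag, beta, z, phi, lam_sel, ok)


def fit_nb_glm(counts_unique: CountMatrix, design: SampleDesign,
               lam: float | str = "bic", n_lambda: int = 8,
               coding: str = "full") -> GlmResults:
    """Fit the nested NB GLM gene by gene on batch-adjusted unique counts."""
    counts_unique = counts_unique.reorder_samples(design.sample_ids)
    X = build_design_matrix(design, coding=coding)
    fits = []
    n_fail = 0
    for li, tag in enumerate(counts_unique.genes):
        f = fit_gene(counts_unique.values[li], X, lam=lam,
                     n_lambda=n_lambda, locus_tag=tag)
        if not f.converged:
            n_fail += 1
        fits.append(f)
    if n_fail:
        log.warning("fit_nb_glm: %d/%d genes flagged non-converged "
                    "(excluded from lfdr pooling)", n_fail, len(fits))
    return GlmResults(fits, list(X.columns))


# ---------------------------------------------------------------- local FDR

@dataclass
class LfdrResult:
    table: pd.DataFrame   # locus_tag coefficient z lfdr call
    pi0: float
    mu0: float
    sigma0: float
    family: str
    lfdr_cut: float
    empirical_null: bool


def _lindsey_density(z: np.ndarray, n_bins: int = 90, degree: int = 7):
    """Marginal density f(z) by a Poisson polynomial fit to histogram counts.

    Returns (bin mids, fitted density at mids, callable density)."""
    lo, hi = np.min(z), np.max(z)
    span = hi - lo
    lo, hi = lo - 0.01 * span, hi + 0.01 * span
    counts, edges = np.histogram(z, bins=n_bins, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    scale = np.std(mids)
    basis = np.column_stack([((mids - np.mean(mids)) / scale) ** k
                             for k in range(degree + 1)])
    fit = sm.GLM(counts, basis, family=sm.families.Poisson()).fit(maxiter=200)
    dens_mids = fit.mu / (len(z) * width)

    coefs = np.asarray(fit.params)

    def density(zq: np.ndarray) -> np.ndarray:
        b = np.column_stack([((zq - np.mean(mids)) / scale) ** k
                             for k in range(degree + 1)])
        return np.exp(b @ coefs) / (len(z) * width)

    return mids, dens_mids, density


def _central_matching(mids: np.ndarray, dens: np.ndarray,
                      z: np.ndarray) -> tuple[float, float, float]:
    """Empirical null N(mu0, sigma0) and pi0 from the histogram center."""
    center = mids[np.argmax(dens)]
    sd = np.std(z)
    m = np.abs(mids - center) <= max(1.2 * sd, 3 * (mids[1] - mids[0]))
    m &= dens > 0
    if m.sum() < 5:
        return 0.0, 1.0, 1.0
    x = mids[m]
    w = np.log(dens[m])
    A = np.column_stack([np.ones(len(x)), x, x ** 2])
    a, b, c = np.linalg.lstsq(A, w, rcond=None)[0]
    if c >= -1e-12:
        return float(np.mean(z)), float(max(np.std(z), 1e-6)), 1.0
    sigma0 = float(np.sqrt(-1.0 / (2.0 * c)))
    mu0 = float(-b / (2.0 * c))
    log_pi0 = (a - b ** 2 / (4.0 * c)) + 0.5 * np.log(2 * np.pi * sigma0 ** 2)
    pi0 = float(np.clip(np.exp(log_pi0), 1e-6, 1.0))
    return mu0, sigma0, pi0


def lfdr_from_z(z: np.ndarray, null: str = "central") -> tuple[
        np.ndarray, float, float, float, bool]:
    """Local FDR per z-value.  Returns (lfdr, pi0, mu0, sigma0, empirical)."""
    z = np.asarray(z, dtype=float)
    if len(z) and np.all(z == z[0]) and len(z) > 1:
        raise ValueError("degenerate z histogram: all z-values identical")
    if len(z) < MIN_POOL:
        log.info("lfdr: only %d pooled z-values (< %d); using the "
                 "theoretical N(0,1) null with unit lfdr", len(z), MIN_POOL)
        return np.ones(len(z)), 1.0, 0.0, 1.0, False
    mids, dens, density = _lindsey_density(z)
    if null == "central":
        mu0, sigma0, pi0 = _central_matching(mids, dens, z)
    elif null == "theoretical":
        mu0, sigma0, pi0 = 0.0, 1.0, 1.0
    else:
        raise ValueError(f"unknown null estimator {null!r}")
    f = np.maximum(density(z), 1e-300)
    f0 = norm.pdf(z, mu0, sigma0)
    lfdr = np.minimum(pi0 * f0 / f, 1.0)
    # enforce monotone nonincreasing lfdr moving away from the null center
    for side in (z >= mu0, z < mu0):
        idx = np.flatnonzero(side)
        order = idx[np.argsort(np.abs(z[idx] - mu0))]
        lfdr[order] = np.minimum.accumulate(lfdr[order])
    return lfdr, pi0, mu0, sigma0, True


def call_lfdr(results: GlmResults, family: str = "e|g",
              lfdr_cut: float = DEFAULT_LFDR_CUT,
              null: str = "central") -> LfdrResult:
    """Pool one coefficient family across genes and call genes by lfdr."""
    prefix = family + "["
    rows = []
    for f in results.converged:
        for c, zv in f.z.items():
            if c.startswith(prefix):
                rows.append((f.locus_tag, c, float(zv)))
    tab = pd.DataFrame(rows, columns=["locus_tag", "coefficient", "z"])
    if not len(tab):
        return LfdrResult(tab.assign(lfdr=[], call=[]), 1.0, 0.0, 1.0,
                          family, lfdr_cut, False)
    lfdr, pi0, mu0, sigma0, empirical = lfdr_from_z(
        tab["z"].to_numpy(), null=null)
    tab["lfdr"] = lfdr
    tab["call"] = np.where(
        (lfdr <= lfdr_cut) & (tab["z"] > mu0), "detrimental",
        np.where((lfdr <= lfdr_cut) & (tab["z"] < mu0), "beneficial", "none"))
    return LfdrResult(tab, pi0, mu0, sigma0, family, lfdr_cut, empirical)
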