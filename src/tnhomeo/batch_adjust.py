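"""Batch-effect removal for integer count matrices.

Per gene, a negative-binomial GLM with biological-condition and batch terms
is fit; the batch log-fold-changes and batch-specific dispersions define a
"with-batch" NB distribution per cell, and centering the batch terms out
defines the batch-free NB distribution.  Each observed count is then mapped
through the quantiles, y' = Finv_free(F_batch(y)), with the discrete CDF
evaluated at the midpoint P(Y < y) + 0.5 P(Y = y), so the adjusted data stay
non-negative integers and an identity batch model maps every count to
itself.

Condition covariates are always included when estimating batch terms so real
biological effects are not absorbed into the correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import nbinom

from .counts_io import CountMatrix, SampleDesign

log = logging.getLogger(__name__)

_MAX_PHI = 1e8  # effectively Poisson


class BatchConfoundingError(ValueError):
    """A batch is perfectly confounded with a biological condition."""


@dataclass
class BatchModel:
    """Estimated batch structure for one count channel."""

    genes: list[str]
    samples: list[str]
    batches: list[str]
    gamma: pd.DataFrame        # genes x batches, log-FC, centered per gene
    delta: pd.DataFrame        # genes x batches, dispersion multiplier
    mu_batch: np.ndarray       # L x N fitted means including batch terms
    mu_free: np.ndarray        # L x N batch-free means
    phi_batch: np.ndarray      # L x n_batches dispersion (Var = mu + mu^2/phi)
    phi_free: np.ndarray       # L, batch-free dispersion
    batch_of_sample: np.ndarray | None = None  # N, index into `batches`
    identity: bool = False


def _condition_labels(design: SampleDesign) -> pd.Series:
    t = design.table
    return t["strain"] + "/" + t["stress"] + "/" + t["level"]


def _check_confounding(design: SampleDesign) -> None:
    cond = _condition_labels(design)
    batch = design.table["batch"]
    ct = pd.crosstab(cond, batch)
    nB = ct.shape[1]
    if nB < 2:
        return
    # a batch is confounded if every condition it contains occurs nowhere else
    for b in ct.columns:
        conds_in_b = ct.index[ct[b] > 0]
        if all((ct.loc[c] > 0).sum() == 1 for c in conds_in_b):
            raise BatchConfoundingError(
                f"batch {b!r} is perfectly confounded with condition(s) "
                f"{list(conds_in_b)}; batch effects are not estimable")


def _mom_phi(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments dispersion for Var = mu + mu^2/phi."""
    resid = float(np.sum((y - mu) ** 2) - np.sum(mu))
    if resid <= 0:
        return _MAX_PHI
    return float(np.clip(np.sum(mu ** 2) / resid, 1e-3, _MAX_PHI))


def estimate_batch_model(counts: CountMatrix, design: SampleDesign,
                         min_total: int = 1) -> BatchModel:
    """Fit the per-gene NB GLM with condition + batch terms.

    Genes whose counts sum below ``min_total``, or whose GLM fails, fall
    back to the identity adjustment for that gene.  With a single batch the
    whole model is the identity.
    """
    design = SampleDesign(design.table)  # validate
    order = design.sample_ids
    counts = counts.reorder_samples(order)
    batches = design.batches
    L, N = counts.shape
    if len(batches) < 2:
        mu = np.maximum(counts.values.astype(float), 0.5)
        return BatchModel(counts.genes, order, batches,
                          gamma=pd.DataFrame(0.0, index=counts.genes,
                                             columns=batches),
                          delta=pd.DataFrame(1.0, index=counts.genes,
                                             columns=batches),
                          mu_batch=mu, mu_free=mu,
                          phi_batch=np.full((L, len(batches)), _MAX_PHI),
                          phi_free=np.full(L, _MAX_PHI),
                          batch_of_sample=np.zeros(N, dtype=int),
                          identity=True)
    sizes = design.table["batch"].value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: "
                         f"{sorted(small.index)}")
    _check_confounding(design)

    cond = _condition_labels(design)
    Xc = pd.get_dummies(cond, drop_first=True, dtype=float)
    Xb = pd.get_dummies(design.table["batch"], drop_first=True, dtype=float)
    X = sm.add_constant(pd.concat([Xc.reset_index(drop=True),
                                   Xb.reset_index(drop=True)], axis=1),
                        has_constant="add")
    Xmat = X.to_numpy()
    batch_cols = [X.columns.get_loc(c) for c in Xb.columns]
    batch_of_sample = np.array([batches.index(b)
                                for b in design.table["batch"]])

    gamma = np.zeros((L, len(batches)))
    mu_batch = np.zeros((L, N))
    mu_free = np.zeros((L, N))
    phi_batch = np.full((L, len(batches)), _MAX_PHI)
    phi_free = np.full(L, _MAX_PHI)

    for li in range(L):
        y = counts.values[li].astype(float)
        if y.sum() < min_total:
            mu_batch[li] = mu_free[li] = np.maximum(y, 0.5)
            continue
        try:
            pois = sm.GLM(y, Xmat, family=sm.families.Poisson()).fit()
            phi0 = _mom_phi(y, pois.mu)
            fit = sm.GLM(y, Xmat,
                         family=sm.families.NegativeBinomial(alpha=1.0 / phi0)
                         ).fit(start_params=pois.params)
            params = fit.params
        except Exception:  # singular / non-convergent gene: identity fallback
            mu_batch[li] = mu_free[li] = np.maximum(y, 0.5)
            continue
        g_raw = np.zeros(len(batches))
        for c, b in zip(batch_cols, Xb.columns):
            g_raw[batches.index(b)] = params[c]
        g_cent = g_raw - g_raw.mean()
        gamma[li] = g_cent
        eta = Xmat @ params
        mu_b = np.exp(eta)
        mu_f = np.exp(eta - g_raw[batch_of_sample] + g_raw.mean())
        mu_batch[li] = mu_b
        mu_free[li] = mu_f
        phi_free[li] = _mom_phi(y, mu_b)  # pooled residual dispersion
        for bi in range(len(batches)):
            m = batch_of_sample == bi
            if m.sum() >= 2:
                phi_batch[li, bi] = _mom_phi(y[m], mu_b[m])
            else:
                phi_batch[li, bi] = phi_free[li]

    delta = phi_batch / np.maximum(phi_free[:, None], 1e-12)
    return BatchModel(counts.genes, order, batches,
                      gamma=pd.DataFrame(gamma, index=counts.genes,
                                         columns=batches),
                      delta=pd.DataFrame(delta, index=counts.genes,
                                         columns=batches),
                      mu_batch=mu_batch, mu_free=mu_free,
                      phi_batch=phi_batch, phi_free=phi_free,
                      batch_of_sample=batch_of_sample)


def _nb_params(mu: np.ndarray, phi: np.ndarray):
    phi = np.clip(phi, 1e-3, _MAX_PHI)
    mu = np.maximum(mu, 1e-8)
    return phi, phi / (phi + mu)


def adjust_counts(counts: CountMatrix, model: BatchModel) -> CountMatrix:
    """Quantile-map each count from its with-batch NB to the batch-free NB."""
    counts = counts.reorder_samples(model.samples)
    if counts.genes != model.genes:
        raise ValueError("batch model was estimated on a different gene list")
    if model.identity:
        return counts
    y = counts.values
    L, N = y.shape
    phi_cell = model.phi_batch[:, model.batch_of_sample]

    n_b, p_b = _nb_params(model.mu_batch, phi_cell)
    n_f, p_f = _nb_params(model.mu_free, model.phi_free[:, None] *
                          np.ones((1, N)))
    u = nbinom.cdf(y - 1, n_b, p_b) + 0.5 * nbinom.pmf(y, n_b, p_b)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    adj = nbinom.ppf(u, n_f, p_f)
    adj = np.nan_to_num(adj, nan=0.0, posinf=0.0).astype(np.int64)
    return counts.with_values(np.maximum(adj, 0))


def batch_adjust(counts: CountMatrix, design: SampleDesign,
                 **kwargs) -> tuple[CountMatrix, BatchModel]:
    """Estimate and apply the batch adjustment in one call."""
    model = estimate_batch_model(counts, design, **kwargs)
    adjusted = adjust_counts(counts, model)
    n_nonzero = int((model.gamma.to_numpy() != 0).any(axis=1).sum())
    log.info("batch adjustment: %d/%d genes with estimated batch terms",
             n_nonzero, len(model.genes))
    return adjusted, model
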