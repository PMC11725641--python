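import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from tnhomeo.counts_io import build_design_matrix
from tnhomeo.glm_lfdr import (GlmResults, call_lfdr, fit_gene, fit_nb_glm,
                              lfdr_from_z)


def nb_negloglik(params, y, X, phi):
    """Brute-force NB log-likelihood for the oracle fit."""
    eta = params[0] + X @ params[1:]
    mu = np.exp(np.clip(eta, -30, 30))
    ll = (gammaln(y + phi) - gammaln(phi) - gammaln(y + 1)
          + phi * np.log(phi / (phi + mu)) + y * np.log(mu / (phi + mu)))
    return -ll.sum()


@pytest.fixture(scope="module")
def toy_counts(two_group_design):
    rng = np.random.default_rng(42)
    X = build_design_matrix(two_group_design, coding="full")
    genes = []
    for mu_c, mu_h in [(50, 20), (10, 80), (30, 30), (5, 40), (100, 12)]:
        y = np.empty(8)
        ctrl = two_group_design.table["stress"].to_numpy() == "control"
        y[ctrl] = rng.poisson(mu_c, ctrl.sum())
        y[~ctrl] = rng.poisson(mu_h, (~ctrl).sum())
        genes.append(y)
    return np.array(genes), X


def test_mle_matches_bruteforce_oracle(toy_counts):
    """lambda=0 fits agree with a generic-optimizer MLE to 1e-4."""
    Y, X = toy_counts
    phi = 50.0
    # after alias dropping only one nested column remains estimable
    for y in Y:
        fit = fit_gene(y, X, phi=phi, lam=0.0)
        kept = [c for c in X.columns if abs(fit.beta[c]) > 0]
        Xk = X[kept].to_numpy()
        res = minimize(nb_negloglik, np.zeros(1 + len(kept)),
                       args=(y, Xk, phi), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        ours = np.r_[fit.beta["const"], [fit.beta[c] for c in kept]]
        np.testing.assert_allclose(ours, res.x, atol=1e-4)


def test_group_mean_identity(two_group_design):
    """With two groups the MLE reproduces the sample means exactly."""
    y = np.array([50, 20, 55, 18, 48, 22, 52, 21], dtype=float)
    X = build_design_matrix(two_group_design, coding="full")
    fit = fit_gene(y, X, phi=1e8, lam=0.0)
    ctrl = two_group_design.table["stress"].to_numpy() == "control"
    mc, mh = y[ctrl].mean(), y[~ctrl].mean()
    assert fit.beta["const"] == pytest.approx(np.log(mc), abs=1e-8)
    nested = [c for c in X.columns if abs(fit.beta[c]) > 0]
    assert len(nested) == 1
    assert fit.beta[nested[0]] == pytest.approx(np.log(mh / mc), abs=1e-8)


def test_constant_counts_give_intercept_only(two_group_design):
    X = build_design_matrix(two_group_design, coding="full")
    fit = fit_gene(np.full(8, 17.0), X, lam="bic")
    assert fit.beta["const"] == pytest.approx(np.log(17.0))
    assert (fit.beta.drop("const") == 0).all()


def test_poisson_limit(two_group_design):
    """NB at huge phi matches a Poisson GLM fit."""
    import statsmodels.api as sm
    y = np.array([50, 20, 55, 18, 48, 22, 52, 21], dtype=float)
    X = build_design_matrix(two_group_design, coding="full")
    fit = fit_gene(y, X, phi=1e8, lam=0.0)
    ctrl = (two_group_design.table["stress"] == "control").to_numpy()
    Xp = np.column_stack([np.ones(8), (~ctrl).astype(float)])
    pois = sm.GLM(y, Xp, family=sm.families.Poisson()).fit()
    kept = [c for c in X.columns if abs(fit.beta[c]) > 0]
    np.testing.assert_allclose([fit.beta["const"], fit.beta[kept[0]]],
                               pois.params, atol=1e-3)


def test_planted_effect_recovered_by_debiased_fit(two_group_design):
    """beta=1.0 planted on NB(mu, phi=1) genes: the unpenalized (debiased)
    fit averages back to the truth, mean estimate in [0.8, 1.2]."""
    rng = np.random.default_rng(9)
    X = build_design_matrix(two_group_design, coding="full")
    ctrl = (two_group_design.table["stress"] == "control").to_numpy()
    betas = []
    for _ in range(60):
        mu = np.where(ctrl, 30.0, 30.0 * np.e)
        phi = 1.0
        y = rng.negative_binomial(phi, phi / (phi + mu)).astype(float)
        if y[ctrl].sum() == 0 or y[~ctrl].sum() == 0:
            continue
        fit = fit_gene(y, X, lam=0.0)
        nested = fit.beta.drop("const")
        betas.append(nested[nested.abs() > 0].sum())
    assert 0.8 < np.mean(betas) < 1.2


class TestLfdr:
    def test_pure_null_calls_below_one_percent(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, 5000)
        lfdr, pi0, *_ = lfdr_from_z(z)
        assert np.mean(lfdr <= 0.2) <= 0.01
        assert pi0 > 0.9

    def test_mixed_signal_fdp_and_power(self):
        rng = np.random.default_rng(4)
        z = np.r_[rng.normal(0, 1, 4500), rng.normal(4, 1, 250),
                  rng.normal(-4, 1, 250)]
        truth = np.r_[np.zeros(4500), np.ones(500)]
        lfdr, *_ = lfdr_from_z(z)
        calls = lfdr <= 0.2
        fdp = np.sum(calls & (truth == 0)) / max(calls.sum(), 1)
        power = np.sum(calls & (truth == 1)) / 500
        assert fdp <= 0.25
        assert power >= 0.6

    def test_small_pool_uses_theoretical_null_unit_lfdr(self):
        lfdr, pi0, mu0, s0, empirical = lfdr_from_z(np.array([0.0]))
        assert lfdr[0] == 1.0
        assert not empirical

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            lfdr_from_z(np.zeros(500))

    def test_lfdr_monotone_from_null_center(self):
        rng = np.random.default_rng(5)
        z = np.r_[rng.normal(0, 1, 3000), rng.normal(3.5, 1, 300)]
        lfdr, pi0, mu0, *_ = lfdr_from_z(z)
        pos = z >= mu0
        order = np.argsort(z[pos])
        assert (np.diff(lfdr[pos][order]) <= 1e-9).all()


def test_call_lfdr_direction_convention(small_experiment):
    """Enriched insertions (z > 0) call detrimental, depleted beneficial."""
    ct, cu, design, truth = small_experiment
    sub = design.subset(design.table["stress"].isin(["control", "heat"]))
    cu_sub = cu.reorder_samples(sub.sample_ids)
    res = fit_nb_glm(cu_sub, sub, n_lambda=6)
    out = call_lfdr(res, family="e|g", lfdr_cut=0.2)
    tab = out.table
    if (tab["call"] == "detrimental").any():
        assert (tab.loc[tab["call"] == "detrimental", "z"] > out.mu0).all()
    if (tab["call"] == "beneficial").any():
        assert (tab.loc[tab["call"] == "beneficial", "z"] < out.mu0).all()
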