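import numpy as np
import pandas as pd
import pytest

from tnhomeo.counts_io import CountMatrix, SampleDesign
from tnhomeo.gp_coessentiality import (GibbsSampler, ThresholdMatrix,
                                       estimate_T, gibbs_fit,
                                       summarize_components)
from tnhomeo.simdata import simulate_gp_counts


def _design(conds, n_reps=4):
    rows = []
    for e, s in conds:
        for j in range(1, n_reps + 1):
            rows.append({"sample_id": f"{e}_{s}_r{j}", "strain": "wt",
                         "stress": e, "level": s, "replicate": j,
                         "batch": "b1"})
    return SampleDesign(pd.DataFrame(rows))


SIX_CONDS = [("heat", "low"), ("heat", "medium"), ("heat", "high"),
             ("oxidative", "low"), ("oxidative", "medium"),
             ("oxidative", "high")]


class TestEstimateT:
    def test_two_regime_recovery(self):
        rng = np.random.default_rng(0)
        L, N = 100, 40
        vals = np.empty((L, N))
        vals[:, :20] = np.clip(rng.normal(2, 1, (L, 20)), 0, None)
        vals[:, 20:] = rng.normal(60, 10, (L, 20))
        cm = CountMatrix([f"g{i}" for i in range(L)],
                         [f"s{i}" for i in range(N)],
                         np.round(vals).astype(int), "unique")
        T = estimate_T(cm)
        assert np.abs(T.T[:, 0] - 2).mean() < 1.0
        assert np.abs(T.T[:, 1] - 60).mean() < 5.0

    def test_essential_mean_clamped_at_ten(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(25, 2, (30, 15)),
                               rng.normal(90, 5, (30, 15))], axis=1)
        cm = CountMatrix([f"g{i}" for i in range(30)],
                         [f"s{i}" for i in range(30)],
                         np.round(vals).astype(int), "unique")
        T = estimate_T(cm)
        assert (T.T[:, 0] <= 10.0).all()

    def test_all_zero_gene_takes_fallback(self):
        cm = CountMatrix(["g0"], [f"s{i}" for i in range(8)],
                         np.zeros((1, 8), int), "unique")
        T = estimate_T(cm)
        assert T.fallback[0]
        assert 0 < T.T[0, 0] < T.T[0, 1]

    def test_too_few_observations_rejected(self):
        cm = CountMatrix(["g0"], ["s0", "s1"], np.array([[1, 2]]), "unique")
        with pytest.raises(ValueError, match="6"):
            estimate_T(cm)


class TestGibbsSampler:
    def test_allocation_conserves_counts(self):
        rng = np.random.default_rng(2)
        L, N, K = 20, 8, 3
        Y = rng.poisson(20, (L, N))
        T = np.column_stack([np.ones(L), np.full(L, 30.0)])
        smp = GibbsSampler(Y, np.repeat([0, 1], 4), T, K=K,
                           rng=np.random.default_rng(3))
        phi = smp.phi_of(smp.state.H)
        m_nk, A_lk = smp._allocate(smp.state, phi)
        np.testing.assert_array_equal(m_nk.sum(axis=1), Y.sum(axis=0))
        np.testing.assert_array_equal(A_lk.sum(axis=1), Y.sum(axis=1))

    def test_zero_prior_probability_forces_H_zero(self):
        d = _design(SIX_CONDS[:2], n_reps=3)
        L = 30
        rng = np.random.default_rng(4)
        cm = CountMatrix([f"gene{i+1:05d}" for i in range(L)], d.sample_ids,
                         rng.poisson(20, (L, 6)), "unique")
        T = ThresholdMatrix(cm.genes,
                            np.column_stack([np.ones(L), np.full(L, 20.0)]),
                            np.full((L, 2), .5), np.ones((L, 2)),
                            np.zeros(L, bool))
        out = gibbs_fit(cm, d, T, K=2, a=0.0, iters=60, burnin=20, thin=2,
                        seed=5)
        assert all((st.H == 0).all() for st in out.states)

    def test_conjugate_rate_matches_sample_mean(self):
        # K=1, H pinned nonessential, constant T: the fitted Poisson rate
        # must track the empirical mean count within 5%
        d = _design([("heat", "low")], n_reps=10)
        L = 40
        rng = np.random.default_rng(6)
        cm = CountMatrix([f"gene{i+1:05d}" for i in range(L)], d.sample_ids,
                         rng.poisson(35, (L, 10)), "unique")
        T = ThresholdMatrix(cm.genes,
                            np.column_stack([np.ones(L), np.full(L, 35.0)]),
                            np.full((L, 2), .5), np.ones((L, 2)),
                            np.zeros(L, bool))
        out = gibbs_fit(cm, d, T, K=1, a=0.0, iters=300, burnin=150, thin=2,
                        seed=7)
        rate = 35.0 * out.theta_mean.mean()
        assert abs(rate - cm.values.mean()) / cm.values.mean() < 0.05

    def test_planted_block_structure_recovered(self):
        d = _design(SIX_CONDS)
        L, K = 120, 2
        H = np.zeros((K, L), int)
        H[0, :40] = 1
        H[1, 40:80] = 1
        T = np.column_stack([np.full(L, 1.0), np.full(L, 60.0)])
        theta = np.array([[0.9, 0.1] if r.startswith("heat") else [0.1, 0.9]
                          for r in d.sample_ids])
        y = simulate_gp_counts(H, theta, T, d, seed=8)
        Tm = ThresholdMatrix(y.genes, T, np.full((L, 2), .5),
                             np.ones((L, 2)), np.zeros(L, bool))
        out = gibbs_fit(y, d, Tm, K=2, iters=300, burnin=150, thin=2,
                        seed=9)
        from itertools import permutations
        hm = out.h_mean
        acc = max(np.mean((hm[list(p)] > 0.5) == H)
                  for p in permutations(range(K)))
        assert acc >= 0.9

    def test_shrinkage_concentrates_on_true_components(self):
        # K=6 truncation on K_true=2 data: the top 2 components soak up
        # >= 80% of the total loading
        d = _design(SIX_CONDS)
        L = 80
        H = np.zeros((2, L), int)
        H[0, :25] = 1
        H[1, 25:50] = 1
        T = np.column_stack([np.full(L, 1.0), np.full(L, 60.0)])
        theta = np.array([[0.9, 0.1] if r.startswith("heat") else [0.1, 0.9]
                          for r in d.sample_ids])
        y = simulate_gp_counts(H, theta, T, d, seed=10)
        Tm = ThresholdMatrix(y.genes, T, np.full((L, 2), .5),
                             np.ones((L, 2)), np.zeros(L, bool))
        out = gibbs_fit(y, d, Tm, K=6, iters=800, burnin=400, thin=2,
                        seed=11)
        summ = summarize_components(out)
        load = summ["loadings"].to_numpy()
        assert load[:, :2].sum() / load.sum() >= 0.8

    def test_determinism_under_seed(self):
        d = _design(SIX_CONDS[:2], n_reps=3)
        L = 20
        rng = np.random.default_rng(12)
        cm = CountMatrix([f"gene{i+1:05d}" for i in range(L)], d.sample_ids,
                         rng.poisson(25, (L, 6)), "unique")
        T = ThresholdMatrix(cm.genes,
                            np.column_stack([np.ones(L), np.full(L, 25.0)]),
                            np.full((L, 2), .5), np.ones((L, 2)),
                            np.zeros(L, bool))
        a = gibbs_fit(cm, d, T, K=2, iters=50, burnin=20, thin=2, seed=13)
        b = gibbs_fit(cm, d, T, K=2, iters=50, burnin=20, thin=2, seed=13)
        np.testing.assert_array_equal(a.h_mean, b.h_mean)
        np.testing.assert_allclose(a.theta_mean, b.theta_mean)

    def test_loglik_finite_at_every_retained_sample(self):
        d = _design(SIX_CONDS[:3], n_reps=3)
        L = 25
        rng = np.random.default_rng(14)
        cm = CountMatrix([f"gene{i+1:05d}" for i in range(L)], d.sample_ids,
                         rng.poisson(15, (L, 9)), "unique")
        T = ThresholdMatrix(cm.genes,
                            np.column_stack([np.ones(L), np.full(L, 15.0)]),
                            np.full((L, 2), .5), np.ones((L, 2)),
                            np.zeros(L, bool))
        out = gibbs_fit(cm, d, T, K=3, iters=80, burnin=40, thin=2, seed=15)
        assert np.isfinite(out.loglik_trace).all()
        assert (out.ess_info["ess"] > 0).all()


class TestSummaries:
    def test_single_component_loadings_are_one(self):
        d = _design([("heat", "low")], n_reps=8)
        L = 30
        rng = np.random.default_rng(16)
        cm = CountMatrix([f"gene{i+1:05d}" for i in range(L)], d.sample_ids,
                         rng.poisson(30, (L, 8)), "unique")
        T = ThresholdMatrix(cm.genes,
                            np.column_stack([np.ones(L), np.full(L, 30.0)]),
                            np.full((L, 2), .5), np.ones((L, 2)),
                            np.zeros(L, bool))
        out = gibbs_fit(cm, d, T, K=1, iters=120, burnin=60, thin=1, seed=17)
        summ = summarize_components(out)
        np.testing.assert_allclose(summ["loadings"].to_numpy(), 1.0)

    def test_empty_components_reported_not_dropped(self):
        d = _design(SIX_CONDS[:2], n_reps=3)
        L = 20
        rng = np.random.default_rng(18)
        cm = CountMatrix([f"gene{i+1:05d}" for i in range(L)], d.sample_ids,
                         rng.poisson(40, (L, 6)), "unique")
        T = ThresholdMatrix(cm.genes,
                            np.column_stack([np.ones(L), np.full(L, 40.0)]),
                            np.full((L, 2), .5), np.ones((L, 2)),
                            np.zeros(L, bool))
        out = gibbs_fit(cm, d, T, K=4, a=0.001, iters=80, burnin=40, thin=2,
                        seed=19)
        summ = summarize_components(out)
        assert len(summ["essential_genes"]) == 4
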