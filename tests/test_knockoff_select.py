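import numpy as np
import pandas as pd
import pytest

from tnhomeo.counts_io import SampleDesign
from tnhomeo.fitness_calls import FitnessMatrix
from tnhomeo.knockoff_select import (build_swap_dataset, knockoff_filter,
                                     knockoff_threshold, make_knockoffs,
                                     _sdp_s)
from tnhomeo.simdata import default_design


def _fitness_fixture(r=12, seed=0):
    design = default_design(strains=("wt",), n_batches=1)
    stressed = design.subset(design.table["stress"] != "control")
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(r)]
    vals = rng.normal(0, 1, (r, len(stressed.sample_ids)))
    fm = FitnessMatrix(
        per_sample=pd.DataFrame(vals, index=genes,
                                columns=stressed.sample_ids),
        per_condition=pd.DataFrame(), design=design)
    return fm, design, genes


class TestBuildSwapDataset:
    def test_row_count_is_samples_by_genes(self):
        fm, design, genes = _fitness_fixture()
        X, Y = build_swap_dataset(fm, design, "wt", genes)
        assert Y.shape == (36, 12)          # 3 stresses x 3 levels x 4 reps
        assert len(X) == 36

    def test_constant_gene_dropped(self):
        fm, design, genes = _fitness_fixture()
        fm.per_sample.loc["g3"] = 1.25
        X, Y = build_swap_dataset(fm, design, "wt", genes)
        assert "g3" not in Y.columns

    def test_columns_standardized(self):
        fm, design, genes = _fitness_fixture()
        _, Y = build_swap_dataset(fm, design, "wt", genes)
        assert np.abs(Y.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(Y.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_small_stress_class_rejected(self):
        fm, design, genes = _fitness_fixture()
        keep = ~((design.table["stress"] == "heat")
                 & ~((design.table["replicate"] == 1)
                     & (design.table["level"] == "low")))
        small = design.subset(keep)  # heat reduced to a single sample
        fm2 = FitnessMatrix(fm.per_sample[
            [s for s in small.sample_ids if s in fm.per_sample.columns]],
            pd.DataFrame(), small)
        with pytest.raises(ValueError, match="heat"):
            build_swap_dataset(fm2, small, "wt", genes)


class TestMakeKnockoffs:
    def test_moments_match_target(self):
        # independent features with known identity covariance, n=500: the
        # joint covariance of [Y, Ytilde] approaches
        # [[I, I-sI], [I-sI, I]] with the equicorrelated s = min(1, 2*1) = 1
        rng = np.random.default_rng(11)
        n, r = 500, 4
        Y = pd.DataFrame(rng.standard_normal((n, r)))
        Yt = make_knockoffs(Y, seed=111, cov=np.eye(r))
        joint = np.cov(np.column_stack([Y, Yt]), rowvar=False)
        D = np.diag(np.full(r, 0.999))
        target = np.block([[np.eye(r), np.eye(r) - D],
                           [np.eye(r) - D, np.eye(r)]])
        assert np.abs(joint - target).max() < 0.1

    def test_identity_covariance_equicorrelated_s_is_one(self):
        from tnhomeo.knockoff_select import _equicorrelated_s
        np.testing.assert_allclose(_equicorrelated_s(np.eye(6)), 1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(rng.standard_normal((40, 6)))
        a = make_knockoffs(Y, seed=11)
        b = make_knockoffs(Y, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicated_columns_survive_shrinkage(self, caplog):
        rng = np.random.default_rng(4)
        Y = pd.DataFrame(rng.standard_normal((30, 5)))
        Y[5] = Y[0]  # exact duplicate
        with caplog.at_level("INFO"):
            Yt = make_knockoffs(Y, seed=5)
        assert Yt.shape == Y.shape
        assert "duplicate" in caplog.text

    def test_sdp_rule_feasible_and_at_least_equicorrelated(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((50, 6))
        Sigma = np.corrcoef(A, rowvar=False)
        from tnhomeo.knockoff_select import _equicorrelated_s
        s_eq = _equicorrelated_s(Sigma)
        s_sdp = _sdp_s(Sigma)
        assert (s_sdp >= s_eq - 1e-8).all()
        assert (s_sdp <= 1.0 + 1e-9).all()
        w = np.linalg.eigvalsh(2 * Sigma - np.diag(s_sdp))
        assert w.min() >= -1e-8


class TestKnockoffFilter:
    def test_threshold_hand_computed(self):
        W = np.array([5.0, 4.0, 3.0, 2.0, 1.0, -1.5, 0.5, 0.8, 0.9, 1.1,
                      2.2, 3.3])
        # q=0.5: smallest t with (1+#{W<=-t})/#{W>=t} <= 0.5
        assert knockoff_threshold(W, 0.5) == pytest.approx(0.5)
        # q=0.1: need 10 positives and no negatives above t -> t=1.6 fails;
        # with the single negative at -1.5, t must exceed 1.5 with >=10
        # positives above, impossible here -> +inf
        assert knockoff_threshold(W, 0.1) == np.inf

    def test_q_one_selects_all_positive(self):
        rng = np.random.default_rng(7)
        Y = pd.DataFrame(rng.standard_normal((36, 20)),
                         columns=[f"g{i}" for i in range(20)])
        Yt = make_knockoffs(Y, seed=8)
        labels = np.repeat(["a", "b", "c"], 12)
        run = knockoff_filter(labels, Y, Yt, q=1.0)
        assert set(run.selected) == set(run.W.index[run.W > 0])

    def test_gene_permutation_permutes_W(self):
        rng = np.random.default_rng(9)
        cols = [f"g{i}" for i in range(15)]
        Y = pd.DataFrame(rng.standard_normal((36, 15)), columns=cols)
        Yt = make_knockoffs(Y, seed=10)
        labels = np.repeat(["a", "b", "c"], 12)
        run1 = knockoff_filter(labels, Y, Yt, q=0.2)
        perm = rng.permutation(15)
        run2 = knockoff_filter(labels, Y.iloc[:, perm], Yt.iloc[:, perm],
                               q=0.2)
        pd.testing.assert_series_equal(run1.W[run2.W.index], run2.W)

    def test_null_simulation_controls_fdp(self):
        # pure-noise features: selections are rare, mean FDP stays near q
        q, reps = 0.1, 15
        labels = np.repeat(["a", "b", "c"], 12)
        fdps = []
        for seed in range(reps):
            rng = np.random.default_rng(200 + seed)
            Y = pd.DataFrame(rng.standard_normal((36, 80)),
                             columns=[f"g{i}" for i in range(80)])
            Y = (Y - Y.mean()) / Y.std(ddof=0)
            Yt = make_knockoffs(Y, seed=seed)
            run = knockoff_filter(labels, Y, Yt, q=q)
            fdps.append(1.0 if run.selected else 0.0)
        mc_se = np.std(fdps) / np.sqrt(reps)
        assert np.mean(fdps) <= q + 2 * mc_se + 1e-9

    def test_planted_predictors_found_with_lasso_statistic(self):
        # smaller instance so the multinomial path stays fast: the lasso
        # statistic still separates strong predictors
        rng = np.random.default_rng(12)
        n, r = 36, 40
        labels = np.repeat(["a", "b", "c"], 12)
        Y = rng.standard_normal((n, r))
        for j in range(6):
            mu = np.zeros(3)
            mu[j % 3] = 2.5
            Y[:, j] += np.array([mu[{"a": 0, "b": 1, "c": 2}[c]]
                                 for c in labels])
        Y = pd.DataFrame((Y - Y.mean(0)) / Y.std(0),
                         columns=[f"g{i}" for i in range(r)])
        Yt = make_knockoffs(Y, seed=13)
        run = knockoff_filter(labels, Y, Yt, q=0.34,
                              statistic="bic_coef_diff", seed=13)
        true = {f"g{j}" for j in range(6)}
        assert len(true & set(run.selected)) >= 3
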