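"""RR-BLUP / W-BLUP / Bayes-Cpi and the classical hybrid predictors."""

import numpy as np
import pandas as pd
import pytest

import hybridpred as hp
from hybridpred.predict import (
    BayesCpi,
    ChainSettings,
    RRBlup,
    WBlup,
    gblup_predict,
    gca_predict,
    mp_predict,
    predict_values,
    shrinkage_params,
)
from hybridpred.sim import CrossingPlan, hybrid_id

from conftest import random_design_matrices


class TestShrinkageParams:
    def test_forced_arithmetic(self):
        lam_a, _ = shrinkage_params(4.0, 1.0, 1.0, 4, 10)
        assert lam_a == pytest.approx(10.0)

    def test_linearity_in_marker_count(self):
        lam1, _ = shrinkage_params(2.0, 0.5, 0.5, 3, 100)
        lam2, _ = shrinkage_params(2.0, 0.5, 0.5, 3, 200)
        assert lam2 == pytest.approx(2 * lam1)

    @pytest.mark.parametrize("bad", [
        dict(sigma2_gca=0.0), dict(sigma2_sca=-1.0), dict(sigma2_e=0.0),
        dict(n_env=0), dict(n_marker=0),
    ])
    def test_invalid_inputs(self, bad):
        kwargs = dict(sigma2_e=1.0, sigma2_gca=1.0, sigma2_sca=1.0, n_env=2, n_marker=10)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            shrinkage_params(**kwargs)


def _dense_mme_solution(y, dm, lam_a, lam_d):
    """Brute-force inversion of the full (1 + 2m) block system."""
    m = dm.m
    C = np.hstack([np.ones((dm.n, 1)), dm.Z_A, dm.Z_D])
    M = C.T @ C + np.diag(np.r_[0.0, np.full(m, lam_a), np.full(m, lam_d)])
    return np.linalg.inv(M) @ (C.T @ y)


class TestRRBlup:
    def test_mme_equals_dense_inversion_both_routes(self):
        rng = np.random.default_rng(20)
        for seed in range(5):
            n, m = int(rng.integers(15, 50)), int(rng.integers(10, 120))
            dm = random_design_matrices(n, m, seed=seed)
            y = np.random.default_rng(seed).normal(size=n)
            lam_a, lam_d = 2.5, 8.0
            expected = _dense_mme_solution(y, dm, lam_a, lam_d)
            for method in ("direct", "dual"):
                eff = RRBlup(y, dm).fit(lam_a, lam_d, method=method)
                got = np.r_[eff.mu, eff.additive.to_numpy(), eff.dominance.to_numpy()]
                assert np.max(np.abs(got - expected)) < 1e-8

    def test_infinite_shrinkage_returns_training_mean(self):
        dm = random_design_matrices(25, 40, seed=3)
        y = np.random.default_rng(3).normal(5.0, 1.0, 25)
        eff = RRBlup(y, dm).fit(1e12, 1e12)
        np.testing.assert_allclose(eff.additive, 0.0, atol=1e-9)
        preds = eff.predict(dm)
        np.testing.assert_allclose(preds, y.mean(), atol=1e-6)

    def test_construction_recovery_noise_free(self):
        dm = random_design_matrices(80, 30, seed=4)
        rng = np.random.default_rng(4)
        a_true = rng.normal(0, 1, 30)
        y = 3.0 + dm.Z_A @ a_true
        eff = RRBlup(y, dm, include_dominance=False).fit(1e-6)
        preds = eff.predict(dm)
        assert np.corrcoef(preds, y)[0, 1] > 0.99

    def test_gblup_equivalence(self):
        dm = random_design_matrices(30, 60, seed=5)
        y = np.random.default_rng(5).normal(size=30)
        lam = 4.0
        rr = RRBlup(y, dm, include_dominance=False).fit(lam).predict(dm)
        gb = gblup_predict(y, dm, dm, lam)
        assert np.max(np.abs(rr.to_numpy() - gb.to_numpy())) < 1e-6

    def test_dominance_vanishes_as_lambda_d_grows(self):
        dm = random_design_matrices(40, 50, seed=6)
        y = np.random.default_rng(6).normal(size=40)
        with_d = RRBlup(y, dm).fit(3.0, 1e10).predict(dm)
        additive = RRBlup(y, dm, include_dominance=False).fit(3.0).predict(dm)
        assert np.max(np.abs(with_d.to_numpy() - additive.to_numpy())) < 1e-4

    def test_invalid_lambdas(self):
        dm = random_design_matrices(10, 5, seed=7)
        y = np.zeros(10)
        with pytest.raises(ValueError):
            RRBlup(y, dm).fit(0.0, 1.0)
        with pytest.raises(ValueError):
            RRBlup(y, dm).fit(1.0, None)


class TestWBlup:
    def test_weight_one_reduces_to_rrblup(self):
        dm = random_design_matrices(30, 40, seed=8)
        y = np.random.default_rng(8).normal(size=30)
        functional = [dm.marker_ids[3], dm.marker_ids[17], dm.marker_ids[30]]
        wb = WBlup(y, dm, functional, weight=1.0).fit(2.0, 5.0).predict(dm)
        rr = RRBlup(y, dm).fit(2.0, 5.0).predict(dm)
        assert np.max(np.abs(wb.to_numpy() - rr.to_numpy())) < 1e-6

    def test_functional_marker_estimated_closer_to_truth(self):
        # one large-effect QTL declared functional: W-BLUP shrinks it less
        wins = 0
        for seed in range(50):
            dm = random_design_matrices(100, 150, seed=100 + seed)
            rng = np.random.default_rng(200 + seed)
            a_true = rng.normal(0, 0.05, 150)
            big = 2.0
            a_true[7] = big
            y = dm.Z_A @ a_true + rng.normal(0, 0.5, 100)
            lam = 50.0
            rr = RRBlup(y, dm, include_dominance=False).fit(lam)
            wb = WBlup(y, dm, [dm.marker_ids[7]], weight=100.0,
                       include_dominance=False).fit(lam)
            if abs(wb.additive.iloc[7] - big) < abs(rr.additive.iloc[7] - big):
                wins += 1
        assert wins >= 45  # >= 90% of 50 replicates

    def test_unknown_or_duplicate_functional_ids(self):
        dm = random_design_matrices(10, 5, seed=9)
        y = np.zeros(10)
        with pytest.raises(KeyError):
            WBlup(y, dm, ["nope"])
        with pytest.raises(ValueError):
            WBlup(y, dm, [dm.marker_ids[0], dm.marker_ids[0]])


@pytest.fixture(scope="module")
def sparse_data():
    dm = random_design_matrices(120, 200, seed=10)
    rng = np.random.default_rng(10)
    beta = np.zeros(200)
    qtl = [20, 60, 100, 140, 180]
    beta[qtl] = rng.choice([-1.0, 1.0], 5) * rng.uniform(0.8, 1.2, 5)
    y = dm.Z_A @ beta + rng.normal(0, 0.6, 120)
    return dm, y, qtl


class TestBayesCpi:

    def test_pi_zero_collapses_to_rrblup(self, sparse_data):
        dm, y, _ = sparse_data
        chain = ChainSettings(iterations=1500, burn_in=500, thin=5, seed=1)
        eff = BayesCpi(y, dm, include_dominance=False).fit(chain, fix_pi=0.0)
        lam = 0.36 / (np.var(y) / 200)
        rr = RRBlup(y, dm, include_dominance=False).fit(lam)
        r = np.corrcoef(eff.additive, rr.additive)[0, 1]
        assert r > 0.98

    def test_sparse_architecture_recovered(self, sparse_data):
        dm, y, qtl = sparse_data
        hits = 0
        for seed in range(10):
            chain = ChainSettings(iterations=1200, burn_in=400, thin=4, seed=seed)
            eff = BayesCpi(y, dm, include_dominance=False).fit(chain)
            pip = eff.inclusion["pip_additive"]
            top = set(pip.sort_values(ascending=False).index[: max(10, len(qtl))])
            if all(dm.marker_ids[q] in top for q in qtl):
                hits += 1
        assert hits >= 8  # top 5% of 200 markers in >= 80% of chains

    def test_seeded_chain_bitwise_reproducible(self, sparse_data):
        dm, y, _ = sparse_data
        chain = ChainSettings(iterations=400, burn_in=100, thin=2, seed=77)
        e1 = BayesCpi(y, dm, include_dominance=False).fit(chain)
        e2 = BayesCpi(y, dm, include_dominance=False).fit(chain)
        assert np.array_equal(e1.additive.to_numpy(), e2.additive.to_numpy())
        assert e1.posterior_pi == e2.posterior_pi

    def test_longer_chain_consistent_posterior(self, sparse_data):
        dm, y, _ = sparse_data
        short = BayesCpi(y, dm, include_dominance=False).fit(
            ChainSettings(1500, 500, 5, seed=3)
        )
        long = BayesCpi(y, dm, include_dominance=False).fit(
            ChainSettings(3000, 500, 5, seed=4)
        )
        r = np.corrcoef(short.additive, long.additive)[0, 1]
        assert r > 0.95

    def test_invalid_chain_settings(self):
        with pytest.raises(ValueError):
            ChainSettings(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainSettings(iterations=100, burn_in=10, thin=0)


class TestPredictValues:
    def test_all_zero_effects_constant(self):
        dm = random_design_matrices(8, 6, seed=11)
        eff = hp.MarkerEffects(
            "rrblup", 4.2,
            pd.Series(0.0, index=list(dm.marker_ids)),
            pd.Series(0.0, index=list(dm.marker_ids)),
        )
        np.testing.assert_allclose(predict_values(eff, dm), 4.2)

    def test_dot_product_oracle(self):
        dm = random_design_matrices(1, 4, seed=12)
        a = pd.Series([0.5, -1.0, 2.0, 0.1], index=list(dm.marker_ids))
        d = pd.Series([0.2, 0.0, -0.3, 1.0], index=list(dm.marker_ids))
        eff = hp.MarkerEffects("rrblup", 1.0, a, d)
        expected = 1.0 + float(dm.Z_A[0] @ a.to_numpy() + dm.Z_D[0] @ d.to_numpy())
        assert predict_values(eff, dm).iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_panel_mismatch_lists_markers(self):
        dm = random_design_matrices(5, 4, seed=13)
        other = random_design_matrices(5, 3, seed=13)
        eff = hp.MarkerEffects(
            "rrblup", 0.0, pd.Series(0.0, index=list(other.marker_ids))
        )
        with pytest.raises(ValueError, match="mismatch"):
            predict_values(eff, dm)


class TestClassicalPredictors:
    def _additive_factorial(self):
        females, males = ["F1", "F2", "F3"], ["M1", "M2"]
        plan = CrossingPlan(tuple((f, m) for f in females for m in males))
        f_eff = {"F1": 1.0, "F2": 0.0, "F3": -1.0}
        m_eff = {"M1": 0.5, "M2": -0.5}
        blues = pd.Series(
            {hybrid_id(f, m): 20 + f_eff[f] + m_eff[m] for f, m in plan.crosses}
        )
        return plan, blues

    def test_gca_predict_recovers_saturated_truth(self):
        plan, blues = self._additive_factorial()
        gca = hp.gca_sca(blues, plan)
        preds = gca_predict(gca, plan)
        np.testing.assert_allclose(preds.loc[blues.index], blues, atol=1e-8)

    def test_gca_predict_unknown_parent_raises(self):
        plan, blues = self._additive_factorial()
        gca = hp.gca_sca(blues, plan)
        t0_plan = CrossingPlan((("F9", "M9"),))
        with pytest.raises(KeyError):
            gca_predict(gca, t0_plan)

    def test_mp_arithmetic_and_symmetry(self):
        blues = pd.Series({"F1": 40.0, "M1": 50.0})
        plan = CrossingPlan((("F1", "M1"),))
        assert mp_predict(blues, plan).iloc[0] == pytest.approx(45.0)

    def test_mp_whole_plan_brute_force(self, small_panel, factorial):
        geno, parents = small_panel
        plan, _, _ = factorial
        rng = np.random.default_rng(14)
        blues = pd.Series(rng.normal(50, 5, len(parents.all_ids)), index=parents.all_ids)
        preds = mp_predict(blues, plan)
        for (f, m), h in zip(plan.crosses, plan.hybrid_ids):
            assert preds[h] == pytest.approx((blues[f] + blues[m]) / 2)

    def test_mp_missing_parent(self):
        with pytest.raises(KeyError):
            mp_predict(pd.Series({"F1": 1.0}), CrossingPlan((("F1", "M1"),)))
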