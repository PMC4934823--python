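"""Two-stage analysis, heterosis, combining ability, variance components."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import hybridpred as hp
from hybridpred.pheno import (
    adjust_entry_means_per_env,
    blues_across_env,
    combining_ability_variances,
    gca_sca,
    heritability,
    mid_parent_stats,
    two_stage_blues,
    variance_components_one_step,
)
from hybridpred.reml import factor_covariance, reml_fit
from hybridpred.sim import CrossingPlan, TrialDesign, hybrid_id


def _balanced_plots(gen_means, n_trials=2, n_reps=2, env="env1", noise=0.0, seed=0):
    """Complete block toy layout: every genotype in every trial and rep."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_trials):
        for r in range(n_reps):
            for g, mu in gen_means.items():
                rows.append(
                    (g, env, f"{env}_t{t}", f"{env}_t{t}_r{r}", f"{env}_t{t}_r{r}_b0",
                     "trait", mu + noise * rng.normal())
                )
    return pd.DataFrame(rows, columns=list(hp.sim.PLOT_COLUMNS))


class TestStageOne:
    def test_noise_free_balanced_equals_raw_means(self):
        means = {"g1": 40.0, "g2": 50.0, "g3": 45.0}
        plots = _balanced_plots(means)
        est = adjust_entry_means_per_env(plots, "env1")
        for g, mu in means.items():
            assert est[g] == pytest.approx(mu, abs=1e-8)

    def test_gls_oracle_at_reml_estimates(self):
        # 3 genotypes x 2 trials with noise; compare against a brute-force
        # GLS solve at the REML variance estimates
        means = {"g1": 40.0, "g2": 50.0, "g3": 45.0}
        plots = _balanced_plots(means, noise=1.0, seed=3)
        est = adjust_entry_means_per_env(plots, "env1")

        genos, gi = np.unique(plots["genotype"], return_inverse=True)
        X = np.zeros((len(plots), len(genos)))
        X[np.arange(len(plots)), gi] = 1.0
        terms = [
            factor_covariance(pd.factorize(plots[c])[0], c)
            for c in ("trial", "replication", "block")
        ]
        res = reml_fit(plots["value"].to_numpy(), X, terms)
        V = res.variances["error"] * np.eye(len(plots))
        for t in terms:
            V += res.variances[t.name] * t.G
        beta = np.linalg.solve(X.T @ np.linalg.solve(V, X), X.T @ np.linalg.solve(V, plots["value"].to_numpy()))
        np.testing.assert_allclose(est.to_numpy(), beta, atol=1e-6)

    def test_unobserved_genotype_absent(self):
        plots = _balanced_plots({"g1": 1.0, "g2": 2.0})
        est = adjust_entry_means_per_env(plots, "env1")
        assert "g3" not in est.index

    def test_single_genotype_errors(self):
        plots = _balanced_plots({"g1": 1.0})
        with pytest.raises(ValueError):
            adjust_entry_means_per_env(plots, "env1")

    def test_lme4_oracle_stage1(self, tmp_path):
        # independent REML implementation on the same small layout
        means = {f"g{i}": float(v) for i, v in enumerate([40, 44, 48, 52, 41, 47])}
        plots = _balanced_plots(means, n_trials=3, noise=1.5, seed=9)
        est = adjust_entry_means_per_env(plots, "env1")
        csv = tmp_path / "plots.csv"
        plots.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            fit <- lmer(value ~ 0 + genotype + (1|trial) + (1|replication) + (1|block),
                        data=d, REML=TRUE,
                        control=lmerControl(check.nobs.vs.nlev="ignore",
                                            check.nobs.vs.nRE="ignore"))
            fe <- fixef(fit)
            write.csv(data.frame(name=names(fe), est=fe), "{tmp_path}/fe.csv",
                      row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        fe = pd.read_csv(tmp_path / "fe.csv")
        fe["genotype"] = fe["name"].str.replace("genotype", "", regex=False)
        merged = fe.set_index("genotype")["est"]
        for g in means:
            assert est[g] == pytest.approx(merged[g], abs=1e-4)


class TestStageTwo:
    def test_single_environment_identity(self):
        s1 = pd.DataFrame({"genotype": ["a", "b"], "environment": "e1", "mean": [1.0, 2.0]})
        blues = blues_across_env(s1)
        assert blues["a"] == 1.0 and blues["b"] == 2.0

    def test_balanced_two_env_equals_simple_mean(self):
        rng = np.random.default_rng(4)
        genos = [f"g{i}" for i in range(6)]
        rows = []
        for env in ("e1", "e2"):
            shift = {"e1": 1.0, "e2": -2.0}[env]
            for g in genos:
                rows.append((g, env, 10 + hash(g) % 5 + shift + rng.normal(0, 0.3)))
        df = pd.DataFrame(rows, columns=["genotype", "environment", "mean"])
        blues = blues_across_env(df)
        simple = df.groupby("genotype")["mean"].mean()
        np.testing.assert_allclose(blues.sort_index(), simple.sort_index(), atol=1e-6)

    def test_two_stage_noise_free_recovers_truth(self, small_panel, factorial):
        geno, parents = small_panel
        plan, _, both = factorial
        vals, _ = hp.simulate_genetic_values(both, n_qtl=20, dominance_sd=0.3, seed=6)
        design = TrialDesign(environments=2, trials_per_env=2, n_checks=2)
        plots = hp.simulate_trials(vals, design, {}, seed=7, mu=20.0,
                                   hybrid_ids=plan.hybrid_ids)
        blues, _ = two_stage_blues(plots)
        for g in vals.index:
            assert blues[g] == pytest.approx(20.0 + vals[g], abs=1e-8)


class TestHeterosis:
    def test_forced_arithmetic(self):
        plan = CrossingPlan((("F1", "M1"), ("F2", "M1")))
        blues = pd.Series(
            {"F1": 40.0, "F2": 40.0, "M1": 50.0,
             hybrid_id("F1", "M1"): 45.0, hybrid_id("F2", "M1"): 49.5}
        )
        stats = mid_parent_stats(blues, plan)
        assert stats.loc["F1xM1", "MP"] == 45.0
        assert stats.loc["F1xM1", "MPH"] == pytest.approx(0.0)
        assert stats.loc["F2xM1", "MPH"] == pytest.approx(10.0)
        assert stats.attrs["mean_abs_mph"] == pytest.approx(5.0)

    def test_missing_parent_names_cross(self):
        plan = CrossingPlan((("F1", "M1"),))
        blues = pd.Series({"F1": 1.0, hybrid_id("F1", "M1"): 2.0})
        with pytest.raises(KeyError, match="M1"):
            mid_parent_stats(blues, plan)

    def test_zero_mid_parent_rejected(self):
        plan = CrossingPlan((("F1", "M1"),))
        blues = pd.Series({"F1": -1.0, "M1": 1.0, hybrid_id("F1", "M1"): 0.5})
        with pytest.raises(ZeroDivisionError):
            mid_parent_stats(blues, plan)

    def test_additive_simulation_mph_zero(self, small_panel, factorial):
        # heterosis null: additive genetics, no noise -> MPH identically 0
        geno, parents = small_panel
        plan, _, both = factorial
        vals, _ = hp.simulate_genetic_values(both, n_qtl=25, dominance_sd=0.0, seed=8)
        blues = 100.0 + vals  # offset keeps MP away from 0
        stats = mid_parent_stats(blues, plan)
        np.testing.assert_allclose(stats["MPH"], 0.0, atol=1e-10)


class TestGcaSca:
    def test_saturated_additive_case(self):
        females, males = ["F1", "F2", "F3"], ["M1", "M2"]
        plan = CrossingPlan(tuple((f, m) for f in females for m in males))
        f_eff = {"F1": 1.0, "F2": -0.5, "F3": -0.5}
        m_eff = {"M1": 2.0, "M2": -2.0}
        blues = pd.Series(
            {hybrid_id(f, m): 10 + f_eff[f] + m_eff[m] for f, m in plan.crosses}
        )
        res = gca_sca(blues, plan)
        np.testing.assert_allclose(res.sca, 0.0, atol=1e-8)
        assert res.mu == pytest.approx(10.0)

    def test_balanced_anova_identity(self):
        rng = np.random.default_rng(12)
        females, males = ["F1", "F2", "F3"], ["M1", "M2"]
        plan = CrossingPlan(tuple((f, m) for f in females for m in males))
        blues = pd.Series(
            {hybrid_id(f, m): rng.normal(50, 3) for f, m in plan.crosses}
        )
        res = gca_sca(blues, plan)
        table = blues.to_frame("y")
        table["f"] = [h.split("x")[0] for h in table.index]
        table["m"] = [h.split("x")[1] for h in table.index]
        grand = table["y"].mean()
        for f in females:
            assert res.gca_f[f] == pytest.approx(
                table[table["f"] == f]["y"].mean() - grand, abs=1e-8
            )
        for m in males:
            assert res.gca_m[m] == pytest.approx(
                table[table["m"] == m]["y"].mean() - grand, abs=1e-8
            )

    def test_sum_to_zero_constraints(self):
        rng = np.random.default_rng(13)
        females = [f"F{i}" for i in range(5)]
        males = [f"M{i}" for i in range(3)]
        crosses = [(f, m) for f in females for m in males]
        plan = CrossingPlan(tuple(crosses[:-2]))  # unbalanced
        blues = pd.Series({hybrid_id(f, m): rng.normal() for f, m in plan.crosses})
        res = gca_sca(blues, plan)
        assert res.gca_f.sum() == pytest.approx(0.0, abs=1e-10)
        assert res.gca_m.sum() == pytest.approx(0.0, abs=1e-10)

    def test_combining_ability_variance_recovery(self):
        rng = np.random.default_rng(14)
        females = [f"F{i}" for i in range(60)]
        males = [f"M{i}" for i in range(15)]
        plan = CrossingPlan(tuple((f, m) for f in females for m in males))
        fe = {f: rng.normal(0, 1.0) for f in females}
        me = {m: rng.normal(0, 1.0) for m in males}
        blues = pd.Series(
            {hybrid_id(f, m): fe[f] + me[m] + rng.normal(0, 0.5) for f, m in plan.crosses}
        )
        ca = combining_ability_variances(blues, plan)
        assert ca["gca"] == pytest.approx(1.0, rel=0.5)
        assert ca["sca"] == pytest.approx(0.25, rel=0.5)


class TestVarianceComponents:
    def test_halved_lrt_zero_statistic_gives_half(self, small_panel, factorial):
        geno, parents = small_panel
        plan, _, both = factorial
        rng = np.random.default_rng(15)
        vals = pd.Series(rng.normal(0, 1, both.n_individuals), index=both.individual_ids)
        design = TrialDesign(environments=2, trials_per_env=2, n_checks=0)
        # lines variance simulated at zero: line values constant
        vals.loc[list(parents.all_ids)] = 0.0
        plots = hp.simulate_trials(vals, design, {"error": 1.0}, seed=16,
                                   hybrid_ids=plan.hybrid_ids)
        vc = variance_components_one_step(
            plots, line_ids=list(parents.all_ids), hybrid_ids=plan.hybrid_ids
        )
        p = vc.lrt_pvalue("lines")
        assert 0.25 <= p <= 0.5 + 1e-9

    def test_nonzero_component_significant(self, small_panel, factorial):
        geno, parents = small_panel
        plan, _, both = factorial
        rng = np.random.default_rng(17)
        vals = pd.Series(rng.normal(0, 2.0, both.n_individuals), index=both.individual_ids)
        design = TrialDesign(environments=2, trials_per_env=2, n_checks=0)
        plots = hp.simulate_trials(vals, design, {"error": 0.3}, seed=18,
                                   hybrid_ids=plan.hybrid_ids)
        vc = variance_components_one_step(
            plots, line_ids=list(parents.all_ids), hybrid_ids=plan.hybrid_ids
        )
        assert vc.lrt_pvalue("hybrids") < 1e-4
        assert vc.variances["hybrids"] > 0.5

    def test_summary_lists_all_components(self, small_panel, factorial):
        geno, parents = small_panel
        plan, _, both = factorial
        vals = pd.Series(0.5, index=both.individual_ids)
        vals.iloc[::2] = -0.5
        plots = hp.simulate_trials(
            vals, TrialDesign(environments=2, n_checks=0), {"error": 0.5}, seed=19,
            hybrid_ids=plan.hybrid_ids,
        )
        vc = variance_components_one_step(
            plots, line_ids=list(parents.all_ids), hybrid_ids=plan.hybrid_ids
        )
        assert set(vc.summary().index) == set(hp.pheno.ONE_STEP_COMPONENTS)


class TestHeritability:
    def test_perfect_heritability(self):
        h = heritability({"hybrids": 1.0, "hybrids_x_env": 0.0, "error": 0.0}, 3, 2)
        assert h.entry_mean == 1.0 and h.plot == 1.0

    def test_forced_arithmetic(self):
        vc = {"hybrids": 1.0, "hybrids_x_env": 1.0, "error": 2.0}
        h = heritability(vc, 2, 2)
        assert h.entry_mean == pytest.approx(0.5)
        assert h.plot == pytest.approx(0.25)

    def test_monotone_in_environments(self):
        vc = {"lines": 1.0, "lines_x_env": 0.8, "error": 1.5}
        values = [heritability(vc, e, 2, "lines").entry_mean for e in (1, 2, 4, 8)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_entry_mean_at_least_plot_basis(self):
        vc = {"hybrids": 0.4, "hybrids_x_env": 0.3, "error": 1.1}
        h = heritability(vc, 4, 2)
        assert h.entry_mean >= h.plot

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            heritability({"hybrids": 1.0, "error": 1.0}, 0, 2)
        with pytest.raises(ValueError):
            heritability({"hybrids": 0.0, "hybrids_x_env": 0.0, "error": 0.0}, 2, 2)
        with pytest.raises(ValueError):
            heritability({"hybrids": 1.0, "error": 1.0}, 2, 2, group="checks")


class TestOutlierScreen:
    def test_gross_error_removed_clean_data_untouched(self):
        means = {"g1": 40.0, "g2": 50.0, "g3": 45.0}
        plots = _balanced_plots(means, noise=0.5, seed=21)
        clean = hp.pheno.remove_outliers(plots, cutoff=4.0)
        assert len(clean) == len(plots)
        spiked = plots.copy()
        spiked.loc[0, "value"] += 100.0
        screened = hp.pheno.remove_outliers(spiked, cutoff=4.0)
        assert len(screened) == len(plots) - 1
        assert screened["value"].max() < 100.0

    def test_invalid_cutoff(self):
        plots = _balanced_plots({"g1": 1.0, "g2": 2.0})
        with pytest.raises(ValueError):
            hp.pheno.remove_outliers(plots, cutoff=0.0)
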