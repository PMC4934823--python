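"""Synthetic-population generator: coding, determinism and moment oracles."""

import numpy as np
import pandas as pd
import pytest

import hybridpred as hp
from hybridpred.sim import TrialDesign, hybrid_id


class TestSimulateParents:
    def test_inbred_coding_and_shape(self):
        geno, parents = hp.simulate_parents(2, 1, n_markers=4, n_chromosomes=1, seed=0)
        assert geno.dosages.shape == (3, 4)
        assert set(np.unique(geno.values())) <= {0.0, 2.0}
        assert parents.n_female == 2 and parents.n_male == 1

    def test_seed_contract_bitwise(self):
        a, _ = hp.simulate_parents(8, 2, n_markers=30, n_chromosomes=2, seed=42)
        b, _ = hp.simulate_parents(8, 2, n_markers=30, n_chromosomes=2, seed=42)
        assert a.dosages.equals(b.dosages)
        assert a.map.equals(b.map)

    def test_maf_distribution_against_allele_count_oracle(self):
        geno, _ = hp.simulate_parents(
            120, 15, n_markers=2000, n_chromosomes=21, maf_low=0.05, maf_high=0.5, seed=3
        )
        # brute-force per-marker allele count
        dos = geno.values()
        counts = dos.sum(axis=0) / 2.0  # reference-allele copies per marker / 2
        p = counts / dos.shape[0]
        maf = np.minimum(p, 1 - p)
        assert maf.min() >= 0.05 - 0.03
        assert maf.max() <= 0.5 + 0.03
        pd.testing.assert_series_equal(
            geno.minor_allele_freq(), pd.Series(maf, index=geno.marker_ids), check_names=False
        )

    def test_map_sorted_within_chromosome(self):
        geno, _ = hp.simulate_parents(5, 2, n_markers=100, n_chromosomes=4, seed=1)
        for _, grp in geno.map.groupby("chrom"):
            assert (np.diff(grp["pos_cm"]) >= 0).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf_low": 0.4, "maf_high": 0.2},
            {"maf_low": 0.01},
            {"n_markers": 2, "n_chromosomes": 5},
        ],
    )
    def test_invalid_arguments(self, kwargs):
        base = dict(n_female=3, n_male=2, n_markers=10, n_chromosomes=2, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            hp.simulate_parents(**base)


class TestFactorial:
    def test_full_factorial(self, small_panel):
        _, parents = small_panel
        plan = hp.make_factorial(parents, "full")
        assert len(plan) == parents.n_female * parents.n_male

    def test_paper_scale_subset_unique(self):
        _, parents = hp.simulate_parents(120, 15, n_markers=25, n_chromosomes=2, seed=0)
        plan = hp.make_factorial(parents, 1604, seed=9)
        assert len(plan) == 1604
        assert len(set(plan.crosses)) == 1604

    def test_over_request_errors(self, small_panel):
        _, parents = small_panel
        with pytest.raises(ValueError):
            hp.make_factorial(parents, parents.n_female * parents.n_male + 1)


class TestHybridGenotypes:
    def test_per_locus_average_oracle(self):
        geno, parents = hp.simulate_parents(10, 5, n_markers=20, n_chromosomes=2, seed=2)
        plan = hp.make_factorial(parents, 25, seed=1)
        hyb = hp.derive_hybrid_genotypes(geno, plan)
        for (f, m), hid in zip(plan.crosses, plan.hybrid_ids):
            expected = (geno.dosages.loc[f].to_numpy() + geno.dosages.loc[m].to_numpy()) / 2
            np.testing.assert_array_equal(hyb.dosages.loc[hid].to_numpy(), expected)

    def test_unlike_homozygotes_yield_heterozygote(self, factorial, small_panel):
        geno, _ = small_panel
        plan, hyb, _ = factorial
        f, m = plan.crosses[0]
        hid = hybrid_id(f, m)
        unlike = geno.dosages.loc[f] != geno.dosages.loc[m]
        assert (hyb.dosages.loc[hid][unlike] == 1.0).all()
        assert (hyb.dosages.loc[hid][~unlike] == geno.dosages.loc[f][~unlike]).all()

    def test_unknown_parent_errors(self, small_panel):
        geno, _ = small_panel
        plan = hp.CrossingPlan((("nope", "M001"),))
        with pytest.raises(KeyError):
            hp.derive_hybrid_genotypes(geno, plan)


class TestGeneticValues:
    def test_additive_architecture_forces_mid_parent(self, small_panel, factorial):
        geno, _ = small_panel
        plan, _, both = factorial
        vals, _ = hp.simulate_genetic_values(both, n_qtl=20, dominance_sd=0.0, seed=5)
        for f, m in plan.crosses:
            assert vals[hybrid_id(f, m)] == pytest.approx((vals[f] + vals[m]) / 2, abs=1e-12)

    def test_single_qtl_span_is_twice_effect(self, small_panel):
        geno, _ = small_panel
        vals, truth = hp.simulate_genetic_values(
            geno, n_qtl=0, large_qtl=(geno.marker_ids[0], 1.7), seed=0
        )
        span = vals.max() - vals.min()
        assert span == pytest.approx(2 * 1.7)

    def test_summation_oracle(self):
        geno, _ = hp.simulate_parents(100, 100, n_markers=80, n_chromosomes=2, seed=7)
        vals, truth = hp.simulate_genetic_values(
            geno, n_qtl=50, additive_sd=0.5, dominance_sd=0.3, seed=8
        )
        # brute-force sum over QTL
        dos = geno.dosages[truth.qtl_marker_ids].to_numpy()
        expected = (dos - 1.0) @ truth.additive_effects + (dos == 1.0) @ truth.dominance_effects
        np.testing.assert_allclose(vals.to_numpy(), expected, atol=1e-12)

    def test_genotypic_variance_matches_2pq_a2(self):
        # truth round-trip: var(g) ~ sum_q 2 p q a^2 for inbreds (x2 for 0/2 coding)
        geno, _ = hp.simulate_parents(2000, 2000, n_markers=300, n_chromosomes=3, seed=9)
        vals, truth = hp.simulate_genetic_values(geno, n_qtl=100, dominance_sd=0.0, seed=10)
        p = geno.allele_freq()[truth.qtl_marker_ids].to_numpy()
        # additive code z = dosage - 1 has variance 4p(1-p) on inbreds
        expected_var = np.sum(4 * p * (1 - p) * truth.additive_effects**2)
        assert np.var(vals) == pytest.approx(expected_var, rel=0.1)

    def test_unknown_large_qtl_errors(self, small_panel):
        geno, _ = small_panel
        with pytest.raises(KeyError):
            hp.simulate_genetic_values(geno, n_qtl=1, large_qtl=("missing", 1.0), seed=0)


class TestTrials:
    def test_degenerate_noise_returns_mu_plus_g(self, small_panel):
        geno, parents = small_panel
        vals = pd.Series(
            np.arange(geno.n_individuals, dtype=float), index=geno.individual_ids
        )
        design = TrialDesign(environments=2, trials_per_env=2, n_checks=2)
        plots = hp.simulate_trials(vals, design, {}, seed=0, mu=7.0, hybrid_ids=[])
        non_check = plots[~plots["genotype"].str.startswith("chk")]
        merged = non_check.assign(expected=lambda d: 7.0 + vals.loc[d["genotype"]].to_numpy())
        np.testing.assert_allclose(merged["value"], merged["expected"], atol=1e-12)

    def test_six_environment_levels(self, small_panel):
        geno, _ = small_panel
        vals = pd.Series(0.0, index=geno.individual_ids)
        plots = hp.simulate_trials(vals, TrialDesign(environments=6), {}, seed=1)
        assert plots["environment"].nunique() == 6

    def test_residual_variance_sample_moment(self):
        geno, _ = hp.simulate_parents(300, 100, n_markers=10, n_chromosomes=1, seed=3)
        vals = pd.Series(0.0, index=geno.individual_ids)
        design = TrialDesign(environments=4, trials_per_env=2, n_checks=0)
        plots = hp.simulate_trials(vals, design, {"error": 2.5}, seed=4, hybrid_ids=[])
        assert plots["value"].var() == pytest.approx(2.5, rel=0.1)

    def test_partial_replication_and_checks(self, small_panel, factorial):
        geno, parents = small_panel
        plan, _, both = factorial
        vals = pd.Series(0.0, index=both.individual_ids)
        design = TrialDesign(
            environments=1, trials_per_env=3, replicated_hybrid_fraction=0.29, n_checks=10
        )
        plots = hp.simulate_trials(vals, design, {}, seed=5, hybrid_ids=plan.hybrid_ids)
        counts = plots.groupby("genotype")["value"].count()
        lines = [g for g in parents.all_ids]
        assert (counts.loc[lines] == 2).all()  # lines in both replications
        checks = [g for g in counts.index if g.startswith("chk")]
        assert len(checks) == 10
        assert (counts.loc[checks] == 6).all()  # every trial, both reps
        hyb_counts = counts.loc[plan.hybrid_ids]
        frac = (hyb_counts == 2).mean()
        assert frac == pytest.approx(0.29, abs=0.1)

    def test_negative_variance_rejected(self, small_panel):
        geno, _ = small_panel
        vals = pd.Series(0.0, index=geno.individual_ids)
        with pytest.raises(ValueError):
            hp.simulate_trials(vals, TrialDesign(), {"error": -1.0}, seed=0)


class TestIO:
    def test_tsv_round_trip(self, toy_geno, tmp_path):
        p, mp_ = tmp_path / "g.tsv", tmp_path / "m.tsv"
        toy_geno.to_tsv(p, mp_)
        back = hp.GenotypeMatrix.from_tsv(p, mp_)
        pd.testing.assert_frame_equal(back.dosages, toy_geno.dosages)
        pd.testing.assert_frame_equal(back.map, toy_geno.map)

    def test_vcf_export_round_trip(self, toy_geno, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        path = tmp_path / "g.vcf"
        toy_geno.to_vcf(path)
        back = {}
        vcf = cyvcf2.VCF(str(path))
        samples = vcf.samples
        for var in vcf:
            back[var.ID] = dict(zip(samples, [sum(gt[:2]) for gt in var.genotypes]))
        for mk in toy_geno.marker_ids:
            for ind in toy_geno.individual_ids:
                assert back[mk][ind] == toy_geno.dosages.at[ind, mk]


class TestLDProxy:
    def test_copies_are_in_strong_ld_with_focal(self, small_panel):
        geno, _ = small_panel
        focal = geno.marker_ids[5]
        out = hp.sim.add_ld_proxy(geno, focal, n_copies=3, flip_rate=0.05, seed=1)
        assert out.n_markers == geno.n_markers + 3
        r2 = hp.markers.ld_r2(out, [focal] + [f"{focal}_ld{i}" for i in (1, 2, 3)])
        off_diag = r2.to_numpy()[0, 1:]
        assert (off_diag > 0.5).all()
        # map stays aligned and local
        assert (out.map.loc[f"{focal}_ld1", "chrom"] == out.map.loc[focal, "chrom"])

    def test_zero_flip_rate_gives_perfect_copies(self, small_panel):
        geno, _ = small_panel
        focal = geno.marker_ids[0]
        out = hp.sim.add_ld_proxy(geno, focal, n_copies=2, flip_rate=0.0, seed=2)
        np.testing.assert_array_equal(
            out.dosages[f"{focal}_ld1"], out.dosages[focal]
        )

    def test_unknown_focal_errors(self, small_panel):
        geno, _ = small_panel
        with pytest.raises(KeyError):
            hp.sim.add_ld_proxy(geno, "nope")
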