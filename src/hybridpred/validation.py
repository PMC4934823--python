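"""End-to-end validation studies: the package's own quality-control suite.

Each function runs one self-contained study on synthetic data — solver
identities, error control of the association scan, parameter recovery of
the one-step REML, the relatedness structure of cross-validated accuracy,
and the resampling trends — and returns the measured quantities.  The
studies are the basis of the acceptance checks in ``tests`` and of
``scripts/acceptance.py``.

All functions take a single integer seed and are deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg

from .crossval import (
    accuracy,
    hybrid_count_study,
    marker_density_study,
    mas_cv,
    population_size_study,
    run_cv,
    sample_t_scheme,
    simulate_polygenic_data,
)
from .gwas import MixedGwas, holm_correct
from .markers import code_design_matrices, kinship
from .pheno import gca_sca, heritability, mid_parent_stats, variance_components_one_step
from .predict import BayesCpi, ChainSettings, RRBlup, gblup_predict
from .sim import (
    CrossingPlan,
    TrialDesign,
    derive_hybrid_genotypes,
    hybrid_id,
    make_factorial,
    simulate_genetic_values,
    simulate_parents,
    simulate_trials,
)

__all__ = [
    "mme_agreement",
    "rrblup_gblup_agreement",
    "holm_oracle_mismatches",
    "fwer_null_scan",
    "qtl_stability",
    "relatedness_ordering",
    "variance_recovery",
    "heterosis_null",
    "bayescpi_collapse",
    "scheme_correctness",
    "resampling_trends",
]


def _random_dm(n, m, seed):
    from .sim import GenotypeMatrix

    rng = np.random.default_rng(seed)
    dosages = pd.DataFrame(
        rng.integers(0, 3, size=(n, m)).astype(float),
        index=[f"i{i}" for i in range(n)],
        columns=[f"mk{j}" for j in range(m)],
    )
    mmap = pd.DataFrame(
        {"chrom": "c1", "pos_cm": np.arange(m, dtype=float)}, index=dosages.columns
    )
    return code_design_matrices(GenotypeMatrix(dosages, mmap))


def mme_agreement(n_instances: int = 25, seed: int = 0) -> float:
    """Max |MME solution - dense direct inversion| over random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        n = int(rng.integers(10, 51))
        m = int(rng.integers(5, 201))
        dm = _random_dm(n, m, seed + 1000 + i)
        y = rng.normal(size=n)
        lam_a = float(rng.uniform(0.5, 20.0))
        lam_d = float(rng.uniform(0.5, 20.0))
        C = np.hstack([np.ones((n, 1)), dm.Z_A, dm.Z_D])
        M = C.T @ C + np.diag(np.r_[0.0, np.full(m, lam_a), np.full(m, lam_d)])
        expected = linalg.inv(M) @ (C.T @ y)
        method = "dual" if 2 * m > n else "direct"
        eff = RRBlup(y, dm).fit(lam_a, lam_d, method=method)
        got = np.r_[eff.mu, eff.additive.to_numpy(), eff.dominance.to_numpy()]
        worst = max(worst, float(np.max(np.abs(got - expected))))
    return worst


def rrblup_gblup_agreement(n_instances: int = 10, seed: int = 0) -> float:
    """Max |additive RR-BLUP - GBLUP| prediction difference."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        n = int(rng.integers(20, 60))
        m = int(rng.integers(30, 150))
        dm = _random_dm(n, m, seed + 2000 + i)
        y = rng.normal(size=n)
        lam = float(rng.uniform(0.5, 50.0))
        rr = RRBlup(y, dm, include_dominance=False).fit(lam).predict(dm)
        gb = gblup_predict(y, dm, dm, lam)
        worst = max(worst, float(np.max(np.abs(rr.to_numpy() - gb.to_numpy()))))
    return worst


def holm_oracle_mismatches(n_vectors: int = 1000, seed: int = 0) -> int:
    """Decisions differing from the brute-force sequential rule."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        p = rng.random(m) ** int(rng.integers(1, 4))
        alpha = float(rng.uniform(0.01, 0.2))
        got = holm_correct(p, alpha)
        expected = np.zeros(m, dtype=bool)
        for i, idx in enumerate(np.argsort(p, kind="stable")):
            if p[idx] < alpha / (m - i):
                expected[idx] = True
            else:
                break
        mismatches += int((got != expected).any())
    return mismatches


def fwer_null_scan(
    n_reps: int = 200, n_genotypes: int = 150, n_markers: int = 500, seed: int = 0
) -> float:
    """Family-wise error of the Holm-corrected scan under the global null.

    The trait is a pure polygenic draw u ~ N(0, K s2u) plus noise — no
    marker has an own effect, but the polygenic background makes naive
    tests anti-conservative.  Returns the fraction of replicates with at
    least one Holm rejection at alpha = 0.05.
    """
    geno, _ = simulate_parents(
        n_genotypes - 10, 10, n_markers=n_markers, n_chromosomes=10, seed=seed
    )
    dm = code_design_matrices(geno)
    K = kinship(dm)
    Kv = K.values + 1e-8 * np.eye(n_genotypes)
    L = np.linalg.cholesky(Kv)
    rng = np.random.default_rng(seed + 1)
    hits = 0
    for _ in range(n_reps):
        u = L @ rng.standard_normal(n_genotypes)
        y = pd.Series(u + rng.normal(0, 0.7, n_genotypes), index=geno.individual_ids)
        res = MixedGwas(y, geno, K).fit()
        if res.holm_significant(0.05):
            hits += 1
    return hits / n_reps


#: generative conditions of the major-QTL stability scenario: one injected
#: QTL calibrated to 30% of hybrid genotypic variance over a 30-QTL
#: polygenic background, entry-mean h2 0.85
QTL_SCENARIO = dict(n_markers=400, n_qtl=30, h2=0.85, large_qtl_share=0.3)


def qtl_stability(n_resamples: int = 100, seed: int = 0) -> tuple[int, float]:
    """Occurrence frequency of a major QTL over estimation-set resamples.

    Returns (number of resamples in which the focal marker is
    Holm-significant, the QTL's realized share of genotypic variance).
    """
    data = simulate_polygenic_data(seed=seed, **QTL_SCENARIO)
    focal = data.hybrid_geno.marker_ids[0]
    z = data.dm_hybrids.Z_A[:, 0]
    a_focal = float(data.truth.qtl_table().loc[focal, "additive"])
    share = float(a_focal**2 * np.var(z) / np.var(data.true_hybrid_values))
    hits = 0
    for r in range(n_resamples):
        scheme = sample_t_scheme(data.plan, seed=seed + 10_000 + r)
        train = list(scheme.est_hybrids)
        res = MixedGwas(
            data.hybrid_blues.loc[train],
            data.hybrid_geno.subset(individuals=train),
            kinship(data.dm_hybrids.rows(train)),
        ).fit()
        if focal in res.holm_significant():
            hits += 1
    return hits, share


def relatedness_ordering(n_runs: int = 30, seed: int = 0) -> dict[str, dict[str, float]]:
    """Mean CV accuracies by scenario for RR-BLUP and MAS(Holm).

    Polygenic architecture with no large QTL: genomic selection should beat
    marker-assisted selection everywhere and accuracy should fall with
    decreasing relatedness (T2 > T1 > T0).
    """
    data = simulate_polygenic_data(n_markers=400, n_qtl=200, h2=0.8, seed=seed)
    rr = run_cv(data, "rrblup", n_runs=n_runs, seed=seed)
    mas_table, _ = mas_cv(data, thresholds={"holm": None}, n_runs=n_runs, seed=seed)
    out = {
        "rrblup": rr.scenario_means("rrblup").to_dict(),
        "mas_holm": mas_table.groupby("scenario")["accuracy"].mean().to_dict(),
        "max_accuracy": float(rr.table["accuracy"].max()),
    }
    return out


#: recovery-study conditions: 36 lines + 164 hybrids (200 genotypes) in 4
#: environments, 3 trials, 2 replications, no checks; all components away
#: from the zero boundary
RECOVERY_SIGMA = {
    "environment": 1.0,
    "trial": 0.3,
    "replication": 0.4,
    "block": 0.15,
    "gxe": 0.3,
    "error": 0.6,
}
RECOVERY_GENETIC = {"lines": 0.6, "hybrids": 0.5}


def variance_recovery(n_reps: int = 20, seed: int = 0) -> dict:
    """One-step REML parameter recovery over simulated trial series.

    For every component the estimate is compared with the realized variance
    of the effects actually drawn in that replicate (within-environment
    stratum variance for the nested trial/replication factors) — the
    estimand that remains well defined at the small level counts of a
    4-environment series.  Returns the medians of the estimate/realized
    ratios and the entry-mean heritability error.
    """
    ratios, h2_err = [], []
    for rep in range(n_reps):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] >> 1)
        rng = np.random.default_rng(rep_seed)
        line_ids = [f"L{i:03d}" for i in range(36)]
        hyb_ids = [f"H{i:03d}xP" for i in range(164)]
        vals = pd.Series(
            np.r_[
                rng.normal(0, np.sqrt(RECOVERY_GENETIC["lines"]), len(line_ids)),
                rng.normal(0, np.sqrt(RECOVERY_GENETIC["hybrids"]), len(hyb_ids)),
            ],
            index=line_ids + hyb_ids,
        )
        design = TrialDesign(environments=4, trials_per_env=3, block_size=20, n_checks=0)
        plots = simulate_trials(
            vals, design, RECOVERY_SIGMA, seed=rep_seed, mu=50.0, hybrid_ids=hyb_ids
        )
        realized = dict(plots.attrs["realized_variances"])
        realized["lines"] = float(np.var(vals.loc[line_ids], ddof=1))
        realized["hybrids"] = float(np.var(vals.loc[hyb_ids], ddof=1))
        realized["lines_x_env"] = realized.pop("gxe_lines")
        realized["hybrids_x_env"] = realized.pop("gxe_hybrids")
        vc = variance_components_one_step(plots, line_ids=line_ids, hybrid_ids=hyb_ids)
        rep_ratios = {
            k: vc.variances[k] / realized[k]
            for k in vc.variances
            if k != "environment"
        }
        # the environment component is identified only at its stratum: the
        # per-environment shift l_e plus the means of the nested trial and
        # replication draws; compare the matching model-side sum
        est_stratum = (
            vc.variances["environment"]
            + vc.variances["trial"] / design.trials_per_env
            + vc.variances["replication"] / design.replications
        )
        rep_ratios["environment"] = est_stratum / realized["environment_stratum"]
        ratios.append(rep_ratios)
        h2_est = heritability(vc.variances, 4, 2, "hybrids").entry_mean
        h2_true = realized["hybrids"] / (
            realized["hybrids"] + realized["hybrids_x_env"] / 4 + realized["error"] / 8
        )
        h2_err.append(h2_est - h2_true)
    R = pd.DataFrame(ratios)
    return {
        "median_ratio": R.median().to_dict(),
        "h2_median_abs_error": float(np.median(np.abs(h2_err))),
    }


def heterosis_null(seed: int = 0) -> dict[str, float]:
    """Purely additive, noise-free population: MPH vanishes, GCA is exact."""
    geno, parents = simulate_parents(30, 8, n_markers=200, n_chromosomes=5, seed=seed)
    plan = make_factorial(parents, "full")
    both = geno.concat(derive_hybrid_genotypes(geno, plan))
    vals, _ = simulate_genetic_values(both, n_qtl=60, dominance_sd=0.0, seed=seed + 1)
    blues = 100.0 + vals
    stats = mid_parent_stats(blues, plan)
    max_abs_mph = float(stats["MPH"].abs().max())

    scheme = sample_t_scheme(plan, n_f_est=20, n_m_est=5, n_hyb_est=80, seed=seed + 2)
    train = blues.loc[list(scheme.est_hybrids)]
    est_plan = CrossingPlan(
        tuple(c for c in plan.crosses if hybrid_id(*c) in set(scheme.est_hybrids))
    )
    ca = gca_sca(train, est_plan)
    t2_err = max(
        abs(ca.predict(*plan.parents_of(h)) - blues[h]) for h in scheme.t2
    )
    return {"max_abs_mph": max_abs_mph, "gca_t2_max_error": float(t2_err)}


def bayescpi_collapse(seed: int = 0) -> dict[str, float]:
    """pi = 0 collapse onto RR-BLUP and bitwise chain reproducibility."""
    dm = _random_dm(120, 200, seed + 3000)
    rng = np.random.default_rng(seed)
    beta = rng.normal(0, 0.2, 200)
    y = dm.Z_A @ beta + rng.normal(0, 0.6, 120)
    chain = ChainSettings(iterations=2000, burn_in=500, thin=5, seed=seed)
    eff = BayesCpi(y, dm, include_dominance=False).fit(chain, fix_pi=0.0)
    lam = 0.36 / (float(np.var(y)) / 200)
    rr = RRBlup(y, dm, include_dominance=False).fit(lam)
    corr = float(np.corrcoef(eff.additive, rr.additive)[0, 1])
    eff2 = BayesCpi(y, dm, include_dominance=False).fit(chain, fix_pi=0.0)
    reproducible = bool(np.array_equal(eff.additive.to_numpy(), eff2.additive.to_numpy()))
    return {"collapse_correlation": corr, "bitwise_reproducible": reproducible}


def scheme_correctness(n_schemes: int = 1000, seed: int = 0) -> dict[str, float]:
    """Brute-force audit of sampled CV schemes plus the accuracy clamp."""
    data = simulate_polygenic_data(n_markers=60, n_qtl=30, h2=0.9, seed=seed)
    plan = data.plan
    violations = 0
    for r in range(n_schemes):
        s = sample_t_scheme(plan, seed=seed + r)
        est_f, est_m = set(s.est_females), set(s.est_males)
        groups = [set(s.est_hybrids), set(s.t2), set(s.t1), set(s.t0)]
        ok = sum(len(g) for g in groups) == len(plan) == len(set.union(*groups))
        ok &= len(s.est_hybrids) == 610
        for h in list(s.est_hybrids) + list(s.t2):
            f, m = plan.parents_of(h)
            ok &= f in est_f and m in est_m
        for h in s.t1:
            f, m = plan.parents_of(h)
            ok &= ((f in est_f) + (m in est_m)) == 1
        for h in s.t0:
            f, m = plan.parents_of(h)
            ok &= f not in est_f and m not in est_m
        violations += int(not ok)
    # clamp: a perfect prediction standardized by h2 < 1 would exceed 1
    obs = data.hybrid_blues.iloc[:50]
    clamped = accuracy(obs * 1.0, obs, h2=0.8)
    return {"violations": violations, "clamped_perfect_accuracy": clamped}


def resampling_trends(n_runs: int = 30, seed: int = 0) -> dict:
    """Estimation-set composition and marker-density effects on accuracy."""
    data = simulate_polygenic_data(n_markers=400, n_qtl=200, h2=0.8, seed=seed)

    pop = population_size_study(data, female_grid=(30, 60, 90, 120), n_runs=n_runs, seed=seed)
    t0_by_size = (
        pop.table[pop.table["scenario"] == "T0"]
        .groupby("model")["accuracy"].mean()
        .reindex([f"females={s}" for s in (30, 60, 90, 120)])
    )

    hyb = hybrid_count_study(data, hybrid_grid=(100, 300, 500, 610), n_runs=n_runs, seed=seed)
    acc_by_count = (
        hyb.table.groupby("model")["accuracy"].mean()
        .reindex([f"hybrids={c}" for c in (100, 300, 500, 610)])
    )

    # the plateau question needs a dense panel: an eighth of it must still
    # carry enough markers to estimate the realized relationships
    dense = simulate_polygenic_data(n_markers=1600, n_qtl=200, h2=0.8, seed=seed)
    m = dense.hybrid_geno.n_markers
    dens = marker_density_study(
        dense, density_grid=(m // 8, m), n_runs=n_runs, seed=seed
    )
    t2 = dens.table[dens.table["scenario"] == "T2"].groupby("model")["accuracy"].mean()
    return {
        "t0_by_females": t0_by_size.to_dict(),
        "accuracy_by_hybrid_count": acc_by_count.to_dict(),
        "t2_eighth_panel": float(t2[f"density={m // 8}"]),
        "t2_full_panel": float(t2[f"density={m}"]),
    }
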