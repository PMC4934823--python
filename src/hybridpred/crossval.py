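"""Relatedness-stratified cross-validation and resampling studies.

Each cross-validation run samples an estimation set of parents (by default
80 of 120 females and 10 of 15 males) and a fixed number of hybrids whose
parents both belong to it (610 of the up-to-800 internal crosses).  Every
remaining hybrid is classified by how many parents it shares with the
estimation parents: T2 (both), T1 (exactly one), T0 (none) — three test
sets of successively decreasing relatedness.  Prediction accuracy is the
Pearson correlation between predicted and observed hybrid performance
divided by the square root of the entry-mean heritability, clamped at 1.

The three resampling studies vary the number of female parents, the number
of estimation hybrids, and the marker density (k markers drawn from every
window of 173) to map how estimation-set composition drives accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import predict as gp
from .gwas import MixedGwas
from .markers import DesignMatrices, code_design_matrices, equidistant_subsample, kinship
from .pheno import combining_ability_variances, gca_sca
from .sim import (
    CrossingPlan,
    GenotypeMatrix,
    ParentSet,
    derive_hybrid_genotypes,
    hybrid_id,
    make_factorial,
    simulate_genetic_values,
    simulate_parents,
)

__all__ = [
    "CVScheme",
    "HybridData",
    "simulate_polygenic_data",
    "sample_t_scheme",
    "accuracy",
    "AccuracyResult",
    "run_cv",
    "MAS_THRESHOLDS",
    "mas_cv",
    "population_size_study",
    "hybrid_count_study",
    "marker_density_study",
]

#: marker-assisted-selection significance levels (label -> raw threshold;
#: None marks the Bonferroni-Holm level)
MAS_THRESHOLDS: dict[str, float | None] = {
    "holm": None,
    "0.0001": 0.0001,
    "0.001": 0.001,
    "0.01": 0.01,
    "0.05": 0.05,
    "0.10": 0.10,
}


@dataclass(frozen=True)
class CVScheme:
    """One cross-validation draw: estimation sets plus T2/T1/T0 test sets."""

    est_females: tuple[str, ...]
    est_males: tuple[str, ...]
    est_hybrids: tuple[str, ...]
    t2: tuple[str, ...]
    t1: tuple[str, ...]
    t0: tuple[str, ...]
    seed: int

    def test_set(self, scenario: str) -> tuple[str, ...]:
        return {"T2": self.t2, "T1": self.t1, "T0": self.t0}[scenario]

    def to_dict(self) -> dict:
        return {
            "est_females": list(self.est_females),
            "est_males": list(self.est_males),
            "est_hybrids": list(self.est_hybrids),
            "T2": list(self.t2),
            "T1": list(self.t1),
            "T0": list(self.t0),
            "seed": self.seed,
        }


def sample_t_scheme(
    plan: CrossingPlan,
    n_f_est: int = 80,
    n_m_est: int = 10,
    n_hyb_est: int = 610,
    seed: int = 0,
    best_effort: bool = False,
) -> CVScheme:
    """Sample estimation parents and hybrids, then classify the test hybrids.

    Estimation parents are drawn uniformly; the estimation hybrids are a
    uniform draw of ``n_hyb_est`` crosses internal to them.  Remaining
    hybrids sharing two / one / zero parents with the estimation parent sets
    form T2 / T1 / T0.  With fewer than ``n_hyb_est`` internal crosses the
    sampler raises unless ``best_effort`` is set, in which case it takes all
    of them.
    """
    females = sorted({f for f, _ in plan.crosses})
    males = sorted({m for _, m in plan.crosses})
    if n_f_est > len(females) or n_m_est > len(males):
        raise ValueError("requested more estimation parents than available")
    rng = np.random.default_rng(seed)
    est_f = set(rng.choice(females, size=n_f_est, replace=False))
    est_m = set(rng.choice(males, size=n_m_est, replace=False))

    internal = [c for c in plan.crosses if c[0] in est_f and c[1] in est_m]
    if len(internal) < n_hyb_est:
        if not best_effort:
            raise ValueError(
                f"only {len(internal)} estimation-internal crosses available, "
                f"{n_hyb_est} requested (pass best_effort=True to take all)"
            )
        n_hyb_est = len(internal)
    idx = rng.choice(len(internal), size=n_hyb_est, replace=False)
    est_crosses = {internal[i] for i in idx}

    t2, t1, t0 = [], [], []
    for c in plan.crosses:
        if c in est_crosses:
            continue
        shared = (c[0] in est_f) + (c[1] in est_m)
        [t0, t1, t2][shared].append(hybrid_id(*c))
    return CVScheme(
        est_females=tuple(sorted(est_f)),
        est_males=tuple(sorted(est_m)),
        est_hybrids=tuple(hybrid_id(*c) for c in sorted(est_crosses)),
        t2=tuple(t2),
        t1=tuple(t1),
        t0=tuple(t0),
        seed=seed,
    )


def accuracy(predicted: pd.Series, observed: pd.Series, h2: float) -> float:
    """Pearson correlation divided by sqrt(h2); values above 1 are set to 1."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    common = predicted.index.intersection(observed.index)
    if len(common) < 3:
        raise ValueError("need at least 3 prediction/observation pairs")
    p = predicted.loc[common].to_numpy(dtype=float)
    o = observed.loc[common].to_numpy(dtype=float)
    if np.std(p) == 0 or np.std(o) == 0:
        raise ValueError("zero variance in predictions or observations")
    r = float(np.corrcoef(p, o)[0, 1])
    return min(r / np.sqrt(h2), 1.0)


@dataclass
class HybridData:
    """Everything a cross-validation study needs about one synthetic trait."""

    parents: ParentSet
    plan: CrossingPlan
    parent_geno: GenotypeMatrix
    hybrid_geno: GenotypeMatrix
    parent_blues: pd.Series
    hybrid_blues: pd.Series
    h2: float
    n_env: int
    sigma2_mean_error: float
    truth: object | None = None
    true_hybrid_values: pd.Series | None = None
    _dm_hybrids: DesignMatrices | None = field(default=None, repr=False)
    _lambdas: tuple[float, float] | None = field(default=None, repr=False)

    @property
    def dm_hybrids(self) -> DesignMatrices:
        if self._dm_hybrids is None:
            self._dm_hybrids = code_design_matrices(self.hybrid_geno)
        return self._dm_hybrids

    def lambdas(self) -> tuple[float, float]:
        """Shrinkage parameters from the combining-ability decomposition.

        sigma2_GCA / sigma2_SCA come from a REML fit of random female and
        male GCA effects to the hybrid BLUEs; the cross-level residual of
        that model absorbs SCA plus the error of the means, so the SCA
        component is its excess over the known mean-level error variance.
        The modified residual variance of the shrinkage definition is the
        mean-level error variance directly (already on a per-entry scale).
        """
        if self._lambdas is None:
            ca = combining_ability_variances(self.hybrid_blues, self.plan)
            m = self.hybrid_geno.n_markers
            vy = float(np.var(self.hybrid_blues))
            gca = max(ca["gca"], 1e-4 * vy)
            sca = max(ca["sca"] - self.sigma2_mean_error, 1e-4 * vy)
            lam_a = self.sigma2_mean_error / (gca / m)
            lam_d = self.sigma2_mean_error / (sca / m)
            self._lambdas = (lam_a, lam_d)
        return self._lambdas

    def subset_markers(self, marker_idx: np.ndarray) -> "HybridData":
        markers = [self.hybrid_geno.marker_ids[i] for i in marker_idx]
        out = HybridData(
            parents=self.parents,
            plan=self.plan,
            parent_geno=self.parent_geno.subset(markers=markers),
            hybrid_geno=self.hybrid_geno.subset(markers=markers),
            parent_blues=self.parent_blues,
            hybrid_blues=self.hybrid_blues,
            h2=self.h2,
            n_env=self.n_env,
            sigma2_mean_error=self.sigma2_mean_error,
            truth=self.truth,
            true_hybrid_values=self.true_hybrid_values,
        )
        out._lambdas = self._lambdas  # shrinkage kept comparable across densities
        return out


def simulate_polygenic_data(
    n_female: int = 120,
    n_male: int = 15,
    n_hybrids: int | str = "full",
    n_markers: int = 1730,
    n_qtl: int = 200,
    h2: float = 0.8,
    dominance_sd: float = 0.0,
    large_qtl_effect: float | None = None,
    large_qtl_share: float | None = None,
    n_env: int = 6,
    seed: int = 0,
) -> HybridData:
    """Synthetic factorial data set at the entry-mean level.

    Parents and hybrids receive true genetic values from ``n_qtl`` additive
    (optionally dominant) QTL; observed BLUEs are the true values plus iid
    Normal noise whose variance is calibrated so the hybrids' entry-mean
    heritability equals ``h2``.  ``large_qtl_effect`` injects one major QTL
    on the first marker of the panel; ``large_qtl_share`` instead calibrates
    that effect so the QTL explains the given share of the hybrids'
    genotypic variance regardless of the random draws.
    """
    if large_qtl_effect is not None and large_qtl_share is not None:
        raise ValueError("give either large_qtl_effect or large_qtl_share")
    ss = np.random.SeedSequence(seed)
    s_par, s_plan, s_qtl, s_noise = [int(s) for s in ss.generate_state(4) >> 1]
    parent_geno, parents = simulate_parents(
        n_female, n_male, n_markers=n_markers, seed=s_par
    )
    plan = make_factorial(parents, n_hybrids, seed=s_plan)
    hybrid_geno = derive_hybrid_genotypes(parent_geno, plan)
    both = parent_geno.concat(hybrid_geno)
    if large_qtl_share is not None:
        # calibrate: share = eff^2 var(z) / (eff^2 var(z) + var(g_rest))
        base, _ = simulate_genetic_values(
            both, n_qtl=n_qtl, additive_sd=1.0, dominance_sd=dominance_sd, seed=s_qtl
        )
        var_rest = float(np.var(base.loc[plan.hybrid_ids]))
        z0 = hybrid_geno.dosages.iloc[:, 0].to_numpy() - 1.0
        var_z = float(np.var(z0))
        if var_z == 0:
            raise ValueError("focal marker monomorphic in hybrids")
        large_qtl_effect = float(
            np.sqrt(large_qtl_share / (1.0 - large_qtl_share) * var_rest / var_z)
        )
    large = (both.marker_ids[0], large_qtl_effect) if large_qtl_effect else None
    values, truth = simulate_genetic_values(
        both, n_qtl=n_qtl, additive_sd=1.0, dominance_sd=dominance_sd,
        large_qtl=large, seed=s_qtl,
    )
    hyb_ids = plan.hybrid_ids
    g_hyb = values.loc[hyb_ids]
    var_g = float(np.var(g_hyb))
    s2 = var_g * (1.0 - h2) / h2 if h2 < 1.0 else 0.0
    rng = np.random.default_rng(s_noise)
    hybrid_blues = g_hyb + rng.normal(0.0, np.sqrt(s2), size=len(g_hyb))
    par_ids = list(parents.all_ids)
    parent_blues = values.loc[par_ids] + rng.normal(0.0, np.sqrt(s2), size=len(par_ids))
    return HybridData(
        parents=parents,
        plan=plan,
        parent_geno=parent_geno,
        hybrid_geno=hybrid_geno,
        parent_blues=parent_blues,
        hybrid_blues=hybrid_blues,
        h2=h2,
        n_env=n_env,
        sigma2_mean_error=s2 if s2 > 0 else 1e-12,
        truth=truth,
        true_hybrid_values=g_hyb,
    )


@dataclass
class AccuracyResult:
    """Per run x scenario x model accuracies with convenience summaries."""

    table: pd.DataFrame  # columns: run, scenario, model, accuracy, n_test

    def means(self, by: tuple[str, ...] = ("model", "scenario")) -> pd.Series:
        return self.table.groupby(list(by))["accuracy"].mean()

    def scenario_means(self, model: str | None = None) -> pd.Series:
        t = self.table if model is None else self.table[self.table["model"] == model]
        return t.groupby("scenario")["accuracy"].mean().reindex(["T2", "T1", "T0"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


_SCHEME_DEFAULTS = {"n_f_est": 80, "n_m_est": 10, "n_hyb_est": 610}


def _fit_model(data: HybridData, model: str, train_ids: list[str], run_seed: int):
    """Fit one predictor on the estimation hybrids; returns a predict(ids) closure."""
    dm_train = data.dm_hybrids.rows(train_ids)
    y_train = data.hybrid_blues.loc[train_ids]
    lam_a, lam_d = data.lambdas()

    if model in ("rrblup", "rrblup-a", "wblup", "bayescpi"):
        if model == "rrblup":
            eff = gp.RRBlup(y_train, dm_train).fit(lam_a, lam_d)
        elif model == "rrblup-a":
            eff = gp.RRBlup(y_train, dm_train, include_dominance=False).fit(lam_a)
        elif model == "wblup":
            K = kinship(dm_train)
            res = MixedGwas(y_train, data.hybrid_geno.subset(individuals=train_ids), K).fit()
            functional = res.top_k(3)
            eff = gp.WBlup(y_train, dm_train, functional).fit(lam_a, lam_d)
        else:
            chain = gp.ChainSettings(iterations=1500, burn_in=500, thin=5, seed=run_seed)
            eff = gp.BayesCpi(y_train, dm_train).fit(chain)
        return lambda ids: eff.predict(data.dm_hybrids.rows(ids))

    if model == "gca":
        sub_plan = CrossingPlan(tuple(c for c in data.plan.crosses
                                      if hybrid_id(*c) in set(train_ids)))
        ca = gca_sca(y_train, sub_plan)
        return lambda ids: pd.Series(
            {h: ca.predict(*data.plan.parents_of(h)) for h in ids}, name="predicted"
        )
    if model == "mp":
        return lambda ids: pd.Series(
            {h: (data.parent_blues[data.plan.parents_of(h)[0]]
                 + data.parent_blues[data.plan.parents_of(h)[1]]) / 2.0 for h in ids},
            name="predicted",
        )
    raise ValueError(f"unknown model {model!r}")


def run_cv(
    data: HybridData,
    model: str = "rrblup",
    n_runs: int = 100,
    seed: int = 0,
    scheme_kwargs: dict | None = None,
) -> AccuracyResult:
    """Relatedness-stratified cross-validation of one predictor.

    For run r the scheme is sampled with seed ``seed + r``; the model is fit
    on the estimation hybrids and evaluated on T2/T1/T0.  GCA- and
    mid-parent-based models are evaluated on T2 only (they are undefined for
    hybrids with unphenotyped/untrained parents).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if model not in ("rrblup", "rrblup-a", "wblup", "bayescpi", "gca", "mp"):
        raise ValueError(f"unknown model {model!r}")
    kw = dict(_SCHEME_DEFAULTS, **(scheme_kwargs or {}))
    scenarios = ("T2",) if model in ("gca", "mp") else ("T2", "T1", "T0")
    rows = []
    for r in range(n_runs):
        scheme = sample_t_scheme(data.plan, seed=seed + r, **kw)
        try:
            predictor = _fit_model(data, model, list(scheme.est_hybrids), seed + r)
        except Exception as err:  # noqa: BLE001 — flagged, never silently dropped
            warnings.warn(f"run {r}: {model} fit failed ({err}); run flagged")
            for sc in scenarios:
                rows.append((r, sc, model, np.nan, len(scheme.test_set(sc))))
            continue
        for sc in scenarios:
            ids = [h for h in scheme.test_set(sc)]
            if len(ids) < 3:
                rows.append((r, sc, model, np.nan, len(ids)))
                continue
            pred = predictor(ids)
            obs = data.hybrid_blues.loc[ids]
            rows.append((r, sc, model, accuracy(pred, obs, data.h2), len(ids)))
    return AccuracyResult(
        pd.DataFrame(rows, columns=["run", "scenario", "model", "accuracy", "n_test"])
    )


def _gls_marker_prediction(data, train_ids, test_ids, selected, scan_res):
    """Joint marker effects by GLS with the polygenic covariance of the scan."""
    dm_train = data.dm_hybrids.rows(train_ids).columns(selected)
    dm_test = data.dm_hybrids.rows(test_ids).columns(selected)
    K = kinship(data.dm_hybrids.rows(train_ids)).values
    n = len(train_ids)
    V = scan_res.sigma2_u * K + scan_res.sigma2_e * np.eye(n)
    y = data.hybrid_blues.loc[train_ids].to_numpy()
    X = np.column_stack([np.ones(n), dm_train.Z_A])
    Vinv_X = np.linalg.solve(V, X)
    beta, *_ = np.linalg.lstsq(X.T @ Vinv_X, Vinv_X.T @ y, rcond=None)
    Xt = np.column_stack([np.ones(len(test_ids)), dm_test.Z_A])
    return pd.Series(Xt @ beta, index=test_ids, name="predicted")


def mas_cv(
    data: HybridData,
    thresholds: dict[str, float | None] | None = None,
    n_runs: int = 100,
    seed: int = 0,
    scheme_kwargs: dict | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker-assisted-selection cross-validation over significance levels.

    Per run: an additive kinship-corrected scan on the estimation set,
    marker selection at each threshold (Bonferroni-Holm for the ``None``
    entry), joint effect estimation by GLS with a polygenic covariance, and
    prediction of the test sets.  Runs with an empty selection contribute
    accuracy 0.  Returns (accuracy table, per-marker occurrence counts per
    threshold).
    """
    thresholds = thresholds or MAS_THRESHOLDS
    kw = dict(_SCHEME_DEFAULTS, **(scheme_kwargs or {}))
    occurrence = pd.DataFrame(
        0, index=data.hybrid_geno.marker_ids, columns=list(thresholds)
    )
    rows = []
    for r in range(n_runs):
        scheme = sample_t_scheme(data.plan, seed=seed + r, **kw)
        train = list(scheme.est_hybrids)
        dm_train = data.dm_hybrids.rows(train)
        K = kinship(dm_train)
        res = MixedGwas(
            data.hybrid_blues.loc[train],
            data.hybrid_geno.subset(individuals=train),
            K,
        ).fit()
        for label, thr in thresholds.items():
            selected = (
                res.holm_significant(alpha) if thr is None else res.significant_at(thr)
            )
            occurrence.loc[selected, label] += 1
            for sc in ("T2", "T1", "T0"):
                ids = list(scheme.test_set(sc))
                if len(ids) < 3:
                    rows.append((r, sc, label, np.nan, len(ids), len(selected)))
                    continue
                if not selected:
                    rows.append((r, sc, label, 0.0, len(ids), 0))
                    continue
                pred = _gls_marker_prediction(data, train, ids, selected, res)
                try:
                    acc = accuracy(pred, data.hybrid_blues.loc[ids], data.h2)
                except ValueError:
                    acc = 0.0  # constant predictions: no usable signal
                rows.append((r, sc, label, acc, len(ids), len(selected)))
    table = pd.DataFrame(
        rows, columns=["run", "scenario", "threshold", "accuracy", "n_test", "n_selected"]
    )
    return table, occurrence


def population_size_study(
    data: HybridData,
    female_grid: tuple[int, ...] = (30, 60, 90, 120),
    n_m_total: int = 15,
    n_runs: int = 30,
    seed: int = 0,
) -> AccuracyResult:
    """Accuracy versus the number of female parents in the population.

    For each grid size a random subset of females (all ``n_m_total`` males)
    defines a subpopulation; estimation sets contain two thirds of those
    females, 10 males and 100 hybrids; the remaining hybrids split into
    T2/T1/T0 as usual.
    """
    females = list(data.parents.female_ids)
    rows = []
    for size in female_grid:
        if size > len(females):
            raise ValueError(f"female_grid value {size} exceeds {len(females)} females")
        n_f_est = int(np.ceil(2 * size / 3))
        for r in range(n_runs):
            rng = np.random.default_rng(seed + 7919 * size + r)
            chosen = set(rng.choice(females, size=size, replace=False))
            sub_plan = CrossingPlan(
                tuple(c for c in data.plan.crosses if c[0] in chosen)
            )
            scheme = sample_t_scheme(
                sub_plan, n_f_est=n_f_est, n_m_est=10, n_hyb_est=100,
                seed=seed + r, best_effort=False,
            )
            sub = _with_plan(data, sub_plan)
            predictor = _fit_model(sub, "rrblup", list(scheme.est_hybrids), seed + r)
            for sc in ("T2", "T1", "T0"):
                ids = list(scheme.test_set(sc))
                if len(ids) < 3:
                    continue
                acc = accuracy(predictor(ids), data.hybrid_blues.loc[ids], data.h2)
                rows.append((r, sc, f"females={size}", acc, len(ids)))
    return AccuracyResult(
        pd.DataFrame(rows, columns=["run", "scenario", "model", "accuracy", "n_test"])
    )


def _with_plan(data: HybridData, plan: CrossingPlan) -> HybridData:
    out = HybridData(
        parents=data.parents,
        plan=plan,
        parent_geno=data.parent_geno,
        hybrid_geno=data.hybrid_geno,
        parent_blues=data.parent_blues,
        hybrid_blues=data.hybrid_blues,
        h2=data.h2,
        n_env=data.n_env,
        sigma2_mean_error=data.sigma2_mean_error,
    )
    out._dm_hybrids = data._dm_hybrids
    out._lambdas = data._lambdas or data.lambdas()
    return out


def hybrid_count_study(
    data: HybridData,
    hybrid_grid: tuple[int, ...] = (610, 500, 300, 100),
    n_runs: int = 30,
    seed: int = 0,
) -> AccuracyResult:
    """Accuracy versus the number of estimation hybrids (80F/10M fixed)."""
    grid = list(dict.fromkeys(hybrid_grid))
    if len(grid) != len(hybrid_grid):
        warnings.warn("duplicate hybrid_grid entries collapsed")
    frames = []
    for count in grid:
        res = run_cv(
            data, "rrblup", n_runs=n_runs, seed=seed,
            scheme_kwargs={"n_hyb_est": count},
        )
        t = res.table.copy()
        t["model"] = f"hybrids={count}"
        frames.append(t)
    return AccuracyResult(pd.concat(frames, ignore_index=True))


def marker_density_study(
    data: HybridData,
    density_grid: tuple[int, ...] | None = None,
    window: int = 173,
    n_runs: int = 30,
    seed: int = 0,
) -> AccuracyResult:
    """Accuracy versus marker density via equidistant window subsampling.

    Densities are target marker counts; each maps to k markers per window
    of ``window``.  The full-panel density reproduces run_cv under the same
    seeds exactly.
    """
    m = data.hybrid_geno.n_markers
    if density_grid is None:
        density_grid = tuple(
            int(m * f) for f in (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0)
        )
    sizes = [min(window, m - s) for s in range(0, m, window)]
    frames = []
    for density in density_grid:
        if density < 1:
            raise ValueError("density must be >= 1 marker")
        if density > m:
            raise ValueError(f"density {density} exceeds panel size {m}")
        # smallest per-window draw whose realized total reaches the target
        k = next(
            k for k in range(1, window + 1)
            if sum(min(k, s) for s in sizes) >= density
        )
        idx = equidistant_subsample(m, k, window=window, seed=seed)
        sub = data.subset_markers(idx)
        res = run_cv(sub, "rrblup", n_runs=n_runs, seed=seed)
        t = res.table.copy()
        t["model"] = f"density={density}"
        t["n_markers"] = len(idx)
        frames.append(t)
    return AccuracyResult(pd.concat(frames, ignore_index=True))
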