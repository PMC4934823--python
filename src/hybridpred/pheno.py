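"""Two-stage phenotypic analysis of multi-environment trial data.

Stage one fits, separately per environment, a model with fixed genotype
effects and random trial / replication / block effects and returns adjusted
entry means.  Stage two combines the per-environment means with a random
environment effect into one best linear unbiased estimate (BLUE) per
genotype.  On top of the BLUEs sit mid-parent heterosis statistics and the
general/specific combining-ability decomposition of hybrid performance.

A one-step alternative treats every effect except the intercept as random
and returns the full variance-component vector (environment, trial,
replication, block, lines, lines x environment, hybrids, hybrids x
environment, error) with halved-LRT significance tests, from which
entry-mean and plot-basis heritabilities are derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import RandomTerm, factor_covariance, reml_fit
from .sim import CrossingPlan

__all__ = [
    "remove_outliers",
    "adjust_entry_means_per_env",
    "blues_across_env",
    "two_stage_blues",
    "mid_parent_stats",
    "GCAResult",
    "gca_sca",
    "combining_ability_variances",
    "OneStepVarianceModel",
    "VarianceComponentsResults",
    "variance_components_one_step",
    "Heritability",
    "heritability",
]

ONE_STEP_COMPONENTS = (
    "environment",
    "trial",
    "replication",
    "block",
    "lines",
    "lines_x_env",
    "hybrids",
    "hybrids_x_env",
    "error",
)


def _check_plots(plots: pd.DataFrame) -> None:
    needed = {"genotype", "environment", "trial", "replication", "block", "value"}
    if not needed.issubset(plots.columns):
        raise ValueError(f"plot records lack columns {sorted(needed - set(plots.columns))}")


def remove_outliers(plots: pd.DataFrame, cutoff: float = 4.0) -> pd.DataFrame:
    """Drop plots whose studentized residual exceeds ``cutoff``.

    Residuals come from the additive genotype + environment decomposition
    (value minus genotype median minus environment median plus grand
    median) and are studentized by their median absolute deviation, so one
    gross error cannot mask itself through the mean and standard deviation.
    A deliberately simple screen; raise the cutoff to keep everything but
    gross errors.
    """
    _check_plots(plots)
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    y = plots["value"]
    g_med = y.groupby(plots["genotype"]).transform("median")
    e_med = y.groupby(plots["environment"]).transform("median")
    resid = y - g_med - e_med + y.median()
    scale = 1.4826 * (resid - resid.median()).abs().median()
    if scale == 0 or not np.isfinite(scale):
        return plots
    keep = (resid / scale).abs() <= cutoff
    return plots[keep].reset_index(drop=True)


def adjust_entry_means_per_env(
    plots: pd.DataFrame, environment: str, trait: str | None = None
) -> pd.Series:
    """Adjusted entry means (mu + g) for one environment.

    Genotype is fixed; trial, replication and block are random with
    REML-estimated variances.  Genotypes not observed in the environment are
    absent from the result.
    """
    _check_plots(plots)
    sub = plots[plots["environment"] == environment]
    if trait is not None:
        sub = sub[sub["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no plots for environment {environment!r}")
    genos, geno_idx = np.unique(sub["genotype"], return_inverse=True)
    if len(genos) < 2:
        raise ValueError("fewer than 2 genotypes in environment")
    n = len(sub)
    X = np.zeros((n, len(genos)))
    X[np.arange(n), geno_idx] = 1.0

    terms = []
    for col in ("trial", "replication", "block"):
        codes = pd.factorize(sub[col])[0]
        if len(np.unique(codes)) > 1:
            terms.append(factor_covariance(codes, col))
    res = reml_fit(sub["value"].to_numpy(), X, terms)
    if not res.converged:
        raise RuntimeError(
            f"stage-1 REML did not converge in {res.n_iter} iterations "
            f"(environment {environment!r})"
        )
    return pd.Series(res.beta, index=genos, name=environment)


def blues_across_env(stage1_means: pd.DataFrame | list[pd.Series]) -> pd.Series:
    """Across-environment BLUEs from stacked per-environment entry means.

    Accepts a long DataFrame (genotype, environment, mean) or the list of
    per-environment Series produced by :func:`adjust_entry_means_per_env`.
    Genotype is fixed, environment random.  With a single environment the
    stage-one means are returned unchanged.
    """
    if isinstance(stage1_means, list):
        stage1_means = pd.concat(
            [s.rename("mean").rename_axis("genotype").reset_index().assign(environment=s.name)
             for s in stage1_means],
            ignore_index=True,
        )
    df = stage1_means
    envs = df["environment"].unique()
    counts = df.groupby("genotype")["mean"].count()
    if (counts < 1).any():
        raise ValueError("genotype observed in zero environments")
    if len(envs) == 1:
        out = df.set_index("genotype")["mean"].sort_index()
        return out.rename("blue")
    genos, geno_idx = np.unique(df["genotype"], return_inverse=True)
    n = len(df)
    X = np.zeros((n, len(genos)))
    X[np.arange(n), geno_idx] = 1.0
    env_codes = pd.factorize(df["environment"])[0]
    res = reml_fit(df["mean"].to_numpy(), X, [factor_covariance(env_codes, "environment")])
    return pd.Series(res.beta, index=genos, name="blue")


def two_stage_blues(
    plots: pd.DataFrame, trait: str | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Run stage one in every environment, then stage two; returns (BLUEs, stage-1 table)."""
    _check_plots(plots)
    envs = sorted(plots["environment"].unique())
    stage1 = [adjust_entry_means_per_env(plots, env, trait=trait) for env in envs]
    long = pd.concat(
        [s.rename("mean").rename_axis("genotype").reset_index().assign(environment=s.name)
         for s in stage1],
        ignore_index=True,
    )
    return blues_across_env(long), long


def mid_parent_stats(blues: pd.Series, plan: CrossingPlan) -> pd.DataFrame:
    """Mid-parent value and relative mid-parent heterosis per cross.

    MP = (P1 + P2)/2 and MPH = 100 (HYB - MP)/MP; the summary attributes
    ``mean_mph`` and ``mean_abs_mph`` are attached to the returned frame.
    """
    rows = []
    for (f, m), hyb in zip(plan.crosses, plan.hybrid_ids):
        for gid in (f, m, hyb):
            if gid not in blues.index:
                raise KeyError(f"no BLUE for {gid!r} (cross {f} x {m})")
        p1, p2, h = blues[f], blues[m], blues[hyb]
        mp = (p1 + p2) / 2.0
        if mp == 0:
            raise ZeroDivisionError(f"mid-parent value is 0 for cross {f} x {m}")
        rows.append((hyb, p1, p2, h, mp, 100.0 * (h - mp) / mp))
    out = pd.DataFrame(rows, columns=["hybrid", "P1", "P2", "HYB", "MP", "MPH"]).set_index("hybrid")
    out.attrs["mean_mph"] = float(out["MPH"].mean())
    out.attrs["mean_abs_mph"] = float(out["MPH"].abs().mean())
    return out


@dataclass
class GCAResult:
    """Combining-ability decomposition of hybrid performance."""

    mu: float
    gca_f: pd.Series
    gca_m: pd.Series
    sca: pd.Series

    def predict(self, female: str, male: str) -> float:
        if female not in self.gca_f.index:
            raise KeyError(f"no GCA estimate for female {female!r}")
        if male not in self.gca_m.index:
            raise KeyError(f"no GCA estimate for male {male!r}")
        return self.mu + float(self.gca_f[female]) + float(self.gca_m[male])


def gca_sca(hybrid_blues: pd.Series, plan: CrossingPlan) -> GCAResult:
    """Least-squares mu + gca_f + gca_m + sca under sum-to-zero constraints.

    SCA is the per-cross residual of the additive combining-ability fit; in
    a balanced factorial the GCAs are the classical row/column mean
    deviations.
    """
    from .sim import hybrid_id

    crosses = [c for c in plan.crosses if hybrid_id(*c) in hybrid_blues.index]
    if not crosses:
        raise ValueError("no hybrid BLUEs for any cross in the plan")
    females = sorted({f for f, _ in crosses})
    males = sorted({m for _, m in crosses})
    y = np.array([hybrid_blues[hybrid_id(f, m)] for f, m in crosses])
    nf, nm = len(females), len(males)
    f_pos = {f: i for i, f in enumerate(females)}
    m_pos = {m: i for i, m in enumerate(males)}
    # effect (sum-to-zero) coding: last level = -sum of the others
    X = np.zeros((len(crosses), 1 + (nf - 1) + (nm - 1)))
    X[:, 0] = 1.0
    for r, (f, m) in enumerate(crosses):
        fi, mi = f_pos[f], m_pos[m]
        if fi < nf - 1:
            X[r, 1 + fi] = 1.0
        else:
            X[r, 1:nf] = -1.0
        if mi < nm - 1:
            X[r, nf + mi] = 1.0
        else:
            X[r, nf:] = -1.0
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu = float(coef[0])
    f_eff = np.append(coef[1:nf], -coef[1:nf].sum())
    m_eff = np.append(coef[nf:], -coef[nf:].sum())
    fitted = X @ coef
    sca = pd.Series(y - fitted, index=[hybrid_id(f, m) for f, m in crosses], name="sca")
    return GCAResult(
        mu=mu,
        gca_f=pd.Series(f_eff, index=females, name="gca_f"),
        gca_m=pd.Series(m_eff, index=males, name="gca_m"),
        sca=sca,
    )


def combining_ability_variances(
    hybrid_blues: pd.Series, plan: CrossingPlan
) -> dict[str, float]:
    """REML variance components of the combining-ability model.

    Random female-GCA and male-GCA effects on hybrid BLUEs; the cross-level
    residual absorbs SCA plus the error of the means.  Returns
    ``{"gca": ..., "sca": ...}`` with the GCA component averaged over the
    two parental sexes (used for the RR-BLUP shrinkage ratios).
    """
    from .sim import hybrid_id

    crosses = [c for c in plan.crosses if hybrid_id(*c) in hybrid_blues.index]
    y = np.array([hybrid_blues[hybrid_id(f, m)] for f, m in crosses])
    f_codes = pd.factorize(np.array([f for f, _ in crosses]))[0]
    m_codes = pd.factorize(np.array([m for _, m in crosses]))[0]
    res = reml_fit(
        y,
        np.ones((len(y), 1)),
        [factor_covariance(f_codes, "gca_f"), factor_covariance(m_codes, "gca_m")],
    )
    return {
        "gca": (res["gca_f"] + res["gca_m"]) / 2.0,
        "sca": res["error"],
    }


class OneStepVarianceModel:
    """One-step variance-component model of the complete trial data.

    Every effect except the intercept is random: environment, trial,
    replication, block, line genetic effects (checks ride along as extra
    line levels), line x environment, hybrid genetic effects, hybrid x
    environment, and the plot residual.
    """

    def __init__(
        self,
        plots: pd.DataFrame,
        line_ids: list[str] | None = None,
        hybrid_ids: list[str] | None = None,
        trait: str | None = None,
    ):
        _check_plots(plots)
        if trait is not None:
            plots = plots[plots["trait"] == trait]
        self.plots = plots.reset_index(drop=True)
        genos = self.plots["genotype"]
        if hybrid_ids is None:
            hybrid_ids = sorted(g for g in genos.unique() if "x" in g)
        if line_ids is None:
            line_ids = sorted(g for g in genos.unique() if "x" not in g)
        self.line_ids = list(line_ids)
        self.hybrid_ids = list(hybrid_ids)
        self._terms = self._build_terms()
        self._y = self.plots["value"].to_numpy()
        self._X = np.ones((len(self.plots), 1))

    def _build_terms(self) -> list[RandomTerm]:
        df = self.plots
        line_set, hyb_set = set(self.line_ids), set(self.hybrid_ids)
        is_line = df["genotype"].isin(line_set).to_numpy()
        is_hyb = df["genotype"].isin(hyb_set).to_numpy()
        geno_codes = pd.factorize(df["genotype"])[0]
        env_codes = pd.factorize(df["environment"])[0]
        gxe = geno_codes * (env_codes.max() + 1) + env_codes

        terms = []
        for col in ("environment", "trial", "replication", "block"):
            codes = pd.factorize(df[col])[0]
            if len(np.unique(codes)) > 1:
                terms.append(factor_covariance(codes, col))
        terms.append(factor_covariance(np.where(is_line, geno_codes, -1), "lines"))
        terms.append(factor_covariance(np.where(is_line, gxe, -1), "lines_x_env"))
        terms.append(factor_covariance(np.where(is_hyb, geno_codes, -1), "hybrids"))
        terms.append(factor_covariance(np.where(is_hyb, gxe, -1), "hybrids_x_env"))
        return terms

    def fit(self, tol: float = 1e-8, max_iter: int = 200) -> "VarianceComponentsResults":
        res = reml_fit(self._y, self._X, self._terms, tol=tol, max_iter=max_iter)
        if not res.converged:
            raise RuntimeError(
                f"one-step REML did not converge within {res.n_iter} iterations; "
                f"last restricted log-likelihood {res.loglik:.6f}"
            )
        return VarianceComponentsResults(self, res)


class VarianceComponentsResults:
    """Fitted one-step variance components with halved-LRT significance tests."""

    def __init__(self, model: OneStepVarianceModel, res):
        self.model = model
        self._res = res
        self.variances = dict(res.variances)
        self.loglik = res.loglik
        self.mu = float(res.beta[0])

    def lrt_pvalue(self, component: str) -> float:
        """Halved chi-square(1) likelihood-ratio p-value for one component.

        The reduced model drops the component; because the null pins the
        variance to the boundary of the parameter space, the p-value is
        halved (a statistic of exactly 0 gives p = 0.5).
        """
        terms = [t for t in self.model._terms if t.name != component]
        if len(terms) == len(self.model._terms):
            raise KeyError(f"unknown or absent component {component!r}")
        reduced = reml_fit(self.model._y, self.model._X, terms)
        lrt = max(2.0 * (self.loglik - reduced.loglik), 0.0)
        return 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 0.5

    def lrt_pvalues(self, components: list[str] | None = None) -> pd.Series:
        names = components or [t.name for t in self.model._terms]
        return pd.Series({c: self.lrt_pvalue(c) for c in names}, name="halved_lrt_p")

    def heritability(self, group: str = "hybrids") -> "Heritability":
        env_count = self.model.plots["environment"].nunique()
        rep_count = (
            self.model.plots.groupby(["genotype", "environment"])["value"].count().max()
        )
        return heritability(self.variances, int(env_count), int(rep_count), group)

    def summary(self) -> pd.DataFrame:
        rows = {k: self.variances.get(k, np.nan) for k in ONE_STEP_COMPONENTS}
        return pd.DataFrame({"sigma2": rows})

    def to_tsv(self, path) -> None:
        self.summary().rename_axis("component").to_csv(path, sep="\t")


def variance_components_one_step(
    plots: pd.DataFrame,
    line_ids: list[str] | None = None,
    hybrid_ids: list[str] | None = None,
    trait: str | None = None,
) -> VarianceComponentsResults:
    """Convenience wrapper: build and fit the one-step model."""
    return OneStepVarianceModel(plots, line_ids, hybrid_ids, trait).fit()


@dataclass(frozen=True)
class Heritability:
    """Entry-mean and plot-basis heritability for one genotype group."""

    entry_mean: float
    plot: float
    group: str
    n_env: int
    n_rep: int


def heritability(
    variances: dict[str, float], n_env: int, n_rep: int, group: str = "hybrids"
) -> Heritability:
    """Heritability from one-step variance components.

    Entry-mean basis: h2 = s2_G / (s2_G + s2_GxE/E + s2_e/(E R));
    plot basis:       h2 = s2_G / (s2_G + s2_GxE + s2_e).
    Both are clamped to [0, 1].
    """
    if n_env < 1 or n_rep < 1:
        raise ValueError("n_env and n_rep must be >= 1")
    if group not in ("lines", "hybrids"):
        raise ValueError("group must be 'lines' or 'hybrids'")
    s_g = variances.get(group, 0.0)
    s_ge = variances.get(f"{group}_x_env", 0.0)
    s_e = variances.get("error", 0.0)
    denom_entry = s_g + s_ge / n_env + s_e / (n_env * n_rep)
    denom_plot = s_g + s_ge + s_e
    if denom_entry == 0 or denom_plot == 0:
        raise ValueError("all variance components are zero")
    clamp = lambda x: float(min(max(x, 0.0), 1.0))  # noqa: E731
    return Heritability(
        entry_mean=clamp(s_g / denom_entry),
        plot=clamp(s_g / denom_plot),
        group=group,
        n_env=n_env,
        n_rep=n_rep,
    )
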