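"""Kinship-corrected genome-wide association scans and downstream accounting.

The scan model is Y = X beta + S s + Z u + e with environment fixed effects,
a fixed SNP effect s tested marker by marker, and a polygenic background
u ~ N(0, K sigma2_u) whose covariance is the marker-derived kinship matrix.
The default mode estimates (sigma2_u, sigma2_e) once under the null model
and reuses them for every marker test (the population-parameters-previously-
determined approximation); an exact mode re-estimates the variance ratio per
marker.  Multiple testing is controlled by the Bonferroni-Holm step-down
procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .markers import KinshipMatrix
from .sim import GenotypeMatrix

__all__ = [
    "MixedGwas",
    "AssociationResults",
    "scan",
    "holm_correct",
    "qq_data",
    "VarianceExplained",
    "variance_explained",
    "top_k_markers",
]


def _reml_neg_loglik(log_gamma, lam, yt, Xt):
    """Restricted -log L of V = sigma2_e (I + gamma H) in rotated coordinates."""
    gamma = np.exp(log_gamma)
    w = 1.0 + gamma * lam
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    try:
        beta = np.linalg.solve(A, Xw.T @ yt)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Xt @ beta
    n, p = Xt.shape
    rss = float(r @ (r / w))
    if rss <= 0:
        return np.inf
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return 0.5 * ((n - p) * np.log(rss / (n - p)) + np.sum(np.log(w)) + logdet_a + (n - p))


class MixedGwas:
    """Mixed-model association scan over stacked per-environment entry means.

    Parameters
    ----------
    entry_means
        Either a long DataFrame with columns (genotype, environment, mean)
        — the within-environment adjusted entry means — or a Series indexed
        by genotype (BLUE-level scan; the fixed part is then an intercept).
    geno
        Genotypes of every scanned individual (lines and hybrids).
    kinship
        Polygenic background covariance over the same individuals.
    effect
        'additive' tests the -1/0/+1 code, 'dominance' the 0/1 heterozygosity
        code (informative only where hybrids are present).
    """

    def __init__(
        self,
        entry_means: pd.DataFrame | pd.Series,
        geno: GenotypeMatrix,
        kinship: KinshipMatrix,
        effect: str = "additive",
    ):
        if effect not in ("additive", "dominance"):
            raise ValueError("effect must be 'additive' or 'dominance'")
        if isinstance(entry_means, pd.Series):
            df = entry_means.rename("mean").rename_axis("genotype").reset_index()
            df["environment"] = "combined"
        else:
            df = entry_means.copy()
        missing = set(df["genotype"]) - set(geno.individual_ids)
        if missing:
            raise KeyError(f"genotypes without marker data: {sorted(missing)[:5]}")
        self.effect = effect
        self.geno = geno
        self.data = df.reset_index(drop=True)

        genos = list(dict.fromkeys(df["genotype"]))
        gpos = {g: i for i, g in enumerate(genos)}
        self._genos = genos
        self._row_of_geno = np.array([gpos[g] for g in df["genotype"]])

        K = kinship.rows(genos)
        H = K[np.ix_(self._row_of_geno, self._row_of_geno)]
        self._y = df["mean"].to_numpy(dtype=float)
        envs = pd.factorize(df["environment"])[0]
        n = len(df)
        if envs.max() == 0:
            X = np.ones((n, 1))
        else:
            X = np.zeros((n, envs.max() + 1))
            X[np.arange(n), envs] = 1.0
        self._X = X
        self._env_codes = envs

        lam, U = np.linalg.eigh((H + H.T) / 2.0)
        self._lam = np.clip(lam, 0.0, None)
        self._U = U

        dos = geno.subset(individuals=genos).values()
        if np.isnan(dos).any():
            raise ValueError("missing dosages; impute before scanning")
        codes = dos - 1.0 if effect == "additive" else (dos == 1.0).astype(float)
        self._marker_codes = codes  # genotypes x markers

    # -- variance components under the null ---------------------------------
    def _fit_null(self) -> tuple[float, float]:
        yt = self._U.T @ self._y
        Xt = self._U.T @ self._X
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(-12.0, 12.0), args=(self._lam, yt, Xt),
            method="bounded", options={"xatol": 1e-8},
        )
        gamma = float(np.exp(res.x))
        # boundary: effectively no polygenic variance
        if res.x <= -11.9:
            gamma = 0.0
        w = 1.0 + gamma * self._lam
        Xw = Xt / w[:, None]
        beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
        r = yt - Xt @ beta
        n, p = Xt.shape
        s2e = float(r @ (r / w)) / (n - p)
        return gamma * s2e, s2e

    def fit(
        self,
        mode: str = "p3d",
        sigma2_u: float | None = None,
        sigma2_e: float | None = None,
    ) -> "AssociationResults":
        """Scan every marker; returns one row per (marker, effect type)."""
        if mode not in ("p3d", "exact"):
            raise ValueError("mode must be 'p3d' or 'exact'")
        if sigma2_u is None or sigma2_e is None:
            s2u, s2e = self._fit_null()
        else:
            s2u, s2e = float(sigma2_u), float(sigma2_e)
        gamma = s2u / s2e if s2e > 0 else 0.0

        yt = self._U.T @ self._y
        Xt = self._U.T @ self._X
        S = self._marker_codes[self._row_of_geno]  # obs x markers
        St = self._U.T @ S
        n, p = Xt.shape

        poly = self._marker_codes.std(axis=0) > 0
        if mode == "p3d":
            est, se, pval = self._wald_p3d(gamma, yt, Xt, St)
        else:
            est = np.full(S.shape[1], np.nan)
            se = np.full(S.shape[1], np.nan)
            pval = np.full(S.shape[1], np.nan)
            for j in np.where(poly)[0]:
                est[j], se[j], pval[j] = self._wald_exact(yt, Xt, St[:, j])
        est[~poly] = np.nan
        se[~poly] = np.nan
        pval[~poly] = np.nan

        mk = self.geno.marker_ids
        table = pd.DataFrame(
            {
                "marker": mk,
                "chrom": self.geno.map["chrom"].to_numpy(),
                "pos_cm": self.geno.map["pos_cm"].to_numpy(),
                "effect_type": self.effect,
                "estimate": est,
                "se": se,
                "p": pval,
                "skipped": ~poly,
            }
        )
        return AssociationResults(
            table=table,
            sigma2_u=s2u,
            sigma2_e=s2e,
            n_genotypes=len(self._genos),
            mode=mode,
        )

    def _wald_p3d(self, gamma, yt, Xt, St):
        w = 1.0 + gamma * self._lam
        sw = 1.0 / np.sqrt(w)
        yw = yt * sw
        Xw = Xt * sw[:, None]
        Sw = St * sw[:, None]
        A = Xw.T @ Xw
        Ainv = np.linalg.inv(A)
        # residualize markers and response on the fixed effects
        coef_x = Ainv @ (Xw.T @ Sw)
        S_perp = Sw - Xw @ coef_x
        y_perp = yw - Xw @ (Ainv @ (Xw.T @ yw))
        ss = np.einsum("ij,ij->j", S_perp, S_perp)
        sy = S_perp.T @ y_perp
        rss0 = float(y_perp @ y_perp)
        n, p = Xt.shape
        with np.errstate(divide="ignore", invalid="ignore"):
            est = sy / ss
            rss1 = rss0 - sy**2 / ss
            df2 = n - p - 1
            fstat = (rss0 - rss1) / (rss1 / df2)
            pval = stats.f.sf(fstat, 1, df2)
            se = np.sqrt(rss1 / df2 / ss)
        return est, se, pval

    def _wald_exact(self, yt, Xt, st):
        Xa = np.column_stack([Xt, st])
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(-12.0, 12.0), args=(self._lam, yt, Xa),
            method="bounded", options={"xatol": 1e-8},
        )
        gamma = float(np.exp(res.x))
        w = 1.0 + gamma * self._lam
        Xw = Xa / w[:, None]
        A = Xa.T @ Xw
        Ainv = np.linalg.inv(A)
        beta = Ainv @ (Xw.T @ yt)
        r = yt - Xa @ beta
        n, p = Xa.shape
        s2e = float(r @ (r / w)) / (n - p)
        se = float(np.sqrt(s2e * Ainv[-1, -1]))
        fstat = (beta[-1] / se) ** 2
        return float(beta[-1]), se, float(stats.f.sf(fstat, 1, n - p))

    def interaction_pvalues(self, marker_ids: list[str]) -> pd.Series:
        """Marker x environment fixed-interaction F-test (needs >= 2 environments)."""
        n_env = self._env_codes.max() + 1
        if n_env < 2:
            raise ValueError("interaction test needs >= 2 environments")
        s2u, s2e = self._fit_null()
        gamma = s2u / s2e if s2e > 0 else 0.0
        w = 1.0 + gamma * self._lam
        sw = 1.0 / np.sqrt(w)
        yt = (self._U.T @ self._y) * sw
        Xt = (self._U.T @ self._X) * sw[:, None]
        out = {}
        pos = {mk: j for j, mk in enumerate(self.geno.marker_ids)}
        for mk in marker_ids:
            z = self._marker_codes[self._row_of_geno, pos[mk]]
            main = (self._U.T @ z) * sw
            inter_cols = []
            for e in range(1, n_env):
                col = z * (self._env_codes == e)
                inter_cols.append((self._U.T @ col) * sw)
            X0 = np.column_stack([Xt, main])
            X1 = np.column_stack([X0] + inter_cols)
            rss0 = _ols_rss(X0, yt)
            rss1 = _ols_rss(X1, yt)
            df1 = X1.shape[1] - X0.shape[1]
            df2 = len(yt) - X1.shape[1]
            fstat = ((rss0 - rss1) / df1) / (rss1 / df2)
            out[mk] = float(stats.f.sf(fstat, df1, df2))
        return pd.Series(out, name="interaction_p")


def _ols_rss(X, y):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


@dataclass
class AssociationResults:
    """Per-marker association tests plus scan metadata."""

    table: pd.DataFrame
    sigma2_u: float
    sigma2_e: float
    n_genotypes: int
    mode: str
    trait: str | None = None

    def pvalues(self) -> pd.Series:
        t = self.table[~self.table["skipped"]]
        return pd.Series(t["p"].to_numpy(), index=t["marker"].to_numpy(), name="p")

    def holm_significant(self, alpha: float = 0.05) -> list[str]:
        p = self.pvalues()
        rejected = holm_correct(p.to_numpy(), alpha)
        return [mk for mk, r in zip(p.index, rejected) if r]

    def significant_at(self, threshold: float) -> list[str]:
        p = self.pvalues()
        return list(p.index[p.to_numpy() < threshold])

    def top_k(self, k: int = 3) -> list[str]:
        return top_k_markers(self, k)

    def qq(self) -> pd.DataFrame:
        return qq_data(self.pvalues().to_numpy())

    def to_tsv(self, path, alpha: float = 0.05) -> None:
        out = self.table.copy()
        sig = set(self.holm_significant(alpha))
        out["holm_significant"] = out["marker"].isin(sig)
        out.to_csv(path, sep="\t", index=False)


def scan(
    entry_means: pd.DataFrame | pd.Series,
    geno: GenotypeMatrix,
    kinship: KinshipMatrix,
    effect: str = "additive",
    mode: str = "p3d",
) -> AssociationResults:
    """Functional wrapper over :class:`MixedGwas`."""
    return MixedGwas(entry_means, geno, kinship, effect).fit(mode=mode)


def holm_correct(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni-Holm step-down decisions.

    Sort ascending and reject while p_(i) < alpha/(m - i + 1); stop at the
    first failure.  Returns a boolean rejection mask aligned with the input.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    reject = np.zeros(m, dtype=bool)
    if m == 0:
        return reject
    order = np.argsort(p, kind="stable")
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def qq_data(pvalues: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 p under the global null."""
    p = np.asarray(pvalues, dtype=float)
    if np.any(p <= 0):
        raise ValueError("p-values must be strictly positive")
    m = len(p)
    obs = np.sort(p)
    exp = np.arange(1, m + 1) / (m + 1)
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(exp), "observed_neglog10": -np.log10(obs)}
    )


@dataclass
class VarianceExplained:
    """Sequential and joint explained variance of the declared QTL set."""

    per_qtl_r2: pd.Series
    r2_adj: float
    p_g: float
    h2: float
    capped: bool = False
    rank_deficient: bool = False


def variance_explained(
    significant: list[str],
    blues: pd.Series,
    geno: GenotypeMatrix,
    h2: float,
    pvalues: pd.Series | None = None,
) -> VarianceExplained:
    """Explained phenotypic and genotypic variance of the significant markers.

    Sequential sums-of-squares R2 per QTL with markers entered in ascending
    p-value order (order of ``significant`` if no p-values are given), joint
    adjusted R2 of the multiple regression of the BLUEs on all markers, and
    p_G = R2_adj / h2 capped at 1.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    if not significant:
        return VarianceExplained(pd.Series(dtype=float), 0.0, 0.0, h2)
    order = list(significant)
    if pvalues is not None:
        order = sorted(order, key=lambda mk: float(pvalues[mk]))
    ids = list(blues.index)
    codes = geno.subset(individuals=ids, markers=order).values() - 1.0
    y = blues.to_numpy(dtype=float)
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    seq = []
    prev = 0.0
    rank_deficient = False
    for k in range(1, len(order) + 1):
        X = np.column_stack([np.ones(n), codes[:, :k]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            rank_deficient = True
        rss = _ols_rss(X, y)
        r2 = 1.0 - rss / tss
        seq.append(r2 - prev)
        prev = r2
    k = len(order)
    r2_adj = 1.0 - (1.0 - prev) * (n - 1) / max(n - k - 1, 1)
    r2_adj = float(np.clip(r2_adj, 0.0, 1.0))
    p_g = r2_adj / h2
    capped = p_g > 1.0
    return VarianceExplained(
        per_qtl_r2=pd.Series(seq, index=order, name="seq_r2"),
        r2_adj=r2_adj,
        p_g=min(p_g, 1.0),
        h2=h2,
        capped=capped,
        rank_deficient=rank_deficient,
    )


def top_k_markers(result: AssociationResults, k: int = 3) -> list[str]:
    """The k most significant markers; p ties broken by (chrom, cM, id)."""
    t = result.table[~result.table["skipped"]]
    if k > len(t):
        raise ValueError(f"k={k} exceeds {len(t)} tested markers")
    t = t.sort_values(["p", "chrom", "pos_cm", "marker"], kind="stable")
    return list(t["marker"].head(k))
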