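"""Genomic and classical predictors of hybrid performance.

RR-BLUP solves Henderson's mixed-model equations for an intercept plus
random additive and dominance marker effects with common shrinkage per
effect class; W-BLUP relaxes the shrinkage on a handful of "functional"
markers (the most significant hits of an association scan in the training
data); Bayes-Cpi is a Gibbs-sampled variable-selection model in which each
marker contributes with probability 1 - pi and pi itself carries a uniform
prior.  GCA- and mid-parent-based predictors cover the classical,
pedigree-style alternatives that only apply when both parents of a target
hybrid were themselves involved in the training data.

All model classes follow a Model(...).fit(...) -> Results pattern; Results
objects carry the estimated intercept and per-marker effects and predict on
new design matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .markers import DesignMatrices
from .pheno import GCAResult
from .sim import CrossingPlan, hybrid_id

__all__ = [
    "shrinkage_params",
    "MarkerEffects",
    "RRBlup",
    "WBlup",
    "BayesCpi",
    "ChainSettings",
    "rrblup_fit",
    "wblup_fit",
    "bayescpi_fit",
    "predict_values",
    "gblup_predict",
    "gca_predict",
    "mp_predict",
]


def shrinkage_params(
    sigma2_e: float,
    sigma2_gca: float,
    sigma2_sca: float,
    n_env: int,
    n_marker: int,
) -> tuple[float, float]:
    """Ridge shrinkage for the additive and dominance marker-effect blocks.

    lambda_A = (sigma2_e / Nr.Env) / (sigma2_GCA / Nr.Marker) and
    lambda_D = (sigma2_e / Nr.Env) / (sigma2_SCA / Nr.Marker): the ratio of
    the environment-averaged residual variance to the per-marker share of
    the combining-ability variance.
    """
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be > 0")
    if sigma2_gca <= 0 or sigma2_sca <= 0:
        raise ValueError("GCA and SCA variances must be > 0")
    if n_env < 1 or n_marker < 1:
        raise ValueError("n_env and n_marker must be >= 1")
    lam_a = (sigma2_e / n_env) / (sigma2_gca / n_marker)
    lam_d = (sigma2_e / n_env) / (sigma2_sca / n_marker)
    return lam_a, lam_d


@dataclass
class MarkerEffects:
    """Fitted intercept plus per-marker additive/dominance effects."""

    model: str
    mu: float
    additive: pd.Series
    dominance: pd.Series | None = None
    inclusion: pd.DataFrame | None = None

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(self.additive.index)

    def predict(self, dm: DesignMatrices) -> pd.Series:
        return predict_values(self, dm)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"additive": self.additive})
        if self.dominance is not None:
            out["dominance"] = self.dominance
        if self.inclusion is not None:
            out = out.join(self.inclusion)
        out.attrs["model"] = self.model
        out.attrs["mu"] = self.mu
        return out

    def to_tsv(self, path) -> None:
        self.summary().rename_axis("marker").to_csv(path, sep="\t")


def _align_y(y, dm: DesignMatrices) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [g for g in dm.individual_ids if g not in y.index]
        if missing:
            raise KeyError(f"no phenotype for {missing[:5]}")
        return y.loc[list(dm.individual_ids)].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != dm.n:
        raise ValueError("phenotype vector length does not match design matrices")
    return y


class RRBlup:
    """Ridge-regression BLUP of marker effects via the mixed-model equations.

    The estimates solve the block system

        [ 1'1    1'Z_A          1'Z_D        ] [mu]   [1'y  ]
        [ Z_A'1  Z_A'Z_A+L_A    Z_A'Z_D      ] [a ] = [Z_A'y]
        [ Z_D'1  Z_D'Z_A        Z_D'Z_D+L_D  ] [d ]   [Z_D'y]

    with L_A = lambda_A I and L_D = lambda_D I (per-marker diagonals in the
    weighted variant).  For m > n the numerically identical n-dimensional
    dual (BLUP) form is used.
    """

    def __init__(self, y, dm: DesignMatrices, include_dominance: bool = True):
        self.dm = dm
        self.include_dominance = include_dominance
        self.y = _align_y(y, dm)

    def fit(
        self,
        lambda_a: float,
        lambda_d: float | None = None,
        method: str = "auto",
        penalty_a: np.ndarray | None = None,
        penalty_d: np.ndarray | None = None,
        model_tag: str = "rrblup",
    ) -> MarkerEffects:
        dm = self.dm
        if lambda_a <= 0:
            raise ValueError("lambda_a must be > 0")
        pa = np.full(dm.m, float(lambda_a)) if penalty_a is None else np.asarray(penalty_a, float)
        if self.include_dominance:
            if lambda_d is None or lambda_d <= 0:
                raise ValueError("lambda_d must be > 0 for the additive+dominance model")
            pd_ = np.full(dm.m, float(lambda_d)) if penalty_d is None else np.asarray(penalty_d, float)
        else:
            pd_ = None
        if method == "auto":
            method = "direct" if 2 * dm.m <= dm.n else "dual"
        if method == "direct":
            mu, a, d = self._solve_direct(pa, pd_)
        elif method == "dual":
            mu, a, d = self._solve_dual(pa, pd_)
        else:
            raise ValueError("method must be 'auto', 'direct' or 'dual'")
        return MarkerEffects(
            model=model_tag if self.include_dominance else f"{model_tag}-additive",
            mu=mu,
            additive=pd.Series(a, index=list(dm.marker_ids), name="additive"),
            dominance=None if d is None else pd.Series(d, index=list(dm.marker_ids), name="dominance"),
        )

    def _solve_direct(self, pa, pd_):
        dm, y = self.dm, self.y
        blocks = [np.ones((dm.n, 1)), dm.Z_A]
        penalty = [np.zeros(1), pa]
        if pd_ is not None:
            blocks.append(dm.Z_D)
            penalty.append(pd_)
        C = np.hstack(blocks)
        M = C.T @ C + np.diag(np.concatenate(penalty))
        try:
            theta = linalg.solve(M, C.T @ y, assume_a="sym")
        except linalg.LinAlgError as err:
            raise RuntimeError(f"singular mixed-model equations: {err}") from err
        mu = float(theta[0])
        a = theta[1 : 1 + dm.m]
        d = theta[1 + dm.m :] if pd_ is not None else None
        return mu, a, d

    def _solve_dual(self, pa, pd_):
        dm, y = self.dm, self.y
        n = dm.n
        V = np.eye(n) + (dm.Z_A / pa) @ dm.Z_A.T
        if pd_ is not None:
            V += (dm.Z_D / pd_) @ dm.Z_D.T
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError as err:
            raise RuntimeError(f"singular mixed-model equations: {err}") from err
        ones = np.ones(n)
        Vinv_1 = linalg.cho_solve((c, low), ones)
        Vinv_y = linalg.cho_solve((c, low), y)
        mu = float(ones @ Vinv_y) / float(ones @ Vinv_1)
        alpha = Vinv_y - Vinv_1 * mu
        a = (dm.Z_A.T @ alpha) / pa
        d = (dm.Z_D.T @ alpha) / pd_ if pd_ is not None else None
        return mu, a, d


class WBlup(RRBlup):
    """RR-BLUP with near-unshrunken effects for declared functional markers.

    Functional-marker columns receive penalty lambda/weight (weight >> 1
    makes them behave like fixed covariates; weight = 1 reduces exactly to
    RR-BLUP).
    """

    def __init__(
        self,
        y,
        dm: DesignMatrices,
        functional_ids: list[str],
        weight: float = 100.0,
        include_dominance: bool = True,
    ):
        super().__init__(y, dm, include_dominance)
        if len(set(functional_ids)) != len(functional_ids):
            raise ValueError("duplicate functional marker ids")
        unknown = [mk for mk in functional_ids if mk not in dm.marker_ids]
        if unknown:
            raise KeyError(f"functional markers not in panel: {unknown}")
        if weight <= 0:
            raise ValueError("weight must be > 0")
        self.functional_ids = list(functional_ids)
        self.weight = float(weight)

    def fit(self, lambda_a: float, lambda_d: float | None = None, method: str = "auto"):
        pos = {mk: j for j, mk in enumerate(self.dm.marker_ids)}
        idx = [pos[mk] for mk in self.functional_ids]
        pa = np.full(self.dm.m, float(lambda_a))
        pa[idx] /= self.weight
        pd_ = None
        if self.include_dominance:
            if lambda_d is None or lambda_d <= 0:
                raise ValueError("lambda_d must be > 0")
            pd_ = np.full(self.dm.m, float(lambda_d))
            pd_[idx] /= self.weight
        return super().fit(
            lambda_a, lambda_d, method=method, penalty_a=pa, penalty_d=pd_,
            model_tag="wblup",
        )


@dataclass(frozen=True)
class ChainSettings:
    """Gibbs chain settings for Bayes-Cpi."""

    iterations: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


class BayesCpi:
    """Bayes-Cpi variable-selection model sampled by Gibbs.

    Each marker's effect enters the model through a Bernoulli(1 - pi)
    inclusion indicator per effect class (additive, dominance); included
    effects share a class variance with a scaled-inverse-chi-square prior
    (df = 4, scale matched to half the phenotypic variance spread over the
    expected number of included markers); pi has a uniform(0, 1) prior,
    giving a Beta full conditional.
    """

    def __init__(self, y, dm: DesignMatrices, include_dominance: bool = True):
        self.dm = dm
        self.include_dominance = include_dominance
        self.y = _align_y(y, dm)

    def fit(self, chain: ChainSettings | None = None, fix_pi: float | None = None) -> MarkerEffects:
        chain = chain or ChainSettings()
        if fix_pi is not None and not 0.0 <= fix_pi < 1.0:
            raise ValueError("fix_pi must be in [0, 1)")
        rng = np.random.default_rng(chain.seed)
        y = self.y
        n = len(y)
        dm = self.dm
        classes = [("additive", dm.Z_A)]
        if self.include_dominance:
            classes.append(("dominance", dm.Z_D))

        vy = float(np.var(y)) or 1.0
        nu = 4.0
        mu = float(np.mean(y))
        resid = y - mu
        s2e = vy * 0.5
        scale_e = vy * 0.5

        state = {}
        for name, Z in classes:
            m = Z.shape[1]
            css = np.einsum("ij,ij->j", Z, Z)
            col_var = max(float(np.sum(css) / n), 1e-12)
            # prior scale: half the phenotypic variance over E[#included] markers
            scale_g = 0.5 * vy / max(col_var * 0.5, 1e-12)
            state[name] = {
                "Z": Z,
                "css": css,
                "beta": np.zeros(m),
                "delta": np.zeros(m, dtype=bool),
                "s2g": max(scale_g, 1e-10),
                "scale_g": max(scale_g, 1e-10),
                "pi": 0.5 if fix_pi is None else float(fix_pi),
                "sum_effect": np.zeros(m),
                "sum_incl": np.zeros(m),
                "sum_pi": 0.0,
            }

        n_kept = 0
        sum_mu = 0.0
        for it in range(chain.iterations):
            # intercept
            resid += mu
            mu = rng.normal(float(np.mean(resid)), np.sqrt(s2e / n))
            resid -= mu

            for name, _Z in classes:
                st = state[name]
                Z, css = st["Z"], st["css"]
                beta, delta = st["beta"], st["delta"]
                lam = s2e / st["s2g"]
                pi = st["pi"]
                log_prior_odds = np.log1p(-pi) - np.log(pi) if 0 < pi < 1 else None
                m = len(beta)
                u_incl = rng.random(m)
                z_eff = rng.standard_normal(m)
                for j in range(m):
                    cj = css[j]
                    if cj == 0.0:
                        continue
                    zj = Z[:, j]
                    rhs = float(zj @ resid)
                    if delta[j]:
                        rhs += cj * beta[j]
                    denom = cj + lam
                    if pi <= 0.0:
                        include = True
                    elif pi >= 1.0:
                        include = False
                    else:
                        log_bf = (
                            log_prior_odds
                            + 0.5 * (np.log(lam) - np.log(denom))
                            + 0.5 * rhs**2 / (s2e * denom)
                        )
                        include = u_incl[j] < 1.0 / (1.0 + np.exp(-log_bf))
                    old = beta[j] if delta[j] else 0.0
                    if include:
                        new = rhs / denom + z_eff[j] * np.sqrt(s2e / denom)
                    else:
                        new = 0.0
                    if new != old:
                        resid -= zj * (new - old)
                    beta[j] = new if include else 0.0
                    delta[j] = include

                m_in = int(delta.sum())
                ss_beta = float(np.sum(beta[delta] ** 2)) if m_in else 0.0
                st["s2g"] = (
                    (ss_beta + nu * st["scale_g"])
                    / rng.chisquare(nu + m_in)
                )
                if fix_pi is None:
                    st["pi"] = rng.beta(m - m_in + 1, m_in + 1)

            ss_resid = float(resid @ resid)
            s2e = (ss_resid + nu * scale_e) / rng.chisquare(nu + n)
            if not np.isfinite(s2e) or s2e <= 0:
                raise RuntimeError(f"non-finite residual variance at iteration {it}")

            if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
                n_kept += 1
                sum_mu += mu
                for name, _Z in classes:
                    st = state[name]
                    st["sum_effect"] += st["beta"]
                    st["sum_incl"] += st["delta"]
                    st["sum_pi"] += st["pi"]

        mk = list(dm.marker_ids)
        post = {name: state[name]["sum_effect"] / n_kept for name, _ in classes}
        incl = pd.DataFrame(
            {f"pip_{name}": state[name]["sum_incl"] / n_kept for name, _ in classes},
            index=mk,
        )
        effects = MarkerEffects(
            model="bayescpi",
            mu=sum_mu / n_kept,
            additive=pd.Series(post["additive"], index=mk, name="additive"),
            dominance=(
                pd.Series(post["dominance"], index=mk, name="dominance")
                if self.include_dominance
                else None
            ),
            inclusion=incl,
        )
        effects.posterior_pi = {
            name: state[name]["sum_pi"] / n_kept for name, _ in classes
        }
        effects.n_samples = n_kept
        return effects


# ---------------------------------------------------------------------------
# functional wrappers and classical predictors
# ---------------------------------------------------------------------------

def rrblup_fit(
    blues, dm: DesignMatrices, lambda_a: float, lambda_d: float | None = None,
    include_dominance: bool = True, method: str = "auto",
) -> MarkerEffects:
    return RRBlup(blues, dm, include_dominance).fit(lambda_a, lambda_d, method=method)


def wblup_fit(
    blues, dm: DesignMatrices, functional_ids: list[str], lambda_a: float,
    lambda_d: float | None = None, w: float = 100.0, include_dominance: bool = True,
) -> MarkerEffects:
    return WBlup(blues, dm, functional_ids, w, include_dominance).fit(lambda_a, lambda_d)


def bayescpi_fit(
    blues, dm: DesignMatrices, chain: ChainSettings | None = None,
    fix_pi: float | None = None, include_dominance: bool = True,
) -> MarkerEffects:
    return BayesCpi(blues, dm, include_dominance).fit(chain, fix_pi)


def predict_values(effects: MarkerEffects, dm: DesignMatrices) -> pd.Series:
    """y_hat = mu + Z_A a + Z_D d over the target design-matrix rows."""
    if tuple(dm.marker_ids) != effects.marker_ids:
        offending = set(dm.marker_ids) ^ set(effects.marker_ids)
        raise ValueError(
            f"marker panel mismatch between effects and targets "
            f"({len(offending)} markers differ, e.g. {sorted(offending)[:3]})"
        )
    yhat = effects.mu + dm.Z_A @ effects.additive.to_numpy()
    if effects.dominance is not None:
        yhat = yhat + dm.Z_D @ effects.dominance.to_numpy()
    return pd.Series(yhat, index=list(dm.individual_ids), name="predicted")


def gblup_predict(
    y_train, dm_train: DesignMatrices, dm_target: DesignMatrices, lambda_a: float
) -> pd.Series:
    """Kinship-based BLUP with K = Z_A Z_A'/m, equivalent to additive RR-BLUP.

    Serves as the independent route for the RR-BLUP/GBLUP identity: with the
    variance ratio matched (lambda_K = lambda_a / m) the predictions agree
    with the marker-effect route to numerical precision.
    """
    y = _align_y(y_train, dm_train)
    n, m = dm_train.n, dm_train.m
    K = dm_train.Z_A @ dm_train.Z_A.T / m
    C = dm_target.Z_A @ dm_train.Z_A.T / m
    Vbar = K + (lambda_a / m) * np.eye(n)
    c, low = linalg.cho_factor(Vbar, lower=True)
    ones = np.ones(n)
    Vinv_1 = linalg.cho_solve((c, low), ones)
    Vinv_y = linalg.cho_solve((c, low), y)
    mu = float(ones @ Vinv_y) / float(ones @ Vinv_1)
    alpha = Vinv_y - Vinv_1 * mu
    return pd.Series(mu + C @ alpha, index=list(dm_target.individual_ids), name="predicted")


def gca_predict(gca: GCAResult, plan: CrossingPlan) -> pd.Series:
    """y_hat(f, m) = mu + gca_f + gca_m for every cross of the plan.

    Raises KeyError when a target parent has no GCA estimate — the signal
    that the target is not a T2-type hybrid.
    """
    preds = {hybrid_id(f, m): gca.predict(f, m) for f, m in plan.crosses}
    return pd.Series(preds, name="predicted")


def mp_predict(parent_blues: pd.Series, plan: CrossingPlan) -> pd.Series:
    """Mid-parent prediction (BLUE(P1) + BLUE(P2)) / 2 per cross."""
    preds = {}
    for f, m in plan.crosses:
        for pid in (f, m):
            if pid not in parent_blues.index:
                raise KeyError(f"no BLUE for parent {pid!r}")
        preds[hybrid_id(f, m)] = (parent_blues[f] + parent_blues[m]) / 2.0
    return pd.Series(preds, name="predicted")
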