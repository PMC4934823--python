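"""End-to-end orchestration: config validation, staged runs, manifests.

A run executes simulate -> qc -> pheno -> gwas -> predict -> cv in order,
persisting every intermediate artifact as plain text (TSV/CSV/JSON) in the
output directory.  A manifest records the config hash, per-stage output
checksums and wall times; re-running a completed pipeline with the same
config skips completed stages and leaves the checksums untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossval as cv
from . import gwas as gw
from . import markers as mk
from . import pheno as ph
from . import predict as gp
from . import sim

__all__ = ["RunConfig", "validate_config", "run_all", "STAGES"]

log = logging.getLogger("hybridpred")

STAGES = ("simulate", "qc", "pheno", "gwas", "predict", "cv")


@dataclass
class SimulationConfig:
    n_female: int = 120
    n_male: int = 15
    n_hybrids: int = 1604
    n_markers: int = 17_300
    n_chromosomes: int = 21
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_qtl: int = 200
    additive_sd: float = 1.0
    dominance_sd: float = 0.2
    environments: int = 6
    trials_per_env: int = 3
    replications: int = 2
    block_size: int = 20
    replicated_hybrid_fraction: float = 0.29
    n_checks: int = 10
    variance_components: dict = field(
        default_factory=lambda: {
            "environment": 1.0,
            "trial": 0.1,
            "replication": 0.1,
            "block": 0.2,
            "gxe": 0.3,
            "error": 1.0,
        }
    )

    def validate(self) -> None:
        if self.n_female < 1 or self.n_male < 1:
            raise ValueError("simulation: need >= 1 parent of each sex")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("simulation: require 0 < maf_low <= maf_high <= 0.5")
        if self.n_hybrids != "full" and int(self.n_hybrids) > self.n_female * self.n_male:
            raise ValueError("simulation: n_hybrids exceeds the full factorial")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("simulation: negative variance component")


@dataclass
class QCConfig:
    max_missing: float = 0.05
    max_het: float = 0.05
    min_maf: float = 0.05

    def validate(self) -> None:
        for name in ("max_missing", "max_het", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"qc.{name} must be in [0, 1], got {v}")


@dataclass
class ModelConfig:
    lambda_weight: float = 100.0
    n_functional: int = 3
    bayescpi_iterations: int = 10_000
    bayescpi_burn_in: int = 2_000
    bayescpi_thin: int = 10
    gwas_alpha: float = 0.05

    def validate(self) -> None:
        if self.bayescpi_burn_in >= self.bayescpi_iterations:
            raise ValueError("models: burn_in must be < iterations")
        if not 0.0 < self.gwas_alpha < 1.0:
            raise ValueError("models: gwas_alpha must be in (0, 1)")
        if self.lambda_weight <= 0 or self.n_functional < 1:
            raise ValueError("models: lambda_weight > 0 and n_functional >= 1 required")


@dataclass
class CVConfig:
    n_f_est: int = 80
    n_m_est: int = 10
    n_hyb_est: int = 610
    n_runs: int = 100
    models: tuple = ("rrblup",)

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ValueError("cv: n_runs must be >= 1")
        known = {"rrblup", "rrblup-a", "wblup", "bayescpi", "gca", "mp"}
        bad = set(self.models) - known
        if bad:
            raise ValueError(f"cv: unknown models {sorted(bad)}")


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "run_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    models: ModelConfig = field(default_factory=ModelConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def validate(self) -> None:
        for section in (self.simulation, self.qc, self.models, self.cv):
            section.validate()

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_SECTIONS = {
    "simulation": SimulationConfig,
    "qc": QCConfig,
    "models": ModelConfig,
    "cv": CVConfig,
}


def validate_config(raw: dict | str | None) -> RunConfig:
    """Build a typed, range-checked RunConfig; unknown keys are rejected.

    ``raw`` may be a YAML string, a dict, or None (all defaults — the
    female x male factorial of 120 x 15 with 1,604 hybrids, 6 environments,
    3 trials, 2 replications, 29% hybrid replication, 5% QC thresholds).
    """
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    top_known = {"seed", "out_dir", *_SECTIONS}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("seed", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        valid = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        bad = set(section) - valid
        if bad:
            raise ValueError(f"unknown keys in {name!r}: {sorted(bad)}")
        kwargs[name] = cls(**section)
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out: Path, config_hash: str):
        self.path = out / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            if self.data.get("config_hash") != config_hash:
                self.data = {"config_hash": config_hash, "stages": {}}
        else:
            self.data = {"config_hash": config_hash, "stages": {}}

    def done(self, stage: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        for fname, digest in entry["outputs"].items():
            p = self.path.parent / fname
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.data["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_all(config: RunConfig | dict | str | None, resume: bool = True) -> dict:
    """Execute every stage in order; returns the manifest dictionary.

    A stage failure halts the run with the failing stage named; outputs of
    completed stages are retained and reused on the next invocation.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, cfg.config_hash())

    state: dict = {}
    for stage in STAGES:
        fn = _STAGE_FUNCS[stage]
        if resume and manifest.done(stage):
            log.info("stage %s: up to date, skipping", stage)
            fn(cfg, out, state, load_only=True)
            continue
        t0 = time.perf_counter()
        try:
            outputs = fn(cfg, out, state, load_only=False)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        manifest.record(stage, outputs, time.perf_counter() - t0)
        log.info("stage %s: done (%.1fs)", stage, time.perf_counter() - t0)
    return manifest.data


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path, state: dict, load_only: bool):
    s = cfg.simulation
    paths = {
        "geno": out / "parent_genotypes.tsv",
        "map": out / "marker_map.tsv",
        "hyb": out / "hybrid_genotypes.tsv",
        "plots": out / "plots.csv",
        "qtl": out / "truth_qtl.tsv",
        "vc": out / "truth_variances.tsv",
    }
    if load_only:
        state["parent_geno"] = sim.GenotypeMatrix.from_tsv(paths["geno"], paths["map"])
        state["hybrid_geno"] = sim.GenotypeMatrix.from_tsv(paths["hyb"], paths["map"])
        state["plots"] = pd.read_csv(paths["plots"])
        f_ids = tuple(i for i in state["parent_geno"].individual_ids if i.startswith("F"))
        m_ids = tuple(i for i in state["parent_geno"].individual_ids if i.startswith("M"))
        state["parents"] = sim.ParentSet(f_ids, m_ids)
        state["plan"] = sim.CrossingPlan(
            tuple(tuple(h.split("x", 1)) for h in state["hybrid_geno"].individual_ids)
        )
        return list(paths.values())

    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(x) for x in ss.generate_state(4) >> 1]
    parent_geno, parents = sim.simulate_parents(
        s.n_female, s.n_male, s.n_markers, s.n_chromosomes,
        s.maf_low, s.maf_high, seed=seeds[0],
    )
    plan = sim.make_factorial(parents, s.n_hybrids, seed=seeds[1])
    hybrid_geno = sim.derive_hybrid_genotypes(parent_geno, plan)
    both = parent_geno.concat(hybrid_geno)
    values, truth = sim.simulate_genetic_values(
        both, s.n_qtl, s.additive_sd, s.dominance_sd, seed=seeds[2]
    )
    design = sim.TrialDesign(
        s.environments, s.trials_per_env, s.replications, s.block_size,
        s.replicated_hybrid_fraction, s.n_checks,
    )
    plots = sim.simulate_trials(
        values, design, s.variance_components, seed=seeds[3],
        hybrid_ids=plan.hybrid_ids,
    )
    parent_geno.to_tsv(paths["geno"], paths["map"])
    hybrid_geno.to_tsv(paths["hyb"])
    plots.to_csv(paths["plots"], index=False)
    truth.to_tsv(paths["qtl"], paths["vc"])
    state.update(
        parent_geno=parent_geno, hybrid_geno=hybrid_geno, plots=plots,
        parents=parents, plan=plan, truth=truth,
    )
    return list(paths.values())


def _stage_qc(cfg: RunConfig, out: Path, state: dict, load_only: bool):
    paths = [out / "parent_genotypes_qc.tsv", out / "qc_report.tsv"]
    if load_only:
        state["parent_geno_qc"] = sim.GenotypeMatrix.from_tsv(paths[0], out / "marker_map.tsv")
        return paths
    q = cfg.qc
    filtered, report = mk.qc_filter(
        state["parent_geno"], q.max_missing, q.max_het, q.min_maf
    )
    filtered.to_tsv(paths[0])
    report.to_frame().rename_axis("rule").to_csv(paths[1], sep="\t")
    state["parent_geno_qc"] = filtered
    return paths


def _stage_pheno(cfg: RunConfig, out: Path, state: dict, load_only: bool):
    paths = {
        "stage1": out / "entry_means.tsv",
        "blues": out / "blues.tsv",
        "vc": out / "variance_components.tsv",
        "het": out / "heterosis.tsv",
    }
    if load_only:
        state["blues"] = pd.read_csv(paths["blues"], sep="\t", index_col=0)["blue"]
        state["stage1"] = pd.read_csv(paths["stage1"], sep="\t")
        state["vc_variances"] = (
            pd.read_csv(paths["vc"], sep="\t", index_col=0)["sigma2"].dropna().to_dict()
        )
    else:
        blues, stage1 = ph.two_stage_blues(state["plots"])
        vc = ph.variance_components_one_step(
            state["plots"],
            line_ids=list(state["parents"].all_ids),
            hybrid_ids=state["plan"].hybrid_ids,
        )
        het = ph.mid_parent_stats(blues, state["plan"])
        stage1.to_csv(paths["stage1"], sep="\t", index=False)
        blues.rename_axis("genotype").to_frame().to_csv(paths["blues"], sep="\t")
        vc.to_tsv(paths["vc"])
        het.to_csv(paths["het"], sep="\t")
        state.update(blues=blues, stage1=stage1, vc_variances=vc.variances)
    h2 = ph.heritability(
        state["vc_variances"], cfg.simulation.environments, cfg.simulation.replications
    )
    state["h2"] = max(h2.entry_mean, 1e-3)
    return list(paths.values())


def _stage_gwas(cfg: RunConfig, out: Path, state: dict, load_only: bool):
    path = out / "gwas_results.tsv"
    if load_only:
        state["gwas"] = pd.read_csv(path, sep="\t")
        return [path]
    markers_qc = state["parent_geno_qc"].marker_ids
    parent_geno = state["parent_geno_qc"]
    hybrid_geno = state["hybrid_geno"].subset(markers=markers_qc)
    both = parent_geno.concat(hybrid_geno)
    dm = mk.code_design_matrices(both)
    K = mk.kinship(dm)
    means = state["stage1"][state["stage1"]["genotype"].isin(both.individual_ids)]
    res = gw.MixedGwas(means, both, K).fit()
    res.to_tsv(path, alpha=cfg.models.gwas_alpha)
    state["gwas_res"] = res
    state["gwas"] = res.table
    state["geno_all"] = both
    state["dm_all"] = dm
    return [path]


def _ensure_geno_all(state: dict) -> None:
    if "geno_all" not in state:
        markers_qc = state["parent_geno_qc"].marker_ids
        both = state["parent_geno_qc"].concat(
            state["hybrid_geno"].subset(markers=markers_qc)
        )
        state["geno_all"] = both
        state["dm_all"] = mk.code_design_matrices(both)


def _stage_predict(cfg: RunConfig, out: Path, state: dict, load_only: bool):
    path = out / "marker_effects.tsv"
    if load_only:
        return [path]
    _ensure_geno_all(state)
    hyb_ids = [h for h in state["plan"].hybrid_ids if h in state["blues"].index]
    dm_hyb = state["dm_all"].rows(hyb_ids)
    y = state["blues"].loc[hyb_ids]
    ca = ph.combining_ability_variances(state["blues"], state["plan"])
    s2e = state["vc_variances"]["error"]
    lam_a, lam_d = gp.shrinkage_params(
        s2e, max(ca["gca"], 1e-8), max(ca["sca"], 1e-8),
        cfg.simulation.environments, dm_hyb.m,
    )
    eff = gp.RRBlup(y, dm_hyb).fit(lam_a, lam_d)
    eff.to_tsv(path)
    state["effects"] = eff
    state["lambdas"] = (lam_a, lam_d)
    return [path]


def _stage_cv(cfg: RunConfig, out: Path, state: dict, load_only: bool):
    path = out / "cv_accuracies.tsv"
    if load_only:
        return [path]
    _ensure_geno_all(state)
    blues = state["blues"]
    plan = state["plan"]
    par_ids = [p for p in state["parents"].all_ids if p in blues.index]
    data = cv.HybridData(
        parents=state["parents"],
        plan=plan,
        parent_geno=state["parent_geno_qc"],
        hybrid_geno=state["geno_all"].subset(individuals=plan.hybrid_ids),
        parent_blues=blues.loc[par_ids],
        hybrid_blues=blues.loc[plan.hybrid_ids],
        h2=max(min(state["h2"], 1.0), 1e-3),
        n_env=cfg.simulation.environments,
        sigma2_mean_error=state["vc_variances"]["error"]
        / (cfg.simulation.environments * cfg.simulation.replications),
    )
    if "lambdas" in state:
        data._lambdas = state["lambdas"]
    frames = []
    for model in cfg.cv.models:
        res = cv.run_cv(
            data, model, n_runs=cfg.cv.n_runs, seed=cfg.seed,
            scheme_kwargs={
                "n_f_est": cfg.cv.n_f_est,
                "n_m_est": cfg.cv.n_m_est,
                "n_hyb_est": cfg.cv.n_hyb_est,
                "best_effort": True,
            },
        )
        frames.append(res.table)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "pheno": _stage_pheno,
    "gwas": _stage_gwas,
    "predict": _stage_predict,
    "cv": _stage_cv,
}
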