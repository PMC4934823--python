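"""Synthetic factorial hybrid populations with known ground truth.

This module emulates the data structure of a hybrid breeding experiment in a
selfing crop: a panel of fully inbred parental lines genotyped with a dense
SNP array, F1 hybrids produced in an incomplete female x male factorial whose
marker profiles are deduced from the parents, a sparse additive + dominance
QTL architecture, and multi-environment field trials laid out as partially
replicated designs with common check genotypes.

Every stochastic operation takes an explicit integer seed and is reproducible
bit for bit.  The generative truth (QTL positions and effects, true genetic
values, true variance components) is returned alongside the data so that
downstream estimators can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParentSet",
    "CrossingPlan",
    "GenotypeMatrix",
    "TrialDesign",
    "SimTruth",
    "PLOT_COLUMNS",
    "simulate_parents",
    "make_factorial",
    "derive_hybrid_genotypes",
    "simulate_genetic_values",
    "simulate_trials",
    "add_ld_proxy",
    "hybrid_id",
]

#: column schema for long-format plot records
PLOT_COLUMNS = (
    "genotype",
    "environment",
    "trial",
    "replication",
    "block",
    "trait",
    "value",
)


def hybrid_id(female: str, male: str) -> str:
    """Canonical identifier of the F1 of ``female`` x ``male``."""
    return f"{female}x{male}"


@dataclass(frozen=True)
class ParentSet:
    """Female and male parental line identifiers of a factorial design."""

    female_ids: tuple[str, ...]
    male_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        females, males = set(self.female_ids), set(self.male_ids)
        if len(females) != len(self.female_ids) or len(males) != len(self.male_ids):
            raise ValueError("parent ids must be unique within each sex")
        if females & males:
            raise ValueError(f"female and male id sets overlap: {sorted(females & males)[:5]}")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.female_ids + self.male_ids

    @property
    def n_female(self) -> int:
        return len(self.female_ids)

    @property
    def n_male(self) -> int:
        return len(self.male_ids)


@dataclass(frozen=True)
class CrossingPlan:
    """Realized crosses of a factorial mating design."""

    crosses: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.crosses)) != len(self.crosses):
            raise ValueError("duplicated crosses in plan")

    def validate_against(self, parents: ParentSet) -> None:
        females, males = set(parents.female_ids), set(parents.male_ids)
        for f, m in self.crosses:
            if f not in females:
                raise KeyError(f"unknown female parent {f!r} in crossing plan")
            if m not in males:
                raise KeyError(f"unknown male parent {m!r} in crossing plan")

    @property
    def hybrid_ids(self) -> list[str]:
        return [hybrid_id(f, m) for f, m in self.crosses]

    def parents_of(self, hybrid: str) -> tuple[str, str]:
        try:
            f, m = hybrid.split("x", 1)
        except ValueError as err:
            raise KeyError(f"not a hybrid id: {hybrid!r}") from err
        return f, m

    def __len__(self) -> int:
        return len(self.crosses)


class GenotypeMatrix:
    """Individuals x markers allele-dosage table with a genetic map.

    Dosages count copies of the arbitrary reference allele: 0 and 2 are the
    two homozygotes, 1 the heterozygote, NaN a missing call.  Inbred lines
    carry only 0/2 (up to a genotyping-error tolerance handled by QC);
    hybrids deduced from inbred parents may be heterozygous.
    """

    def __init__(self, dosages: pd.DataFrame, marker_map: pd.DataFrame):
        if not dosages.columns.equals(marker_map.index):
            if not set(dosages.columns) <= set(marker_map.index):
                raise ValueError("dosage columns and marker map disagree")
            marker_map = marker_map.loc[dosages.columns]
        for col in ("chrom", "pos_cm"):
            if col not in marker_map.columns:
                raise ValueError(f"marker map lacks column {col!r}")
        self.dosages = dosages.astype(float)
        self.map = marker_map

    # -- basic introspection ------------------------------------------------
    @property
    def individual_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def values(self) -> np.ndarray:
        return self.dosages.to_numpy()

    def subset(self, individuals: Sequence[str] | None = None,
               markers: Sequence[str] | None = None) -> "GenotypeMatrix":
        d = self.dosages
        if individuals is not None:
            d = d.loc[list(individuals)]
        if markers is not None:
            d = d[list(markers)]
        return GenotypeMatrix(d, self.map.loc[d.columns])

    def concat(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.marker_ids != other.marker_ids:
            raise ValueError("marker panels differ; cannot concatenate")
        return GenotypeMatrix(pd.concat([self.dosages, other.dosages]), self.map)

    def allele_freq(self) -> pd.Series:
        """Frequency of the reference allele per marker (non-missing calls)."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def minor_allele_freq(self) -> pd.Series:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- IO -----------------------------------------------------------------
    def to_tsv(self, path, map_path=None) -> None:
        out = self.dosages.copy()
        out.index.name = "individual"
        out.to_csv(path, sep="\t", na_rep="NA")
        if map_path is not None:
            m = self.map.copy()
            m.index.name = "marker"
            m.to_csv(map_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, map_path=None) -> "GenotypeMatrix":
        d = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        d.index.name = None
        if map_path is not None:
            m = pd.read_csv(map_path, sep="\t", index_col=0)
            m.index.name = None
        else:
            # fallback map: single pseudo-chromosome, unit spacing
            m = pd.DataFrame(
                {"chrom": "un", "pos_cm": np.arange(d.shape[1], dtype=float)},
                index=d.columns,
            )
        return cls(d, m)

    def to_vcf(self, path) -> None:
        """Export as a minimal diploid VCF (GT only, chromosome + cM as POS)."""
        dos = self.dosages
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in pd.unique(self.map["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(dos.index) + "\n")
            for j, mk in enumerate(dos.columns):
                chrom = self.map.at[mk, "chrom"]
                # cM positions mapped to integer bp-like coordinates (x 1e4)
                pos = int(round(float(self.map.at[mk, "pos_cm"]) * 10_000)) + 1
                calls = [gt_map.get(v, "./.") for v in dos.iloc[:, j]]
                fh.write(f"{chrom}\t{pos}\t{mk}\tA\tB\t.\tPASS\t.\tGT\t")
                fh.write("\t".join(calls) + "\n")


@dataclass(frozen=True)
class TrialDesign:
    """Partially replicated multi-environment trial layout.

    Each environment holds ``trials_per_env`` adjacent trials linked by
    ``n_checks`` common check genotypes; within a trial, lines and checks are
    grown in both replications while only ``replicated_hybrid_fraction`` of
    the hybrids is; plots are grouped into incomplete blocks of
    ``block_size`` within each replication.
    """

    environments: int = 6
    trials_per_env: int = 3
    replications: int = 2
    block_size: int = 20
    replicated_hybrid_fraction: float = 0.29
    n_checks: int = 10

    def __post_init__(self) -> None:
        for name in ("environments", "trials_per_env", "replications", "block_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.replicated_hybrid_fraction <= 1.0:
            raise ValueError("replicated_hybrid_fraction must be in [0, 1]")
        if self.n_checks < 0:
            raise ValueError("n_checks must be >= 0")


@dataclass
class SimTruth:
    """Generative ground truth of a simulated data set."""

    qtl_marker_ids: list[str]
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    true_genetic_values: pd.Series
    true_variance_components: dict[str, float] = field(default_factory=dict)

    def qtl_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.qtl_marker_ids,
                "additive": self.additive_effects,
                "dominance": self.dominance_effects,
            }
        ).set_index("marker")

    def to_tsv(self, qtl_path, variance_path) -> None:
        self.qtl_table().to_csv(qtl_path, sep="\t")
        pd.Series(self.true_variance_components, name="sigma2").rename_axis(
            "component"
        ).to_csv(variance_path, sep="\t")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_parents(
    n_female: int = 120,
    n_male: int = 15,
    n_markers: int = 17_300,
    n_chromosomes: int = 21,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
) -> tuple[GenotypeMatrix, ParentSet]:
    """Simulate a post-QC inbred parental panel in linkage equilibrium.

    Per-marker reference-allele frequencies are drawn uniform on
    ``[maf_low, maf_high]`` (mirroring a 5% minor-allele-frequency QC floor),
    and each inbred line carries dosage 2 with that probability, else 0.
    Markers are assigned uniform cM positions on ``n_chromosomes``
    equally sized chromosomes of 150 cM.
    """
    if n_female < 1 or n_male < 1:
        raise ValueError("need at least one parent of each sex")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if maf_low < 0.05:
        raise ValueError("maf_low below the 0.05 QC floor")
    if n_markers < n_chromosomes:
        raise ValueError("fewer markers than chromosomes")

    rng = np.random.default_rng(seed)
    n = n_female + n_male
    p = rng.uniform(maf_low, maf_high, size=n_markers)
    # count-based columns keep every realized frequency inside the target
    # band (a Bernoulli draw would scatter small-panel frequencies below the
    # QC floor); carriers are a random subset of lines per marker
    counts = np.clip(
        np.round(p * n).astype(int),
        int(np.ceil(maf_low * n)),
        int(np.floor(maf_high * n)) if maf_high < 0.5 else n // 2,
    )
    dosages = np.zeros((n, n_markers))
    u = rng.random((n, n_markers))
    # the `counts[j]` smallest u-values in column j become carriers
    order = np.argsort(u, axis=0)
    col = np.arange(n_markers)
    for rank in range(counts.max()):
        rows = order[rank, :]
        active = rank < counts
        dosages[rows[active], col[active]] = 2.0

    female_ids = tuple(f"F{i + 1:03d}" for i in range(n_female))
    male_ids = tuple(f"M{i + 1:03d}" for i in range(n_male))
    marker_ids = [f"snp{j + 1:05d}" for j in range(n_markers)]

    chrom_of = np.sort(rng.integers(0, n_chromosomes, size=n_markers))
    # guarantee every chromosome gets at least one marker
    chrom_of[:n_chromosomes] = np.arange(n_chromosomes)
    chrom_of = np.sort(chrom_of)
    pos = rng.uniform(0.0, 150.0, size=n_markers)
    map_df = pd.DataFrame(
        {"chrom": [f"chr{c + 1}" for c in chrom_of], "pos_cm": pos}, index=marker_ids
    )
    # sort positions within chromosome, keeping marker order stable per chrom
    map_df["pos_cm"] = (
        map_df.groupby("chrom", sort=False)["pos_cm"].transform(lambda s: np.sort(s.values))
    )

    geno = GenotypeMatrix(
        pd.DataFrame(dosages, index=list(female_ids + male_ids), columns=marker_ids),
        map_df,
    )
    return geno, ParentSet(female_ids, male_ids)


def make_factorial(
    parents: ParentSet, n_hybrids: int | str = "full", seed: int = 0
) -> CrossingPlan:
    """All female x male pairs, or a uniform random subset without replacement."""
    full = [(f, m) for f in parents.female_ids for m in parents.male_ids]
    if n_hybrids == "full":
        return CrossingPlan(tuple(full))
    n_hybrids = int(n_hybrids)
    if n_hybrids > len(full):
        raise ValueError(
            f"requested {n_hybrids} hybrids but only {len(full)} crosses possible"
        )
    if n_hybrids < 0:
        raise ValueError("n_hybrids must be >= 0")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(full), size=n_hybrids, replace=False)
    return CrossingPlan(tuple(full[i] for i in sorted(idx)))


def derive_hybrid_genotypes(
    parent_geno: GenotypeMatrix, plan: CrossingPlan
) -> GenotypeMatrix:
    """Deduce F1 marker profiles from the parental fingerprints.

    At every marker the hybrid dosage is the mean of the two (inbred)
    parental dosages; a missing parental call propagates to the hybrid.
    """
    dos = parent_geno.dosages
    missing = [
        pid
        for pair in plan.crosses
        for pid in pair
        if pid not in dos.index
    ]
    if missing:
        raise KeyError(f"crossing plan references ungenotyped parents: {sorted(set(missing))[:5]}")
    females = [f for f, _ in plan.crosses]
    males = [m for _, m in plan.crosses]
    hyb = (dos.loc[females].to_numpy() + dos.loc[males].to_numpy()) / 2.0
    out = pd.DataFrame(hyb, index=plan.hybrid_ids, columns=dos.columns)
    return GenotypeMatrix(out, parent_geno.map)


def simulate_genetic_values(
    geno: GenotypeMatrix,
    n_qtl: int = 100,
    additive_sd: float = 1.0,
    dominance_sd: float = 0.0,
    large_qtl: tuple[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.Series, SimTruth]:
    """Draw a sparse QTL architecture and compute true genetic values.

    ``g_i = sum_q a_q z_A(i, q) + d_q z_D(i, q)`` with homozygotes coded
    -1/+1 and heterozygotes 0 on the additive scale, heterozygotes 1 on the
    dominance scale.  Effects are Normal(0, sd^2); ``large_qtl`` optionally
    injects one marker with a fixed additive effect (a monogenic or
    major-QTL scenario).
    """
    if n_qtl > geno.n_markers:
        raise ValueError("n_qtl exceeds number of markers")
    if n_qtl < 0:
        raise ValueError("n_qtl must be >= 0")
    rng = np.random.default_rng(seed)
    qtl_idx = np.sort(rng.choice(geno.n_markers, size=n_qtl, replace=False))
    qtl_ids = [geno.marker_ids[i] for i in qtl_idx]
    a = rng.normal(0.0, additive_sd, size=n_qtl)
    d = rng.normal(0.0, dominance_sd, size=n_qtl) if dominance_sd > 0 else np.zeros(n_qtl)

    if large_qtl is not None:
        marker, effect = large_qtl
        if marker not in geno.dosages.columns:
            raise KeyError(f"large_qtl marker {marker!r} not in panel")
        if marker not in qtl_ids:
            qtl_ids.append(marker)
            a = np.append(a, effect)
            d = np.append(d, 0.0)
        else:
            a[qtl_ids.index(marker)] = effect

    dos = geno.dosages[qtl_ids].to_numpy()
    z_a = dos - 1.0
    z_d = (dos == 1.0).astype(float)
    g = z_a @ a + z_d @ d
    values = pd.Series(g, index=geno.individual_ids, name="genetic_value")
    truth = SimTruth(
        qtl_marker_ids=list(qtl_ids),
        additive_effects=a,
        dominance_effects=d,
        true_genetic_values=values,
    )
    return values, truth


def simulate_trials(
    true_values: pd.Series,
    design: TrialDesign,
    variance_components: dict[str, float],
    trait_name: str = "trait",
    seed: int = 0,
    mu: float = 0.0,
    hybrid_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate plot-level phenotypes under a partially replicated layout.

    ``value = mu + l + t + r + b + g + (g x l) + e`` with every random term
    iid Normal(0, its component).  Recognised variance component keys:
    ``environment, trial, replication, block, gxe, error`` (absent keys are
    treated as 0).  All genotypes are split randomly over the trials of each
    environment; lines/checks plus a ``replicated_hybrid_fraction`` of the
    hybrids appear in both replications, the remaining hybrids in one.

    Returns a long-format DataFrame with columns :data:`PLOT_COLUMNS`.
    """
    for k, v in variance_components.items():
        if v < 0:
            raise ValueError(f"negative variance component {k!r}")
    sd = {
        k: float(np.sqrt(variance_components.get(k, 0.0)))
        for k in ("environment", "trial", "replication", "block", "gxe", "error")
    }
    rng = np.random.default_rng(seed)
    genotypes = list(true_values.index)
    hybrids = set(hybrid_ids) if hybrid_ids is not None else {g for g in genotypes if "x" in g}
    # common checks link the trials: present in every trial, both replications
    checks = [f"chk{i + 1:02d}" for i in range(design.n_checks)]
    check_values = {c: 0.0 for c in checks}

    rows: list[tuple] = []
    drawn: dict[str, list] = {k: [] for k in ("environment", "trial", "replication",
                                             "block", "gxe_lines", "gxe_hybrids", "error")}
    env_of_draw: dict[str, list] = {}
    env_starts: list[tuple[int, int]] = []
    for env_i in range(design.environments):
        env = f"env{env_i + 1}"
        l_eff = rng.normal(0.0, sd["environment"])
        drawn["environment"].append(l_eff)
        env_of_draw.setdefault("trial", []).extend([env_i] * design.trials_per_env)
        env_of_draw.setdefault("replication", []).extend([env_i] * design.replications)
        env_starts.append((len(drawn["trial"]), len(drawn["replication"])))
        gxe = {g: rng.normal(0.0, sd["gxe"]) for g in genotypes + checks}
        for g, v in gxe.items():
            drawn["gxe_hybrids" if g in hybrids else "gxe_lines"].append(v)
        perm = rng.permutation(len(genotypes))
        # replications are complete replicates of the environment, crossed
        # with the adjacent trials; blocks remain nested in trial x rep
        rep_effs = rng.normal(0.0, sd["replication"], size=design.replications)
        drawn["replication"].extend(rep_effs)
        for trial_i in range(design.trials_per_env):
            trial = f"t{trial_i + 1}"
            t_eff = rng.normal(0.0, sd["trial"])
            drawn["trial"].append(t_eff)
            members = [genotypes[k] for k in perm[trial_i::design.trials_per_env]] + checks
            for rep_i in range(design.replications):
                rep = f"r{rep_i + 1}"
                r_eff = rep_effs[rep_i]
                if rep_i == 0 or design.replications == 1:
                    grown = list(members)
                else:
                    hyb_members = [g for g in members if g in hybrids]
                    n_rep = int(round(design.replicated_hybrid_fraction * len(hyb_members)))
                    chosen = set(
                        rng.choice(len(hyb_members), size=n_rep, replace=False)
                    ) if n_rep else set()
                    grown = [g for g in members if g not in hybrids]
                    grown += [g for k, g in enumerate(hyb_members) if k in chosen]
                order = rng.permutation(len(grown))
                n_blocks = max(1, int(np.ceil(len(grown) / design.block_size)))
                b_eff = rng.normal(0.0, sd["block"], size=n_blocks)
                drawn["block"].extend(b_eff)
                for plot_i, gi in enumerate(order):
                    g = grown[gi]
                    blk = plot_i // design.block_size
                    e_eff = rng.normal(0.0, sd["error"])
                    drawn["error"].append(e_eff)
                    g_val = check_values[g] if g in check_values else true_values[g]
                    val = (
                        mu
                        + l_eff
                        + t_eff
                        + r_eff
                        + b_eff[blk]
                        + g_val
                        + gxe[g]
                        + e_eff
                    )
                    rows.append(
                        (g, env, f"{env}_{trial}", f"{env}_{rep}",
                         f"{env}_{trial}_{rep}_b{blk + 1}", trait_name, val)
                    )
    out = pd.DataFrame(rows, columns=list(PLOT_COLUMNS))
    # realized variances of the drawn effects, the parameter-recovery oracle;
    # factors nested in environment are centred within it (their between-
    # environment mean component is not separable from the environment term)
    realized = {}
    for k, v in drawn.items():
        arr = np.asarray(v, dtype=float)
        if k in env_of_draw:
            env_idx = np.asarray(env_of_draw[k])
            groups = np.unique(env_idx)
            ss = sum(
                float(np.sum((arr[env_idx == e] - arr[env_idx == e].mean()) ** 2))
                for e in groups
            )
            dof = len(arr) - len(groups)
            realized[k] = ss / dof if dof > 0 else 0.0
        else:
            realized[k] = float(np.var(arr, ddof=1)) if len(arr) > 1 else 0.0
    # environment-stratum shifts: l_e plus the means of its nested trial and
    # replication draws — the quantity identified at the environment level
    shifts = []
    t_arr = np.asarray(drawn["trial"]); r_arr = np.asarray(drawn["replication"])
    for e, (t0, r0) in enumerate(env_starts):
        t_mean = t_arr[t0:t0 + design.trials_per_env].mean()
        r_mean = r_arr[r0:r0 + design.replications].mean()
        shifts.append(drawn["environment"][e] + t_mean + r_mean)
    realized["environment_stratum"] = (
        float(np.var(shifts, ddof=1)) if len(shifts) > 1 else 0.0
    )
    out.attrs["realized_variances"] = realized
    return out


def add_ld_proxy(
    geno: GenotypeMatrix,
    focal_marker: str,
    n_copies: int = 5,
    flip_rate: float = 0.05,
    seed: int = 0,
) -> GenotypeMatrix:
    """Emulate a local LD block by duplicating a focal marker with noise.

    Each copy repeats the focal column with every dosage flipped to the
    opposite homozygote with probability ``flip_rate`` (heterozygous calls
    are left untouched), and is placed on the same chromosome at a small
    cM offset.  This gives a bundle of markers in strong but imperfect
    LD with the focal one — the situation where a major QTL is tagged by
    several nearby array markers.
    """
    if focal_marker not in geno.dosages.columns:
        raise KeyError(f"focal marker {focal_marker!r} not in panel")
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dos = geno.dosages.copy()
    mmap = geno.map.copy()
    focal = dos[focal_marker].to_numpy()
    chrom = mmap.at[focal_marker, "chrom"]
    pos = float(mmap.at[focal_marker, "pos_cm"])
    insert_at = dos.columns.get_loc(focal_marker) + 1
    for i in range(n_copies):
        copy = focal.copy()
        flip = (rng.random(len(copy)) < flip_rate) & (copy != 1.0)
        copy[flip] = 2.0 - copy[flip]
        name = f"{focal_marker}_ld{i + 1}"
        dos.insert(insert_at + i, name, copy)
        mmap.loc[name] = [chrom, pos + 0.1 * (i + 1)]
    # keep the map aligned with (and sorted like) the dosage columns
    return GenotypeMatrix(dos, mmap.loc[dos.columns])
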