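"""Marker QC, F-infinity design coding, kinship, LD and density subsampling.

The additive/dominance parameterisation follows the F-infinity metric:
homozygotes are coded -1/+1 and heterozygotes 0 on the additive axis, while
the dominance axis indicates heterozygosity (1 for dosage 1, else 0).  Inbred
lines therefore carry an all-zero dominance row, which is what makes the
dominance variance identifiable only through the hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sim import GenotypeMatrix

__all__ = [
    "QCReport",
    "DesignMatrices",
    "KinshipMatrix",
    "qc_filter",
    "impute_mean",
    "code_design_matrices",
    "kinship",
    "ld_r2",
    "equidistant_subsample",
]


@dataclass(frozen=True)
class QCReport:
    """Per-rule removal counts of a marker QC pass.

    A marker is attributed to the *first* rule it fails, in the fixed order
    monomorphic -> missingness -> heterozygosity -> MAF, so the counts always
    partition the removals.
    """

    n_input: int
    n_monomorphic: int
    n_missing: int
    n_het: int
    n_maf: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = self.n_monomorphic + self.n_missing + self.n_het + self.n_maf
        if self.n_input != self.n_retained + removed:
            raise ValueError("QC report counts do not partition the input")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": [
                    self.n_input,
                    self.n_monomorphic,
                    self.n_missing,
                    self.n_het,
                    self.n_maf,
                    self.n_retained,
                ]
            },
            index=["input", "monomorphic", "missing", "heterozygosity", "maf", "retained"],
        )


@dataclass(frozen=True)
class DesignMatrices:
    """Additive (-1/0/+1) and dominance (0/1) design matrices plus ids."""

    Z_A: np.ndarray
    Z_D: np.ndarray
    individual_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.Z_A.shape[0]

    @property
    def m(self) -> int:
        return self.Z_A.shape[1]

    def rows(self, individuals: Sequence[str]) -> "DesignMatrices":
        pos = {g: i for i, g in enumerate(self.individual_ids)}
        try:
            idx = [pos[g] for g in individuals]
        except KeyError as err:
            raise KeyError(f"individual {err.args[0]!r} not in design matrices") from err
        return DesignMatrices(
            self.Z_A[idx], self.Z_D[idx], tuple(individuals), self.marker_ids
        )

    def columns(self, markers: Sequence[str]) -> "DesignMatrices":
        pos = {mk: j for j, mk in enumerate(self.marker_ids)}
        idx = [pos[mk] for mk in markers]
        return DesignMatrices(
            self.Z_A[:, idx], self.Z_D[:, idx], self.individual_ids, tuple(markers)
        )


@dataclass(frozen=True)
class KinshipMatrix:
    """Marker-derived genomic relationship matrix (additive or dominance)."""

    values: np.ndarray
    individual_ids: tuple[str, ...]
    flavor: str

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.individual_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def rows(self, individuals: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.individual_ids)}
        idx = [pos[g] for g in individuals]
        return self.values[np.ix_(idx, idx)]


def qc_filter(
    geno: GenotypeMatrix,
    max_missing: float = 0.05,
    max_het: float = 0.05,
    min_maf: float = 0.05,
    inbred_ids: Iterable[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove monomorphic, high-missing, high-heterozygosity and rare markers.

    Heterozygosity is assessed on the inbred individuals only (all
    individuals are taken as inbred when ``inbred_ids`` is None); MAF on the
    non-missing calls of all individuals.  Retained markers keep their
    original order.
    """
    for name, v in (("max_missing", max_missing), ("max_het", max_het), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if geno.n_individuals == 0 or geno.n_markers == 0:
        raise ValueError("empty genotype matrix")

    d = geno.dosages
    inbred = d.loc[list(inbred_ids)] if inbred_ids is not None else d

    n_nonmiss = d.notna().sum(axis=0)
    miss_frac = d.isna().mean(axis=0)
    het_frac = (inbred == 1.0).sum(axis=0) / inbred.notna().sum(axis=0).replace(0, np.nan)
    het_frac = het_frac.fillna(0.0)
    maf = geno.minor_allele_freq()
    mono = (d.nunique(dropna=True) <= 1) | (n_nonmiss == 0)

    fail_mono = mono
    fail_miss = ~fail_mono & (miss_frac > max_missing)
    fail_het = ~fail_mono & ~fail_miss & (het_frac > max_het)
    fail_maf = ~fail_mono & ~fail_miss & ~fail_het & (maf < min_maf)
    keep = ~(fail_mono | fail_miss | fail_het | fail_maf)

    report = QCReport(
        n_input=geno.n_markers,
        n_monomorphic=int(fail_mono.sum()),
        n_missing=int(fail_miss.sum()),
        n_het=int(fail_het.sum()),
        n_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
    )
    kept = [mk for mk, k in zip(d.columns, keep) if k]
    return geno.subset(markers=kept), report


def impute_mean(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the column mean rounded to a legal dosage."""
    d = geno.dosages.copy()
    means = d.mean(axis=0, skipna=True)
    fill = means.round().clip(0, 2)
    return GenotypeMatrix(d.fillna(fill), geno.map)


def code_design_matrices(geno: GenotypeMatrix, impute: bool = False) -> DesignMatrices:
    """Code dosages into F-infinity additive and dominance design matrices."""
    if impute:
        geno = impute_mean(geno)
    dos = geno.values()
    if np.isnan(dos).any():
        bad = [mk for mk, m in zip(geno.marker_ids, np.isnan(dos).any(axis=0)) if m]
        raise ValueError(
            f"missing dosages in {len(bad)} markers (e.g. {bad[:3]}); "
            "impute first or pass impute=True"
        )
    z_a = dos - 1.0
    z_d = (dos == 1.0).astype(float)
    return DesignMatrices(
        z_a, z_d, tuple(geno.individual_ids), tuple(geno.marker_ids)
    )


def kinship(
    dm: DesignMatrices, flavor: str = "additive", normalization: str = "marker_count"
) -> KinshipMatrix:
    """Genomic relationship matrix K = W W' / c.

    ``W`` is the additive or dominance design matrix; the default scaling
    divides by the marker count m, an alternative divides by 2*sum(p(1-p))
    computed from the additive codes (VanRaden-style).
    """
    if dm.m == 0:
        raise ValueError("no markers in design matrices")
    W = dm.Z_A if flavor == "additive" else dm.Z_D
    if flavor not in ("additive", "dominance"):
        raise ValueError("flavor must be 'additive' or 'dominance'")
    if normalization == "marker_count":
        c = float(dm.m)
    elif normalization == "vanraden":
        p = (dm.Z_A.mean(axis=0) + 1.0) / 2.0
        c = float(2.0 * np.sum(p * (1.0 - p)))
        if c == 0:
            raise ValueError("all markers monomorphic; VanRaden scaling undefined")
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    K = (W @ W.T) / c
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, dm.individual_ids, flavor)


def ld_r2(
    geno: GenotypeMatrix, marker_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise squared Pearson correlation of additive codes.

    Monomorphic markers have undefined correlation; their rows/columns are
    NaN (diagonal included).
    """
    markers = list(marker_subset) if marker_subset is not None else geno.marker_ids
    sub = geno.subset(markers=markers)
    X = sub.values() - 1.0
    sd = X.std(axis=0)
    poly = sd > 0
    r2 = np.full((len(markers), len(markers)), np.nan)
    if poly.any():
        r = np.corrcoef(X[:, poly], rowvar=False)
        r = np.atleast_2d(r)
        r2[np.ix_(poly, poly)] = r**2
    return pd.DataFrame(r2, index=markers, columns=markers)


def equidistant_subsample(
    m_total: int, k: int, window: int = 173, seed: int = 0
) -> np.ndarray:
    """Draw k markers from every consecutive window of `window` markers.

    The marker axis is cut into consecutive windows; from each full window k
    indices are drawn uniformly without replacement (a trailing partial
    window contributes min(k, its size)).  Returns the sorted union, so
    k = window returns every index.
    """
    if not 1 <= k <= window:
        raise ValueError("require 1 <= k <= window")
    if m_total < 1:
        raise ValueError("m_total must be >= 1")
    rng = np.random.default_rng(seed)
    picked: list[np.ndarray] = []
    for start in range(0, m_total, window):
        size = min(window, m_total - start)
        take = min(k, size)
        picked.append(start + rng.choice(size, size=take, replace=False))
    return np.sort(np.concatenate(picked))
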