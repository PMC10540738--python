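"""Shared domain types: genotype matrix, trait specifications, MET phenotype
table, and run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # genotype-code sentinel

TRAIT_KINDS = ("replicated_quantitative", "accession_mean_quantitative", "qualitative")


@dataclass
class GenotypeMatrix:
    """Accession x marker genotype codes with a physical marker map.

    Codes: 0 = homozygous reference (AA), 1 = heterozygous (AB),
    2 = homozygous alternate (BB), -1 = missing. ``map`` is a DataFrame
    indexed like ``marker_ids`` with columns chrom, pos, ref, alt; positions
    are 1-based bp and strictly increasing within each chromosome.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray  # int8, shape (n_accessions, n_markers)
    map: pd.DataFrame  # columns: chrom, pos, ref, alt

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.validate()

    def validate(self) -> None:
        n, m = self.codes.shape
        if n != len(self.accession_ids):
            raise ValueError("codes rows != number of accessions")
        if m != len(self.marker_ids):
            raise ValueError("codes columns != number of markers")
        if len(set(self.accession_ids)) != n:
            raise ValueError("duplicate accession ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.codes[bad])}")
        if list(self.map.index) != self.marker_ids:
            raise ValueError("map index must equal marker_ids")
        for col in ("chrom", "pos"):
            if col not in self.map.columns:
                raise ValueError(f"map missing column {col!r}")
        if (self.map["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        for _, grp in self.map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing per chromosome")

    # -- convenience ------------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def dosage(self, impute: bool = False) -> np.ndarray:
        """Float dosage matrix with NaN (or column-mean, if impute) missing."""
        d = self.codes.astype(float)
        d[self.codes == MISSING] = np.nan
        if impute:
            mu = np.nanmean(d, axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            idx = np.where(np.isnan(d))
            d[idx] = mu[idx[1]]
        return d

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker from observed allele counts."""
        d = self.dosage()
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset(
        self,
        accessions: Sequence[str] | np.ndarray | None = None,
        markers: Sequence[str] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        acc_idx = np.arange(self.n_accessions)
        mk_idx = np.arange(self.n_markers)
        if accessions is not None:
            if np.asarray(accessions).dtype == bool:
                acc_idx = np.flatnonzero(accessions)
            else:
                lut = {a: i for i, a in enumerate(self.accession_ids)}
                acc_idx = np.array([lut[a] for a in accessions])
        if markers is not None:
            if np.asarray(markers).dtype == bool:
                mk_idx = np.flatnonzero(markers)
            else:
                lut = {m: i for i, m in enumerate(self.marker_ids)}
                mk_idx = np.array([lut[m] for m in markers])
        return GenotypeMatrix(
            accession_ids=[self.accession_ids[i] for i in acc_idx],
            marker_ids=[self.marker_ids[i] for i in mk_idx],
            codes=self.codes[np.ix_(acc_idx, mk_idx)].copy(),
            map=self.map.iloc[mk_idx].copy(),
        )


@dataclass(frozen=True)
class TraitSpec:
    name: str
    kind: str
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "qualitative" and not self.categories:
            raise ValueError("qualitative trait requires categories")


@dataclass
class METTable:
    """Long-format MET phenotype records.

    ``data`` columns: accession, environment, replicate, trait, value.
    Replicated quantitative traits allow up to ``max_replicates`` plants per
    accession x environment cell; accession-mean and qualitative traits have
    exactly one record per cell. Missing cells are allowed (unbalanced).
    """

    data: pd.DataFrame
    trait_specs: dict[str, TraitSpec] = field(default_factory=dict)
    max_replicates: int = 3

    REQUIRED = ("accession", "environment", "replicate", "trait", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"METTable missing columns {missing}")
        self.validate()

    def validate(self) -> None:
        for trait, grp in self.data.groupby("trait", sort=False):
            spec = self.trait_specs.get(str(trait))
            if spec is None:
                continue
            counts = grp.groupby(["accession", "environment"]).size()
            if spec.kind == "replicated_quantitative":
                if (counts > self.max_replicates).any():
                    raise ValueError(
                        f"trait {trait!r}: more than {self.max_replicates} "
                        "replicates in a cell"
                    )
            else:
                if (counts > 1).any():
                    raise ValueError(
                        f"trait {trait!r}: multiple values per accession x environment"
                    )
            if spec.kind == "qualitative":
                vals = set(str(v) for v in grp["value"].dropna())
                extra = vals - set(spec.categories or ())
                if extra:
                    raise ValueError(f"trait {trait!r}: unknown categories {sorted(extra)}")
            else:
                vals = pd.to_numeric(grp["value"], errors="coerce")
                if vals.isna().sum() > grp["value"].isna().sum():
                    raise ValueError(f"trait {trait!r}: non-numeric value")

    def trait(self, name: str) -> pd.DataFrame:
        out = self.data[self.data["trait"] == name].copy()
        if out.empty:
            raise KeyError(f"unknown trait {name!r}")
        spec = self.trait_specs.get(name)
        if spec is None or spec.kind != "qualitative":
            out["value"] = pd.to_numeric(out["value"])
        return out

    def environments(self) -> list[str]:
        return sorted(set(map(str, self.data["environment"])))


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults follow the published analysis."""

    seed: int = 0
    maf_min: float = 0.05
    snp_missing_max: float = 0.25
    ind_missing_max: float = 0.25
    het_max: float = 0.05
    r2_baseline: float = 0.4456
    region_window_bp: int = 2_000_000
    locus_gap_bp: int = 100_000
    contrast_alpha: float = 0.05
    corr_p: float = 0.01
    min_class_n: int = 3
    gwas_alpha: float = 0.05
    dprime_threshold: float = 0.8
    hwe_min_p: float = 0.001
    environments: tuple[str, ...] = ()
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("maf_min", "snp_missing_max", "ind_missing_max", "het_max",
                     "contrast_alpha", "corr_p", "gwas_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.region_window_bp <= 0 or self.locus_gap_bp <= 0:
            raise ValueError("window/gap must be positive")

    def with_updates(self, **kw) -> "RunConfig":
        return replace(self, **kw)
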