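"""Synthetic genotype and MET phenotype generation.

Genotypes are organized in LD blocks: within a block every marker copies one
shared binary allele draw with probability ``s`` and otherwise draws an
independent allele at the same frequency, giving an exact pairwise dosage
correlation of s**2 (so s = target_r2 ** 0.25 hits a requested r-squared).
Phenotypes follow the replicated MET model

    Y_ijk = mu + G_i + sum_q qval_q(code_iq) * mult_qj + E_j + GE_ij + eps_ijk

with independent Normal components, where the per-QTL genotypic value uses
the F2 parametrization: code 0 -> +a, code 2 -> -a, code 1 -> d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metstab.io_cli.types import MISSING, GenotypeMatrix, METTable, TraitSpec

QTI_TYPES = ("none", "magnitude", "conditional_neutral", "antagonistic")
ACTIONS = ("additive", "dominant", "recessive", "overdominant")


@dataclass(frozen=True)
class PlantedQTLSpec:
    """Truth record for one planted QTL."""

    marker_index: int
    trait: str
    a: float
    d: float
    env_multipliers: tuple[float, ...]
    action: str
    qti_type_truth: str

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.qti_type_truth not in QTI_TYPES:
            raise ValueError(f"unknown QTI type {self.qti_type_truth!r}")
        m = np.asarray(self.env_multipliers, dtype=float)
        implied = classify_multipliers(m)
        if implied != self.qti_type_truth:
            raise ValueError(
                f"env_multipliers {tuple(m)} imply {implied!r}, "
                f"not {self.qti_type_truth!r}"
            )

    def genotypic_value(self, codes: np.ndarray) -> np.ndarray:
        """Per-accession genotypic value: 0 -> +a, 2 -> -a, 1 -> d."""
        v = np.zeros(codes.shape, dtype=float)
        v[codes == 0] = self.a
        v[codes == 2] = -self.a
        v[codes == 1] = self.d
        return v


def classify_multipliers(m: np.ndarray, tol: float = 1e-9) -> str:
    """Truth QTI type implied by per-environment effect multipliers."""
    m = np.asarray(m, dtype=float)
    nz = m[np.abs(m) > tol]
    if nz.size and (nz > 0).any() and (nz < 0).any():
        return "antagonistic"
    if (np.abs(m) <= tol).any():
        return "conditional_neutral"
    if np.allclose(m, m[0], atol=tol):
        return "none"
    return "magnitude"


def planted_qtl(marker_index: int, trait: str, a: float, action: str,
                env_multipliers: tuple[float, ...]) -> PlantedQTLSpec:
    """Convenience constructor deriving d and the truth QTI label from the
    declared action and multipliers."""
    d = {"additive": 0.0, "dominant": a, "recessive": -a, "overdominant": 2.0 * a}[action]
    return PlantedQTLSpec(marker_index, trait, a, d, tuple(env_multipliers),
                          action, classify_multipliers(np.asarray(env_multipliers)))


@dataclass
class ScenarioSpec:
    n_accessions: int = 200
    n_snps: int = 3000
    n_chromosomes: int = 12
    block_len_mean: float = 8.0
    block_r2: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_missing_rate: float = 0.02
    het_rate: float = 0.02
    environments: tuple[str, ...] = ("E1", "E2", "E3", "E4")
    replicates: int = 3
    mu: float = 10.0
    sigma2_g: float = 4.0
    sigma2_e: float = 1.0
    sigma2_ge: float = 1.0
    sigma2_eps: float = 1.0
    planted_qtls: list[PlantedQTLSpec] = field(default_factory=list)
    hwe_mode: bool = False  # random-mating genotypes (two gamete draws)
    n_subpopulations: int = 1
    subpop_shift: float = 0.0  # allele-frequency shift between subpopulations
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"infeasible maf_range {self.maf_range}")
        for name in ("sigma2_g", "sigma2_e", "sigma2_ge", "sigma2_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.environments) < 3:
            raise ValueError("at least 3 environments required")
        for q in self.planted_qtls:
            if not 0 <= q.marker_index < self.n_snps:
                raise ValueError(f"QTL marker index {q.marker_index} out of range")
            if len(q.env_multipliers) != len(self.environments):
                raise ValueError("env_multipliers length != number of environments")


def gen_genotypes(scenario: ScenarioSpec) -> GenotypeMatrix:
    """Blockwise-LD genotypes for mostly homozygous (inbred-like) accessions."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n, m = sc.n_accessions, sc.n_snps
    s = float(np.clip(sc.block_r2, 0.0, 1.0)) ** 0.25

    subpop = rng.integers(0, sc.n_subpopulations, size=n) if sc.n_subpopulations > 1 \
        else np.zeros(n, dtype=int)

    codes = np.empty((n, m), dtype=np.int8)
    block_ids = np.empty(m, dtype=int)
    block_counter = 0
    chroms: list[str] = []
    positions = np.empty(m, dtype=int)
    per_chrom = int(np.ceil(m / sc.n_chromosomes))
    j = 0
    chrom_idx = 0
    pos = 0
    chrom_count = 0
    while j < m:
        block_len = min(1 + rng.poisson(max(sc.block_len_mean - 1.0, 0.0)),
                        m - j, per_chrom - chrom_count or per_chrom)
        p = rng.uniform(*sc.maf_range)
        # subpopulation-specific allele frequencies (optional structure):
        # independent per-block shifts keep clusters multidimensional
        if sc.n_subpopulations > 1 and sc.subpop_shift > 0:
            shifts = rng.normal(0.0, sc.subpop_shift, sc.n_subpopulations)
            p_sub = np.clip(p + shifts[subpop], 0.01, 0.99)
        else:
            p_sub = np.full(n, p)
        n_gam = 2 if sc.hwe_mode else 1
        bases = [(rng.random(n) < p_sub).astype(np.int8) for _ in range(n_gam)]
        for _ in range(block_len):
            gametes = []
            for base in bases:
                copy = rng.random(n) < s
                indep = (rng.random(n) < p_sub).astype(np.int8)
                gametes.append(np.where(copy, base, indep))
            if sc.hwe_mode:
                col = (gametes[0] + gametes[1]).astype(np.int8)
            else:
                col = (2 * gametes[0]).astype(np.int8)
                het = rng.random(n) < sc.het_rate
                col[het] = 1
            codes[:, j] = col
            block_ids[j] = block_counter
            pos += int(rng.integers(1_000, 50_000))
            positions[j] = pos
            chroms.append(f"chr{chrom_idx + 1:02d}")
            j += 1
            chrom_count += 1
            if chrom_count >= per_chrom:
                chrom_idx += 1
                chrom_count = 0
                pos = 0
                break
        block_counter += 1

    if sc.snp_missing_rate > 0:
        miss = rng.random((n, m)) < sc.snp_missing_rate
        codes[miss] = MISSING

    marker_ids = [f"S{c}_{p}" for c, p in zip(chroms, positions)]
    mp = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": "A", "alt": "T"}, index=marker_ids
    )
    g = GenotypeMatrix([f"acc{i:04d}" for i in range(n)], marker_ids, codes, mp)
    g.subpopulations = subpop      # type: ignore[attr-defined]
    g.block_ids = block_ids        # type: ignore[attr-defined]
    return g


def _complete_codes(scenario: ScenarioSpec, genotypes: GenotypeMatrix,
                    marker_index: int) -> np.ndarray:
    """Marker codes with missing entries filled from the major allele, so
    planted truth is unaffected by the release-time missingness."""
    col = genotypes.codes[:, marker_index].astype(int)
    obs = col[col != MISSING]
    fill = 0 if obs.size == 0 or (obs == 0).sum() >= (obs == 2).sum() else 2
    col = col.copy()
    col[col == MISSING] = fill
    return col


def gen_met_phenotypes(
    genotypes: GenotypeMatrix,
    scenario: ScenarioSpec,
    trait: str = "trait1",
) -> tuple[METTable, pd.DataFrame]:
    """Replicated MET phenotypes plus the planted-truth table."""
    sc = scenario
    rng = np.random.default_rng(sc.seed + 1)
    n = genotypes.n_accessions
    envs = list(sc.environments)
    e, k = len(envs), sc.replicates

    g_poly = rng.normal(0.0, np.sqrt(sc.sigma2_g), n)
    e_eff = rng.normal(0.0, np.sqrt(sc.sigma2_e), e)
    ge = rng.normal(0.0, np.sqrt(sc.sigma2_ge), (n, e))

    qtl_signal = np.zeros((n, e))
    truth_rows = []
    for q in (x for x in sc.planted_qtls if x.trait == trait):
        codes = _complete_codes(sc, genotypes, q.marker_index)
        gv = q.genotypic_value(codes)
        qtl_signal += gv[:, None] * np.asarray(q.env_multipliers)[None, :]
        truth_rows.append({
            "marker_id": genotypes.marker_ids[q.marker_index],
            "marker_index": q.marker_index,
            "trait": q.trait, "a": q.a, "d": q.d,
            "action": q.action, "qti_type_truth": q.qti_type_truth,
            "env_multipliers": ";".join(f"{m:g}" for m in q.env_multipliers),
        })

    eps = rng.normal(0.0, np.sqrt(sc.sigma2_eps), (n, e, k))
    y = (sc.mu + g_poly[:, None, None] + qtl_signal[:, :, None]
         + e_eff[None, :, None] + ge[:, :, None] + eps)

    recs = {
        "accession": np.repeat(genotypes.accession_ids, e * k),
        "environment": np.tile(np.repeat(envs, k), n),
        "replicate": np.tile(np.arange(1, k + 1), n * e),
        "trait": trait,
        "value": y.ravel(),
    }
    met = METTable(
        data=pd.DataFrame(recs),
        trait_specs={trait: TraitSpec(trait, "replicated_quantitative")},
        max_replicates=k,
    )
    return met, pd.DataFrame(truth_rows)


def gen_qualitative_trait(
    genotypes: GenotypeMatrix,
    scenario: ScenarioSpec,
    trait: str = "qual1",
    categories: tuple[str, ...] = ("low", "high"),
    thresholds: np.ndarray | None = None,
    latent_marker_effects: dict[int, float] | None = None,
) -> METTable:
    """Ordinal per-accession trait from thresholding a latent G + E + eps
    variable (no GE term)."""
    sc = scenario
    rng = np.random.default_rng(sc.seed + 2)
    n = genotypes.n_accessions
    envs = list(sc.environments)
    e = len(envs)
    latent = (rng.normal(0.0, np.sqrt(sc.sigma2_g), n)[:, None]
              + rng.normal(0.0, np.sqrt(sc.sigma2_e), e)[None, :]
              + rng.normal(0.0, np.sqrt(sc.sigma2_eps), (n, e)))
    for idx, eff in (latent_marker_effects or {}).items():
        codes = _complete_codes(sc, genotypes, idx)
        latent += (eff * (codes == 2).astype(float))[:, None]
    if thresholds is None:
        ncat = len(categories)
        qs = np.quantile(latent, np.linspace(0, 1, ncat + 1)[1:-1])
        thresholds = np.atleast_1d(qs)
    cat_idx = np.searchsorted(np.asarray(thresholds), latent)
    recs = {
        "accession": np.repeat(genotypes.accession_ids, e),
        "environment": np.tile(envs, n),
        "replicate": 1,
        "trait": trait,
        "value": np.asarray(categories, dtype=object)[cat_idx.ravel()],
    }
    return METTable(
        data=pd.DataFrame(recs),
        trait_specs={trait: TraitSpec(trait, "qualitative", tuple(categories))},
    )
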