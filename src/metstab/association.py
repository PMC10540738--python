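"""SNP filtering, IBS kinship, single-marker mixed-model association scans on
per-accession responses (trait means, stability indices, GEI effect vectors),
the two-stage GWEIS, and the effective-number-of-tests threshold.

The scan follows the exact single-marker REML approach: the kinship matrix is
eigendecomposed once, and for every marker the genetic-to-residual variance
ratio is re-estimated by maximizing the rotated REML likelihood, followed by a
GLS effect estimate and t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from metstab.io_cli.types import MISSING, GenotypeMatrix

__all__ = [
    "FilterReport",
    "KinshipMatrix",
    "filter_snps",
    "kinship",
    "lmm_scan",
    "gweis_two_stage",
    "stage1_effects",
    "significance_threshold",
    "summarize_mta_classes",
]


@dataclass
class FilterReport:
    n_accessions_in: int
    n_markers_in: int
    accessions_removed_missing: int = 0
    markers_removed_missing: int = 0
    markers_removed_maf: int = 0
    markers_removed_het: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_snps(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    snp_missing_max: float = 0.25,
    ind_missing_max: float = 0.25,
    het_max: float = 0.05,
    literal_homozygous_filter: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the association quality filters in order: accessions by
    missingness, markers by missingness, markers by MAF, then markers by
    heterozygous fraction (or, literally, homozygous fraction)."""
    rep = FilterReport(g.n_accessions, g.n_markers)
    miss = g.codes == MISSING

    acc_keep = miss.mean(axis=1) <= ind_missing_max
    rep.accessions_removed_missing = int((~acc_keep).sum())
    g = g.subset(accessions=acc_keep)

    miss = g.codes == MISSING
    mk_keep = miss.mean(axis=0) <= snp_missing_max
    rep.markers_removed_missing = int((~mk_keep).sum())
    g = g.subset(markers=mk_keep)

    maf = g.maf()
    mk_keep = ~(maf < maf_min)  # boundary MAF == maf_min is retained
    mk_keep &= ~np.isnan(maf)
    rep.markers_removed_maf = int((~mk_keep).sum())
    g = g.subset(markers=mk_keep)

    obs = g.codes != MISSING
    with np.errstate(invalid="ignore"):
        het_frac = (g.codes == 1).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
        hom_frac = ((g.codes == 0) | (g.codes == 2)).sum(axis=0) / np.maximum(
            obs.sum(axis=0), 1)
    frac = hom_frac if literal_homozygous_filter else het_frac
    mk_keep = frac < het_max
    rep.markers_removed_het = int((~mk_keep).sum())
    g = g.subset(markers=mk_keep)

    if g.n_markers == 0 or g.n_accessions == 0:
        raise ValueError("all markers or accessions removed by filters")
    return g, rep


@dataclass
class KinshipMatrix:
    accession_ids: list[str]
    values: np.ndarray
    variant: str  # 'ibs_emma' | 'centered_ibs'

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accession_ids,
                            columns=self.accession_ids)


def kinship(g: GenotypeMatrix, variant: str = "ibs_emma") -> KinshipMatrix:
    """Identity-by-state kinship.

    ibs_emma: K_ij = mean over shared non-missing markers of
    1 - |g_i - g_j| / 2 (additive treatment of heterozygotes).
    centered_ibs: VanRaden-style centered dosage cross-product used for
    structure/MDS summaries.
    """
    d = g.dosage()
    obs = ~np.isnan(d)
    if variant == "ibs_emma":
        x = np.nan_to_num(d, nan=0.0)
        o = obs.astype(float)
        # sum over shared markers of |gi - gj| via the identity
        # |a-b| = a + b - 2*min(a,b); computed per code level instead
        n_shared = o @ o.T
        if (n_shared == 0).any():
            raise ValueError("accession pair with zero shared markers")
        diff = np.zeros((g.n_accessions, g.n_accessions))
        for a in (0.0, 1.0, 2.0):
            for b in (0.0, 1.0, 2.0):
                if a >= b:
                    continue
                ia = ((d == a) & obs).astype(float)
                ib = ((d == b) & obs).astype(float)
                diff += (b - a) * (ia @ ib.T + ib @ ia.T)
        K = 1.0 - diff / (2.0 * n_shared)
    elif variant == "centered_ibs":
        p = np.nanmean(d, axis=0) / 2.0
        z = np.where(obs, d - 2.0 * p, 0.0)
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0:
            raise ValueError("no polymorphic markers")
        K = (z @ z.T) / denom
    else:
        raise ValueError(f"unknown kinship variant {variant!r}")
    K = (K + K.T) / 2.0
    return KinshipMatrix(list(g.accession_ids), K, variant)


# ---------------------------------------------------------------------------
# single-marker mixed-model scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def _reml_delta_neg2(log_delta: float, lam: np.ndarray, Ux: np.ndarray,
                     Uy: np.ndarray) -> float:
    """-2 REML log-likelihood in the rotated basis, profiled over the scale;
    delta = sigma2_g / sigma2_e so marginal variance ∝ (delta*lam + 1)."""
    delta = np.exp(log_delta)
    h = delta * lam + 1.0
    n, p = Ux.shape
    Xw = Ux / h[:, None]
    XtHX = Ux.T @ Xw
    XtHy = Xw.T @ Uy
    beta = np.linalg.solve(XtHX, XtHy)
    r = Uy - Ux @ beta
    rss = r @ (r / h)
    df = n - p
    s2 = max(rss / df, np.finfo(float).tiny)
    _, ld = np.linalg.slogdet(XtHX)
    return df * np.log(s2) + np.log(h).sum() + ld


def _gls_test(delta: float, lam: np.ndarray, Ux: np.ndarray, Uy: np.ndarray):
    h = delta * lam + 1.0
    Xw = Ux / h[:, None]
    XtHX = Ux.T @ Xw
    XtHy = Xw.T @ Uy
    cov_unscaled = np.linalg.inv(XtHX)
    beta = cov_unscaled @ XtHy
    r = Uy - Ux @ beta
    df = len(Uy) - Ux.shape[1]
    s2 = (r @ (r / h)) / df
    se = np.sqrt(max(s2 * cov_unscaled[-1, -1], 0.0))
    if se == 0:
        return beta[-1], se, 1.0
    t = beta[-1] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(beta[-1]), float(se), float(min(max(p, np.finfo(float).tiny), 1.0))


def lmm_scan(
    y: pd.Series,
    g: GenotypeMatrix,
    K: KinshipMatrix,
    trait: str = "trait",
    analysis: str = "mean",
    exact_per_marker: bool = True,
    min_n: int = 10,
) -> ScanResult:
    """Per-marker mixed-model association of a per-accession response.

    Missing marker dosages are mean-imputed so the kinship eigendecomposition
    is shared; the per-marker variance ratio is re-estimated exactly unless
    ``exact_per_marker`` is False (null-model-once approximation).
    """
    common = [a for a in g.accession_ids if a in y.index and not pd.isna(y[a])]
    if len(common) < min_n:
        raise ValueError("too few accessions with phenotype")
    gsub = g.subset(accessions=common)
    yv = y.loc[common].to_numpy(dtype=float)
    idx = [K.accession_ids.index(a) for a in common]
    Kv = K.values[np.ix_(idx, idx)]

    warnings: list[str] = []
    lam, U = np.linalg.eigh(Kv)
    lam = np.clip(lam, 0.0, None)
    Uy = U.T @ yv
    n = len(yv)
    ones = U.T @ np.ones((n, 1))

    if np.std(yv) == 0:
        warnings.append("constant response: all p-values set to 1")

    d = gsub.dosage()
    n_obs = (~np.isnan(d)).sum(axis=0)
    mu = np.nanmean(d, axis=0)
    dd = np.where(np.isnan(d), mu[None, :], d)

    def fit_delta(Ux):
        res = optimize.minimize_scalar(
            _reml_delta_neg2, bounds=(-12.0, 12.0), args=(lam, Ux, Uy),
            method="bounded", options={"xatol": 1e-7},
        )
        return np.exp(res.x)

    delta_null = fit_delta(ones)
    rows = []
    maf = gsub.maf()
    for j, mid in enumerate(gsub.marker_ids):
        x = dd[:, j]
        if np.std(x) == 0:
            rows.append((mid, trait, analysis, np.nan, np.nan, np.nan,
                         maf[j], int(n_obs[j]), "monomorphic"))
            continue
        Ux = np.column_stack([ones, U.T @ x])
        if np.std(yv) == 0:
            beta, se, p = 0.0, np.nan, 1.0
        else:
            delta = fit_delta(Ux) if exact_per_marker else delta_null
            beta, se, p = _gls_test(delta, lam, Ux, Uy)
        rows.append((mid, trait, analysis, beta, se, p, maf[j],
                     int(n_obs[j]), ""))
    table = pd.DataFrame(
        rows, columns=["marker_id", "trait", "analysis", "beta", "se", "p",
                       "maf", "n", "note"],
    )
    table = table.merge(
        gsub.map.reset_index(names="marker_id")[["marker_id", "chrom", "pos"]],
        on="marker_id", how="left",
    )
    return ScanResult(table=table, warnings=warnings)


# ---------------------------------------------------------------------------
# two-stage GWEIS
# ---------------------------------------------------------------------------


def stage1_effects(met, trait: str) -> tuple[pd.Series, pd.DataFrame]:
    """Least-squares genotype means and per-environment GEI effects from the
    accession x environment cell-mean model Y_ij = mu + G_i + E_j + (GE)_ij."""
    df = met.trait(trait).dropna(subset=["value"])
    cell = df.groupby(["accession", "environment"])["value"].mean().unstack()
    dropped = cell.index[cell.isna().all(axis=1)]
    cell = cell.drop(index=dropped)
    grand = np.nanmean(cell.to_numpy())
    acc_eff = cell.mean(axis=1, skipna=True) - grand
    env_eff = cell.mean(axis=0, skipna=True) - grand
    expected = grand + acc_eff.to_numpy()[:, None] + env_eff.to_numpy()[None, :]
    ge = cell - expected
    means = cell.mean(axis=1, skipna=True)
    means.name = trait
    return means, ge


def gweis_two_stage(
    met,
    trait: str,
    g: GenotypeMatrix,
    K: KinshipMatrix,
    exact_per_marker: bool = True,
) -> dict[str, ScanResult]:
    """Stage 1: fixed-effects decomposition of cell means into genotype means
    and per-environment GEI effects. Stage 2: mixed-model scan of the mean
    vector (meanQTL candidates) and each environment's GEI vector (QTI
    candidates, tagged ``gei:<env>``)."""
    means, ge = stage1_effects(met, trait)
    if ge.shape[1] < 2:
        raise ValueError("GWEIS requires >= 2 environments")
    out: dict[str, ScanResult] = {}
    out["mean"] = lmm_scan(means, g, K, trait=trait, analysis="mean",
                           exact_per_marker=exact_per_marker)
    for env in ge.columns:
        vec = ge[env].dropna()
        out[f"gei:{env}"] = lmm_scan(vec, g, K, trait=trait,
                                     analysis=f"gei:{env}",
                                     exact_per_marker=exact_per_marker)
    return out


# ---------------------------------------------------------------------------
# multiple-testing threshold
# ---------------------------------------------------------------------------


def li_ji_meff(eigenvalues: np.ndarray) -> float:
    """Effective number of tests from correlation-matrix eigenvalues:
    f(lambda) = I(lambda >= 1) + (lambda - floor(lambda))."""
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    lam = np.round(lam, 10)  # guard floor() against eigensolver jitter
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def significance_threshold(
    g: GenotypeMatrix, alpha: float = 0.05, method: str = "sidak"
) -> tuple[float, float]:
    """Genome-wide p-value cutoff from the Li-Ji effective number of
    independent tests, summed over chromosomes."""
    d = g.dosage(impute=True)
    meff = 0.0
    for chrom in pd.unique(g.map["chrom"]):
        cols = np.flatnonzero((g.map["chrom"] == chrom).to_numpy())
        X = d[:, cols]
        sd = X.std(axis=0)
        X = X[:, sd > 0]
        if X.shape[1] == 0:
            continue
        if X.shape[1] == 1:
            meff += 1.0
            continue
        R = np.corrcoef(X, rowvar=False)
        lam = np.linalg.eigvalsh(R)
        meff += li_ji_meff(lam)
    meff = max(meff, 1.0)
    if method == "sidak":
        cutoff = 1.0 - (1.0 - alpha) ** (1.0 / meff)
    elif method == "bonferroni":
        cutoff = alpha / meff
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(cutoff), float(meff)


def summarize_mta_classes(mtas: pd.DataFrame) -> pd.Series:
    """Count significant marker-trait associations per analysis class
    (mean / stability / gei:*) plus the total."""
    cls = mtas["analysis"].map(
        lambda a: "gei" if str(a).startswith("gei") else str(a))
    counts = cls.value_counts()
    counts["total"] = int(counts.sum())
    return counts
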