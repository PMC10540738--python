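"""Stability indices: WAASB from the SVD of the BLUPge matrix, and the
GGE average-environment-coordination (AEC) ordinate projection; plus the
mean-vs-stability correlation screen."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "WAASBResult",
    "GGEDecomposition",
    "waasb",
    "gge_aec_stability",
    "correlate_mean_stability",
    "scale_unit_variance",
]


@dataclass
class WAASBResult:
    genotypes: list[str]
    waasb: pd.Series            # per genotype, >= 0; lowest = most stable
    ipca: np.ndarray            # genotype x retained-axis scores (U * Lambda)
    explained: np.ndarray       # EP_k, proportions summing to 1

    def ranking(self) -> pd.Series:
        return self.waasb.sort_values()


def waasb(blup_ge: pd.DataFrame) -> WAASBResult:
    """Weighted average of absolute IPCA scores of the genotype-by-environment
    BLUP matrix; all p = min(g-1, e-1) axes are retained."""
    if blup_ge.shape[1] < 3:
        raise ValueError("WAASB requires at least 3 environments")
    M = blup_ge.to_numpy(dtype=float)
    g, e = M.shape
    p = min(g - 1, e - 1)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = s[:p]
    scores = U[:, :p] * s
    total = (s**2).sum()
    if total <= 0:
        ep = np.zeros(p)
        w = np.zeros(g)
    else:
        ep = s**2 / total
        w = np.abs(scores) @ ep / ep.sum()
    return WAASBResult(
        genotypes=list(blup_ge.index),
        waasb=pd.Series(w, index=blup_ge.index, name="WAASB"),
        ipca=scores,
        explained=ep,
    )


@dataclass
class GGEDecomposition:
    genotypes: list[str]
    environments: list[str]
    centered: np.ndarray         # environment-centered mean matrix
    singular_values: np.ndarray
    genotype_scores: np.ndarray  # xi * lambda (genotype-focused), K=2 columns
    env_scores: np.ndarray       # eta (unscaled), K=2 columns
    aec_axis: np.ndarray         # unit vector of the AEC abscissa
    projection: pd.Series        # P_i >= 0 per genotype
    rank_deficient: bool = False
    imputed_cells: int = 0


def gge_aec_stability(means: pd.DataFrame) -> GGEDecomposition:
    """AEC-ordinate projection stability from a genotype x environment trait
    mean table. Missing cells are imputed with the environment mean (flagged);
    the matrix is centered by environment, decomposed by SVD with
    genotype-focused singular value partitioning, and each genotype's 2-D
    score is projected perpendicularly onto the average-environment axis."""
    if means.shape[1] < 3:
        raise ValueError("AEC stability requires at least 3 environments")
    M = means.to_numpy(dtype=float).copy()
    n_imputed = int(np.isnan(M).sum())
    if n_imputed:
        col_mean = np.nanmean(M, axis=0)
        idx = np.where(np.isnan(M))
        M[idx] = col_mean[idx[1]]
    centered = M - M.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    K = 2
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    rank_def = rank < K
    k_use = max(min(K, rank), 1)
    gsc = U[:, :K] * s[:K]          # genotype-focused: U * Lambda
    esc = Vt[:K].T                   # environment scores: V
    # fix axis signs so the average environment has positive PC1 coordinate
    avg_env = esc.mean(axis=0)
    if avg_env[0] < 0:
        gsc[:, 0] *= -1
        esc[:, 0] *= -1
        avg_env = esc.mean(axis=0)
    norm = np.linalg.norm(avg_env[:k_use])
    if norm == 0:
        proj = np.zeros(M.shape[0])
    else:
        axis = np.zeros(K)
        axis[:k_use] = avg_env[:k_use] / norm
        along = gsc[:, :K] @ axis
        perp = gsc[:, :K] - np.outer(along, axis)
        proj = np.linalg.norm(perp, axis=1)
    return GGEDecomposition(
        genotypes=list(means.index),
        environments=list(means.columns),
        centered=centered,
        singular_values=s,
        genotype_scores=gsc,
        env_scores=esc,
        aec_axis=axis if norm else np.zeros(K),
        projection=pd.Series(proj, index=means.index, name="P_AEC"),
        rank_deficient=rank_def,
        imputed_cells=n_imputed,
    )


def correlate_mean_stability(
    summaries: pd.DataFrame, p_threshold: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame, list[int]]:
    """Pairwise Pearson correlations between per-trait mean/BLUPg and
    stability summaries (columns of ``summaries``), masked at the given
    p-value, with a complete-linkage clustering order on 1 - r."""
    cols = list(summaries.columns)
    if len(cols) < 3:
        raise ValueError("need >= 3 summary columns")
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            xi = summaries[cols[i]].to_numpy(dtype=float)
            xj = summaries[cols[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(xi) | np.isnan(xj))
            if ok.sum() < 3 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                continue
            res = stats.pearsonr(xi[ok], xj[ok])
            r[i, j] = res.statistic
            p[i, j] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    masked = rdf.where((pdf < p_threshold) | np.eye(k, dtype=bool))
    dist = 1.0 - np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    order = list(leaves_list(linkage(squareform(dist, checks=False),
                                     method="complete")))
    return masked, pdf, order


def scale_unit_variance(values: np.ndarray | pd.Series,
                        center: bool = False) -> np.ndarray:
    """Scale to unit standard deviation; optionally center to mean zero."""
    x = np.asarray(values, dtype=float)
    sd = np.std(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("constant input cannot be unit-variance scaled")
    out = x / sd
    if center:
        out = out - out.mean()
    return out
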