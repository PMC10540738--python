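"""Mode-of-inheritance classification from marker allelic-class means,
additive/dominance genotypic values, QTI typing from per-environment
homozygote effects, and QTL-level consensus."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from metstab.io_cli.types import MISSING

__all__ = [
    "ClassMeans",
    "GeneActionResult",
    "QTITypeResult",
    "class_means",
    "classify_mode",
    "qti_effect_profile",
    "qtl_consensus",
    "mode_percentage",
    "analysable_count",
]

MODES = ("additive", "dominant", "recessive", "overdominant",
         "non_conclusive", "not_analysable")


@dataclass
class ClassMeans:
    means: dict[int, float]     # by code 0 (AA), 1 (AB), 2 (BB)
    ses: dict[int, float]
    counts: dict[int, int]
    resid_var: float
    resid_df: int
    dropped: list[int] = field(default_factory=list)

    @property
    def analysable(self) -> bool:
        return len(self.means) >= 2


def class_means(
    response: pd.Series,
    codes: np.ndarray | pd.Series,
    min_class_n: int = 3,
) -> ClassMeans:
    """Least-squares marginal means per allelic state; states represented by
    fewer than ``min_class_n`` accessions are dropped."""
    y = np.asarray(response, dtype=float)
    c = np.asarray(codes, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(c) | (c == MISSING))
    y, c = y[ok], c[ok].astype(int)
    if y.size == 0:
        raise ValueError("no paired observations")
    means, ses, counts, dropped = {}, {}, {}, []
    groups = {k: y[c == k] for k in (0, 1, 2) if (c == k).any()}
    kept = {k: v for k, v in groups.items() if len(v) >= min_class_n}
    dropped = [k for k in groups if k not in kept]
    rss = sum(((v - v.mean()) ** 2).sum() for v in kept.values())
    df = sum(len(v) for v in kept.values()) - len(kept)
    resid_var = rss / df if df > 0 else np.nan
    for k, v in kept.items():
        means[k] = float(v.mean())
        counts[k] = int(len(v))
        ses[k] = float(np.sqrt(resid_var / len(v))) if df > 0 else np.nan
    return ClassMeans(means, ses, counts, resid_var, max(df, 0), dropped)


@dataclass
class GeneActionResult:
    marker: str
    trait: str
    response_kind: str           # blup_g | stability
    cm: ClassMeans | None
    mode: str
    a: float | None = None
    d: float | None = None
    minor_direction: str | None = None   # increases | decreases
    ambiguous: bool = False
    note: str = ""


def _contrast_p(cm: ClassMeans, weights: dict[int, float]) -> float:
    est = sum(w * cm.means[k] for k, w in weights.items())
    var = cm.resid_var * sum(w * w / cm.counts[k] for k, w in weights.items())
    if not np.isfinite(var) or var <= 0 or cm.resid_df <= 0:
        return 1.0
    t = est / np.sqrt(var)
    return float(2.0 * stats.t.sf(abs(t), cm.resid_df))


def classify_mode(
    cm: ClassMeans,
    marker: str = "",
    trait: str = "",
    response_kind: str = "blup_g",
    alpha: float = 0.05,
    minor_hom_code: int = 2,
) -> GeneActionResult:
    """Contrast-based inheritance mode.

    Additive contrast H0: AB - (AA+BB)/2 = 0. If rejected, the dominance and
    recessivity contrasts relative to the favourable homozygote are tested;
    if all are rejected and AB exceeds both homozygotes the mode is
    overdominant. ``minor_hom_code`` tells which homozygote carries the minor
    allele for the direction call.
    """
    res = GeneActionResult(marker, trait, response_kind, cm, "not_analysable")
    if cm is None or not cm.analysable:
        return res
    have = set(cm.means)
    if {0, 2} <= have:
        res.a = (cm.means[0] - cm.means[2]) / 2.0
    if {0, 1, 2} <= have:
        res.d = cm.means[1] - (cm.means[0] + cm.means[2]) / 2.0
    if {0, 2} <= have:
        minor_mean = cm.means[2] if minor_hom_code == 2 else cm.means[0]
        major_mean = cm.means[0] if minor_hom_code == 2 else cm.means[2]
        res.minor_direction = "increases" if minor_mean > major_mean else "decreases"

    if 1 not in have:
        if {0, 2} <= have:
            res.mode = "additive"
            res.note = "heterozygote class absent; dominance untestable"
            res.ambiguous = True
        return res
    if not {0, 2} <= have:
        res.mode = "not_analysable"
        res.note = "a homozygote class missing"
        return res

    AA, AB, BB = cm.means[0], cm.means[1], cm.means[2]
    p_add = _contrast_p(cm, {1: 1.0, 0: -0.5, 2: -0.5})
    if p_add >= alpha:
        res.mode = "additive"
        return res
    if BB > AA:   # B allele has a positive effect
        p_dom = _contrast_p(cm, {1: 1.0, 2: -1.0})
        p_rec = _contrast_p(cm, {1: 1.0, 0: -1.0})
    else:
        p_dom = _contrast_p(cm, {1: 1.0, 0: -1.0})
        p_rec = _contrast_p(cm, {1: 1.0, 2: -1.0})
    dom_ok = p_dom >= alpha
    rec_ok = p_rec >= alpha
    if dom_ok and rec_ok:
        res.mode = "non_conclusive"
        res.note = "both dominant and recessive nulls retained"
    elif dom_ok:
        res.mode = "dominant"
    elif rec_ok:
        res.mode = "recessive"
    elif AB > max(AA, BB):
        res.mode = "overdominant"
    else:
        res.mode = "non_conclusive"
        res.note = "all contrasts rejected, AB not above both homozygotes"
    return res


@dataclass
class QTITypeResult:
    marker: str
    trait: str
    env_effects: pd.DataFrame    # per environment: effect (BB-AA), p, n_AA, n_BB
    qti_type: str                # QTL3 | QTL4 | QTL5 | non_conclusive
    interaction_p: float | None = None
    hotelling: tuple[float, float] | None = None  # (T2 statistic, p)
    excluded_envs: list[str] = field(default_factory=list)


def qti_effect_profile(
    blup_ge: pd.DataFrame,
    codes: pd.Series,
    marker: str = "",
    trait: str = "",
    alpha: float = 0.05,
    min_class_n: int = 3,
) -> QTITypeResult:
    """QTI typing from per-environment homozygote contrasts on BLUPge.

    Per environment the BB - AA difference is tested by one-way ANOVA; the
    profile of significant effects maps to QTL3 (all significant, same sign,
    unequal magnitude, with a significant SNPxE term), QTL4 (conditionally
    neutral), or QTL5 (antagonistic). A Hotelling-style multivariate
    homozygote comparison across environments is reported as support.
    """
    codes = codes.reindex(blup_ge.index)
    is_aa = (codes == 0).to_numpy()
    is_bb = (codes == 2).to_numpy()
    if is_aa.sum() < min_class_n or is_bb.sum() < min_class_n:
        return QTITypeResult(marker, trait, pd.DataFrame(), "non_conclusive")
    rows = []
    excluded = []
    for env in blup_ge.columns:
        v = blup_ge[env].to_numpy(dtype=float)
        aa = v[is_aa & ~np.isnan(v)]
        bb = v[is_bb & ~np.isnan(v)]
        if len(aa) == 0 or len(bb) == 0:
            excluded.append(str(env))
            continue
        eff = bb.mean() - aa.mean()
        if len(aa) > 1 and len(bb) > 1 and (np.var(aa) + np.var(bb)) > 0:
            f, p = stats.f_oneway(aa, bb)
        else:
            p = 1.0
        rows.append((str(env), float(eff), float(p), len(aa), len(bb)))
    env_df = pd.DataFrame(rows, columns=["environment", "effect", "p", "n_AA", "n_BB"])

    # SNP + E + SNPxE model on the homozygotes (interaction term test)
    long = blup_ge.loc[is_aa | is_bb].stack().rename("y").reset_index()
    long.columns = ["accession", "environment", "y"]
    long["snp"] = [0 if a in set(blup_ge.index[is_aa]) else 1
                   for a in long["accession"]]
    inter_p = None
    try:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        m_full = smf.ols("y ~ C(snp) * C(environment)", data=long).fit()
        m_red = smf.ols("y ~ C(snp) + C(environment)", data=long).fit()
        cmp_tab = sm.stats.anova_lm(m_red, m_full)
        inter_p = float(cmp_tab["Pr(>F)"].iloc[1])
    except Exception:
        pass

    hotelling = _hotelling_two_sample(blup_ge.loc[is_aa].to_numpy(float),
                                      blup_ge.loc[is_bb].to_numpy(float))

    sig = env_df["p"] < alpha
    eff = env_df["effect"]
    # sign opposition must come from substantial effects: a barely-nonzero
    # significant blip in an otherwise neutral environment is not a reversal
    substantial = sig & (eff.abs() >= 0.25 * eff.abs()[sig].max()
                         if sig.any() else False)
    if sig.sum() == 0 or env_df.empty:
        qti = "non_conclusive"
    elif (substantial & (eff > 0)).any() and (substantial & (eff < 0)).any():
        qti = "QTL5"
    elif sig.any() and (~sig).any():
        qti = "QTL4"
    elif sig.all():
        same_sign = (eff > 0).all() or (eff < 0).all()
        unequal = not np.allclose(eff, eff.iloc[0], rtol=1e-2)
        if same_sign and unequal and (inter_p is None or inter_p < alpha):
            qti = "QTL3"
        elif same_sign and (inter_p is not None and inter_p >= alpha):
            qti = "consistent_effect"
        else:
            qti = "non_conclusive"
    else:
        qti = "non_conclusive"
    return QTITypeResult(marker, trait, env_df, qti, inter_p, hotelling, excluded)


def _hotelling_two_sample(A: np.ndarray, B: np.ndarray):
    """Two-sample Hotelling T^2 across environments (rows = accessions)."""
    A = A[~np.isnan(A).any(axis=1)]
    B = B[~np.isnan(B).any(axis=1)]
    n1, n2 = len(A), len(B)
    k = A.shape[1] if A.ndim == 2 else 1
    if n1 <= k or n2 <= k:
        return None
    d = A.mean(axis=0) - B.mean(axis=0)
    S = ((n1 - 1) * np.cov(A, rowvar=False) + (n2 - 1) * np.cov(B, rowvar=False)) / (
        n1 + n2 - 2)
    try:
        t2 = float((n1 * n2) / (n1 + n2) * d @ np.linalg.solve(S, d))
    except np.linalg.LinAlgError:
        return None
    f = t2 * (n1 + n2 - k - 1) / (k * (n1 + n2 - 2))
    p = float(stats.f.sf(f, k, n1 + n2 - k - 1))
    return (t2, p)


def qtl_consensus(results: list[GeneActionResult]) -> tuple[str, str | None]:
    """QTL-level mode and direction: unanimous across member SNPs or
    non-conclusive."""
    usable = [r for r in results if r.mode != "not_analysable"]
    if not usable:
        return "not_analysable", None
    modes = {r.mode for r in usable}
    dirs = {r.minor_direction for r in usable if r.minor_direction is not None}
    mode = modes.pop() if len(modes) == 1 else "non_conclusive"
    direction = dirs.pop() if len(dirs) == 1 else None
    if len(dirs) > 1:
        mode = "non_conclusive" if mode != "not_analysable" else mode
    return mode, direction


# ---------------------------------------------------------------------------
# summary reporters
# ---------------------------------------------------------------------------


def mode_percentage(count: int, total: int, decimals: int = 2) -> float:
    """Percentage of QTLs in a mode class, as printed in summaries."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def analysable_count(total: int, not_analysable: int, non_conclusive: int) -> int:
    """QTLs for which mode and direction could be assessed."""
    n = total - not_analysable - non_conclusive
    if n < 0:
        raise ValueError("counts exceed total")
    return n
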