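"""Haplotype machinery: two-locus EM-based D' and r2, solid-spine block
discovery with Haploview-style marker filters, EM haplotype assignment, and
haplotype-trait association (two-way ANOVA with Tukey letters for
quantitative traits; chi-square with standardized Pearson residuals for
qualitative traits)."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from metstab.io_cli.types import MISSING, GenotypeMatrix

__all__ = [
    "dprime",
    "hwe_pvalue",
    "HaplotypeBlock",
    "solid_spine_blocks",
    "assign_haplotypes",
    "frequency_class",
    "haplotype_anova",
    "haplotype_chisq",
    "HaplotypeAssociation",
]


def dprime(x: np.ndarray, y: np.ndarray, tol: float = 1e-6,
           max_iter: int = 1000) -> tuple[float, float]:
    """Lewontin's D' and r2 for two markers from unphased diploid codes.

    Two-locus haplotype frequencies are estimated by EM; only the double
    heterozygotes are phase-ambiguous. Returns (|D'|, r2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | (x == MISSING) | np.isnan(y) | (y == MISSING))
    x, y = x[ok].astype(int), y[ok].astype(int)
    if len(x) == 0 or len(set(x)) < 2 or len(set(y)) < 2:
        raise ValueError("monomorphic or empty input")

    # known haplotype counts; haplotypes indexed (alt1, alt2) in {0,1}^2
    counts = np.zeros(4)  # order: (0,0) (0,1) (1,0) (1,1)
    n_dh = 0
    for c1, c2 in zip(x, y):
        if c1 == 1 and c2 == 1:
            n_dh += 1
            continue
        a1 = [0] * (2 - c1) + [1] * c1
        a2 = [0] * (2 - c2) + [1] * c2
        if c1 == 1:
            for al in a1:
                counts[al * 2 + a2[0]] += 1
        elif c2 == 1:
            for al in a2:
                counts[a1[0] * 2 + al] += 1
        else:
            counts[a1[0] * 2 + a2[0]] += 2

    total = counts.sum() + 2 * n_dh
    p = np.full(4, 0.25) if total == 0 else (counts + 0.5 * n_dh) / max(total, 1)
    p = p / p.sum()
    for _ in range(max_iter):
        # E-step: split double heterozygotes between cis (00/11) and
        # trans (01/10) phases
        cis = p[0] * p[3]
        trans = p[1] * p[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = counts.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new = new / new.sum()
        if np.abs(new - p).max() < tol:
            p = new
            break
        p = new
    q1 = p[2] + p[3]  # alt-allele frequency at locus 1
    q2 = p[1] + p[3]
    D = p[3] - q1 * q2
    if D >= 0:
        dmax = min(q1 * (1 - q2), (1 - q1) * q2)
    else:
        dmax = min(q1 * q2, (1 - q1) * (1 - q2))
    dp = abs(D) / dmax if dmax > 0 else 0.0
    denom = q1 * (1 - q1) * q2 * (1 - q2)
    r2 = D * D / denom if denom > 0 else 0.0
    return float(min(dp, 1.0)), float(r2)


def hwe_pvalue(codes: np.ndarray) -> float:
    """Hardy-Weinberg equilibrium p-value: exact enumeration below n=100,
    chi-square otherwise."""
    c = np.asarray(codes)
    c = c[(c != MISSING) & ~np.isnan(c.astype(float))].astype(int)
    n = len(c)
    if n == 0:
        return 1.0
    n_het = int((c == 1).sum())
    n_hom_alt = int((c == 2).sum())
    n_alt = 2 * n_hom_alt + n_het
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    if n < 100:
        return _hwe_exact(n_het, n, n_alt)
    q = n_alt / (2 * n)
    exp = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    obs = np.array([n - n_het - n_hom_alt, n_het, n_hom_alt])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum((obs - exp) ** 2 / exp)
    return float(stats.chi2.sf(chi2, 1))


def _hwe_exact(n_het: int, n: int, n_alt: int) -> float:
    """Exact HWE test: probability of heterozygote counts at least as
    unlikely as observed, given allele counts."""
    n_ref = 2 * n - n_alt
    rare = min(n_alt, n_ref)
    hets = range(rare % 2, rare + 1, 2)
    logp = {}
    for h in hets:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        logp[h] = (_lgamma(n + 1) - _lgamma(hom_r + 1) - _lgamma(h + 1)
                   - _lgamma(hom_c + 1) + h * np.log(2) + _lgamma(rare + 1)
                   + _lgamma(2 * n - rare + 1) - _lgamma(2 * n + 1))
    mx = max(logp.values())
    probs = {h: np.exp(v - mx) for h, v in logp.items()}
    z = sum(probs.values())
    obs_rare_het = n_het
    p_obs = probs.get(obs_rare_het, 0.0)
    return float(min(sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / z, 1.0))


def _lgamma(x):
    from scipy.special import gammaln
    return gammaln(x)


@dataclass
class HaplotypeBlock:
    chrom: str
    marker_ids: list[str]
    marker_indices: list[int]
    haplotypes: list[str] = field(default_factory=list)      # strings over {0,1}
    frequencies: dict[str, pd.Series] = field(default_factory=dict)

    def classify_frequencies(self, collection: str = "all") -> pd.Series:
        return self.frequencies[collection].map(frequency_class)


def frequency_class(freq: float) -> str:
    """Major (>10%), rare (<1%), else minor."""
    if freq > 0.10:
        return "major"
    if freq < 0.01:
        return "rare"
    return "minor"


def solid_spine_blocks(
    g: GenotypeMatrix,
    markers: list[str] | None = None,
    dprime_threshold: float = 0.8,
    maf_min: float = 0.001,
    hwe_min_p: float = 0.001,
    missing_max: float = 0.75,
    max_span_bp: int = 1_000_000,
) -> list[HaplotypeBlock]:
    """Solid-spine haplotype blocks: maximal position-ordered runs in which
    the first and the last marker each have D' >= threshold with every
    intermediate marker (and with each other). Markers failing the
    Haploview-style filters (MAF, HWE, missingness) are excluded first."""
    if markers is None:
        markers = list(g.marker_ids)
    idx = [g.marker_ids.index(m) for m in markers]
    keep = []
    for i in idx:
        col = g.codes[:, i]
        obs = col != MISSING
        if obs.mean() < (1.0 - missing_max):
            continue
        vals = col[obs]
        if len(vals) == 0:
            continue
        q = vals.mean() / 2.0
        if min(q, 1 - q) < maf_min:
            continue
        if hwe_pvalue(col) < hwe_min_p:
            continue
        keep.append(i)
    if len(keep) < 2:
        raise ValueError("fewer than 2 markers after filters")
    keep.sort(key=lambda i: (str(g.map["chrom"].iloc[i]), int(g.map["pos"].iloc[i])))

    dp_cache: dict[tuple[int, int], float] = {}

    def dp(i, j):
        key = (min(i, j), max(i, j))
        if key not in dp_cache:
            try:
                dp_cache[key] = dprime(g.codes[:, key[0]], g.codes[:, key[1]])[0]
            except ValueError:
                dp_cache[key] = 0.0
        return dp_cache[key]

    blocks: list[HaplotypeBlock] = []
    by_chrom: dict[str, list[int]] = {}
    for i in keep:
        by_chrom.setdefault(str(g.map["chrom"].iloc[i]), []).append(i)

    for chrom, cols in by_chrom.items():
        pos = [int(g.map["pos"].iloc[i]) for i in cols]
        start = 0
        while start < len(cols):
            best_end = start
            for end in range(start + 1, len(cols)):
                if pos[end] - pos[start] >= max_span_bp:
                    break
                run = cols[start:end + 1]
                first, last = run[0], run[-1]
                spine = all(dp(first, m) >= dprime_threshold for m in run[1:]) and \
                    all(dp(last, m) >= dprime_threshold for m in run[:-1])
                if spine:
                    best_end = end
            if best_end > start:
                run = cols[start:best_end + 1]
                blocks.append(HaplotypeBlock(
                    chrom=chrom,
                    marker_ids=[g.marker_ids[i] for i in run],
                    marker_indices=list(run),
                ))
                start = best_end + 1
            else:
                start += 1
    return blocks


def assign_haplotypes(
    block: HaplotypeBlock,
    g: GenotypeMatrix,
    posterior_min: float = 0.9,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-accession haplotype copy counts for a block.

    Fully homozygous accessions get 2 copies of one haplotype; single-site
    heterozygotes get 1+1; multi-site heterozygotes are resolved by the EM
    posterior when it exceeds ``posterior_min`` and left unassigned
    otherwise. Also populates block.haplotypes and block.frequencies['all'].
    """
    cols = block.marker_indices
    codes = g.codes[:, cols].astype(int)
    n, m = codes.shape

    # enumerate candidate haplotype pairs per accession (missing -> skip)
    cand_pairs: list[list[tuple[str, str]] | None] = []
    for i in range(n):
        row = codes[i]
        if (row == MISSING).any():
            cand_pairs.append(None)
            continue
        het_sites = np.flatnonzero(row == 1)
        base1 = np.where(row == 2, 1, 0)
        base2 = base1.copy()
        if len(het_sites) == 0:
            h = "".join(map(str, base1))
            cand_pairs.append([(h, h)])
            continue
        pairs = []
        first = het_sites[0]
        for phase in itertools.product((0, 1), repeat=len(het_sites) - 1):
            ph = (0,) + phase  # fix the first het site to break pair symmetry
            h1 = base1.copy()
            h2 = base2.copy()
            for s, side in zip(het_sites, ph):
                h1[s] = side
                h2[s] = 1 - side
            pairs.append(("".join(map(str, h1)), "".join(map(str, h2))))
        cand_pairs.append(pairs)

    haps = sorted({h for pr in cand_pairs if pr for ab in pr for h in ab})
    hidx = {h: k for k, h in enumerate(haps)}
    H = len(haps)
    rng = np.random.default_rng(seed)

    def em(p0):
        p = p0.copy()
        for _ in range(max_iter):
            new = np.zeros(H)
            for pr in cand_pairs:
                if not pr:
                    continue
                ws = np.array([p[hidx[a]] * p[hidx[b]] for a, b in pr])
                tot = ws.sum()
                ws = ws / tot if tot > 0 else np.full(len(pr), 1 / len(pr))
                for (a, b), w in zip(pr, ws):
                    new[hidx[a]] += w
                    new[hidx[b]] += w
            new = new / new.sum()
            if np.abs(new - p).max() < tol:
                return new
            p = new
        return p

    best_p, best_ll = None, -np.inf
    for s in range(max(n_starts, 1)):
        p0 = np.full(H, 1.0 / H) if s == 0 else rng.dirichlet(np.ones(H))
        p = em(p0)
        ll = 0.0
        for pr in cand_pairs:
            if not pr:
                continue
            lik = sum(p[hidx[a]] * p[hidx[b]] * (1 if a == b else 2) for a, b in pr)
            ll += np.log(max(lik, 1e-300))
        if ll > best_ll:
            best_p, best_ll = p, ll
    p = best_p

    rows = []
    assigned_counts = np.zeros(H)
    for i, pr in enumerate(cand_pairs):
        acc = g.accession_ids[i]
        if pr is None:
            rows.append((acc, None, None, np.nan, False))
            continue
        if len(pr) == 1:
            a, b = pr[0]
            rows.append((acc, a, b, 1.0, True))
            assigned_counts[hidx[a]] += 1
            assigned_counts[hidx[b]] += 1
            continue
        ws = np.array([p[hidx[a]] * p[hidx[b]] * (1 if a == b else 2) for a, b in pr])
        ws = ws / ws.sum()
        k = int(np.argmax(ws))
        if ws[k] > posterior_min:
            a, b = pr[k]
            rows.append((acc, a, b, float(ws[k]), True))
            assigned_counts[hidx[a]] += 1
            assigned_counts[hidx[b]] += 1
        else:
            rows.append((acc, None, None, float(ws[k]), False))
    out = pd.DataFrame(rows, columns=["accession", "hap1", "hap2",
                                      "posterior", "assigned"])
    tot = assigned_counts.sum()
    freqs = pd.Series(assigned_counts / tot if tot > 0 else assigned_counts,
                      index=haps, name="frequency")
    freqs = freqs[freqs > 0]
    block.haplotypes = list(freqs.index)
    block.frequencies["all"] = freqs
    return out


@dataclass
class HaplotypeAssociation:
    trait: str
    anova: pd.DataFrame | None = None
    cell_stats: pd.DataFrame | None = None
    tukey_letters: dict[str, str] | None = None
    chi2: tuple[float, float, int] | None = None   # stat, p, dof
    residuals: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None
    note: str = ""


def haplotype_anova(
    values: pd.Series,
    presence: pd.Series,
    collection: pd.Series,
    trait: str = "trait",
    alpha: float = 0.05,
) -> HaplotypeAssociation:
    """Two-way ANOVA Y ~ haplotype-class + collection + interaction, with cell
    means/SDs and Tukey-HSD compact letters over haplotype x collection
    cells."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame({"y": pd.to_numeric(values), "hap": presence.astype(str),
                       "coll": collection.astype(str)}).dropna()
    if df["hap"].nunique() < 2:
        return HaplotypeAssociation(trait, note="fewer than 2 haplotype classes")
    has_inter = df.groupby(["hap", "coll"]).size().min() >= 2 \
        and df["coll"].nunique() >= 2
    formula = "y ~ C(hap) * C(coll)" if has_inter else "y ~ C(hap) + C(coll)" \
        if df["coll"].nunique() >= 2 else "y ~ C(hap)"
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    cells = (df.groupby(["hap", "coll"])["y"].agg(["mean", "std", "count"])
             .reset_index())
    letters = None
    df["cell"] = df["hap"] + "|" + df["coll"]
    if df["cell"].nunique() >= 2 and df.groupby("cell").size().min() >= 2:
        tk = pairwise_tukeyhsd(df["y"], df["cell"], alpha=alpha)
        letters = _compact_letters(
            list(tk.groupsunique),
            [(list(tk.groupsunique).index(a), list(tk.groupsunique).index(b), rej)
             for (a, b), rej in zip(
                 itertools.combinations(tk.groupsunique, 2), tk.reject)],
        )
    return HaplotypeAssociation(trait, anova=anova, cell_stats=cells,
                                tukey_letters=letters)


def _compact_letters(groups: list[str],
                     pairs: list[tuple[int, int, bool]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise rejections."""
    differ = {(min(i, j), max(i, j)) for i, j, rej in pairs if rej}
    letters: list[set[int]] = [set(range(len(groups)))]
    for i, j in sorted(differ):
        for s in list(letters):
            if i in s and j in s:
                letters.remove(s)
                s1, s2 = s - {j}, s - {i}
                for cand in (s1, s2):
                    if not any(cand <= other for other in letters):
                        letters.append(cand)
    letters.sort(key=lambda s: min(s) if s else 0)
    out = {gname: "" for gname in groups}
    for k, s in enumerate(letters):
        ch = chr(ord("a") + k)
        for i in s:
            out[groups[i]] += ch
    return out


def haplotype_chisq(
    categories: pd.Series,
    presence: pd.Series,
    collection: pd.Series | None = None,
    trait: str = "trait",
    alpha: float = 0.05,
) -> HaplotypeAssociation:
    """Chi-square independence test of haplotype presence vs phenotype
    category, Bonferroni-corrected pairwise comparisons, and standardized
    Pearson residuals d_ij = (O-E)/sqrt(E(1-p_row)(1-p_col))."""
    df = pd.DataFrame({"cat": categories.astype(str),
                       "hap": presence.astype(str)}).dropna()
    tab = pd.crosstab(df["hap"], df["cat"])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return HaplotypeAssociation(trait, note="degenerate table: test undefined")
    res = stats.chi2_contingency(tab, correction=False)
    note = ""
    if (res.expected_freq == 0).any():
        note = "zero expected counts: exact-test fallback"
        if tab.shape == (2, 2):
            p = stats.fisher_exact(tab.to_numpy())[1]
            res = type(res)(np.nan, p, res.dof, res.expected_freq)
    n = tab.to_numpy().sum()
    rowp = tab.sum(axis=1).to_numpy() / n
    colp = tab.sum(axis=0).to_numpy() / n
    E = res.expected_freq
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (tab.to_numpy() - E) / np.sqrt(
            E * (1 - rowp)[:, None] * (1 - colp)[None, :])
    residuals = pd.DataFrame(d, index=tab.index, columns=tab.columns)

    # Bonferroni-corrected pairwise haplotype-class comparisons
    hs = list(tab.index)
    m = len(hs) * (len(hs) - 1) // 2
    rows = []
    for a, b in itertools.combinations(hs, 2):
        sub = tab.loc[[a, b]]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        if sub.shape[1] < 2:
            continue
        pr = stats.chi2_contingency(sub, correction=False).pvalue
        rows.append((a, b, pr, min(pr * m, 1.0)))
    pairwise = pd.DataFrame(rows, columns=["class_a", "class_b", "p", "p_bonf"])
    return HaplotypeAssociation(
        trait, chi2=(float(res.statistic), float(res.pvalue), int(res.dof)),
        residuals=residuals, pairwise=pairwise, note=note,
    )
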