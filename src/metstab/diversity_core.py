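"""Diversity summaries (per-site nucleotide diversity, MAF, PCoA/MDS on IBS
distances, kinship distribution) and the mixed-strategy core-collection
selector with representativeness diagnostics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from metstab.io_cli.types import MISSING, GenotypeMatrix
from metstab.association import kinship

__all__ = [
    "prefilter_and_sample",
    "DiversityProfile",
    "diversity_profile",
    "pcoa",
    "CoreSelection",
    "select_core",
    "replace_accession",
    "representativeness_report",
    "collection_size",
]


def prefilter_and_sample(
    g: GenotypeMatrix,
    ind_missing_max: float = 0.30,
    snp_missing_max: float = 0.10,
    marker_fraction: float = 0.20,
    seed: int = 0,
) -> GenotypeMatrix:
    """Core-collection preprocessing: random marker subsample, accession and
    marker missingness filters (in that order: subsample, then >30%
    accessions, then >10% markers), then major-allele
    imputation of the remaining missing entries."""
    rng = np.random.default_rng(seed)
    m = g.n_markers
    take = max(int(round(marker_fraction * m)), 1)
    cols = np.sort(rng.choice(m, size=take, replace=False))
    mask = np.zeros(m, dtype=bool)
    mask[cols] = True
    g = g.subset(markers=mask)

    miss = g.codes == MISSING
    g = g.subset(accessions=miss.mean(axis=1) <= ind_missing_max)
    miss = g.codes == MISSING
    g = g.subset(markers=miss.mean(axis=0) <= snp_missing_max)
    if g.n_markers == 0 or g.n_accessions == 0:
        raise ValueError("prefilter removed everything")

    codes = g.codes.copy()
    for j in range(g.n_markers):
        col = codes[:, j]
        obs = col[col != MISSING]
        if len(obs) == 0:
            codes[:, j] = 0
            continue
        vals, cnts = np.unique(obs, return_counts=True)
        codes[col == MISSING, j] = vals[np.argmax(cnts)]
    return GenotypeMatrix(g.accession_ids, g.marker_ids, codes, g.map)


@dataclass
class DiversityProfile:
    pi: pd.Series                 # per marker
    maf: pd.Series
    snp_density: pd.DataFrame     # chrom, bin_start, count (1 Mb bins)
    mds: pd.DataFrame             # accessions x first 3 axes
    kinship_summary: dict[str, float] = field(default_factory=dict)


def per_site_pi(g: GenotypeMatrix) -> pd.Series:
    """2p(1-p) * n/(n-1) per site, with p from observed allele counts and n
    the number of non-missing accessions."""
    d = g.dosage()
    n = (~np.isnan(d)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
        corr = np.where(n > 1, n / np.where(n > 1, n - 1.0, 1.0), np.nan)
        pi = 2.0 * p * (1.0 - p) * corr
    return pd.Series(pi, index=g.marker_ids, name="pi")


def pcoa(dist: np.ndarray, n_axes: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Classical scaling (PCoA): eigendecomposition of the double-centered
    squared-distance matrix, truncating negative eigenvalues."""
    D2 = np.asarray(dist, dtype=float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > 1e-10
    w, V = w[pos], V[:, pos]
    k = min(n_axes, len(w))
    coords = V[:, :k] * np.sqrt(w[:k])
    return coords, w


def diversity_profile(g: GenotypeMatrix, bin_bp: int = 1_000_000) -> DiversityProfile:
    pi = per_site_pi(g)
    maf = pd.Series(g.maf(), index=g.marker_ids, name="maf")
    dens = (g.map.assign(bin_start=(g.map["pos"] - 1) // bin_bp * bin_bp + 1)
            .groupby(["chrom", "bin_start"]).size().rename("count").reset_index())
    K = kinship(g, variant="centered_ibs")
    ibs = kinship(g, variant="ibs_emma")
    dist = 1.0 - ibs.values
    np.fill_diagonal(dist, 0.0)
    coords, _ = pcoa(dist, n_axes=3)
    mds = pd.DataFrame(coords, index=g.accession_ids,
                       columns=[f"axis{k+1}" for k in range(coords.shape[1])])
    off = K.values[~np.eye(len(K.values), dtype=bool)]
    summary = {"mean": float(off.mean()), "sd": float(off.std()),
               "q05": float(np.quantile(off, 0.05)),
               "q95": float(np.quantile(off, 0.95))}
    return DiversityProfile(pi, maf, dens, mds, summary)


@dataclass
class CoreSelection:
    genetic_subcore: list[str]
    phenotypic_subcore: list[str]
    geographic_fill: list[str]
    replacement: list[str] = field(default_factory=list)
    target_fraction: float = 0.0

    @property
    def selected(self) -> list[str]:
        seen: dict[str, None] = {}
        for group in (self.genetic_subcore, self.phenotypic_subcore,
                      self.geographic_fill, self.replacement):
            for a in group:
                seen.setdefault(a, None)
        return list(seen)


def _maximin(coords: pd.DataFrame, k: int) -> list[str]:
    """Greedy farthest-point sampling, seeded at the accession farthest from
    the centroid."""
    X = coords.to_numpy(dtype=float)
    ids = list(coords.index)
    n = len(ids)
    k = min(k, n)
    centroid = X.mean(axis=0)
    first = int(np.argmax(((X - centroid) ** 2).sum(axis=1)))
    chosen = [first]
    mind = ((X - X[first]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, ((X - X[nxt]) ** 2).sum(axis=1))
    return [ids[i] for i in chosen]


def select_core(
    g: GenotypeMatrix,
    quantitative: pd.DataFrame | None = None,
    qualitative: pd.DataFrame | None = None,
    geography: pd.Series | None = None,
    fraction: float = 0.167,
    n_extreme: int = 10,
    genetic_share: float = 0.35,
    seed: int = 0,
) -> tuple[CoreSelection, pd.DataFrame]:
    """Mixed-strategy core selection.

    Genetic sub-core: greedy maximin on the first three PCoA axes of the IBS
    distance. Phenotypic sub-core: the ``n_extreme`` highest and lowest
    accessions per quantitative trait plus seeded random picks per
    qualitative category. Geographic fill: one accession per unrepresented
    region. Returns the selection and the PCoA coordinates used.
    """
    rng = np.random.default_rng(seed)
    n = g.n_accessions
    target = max(int(round(fraction * n)), 1)
    ibs = kinship(g, variant="ibs_emma")
    dist = 1.0 - ibs.values
    np.fill_diagonal(dist, 0.0)
    coords, _ = pcoa(dist, n_axes=3)
    coords = pd.DataFrame(coords, index=g.accession_ids)

    n_gen = min(max(int(round(genetic_share * target)), 1), n)
    genetic = _maximin(coords, n_gen)

    phenotypic: list[str] = []
    budget = max(target - n_gen, 0)
    if quantitative is not None:
        for col in quantitative.columns:
            vals = pd.to_numeric(quantitative[col], errors="coerce").dropna()
            vals = vals[vals.index.isin(g.accession_ids)]
            srt = vals.sort_values()
            phenotypic.extend(srt.index[-n_extreme:])
            phenotypic.extend(srt.index[:n_extreme])
    if qualitative is not None and budget > 0:
        for col in qualitative.columns:
            ser = qualitative[col].dropna()
            ser = ser[ser.index.isin(g.accession_ids)]
            shares = ser.value_counts(normalize=True)
            for cat, share in shares.items():
                take = int(np.ceil(share * budget))
                pool = list(ser.index[ser == cat])
                rng.shuffle(pool)
                phenotypic.extend(pool[:take])
    phenotypic = list(dict.fromkeys(phenotypic))

    geographic: list[str] = []
    if geography is not None:
        chosen = set(genetic) | set(phenotypic)
        geo = geography[geography.index.isin(g.accession_ids)]
        represented = set(geo.reindex(list(chosen & set(geo.index))).dropna())
        for region, members in geo.groupby(geo).groups.items():
            if region not in represented:
                pool = sorted(members)
                geographic.append(pool[int(rng.integers(0, len(pool)))])

    sel = CoreSelection(genetic, phenotypic, geographic,
                        target_fraction=fraction)
    if fraction >= 1.0:
        missing = [a for a in g.accession_ids if a not in set(sel.selected)]
        sel.geographic_fill = geographic + missing
    return sel, coords


def replace_accession(
    selection: CoreSelection, coords: pd.DataFrame, dropped: str
) -> tuple[CoreSelection, str, float]:
    """Replace a dropped accession with its nearest unselected PCoA
    neighbour."""
    current = selection.selected
    if dropped not in current:
        raise ValueError(f"{dropped!r} not in selection")
    pool = [a for a in coords.index if a not in set(current)]
    if not pool:
        raise ValueError("no replacement candidates")
    x0 = coords.loc[dropped].to_numpy(dtype=float)
    d = ((coords.loc[pool].to_numpy(dtype=float) - x0) ** 2).sum(axis=1)
    best = pool[int(np.argmin(d))]
    for group in (selection.genetic_subcore, selection.phenotypic_subcore,
                  selection.geographic_fill, selection.replacement):
        if dropped in group:
            group.remove(dropped)
    selection.replacement.append(best)
    return selection, best, float(np.sqrt(d.min()))


def representativeness_report(
    core_ids: list[str],
    g: GenotypeMatrix,
    quantitative: pd.DataFrame | None = None,
    qualitative: pd.DataFrame | None = None,
    p_flag: float = 0.001,
) -> pd.DataFrame:
    """Core-vs-full diagnostics: rank-sum tests per quantitative trait,
    chi-square coverage per qualitative trait, and pi/MAF spectrum
    comparisons; rows flagged at p < ``p_flag``."""
    core_set = set(core_ids)
    if not core_set <= set(g.accession_ids):
        raise ValueError("core is not a subset of the collection")
    rows = []
    if quantitative is not None:
        for col in quantitative.columns:
            vals = pd.to_numeric(quantitative[col], errors="coerce").dropna()
            a = vals[vals.index.isin(core_set)]
            b = vals
            if len(a) and len(b) and a.nunique() > 1:
                p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            else:
                p = 1.0
            rows.append(("quantitative", col, float(p), p < p_flag))
    if qualitative is not None:
        for col in qualitative.columns:
            ser = qualitative[col].dropna()
            tab = pd.crosstab(ser.index.isin(core_set), ser)
            if tab.shape[0] == 2 and tab.shape[1] >= 2:
                p = stats.chi2_contingency(tab, correction=False).pvalue
            else:
                p = 1.0
            rows.append(("qualitative", col, float(p), p < p_flag))
    core_g = g.subset(accessions=[a for a in g.accession_ids if a in core_set])
    for name, full_v, core_v in (
        ("pi", per_site_pi(g), per_site_pi(core_g)),
        ("maf", pd.Series(g.maf(), index=g.marker_ids),
         pd.Series(core_g.maf(), index=core_g.marker_ids)),
    ):
        a = core_v.dropna()
        b = full_v.dropna()
        if a.nunique() > 1 and b.nunique() > 1:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            p = 1.0
        rows.append(("spectrum", name, float(p), p < p_flag))
    return pd.DataFrame(rows, columns=["kind", "name", "p", "flagged"])


def collection_size(classification_counts: dict[str, int]) -> int:
    """Total collection size from per-classification entry counts."""
    if any(v < 0 for v in classification_counts.values()):
        raise ValueError("negative count")
    return int(sum(classification_counts.values()))
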