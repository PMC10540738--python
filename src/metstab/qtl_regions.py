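"""Candidate regions, loci, and QTL grouping from significant SNPs using
squared-dosage-correlation LD, a genome-derived r-squared baseline, the
<2 Mb window rule, and 100 kb locus merging."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metstab.io_cli.types import GenotypeMatrix

__all__ = [
    "Locus",
    "QTLRecord",
    "interchrom_r2_baseline",
    "pairwise_r2",
    "candidate_region",
    "build_loci",
    "group_qtls",
    "colocalization_label",
]


def _pairwise_complete_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return np.nan
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def interchrom_r2_baseline(
    g: GenotypeMatrix,
    percentile: float = 95.0,
    max_pairs: int = 50_000,
    seed: int = 0,
) -> float:
    """Percentile of r-squared over (a sample of) inter-chromosomal marker
    pairs; the default 95th percentile defines the LD baseline."""
    chroms = g.map["chrom"].to_numpy()
    if len(set(chroms)) < 2:
        raise ValueError("need >= 2 chromosomes")
    d = g.dosage()
    rng = np.random.default_rng(seed)
    m = g.n_markers
    pairs = []
    n_all = 0
    for i in range(m):
        n_all += int((chroms != chroms[i]).sum())
    n_all //= 2
    if n_all <= max_pairs:
        for i in range(m):
            for j in range(i + 1, m):
                if chroms[i] != chroms[j]:
                    pairs.append((i, j))
    else:
        seen = set()
        while len(pairs) < max_pairs:
            i, j = rng.integers(0, m, 2)
            if i == j or chroms[i] == chroms[j]:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            pairs.append(key)
    vals = np.array([_pairwise_complete_r2(d[:, i], d[:, j]) for i, j in pairs])
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no computable inter-chromosomal pairs")
    return float(np.percentile(vals, percentile))


def pairwise_r2(g: GenotypeMatrix, window_bp: int | None = None) -> pd.DataFrame:
    """Sparse long-format r-squared table for same-chromosome marker pairs
    within ``window_bp`` (all pairs per chromosome when None)."""
    d = g.dosage()
    chrom = g.map["chrom"].to_numpy()
    pos = g.map["pos"].to_numpy()
    rows = []
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        for a_i, i in enumerate(cols):
            for j in cols[a_i + 1:]:
                if window_bp is not None and abs(int(pos[j]) - int(pos[i])) >= window_bp:
                    break
                r2 = _pairwise_complete_r2(d[:, i], d[:, j])
                if not np.isnan(r2):
                    rows.append((g.marker_ids[i], g.marker_ids[j], c,
                                 int(pos[i]), int(pos[j]), r2))
    return pd.DataFrame(
        rows, columns=["marker_a", "marker_b", "chrom", "pos_a", "pos_b", "r2"]
    )


def candidate_region(
    lead_marker: str,
    g: GenotypeMatrix,
    baseline: float,
    window_bp: int = 2_000_000,
) -> tuple[str, int, int, list[str]]:
    """Interval spanned by SNPs in LD with the lead (r2 > baseline) within a
    strict ``window_bp`` distance of it; always contains the lead."""
    j = g.marker_ids.index(lead_marker)
    chrom = g.map["chrom"].iloc[j]
    lead_pos = int(g.map["pos"].iloc[j])
    d = g.dosage()
    members = [lead_marker]
    lo = hi = lead_pos
    for i in np.flatnonzero((g.map["chrom"] == chrom).to_numpy()):
        if i == j:
            continue
        p = int(g.map["pos"].iloc[i])
        if abs(p - lead_pos) >= window_bp:
            continue
        r2 = _pairwise_complete_r2(d[:, i], d[:, j])
        if not np.isnan(r2) and r2 > baseline:
            members.append(g.marker_ids[i])
            lo = min(lo, p)
            hi = max(hi, p)
    return str(chrom), lo, hi, members


@dataclass
class Locus:
    id: str
    chrom: str
    start: int
    end: int
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start > end")


def build_loci(
    regions: list[tuple[str, int, int, list[str]]],
    gap_bp: int = 100_000,
) -> list[Locus]:
    """Merge candidate regions that overlap or lie within ``gap_bp`` of each
    other (transitively, per chromosome); ids ordered by chromosome then
    position."""
    by_chrom: dict[str, list[tuple[int, int, list[str]]]] = {}
    for chrom, start, end, members in regions:
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end), list(members)))
    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda t: (t[0], t[1]))
        merged: list[list] = []
        for start, end, members in ivs:
            if merged and start <= merged[-1][1] + gap_bp:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2].extend(members)
            else:
                merged.append([start, end, list(members)])
        for start, end, members in merged:
            loci.append(Locus(id="", chrom=chrom, start=start, end=end,
                              members=sorted(set(members))))
    loci.sort(key=lambda L: (L.chrom, L.start))
    for i, L in enumerate(loci, start=1):
        L.id = f"L{i:03d}"
    return loci


@dataclass
class QTLRecord:
    trait: str
    analysis_class: str  # meanQTL | stbQTL | QTI
    locus_id: str
    member_mtas: list[str]
    colocalization: str = ""


_CLASS_OF_ANALYSIS = {"mean": "meanQTL", "stability": "stbQTL"}


def _analysis_class(analysis: str) -> str:
    if str(analysis).startswith("gei"):
        return "QTI"
    return _CLASS_OF_ANALYSIS.get(str(analysis), str(analysis))


def colocalization_label(classes: set[str]) -> str:
    mapping = {
        frozenset({"meanQTL"}): "mean_specific",
        frozenset({"stbQTL"}): "stb_specific",
        frozenset({"QTI"}): "qti_specific",
        frozenset({"meanQTL", "stbQTL"}): "mean+stability",
        frozenset({"QTI", "stbQTL"}): "qti+stb",
        frozenset({"meanQTL", "QTI"}): "mean+qti",
        frozenset({"meanQTL", "stbQTL", "QTI"}): "all_classes",
    }
    return mapping[frozenset(classes)]


def qtl_class_counts(qtls: list["QTLRecord"] | dict[str, int]) -> pd.Series:
    """Per-class QTL counts (meanQTL / stbQTL / QTI) plus the total, from a
    QTL list or a precomputed count mapping."""
    if isinstance(qtls, dict):
        counts = pd.Series(qtls, dtype=int)
    else:
        counts = pd.Series([q.analysis_class for q in qtls]).value_counts()
    counts["total"] = int(counts.sum())
    return counts


def group_qtls(
    mtas: pd.DataFrame, loci: list[Locus]
) -> tuple[list[QTLRecord], pd.Series]:
    """One QTL per (trait, analysis class, locus); colocalization labels per
    trait x locus, plus a summary count per label."""
    locus_of: dict[str, str] = {}
    for L in loci:
        for m in L.members:
            locus_of[m] = L.id
    recs: dict[tuple[str, str, str], QTLRecord] = {}
    for _, row in mtas.iterrows():
        lid = locus_of.get(row["marker_id"])
        assert lid is not None, "MTA outside all loci (every MTA seeds a region)"
        cls = _analysis_class(row["analysis"])
        key = (str(row["trait"]), cls, lid)
        if key not in recs:
            recs[key] = QTLRecord(trait=key[0], analysis_class=cls,
                                  locus_id=lid, member_mtas=[])
        recs[key].member_mtas.append(str(row["marker_id"]))
    by_trait_locus: dict[tuple[str, str], set[str]] = {}
    for (trait, cls, lid) in recs:
        by_trait_locus.setdefault((trait, lid), set()).add(cls)
    for key, rec in recs.items():
        rec.colocalization = colocalization_label(by_trait_locus[(key[0], key[2])])
    qtls = sorted(recs.values(), key=lambda r: (r.locus_id, r.trait, r.analysis_class))
    summary = pd.Series(
        pd.Series([q.colocalization for q in qtls]).value_counts(), dtype=int
    )
    return qtls, summary
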