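"""End-to-end pipeline: filter -> variance decomposition/BLUP -> stability ->
GWAS/GWEIS -> loci/QTL -> gene action -> haplotype blocks, with TSV outputs
and a machine-readable JSON summary. Outputs are a pure function of
(inputs, config, seed)."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from metstab import association, gene_action, haplotypes, met_models, qtl_regions, stability
from metstab.io_cli.types import GenotypeMatrix, METTable, RunConfig

log = logging.getLogger("metstab")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    genotypes: GenotypeMatrix,
    met: METTable,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage on the replicated quantitative traits in ``met``.

    Returns the JSON-serializable summary; when ``out_dir`` is given, per-
    stage TSV tables and summary.json are written there.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s", name)
                return fn()
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return deco

    @stage("filter")
    def filtered():
        try:
            g, rep = association.filter_snps(
                genotypes, maf_min=config.maf_min,
                snp_missing_max=config.snp_missing_max,
                ind_missing_max=config.ind_missing_max, het_max=config.het_max)
            summary["stages"]["filter"] = rep.as_dict()
        except ValueError:
            # every marker filtered out: downstream stages run empty
            g = genotypes.subset(markers=np.zeros(genotypes.n_markers, bool))
            summary["stages"]["filter"] = {"n_markers_out": 0}
        return g

    rep_traits = [t for t, s in met.trait_specs.items()
                  if s.kind == "replicated_quantitative"]
    mean_traits = [t for t, s in met.trait_specs.items()
                   if s.kind == "accession_mean_quantitative"]

    @stage("anova")
    def anova_out():
        rows, blupsets = [], {}
        for trait in rep_traits:
            vc, bl = met_models.fit_met_mixed(met, trait, lrt=True)
            pct = vc.percent_of_total
            rows.append({
                "trait": trait, "grand_mean": vc.grand_mean,
                "sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e,
                "sigma2_ge": vc.sigma2_ge, "sigma2_eps": vc.sigma2_eps,
                "pct_g": pct["g"], "pct_e": pct["e"], "pct_ge": pct["ge"],
                "pct_eps": pct["eps"], "H2": vc.H2,
                **{f"lrt_p_{k}": v[1] for k, v in vc.lrt.items()},
            })
            blupsets[trait] = bl
        df = pd.DataFrame(rows)
        df.to_csv(out / "variance_components.tsv", sep="\t", index=False)
        for trait, bl in blupsets.items():
            bl.blup_g.to_csv(out / f"blup_g_{trait}.tsv", sep="\t")
            bl.blup_ge.to_csv(out / f"blup_ge_{trait}.tsv", sep="\t")
        summary["stages"]["anova"] = {"n_traits": len(rows)}
        return df, blupsets

    vc_table, blupsets = anova_out

    @stage("stability")
    def stab_out():
        # replicated traits get WAASB on BLUPge; accession-mean traits get
        # the AEC-ordinate projection on their mean table
        rows = {}
        for trait in rep_traits:
            w = stability.waasb(blupsets[trait].blup_ge)
            rows[trait] = w.waasb
        for trait in mean_traits:
            means = (met.trait(trait)
                     .groupby(["accession", "environment"])["value"]
                     .mean().unstack())
            rows[trait] = stability.gge_aec_stability(means).projection
        df = pd.DataFrame(rows)
        df.to_csv(out / "stability_indices.tsv", sep="\t")
        summary["stages"]["stability"] = {"n_traits": len(rows)}
        return df

    @stage("gwas")
    def gwas_out():
        empty = pd.DataFrame(columns=["marker_id", "trait", "analysis", "beta",
                                      "se", "p", "maf", "n", "note", "chrom",
                                      "pos", "pass_threshold"])
        if filtered.n_markers == 0:
            empty.to_csv(out / "associations.tsv", sep="\t", index=False)
            summary["stages"]["gwas"] = {"cutoff": None, "meff": 0,
                                         "n_tests": 0, "n_mtas": 0,
                                         "mta_classes": {"total": 0}}
            return empty, None
        K = association.kinship(filtered, variant="ibs_emma")
        cutoff, meff = association.significance_threshold(
            filtered, alpha=config.gwas_alpha)
        mtas = []
        for trait in rep_traits:
            res = association.gweis_two_stage(met, trait, filtered, K)
            stab_res = association.lmm_scan(
                stab_out[trait], filtered, K, trait=trait, analysis="stability")
            for r in list(res.values()) + [stab_res]:
                t = r.table.copy()
                t["pass_threshold"] = t["p"] < cutoff
                mtas.append(t)
        for trait in mean_traits:
            means = (met.trait(trait)
                     .groupby("accession")["value"].mean())
            for y, analysis in ((means, "mean"),
                                (stab_out[trait], "stability")):
                r = association.lmm_scan(y, filtered, K, trait=trait,
                                         analysis=analysis)
                t = r.table.copy()
                t["pass_threshold"] = t["p"] < cutoff
                mtas.append(t)
        all_scans = pd.concat(mtas, ignore_index=True)
        all_scans.to_csv(out / "associations.tsv", sep="\t", index=False)
        sig = all_scans[all_scans["pass_threshold"] == True]  # noqa: E712
        summary["stages"]["gwas"] = {
            "cutoff": cutoff, "meff": meff, "n_tests": int(len(all_scans)),
            "n_mtas": int(len(sig)),
            "mta_classes": association.summarize_mta_classes(sig).to_dict()
            if len(sig) else {"total": 0},
        }
        return sig, cutoff

    sig_mtas, cutoff = gwas_out

    @stage("qtl")
    def qtl_out():
        if sig_mtas.empty:
            summary["stages"]["qtl"] = {"n_loci": 0, "n_qtls": 0}
            return [], []
        baseline = config.r2_baseline
        regions = [
            qtl_regions.candidate_region(m, filtered, baseline,
                                         config.region_window_bp)
            for m in sig_mtas["marker_id"].unique()
        ]
        loci = qtl_regions.build_loci(regions, gap_bp=config.locus_gap_bp)
        qtls, coloc = qtl_regions.group_qtls(sig_mtas, loci)
        pd.DataFrame([
            {"locus": L.id, "chrom": L.chrom, "start0": L.start - 1,
             "end": L.end, "n_members": len(L.members)} for L in loci
        ]).to_csv(out / "loci.bed", sep="\t", index=False, header=False)
        pd.DataFrame([
            {"trait": q.trait, "class": q.analysis_class, "locus": q.locus_id,
             "n_mtas": len(q.member_mtas),
             "colocalization": q.colocalization} for q in qtls
        ]).to_csv(out / "qtls.tsv", sep="\t", index=False)
        summary["stages"]["qtl"] = {
            "n_loci": len(loci), "n_qtls": len(qtls),
            "colocalization": coloc.to_dict(),
        }
        return loci, qtls

    loci, qtls = qtl_out

    @stage("gene_action")
    def ga_out():
        rows = []
        maf = pd.Series(filtered.maf(), index=filtered.marker_ids)
        for _, row in sig_mtas.iterrows():
            trait = row["trait"]
            if trait not in blupsets:
                continue
            mcol = filtered.marker_ids.index(row["marker_id"])
            codes = pd.Series(filtered.codes[:, mcol],
                              index=filtered.accession_ids)
            resp = blupsets[trait].blup_g.reindex(codes.index)
            cm = gene_action.class_means(resp, codes,
                                         min_class_n=config.min_class_n)
            d = codes[codes != -1].astype(float)
            minor_code = 2 if (d.mean() / 2.0) <= 0.5 else 0
            res = gene_action.classify_mode(
                cm, marker=row["marker_id"], trait=trait,
                alpha=config.contrast_alpha, minor_hom_code=minor_code)
            rows.append({
                "marker_id": row["marker_id"], "trait": trait,
                "analysis": row["analysis"], "mode": res.mode,
                "a": res.a, "d": res.d, "direction": res.minor_direction,
                "maf": maf[row["marker_id"]],
            })
        df = pd.DataFrame(rows)
        if not df.empty:
            df.to_csv(out / "gene_action.tsv", sep="\t", index=False)
            counts = df["mode"].value_counts().to_dict()
        else:
            counts = {}
        summary["stages"]["gene_action"] = {"mode_counts": counts}
        return df

    @stage("haplotypes")
    def hap_out():
        n_blocks = 0
        for L in loci:
            if len(L.members) < 2:
                continue
            try:
                blocks = haplotypes.solid_spine_blocks(
                    filtered, markers=L.members,
                    dprime_threshold=config.dprime_threshold,
                    hwe_min_p=config.hwe_min_p)
            except ValueError:
                continue
            for b in blocks:
                haplotypes.assign_haplotypes(b, filtered, seed=config.seed)
                n_blocks += 1
        summary["stages"]["haplotypes"] = {"n_blocks": n_blocks}
        return n_blocks

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
    return summary


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
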