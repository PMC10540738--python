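"""Readers for genotype (VCF / CSV matrix / HapMap-like TSV) and phenotype
(long CSV) inputs."""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from metstab.io_cli.types import MISSING, GenotypeMatrix, METTable, TraitSpec

_MISSING_TOKENS = {".", "NA", "N", "-9", "", "nan", "NaN", "./.", ".|."}


class ParseError(ValueError):
    pass


def read_genotypes(path: str | Path, format: str = "vcf", strict: bool = True) -> GenotypeMatrix:
    """Read a genotype matrix.

    format: 'vcf' (uncompressed VCF 4.x, biallelic SNPs), 'matrix_csv'
    (rows = accessions, columns = markers, plus a sidecar-free inline map
    header, see :func:`metstab.io_cli.writers.write_genotypes`), or
    'hapmap_tsv'. ``strict`` raises on non-biallelic / half-call records;
    otherwise they are dropped.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path, strict=strict)
    if format == "matrix_csv":
        return _read_matrix_csv(path)
    if format == "hapmap_tsv":
        return _read_hapmap(path, strict=strict)
    raise ValueError(f"unknown genotype format {format!r}")


def _gt_to_code(gt: str) -> int:
    gt = gt.split(":", 1)[0]
    if gt in _MISSING_TOKENS:
        return MISSING
    alleles = gt.replace("|", "/").split("/")
    if len(alleles) != 2:
        raise ParseError(f"non-diploid genotype {gt!r}")
    if "." in alleles:
        return MISSING  # half-calls treated as missing when not strict
    try:
        return int(alleles[0] != "0") + int(alleles[1] != "0")
    except ValueError as exc:  # pragma: no cover
        raise ParseError(f"bad genotype {gt!r}") from exc


def _read_vcf(path: Path, strict: bool) -> GenotypeMatrix:
    accessions: list[str] = []
    marker_ids: list[str] = []
    rows: list[list[int]] = []
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ParseError(f"{path}:{lineno}: VCF has no sample columns")
                accessions = fields[9:]
                continue
            if not accessions:
                raise ParseError(f"{path}:{lineno}: record before #CHROM header")
            f = line.split("\t")
            if len(f) < 10:
                raise ParseError(f"{path}:{lineno}: truncated VCF record")
            chrom, pos, vid, ref, alt = f[0], f[1], f[2], f[3], f[4]
            if "," in alt or len(ref) != 1 or (len(alt) != 1 and alt != "."):
                if strict:
                    raise ParseError(f"{path}:{lineno}: non-biallelic-SNP record")
                continue
            fmt = f[8].split(":")
            if "GT" not in fmt:
                raise ParseError(f"{path}:{lineno}: no GT in FORMAT")
            gt_i = fmt.index("GT")
            try:
                codes = [
                    _gt_to_code(s.split(":")[gt_i] if ":" in s else s) for s in f[9:]
                ]
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if vid == ".":
                vid = f"{chrom}_{pos}"
            marker_ids.append(vid)
            rows.append(codes)
            chroms.append(chrom)
            poss.append(int(pos))
            refs.append(ref)
            alts.append(alt)
    if len(set(marker_ids)) != len(marker_ids):
        raise ParseError(f"{path}: duplicate marker ids")
    codes = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(accessions), 0), np.int8)
    mp = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
                      index=marker_ids)
    # sort by chromosome then position (stable, keeps file chrom order)
    order = _sort_order(mp)
    mp = mp.iloc[order]
    codes = codes[:, order]
    return GenotypeMatrix(accessions, list(mp.index), codes, mp)


def _sort_order(mp: pd.DataFrame) -> np.ndarray:
    chrom_rank = {c: i for i, c in enumerate(pd.unique(mp["chrom"]))}
    key = [(chrom_rank[c], p) for c, p in zip(mp["chrom"], mp["pos"])]
    return np.array(sorted(range(len(key)), key=lambda i: key[i]))


def _read_matrix_csv(path: Path) -> GenotypeMatrix:
    """CSV with three map header rows (#chrom/#pos/#ref-alt) then one row per
    accession; written by :func:`write_genotypes`."""
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    header_rows = [ln for ln in lines[:4] if ln.startswith("#")]
    if len(header_rows) != 3:
        raise ParseError(f"{path}: expected 3 '#' map header rows")
    body = "\n".join(ln for ln in lines if not ln.startswith("#"))
    df = pd.read_csv(io.StringIO(body), index_col=0, dtype=str)
    marker_ids = [str(c) for c in df.columns]
    hdr = {}
    for ln in header_rows:
        name, _, rest = ln[1:].partition(",")
        hdr[name] = rest.split(",")
    for k in ("chrom", "pos", "alleles"):
        if k not in hdr or len(hdr[k]) != len(marker_ids):
            raise ParseError(f"{path}: malformed map header row {k!r}")
    refs, alts = zip(*[a.split("/") for a in hdr["alleles"]]) if marker_ids else ((), ())
    codes = np.full(df.shape, MISSING, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, v in enumerate(df[col]):
            s = str(v).strip()
            codes[i, j] = MISSING if s in _MISSING_TOKENS else int(float(s))
    mp = pd.DataFrame(
        {"chrom": hdr["chrom"], "pos": [int(p) for p in hdr["pos"]],
         "ref": list(refs), "alt": list(alts)},
        index=marker_ids,
    )
    order = _sort_order(mp)
    return GenotypeMatrix([str(a) for a in df.index], list(mp.index[order]),
                          codes[:, order], mp.iloc[order])


def _read_hapmap(path: Path, strict: bool) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["rs#", "alleles", "chrom", "pos"]
    if [c for c in need if c not in df.columns]:
        raise ParseError(f"{path}: HapMap header must contain {need}")
    sample_cols = list(df.columns[11:]) if df.shape[1] > 11 else list(df.columns[4:])
    marker_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for _, rec in df.iterrows():
        try:
            ref, alt = str(rec["alleles"]).split("/")
        except ValueError:
            if strict:
                raise ParseError(f"{path}: bad alleles field {rec['alleles']!r}")
            continue
        codes = []
        for s in rec[sample_cols]:
            s = str(s).strip()
            if s in _MISSING_TOKENS or s == "NN":
                codes.append(MISSING)
            elif len(s) == 2:
                codes.append(int(s[0] != ref) + int(s[1] != ref))
            else:
                raise ParseError(f"{path}: bad HapMap call {s!r}")
        marker_ids.append(str(rec["rs#"]))
        chroms.append(str(rec["chrom"]))
        poss.append(int(rec["pos"]))
        refs.append(ref)
        alts.append(alt)
        rows.append(codes)
    if len(set(marker_ids)) != len(marker_ids):
        raise ParseError(f"{path}: duplicate marker ids")
    codes = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(sample_cols), 0), np.int8)
    mp = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
                      index=marker_ids)
    order = _sort_order(mp)
    return GenotypeMatrix(sample_cols, list(mp.index[order]), codes[:, order], mp.iloc[order])


def read_phenotypes(path: str | Path, trait_specs: dict[str, TraitSpec]) -> METTable:
    """Read a long-format phenotype CSV (accession, environment, replicate,
    trait, value) and validate against the trait specifications."""
    df = pd.read_csv(path, dtype={"accession": str, "environment": str, "trait": str})
    missing = [c for c in METTable.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: phenotype CSV missing columns {missing}")
    unknown = set(df["trait"]) - set(trait_specs)
    if unknown:
        raise ParseError(f"{path}: unknown traits {sorted(unknown)}")
    return METTable(data=df, trait_specs=dict(trait_specs))
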