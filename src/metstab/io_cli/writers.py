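"""Writers mirroring the readers; read -> write -> read is lossless for
codes, map, and identifiers."""

from __future__ import annotations

from pathlib import Path

from metstab.io_cli.types import MISSING, GenotypeMatrix, METTable


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "vcf") -> None:
    path = Path(path)
    if format == "vcf":
        _write_vcf(g, path)
    elif format == "matrix_csv":
        _write_matrix_csv(g, path)
    elif format == "hapmap_tsv":
        _write_hapmap(g, path)
    else:
        raise ValueError(f"unsupported output format {format!r}")


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.accession_ids) + "\n")
        for j, mid in enumerate(g.marker_ids):
            rec = g.map.iloc[j]
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in g.codes[:, j])
            fh.write(f"{rec['chrom']}\t{rec['pos']}\t{mid}\t{rec.get('ref', 'A')}\t"
                     f"{rec.get('alt', 'T')}\t.\tPASS\t.\tGT\t{gts}\n")


def _write_matrix_csv(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom," + ",".join(map(str, g.map["chrom"])) + "\n")
        fh.write("#pos," + ",".join(map(str, g.map["pos"])) + "\n")
        alleles = [f"{r}/{a}" for r, a in zip(g.map.get("ref", ["A"] * g.n_markers),
                                             g.map.get("alt", ["T"] * g.n_markers))]
        fh.write("#alleles," + ",".join(alleles) + "\n")
        fh.write("accession," + ",".join(g.marker_ids) + "\n")
        for i, acc in enumerate(g.accession_ids):
            row = ["NA" if c == MISSING else str(int(c)) for c in g.codes[i]]
            fh.write(acc + "," + ",".join(row) + "\n")


_HAPMAP_FILLER = ("+", "NA", "NA", "NA", "NA", "NA", "NA")


def _write_hapmap(g: GenotypeMatrix, path: Path) -> None:
    header = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
              "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]
    with open(path, "w") as fh:
        fh.write("\t".join(header + g.accession_ids) + "\n")
        for j, mid in enumerate(g.marker_ids):
            rec = g.map.iloc[j]
            ref, alt = rec.get("ref", "A"), rec.get("alt", "T")
            calls = {0: ref + ref, 1: ref + alt, 2: alt + alt, MISSING: "NN"}
            row = [mid, f"{ref}/{alt}", str(rec["chrom"]), str(rec["pos"]),
                   *_HAPMAP_FILLER,
                   *(calls[int(c)] for c in g.codes[:, j])]
            fh.write("\t".join(row) + "\n")


def write_phenotypes(met: METTable, path: str | Path) -> None:
    met.data.to_csv(path, index=False, na_rep="NA")
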