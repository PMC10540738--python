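# metstab

Multi-environment-trial (MET) stability genetics in Python: variance
decomposition and heritability for replicated trials, WAASB and GGE/AEC
stability indices, kinship-corrected single-marker mixed-model GWAS and
two-stage GWEIS, LD-based candidate-region/locus/QTL construction,
inheritance-mode and QTL-by-environment-interaction typing, solid-spine
haplotype-block association, and diversity/core-collection tooling — all
exercisable end-to-end on a built-in synthetic data generator, so no external
downloads are needed.

## Package layout

| module | contents |
|---|---|
| `metstab.io_cli` | genotype/phenotype data model, VCF / CSV-matrix / HapMap readers and writers, YAML config, pipeline driver, CLI |
| `metstab.synthetic_data` | blockwise-LD genotype simulator, MET phenotype generator with planted QTLs (gene action + environment-response profiles), latent-threshold qualitative traits |
| `metstab.met_models` | REML variance components (mu fixed; G, E, GxE random), BLUPg/BLUPge from the environment-fixed parametrization, broad-sense H², LRT of components, fixed-effects two-way ANOVA |
| `metstab.stability` | WAASB from the SVD of BLUPge, AEC-ordinate projection from the GGE decomposition, mean-stability correlation screen |
| `metstab.association` | SNP/accession filters, IBS and centered-IBS kinship, exact per-marker mixed-model scan, two-stage GWEIS, Li-Ji effective-number-of-tests threshold |
| `metstab.qtl_regions` | inter-chromosomal r² baseline, candidate regions (<2 Mb window), locus merging (100 kb), QTL grouping and colocalization labels |
| `metstab.gene_action` | allelic-class means, additive/dominant/recessive/overdominant contrasts, a and d genotypic values, QTI typing (QTL3/4/5), QTL-level consensus |
| `metstab.haplotypes` | EM-based D' and r², solid-spine blocks with Haploview-style filters, haplotype assignment, two-way ANOVA and chi-square haplotype association |
| `metstab.diversity_core` | per-site pi, MAF, PCoA/MDS, mixed-strategy core selection (maximin + phenotypic extremes + geographic fill), representativeness diagnostics |

## CLI

```bash
metstab --seed 1 --out results simulate --n-accessions 200 --n-snps 3000
metstab --seed 1 --out results run results/genotypes.vcf results/phenotypes.csv
```

Subcommands: `simulate`, `filter`, `anova`, `stability`, `gwas`, `gweis`,
`qtl`, `gene-action`, `haplotypes`, `core-select`, `run`. Global flags:
`--config <yaml>`, `--seed`, `--out`, `--log-level`. All analysis thresholds
(MAF ≥ 0.05, ≤25% missingness, heterozygosity < 5%, r² baseline 0.4456,
<2 Mb windows, 100 kb locus gap, ...) live in the config with sensible
defaults and can be overridden from a YAML file.

## Python example

```python
from metstab.synthetic_data import ScenarioSpec, gen_genotypes, gen_met_phenotypes, planted_qtl
from metstab.io_cli.types import RunConfig
from metstab.io_cli.pipeline import run_pipeline

sc = ScenarioSpec(n_accessions=200, n_snps=3000, seed=1,
                  planted_qtls=[planted_qtl(50, "trait1", 1.5, "additive", (1, 1, 1, 1))])
g = gen_genotypes(sc)
met, truth = gen_met_phenotypes(g, sc)
summary = run_pipeline(g, met, RunConfig(seed=1), out_dir="results")
```

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: printed-count
consistency of the summary reporters, literal-formula oracle equivalence for
WAASB/AEC/the mixed-model scan/Meff/D', REML parameter recovery on balanced
simulations, gene-action and QTI-type recovery from planted truth, error
control (null-GWAS type I, GWEIS negative control, representativeness null
rate), and stability-ranking validity. The full suite takes a few minutes on
one CPU.

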