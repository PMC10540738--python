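import numpy as np
import pandas as pd
import pytest

from metstab.io_cli.types import GenotypeMatrix, METTable, TraitSpec
from metstab.synthetic_data import ScenarioSpec, gen_genotypes, gen_met_phenotypes


def make_genotypes(codes, chrom=None, pos=None, acc=None, mid=None):
    """Small helper to build a GenotypeMatrix from a raw code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    acc = acc or [f"a{i}" for i in range(n)]
    mid = mid or [f"m{j}" for j in range(m)]
    chrom = chrom or ["chr1"] * m
    pos = pos if pos is not None else list(range(1000, 1000 + 1000 * m, 1000))
    mp = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "T"},
                      index=mid)
    return GenotypeMatrix(acc, mid, codes, mp)


@pytest.fixture(scope="session")
def small_scenario():
    return ScenarioSpec(n_accessions=80, n_snps=120, n_chromosomes=3,
                        snp_missing_rate=0.02, seed=42)


@pytest.fixture(scope="session")
def small_genotypes(small_scenario):
    return gen_genotypes(small_scenario)


@pytest.fixture(scope="session")
def small_met(small_scenario, small_genotypes):
    met, truth = gen_met_phenotypes(small_genotypes, small_scenario)
    return met


@pytest.fixture()
def met_factory():
    """Build a METTable for one replicated trait from a (g, e, k) value
    array."""

    def build(y, trait="t", envs=None):
        y = np.asarray(y, dtype=float)
        n, e, k = y.shape
        envs = envs or [f"E{j+1}" for j in range(e)]
        recs = {
            "accession": np.repeat([f"a{i}" for i in range(n)], e * k),
            "environment": np.tile(np.repeat(envs, k), n),
            "replicate": np.tile(np.arange(1, k + 1), n * e),
            "trait": trait,
            "value": y.ravel(),
        }
        return METTable(pd.DataFrame(recs),
                        {trait: TraitSpec(trait, "replicated_quantitative")},
                        max_replicates=k)

    return build
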