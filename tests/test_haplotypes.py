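import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metstab.haplotypes import (assign_haplotypes, dprime, frequency_class,
                                haplotype_anova, haplotype_chisq, hwe_pvalue,
                                solid_spine_blocks)
from metstab.io_cli.types import MISSING
from metstab.synthetic_data import ScenarioSpec, gen_genotypes

from conftest import make_genotypes


class TestDprime:
    def test_complete_association(self):
        # only cis haplotypes (ref-ref / alt-alt), including double hets
        x = np.array([0, 0, 2, 2, 1, 1, 0, 2])
        y = np.array([0, 0, 2, 2, 1, 1, 0, 2])
        dp, r2 = dprime(x, y)
        assert dp == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_counting_oracle_homozygotes_only(self):
        rng = np.random.default_rng(0)
        x = rng.choice([0, 2], size=200)
        y = np.where(rng.random(200) < 0.8, x, rng.choice([0, 2], size=200))
        dp, r2 = dprime(x, y)
        # direct haplotype counting (phase known for homozygotes)
        n = len(x)
        p11 = ((x == 2) & (y == 2)).mean()
        q1 = (x == 2).mean()
        q2 = (y == 2).mean()
        D = p11 - q1 * q2
        dmax = min(q1 * (1 - q2), (1 - q1) * q2) if D >= 0 else \
            min(q1 * q2, (1 - q1) * (1 - q2))
        assert dp == pytest.approx(abs(D) / dmax, abs=1e-4)
        assert r2 == pytest.approx(D**2 / (q1 * (1 - q1) * q2 * (1 - q2)),
                                   abs=1e-4)

    def test_independent_markers_near_zero(self):
        rng = np.random.default_rng(1)
        dps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.binomial(2, 0.5, size=2000)
            y = rng.binomial(2, 0.5, size=2000)
            dps.append(dprime(x, y)[0])
        assert np.mean(dps) < 0.1

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            dprime(np.zeros(10), np.array([0, 2] * 5))

    def test_dprime_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.choice([0, 1, 2], size=100)
            y = rng.choice([0, 1, 2], size=100)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            dp, r2 = dprime(x, y)
            assert 0.0 <= dp <= 1.0
            assert 0.0 <= r2 <= 1.0


class TestHWE:
    def test_equilibrium_accepted(self):
        rng = np.random.default_rng(3)
        codes = rng.binomial(2, 0.4, size=80)
        assert hwe_pvalue(codes) > 0.001

    def test_het_deficit_rejected(self):
        codes = np.array([0] * 40 + [2] * 40)  # no hets at p=0.5
        assert hwe_pvalue(codes) < 1e-6

    def test_chi2_branch_large_n(self):
        rng = np.random.default_rng(4)
        codes = rng.binomial(2, 0.3, size=500)
        assert hwe_pvalue(codes) > 0.001


class TestSolidSpine:
    def _hwe_genotypes(self, seed=5, **kw):
        sc = ScenarioSpec(n_accessions=120, n_snps=kw.pop("n_snps", 12),
                          n_chromosomes=1, hwe_mode=True, snp_missing_rate=0,
                          block_r2=kw.pop("block_r2", 0.95),
                          block_len_mean=kw.pop("block_len_mean", 12),
                          seed=seed, **kw)
        return gen_genotypes(sc)

    def test_complete_ld_single_block(self):
        rng = np.random.default_rng(6)
        hap = rng.binomial(1, 0.4, size=(150, 2))  # two gametes
        col = (hap[:, 0] + hap[:, 1]).astype(np.int8)
        codes = np.column_stack([col, col, col])
        g = make_genotypes(codes)
        blocks = solid_spine_blocks(g)
        assert len(blocks) == 1
        assert blocks[0].marker_ids == ["m0", "m1", "m2"]

    def test_broken_spine_splits(self):
        rng = np.random.default_rng(7)
        hap = rng.binomial(1, 0.4, size=(200, 2))
        col = (hap[:, 0] + hap[:, 1]).astype(np.int8)
        other = rng.binomial(2, 0.5, size=200).astype(np.int8)
        codes = np.column_stack([col, col, other, other])
        g = make_genotypes(codes)
        blocks = solid_spine_blocks(g)
        got = [b.marker_ids for b in blocks]
        assert ["m0", "m1"] in got
        # m2/m3 are identical so they form their own block
        assert ["m2", "m3"] in got

    def test_matches_exhaustive_oracle(self):
        g = self._hwe_genotypes(seed=8, n_snps=10)
        blocks = solid_spine_blocks(g, dprime_threshold=0.8)

        def dp(i, j):
            return dprime(g.codes[:, i], g.codes[:, j])[0]

        # oracle: greedy maximal runs with the solid-spine criterion
        def spine_ok(run):
            f, l = run[0], run[-1]
            return all(dp(f, m) >= 0.8 for m in run[1:]) and \
                all(dp(l, m) >= 0.8 for m in run[:-1])

        expected = []
        start = 0
        while start < g.n_markers:
            best = start
            for end in range(start + 1, g.n_markers):
                if spine_ok(list(range(start, end + 1))):
                    best = end
            if best > start:
                expected.append([g.marker_ids[i] for i in range(start, best + 1)])
                start = best + 1
            else:
                start += 1
        assert [b.marker_ids for b in blocks] == expected

    def test_filters_exclude_markers(self):
        rng = np.random.default_rng(9)
        good = rng.binomial(2, 0.4, size=(100, 2)).astype(np.int8)
        rare = np.zeros((100, 1), dtype=np.int8)       # MAF 0 < 0.001
        codes = np.column_stack([good, rare])
        g = make_genotypes(codes)
        with pytest.raises(ValueError):
            solid_spine_blocks(g, maf_min=0.5)  # everything fails


class TestAssignment:
    def test_homozygous_two_copies(self):
        codes = np.array([[0, 0], [2, 2], [0, 2]], dtype=np.int8)
        g = make_genotypes(codes)
        from metstab.haplotypes import HaplotypeBlock
        b = HaplotypeBlock("chr1", ["m0", "m1"], [0, 1])
        out = assign_haplotypes(b, g)
        assert out.loc[0, "hap1"] == out.loc[0, "hap2"] == "00"
        assert out.loc[1, "hap1"] == out.loc[1, "hap2"] == "11"
        assert out.loc[2, "hap1"] == "01" or out.loc[2, "hap2"] == "01"

    def test_single_het_one_copy_each(self):
        codes = np.array([[1, 0], [0, 0], [2, 0]], dtype=np.int8)
        g = make_genotypes(codes)
        from metstab.haplotypes import HaplotypeBlock
        b = HaplotypeBlock("chr1", ["m0", "m1"], [0, 1])
        out = assign_haplotypes(b, g)
        assert sorted([out.loc[0, "hap1"], out.loc[0, "hap2"]]) == ["00", "10"]

    def test_phased_truth_accuracy(self):
        """Simulated gamete-level truth: assignment accuracy > 95% at low
        het rate."""
        rng = np.random.default_rng(10)
        n, m = 150, 5
        base = rng.binomial(1, 0.4, size=n)
        gam = np.empty((2, n, m), dtype=int)
        for s in range(2):
            for j in range(m):
                copy = rng.random(n) < 0.97
                gam[s, :, j] = np.where(copy, base, rng.binomial(1, 0.4, n))
        # inbred-like: gamete 2 mostly equals gamete 1
        dup = rng.random(n) < 0.9
        gam[1, dup] = gam[0, dup]
        codes = (gam[0] + gam[1]).astype(np.int8)
        g = make_genotypes(codes)
        from metstab.haplotypes import HaplotypeBlock
        b = HaplotypeBlock("chr1", [f"m{j}" for j in range(m)], list(range(m)))
        out = assign_haplotypes(b, g)
        truth = {"".join(map(str, gam[0, i])) for i in range(n)}
        ok = 0
        tot = 0
        for i, row in out.iterrows():
            if not row["assigned"]:
                continue
            tot += 1
            t1 = "".join(map(str, gam[0, i]))
            t2 = "".join(map(str, gam[1, i]))
            if {row["hap1"], row["hap2"]} == {t1, t2}:
                ok += 1
        assert tot > 0.8 * n
        assert ok / tot > 0.95


def test_frequency_classes():
    assert frequency_class(0.2) == "major"
    assert frequency_class(0.10) == "minor"     # boundary: not > 10%
    assert frequency_class(0.05) == "minor"
    assert frequency_class(0.005) == "rare"
    assert frequency_class(0.01) == "minor"     # boundary: not < 1%


class TestAnova:
    def _data(self, effect, seed=0, n=100):
        rng = np.random.default_rng(seed)
        hap = pd.Series(rng.choice(["H1", "X"], size=2 * n))
        coll = pd.Series(["C1"] * n + ["C2"] * n)
        y = pd.Series(rng.normal(size=2 * n) + effect * (hap == "H1"))
        return y, hap, coll

    def test_null_not_significant(self):
        ps = []
        for seed in range(10):
            y, hap, coll = self._data(0.0, seed=seed)
            res = haplotype_anova(y, hap, coll)
            ps.append(res.anova.loc["C(hap)", "PR(>F)"])
        assert (np.array(ps) < 0.05).mean() <= 0.3

    def test_planted_effect_detected(self):
        hits = 0
        for seed in range(10):
            y, hap, coll = self._data(1.0, seed=100 + seed)
            res = haplotype_anova(y, hap, coll)
            if res.anova.loc["C(hap)", "PR(>F)"] < 0.05:
                hits += 1
        assert hits >= 9

    def test_tukey_letters_agree_with_bonferroni(self):
        rng = np.random.default_rng(11)
        y = pd.Series(np.concatenate([
            rng.normal(0, 0.3, 40), rng.normal(3, 0.3, 40),
            rng.normal(6, 0.3, 40)]))
        hap = pd.Series(["A"] * 40 + ["B"] * 40 + ["C"] * 40)
        coll = pd.Series(["C1"] * 120)
        res = haplotype_anova(y, hap, coll)
        letters = res.tukey_letters
        # clearly separated: all three cells get distinct letters
        assert len({letters[k] for k in letters}) == 3
        # Bonferroni all-pairs t-tests agree on separation
        for a, b in (("A", "B"), ("B", "C"), ("A", "C")):
            t, p = stats.ttest_ind(y[hap == a], y[hap == b])
            assert p * 3 < 0.05


class TestChisq:
    def test_hand_computed_2x2(self):
        cat = pd.Series(["x"] * 60 + ["y"] * 60)
        hap = pd.Series(["H"] * 50 + ["X"] * 10 + ["H"] * 10 + ["X"] * 50)
        res = haplotype_chisq(cat, hap)
        tab = np.array([[50, 10], [10, 50]])
        n = tab.sum()
        exp = np.outer(tab.sum(1), tab.sum(0)) / n
        chi2 = ((tab - exp) ** 2 / exp).sum()
        assert res.chi2[0] == pytest.approx(chi2, abs=1e-9)
        rowp = tab.sum(1) / n
        colp = tab.sum(0) / n
        d = (tab - exp) / np.sqrt(exp * (1 - rowp)[:, None] * (1 - colp)[None, :])
        assert np.allclose(res.residuals.to_numpy(), d, atol=1e-9)

    def test_null_p_uniformish(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            cat = pd.Series(rng.choice(["x", "y"], size=200))
            hap = pd.Series(rng.choice(["H", "X"], size=200))
            res = haplotype_chisq(cat, hap)
            ps.append(res.chi2[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_table(self):
        cat = pd.Series(["x"] * 20)
        hap = pd.Series(["H", "X"] * 10)
        res = haplotype_chisq(cat, hap)
        assert res.chi2 is None
        assert "undefined" in res.note
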