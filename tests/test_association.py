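import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metstab.association import (filter_snps, gweis_two_stage, kinship,
                                 li_ji_meff, lmm_scan, significance_threshold,
                                 stage1_effects, summarize_mta_classes)
from metstab.io_cli.types import MISSING
from metstab.synthetic_data import (ScenarioSpec, gen_genotypes,
                                    gen_met_phenotypes, planted_qtl)

from conftest import make_genotypes


class TestFilter:
    def _fixture(self):
        """10 accessions x 6 markers with exactly one violation per rule."""
        rng = np.random.default_rng(0)
        codes = rng.choice([0, 2], size=(10, 6), p=[0.6, 0.4]).astype(np.int8)
        codes[0, :3] = MISSING          # accession 0: 50% missing -> dropped
        codes[1:, 1] = [MISSING, MISSING, MISSING, 0, 0, 0, 0, 0, 2]
        # marker 1 after dropping acc0: 3/9 = 33% missing -> dropped
        codes[1:, 2] = [0] * 9          # marker 2: monomorphic, MAF 0 -> dropped
        codes[1:, 3] = [1, 0, 2, 0, 2, 0, 2, 0, 2]  # marker 3: 11% het -> dropped
        codes[1:, 4] = [0, 2, 0, 2, 0, 2, 0, 2, 0]
        codes[1:, 5] = [2, 0, 2, 0, 2, 0, 2, 0, 2]
        return make_genotypes(codes)

    def test_hand_enumerated_fixture(self):
        g = self._fixture()
        out, rep = filter_snps(g)
        assert rep.accessions_removed_missing == 1
        assert rep.markers_removed_missing == 1
        assert rep.markers_removed_maf == 1
        assert rep.markers_removed_het == 1
        assert out.n_accessions == 9
        assert set(out.marker_ids) <= {"m0", "m4", "m5"}

    def test_missing_30pct_marker_removed(self):
        codes = np.zeros((10, 10), dtype=np.int8)
        codes[:, :9] = np.tile([0, 2] * 5, (9, 1)).T
        codes[:3, 9] = MISSING          # marker 9: 30% missing
        codes[3:, 9] = [0, 2] * 3 + [0]
        g = make_genotypes(codes)
        out, rep = filter_snps(g)
        assert rep.markers_removed_missing == 1

    def test_maf_boundary_kept(self):
        # 10 accessions: one alt hom -> MAF 0.1; and one with exactly 0.05
        codes = np.zeros((20, 2), dtype=np.int8)
        codes[:10, 0] = [2] + [0] * 9   # MAF .1 -> kept
        codes[0, 1] = 1                 # single het among 20 -> MAF 1/40=0.025
        g = make_genotypes(codes)
        out, rep = filter_snps(g, het_max=1.0)
        assert "m0" in out.marker_ids and "m1" not in out.marker_ids
        codes2 = np.zeros((10, 1), dtype=np.int8)
        codes2[0, 0] = 1                # MAF 0.05 exactly -> retained
        out2, _ = filter_snps(make_genotypes(codes2), het_max=1.0)
        assert out2.n_markers == 1

    def test_empty_result_errors(self):
        g = self._fixture()
        with pytest.raises(ValueError):
            filter_snps(g, maf_min=0.9)


class TestKinship:
    def test_identical_and_opposite(self):
        codes = np.array([[0, 2, 0, 2], [0, 2, 0, 2], [2, 0, 2, 0]],
                         dtype=np.int8)
        K = kinship(make_genotypes(codes), "ibs_emma")
        assert K.values[0, 1] == pytest.approx(1.0)
        assert K.values[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(K.values), 1.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        codes = rng.choice([0, 1, 2, MISSING], size=(5, 8),
                           p=[0.4, 0.1, 0.4, 0.1]).astype(np.int8)
        g = make_genotypes(codes)
        K = kinship(g, "ibs_emma").values
        for i, j in itertools.product(range(5), range(5)):
            vals = []
            for m in range(8):
                a, b = codes[i, m], codes[j, m]
                if a == MISSING or b == MISSING:
                    continue
                vals.append(1.0 - abs(int(a) - int(b)) / 2.0)
            assert K[i, j] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_centered_ibs_psd(self):
        sc = ScenarioSpec(n_accessions=40, n_snps=60, seed=4)
        g = gen_genotypes(sc)
        K = kinship(g, "centered_ibs").values
        w = np.linalg.eigvalsh(K)
        assert w.min() > -1e-8

    def test_zero_shared_markers_error(self):
        codes = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        with pytest.raises(ValueError):
            kinship(make_genotypes(codes), "ibs_emma")


class TestLmmScan:
    def test_identity_kinship_equals_ols(self):
        rng = np.random.default_rng(2)
        sc = ScenarioSpec(n_accessions=60, n_snps=25, snp_missing_rate=0,
                          seed=11)
        g = gen_genotypes(sc)
        y = pd.Series(rng.normal(size=60), index=g.accession_ids)
        K = kinship(g, "ibs_emma")
        K.values = np.eye(60)
        res = lmm_scan(y, g, K).table
        for _, row in res.iterrows():
            if row["note"]:
                continue
            x = g.dosage(impute=True)[:, g.marker_ids.index(row["marker_id"])]
            sl, ic, r, p_ols, se = stats.linregress(x, y.to_numpy())
            assert row["p"] == pytest.approx(p_ols, abs=1e-8)
            assert row["beta"] == pytest.approx(sl, abs=1e-8)

    def test_affine_invariance(self):
        sc = ScenarioSpec(n_accessions=50, n_snps=15, seed=12)
        g = gen_genotypes(sc)
        K = kinship(g)
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=50), index=g.accession_ids)
        p1 = lmm_scan(y, g, K).table["p"]
        p2 = lmm_scan(3.0 * y + 7.0, g, K).table["p"]
        assert np.allclose(p1.dropna(), p2.dropna(), atol=1e-6)

    def test_duplicated_marker_leaves_others_unchanged(self):
        sc = ScenarioSpec(n_accessions=40, n_snps=10, snp_missing_rate=0,
                          seed=13)
        g = gen_genotypes(sc)
        K = kinship(g)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=40), index=g.accession_ids)
        base = lmm_scan(y, g, K).table.set_index("marker_id")["p"]
        codes2 = np.column_stack([g.codes, g.codes[:, 0]])
        g2 = make_genotypes(codes2, chrom=["chr1"] * 11,
                            pos=list(range(1000, 12000, 1000)),
                            acc=g.accession_ids,
                            mid=g.marker_ids + ["dup"])
        dup = lmm_scan(y, g2, K).table.set_index("marker_id")["p"]
        for m in g.marker_ids:
            if np.isfinite(base[m]):
                assert dup[m] == pytest.approx(base[m], abs=1e-10)

    def test_constant_response_warns(self):
        sc = ScenarioSpec(n_accessions=30, n_snps=5, seed=14)
        g = gen_genotypes(sc)
        K = kinship(g)
        y = pd.Series(np.ones(30), index=g.accession_ids)
        res = lmm_scan(y, g, K)
        assert res.warnings
        assert (res.table["p"].dropna() == 1.0).all()

    def test_structured_simulation_inflation_controlled(self):
        """Two subpopulations with a phenotype shift: kinship model keeps the
        genomic inflation factor low while naive OLS inflates."""
        sc = ScenarioSpec(n_accessions=120, n_snps=300, n_subpopulations=2,
                          subpop_shift=0.35, snp_missing_rate=0, seed=15)
        g = gen_genotypes(sc)
        rng = np.random.default_rng(5)
        y = pd.Series(g.subpopulations * 1.5 + rng.normal(size=120),
                      index=g.accession_ids)
        K = kinship(g, "ibs_emma")
        p_lmm = lmm_scan(y, g, K).table["p"].dropna().to_numpy()
        d = g.dosage(impute=True)
        p_ols = np.array([
            stats.linregress(d[:, j], y.to_numpy()).pvalue
            for j in range(g.n_markers) if d[:, j].std() > 0
        ])

        def gif(p):
            chi = stats.chi2.isf(np.clip(p, 1e-300, 1), 1)
            return np.median(chi) / stats.chi2.isf(0.5, 1)

        assert gif(p_lmm) <= 1.15
        assert gif(p_ols) > 1.3

    def test_power_monotone_in_effect(self):
        pvals = {}
        for a in (0.25, 0.5, 1.0):
            ps = []
            for seed in range(5):
                sc = ScenarioSpec(n_accessions=150, n_snps=10,
                                  snp_missing_rate=0, sigma2_g=0.5,
                                  sigma2_eps=0.5, seed=300 + seed,
                                  planted_qtls=[planted_qtl(
                                      2, "trait1", a, "additive", (1, 1, 1, 1))])
                g = gen_genotypes(sc)
                met, _ = gen_met_phenotypes(g, sc)
                means, _ = stage1_effects(met, "trait1")
                K = kinship(g)
                t = lmm_scan(means, g, K).table
                ps.append(t.set_index("marker_id")["p"].iloc[2])
            pvals[a] = np.median(ps)
        assert pvals[1.0] <= pvals[0.5] <= pvals[0.25]


class TestGweis:
    def test_stage1_sum_zero_on_balanced(self, met_factory):
        rng = np.random.default_rng(6)
        met = met_factory(rng.normal(size=(12, 4, 3)))
        means, ge = stage1_effects(met, "t")
        assert np.allclose(ge.sum(axis=1), 0.0, atol=1e-10)
        assert np.allclose(ge.sum(axis=0), 0.0, atol=1e-10)

    def test_no_gei_negative_control(self):
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            sc = ScenarioSpec(n_accessions=100, n_snps=60, sigma2_ge=0.0,
                              snp_missing_rate=0, seed=500 + seed)
            g = gen_genotypes(sc)
            met, _ = gen_met_phenotypes(g, sc)
            K = kinship(g)
            cutoff, _ = significance_threshold(g, alpha=0.05)
            res = gweis_two_stage(met, "trait1", g, K)
            n_sig = sum(int((r.table["p"].dropna() < cutoff).sum())
                        for k, r in res.items() if k.startswith("gei"))
            if n_sig > 0:
                hits += 1
        assert hits <= 2

    def test_conditional_neutral_power(self):
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            sc = ScenarioSpec(n_accessions=200, n_snps=30, sigma2_g=0.5,
                              sigma2_ge=0.25, sigma2_eps=0.5,
                              snp_missing_rate=0, het_rate=0,
                              seed=700 + seed,
                              planted_qtls=[planted_qtl(
                                  5, "trait1", 1.0, "additive", (1, 0, 0, 0))])
            g = gen_genotypes(sc)
            met, _ = gen_met_phenotypes(g, sc)
            K = kinship(g)
            cutoff, _ = significance_threshold(g, alpha=0.05)
            res = gweis_two_stage(met, "trait1", g, K)
            p_e1 = res["gei:E1"].table.set_index("marker_id")["p"].iloc[5]
            if p_e1 < cutoff:
                hits += 1
        assert hits / n_seeds > 0.8


class TestThreshold:
    def _orthogonal_genotypes(self, k):
        """2^k accessions, k mutually orthogonal 0/2 dosage columns."""
        n = 2**k
        codes = np.zeros((n, k), dtype=np.int8)
        for j in range(k):
            codes[:, j] = [2 if (i >> j) & 1 else 0 for i in range(n)]
        return make_genotypes(codes)

    def test_orthogonal_meff_equals_m(self):
        g = self._orthogonal_genotypes(4)
        cutoff, meff = significance_threshold(g, alpha=0.05)
        assert meff == pytest.approx(4.0, abs=1e-8)
        assert cutoff == pytest.approx(1 - 0.95 ** (1 / 4), abs=1e-12)

    def test_duplicated_meff_m_over_2(self):
        g = self._orthogonal_genotypes(3)
        codes = np.repeat(g.codes, 2, axis=1)
        g2 = make_genotypes(codes, pos=list(range(1000, 7000, 1000)))
        _, meff = significance_threshold(g2)
        assert meff == pytest.approx(3.0, abs=1e-8)

    def test_single_marker(self):
        g = make_genotypes(np.array([[0], [2], [0], [2]], dtype=np.int8))
        cutoff, meff = significance_threshold(g, alpha=0.05)
        assert meff == 1.0 and cutoff == pytest.approx(0.05)

    def test_ld_fixture_matches_eigen_oracle(self):
        sc = ScenarioSpec(n_accessions=80, n_snps=50, n_chromosomes=1,
                          snp_missing_rate=0, seed=21)
        g = gen_genotypes(sc)
        _, meff = significance_threshold(g)
        d = g.dosage()
        d = d[:, d.std(axis=0) > 0]
        lam = np.linalg.eigvalsh(np.corrcoef(d, rowvar=False))
        oracle = sum((1.0 if l >= 1 else 0.0) + (l - np.floor(l))
                     for l in np.clip(lam, 0, None))
        assert meff == pytest.approx(oracle, abs=1e-8)

    def test_bonferroni_flag(self):
        g = self._orthogonal_genotypes(3)
        cutoff, meff = significance_threshold(g, alpha=0.05,
                                              method="bonferroni")
        assert cutoff == pytest.approx(0.05 / 3)


def test_summarize_mta_classes():
    df = pd.DataFrame({"analysis": ["mean"] * 3 + ["stability"] * 2
                       + ["gei:E1", "gei:E2"]})
    s = summarize_mta_classes(df)
    assert s["mean"] == 3 and s["stability"] == 2 and s["gei"] == 2
    assert s["total"] == 7
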