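import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stresshap.genotypes import GenotypeMatrix
from stresshap.kinship import KinshipMatrix, compute_kinship
from stresshap.mtmm import (MtmmFit, QTLRegion, build_trait_vectors,
                            fit_mtmm_varcomp, gls_f_tests, ld_r2,
                            regions_to_bed, select_qtl_regions)

TRAITS = ["Drought", "P_rapae", "Drought_Pieris", "Botrytis_Pieris",
          "P_xylostella", "F_occidentalis", "M_persicae"]


def _geno(calls, positions=None, chrom="1"):
    n, m = calls.shape
    markers = pd.DataFrame(
        {"marker_id": [f"m{j}" for j in range(m)],
         "chromosome": chrom,
         "position": positions if positions is not None
         else np.arange(1, m + 1)})
    return GenotypeMatrix([f"a{i}" for i in range(n)], markers, calls)


class TestTraitVectors:
    def _responses(self, data):
        return pd.DataFrame(data, columns=TRAITS)

    def test_perfectly_correlated_group_explains_everything(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=100)
        df = pd.DataFrame({t: rng.normal(size=100) for t in TRAITS})
        for t in ["P_rapae", "P_xylostella", "Drought_Pieris",
                  "Botrytis_Pieris"]:
            df[t] = base * {"P_rapae": 1.0, "P_xylostella": 2.0,
                            "Drought_Pieris": -1.0,
                            "Botrytis_Pieris": 0.5}[t]
        tv = build_trait_vectors(df)
        assert tv.explained_fraction_p1 == pytest.approx(1.0, abs=1e-10)

    def test_independent_columns_limit(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({t: rng.normal(size=2000) for t in TRAITS})
        tv = build_trait_vectors(df)
        assert tv.explained_fraction_p1 == pytest.approx(0.25, abs=0.05)

    def test_composites_standardized_and_sign_fixed(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({t: rng.normal(size=300) for t in TRAITS})
        tv = build_trait_vectors(df)
        assert tv.p1.std(ddof=1) == pytest.approx(1.0)
        assert tv.p2.std(ddof=1) == pytest.approx(1.0)
        # sign convention: positive correlation with the group mean
        Z = (df[["F_occidentalis", "M_persicae", "Drought"]]
             .apply(lambda c: (c - c.mean()) / c.std()))
        assert np.corrcoef(tv.p2, Z.mean(axis=1))[0, 1] > 0

    def test_too_few_accessions(self):
        df = pd.DataFrame({t: [1.0, 2.0] for t in TRAITS})
        with pytest.raises(ValueError, match="at least 3"):
            build_trait_vectors(df)


class TestVarcomp:
    @pytest.fixture(scope="class")
    def panel(self):
        from stresshap.simulate import SimulationTruth, simulate_genotypes_ibd
        geno, _ = simulate_genotypes_ibd(
            SimulationTruth(seed=2, n_accessions=300, n_markers=2000))
        return compute_kinship(geno)

    def test_duplicated_trait_fully_correlated(self, panel):
        rng = np.random.default_rng(3)
        L = np.linalg.cholesky(panel.K + 1e-8 * np.eye(panel.n))
        p1 = L @ rng.standard_normal(panel.n) + 0.5 * rng.standard_normal(panel.n)
        fit = fit_mtmm_varcomp(p1, p1.copy(), panel)
        assert fit.genetic_correlation >= 0.99
        assert fit.residual_correlation >= 0.99

    def test_recovers_genetic_correlation(self, panel):
        rng = np.random.default_rng(4)
        L = np.linalg.cholesky(panel.K + 1e-8 * np.eye(panel.n))
        Vg = np.array([[1.0, 0.5], [0.5, 1.0]])
        cors = []
        for _ in range(20):
            G = L @ rng.standard_normal((panel.n, 2)) @ np.linalg.cholesky(Vg).T
            Y = G + rng.standard_normal((panel.n, 2))
            fit = fit_mtmm_varcomp(Y[:, 0], Y[:, 1], panel)
            cors.append(fit.genetic_correlation)
        assert np.mean(cors) == pytest.approx(0.5, abs=0.15)

    def test_identity_kinship_flags_nonidentifiability(self):
        n = 60
        K = KinshipMatrix([f"a{i}" for i in range(n)], np.eye(n))
        rng = np.random.default_rng(5)
        with pytest.warns(UserWarning, match="identity-like"):
            fit = fit_mtmm_varcomp(rng.normal(size=n), rng.normal(size=n), K)
        assert not fit.identifiable


def _stacked_ols_f(y, n, s1, s2, x):
    xx = np.concatenate([x, x])
    xs1 = np.concatenate([x, np.zeros(n)])

    def rss(cols):
        X = np.column_stack(cols)
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ b
        return float(r @ r)

    r0, r1, r2 = rss([s1, s2]), rss([s1, s2, xx]), rss([s1, s2, xx, xs1])
    dff = 2 * n - 4
    return (
        stats.f.sf(((r0 - r2) / 2) / (r2 / dff), 2, dff),
        stats.f.sf((r0 - r1) / (r1 / (2 * n - 3)), 1, 2 * n - 3),
        stats.f.sf((r1 - r2) / (r2 / dff), 1, dff),
    )


class TestGlsTests:
    def test_identity_covariance_matches_stacked_ols_oracle(self):
        rng = np.random.default_rng(6)
        n = 30
        calls = rng.integers(0, 2, (n, 60))
        geno = _geno(calls)
        K = compute_kinship(geno)
        p1, p2 = rng.normal(size=n), rng.normal(size=n)
        fit = MtmmFit(Vg=np.zeros((2, 2)), Ve=np.eye(2), reml_loglik=0.0,
                      converged=True)
        res = gls_f_tests(geno, fit, p1, p2, K, maf_min=0.05)
        y = np.concatenate([p1, p2])
        s1 = np.concatenate([np.ones(n), np.zeros(n)])
        s2 = 1 - s1
        for _, row in res.iterrows():
            j = geno.markers.index[geno.markers.marker_id == row.marker_id][0]
            exp = _stacked_ols_f(y, n, s1, s2, geno.calls[:, j].astype(float))
            assert row.p_full == pytest.approx(exp[0], abs=1e-8)
            assert row.p_common == pytest.approx(exp[1], abs=1e-8)
            assert row.p_specific == pytest.approx(exp[2], abs=1e-8)

    def test_scaled_identity_invariance(self):
        """With Omega = sigma^2 I the tests are invariant to sigma^2."""
        rng = np.random.default_rng(7)
        n = 40
        geno = _geno(rng.integers(0, 2, (n, 30)))
        K = compute_kinship(geno)
        p1, p2 = rng.normal(size=n), rng.normal(size=n)
        f1 = MtmmFit(np.zeros((2, 2)), np.eye(2), 0.0, True)
        f9 = MtmmFit(np.zeros((2, 2)), 9.0 * np.eye(2), 0.0, True)
        r1 = gls_f_tests(geno, f1, p1, p2, K)
        r9 = gls_f_tests(geno, f9, p1, p2, K)
        np.testing.assert_allclose(r1.p_full, r9.p_full, atol=1e-10)
        np.testing.assert_allclose(r1.p_specific, r9.p_specific, atol=1e-10)

    def test_common_effect_dominates_common_test(self):
        rng = np.random.default_rng(8)
        n = 150
        ratios = []
        for _ in range(20):
            calls = rng.integers(0, 2, (n, 20))
            geno = _geno(calls)
            K = compute_kinship(geno)
            x = calls[:, 0].astype(float)
            p1 = 1.0 * x + rng.normal(0, 1, n)
            p2 = 1.0 * x + rng.normal(0, 1, n)
            fit = MtmmFit(np.zeros((2, 2)), np.eye(2), 0.0, True)
            res = gls_f_tests(geno, fit, p1, p2, K).set_index("marker_id")
            ratios.append(res.loc["m0", "p_common"]
                          / max(res.loc["m0", "p_specific"], 1e-300))
        assert np.median(ratios) < 1e-3

    def test_marker_order_permutation_stable(self):
        rng = np.random.default_rng(9)
        n = 50
        calls = rng.integers(0, 2, (n, 40))
        pos = np.arange(1, 41) * 10
        geno = _geno(calls, positions=pos)
        # same markers, shuffled input order (container re-sorts by position)
        perm = rng.permutation(40)
        geno_p = _geno(calls[:, perm], positions=pos[perm])
        K = compute_kinship(geno)
        p1, p2 = rng.normal(size=n), rng.normal(size=n)
        fit = MtmmFit(np.eye(2) * 0.3, np.eye(2), 0.0, True)
        # markers carry different labels after permutation: match by position
        a = gls_f_tests(geno, fit, p1, p2, K).set_index("position")
        b = gls_f_tests(geno_p, fit, p1, p2, K).set_index("position")
        common = a.index.intersection(b.index)
        np.testing.assert_allclose(a.loc[common, "p_full"],
                                   b.loc[common, "p_full"], atol=1e-12)

    def test_maf_filter_strict(self):
        rng = np.random.default_rng(10)
        n = 40
        calls = rng.integers(0, 2, (n, 10))
        calls[:, 0] = 0
        calls[:2, 0] = 1       # maf = 0.05 exactly -> excluded (strict >)
        geno = _geno(calls)
        K = compute_kinship(geno)
        fit = MtmmFit(np.zeros((2, 2)), np.eye(2), 0.0, True)
        res = gls_f_tests(geno, fit, rng.normal(size=n), rng.normal(size=n),
                          K, maf_min=0.05)
        assert "m0" not in set(res.marker_id)


class TestQtlRegions:
    def _results(self, positions, pvals, chrom="1"):
        return pd.DataFrame(
            {"marker_id": [f"m{i}" for i in range(len(positions))],
             "chromosome": chrom, "position": positions,
             "p_specific": pvals})

    def test_no_significant_snps(self):
        res = self._results([100, 200], [0.5, 0.2])
        assert select_qtl_regions(res) == []

    def test_overlapping_windows_merge(self):
        res = self._results([10_000, 25_000], [1e-5, 1e-6])
        regions = select_qtl_regions(res, window_bp=20_000)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (1, 35_000)
        assert r.member_snps == ["m0", "m1"]
        assert r.peak_neglog10p == pytest.approx(6.0)

    def test_distant_windows_stay_separate(self):
        res = self._results([10_000, 100_000], [1e-5, 1e-5])
        regions = select_qtl_regions(res, window_bp=20_000)
        assert len(regions) == 2

    def test_merging_independent_of_input_order(self):
        res = self._results([25_000, 10_000, 200_000], [1e-6, 1e-5, 1e-5])
        r1 = select_qtl_regions(res, window_bp=20_000)
        r2 = select_qtl_regions(res.iloc[::-1].reset_index(drop=True),
                                window_bp=20_000)
        assert [(r.start, r.end) for r in r1] == [(r.start, r.end) for r in r2]

    def test_bed_conversion_half_open(self):
        regions = [QTLRegion("1", 1, 35_000, ["m0"], 5.0)]
        bed = regions_to_bed(regions)
        assert bed.loc[0, "start"] == 0
        assert bed.loc[0, "end"] == 35_000


class TestLd:
    def test_self_and_complement(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 2, 20)
        calls = np.column_stack([x, 1 - x, rng.integers(0, 2, 20)])
        geno = _geno(calls, positions=[100, 200, 300])
        r2 = ld_r2(geno, "m0", window_bp=1000)
        assert r2["m0"] == pytest.approx(1.0)
        assert r2["m1"] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        a = np.array([0, 0, 1, 1, 0, 1])
        b = np.array([0, 1, 1, 1, 0, 0])
        geno = _geno(np.column_stack([a, b]), positions=[100, 200])
        r2 = ld_r2(geno, "m0", window_bp=1000)
        assert r2["m1"] == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2,
                                         abs=1e-12)

    def test_monomorphic_companion_is_nan(self):
        a = np.array([0, 1, 0, 1])
        b = np.array([1, 1, 1, 1])
        geno = _geno(np.column_stack([a, b]), positions=[100, 200])
        r2 = ld_r2(geno, "m0", window_bp=1000)
        assert np.isnan(r2["m1"])

    def test_window_respected(self):
        rng = np.random.default_rng(12)
        calls = rng.integers(0, 2, (10, 3))
        geno = _geno(calls, positions=[100, 200, 50_000])
        r2 = ld_r2(geno, "m0", window_bp=1000)
        assert "m2" not in r2.index
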