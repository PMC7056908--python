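import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riqtl._errors import ConfigError, DataError
from riqtl import mapping as mp
from riqtl.simulate import ChromosomeSpec, SimConfig, ri_recomb_fraction, \
    simulate_genotypes

from conftest import toy_genotypes, trait_frame


class TestDosage:
    def test_typed_marker_codes(self):
        g = toy_genotypes([["B", "D", "H"], ["B", "D", "U"]])
        d = mp.dosage(g, "1", 0.0)
        assert d[0] == 0.0 and d[1] == 2.0 and np.isnan(d[2])

    def test_concordant_flanks_at_zero_distance(self):
        """With vanishing map distance a B/B strain stays at dosage 0."""
        g = toy_genotypes([["B"], ["B"]], spacing_cM=1e-7)
        assert mp.dosage(g, "1", 5e-8)[0] == pytest.approx(0.0, abs=1e-8)

    def test_discordant_flanks_match_two_state_enumeration(self):
        """B...D flanks at 2+8 cM agree with the hand-enumerated chain."""
        g = toy_genotypes([["B"], ["D"]], spacing_cM=10.0)
        got = mp.dosage(g, "1", 2.0)[0]
        rho_l = float(ri_recomb_fraction(2.0))
        rho_r = float(ri_recomb_fraction(8.0))
        # state D requires a switch on the left leg and none on the right
        p_d = rho_l * (1 - rho_r)
        p_b = (1 - rho_l) * rho_r
        assert got == pytest.approx(2 * p_d / (p_d + p_b), abs=1e-12)

    def test_off_map_position_rejected(self):
        g = toy_genotypes([["B"], ["D"]])
        with pytest.raises(DataError, match="off the map"):
            mp.dosage(g, "1", 99.0)
        with pytest.raises(DataError, match="chromosome"):
            mp.dosage(g, "7", 0.0)

    def test_single_flank_when_one_side_missing(self):
        g = toy_genotypes([["U"], ["D"]], spacing_cM=10.0)
        d = mp.dosage(g, "1", 5.0)[0]
        rho = float(ri_recomb_fraction(5.0))
        assert d == pytest.approx(2 * (1 - rho), abs=1e-12)


class TestHkScan:
    def test_constant_trait_gives_zero_scan(self):
        g = toy_genotypes([list("BDBDBDBDBD"), list("BBDDBBDDBD")])
        t = trait_frame([5.0] * 10)
        with pytest.warns(UserWarning):
            scan = mp.hk_scan(g, t, step_cM=None)
        assert (scan.lrs == 0).all()

    def test_matches_closed_form_ols(self):
        """LRS and slope equal the closed-form least-squares oracle."""
        calls = [list("BBBBBDDDDD"), list("BBBBBDDDDD")]
        g = toy_genotypes(calls)
        y = np.array([10.0, 11.0, 9.0, 10.0, 12.0, 14.0, 15.0, 13.0, 14.0, 16.0])
        scan = mp.hk_scan(g, trait_frame(y), step_cM=None)
        x = np.array([0.0] * 5 + [2.0] * 5)
        xc, yc = x - x.mean(), y - y.mean()
        beta = xc @ yc / (xc @ xc)
        rss1 = ((yc - beta * xc) ** 2).sum()
        rss0 = (yc ** 2).sum()
        expect = 10 * np.log(rss0 / rss1)
        assert scan.lrs[0] == pytest.approx(expect, abs=1e-9)
        assert scan.additive[0] == pytest.approx(beta, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-100, 100), sign=st.sampled_from([-1.0, 1.0]))
    def test_lrs_invariant_under_affine_trait_transform(self, a, b, sign):
        g = toy_genotypes([list("BDBDBDBDBD"), list("BBDDBBDDBD")])
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        s1 = mp.hk_scan(g, trait_frame(y), step_cM=None)
        s2 = mp.hk_scan(g, trait_frame(sign * a * y + b), step_cM=None)
        np.testing.assert_allclose(s1.lrs, s2.lrs, atol=1e-9)

    def test_requires_shared_strains(self):
        g = toy_genotypes([["B", "D"], ["D", "B"]])
        with pytest.raises(DataError, match="shared"):
            mp.hk_scan(g, trait_frame([1.0, 2.0], strains=["X", "Y"]))


class TestPermutations:
    def test_constant_trait_thresholds_zero(self):
        g = toy_genotypes([list("BDBDBDBDBD"), list("BBDDBBDDBD")])
        thr = mp.permutation_thresholds(g, trait_frame([2.0] * 10), n_perm=100, seed=0)
        assert thr.significant_lrs == 0.0 and thr.suggestive_lrs == 0.0

    def test_fixed_seed_reproducible(self, small_mapping_config):
        g = simulate_genotypes(small_mapping_config)
        y = np.random.default_rng(1).normal(size=g.n_strains)
        t = trait_frame(y, strains=g.strains)
        a = mp.permutation_thresholds(g, t, n_perm=150, seed=42)
        b = mp.permutation_thresholds(g, t, n_perm=150, seed=42)
        assert a.significant_lrs == b.significant_lrs
        assert a.suggestive_lrs <= a.significant_lrs

    def test_small_n_perm_rejected(self):
        g = toy_genotypes([list("BDBD")])
        with pytest.raises(ConfigError):
            mp.permutation_thresholds(g, trait_frame([1.0, 2, 3, 4]), n_perm=50)


class TestBootstrapAndInterval:
    def test_frequencies_sum_to_one_and_peak_at_planted(self):
        """Noise-free single-QTL panel: all bootstrap mass at the QTL marker."""
        rng = np.random.default_rng(0)
        calls = rng.choice(["B", "D"], size=(5, 40))
        g = toy_genotypes(calls.tolist())
        y = (calls[2] == "D") * 10.0
        bf = mp.bootstrap_peak(g, trait_frame(y.tolist()), n_boot=200, seed=1,
                               step_cM=None)
        assert bf["frequency"].sum() == pytest.approx(1.0)
        assert bf["frequency"].idxmax() == 2

    def test_support_interval_brackets_peak(self):
        pos = pd.DataFrame({"chromosome": ["1"] * 7, "cM": np.arange(7.0),
                            "Mb": np.arange(7.0) * 2})
        lrs = np.array([0, 2, 12, 18, 12, 2, 0], float)
        scan = mp.QTLScan(positions=pos, lrs=lrs, additive=np.zeros(7))
        chrom, lo, hi = mp.support_interval(scan, drop_lod=1.5)
        # 1.5 LOD (6.9 LRS) below the peak of 18 keeps positions 2..4
        assert chrom == "1" and (lo, hi) == (4.0, 8.0)

    def test_flat_scan_has_no_interval(self):
        pos = pd.DataFrame({"chromosome": ["1"], "cM": [0.0], "Mb": [0.0]})
        scan = mp.QTLScan(positions=pos, lrs=np.zeros(1), additive=np.zeros(1))
        with pytest.raises(DataError, match="flat"):
            mp.support_interval(scan)


class TestKinship:
    def test_identical_strains_have_equal_rows(self):
        calls = [["B", "B", "D"], ["D", "D", "B"], ["B", "B", "B"], ["D", "D", "B"]]
        g = toy_genotypes(calls)
        K = mp.kinship(g, maf_min=0.0).matrix
        np.testing.assert_allclose(K[0], K[1], atol=1e-12)

    def test_matches_brute_force_product(self):
        rng = np.random.default_rng(3)
        calls = rng.choice(["B", "D"], size=(60, 12))
        g = toy_genotypes(calls.tolist(), spacing_cM=1.0)
        K = mp.kinship(g).matrix
        Z = np.where(calls == "D", 2.0, 0.0).T
        keep = g.maf() > 0.05
        Z = Z[:, keep]
        Z = Z - Z.mean(axis=0)
        np.testing.assert_allclose(K, Z @ Z.T / Z.shape[1], atol=1e-10)

    def test_loco_excludes_scanned_chromosome(self):
        rng = np.random.default_rng(4)
        g12 = rng.choice(["B", "D"], size=(10, 20))
        gother = rng.choice(["B", "D"], size=(10, 20))
        markers = pd.DataFrame({
            "marker_id": [f"m{j}" for j in range(20)],
            "chromosome": ["12"] * 10 + ["1"] * 10,
            "cM": list(range(10)) + list(range(10)),
            "Mb": [float(2 * j) for j in range(10)] + [float(2 * j) for j in range(10)],
        })
        from riqtl.io_formats import GenotypeMatrix
        a = GenotypeMatrix([f"S{i}" for i in range(20)], markers,
                           np.vstack([g12, gother]))
        flipped = np.vstack([np.where(g12 == "B", "D", "B"), gother])
        b = GenotypeMatrix([f"S{i}" for i in range(20)], markers, flipped)
        Ka = mp.kinship(a, loco_chromosome="12").matrix
        Kb = mp.kinship(b, loco_chromosome="12").matrix
        np.testing.assert_allclose(Ka, Kb, atol=1e-12)

    def test_non_psd_matrix_rejected(self):
        with pytest.raises(DataError, match="positive semi-definite"):
            mp.KinshipMatrix(matrix=np.array([[1.0, 2.0], [2.0, 1.0]]),
                             strains=["a", "b"])


class TestLmm:
    def _toy(self, n=20, n_markers=12, seed=5):
        rng = np.random.default_rng(seed)
        while True:
            calls = rng.choice(["B", "D"], size=(n_markers, n))
            g = toy_genotypes(calls.tolist(), spacing_cM=5.0)
            if (g.maf() > 0.05).all():
                break
        y = rng.normal(size=n) + 1.5 * (calls[4] == "D")
        return g, trait_frame(y.tolist())

    def test_identity_kinship_collapses_to_ols(self):
        """With K = I the mixed model equals Haley-Knott at typed markers."""
        g, t = self._toy()
        hk = mp.hk_scan(g, t, step_cM=None)
        K = mp.KinshipMatrix(matrix=np.eye(g.n_strains), strains=g.strains)
        lmm = mp.lmm_scan(g, t, kinship_override=K)
        np.testing.assert_allclose(lmm.lrs, hk.lrs, atol=1e-6)

    def test_loglik_matches_dense_multivariate_normal(self):
        """Profiled eigen-rotated likelihood equals the dense MVN density,
        and a dense lambda grid never beats the bounded optimizer."""
        from scipy.linalg import eigh
        from scipy.stats import multivariate_normal
        rng = np.random.default_rng(8)
        n = 8
        Z = rng.choice([0.0, 2.0], size=(n, 30))
        Zc = Z - Z.mean(axis=0)
        K = Zc @ Zc.T / 30
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.choice([0.0, 2.0], n)])
        s, U = eigh(K)
        s = np.clip(s, 0, None)
        fit = mp._fit_lmm(s, U.T @ y, U.T @ X)
        ll, beta = mp._profile_loglik(fit.lam, s, U.T @ y, U.T @ X)
        w = 1.0 / (fit.lam * s + 1.0)
        resid = U.T @ y - (U.T @ X) @ beta
        sigma2 = float((w * resid ** 2).sum()) / n
        dense = multivariate_normal.logpdf(y, mean=X @ beta,
                                           cov=sigma2 * (fit.lam * K + np.eye(n)))
        assert ll == pytest.approx(dense, abs=1e-6)
        grid = 10.0 ** np.linspace(-5, 5, 4001)
        best = max(mp._profile_loglik(l, s, U.T @ y, U.T @ X)[0] for l in grid)
        assert fit.loglik >= best - 1e-6

    def test_small_lambda_limit_recovers_hk(self):
        """As the genetic variance ratio vanishes the LMM LRS matches OLS."""
        g, t = self._toy(seed=9)
        hk = mp.hk_scan(g, t, step_cM=None)
        K = mp.kinship(g)
        from scipy.linalg import eigh
        s, U = eigh(K.matrix)
        s = np.clip(s, 0, None)
        y = t["value"].to_numpy()
        lam = 1e-5
        ll0, _ = mp._profile_loglik(lam, s, U.T @ y, U.T @ np.ones((len(y), 1)))
        dos = g.dosage_matrix()
        for i in (0, 4):
            X = np.column_stack([np.ones(len(y)), dos[i]])
            ll1, _ = mp._profile_loglik(lam, s, U.T @ y, U.T @ X)
            assert 2 * (ll1 - ll0) == pytest.approx(hk.lrs[i], abs=1e-3)


class TestRobustness:
    def test_no_outliers_three_identical_scans(self):
        rng = np.random.default_rng(2)
        calls = rng.choice(["B", "D"], size=(6, 20))
        g = toy_genotypes(calls.tolist())
        t = trait_frame(rng.normal(size=20).tolist())
        out = mp.robustness_suite(g, t, [], [], step_cM=None)
        assert out["lrs"].nunique() == 1 and out["n_strains"].nunique() == 1

    def test_censored_scenario_drops_flagged_strains(self):
        rng = np.random.default_rng(2)
        calls = rng.choice(["B", "D"], size=(6, 20))
        g = toy_genotypes(calls.tolist())
        t = trait_frame(rng.normal(size=20).tolist())
        out = mp.robustness_suite(g, t, ["S0"], ["S1"], step_cM=None)
        assert out.set_index("scenario").loc["censored", "n_strains"] == 18

    def test_planted_qtl_peak_stable_across_scenarios(self):
        from riqtl.simulate import make_fixture, ExpressionSpec, OutlierSpec
        from riqtl.phenotypes import strain_summary, detect_outliers
        cfg = SimConfig(n_strains=60,
                        chromosomes=[ChromosomeSpec(c, 60.0, 4.0) for c in "123"],
                        qtl=[("2@28", 3.0)], var_strain=1.0, var_within=1.0,
                        replicates_per_strain=(3, 3), field_level=False,
                        age_slope=0.0, outliers=OutlierSpec(n_high=2, n_low=1),
                        expression=ExpressionSpec(n_genes=60, n_interval_genes=6,
                                                  n_cis_genes=2, n_module_genes=6),
                        interval=("2", 50.0, 60.0), seed=6)
        fx = make_fixture(cfg)
        t = strain_summary(fx.animals)
        high, low = detect_outliers(t)
        out = mp.robustness_suite(fx.genotypes, t, high, low)
        assert (out["chromosome"] == "2").all()
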