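import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riqtl._errors import ConfigError, DataError
from riqtl import phenotypes as ph

from conftest import trait_frame


def rec(strain="A", counts=None, field_area=56.1, nerve_area=673.2, **kw):
    return ph.AnimalRecord(strain=strain, field_counts_necrotic=counts,
                           field_area_um2=field_area, nerve_area_um2=nerve_area, **kw)


class TestNerveCounts:
    def test_nerve_equals_sampled_area(self):
        """12 fields of 5 with nerve area equal to sampled area gives 60."""
        necro, dens, _ = ph.nerve_counts(rec(counts=[5.0] * 12))
        assert necro == 60
        assert dens == pytest.approx(60 / (12 * 56.1))

    def test_all_zero_fields(self):
        necro, dens, _ = ph.nerve_counts(rec(counts=[0.0] * 12))
        assert necro == 0 and dens == 0.0

    def test_extrapolation_to_nerve_area(self):
        """Counts 1..12 over 673.2 um2 extrapolated to 10,000 um2 -> 1,159."""
        r = rec(counts=list(map(float, range(1, 13))), nerve_area=10_000.0)
        necro, _, _ = ph.nerve_counts(r)
        assert necro == round(78 / 673.2 * 10_000)

    def test_minimum_field_count_enforced(self):
        with pytest.raises(DataError, match="minimum"):
            rec(counts=[1.0] * 11)


class TestStrainSummary:
    def test_single_animal_has_no_sem(self):
        t = ph.strain_summary([rec(counts=[5.0] * 12)])
        assert t.loc["A", "value"] == 60 and np.isnan(t.loc["A", "se"])

    def test_equal_replicates_have_zero_sem(self):
        t = ph.strain_summary([rec(counts=[5.0] * 12), rec(counts=[5.0] * 12)])
        assert t.loc["A", "se"] == 0.0 and t.loc["A", "n"] == 2

    def test_recovers_generator_means(self, demo_fixture):
        """Strain means land within a few SEM of the generator's values."""
        t = ph.strain_summary(demo_fixture.animals)
        assert len(t) == demo_fixture.genotypes.n_strains
        assert 1000 < t["value"].mean() < 3500


class TestWinsorize:
    def test_printed_high_pairs(self):
        """Three high outliers above a retained max of 3,733 become
        3,734 / 3,735 / 3,736 in ascending raw order."""
        t = trait_frame([3733, 2000, 1000, 617, 4121, 5552, 5825],
                        strains=["r1", "r2", "r3", "r4", "BXD29", "BXD56", "BXD102"])
        w = ph.winsorize(t, ["BXD29", "BXD56", "BXD102"], [])
        assert w.loc["BXD29", "value"] == 3734
        assert w.loc["BXD56", "value"] == 3735
        assert w.loc["BXD102", "value"] == 3736

    def test_printed_low_pair(self):
        """A low outlier of 376 below a retained min of 617 becomes 616."""
        t = trait_frame([617, 1000, 2000, 3733, 376],
                        strains=["r1", "r2", "r3", "r4", "BXD71"])
        w = ph.winsorize(t, [], ["BXD71"])
        assert w.loc["BXD71", "value"] == 616

    def test_simple_rule(self):
        t = trait_frame([1, 2, 3, 100])
        w = ph.winsorize(t, ["S3"], [])
        assert w["value"].tolist() == [1, 2, 3, 4]

    def test_overlapping_sets_rejected(self):
        t = trait_frame([1, 2, 3, 4])
        with pytest.raises(ConfigError, match="overlap"):
            ph.winsorize(t, ["S0"], ["S0"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=20, unique=True),
           st.data())
    def test_rank_and_identity_preservation(self, values, data):
        """Winsorization preserves rank order and leaves retained values
        bit-identical."""
        t = trait_frame(values)
        order = t["value"].sort_values()
        k_hi = data.draw(st.integers(0, 2))
        k_lo = data.draw(st.integers(0, min(2, len(values) - k_hi - 1)))
        high = list(order.index[-k_hi:]) if k_hi else []
        low = list(order.index[:k_lo]) if k_lo else []
        w = ph.winsorize(t, high, low)
        kept = [s for s in t.index if s not in set(high) | set(low)]
        assert (w.loc[kept, "value"] == t.loc[kept, "value"]).all()
        assert (w["value"].rank().sort_values().index
                == t["value"].rank().sort_values().index).all()


class TestDetectOutliers:
    def test_no_extremes(self):
        high, low = ph.detect_outliers(trait_frame([1, 2, 3, 4, 5]))
        assert high == [] and low == []

    def test_far_value_flagged_high(self):
        high, low = ph.detect_outliers(trait_frame([1, 2, 3, 4, 50]))
        assert high == ["S4"] and low == []

    def test_injected_outliers_recovered(self):
        """Fence detection finds the strains the generator inflated."""
        from riqtl.simulate import (ChromosomeSpec, OutlierSpec, SimConfig,
                                    make_fixture)
        from riqtl.phenotypes import strain_summary
        found = 0
        for seed in range(8):
            cfg = SimConfig(n_strains=40,
                            chromosomes=[ChromosomeSpec("12", 60.0, 5.0)],
                            qtl=[], outliers=OutlierSpec(n_high=2, n_low=1,
                                                         inflation=8.0),
                            var_strain=10_000.0, var_within=10_000.0,
                            baseline=10_000.0, interval=("12", 100.0, 110.0),
                            field_level=False, age_slope=0.0,
                            replicates_per_strain=(4, 4), seed=seed)
            fx = make_fixture(cfg)
            high, low = ph.detect_outliers(strain_summary(fx.animals))
            want_h = set(fx.truth["outlier_high_strains"])
            want_l = set(fx.truth["outlier_low_strains"])
            found += want_h <= set(high) and want_l <= set(low)
        assert found >= 7


class TestHeritability:
    def test_zero_within_variance(self):
        t = trait_frame([1.0, 2.0, 3.0], se=[0.0, 0.0, 0.0], n=[2, 2, 2])
        h = ph.heritability(t)
        assert h.Ve == 0.0 and h.h2_conventional == pytest.approx(1.0)
        assert h.h2_rix == pytest.approx(1.0)

    def test_identical_strains_clamp_to_zero(self):
        t = trait_frame([5.0, 5.0, 5.0], se=[1.0, 1.0, 1.0], n=[10, 10, 10])
        h = ph.heritability(t)
        assert h.Va == 0.0 and h.h2_conventional == 0.0

    def test_matches_hand_anova(self):
        """Balanced 3x2 toy agrees with explicit sums of squares to 1e-9."""
        recs = [ph.AnimalRecord(strain=s, necrotic_count=v)
                for s, vals in (("a", (0.9, 1.1)), ("b", (1.9, 2.1)), ("c", (2.9, 3.1)))
                for v in vals]
        h = ph.heritability(recs)
        # hand ANOVA: group means 1,2,3; grand 2
        ssb = 2 * ((1 - 2) ** 2 + (3 - 2) ** 2)
        ssw = 6 * 0.01
        msb, msw = ssb / 2, ssw / 3
        n0 = (6 - 12 / 6) / 2
        va = (msb - msw) / n0
        assert h.Va == pytest.approx(va, abs=1e-9)
        assert h.Ve == pytest.approx(msw, abs=1e-9)
        assert h.h2_conventional == pytest.approx(va / (va + msw), abs=1e-9)
        assert h.h2_rix == pytest.approx(va / (va + msw / 2), abs=1e-9)

    def test_summary_path_equals_replicate_path(self):
        rng = np.random.default_rng(0)
        recs = [ph.AnimalRecord(strain=f"s{i}", necrotic_count=float(v))
                for i in range(10) for v in rng.normal(i, 1.0, 4)]
        t = ph.strain_summary(recs)
        a, b = ph.heritability(recs), ph.heritability(t)
        assert a.Va == pytest.approx(b.Va, rel=1e-9)
        assert a.h2_rix == pytest.approx(b.h2_rix, rel=1e-9)

    def test_rix_exceeds_conventional_and_is_monotone(self):
        t1 = trait_frame([1.0, 2.0, 3.0], se=[0.5, 0.5, 0.5], n=[2, 2, 2])
        t2 = trait_frame([1.0, 2.0, 3.0],
                         se=[0.5 / np.sqrt(2), 0.5 / np.sqrt(2), 0.5 / np.sqrt(2)],
                         n=[4, 4, 4])
        h1, h2 = ph.heritability(t1), ph.heritability(t2)
        assert h1.h2_rix >= h1.h2_conventional
        assert h2.h2_rix >= h1.h2_rix        # larger n_bar, same components

    def test_undefined_without_replication(self):
        t = trait_frame([1.0, 2.0], n=[1, 1])
        with pytest.raises(DataError, match="undefined"):
            ph.heritability(t)


class TestAgeAndSex:
    def test_exact_line_recovered(self):
        recs = [ph.AnimalRecord(strain="a", age_months=13.0 + x,
                                necrotic_count=34.0 * x + 100)
                for x in (0.0, 1.0, 2.0, 5.0, 10.0)]
        slope, r2 = ph.age_regression(recs)
        assert slope == pytest.approx(34.0) and r2 == pytest.approx(1.0)

    def test_constant_counts_give_zero_slope(self):
        recs = [ph.AnimalRecord(strain="a", age_months=13.0 + x, necrotic_count=7.0)
                for x in range(5)]
        slope, r2 = ph.age_regression(recs)
        assert slope == 0.0 and r2 == 0.0

    def test_constant_age_rejected(self):
        recs = [ph.AnimalRecord(strain="a", age_months=15.0, necrotic_count=float(i))
                for i in range(5)]
        with pytest.raises(DataError, match="constant age"):
            ph.age_regression(recs)

    def test_identical_groups_give_p_one(self):
        recs = [ph.AnimalRecord(strain="a", sex=s, necrotic_count=v)
                for s in "MF" for v in (1.0, 2.0, 3.0)]
        m, f, p = ph.sex_compare(recs)
        assert m == f and p == 1.0

    def test_separated_groups_significant(self):
        recs = ([ph.AnimalRecord(strain="a", sex="M", necrotic_count=v)
                 for v in (1.0, 2.0, 3.0)]
                + [ph.AnimalRecord(strain="a", sex="F", necrotic_count=v)
                   for v in (101.0, 102.0, 103.0)])
        _, _, p = ph.sex_compare(recs)
        assert p < 0.01

    def test_welch_matches_textbook_formula(self):
        xm = np.array([3.1, 4.5, 2.2, 5.0, 3.3])
        xf = np.array([6.0, 7.2, 5.5, 8.1])
        recs = ([ph.AnimalRecord(strain="a", sex="M", necrotic_count=float(v)) for v in xm]
                + [ph.AnimalRecord(strain="a", sex="F", necrotic_count=float(v)) for v in xf])
        _, _, p = ph.sex_compare(recs)
        vm, vf = xm.var(ddof=1) / len(xm), xf.var(ddof=1) / len(xf)
        tstat = (xm.mean() - xf.mean()) / np.sqrt(vm + vf)
        df = (vm + vf) ** 2 / (vm ** 2 / (len(xm) - 1) + vf ** 2 / (len(xf) - 1))
        from scipy.stats import t as tdist
        p_ref = 2 * tdist.sf(abs(tstat), df)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_paired_mode_requires_replicated_sexes(self):
        recs = [ph.AnimalRecord(strain="a", sex="M", necrotic_count=1.0),
                ph.AnimalRecord(strain="a", sex="F", necrotic_count=2.0)]
        with pytest.raises(DataError):
            ph.sex_compare(recs, paired_by_strain=True)
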