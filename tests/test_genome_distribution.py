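"""Background sampling, annotation, test battery, FDR and profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from radsig import genome_distribution as gd
from radsig.genome import InMemoryGenome
from radsig.records import CallableRegions, FeatureTrack, ValidationError


class TestBackgroundSampling:
    def test_positions_inside_callable_and_deterministic(self):
        regions = CallableRegions({"chr1": [(1, 1000)]})
        a = gd.sample_background(regions, 10, seed=5)
        b = gd.sample_background(regions, 10, seed=5)
        assert a["pos"].between(1, 1000).all()
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_split_between_equal_chromosomes(self):
        regions = CallableRegions({"chr1": [(1, 50_000)], "chr2": [(1, 50_000)]})
        draw = gd.sample_background(regions, 100_000, seed=1)
        n1 = int((draw["chrom"] == "chr1").sum())
        sd = np.sqrt(100_000 * 0.25)
        assert abs(n1 - 50_000) < 3 * sd

    def test_invalid_inputs(self):
        regions = CallableRegions({"chr1": [(1, 100)]})
        with pytest.raises(ValidationError):
            gd.sample_background(regions, 0, seed=1)
        with pytest.raises(ValidationError):
            gd.sample_background(CallableRegions({}), 10, seed=1)


class TestAnnotation:
    def test_gc_extremes(self):
        genome = InMemoryGenome({"chrG": "G" * 500, "chrA": "A" * 500})
        ann = gd.annotate_positions(
            pd.DataFrame({"chrom": ["chrG", "chrA"], "pos": [250, 250]}), genome
        )
        assert ann["gc"].tolist() == [1.0, 0.0]

    def test_complexity_poly_a_is_zero(self):
        genome = InMemoryGenome({"chr1": "A" * 500})
        ann = gd.annotate_positions(pd.DataFrame({"chrom": ["chr1"], "pos": [250]}), genome)
        assert ann["complexity"].iloc[0] == 0.0

    def test_complexity_maximal_for_period_four(self):
        # ACGT repeated: exactly 4 distinct 3-mers, uniform -> 2 bits of 6
        genome = InMemoryGenome({"chr1": "ACGT" * 125})
        ann = gd.annotate_positions(pd.DataFrame({"chrom": ["chr1"], "pos": [250]}), genome)
        # 99 3-mers in the window split 25/25/25/24 -> entropy a hair below 2 bits
        assert ann["complexity"].iloc[0] == pytest.approx(2.0 / 6.0, abs=1e-3)
        # no period-4 sequence can exceed it: at most 4 distinct 3-mers
        rng = np.random.default_rng(2)
        for _ in range(10):
            unit = "".join(rng.choice(list("ACGT"), size=4))
            other = InMemoryGenome({"chr1": unit * 125})
            a = gd.annotate_positions(
                pd.DataFrame({"chrom": ["chr1"], "pos": [250]}), other
            )
            assert a["complexity"].iloc[0] <= 2.0 / 6.0 + 1e-12

    def test_track_gap_returns_default_with_flag(self):
        genome = InMemoryGenome({"chr1": "ACGT" * 250})
        track = FeatureTrack("timing", "quantitative", {"chr1": [(1, 100, 0.7)]}, -9.0)
        ann = gd.annotate_positions(
            pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [50, 500]}), genome, [track]
        )
        assert ann["timing"].tolist() == [0.7, -9.0]
        assert ann["timing_covered"].tolist() == [True, False]

    def test_truncated_window_flagged(self):
        genome = InMemoryGenome({"chr1": "ACGT" * 250})
        ann = gd.annotate_positions(
            pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 500]}), genome
        )
        assert ann["window_truncated"].tolist() == [True, False]


class TestCompareFeature:
    def test_two_proportion_z_value(self):
        variants = [1] * 10 + [0] * 90
        background = [1] * 20 + [0] * 80
        result = gd.compare_feature(variants, background, "binary")
        # pooled SE = sqrt(0.15 * 0.85 * 2/100)
        assert result.statistic == pytest.approx(-1.980, abs=1e-3)

    def test_identical_quantitative_samples(self):
        values = [1.0, 2.0, 3.0]
        result = gd.compare_feature(values, values, "quantitative")
        assert result.statistic == 0.0 and result.raw_p == 1.0

    def test_flat_categorical_table(self):
        result = gd.compare_feature(
            ["a"] * 10 + ["b"] * 10, ["a"] * 10 + ["b"] * 10, "categorical"
        )
        assert result.statistic == pytest.approx(0.0)
        assert result.raw_p == pytest.approx(1.0)

    def test_single_label_degenerate(self):
        result = gd.compare_feature(["a"] * 5, ["a"] * 7, "categorical")
        assert result.degenerate and result.raw_p == 1.0

    def test_z_squared_equals_chi2_on_random_tables(self):
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 100:
            n1, n2 = rng.integers(20, 200, size=2)
            k1, k2 = rng.integers(1, n1), rng.integers(1, n2)
            p1, p2 = k1 / n1, k2 / n2
            if p1 == p2:
                continue
            z = gd.compare_feature(
                [1] * k1 + [0] * (n1 - k1), [1] * k2 + [0] * (n2 - k2), "binary"
            ).statistic
            table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
            chi2 = stats.chi2_contingency(table, correction=False)[0]
            assert z**2 == pytest.approx(chi2, rel=1e-8)
            checked += 1


class TestBenjaminiYekutieli:
    def test_hand_computed_example(self):
        qs = gd.adjust_benjamini_yekutieli([0.01, 0.02, 0.03])
        assert qs == pytest.approx([0.055, 0.055, 0.055])

    def test_single_p_unchanged(self):
        assert gd.adjust_benjamini_yekutieli([0.04]) == pytest.approx([0.04])

    def test_dominates_benjamini_hochberg_and_capped(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            ps = rng.random(rng.integers(2, 40))
            by = gd.adjust_benjamini_yekutieli(ps)
            bh = multipletests(ps, method="fdr_bh")[1]
            assert (by >= bh - 1e-12).all()
            assert (by <= 1.0).all()
            order = np.argsort(ps)
            assert (np.diff(by[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            gd.adjust_benjamini_yekutieli([0.1, 1.3])


class TestSignificanceRule:
    def _result(self, p, m1, m2):
        return gd.FeatureTestResult(
            "f", "quantitative", 0.0, p,
            group_summary={"mean_variant": m1, "mean_background": m2},
        )

    def test_dual_rule(self):
        results = gd.flag_significant(
            [self._result(0.0005, 0.10, 0.20),   # q small, 50% magnitude
             self._result(0.0005, 0.100, 0.101), # q small, 1% magnitude
             self._result(0.5, 0.0, 1.0)]        # q large, huge magnitude
        )
        assert [r.significant for r in results] == [True, False, False]
        assert results[0].magnitude_diff == pytest.approx(0.5)

    def test_both_means_zero(self):
        (r,) = gd.flag_significant([self._result(0.001, 0.0, 0.0)])
        assert r.magnitude_diff == 0.0 and not r.significant


class TestDensityRatio:
    def test_identical_distributions_give_unit_ratios(self):
        values = np.repeat([1.0, 2.0, 3.0, 4.0], 50)
        table = gd.density_ratio(values, values, bins=[0.5, 1.5, 2.5, 3.5, 4.5])
        assert table["ratio"].to_numpy() == pytest.approx(np.ones(4))

    def test_concentrated_variants(self):
        background = np.repeat([1.0, 2.0, 3.0, 4.0], 25)
        variants = np.full(40, 4.0)
        table = gd.density_ratio(variants, background, bins=[0.5, 1.5, 2.5, 3.5, 4.5])
        assert table["ratio"].iloc[3] == pytest.approx(4.0)

    def test_zero_background_bin_flagged(self):
        table = gd.density_ratio([1.0, 5.0], [1.0, 1.1], bins=[0, 2, 10])
        assert not table["defined"].iloc[1]
        assert np.isnan(table["ratio"].iloc[1])

    def test_empty_variants_rejected(self):
        with pytest.raises(ValidationError):
            gd.density_ratio([], [1.0], bins=[0, 1])


def _profile_inputs(rng, n, effect):
    """Variant/background feature frames plus genome-bin means.

    ``effect > 0`` concentrates variants where the feature is high via
    exp(effect * x) rejection sampling, mirroring chromatin-coupled placement.
    """
    background = rng.normal(size=4 * n)
    if effect == 0:
        variants = rng.normal(size=n)
    else:
        pool = rng.normal(size=20 * n)
        keep = rng.random(20 * n) < np.exp(effect * (pool - 3.0))
        variants = pool[keep][:n]
    bins = pd.DataFrame({"x": np.linspace(-2, 2, 30)})
    return (
        pd.DataFrame({"x": variants}),
        pd.DataFrame({"x": background}),
        bins,
    )


class TestProbabilityProfile:
    def test_null_profile_near_uniform(self):
        rng = np.random.default_rng(21)
        var, bg, bins = _profile_inputs(rng, 5000, effect=0)
        profile, fit = gd.indel_probability_profile(var, bg, bins, ["x"])
        assert profile.sum() == pytest.approx(1.0)
        assert profile.max() / profile.min() < 1.2

    def test_implanted_effect_recovered(self):
        rng = np.random.default_rng(22)
        var, bg, bins = _profile_inputs(rng, 3000, effect=1.0)
        profile, fit = gd.indel_probability_profile(var, bg, bins, ["x"])
        assert fit.coefficients[0] > 0
        assert profile.iloc[-1] > profile.iloc[0]

    def test_uniform_profile_flatter_than_correlated(self):
        rng = np.random.default_rng(23)
        var_u, bg, bins = _profile_inputs(rng, 3000, effect=0)
        var_c, _, _ = _profile_inputs(rng, 3000, effect=1.0)
        flat, _ = gd.indel_probability_profile(var_u, bg, bins, ["x"])
        peaked, _ = gd.indel_probability_profile(var_c, bg, bins, ["x"])
        cv = lambda s: s.std() / s.mean()
        assert cv(flat) < cv(peaked)

    def test_perfect_separation_falls_back_to_penalized(self):
        var = pd.DataFrame({"x": np.linspace(1.0, 2.0, 50)})
        bg = pd.DataFrame({"x": np.linspace(-2.0, -1.0, 50)})
        bins = pd.DataFrame({"x": np.linspace(-2, 2, 10)})
        profile, fit = gd.indel_probability_profile(var, bg, bins, ["x"])
        assert fit.penalized_fallback
        assert profile.sum() == pytest.approx(1.0)
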