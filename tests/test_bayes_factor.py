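"""Unit and property tests for the AAFBF building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssdbf import (
    DegenerateDataError,
    DeltaDistribution,
    FractionSpec,
    Hypothesis,
    SummaryStats,
    VarianceModel,
    aafbf,
    bf_from_raw,
    complexity_equality,
    complexity_onesided,
    fit_equality,
    fit_onesided,
    pooled_variance,
    posterior_delta,
    prior_delta,
    summarize,
)

EQ = VarianceModel.EQUAL_VAR
UQ = VarianceModel.UNEQUAL_VAR


def stats(n1=100, n2=100, m1=0.0, m2=0.0, v1=1.0, v2=1.0, model=EQ):
    return SummaryStats(n1=n1, n2=n2, mean1=m1, mean2=m2, var1=v1, var2=v2, model=model)


class TestSummarize:
    def test_hand_example(self):
        s = summarize([1, 3], [2, 2, 2, 4], EQ)
        assert (s.n1, s.n2) == (2, 4)
        assert s.mean1 == pytest.approx(2.0)
        assert s.var1 == pytest.approx(2.0)
        assert s.mean2 == pytest.approx(2.5)
        assert s.var2 == pytest.approx(1.0)

    def test_rejects_degenerate_and_short_input(self):
        with pytest.raises(DegenerateDataError):
            summarize([0, 0], [1, 1], EQ)
        with pytest.raises(ValueError):
            summarize([1.0], [1, 2], EQ)
        with pytest.raises(ValueError):
            summarize([1, np.nan, 2], [1, 2], EQ)

    def test_seeded_sample_means_near_population_means(self):
        rng = np.random.default_rng(7)
        s = summarize(rng.normal(0, 1, 100), rng.normal(0, 1, 100), EQ)
        assert abs(s.mean1) < 3 / np.sqrt(100)
        assert abs(s.mean2) < 3 / np.sqrt(100)


class TestPooledVariance:
    def test_equal_inputs(self):
        assert pooled_variance(stats(v1=1, v2=1)) == pytest.approx(1.0)

    def test_hand_value(self):
        assert pooled_variance(stats(n1=20, n2=10, v1=1.5, v2=0.5)) == pytest.approx(33 / 28)

    def test_near_zero_variance_limit(self):
        assert pooled_variance(stats(n1=10, n2=10, v1=2.0, v2=1e-12)) == pytest.approx(1.0)

    def test_requires_equal_variance_model(self):
        with pytest.raises(ValueError):
            pooled_variance(stats(model=UQ))


class TestDeltaDistributions:
    def test_posterior_equal_variance(self):
        d = posterior_delta(stats())
        assert d.mean == pytest.approx(0.0)
        assert d.variance == pytest.approx(0.02)

    def test_posterior_welch(self):
        d = posterior_delta(stats(v1=4 / 3, v2=2 / 3, model=UQ))
        assert d.variance == pytest.approx(0.02)

    def test_posterior_mean_is_mean_difference(self):
        assert posterior_delta(stats(m1=0.5, v1=3, v2=0.2)).mean == pytest.approx(0.5)

    def test_prior_fraction_b(self):
        p = prior_delta(stats(), FractionSpec(1))
        assert p.mean == pytest.approx(0.0)
        assert p.variance == pytest.approx(4.0)
        assert complexity_equality(p) == pytest.approx(1 / np.sqrt(8 * np.pi), rel=1e-6)

    def test_prior_variance_inverse_in_multiplier(self):
        assert prior_delta(stats(), FractionSpec(2)).variance == pytest.approx(2.0)

    def test_prior_mean_zero_for_any_stats(self):
        p = prior_delta(stats(m1=3.2, m2=-1.0, v1=5, v2=0.3, model=UQ), FractionSpec(3))
        assert np.all(np.asarray(p.mean) == 0.0)


class TestFitComplexity:
    def test_savage_dickey_density_at_zero(self):
        assert fit_equality(DeltaDistribution(0.0, 0.02)) == pytest.approx(2.82095, rel=1e-4)
        assert fit_equality(DeltaDistribution(0.5, 0.02)) == pytest.approx(
            2.82095 * np.exp(-6.25), rel=1e-4
        )

    def test_density_vanishes_with_diffuse_distribution(self):
        assert fit_equality(DeltaDistribution(0.0, 1e12)) < 1e-5

    def test_onesided_fit(self):
        assert fit_onesided(DeltaDistribution(0.0, 1.0)) == pytest.approx(0.5)
        assert fit_onesided(DeltaDistribution(0.5, 0.02)) == pytest.approx(0.99980, abs=1e-4)
        a = fit_onesided(DeltaDistribution(0.7, 0.3))
        b = fit_onesided(DeltaDistribution(-0.7, 0.3))
        assert a + b == pytest.approx(1.0)

    def test_onesided_complexity_is_half_and_scale_free(self):
        for var in (1e-6, 1.0, 1e6):
            assert complexity_onesided(DeltaDistribution(0.0, var)) == 0.5
        with pytest.raises(ValueError):
            complexity_onesided(DeltaDistribution(0.1, 1.0))


class TestAAFBF:
    def test_symmetric_data_makes_onesided_equal_twosided(self):
        s = stats(m1=0.0, m2=0.0)
        two = aafbf(s, Hypothesis.TWO_SIDED)
        one = aafbf(s, Hypothesis.ONE_SIDED)
        assert one.fit_alt == pytest.approx(0.5)
        assert one.bf_0alt == pytest.approx(two.bf_0alt, rel=1e-12)

    def test_composition_of_onesided_bf(self):
        s = stats(m1=0.3, n1=40, n2=40)
        res = aafbf(s, Hypothesis.ONE_SIDED)
        bf01 = res.fit_0 / res.complexity_0
        bf21 = res.fit_alt / res.complexity_alt
        assert res.bf_0alt == pytest.approx(bf01 / bf21, rel=1e-12)

    def test_reciprocal_consistency(self):
        res = aafbf(stats(m1=0.4), Hypothesis.ONE_SIDED, FractionSpec(2))
        assert res.bf_0alt * res.bf_alt0 == pytest.approx(1.0, rel=1e-12)

    def test_fraction_scaling_law(self):
        base = aafbf(stats(m1=0.2))
        for m in (2, 3):
            res = aafbf(stats(m1=0.2), fraction=FractionSpec(m))
            assert res.bf_0alt == pytest.approx(base.bf_0alt / np.sqrt(m), rel=1e-10)
            assert res.complexity_0 == pytest.approx(base.complexity_0 * np.sqrt(m), rel=1e-10)

    def test_equal_and_welch_models_coincide_for_balanced_equal_variances(self):
        a = aafbf(stats(v1=1.7, v2=1.7, m1=0.3), Hypothesis.ONE_SIDED)
        b = aafbf(stats(v1=1.7, v2=1.7, m1=0.3, model=UQ), Hypothesis.ONE_SIDED)
        assert a.bf_0alt == pytest.approx(b.bf_0alt, rel=1e-12)
        assert a.fit_0 == pytest.approx(b.fit_0, rel=1e-12)

    def test_log_bf_finite_when_plain_bf_overflows(self):
        # huge sample, huge effect: BF10 overflows but the log stays usable
        s = stats(n1=10_000, n2=10_000, m1=1.0)
        res = aafbf(s)
        assert res.bf_0alt == 0.0 or res.bf_0alt < 1e-300
        assert np.isfinite(res.log_bf_0alt)

    def test_serialization_keys(self):
        d = aafbf(stats(), Hypothesis.ONE_SIDED, FractionSpec(2)).to_dict()
        assert set(d) == {
            "fit_0", "complexity_0", "fit_alt", "complexity_alt",
            "bf_0alt", "bf_alt0", "hypothesis", "fraction_multiplier",
        }
        assert d["fraction_multiplier"] == 2
        assert d["complexity_alt"] == 0.5


class TestRawDataInvariances:
    def test_location_shift_leaves_bf_unchanged(self):
        rng = np.random.default_rng(11)
        g1, g2 = rng.normal(0.3, 1, 40), rng.normal(0, 1.2, 35)
        for hyp in Hypothesis:
            a = bf_from_raw(g1, g2, UQ, hyp)
            b = bf_from_raw(g1 + 100, g2 + 100, UQ, hyp)
            assert a.bf_0alt == pytest.approx(b.bf_0alt, rel=1e-9)

    def test_common_rescaling_leaves_bf_unchanged(self):
        rng = np.random.default_rng(12)
        g1, g2 = rng.normal(0.3, 1, 30), rng.normal(0, 1, 30)
        a = bf_from_raw(g1, g2, EQ)
        b = bf_from_raw(3 * g1, 3 * g2, EQ)
        assert a.bf_0alt == pytest.approx(b.bf_0alt, rel=1e-9)
        # densities each scale by 1/k
        assert b.fit_0 == pytest.approx(a.fit_0 / 3, rel=1e-9)
        assert b.complexity_0 == pytest.approx(a.complexity_0 / 3, rel=1e-9)

    def test_identical_large_samples_support_the_null(self):
        rng = np.random.default_rng(13)
        g = rng.normal(0, 1, 500)
        assert bf_from_raw(g, g + 1e-9, EQ).bf_0alt > 1


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    n1=st.integers(5, 300),
    n2=st.integers(5, 300),
    m1=st.floats(-2, 2),
    m2=st.floats(-2, 2),
    v1=st.floats(0.05, 10),
    v2=st.floats(0.05, 10),
    mult=st.sampled_from([1, 2, 3]),
    welch=st.booleans(),
    onesided=st.booleans(),
)
def test_bf_invariants_hold_on_random_instances(n1, n2, m1, m2, v1, v2, mult, welch, onesided):
    """Reciprocal consistency, sqrt(m) scaling, and positivity, on random stats."""
    model = UQ if welch else EQ
    hyp = Hypothesis.ONE_SIDED if onesided else Hypothesis.TWO_SIDED
    s = SummaryStats(n1=n1, n2=n2, mean1=m1, mean2=m2, var1=v1, var2=v2, model=model)
    res = aafbf(s, hyp, FractionSpec(mult))
    assert res.fit_0 >= 0 and res.complexity_0 > 0
    assert np.isfinite(res.log_bf_0alt)
    assert res.bf_0alt * res.bf_alt0 == pytest.approx(1.0, rel=1e-12, abs=1e-300)
    if hyp is Hypothesis.ONE_SIDED:
        assert res.complexity_alt == 0.5
        assert 0.0 <= res.fit_alt <= 1.0
    base = aafbf(s, hyp, FractionSpec(1))
    # BF21 carries no fraction, so BF_0alt scales exactly as 1/sqrt(m)
    assert res.log_bf_0alt == pytest.approx(
        base.log_bf_0alt - 0.5 * np.log(mult), rel=1e-10, abs=1e-10
    )
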