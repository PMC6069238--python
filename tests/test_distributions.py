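"""Lognormal fitting, censoring substitution and the closed-form algebra."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dustintake as di
from dustintake.errors import (
    DataError,
    InsufficientDataError,
    InvalidCompositionError,
    InvalidSummaryError,
    InvalidTableError,
)


class TestFitFromMoments:
    @pytest.mark.parametrize(
        "mean,sd,exp_mu,exp_sigma",
        [
            (2.32, 15.41, -1.063, 1.952),   # dust concentration row
            (26.65, 36.54, 2.754, 1.029),   # dust ingestion-rate row
        ],
    )
    def test_survey_rows(self, mean, sd, exp_mu, exp_sigma):
        spec = di.fit_from_moments(di.SummaryMoments(mean, sd))
        assert spec.mu == pytest.approx(exp_mu, abs=1e-3)
        assert spec.sigma == pytest.approx(exp_sigma, abs=1e-3)

    def test_simulation_cross_check(self, rng):
        """Moment matching agrees with the sample moments of large draws."""
        spec = di.fit_from_moments(di.SummaryMoments(2.32, 15.41))
        draws = spec.sample(10**7, rng)
        # heavy tail (sigma ~ 1.95): the sample mean is slow; generous band
        assert draws.mean() == pytest.approx(2.32, rel=0.05)
        assert np.median(draws) == pytest.approx(spec.median, rel=0.01)

    def test_zero_sd_is_point_mass(self):
        spec = di.fit_from_moments(di.SummaryMoments(3.5, 0.0))
        assert spec.is_point_mass
        assert spec.mean == pytest.approx(3.5)

    @pytest.mark.parametrize("mean,sd", [(-1.0, 1.0), (0.0, 1.0), (1.0, -0.1)])
    def test_invalid_summary(self, mean, sd):
        with pytest.raises(InvalidSummaryError):
            di.SummaryMoments(mean, sd)

    @given(
        mean=st.floats(0.01, 1e3),
        sd=st.floats(0.01, 1e3),
    )
    def test_round_trip_moments(self, mean, sd):
        """Analytic mean/SD of the fitted spec reproduce the inputs."""
        spec = di.fit_from_moments(di.SummaryMoments(mean, sd))
        assert spec.mean == pytest.approx(mean, rel=1e-12)
        assert spec.sd == pytest.approx(sd, rel=1e-12)


class TestFitFromPercentiles:
    def test_two_point_exact(self):
        table = di.PercentileTable([(0.25, math.exp(-1)), (0.75, math.exp(1))])
        spec = di.fit_from_percentiles(table)
        assert spec.mu == pytest.approx(0.0, abs=1e-12)
        assert spec.sigma == pytest.approx(1.4826, abs=1e-3)

    def test_growth_chart_row(self):
        """The 7-point body-weight chart fits tightly in probit space."""
        table = di.PercentileTable(
            [(0.03, 13.5), (0.15, 15.1), (0.25, 15.8), (0.50, 17.3),
             (0.75, 19.0), (0.85, 20.1), (0.97, 22.9)]
        )
        spec = di.fit_from_percentiles(table)
        assert spec.mu == pytest.approx(2.858, abs=0.01)
        assert spec.sigma == pytest.approx(0.140, abs=0.01)
        from scipy.stats import norm

        resid = np.log(table.values) - (spec.mu + spec.sigma * norm.ppf(table.probabilities))
        assert np.max(np.abs(resid)) < 0.02

    def test_single_entry_rejected(self):
        with pytest.raises(InsufficientDataError):
            di.fit_from_percentiles(di.PercentileTable([(0.5, 17.3)]))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(DataError):
            di.fit_from_percentiles(di.PercentileTable([(0.25, 0.0), (0.75, 1.0)]))

    def test_duplicate_probabilities_rejected(self):
        with pytest.raises(InvalidTableError):
            di.PercentileTable([(0.5, 1.0), (0.5, 2.0)])

    @given(
        mu=st.floats(-3, 3),
        sigma=st.floats(0.05, 3),
    )
    def test_exact_recovery_from_consistent_table(self, mu, sigma):
        """An exactly lognormal-consistent table recovers (mu, sigma)."""
        truth = di.LognormalSpec(mu, sigma)
        table = di.generate_growth_chart(truth, (0.03, 0.15, 0.25, 0.5, 0.75, 0.85, 0.97))
        spec = di.fit_from_percentiles(table)
        assert spec.mu == pytest.approx(mu, abs=1e-9)
        assert spec.sigma == pytest.approx(sigma, abs=1e-9)


class TestHalfLodSubstitution:
    def test_mixed_sample(self):
        sample = di.CensoredSample(values=[0.01, 0.08], censored=[True, False], lod=0.025)
        assert di.substitute_half_lod(sample) == [0.0125, 0.08]

    def test_no_censoring_identity(self):
        sample = di.CensoredSample(values=[0.1, 0.2], censored=[False, False], lod=0.025)
        assert di.substitute_half_lod(sample) == [0.1, 0.2]

    def test_empty_sample(self):
        sample = di.CensoredSample(values=[], censored=[], lod=0.025)
        assert di.substitute_half_lod(sample) == []

    def test_invalid_lod(self):
        with pytest.raises(DataError):
            di.CensoredSample(values=[0.1], censored=[False], lod=0.0)

    @given(st.data())
    def test_substitution_preserves_structure(self, data):
        n = data.draw(st.integers(0, 30))
        values = data.draw(
            st.lists(st.floats(0.0, 100.0), min_size=n, max_size=n)
        )
        flags = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        lod = data.draw(st.floats(0.001, 10.0))
        sample = di.CensoredSample(values=values, censored=flags, lod=lod)
        out = di.substitute_half_lod(sample)
        assert len(out) == n
        for v, c, o in zip(values, flags, out):
            assert o == (lod / 2.0 if c else v)


class TestFitFromCensored:
    def test_parameter_recovery(self):
        """Negligible censoring: moment fit of 1e5 draws recovers the truth."""
        truth = di.LognormalSpec(0.0, 1.0)
        spec_gen = di.SyntheticStudySpec(
            truth_ir=truth, truth_conc=truth, truth_bw=truth,
            n_homes=100_000, lod=truth.quantile(1e-4), seed=11,
        )
        sample = di.generate_censored_concentrations(spec_gen)
        fitted = di.fit_from_censored(sample)
        assert fitted.mu == pytest.approx(0.0, abs=0.02)
        assert fitted.sigma == pytest.approx(1.0, abs=0.02)

    def test_all_censored_gives_point_mass(self):
        sample = di.CensoredSample(
            values=[0.01, 0.02, 0.01], censored=[True, True, True], lod=0.05
        )
        fitted = di.fit_from_censored(sample)
        assert fitted.is_point_mass
        assert fitted.mean == pytest.approx(0.025)

    def test_constant_sample(self):
        sample = di.CensoredSample(values=[2.0, 2.0, 2.0], censored=[False] * 3, lod=0.01)
        fitted = di.fit_from_censored(sample)
        assert fitted.is_point_mass
        assert fitted.mu == pytest.approx(math.log(2.0))

    def test_too_few_observations(self):
        sample = di.CensoredSample(values=[1.0, 2.0], censored=[False, False], lod=0.01)
        with pytest.raises(InsufficientDataError):
            di.fit_from_censored(sample)


class TestQuantileAndAlgebra:
    @pytest.mark.parametrize(
        "mu,sigma,p,expected",
        [
            (0.0, 1.0, 0.5, 1.0),
            (0.0, 1.0, 0.975, 7.0993),  # exp(1.95996)
            (1.3, 0.7, 0.5, math.exp(1.3)),
        ],
    )
    def test_quantile_values(self, mu, sigma, p, expected):
        assert di.lognormal_quantile(di.LognormalSpec(mu, sigma), p) == pytest.approx(
            expected, rel=1e-4
        )

    def test_quantile_domain(self):
        with pytest.raises(DataError):
            di.lognormal_quantile(di.LognormalSpec(0, 1), 1.0)

    @given(
        mu=st.floats(-5, 5),
        sigma=st.floats(0.01, 3),
        p1=st.floats(0.01, 0.98),
        dp=st.floats(0.001, 0.01),
    )
    def test_quantile_strictly_increasing(self, mu, sigma, p1, dp):
        spec = di.LognormalSpec(mu, sigma)
        assert spec.quantile(p1 + dp) > spec.quantile(p1)

    def test_combine_identity(self):
        spec = di.LognormalSpec(0.0, 1.0)
        out = di.combine_product_quotient([spec], scale=1.0)
        assert out.mu == pytest.approx(0.0) and out.sigma == pytest.approx(1.0)

    def test_combine_log_variance_additivity(self):
        out = di.combine_product_quotient(
            [di.LognormalSpec(0, 0.6), di.LognormalSpec(0, 0.8)]
        )
        assert out.sigma == pytest.approx(1.0)
        assert out.mu == pytest.approx(0.0)

    def test_combine_empty_numerators(self):
        with pytest.raises(InvalidCompositionError):
            di.combine_product_quotient([], [di.LognormalSpec(0, 1)])

    def test_combine_matches_brute_force_monte_carlo(self, rng):
        """Product/quotient law vs direct simulation at P50/P90/P99."""
        a = di.LognormalSpec(0.5, 0.9)
        b = di.LognormalSpec(-0.2, 1.3)
        c = di.LognormalSpec(1.0, 0.3)
        combined = di.combine_product_quotient([a, b], [c], scale=2.0)
        n = 10**6
        draws = 2.0 * a.sample(n, rng) * b.sample(n, rng) / c.sample(n, rng)
        for p in (0.5, 0.9, 0.99):
            emp = np.quantile(draws, p, method="inverted_cdf")
            assert emp == pytest.approx(combined.quantile(p), rel=0.02)


class TestRsd:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(26.65, 36.54, 1.37), (2.32, 15.41, 6.64), (5.0, 0.0, 0.0)],
    )
    def test_values(self, mean, sd, expected):
        assert round(di.rsd(di.SummaryMoments(mean, sd)), 2) == expected


class TestConsistencyDiagnostics:
    def test_inconsistent_row_is_flagged_not_corrected(self):
        """A summary row whose moments and P95 disagree under one lognormal
        is surfaced as a diagnostic; the fitted spec still matches the moments."""
        diag = di.scenario_consistency("cypermethrin_dust")
        assert diag["concentration"]["flagged"]
        sc = di.load_scenario("cypermethrin_dust")
        assert sc.conc.mean == pytest.approx(18.33, rel=1e-9)
        assert sc.conc.sd == pytest.approx(55.92, rel=1e-9)
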