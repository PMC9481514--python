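"""Forward probability computations: sensory, distance moments, liking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import chi2, norm

from grtunfold import (
    ConditioningError,
    CriteriaOrderError,
    DimensionMismatchError,
    IdealDistribution,
    ModelSpec,
    StimulusDistribution,
    count_free_parameters,
    delta_squared_moments,
    difference_distribution,
    liking_rating_probabilities_approx,
    liking_rating_probabilities_exact,
    luce_choice_probability,
    predicted_frequency_array,
    predicted_probability_array,
    predicted_sensory_array,
    quadform_decomposition,
    sensory_rating_probabilities,
)
from grtunfold.model import chi2_equal_covariance_liking_probabilities

from conftest import random_ideal


class TestSensoryRatingProbabilities:
    @pytest.mark.parametrize(
        "mean, criteria, expected",
        [
            (0.0, [0.0], [0.5, 0.5]),
            # oracle: numerical integration of the unit-normal pdf per interval
            (0.5, [-1.0, 0.0, 1.0], [0.0668072, 0.2417303, 0.3829249, 0.3085375]),
        ],
    )
    def test_known_values(self, mean, criteria, expected):
        probs = sensory_rating_probabilities(mean, np.array(criteria))
        np.testing.assert_allclose(probs, expected, atol=1e-7)

    def test_agrees_with_quadrature(self):
        mean, criteria = -0.7, np.array([-1.3, 0.2, 0.9])
        probs = sensory_rating_probabilities(mean, criteria)
        cuts = np.concatenate([[-8.0 + mean], criteria, [8.0 + mean]])
        oracle = [
            integrate.quad(lambda x: norm.pdf(x, mean, 1.0), a, b)[0]
            for a, b in zip(cuts[:-1], cuts[1:])
        ]
        np.testing.assert_allclose(probs, oracle, atol=1e-9)

    @given(
        mean=st.floats(-5, 5),
        start=st.floats(-3, 3),
        gaps=st.lists(st.floats(0.01, 2), min_size=1, max_size=8),
    )
    @settings(deadline=None)
    def test_normalization(self, mean, start, gaps):
        criteria = start + np.cumsum([0.0] + gaps)
        probs = sensory_rating_probabilities(mean, criteria)
        assert abs(probs.sum() - 1.0) < 1e-12
        assert np.all(probs >= 0)

    def test_nonmonotone_criteria_rejected(self):
        with pytest.raises(CriteriaOrderError):
            sensory_rating_probabilities(0.0, np.array([1.0, 0.0]))


class TestPredictedSensoryArray:
    def test_matches_per_cell_computation(self, model_small):
        arr = predicted_sensory_array(model_small)
        for i, stim in enumerate(model_small.stimuli):
            for d in range(model_small.spec.n_dims):
                expected = sensory_rating_probabilities(
                    stim.mean[d], model_small.criteria.sensory[d]
                )
                np.testing.assert_allclose(arr[i, d], expected, atol=1e-14)
        np.testing.assert_allclose(arr.sum(axis=2), 1.0, atol=1e-12)

    def test_identical_means_give_identical_slices(self, model_small):
        from grtunfold import CriteriaSet, GrtUnfoldingModel

        stimuli = tuple(
            StimulusDistribution(stimulus_id=s.stimulus_id, mean=np.zeros(2))
            for s in model_small.stimuli
        )
        model = GrtUnfoldingModel(
            spec=model_small.spec,
            stimuli=stimuli,
            ideal=model_small.ideal,
            criteria=model_small.criteria,
        )
        arr = predicted_sensory_array(model)
        assert np.all(arr == arr[0])


class TestDifferenceDistribution:
    def test_definition(self, rng):
        ideal = random_ideal(rng, 3)
        stim = StimulusDistribution("s", rng.normal(size=3))
        diff = difference_distribution(ideal, stim)
        np.testing.assert_allclose(diff.mean, ideal.mean - stim.mean)
        np.testing.assert_allclose(diff.covariance - ideal.covariance, np.eye(3))

    def test_dimension_mismatch(self, rng):
        ideal = random_ideal(rng, 3)
        with pytest.raises(DimensionMismatchError):
            difference_distribution(ideal, StimulusDistribution("s", np.zeros(2)))


class TestDeltaSquaredMoments:
    @pytest.mark.parametrize(
        "dim, cov, mu_w, expected_mean, expected_var",
        [
            # Sigma_Y = I, equal means: Delta^2 = 2 * chi2_D
            (6, np.eye(6), np.zeros(6), 12.0, 48.0),
            (1, np.eye(1), np.zeros(1), 2.0, 8.0),
            # oracle: Monte Carlo over draws of w (frozen: mean 6.9978, var 49.48
            # over 2e6 draws) and the quadratic-form decomposition identity
            (2, np.diag([2.0, 0.5]), np.array([1.0, 1.0]), 7.0, 49.5),
        ],
    )
    def test_closed_forms(self, dim, cov, mu_w, expected_mean, expected_var):
        ideal = IdealDistribution(mean=mu_w, covariance=cov)
        stim = StimulusDistribution("s", np.zeros(dim))
        mom = delta_squared_moments(ideal, stim)
        assert mom.mean == pytest.approx(expected_mean, abs=1e-12)
        assert mom.variance == pytest.approx(expected_var, abs=1e-12)

    def test_moment_lower_bounds(self, rng):
        # mean >= D and variance >= 2D for any positive-definite ideal cov
        for _ in range(50):
            d = int(rng.integers(1, 6))
            ideal = random_ideal(rng, d)
            mom = delta_squared_moments(ideal, StimulusDistribution("s", rng.normal(size=d)))
            assert mom.mean >= d
            assert mom.variance >= 2 * d

    def test_singular_covariance_rejected(self):
        with pytest.raises(ConditioningError, match="eigenvalue"):
            IdealDistribution(mean=np.zeros(2), covariance=np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestQuadformDecomposition:
    def test_identity_covariance(self, rng):
        for d in (1, 3, 6):
            ideal = IdealDistribution(mean=np.zeros(d), covariance=np.eye(d))
            dec = quadform_decomposition(ideal, StimulusDistribution("s", np.zeros(d)))
            np.testing.assert_allclose(dec.weights, 2.0)
            np.testing.assert_allclose(dec.noncentralities, 0.0)

    def test_diagonal_example(self):
        ideal = IdealDistribution(mean=np.array([1.0, 1.0]), covariance=np.diag([2.0, 0.5]))
        dec = quadform_decomposition(ideal, StimulusDistribution("s", np.zeros(2)))
        np.testing.assert_allclose(sorted(dec.weights), [1.5, 3.0])
        np.testing.assert_allclose(sorted(dec.noncentralities), [1 / 3, 2 / 3])
        assert dec.implied_mean == pytest.approx(7.0, abs=1e-10)
        assert dec.implied_variance == pytest.approx(49.5, abs=1e-10)

    def test_moment_identity_over_random_models(self, rng):
        # decomposition-implied moments must equal the closed forms
        for _ in range(200):
            d = int(rng.integers(1, 7))
            ideal = random_ideal(rng, d)
            stim = StimulusDistribution("s", rng.normal(size=d))
            dec = quadform_decomposition(ideal, stim)
            mom = delta_squared_moments(ideal, stim)
            assert dec.implied_mean == pytest.approx(mom.mean, rel=1e-8)
            assert dec.implied_variance == pytest.approx(mom.variance, rel=1e-8)


class TestLikingProbabilitiesApprox:
    def test_normal_cdf_example(self):
        # moments (7, 49.5); middle rating mass between squared criteria 1 and 9
        ideal = IdealDistribution(mean=np.array([1.0, 1.0]), covariance=np.diag([2.0, 0.5]))
        stim = StimulusDistribution("s", np.zeros(2))
        probs = liking_rating_probabilities_approx(ideal, stim, np.array([3.0, 1.0]))
        s = np.sqrt(49.5)
        expected_mid = norm.cdf(2.0 / s) - norm.cdf(-6.0 / s)
        assert probs[1] == pytest.approx(expected_mid, abs=1e-12)
        assert probs[1] == pytest.approx(0.415, abs=1e-3)

    def test_single_criterion_limits(self, rng):
        # a huge single criterion leaves one effective interval: all mass on
        # the top rating; a vanishing criterion starves the top rating under
        # the exact law
        ideal = random_ideal(rng, 3)
        stim = StimulusDistribution("s", rng.normal(size=3))
        approx_top = liking_rating_probabilities_approx(ideal, stim, np.array([1e4]))
        assert approx_top[-1] == pytest.approx(1.0, abs=1e-9)
        exact_tiny = liking_rating_probabilities_exact(
            ideal, stim, np.array([1e-6]), method="inversion"
        )
        assert exact_tiny[-1] == pytest.approx(0.0, abs=1e-6)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50)
    def test_normalization(self, seed):
        r = np.random.default_rng(seed)
        ideal = random_ideal(r, int(r.integers(1, 6)))
        stim = StimulusDistribution("s", r.normal(size=ideal.n_dims))
        lik = np.sort(r.uniform(0.2, 8.0, size=int(r.integers(1, 6))))[::-1]
        lik = np.unique(lik)[::-1]
        probs = liking_rating_probabilities_approx(ideal, stim, lik)
        assert abs(probs.sum() - 1.0) < 1e-12


class TestLikingProbabilitiesExact:
    def test_chi2_limit(self):
        # Sigma_Y = I and equal means: Delta^2 = 2 chi2_6
        ideal = IdealDistribution(mean=np.zeros(6), covariance=np.eye(6))
        stim = StimulusDistribution("s", np.zeros(6))
        lik = np.array([3.0, 2.0, 1.0])
        probs = liking_rating_probabilities_exact(ideal, stim, lik, method="inversion")
        assert probs[3] == pytest.approx(chi2.cdf(0.5, 6), abs=1e-6)
        assert probs[2] == pytest.approx(chi2.cdf(2.0, 6) - chi2.cdf(0.5, 6), abs=1e-6)
        oracle = chi2_equal_covariance_liking_probabilities(lik, 6)
        np.testing.assert_allclose(probs, oracle, atol=1e-6)

    def test_montecarlo_agrees_with_inversion(self, rng):
        ideal = random_ideal(rng, 3)
        stim = StimulusDistribution("s", rng.normal(size=3))
        lik = np.array([6.0, 3.0, 1.5])
        n_draws = 200_000
        p_inv = liking_rating_probabilities_exact(ideal, stim, lik, method="inversion")
        p_mc = liking_rating_probabilities_exact(
            ideal, stim, lik, method="montecarlo", n_draws=n_draws, seed=5
        )
        se = np.sqrt(np.maximum(p_inv * (1 - p_inv), 1e-12) / n_draws)
        assert np.all(np.abs(p_mc - p_inv) <= 3 * se + 1e-5)

    def test_one_dimensional_reduction(self):
        # at D=1 the distance is |w| with w ~ N(mu_W, sigma2_Y + 1); the exact
        # path must match direct normal-CDF integration on the distance scale
        sigma2 = 0.7
        mu_w = 1.3
        ideal = IdealDistribution(mean=np.array([mu_w]), covariance=np.array([[sigma2]]))
        stim = StimulusDistribution("s", np.zeros(1))
        lik = np.array([3.0, 1.5, 0.5])
        probs = liking_rating_probabilities_exact(ideal, stim, lik, method="inversion")
        sd_w = np.sqrt(sigma2 + 1.0)

        def p_distance_interval(a, b):
            # P(a < |w|/sqrt(sigma2) <= b)
            lo, hi = a * np.sqrt(sigma2), b * np.sqrt(sigma2)
            return (
                norm.cdf(hi, mu_w, sd_w)
                - norm.cdf(lo, mu_w, sd_w)
                + norm.cdf(-lo, mu_w, sd_w)
                - norm.cdf(-hi, mu_w, sd_w)
            )

        bounds = np.concatenate([[np.inf], lik, [0.0]])
        oracle = [p_distance_interval(bounds[j + 1], bounds[j]) for j in range(4)]
        np.testing.assert_allclose(probs, oracle, atol=1e-6)

    def test_unknown_method_rejected(self, rng):
        ideal = random_ideal(rng, 2)
        with pytest.raises(ValueError, match="method"):
            liking_rating_probabilities_exact(
                ideal, StimulusDistribution("s", np.zeros(2)), np.array([1.0]), method="bogus"
            )

    def test_top_rating_monotone_in_displacement(self):
        # moving the stimulus farther from the ideal cannot raise top-rating mass
        ideal = IdealDistribution(
            mean=np.array([1.0, -0.5]), covariance=np.array([[1.5, -0.6], [-0.6, 3.0]])
        )
        lik = np.array([4.0, 2.0, 1.0])
        tops = []
        for c in (1.0, 1.5, 2.0, 4.0):
            stim = StimulusDistribution("s", ideal.mean - c * np.array([0.8, 1.1]))
            probs = liking_rating_probabilities_exact(ideal, stim, lik, method="inversion")
            tops.append(probs[-1])
        assert np.all(np.diff(tops) <= 1e-9)


class TestPredictedFrequencies:
    def test_row_sums_match_design_totals(self, model_small):
        n, d = model_small.spec.n_stimuli, model_small.spec.n_dims
        totals = np.full((n, d + 1), 56.0)
        totals[:, d] = 52.0
        freq = predicted_frequency_array(model_small, totals)
        np.testing.assert_allclose(freq[:, :d].sum(axis=2), 56.0, atol=1e-9)
        np.testing.assert_allclose(freq[:, d].sum(axis=1), 52.0, atol=1e-9)

    def test_zero_totals_and_elementwise_definition(self, model_small):
        assert np.all(predicted_frequency_array(model_small, 0.0) == 0.0)
        probs = predicted_probability_array(model_small)
        freq = predicted_frequency_array(model_small, 10.0)
        np.testing.assert_allclose(freq, 10.0 * probs, atol=1e-12)


class TestLuceChoice:
    @pytest.mark.parametrize(
        "v_a, v_b, expected",
        [(2.0, 2.0, 0.5), (3.0, 1.0, 0.75), (0.0, 1.0, 0.0)],
    )
    def test_values(self, v_a, v_b, expected):
        p = luce_choice_probability(v_a, v_b)
        assert p == pytest.approx(expected)
        assert p + luce_choice_probability(v_b, v_a) == pytest.approx(1.0)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            luce_choice_probability(0.0, 0.0)


class TestCountFreeParameters:
    @pytest.mark.parametrize(
        "n, d, r, expected_items",
        [
            (20, 6, 7, (114, 36, 6, 21, 6)),
            (1, 1, 2, (0, 1, 1, 1, 1)),
            (6, 2, 4, (10, 6, 2, 3, 3)),
        ],
    )
    def test_full_covariance(self, n, d, r, expected_items):
        spec = ModelSpec.create(n, d, r)
        items = count_free_parameters(spec, "full")
        got = (
            items["stimulus_means"],
            items["sensory_criteria"],
            items["ideal_mean"],
            items["ideal_covariance"],
            items["liking_criteria"],
        )
        assert got == expected_items
        assert items["total"] == sum(expected_items)

    def test_diagonal_covariance(self):
        spec = ModelSpec.create(20, 6, 7)
        assert count_free_parameters(spec, "diagonal")["ideal_covariance"] == 6
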