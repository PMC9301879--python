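"""Observer-model likelihoods, estimates, decision strategies and simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventriloquo import (
    LikelihoodParams,
    ObserverSpec,
    PriorParams,
    StimulusPair,
    simulate_av_responses,
)
from ventriloquo.observers import (
    LocationEstimates,
    continuous_responses,
    decide,
    estimate_locations,
    joint_likelihood_common,
    joint_likelihood_independent,
    posterior_common_cause,
)
from ventriloquo.validation import (
    quad_likelihood_common,
    quad_likelihood_independent,
)


class TestJointLikelihoods:
    def test_common_cause_unit_case(self, unit_params):
        lik, prior = unit_params
        expected = 1.0 / (2.0 * np.pi * np.sqrt(3.0))
        assert joint_likelihood_common((0.0, 0.0), lik, prior) == pytest.approx(expected)

    def test_independent_unit_case(self, unit_params):
        lik, prior = unit_params
        assert joint_likelihood_independent((0.0, 0.0), lik, prior) == pytest.approx(
            1.0 / (4.0 * np.pi)
        )

    def test_common_cause_modality_symmetry(self):
        lik = LikelihoodParams(0.0, 2.0, 0.0, 1.0)
        swapped = LikelihoodParams(0.0, 1.0, 0.0, 2.0)
        prior = PriorParams(0.5, 7.0, 0.5)
        assert joint_likelihood_common((3.0, -1.0), lik, prior) == pytest.approx(
            joint_likelihood_common((-1.0, 3.0), swapped, prior)
        )

    def test_independent_factorizes(self):
        lik = LikelihoodParams(0.0, 2.0, 0.0, 1.0)
        prior = PriorParams(1.0, 5.0, 0.5)
        joint = joint_likelihood_independent((3.0, -2.0), lik, prior)
        # product of the two marginals, each a 1-D Gaussian density in closed form
        from scipy.stats import norm

        pA = norm.pdf(3.0, loc=1.0, scale=np.sqrt(4.0 + 25.0))
        pV = norm.pdf(-2.0, loc=1.0, scale=np.sqrt(1.0 + 25.0))
        assert joint == pytest.approx(pA * pV, rel=1e-12)

    @pytest.mark.parametrize(
        "x_A,x_V,lik,prior",
        [
            (1.0, -1.0, LikelihoodParams(0, 2, 0, 1), PriorParams(0, 10, 0.5)),
            (3.0, -2.0, LikelihoodParams(0, 2, 0, 1), PriorParams(1, 5, 0.5)),
        ],
    )
    def test_closed_forms_match_quadrature(self, x_A, x_V, lik, prior):
        assert joint_likelihood_common((x_A, x_V), lik, prior) == pytest.approx(
            quad_likelihood_common(x_A, x_V, lik, prior), rel=1e-6
        )
        assert joint_likelihood_independent((x_A, x_V), lik, prior) == pytest.approx(
            quad_likelihood_independent(x_A, x_V, lik, prior), rel=1e-6
        )

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            LikelihoodParams(0.0, -1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            PriorParams(0.0, 0.0, 0.5)


class TestCausalPosterior:
    def test_extreme_causal_priors(self, unit_params):
        lik, _ = unit_params
        sample = (2.0, -3.0)
        assert posterior_common_cause(sample, lik, PriorParams(0, 1, 1.0)) == 1.0
        assert posterior_common_cause(sample, lik, PriorParams(0, 1, 0.0)) == 0.0

    def test_unit_case_value(self, unit_params):
        lik, prior = unit_params
        c1 = 1.0 / (2.0 * np.pi * np.sqrt(3.0))
        c2 = 1.0 / (4.0 * np.pi)
        assert posterior_common_cause((0.0, 0.0), lik, prior) == pytest.approx(
            c1 / (c1 + c2)
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        pc=st.lists(st.floats(0.01, 0.99), min_size=2, max_size=2, unique=True),
        x_A=st.floats(-20, 20),
        x_V=st.floats(-20, 20),
    )
    def test_monotone_in_causal_prior(self, pc, x_A, x_V):
        lik = LikelihoodParams(0.0, 3.0, 0.0, 1.5)
        lo, hi = sorted(pc)
        p_lo = posterior_common_cause((x_A, x_V), lik, PriorParams(0, 10, lo))
        p_hi = posterior_common_cause((x_A, x_V), lik, PriorParams(0, 10, hi))
        assert p_hi >= p_lo


class TestEstimates:
    def test_no_prior_weighted_average(self):
        lik = LikelihoodParams(0.0, 2.0, 0.0, 1.0)
        est = estimate_locations((10.0, 0.0), lik, use_prior=False)
        assert est.fused == pytest.approx(2.0)
        assert (est.seg_A, est.seg_V) == (10.0, 0.0)

    def test_equal_precision_shrinkage_halves(self):
        lik = LikelihoodParams(0.0, 3.0, 0.0, 1.0)
        prior = PriorParams(0.0, 3.0, 0.5)
        est = estimate_locations((8.0, 0.0), lik, prior)
        assert est.seg_A == pytest.approx(4.0)

    def test_requires_prior_when_flagged(self):
        lik = LikelihoodParams()
        with pytest.raises(ValueError):
            estimate_locations((0.0, 0.0), lik, None, use_prior=True)


class TestDecide:
    def test_model_selection_picks_fused_above_half(self):
        est = LocationEstimates(fused=2.0, seg_A=5.0, seg_V=-1.0, posterior_c1=0.6)
        assert decide("MS", est) == (2.0, 2.0)

    def test_model_selection_tie_segregates(self):
        est = LocationEstimates(fused=2.0, seg_A=5.0, seg_V=-1.0, posterior_c1=0.5)
        assert decide("MS", est) == (5.0, -1.0)

    def test_model_averaging_arithmetic(self):
        est = LocationEstimates(fused=2.0, seg_A=5.0, seg_V=3.0, posterior_c1=0.6)
        s_A, s_V = decide("MA", est)
        assert s_A == pytest.approx(0.6 * 2.0 + 0.4 * 5.0)
        assert s_V == pytest.approx(0.6 * 2.0 + 0.4 * 3.0)

    def test_probability_matching_shares_xi(self):
        fused_est = LocationEstimates(1.0, 9.0, -9.0, posterior_c1=0.7, xi=0.5)
        assert decide("PM", fused_est) == (1.0, 1.0)
        seg_est = LocationEstimates(1.0, 9.0, -9.0, posterior_c1=0.3, xi=0.5)
        assert decide("PM", seg_est) == (9.0, -9.0)

    def test_probability_matching_requires_xi(self):
        est = LocationEstimates(1.0, 2.0, 3.0, posterior_c1=0.5)
        with pytest.raises(ValueError):
            decide("PM", est)

    @settings(max_examples=50, derandomize=True)
    @given(
        p=st.floats(0.0, 1.0),
        fused=st.floats(-20, 20),
        seg=st.floats(-20, 20),
    )
    def test_averaging_bounded_by_branches(self, p, fused, seg):
        est = LocationEstimates(fused, seg, seg, posterior_c1=p)
        s_A, _ = decide("MA", est)
        lo, hi = min(fused, seg), max(fused, seg)
        assert lo - 1e-12 <= s_A <= hi + 1e-12


class TestSimulation:
    def test_histograms_normalized(self):
        spec = ObserverSpec("CI-MA", LikelihoodParams(), PriorParams())
        pred = simulate_av_responses(spec, StimulusPair(-5, 15), n_sim=500, seed=3)
        assert pred.p_A.sum() == pytest.approx(1.0, abs=1e-12)
        assert pred.p_V.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(pred.p_A) == 12

    def test_degenerate_noise_concentrates_on_speaker_button(self):
        spec = ObserverSpec("FFnp", LikelihoodParams(0.0, 0.01, 0.0, 0.01))
        pred = simulate_av_responses(spec, StimulusPair(5, 5), n_sim=200, seed=0)
        assert pred.p_A[7] == 1.0  # button 8
        assert pred.p_V[7] == 1.0

    def test_forced_fusion_predicts_identical_modalities(self):
        spec = ObserverSpec("FF", LikelihoodParams(), PriorParams())
        pred = simulate_av_responses(spec, StimulusPair(-15, 15), n_sim=2000, seed=1)
        np.testing.assert_array_equal(pred.p_A, pred.p_V)

    def test_ci_with_certain_common_cause_collapses_to_forced_fusion(self):
        lik = LikelihoodParams(0.0, 6.0, 0.0, 2.0)
        ci = ObserverSpec("CI-MA", lik, PriorParams(0.0, 25.0, 1.0))
        ff = ObserverSpec("FF", lik, PriorParams(0.0, 25.0, 1.0))
        pair = StimulusPair(-5.0, 15.0)
        p_ci = simulate_av_responses(ci, pair, n_sim=100_000, seed=5)
        p_ff = simulate_av_responses(ff, pair, n_sim=100_000, seed=6)
        tv = 0.5 * np.abs(p_ci.p_A - p_ff.p_A).sum()
        assert tv < 0.01

    def test_deterministic_in_seed(self):
        spec = ObserverSpec("CI-PM", LikelihoodParams(), PriorParams())
        a = simulate_av_responses(spec, StimulusPair(-5, 5), n_sim=1000, seed=9)
        b = simulate_av_responses(spec, StimulusPair(-5, 5), n_sim=1000, seed=9)
        np.testing.assert_array_equal(a.p_A, b.p_A)
        np.testing.assert_array_equal(a.p_V, b.p_V)

    @pytest.mark.parametrize("family", ["CI-MA", "CI-PM", "CI-MS", "FF", "SG"])
    def test_mirror_symmetry(self, family):
        """Symmetric observers produce mirror-image histograms for mirrored pairs."""
        spec = ObserverSpec(
            family, LikelihoodParams(0.0, 6.0, 0.0, 2.0), PriorParams(0.0, 20.0, 0.5)
        )
        n = 200_000
        left = simulate_av_responses(spec, StimulusPair(-15, 5), n_sim=n, seed=2)
        right = simulate_av_responses(spec, StimulusPair(15, -5), n_sim=n, seed=3)
        tv = 0.5 * np.abs(left.p_A - right.p_A[::-1]).sum()
        assert tv < 0.02

    def test_rejects_prior_for_no_prior_family(self):
        with pytest.raises(ValueError):
            ObserverSpec("FFnp", LikelihoodParams(), PriorParams())
        with pytest.raises(ValueError):
            ObserverSpec("CI-MA", LikelihoodParams(), None)

    def test_probability_matching_selects_per_trial_posterior(self):
        """CI-PM picks the fused branch exactly when the posterior beats ξ,
        with one shared ξ for the A and V responses of a trial."""
        lik = LikelihoodParams(0.0, 6.0, 0.0, 2.0)
        prior = PriorParams(0.0, 25.0, 0.5)
        spec = ObserverSpec("CI-PM", lik, prior)
        rng = np.random.default_rng(11)
        x_A = rng.normal(-5.0, 6.0, size=5000)
        x_V = rng.normal(5.0, 2.0, size=5000)
        xi = rng.uniform(size=5000)
        r_A, r_V = continuous_responses(spec, x_A, x_V, xi)
        post = posterior_common_cause((x_A, x_V), lik, prior)
        fused = continuous_responses(ObserverSpec("FF", lik, prior), x_A, x_V)[0]
        seg_A = continuous_responses(ObserverSpec("SG", lik, prior), x_A, x_V)[0]
        seg_V = continuous_responses(ObserverSpec("SG", lik, prior), x_A, x_V)[1]
        common = post > xi
        np.testing.assert_allclose(r_A, np.where(common, fused, seg_A))
        np.testing.assert_allclose(r_V, np.where(common, fused, seg_V))
        # both branches actually occur
        assert 0.05 < common.mean() < 0.95
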