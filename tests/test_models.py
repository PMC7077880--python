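import itertools
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import contextprob as cp
from contextprob.models import (
    FrequencyState,
    free_parameter_names,
    predict_core,
    rw_features,
    window_features,
)


def state(f_s, f_os):
    return FrequencyState.from_frequencies(f_s, f_os)


class TestWeightProbability:
    def test_identity_at_gamma_one(self):
        f = np.linspace(0, 1, 11)
        assert np.allclose(cp.weight_probability(f, 1.0), f)

    @pytest.mark.parametrize("gamma", [0.3, 0.61, 1.0, 2.5])
    def test_endpoints_fixed(self, gamma):
        assert cp.weight_probability(0.0, gamma) == 0.0
        assert cp.weight_probability(1.0, gamma) == pytest.approx(1.0)

    def test_high_precision_value(self):
        # frozen from a 30-digit symbolic evaluation of the weighting function
        assert cp.weight_probability(0.1, 0.61) == pytest.approx(
            0.186302566377174150511752411145, abs=1e-12
        )

    def test_small_probabilities_overweighted_below_one(self):
        assert cp.weight_probability(0.05, 0.6) > 0.05
        assert cp.weight_probability(0.9, 0.6) < 0.9

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0.28, 5.0),
        st.floats(0.0, 0.99),
        st.floats(1e-3, 0.01),
    )
    def test_strictly_increasing_on_monotone_region(self, gamma, f, df):
        """The one-parameter weighting form is strictly increasing for
        curvature above ~0.279; below that it is famously non-monotone."""
        assert cp.weight_probability(f + df, gamma) > cp.weight_probability(f, gamma)

    def test_known_non_monotonicity_at_extreme_curvature(self):
        # characterizes the classic breakdown of this functional form
        assert cp.weight_probability(0.27, 0.125) < cp.weight_probability(0.25, 0.125)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.05, 5.0), st.floats(0.01, 0.99))
    def test_complement_symmetry_only_at_one(self, gamma, f):
        s = cp.weight_probability(f, gamma) + cp.weight_probability(1 - f, gamma)
        if math.isclose(gamma, 1.0):
            assert s == pytest.approx(1.0)
        # asymmetric in general; at gamma=1 exactly symmetric
        assert cp.weight_probability(f, 1.0) + cp.weight_probability(1 - f, 1.0) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cp.weight_probability(1.2, 0.5)
        with pytest.raises(ValueError):
            cp.weight_probability(0.5, 0.0)


class TestURD:
    def test_reference_term_vanishes_when_f_equals_reference(self):
        st_ = FrequencyState(f_S=0.42, f_OS=0.42, f_overall=0.42, sigma_hat=0.49, sigma_sq_hat=0.24)
        assert cp.predict_urd(st_, cp.ModelSpec("URD"), cp.ModelParams()) == pytest.approx(0.42)

    def test_hand_worked_value(self):
        # f_S = .5, f_overall = .3, sigma = .5 -> .5 + .5 * .2 = .6
        st_ = FrequencyState(f_S=0.5, f_OS=0.1, f_overall=0.3, sigma_hat=0.5, sigma_sq_hat=0.25)
        assert cp.predict_urd(st_, cp.ModelSpec("URD"), cp.ModelParams()) == pytest.approx(0.6)

    def test_zero_uncertainty_gates_context(self):
        st_ = FrequencyState(f_S=1.0, f_OS=0.1, f_overall=0.55, sigma_hat=0.0, sigma_sq_hat=0.0)
        assert cp.predict_urd(st_, cp.ModelSpec("URD"), cp.ModelParams()) == pytest.approx(1.0)

    def test_loss_aversion_scales_negative_deviations_only(self):
        spec = cp.ModelSpec("URD", weighted=True, loss_averse=True)
        params = cp.ModelParams(gamma=1.0, lam=2.0)
        below = FrequencyState(f_S=0.4, f_OS=0.8, f_overall=0.6, sigma_hat=0.5, sigma_sq_hat=0.25)
        above = FrequencyState(f_S=0.6, f_OS=0.2, f_overall=0.4, sigma_hat=0.5, sigma_sq_hat=0.25)
        assert cp.predict_urd(below, spec, params) == pytest.approx(0.4 + 2.0 * 0.5 * -0.2)
        assert cp.predict_urd(above, spec, params) == pytest.approx(0.6 + 0.5 * 0.2)

    def test_variance_weighting_uses_sigma_squared(self):
        spec = cp.ModelSpec("URD", uncertainty_stat="variance")
        st_ = FrequencyState(f_S=0.5, f_OS=0.1, f_overall=0.3, sigma_hat=0.5, sigma_sq_hat=0.25)
        assert cp.predict_urd(st_, spec, cp.ModelParams()) == pytest.approx(0.5 + 0.25 * 0.2)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0.0, 0.98),
        st.floats(0.0, 1.0),
        st.floats(0.28, 3.0),
        st.floats(0.0, 0.5),
    )
    def test_monotone_in_f_s(self, f_s, f_os, gamma, sigma):
        """URD prediction strictly increases with f_S when the reference and
        the uncertainty weight are held fixed (1 + tau > 0), for curvature in
        the weighting function's monotone region."""
        spec = cp.ModelSpec("URD", weighted=True, clip=False)
        params = cp.ModelParams(gamma=gamma)
        f_overall = 0.5 * (f_s + f_os)
        lo = FrequencyState(f_s, f_os, f_overall, sigma, sigma**2)
        hi = FrequencyState(f_s + 0.02, f_os, f_overall, sigma, sigma**2)
        assert cp.predict_urd(hi, spec, params) > cp.predict_urd(lo, spec, params)

    def test_context_effect_largest_at_half(self):
        """With a fixed reference offset, |prediction - w| peaks at f_S = 0.5."""
        effects = {}
        for f in (0.1, 0.3, 0.5, 0.7, 0.9):
            st_ = FrequencyState.from_frequencies(f, f)
            st_ = replace(st_, f_overall=f - 0.1)
            pred = cp.predict_urd(st_, cp.ModelSpec("URD"), cp.ModelParams())
            effects[f] = abs(pred - f)
        assert max(effects, key=effects.get) == 0.5


class TestNormalizationModels:
    @pytest.mark.parametrize(
        "f_s,f_os,expected",
        [(0.1, 0.5, 0.167), (0.1, 0.9, 0.1), (0.9, 0.1, 0.9), (0.9, 0.5, 0.643)],
    )
    def test_dn1_parameter_free_worked_examples(self, f_s, f_os, expected):
        params = cp.ModelParams(a=0.0, b=0.0)
        assert round(cp.predict_dn1(state(f_s, f_os), params), 3) == expected

    def test_dn1_predicts_small_effect_at_low_large_at_high(self):
        params = cp.ModelParams(a=0.0, b=0.0)
        low = cp.predict_dn1(state(0.1, 0.5), params) - cp.predict_dn1(state(0.1, 0.9), params)
        high = cp.predict_dn1(state(0.9, 0.1), params) - cp.predict_dn1(state(0.9, 0.5), params)
        assert low == pytest.approx(0.067, abs=5e-4)
        assert high > low

    def test_dn2(self):
        assert cp.predict_dn2(state(0.37, 0.9), cp.ModelParams(a=1.0, b=0.0)) == pytest.approx(0.37)
        assert cp.predict_dn2(state(0.5, 0.5), cp.ModelParams(a=2.0, b=2.0)) == pytest.approx(0.5)
        assert cp.predict_dn2(state(0.5, 0.5), cp.ModelParams(a=1.0, b=5.0)) < 0.15

    def test_rn(self):
        assert cp.predict_rn(state(0.4, 0.4), cp.ModelParams(a=0.0, b=1.0)) == pytest.approx(0.4)
        assert cp.predict_rn(state(0.5, 0.1), cp.ModelParams(a=0.0, b=0.5)) == pytest.approx(
            0.5 / 0.9
        )
        # numerator exceeding denominator clips at 1
        assert cp.predict_rn(state(0.9, 0.8), cp.ModelParams(a=1.0, b=0.2)) == 1.0

    def test_nonpositive_denominators_error(self):
        with pytest.raises(ValueError):
            cp.predict_dn1(state(0.0, 0.0), cp.ModelParams(a=0.0, b=0.0))
        with pytest.raises(ValueError):
            cp.predict_rn(state(0.4, 0.4), cp.ModelParams(a=0.0, b=0.0))
        with pytest.raises(ValueError):
            cp.predict_dn2(state(0.5, 0.5), cp.ModelParams(a=1.0, b=-2.0))

    @settings(deadline=None, derandomize=True)
    @given(
        st.sampled_from(sorted(cp.MODEL_REGISTRY)),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.1, 4.9),
        st.floats(-1.9, 1.9),
        st.floats(0.2, 4.9),
    )
    def test_all_predictions_bounded(self, name, f_s, f_os, gamma, a, b):
        """Every registry model maps frequencies into [0, 1] (after clipping)."""
        spec = cp.get_model_spec(name)
        params = cp.ModelParams(gamma=gamma, a=a, b=b)
        try:
            p = predict_core(spec, params, f_s, f_os)
        except ValueError:
            return  # non-positive denominator is a contracted error
        assert 0.0 <= p <= 1.0


class TestRegistry:
    def test_nine_models_and_free_params(self):
        expected = {
            "URD": (),
            "URD-g": ("gamma",),
            "URD-g-l": ("gamma", "lam"),
            "DN-1": ("a", "b"),
            "DN-2": ("a", "b"),
            "DN-1-g": ("a", "b", "gamma"),
            "DN-2-g": ("a", "b", "gamma"),
            "RN": ("a", "b"),
            "RN-g": ("a", "b", "gamma"),
        }
        assert set(cp.MODEL_REGISTRY) == set(expected)
        for name, params in expected.items():
            assert free_parameter_names(cp.get_model_spec(name)) == params

    def test_rw_framework_adds_learning_rate(self):
        spec = cp.get_model_spec("URD-g", framework="rescorla_wagner")
        assert free_parameter_names(spec) == ("gamma", "alpha")

    def test_unicode_aliases(self):
        assert cp.get_model_spec("URD-γ") == cp.get_model_spec("URD-g")

    def test_loss_aversion_requires_weighted_urd(self):
        with pytest.raises(ValueError):
            cp.ModelSpec("DN1", loss_averse=True)
        with pytest.raises(ValueError):
            cp.ModelSpec("URD", weighted=False, loss_averse=True)

    def test_spec_roundtrip_json(self):
        spec = cp.get_model_spec("DN-2-g")
        assert cp.ModelSpec.from_dict(spec.to_dict()) == spec


def _toy_trials(outcomes_a, outcomes_b, design):
    """Interleave two stimuli of context 1 with the given outcome strings."""
    ctx = design.contexts[0]
    trials = []
    t = 0
    for oa, ob in itertools.zip_longest(outcomes_a, outcomes_b):
        for s, o in ((ctx.stimulus_ids[0], oa), (ctx.stimulus_ids[1], ob)):
            if o is None:
                continue
            trials.append(
                cp.TrialRecord(
                    session="main",
                    block_index=0,
                    trial_index=t,
                    context_id=ctx.context_id,
                    stimulus_id=s,
                    true_prob=ctx.prob_of(s),
                    outcome=int(o),
                    magnitude=int(o),
                )
            )
            t += 1
    return trials


class TestWindowStats:
    def test_hand_example(self, exp1):
        trials = _toy_trials([1, 0, 1, 1, 0], [0, 0, 0, 0, 0], exp1)
        # fifth presentation of stimulus A is trial index 8
        st_ = cp.window_stats(trials, 8, exp1.contexts[0].stimulus_ids[0], n_past=4)
        assert st_.f_S == pytest.approx(0.75)
        assert st_.sigma_hat == pytest.approx(math.sqrt(0.75 * 0.25))
        assert st_.sigma_sq_hat == pytest.approx(st_.sigma_hat**2)

    def test_all_reward_history_has_zero_sigma(self, exp1):
        trials = _toy_trials([1, 1, 1, 1], [1, 1, 1, 1], exp1)
        st_ = cp.window_stats(trials, 6, exp1.contexts[0].stimulus_ids[0], n_past=10)
        assert st_.f_S == 1.0 and st_.sigma_hat == 0.0

    def test_reference_is_mean_of_equal_frequencies(self, exp1):
        trials = _toy_trials([1, 0, 1, 0, 0], [1, 0, 1, 0], exp1)
        # 5th presentation of A (trial 8): both histories are [1,0,1,0]
        st_ = cp.window_stats(trials, 8, exp1.contexts[0].stimulus_ids[0], n_past=4)
        assert st_.f_S == st_.f_OS == st_.f_overall == 0.5

    def test_unseen_stimulus_uses_prior(self, exp1):
        trials = _toy_trials([1], [], exp1)
        st_ = cp.window_stats(trials, 0, exp1.contexts[0].stimulus_ids[0], n_past=5)
        assert st_.f_S == 0.5 and st_.f_OS == 0.5

    def test_statistics_exclude_current_outcome(self, exp1):
        trials = _toy_trials([0, 1], [0, 0], exp1)
        # second presentation of A (trial 2): window sees only the first 0
        st_ = cp.window_stats(trials, 2, exp1.contexts[0].stimulus_ids[0], n_past=5)
        assert st_.f_S == 0.0


class TestRWUpdate:
    def test_full_update(self):
        st_ = cp.rw_update(state(0.5, 0.5), 1, alpha=1.0)
        assert st_.f_S == 1.0

    def test_no_update(self):
        st_ = cp.rw_update(state(0.31, 0.5), 1, alpha=0.0)
        assert st_.f_S == pytest.approx(0.31)

    def test_hand_example(self):
        st_ = cp.rw_update(state(0.5, 0.5), 1, alpha=0.2)
        assert st_.f_S == pytest.approx(0.6)
        assert st_.sigma_sq_hat == pytest.approx(0.24)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            cp.rw_update(state(0.5, 0.5), 1, alpha=1.5)


class TestSeriesEquivalence:
    def test_window_predictions_match_bruteforce_all_length6_histories(self, exp1):
        """Vectorized window features equal a naive recomputation on every
        one of the 64 six-outcome histories."""
        spec = cp.ModelSpec("URD")
        params = cp.ModelParams(n_past=3)
        ctx = exp1.contexts[0]
        for bits in itertools.product((0, 1), repeat=6):
            trials = _toy_trials(bits[:3], bits[3:], exp1)
            ds = cp.SubjectDataset("toy", exp1, trials)
            idx, pred = cp.predict_series(ds, spec, params)
            for i, tr in enumerate(trials):
                st_ = cp.window_stats(trials, tr.trial_index, tr.stimulus_id, 3)
                expected = cp.predict_urd(st_, spec, params)
                assert pred[i] == pytest.approx(expected, abs=1e-12)

    def test_rw_matches_manual_tracker(self, exp1):
        trials = _toy_trials([1, 0, 1, 1], [0, 1, 0, 0], exp1)
        f_s, f_os, _ = rw_features(trials, exp1, alpha=0.3)
        track = {s: 0.5 for s in exp1.stimuli}
        for i, tr in enumerate(trials):
            os_id = exp1.context_of(tr.stimulus_id).other_stimulus(tr.stimulus_id)
            assert f_s[i] == pytest.approx(track[tr.stimulus_id], abs=1e-12)
            assert f_os[i] == pytest.approx(track[os_id], abs=1e-12)
            track[tr.stimulus_id] += 0.3 * (tr.outcome - track[tr.stimulus_id])

    def test_rw_alpha_one_equals_window_one(self, exp1):
        """A full-update tracker reproduces the one-trial window exactly."""
        trials = _toy_trials([1, 0, 1], [0, 1, 1], exp1)
        w_s, w_os, _ = window_features(trials, exp1, n_past=1)
        r_s, r_os, _ = rw_features(trials, exp1, alpha=1.0)
        assert np.allclose(w_s, r_s) and np.allclose(w_os, r_os)

    def test_asymptotic_context_split_at_half(self, exp1):
        """Frequency-matched histories drive the plain URD prediction to
        0.6 for 50% with a 10% partner and 0.4 with a 90% partner."""
        spec = cp.ModelSpec("URD")
        st_low = FrequencyState(f_S=0.5, f_OS=0.1, f_overall=0.3, sigma_hat=0.5, sigma_sq_hat=0.25)
        st_high = FrequencyState(f_S=0.5, f_OS=0.9, f_overall=0.7, sigma_hat=0.5, sigma_sq_hat=0.25)
        assert cp.predict_urd(st_low, spec, cp.ModelParams()) == pytest.approx(0.6)
        assert cp.predict_urd(st_high, spec, cp.ModelParams()) == pytest.approx(0.4)
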