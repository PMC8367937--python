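import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from durdisc import observers, task
from durdisc.observers import (IRM1, IRM2, KALMAN, IRMState, KalmanState,
                               SensoryParams, SubjectParams, decide,
                               initial_state, irm_update, kalman_gain,
                               kalman_update, read_records, records_to_frame,
                               sample_subject_population, sense,
                               simulate_experiment, simulate_trial,
                               steady_state_gain, write_records)
from durdisc.task import LONGER, SHORTER, TrialPlan


class TestSense:
    def test_noiseless_limit_is_log_duration(self, rng):
        x = sense(1.0, SensoryParams(1e-12), rng)
        assert x == pytest.approx(0.0, abs=1e-10)

    def test_monte_carlo_mean_and_sd(self, rng):
        draws = [sense(2.4, SensoryParams(0.2), rng) for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(math.log(2.4), abs=0.005)
        assert np.std(draws) == pytest.approx(0.2, abs=0.005)

    def test_rejects_nonpositive_duration(self, rng):
        with pytest.raises(ValueError):
            sense(0.0, SensoryParams(0.2), rng)


class TestKalmanGain:
    def test_direct_evaluation(self):
        assert kalman_gain(0.0, 0.9, 0.04) == pytest.approx(0.9 / 0.94)
        assert kalman_gain(0.1, 0.0, 0.1) == pytest.approx(0.5)

    def test_noiseless_likelihood_takes_full_weight(self):
        assert kalman_gain(0.2, 0.9, 1e-15) == pytest.approx(1.0)

    def test_rejects_all_zero_variances(self):
        with pytest.raises(ValueError):
            kalman_gain(0.0, 0.0, 0.0)

    @given(vp=st.floats(0, 5), q=st.floats(0.001, 5), vm=st.floats(0.001, 5))
    def test_monotone_in_prior_and_sensory_variance(self, vp, q, vm):
        k = kalman_gain(vp, q, vm)
        assert 0 < k <= 1
        assert kalman_gain(vp + 0.1, q, vm) > k
        assert kalman_gain(vp, q, vm + 0.1) < k


class TestKalmanUpdate:
    def test_chained_evaluation(self):
        state = KalmanState(mu_p=0.0, var_p=0.0, q=0.9, var_m=0.04)
        new, k = kalman_update(state, 1.0)
        assert k == pytest.approx(0.9 / 0.94)
        assert new.mu_p == pytest.approx(0.9 / 0.94)
        assert new.var_p == pytest.approx((0.9 / 0.94) * 0.04)

    def test_posterior_variance_identity(self):
        state = KalmanState(mu_p=0.3, var_p=0.5, q=0.9, var_m=0.09)
        new, k = kalman_update(state, -1.0)
        assert new.var_p == pytest.approx(k * state.var_m)
        assert new.var_p < state.var_m

    @given(mu=st.floats(-3, 3), vp=st.floats(0, 2))
    def test_prior_mean_is_fixed_point(self, mu, vp):
        state = KalmanState(mu_p=mu, var_p=vp, q=0.9, var_m=0.04)
        new, _ = kalman_update(state, mu)
        assert new.mu_p == pytest.approx(mu)

    def test_q_zero_matches_conjugate_gaussian_posterior(self, rng):
        """With no process noise the filter is exact Bayesian conjugacy."""
        mu0, v0, vm = 0.4, 1.3, 0.09
        xs = rng.normal(0.0, 0.5, size=25)
        state = KalmanState(mu_p=mu0, var_p=v0, q=0.0, var_m=vm)
        for i, x in enumerate(xs, start=1):
            state, _ = kalman_update(state, float(x))
            precision = 1.0 / v0 + i / vm
            post_mean = (mu0 / v0 + xs[:i].sum() / vm) / precision
            assert state.mu_p == pytest.approx(post_mean, abs=1e-9)
            assert state.var_p == pytest.approx(1.0 / precision, abs=1e-9)


class TestSteadyStateGain:
    @pytest.mark.parametrize("q,vm,expected", [(0.9, 0.04, 0.9591),
                                               (0.9, 0.36, 0.7656)])
    def test_quadratic_root(self, q, vm, expected):
        assert steady_state_gain(q, vm) == pytest.approx(expected, abs=1e-4)

    def test_volatile_prior_limit(self):
        assert steady_state_gain(1e6, 0.04) == pytest.approx(1.0, abs=1e-3)

    @given(q=st.floats(0.01, 5), vm=st.floats(0.01, 5))
    def test_iterated_updates_converge_to_fixed_point(self, q, vm):
        state = KalmanState(mu_p=0.0, var_p=vm + q, q=q, var_m=vm)
        for _ in range(100):
            state, k = kalman_update(state, 0.0)
        assert k == pytest.approx(steady_state_gain(q, vm), abs=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            steady_state_gain(0.0, 0.1)


class TestIRMUpdate:
    @pytest.mark.parametrize("g,prev,x,expected", [(0.15, 0.0, 1.0, 0.85),
                                                   (0.0, 5.0, 2.0, 2.0),
                                                   (0.5, 2.0, 4.0, 3.0)])
    def test_ewma_examples(self, g, prev, x, expected):
        state = IRMState(I=prev, g=g)
        assert irm_update(state, x).I == pytest.approx(expected)

    @given(g=st.floats(0, 0.99), i0=st.floats(-2, 2),
           xs=st.lists(st.floats(-2, 2), min_size=1, max_size=12))
    def test_matches_closed_form_expansion(self, g, i0, xs):
        state = IRMState(I=i0, g=g)
        for x in xs:
            state = irm_update(state, x)
        n = len(xs)
        closed = (1 - g) * sum(g**j * xs[n - 1 - j] for j in range(n)) \
            + g**n * i0
        assert state.I == pytest.approx(closed, abs=1e-9)


class TestDecide:
    def test_orders(self, rng):
        assert decide(0.1, 0.3, rng) == LONGER
        assert decide(0.3, 0.1, rng) == SHORTER

    def test_ties_break_fairly(self, rng):
        longer = sum(decide(0.2, 0.2, rng) == LONGER for _ in range(4000))
        assert 0.45 < longer / 4000 < 0.55

    def test_rejects_non_finite(self, rng):
        with pytest.raises(ValueError):
            decide(math.nan, 0.0, rng)


def _plan(standard=1.2, delta=0.5, direction=LONGER, index=1):
    return TrialPlan(index=index, standard=standard, delta_d=delta,
                     direction=direction)


class TestSimulateTrial:
    @pytest.mark.parametrize("model", observers.MODELS)
    def test_near_noiseless_accuracy(self, model, rng):
        params = SubjectParams(subject=1, sigma_m=0.001, model=model)
        state = initial_state(params)
        n_correct = 0
        for i in range(300):
            rec, state = simulate_trial(params, state, _plan(index=i + 1), rng)
            n_correct += rec.correct
        assert n_correct / 300 > 0.99

    def test_irm1_state_ignores_comparison(self):
        params = SubjectParams(subject=1, sigma_m=0.2, model=IRM1)
        states = []
        for direction in (SHORTER, LONGER):
            rng = np.random.default_rng(99)
            _, state = simulate_trial(params, initial_state(params),
                                      _plan(direction=direction), rng)
            states.append(state)
        assert states[0] == states[1]

    @pytest.mark.parametrize("model", [IRM2, KALMAN])
    def test_other_models_track_comparison(self, model):
        params = SubjectParams(subject=1, sigma_m=0.2, model=model)
        states = []
        for direction in (SHORTER, LONGER):
            rng = np.random.default_rng(99)
            _, state = simulate_trial(params, initial_state(params),
                                      _plan(direction=direction), rng)
            states.append(state)
        assert states[0] != states[1]

    def test_record_invariants(self, rng):
        params = SubjectParams(subject=1, sigma_m=0.4, model=KALMAN)
        state = initial_state(params)
        for i in range(100):
            direction = LONGER if i % 2 else SHORTER
            rec, state = simulate_trial(params, state,
                                        _plan(direction=direction, index=i + 1),
                                        rng)
            truly_longer = rec.comparison_s > rec.standard_s
            assert rec.correct == ((rec.response == LONGER) == truly_longer)
            assert (rec.feedback_code == 0) == rec.correct
            if not rec.correct:
                assert rec.feedback_code == (1 if truly_longer else -1)
            assert 0 < rec.gain <= 1


class TestPopulation:
    def test_draws_respect_bounds_and_seed(self):
        pop = sample_subject_population(500, seed=8)
        sig = np.array([p.sigma_m for p in pop])
        assert (sig >= observers.DEFAULT_SIGMA_M_BOUNDS[0]).all()
        again = sample_subject_population(500, seed=8)
        assert pop == again

    def test_mean_matches_truncated_normal(self):
        from scipy.stats import truncnorm
        mean, spread, lo = 0.2, 0.25, 0.25
        a = (lo - mean) / spread
        pop = sample_subject_population(2000, sigma_m_mean=mean,
                                        sigma_m_spread=spread,
                                        bounds=(lo, math.inf), seed=4)
        sig = np.array([p.sigma_m for p in pop])
        target = truncnorm.mean(a, math.inf, loc=mean, scale=spread)
        se = truncnorm.std(a, math.inf, loc=mean, scale=spread) / math.sqrt(2000)
        assert abs(sig.mean() - target) < 3 * se

    def test_zero_spread_limit(self):
        pop = sample_subject_population(10, sigma_m_spread=1e-9,
                                        bounds=(0.05, math.inf), seed=1)
        sig = {round(p.sigma_m, 6) for p in pop}
        assert len(sig) == 1

    def test_rejects_bad_bounds(self):
        with pytest.raises(ValueError):
            sample_subject_population(5, bounds=(0.5, 0.2), seed=0)


class TestSimulateExperiment:
    def test_shape_and_determinism(self):
        pop = sample_subject_population(4, seed=2)
        design = task.make_fixed_design(168, seed=3)
        rec1 = simulate_experiment(pop, design, seed=5)
        rec2 = simulate_experiment(pop, design, seed=5)
        assert len(rec1) == 4 * 168
        assert rec1 == rec2

    def test_adding_subjects_keeps_earlier_streams(self):
        design = task.make_fixed_design(168, seed=3)
        pop3 = sample_subject_population(3, seed=2)
        pop2 = pop3[:2]
        rec3 = simulate_experiment(pop3, design, seed=5)
        rec2 = simulate_experiment(pop2, design, seed=5)
        assert rec3[: len(rec2)] == rec2

    def test_accuracy_declines_with_noise(self):
        design = task.make_fixed_design(336, seed=1)
        accs = []
        for sigma in (0.1, 0.4, 1.0):
            pop = [SubjectParams(subject=i + 1, sigma_m=sigma, model=KALMAN)
                   for i in range(8)]
            rec = records_to_frame(simulate_experiment(pop, design, seed=7))
            accs.append(rec["correct"].mean())
        assert accs[0] > accs[1] > accs[2]

    def test_gain_bookkeeping_consistency(self, small_kalman_records):
        df = small_kalman_records
        per_subject = df.groupby("subject")["gain"].mean()
        assert df["gain"].mean() == pytest.approx(per_subject.mean(), abs=1e-12)
        assert ((df["gain"] > 0) & (df["gain"] <= 1)).all()


def test_record_csv_round_trip(tmp_path, small_kalman_records):
    path = tmp_path / "records.csv"
    write_records(small_kalman_records, path)
    back = read_records(path)
    assert list(back.columns) == list(small_kalman_records.columns)
    for col in back.columns:
        if back[col].dtype.kind == "f":
            np.testing.assert_allclose(back[col], small_kalman_records[col],
                                       rtol=1e-11)
        else:
            assert (back[col] == small_kalman_records[col]).all()
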