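"""Analog perceptron: rate function, both learning rules, capacity scan."""

import numpy as np
import pytest

from sgdege.perceptron import (
    PerceptronParams,
    PerceptronState,
    capacity_scan,
    delta_rule_trial,
    init_perceptron,
    make_patterns_1d,
    perceptron_rate,
    run_perceptron,
    sgdege_percep_trial,
)


class _ForcedRng:
    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


def _small_setup(seed=0, p=1, **kw):
    params = PerceptronParams(Nm=50, p=p, **kw)
    pattern = make_patterns_1d(params, seed)
    state = init_perceptron(params, seed + 1)
    return params, pattern, state


class TestRate:
    def test_zero_weights_rectified_to_silence(self):
        params, pattern, state = _small_setup()
        state.w[:] = 0.0
        assert perceptron_rate(state, pattern.x[0], False, params) == 0.0

    def test_perturbation_from_threshold_gives_A(self):
        params = PerceptronParams(Nm=4, p=1)
        x = np.array([1, 1, 0, 0], dtype=np.uint8)
        state = PerceptronState(w=np.array([params.theta, 0.0, 5.0, 5.0]), v=np.zeros(4))
        # w.x == theta, so the unperturbed rate is 0 and the perturbed rate A
        assert perceptron_rate(state, x, False, params) == 0.0
        assert perceptron_rate(state, x, True, params) == params.A == 2.0

    def test_rate_saturates_at_pmax(self):
        params = PerceptronParams(Nm=4, p=1)
        x = np.ones(4, dtype=np.uint8)
        state = PerceptronState(w=np.full(4, 1e4), v=np.zeros(4))
        assert perceptron_rate(state, x, False, params) == params.Pmax == 100.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PerceptronParams(f=0.0)
        with pytest.raises(ValueError):
            PerceptronParams(target_lo=5.0, target_hi=3.0)


class TestSgdegeTrial:
    def test_unperturbed_trial_leaves_w(self):
        params, pattern, state = _small_setup()
        w0 = state.w.copy()
        v0 = state.v.copy()
        sgdege_percep_trial(state, pattern, 0, params, _ForcedRng(0.99))
        assert np.array_equal(state.w, w0)
        assert not np.array_equal(state.v, v0)

    def test_perturbed_update_moves_rate_by_dP(self):
        """In the linear unclipped regime one update changes the pattern's
        unperturbed rate by exactly -c*dP (per-synapse steps are 1/(gamma*n))."""
        params, pattern, state = _small_setup()
        state.w += 1.0  # keep all weights safely away from the zero clip
        r_before = perceptron_rate(state, pattern.x[0], False, params)
        sgdege_percep_trial(state, pattern, 0, params, _ForcedRng(0.0))
        r_after = perceptron_rate(state, pattern.x[0], False, params)
        assert abs(r_after - r_before) == pytest.approx(params.dP)

    def test_weights_clipped_at_zero(self):
        params, pattern, state = _small_setup()
        state.w[:] = 0.0
        state.v[:] = 0.0
        for k in range(20):
            sgdege_percep_trial(state, pattern, 0, params, _ForcedRng(0.0))
            assert (state.w >= 0).all() and (state.v >= 0).all()


class TestDeltaTrial:
    def test_no_update_at_target(self):
        params, pattern, state = _small_setup()
        state.w[:] = (pattern.R[0] / params.gamma + params.theta) / pattern.x[0].sum()
        state.w *= pattern.x[0]  # exact current on the active fibres only
        w0 = state.w.copy()
        delta_rule_trial(state, pattern, 0, 0.1, params)
        assert np.allclose(state.w, w0)

    def test_single_pattern_error_decays_geometrically(self):
        params, pattern, state = _small_setup()
        state.w += 0.5
        lr = 0.1
        errs = []
        for _ in range(30):
            errs.append(abs(perceptron_rate(state, pattern.x[0], False, params) - pattern.R[0]))
            delta_rule_trial(state, pattern, 0, lr, params)
        errs = np.array(errs)
        ratios = errs[1:10] / errs[:9]
        assert np.allclose(ratios, 1 - lr, atol=1e-6)

    def test_invalid_learning_rate(self):
        params, pattern, state = _small_setup()
        with pytest.raises(ValueError):
            delta_rule_trial(state, pattern, 0, 0.0, params)


class TestRunPerceptron:
    def test_zero_sweeps_reports_initial_error(self):
        params = PerceptronParams(Nm=100, p=3)
        curve, state, pattern = run_perceptron("delta", params, 0, seed=4)
        rates = [perceptron_rate(state, pattern.x[mu], False, params) for mu in range(3)]
        expected = float(np.abs(np.array(rates) - pattern.R).mean())
        assert curve.mean_error_hz.iloc[0] == pytest.approx(expected)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            run_perceptron("adam", PerceptronParams(), 10, seed=0)

    def test_deterministic_given_seed(self):
        params = PerceptronParams(Nm=200, p=5)
        c1, s1, _ = run_perceptron("sgdege", params, 200, seed=3)
        c2, s2, _ = run_perceptron("sgdege", params, 200, seed=3)
        assert c1.equals(c2) and np.array_equal(s1.w, s2.w)

    def test_weights_nonnegative_after_learning(self):
        params = PerceptronParams(p=20)
        for algo in ("sgdege", "delta"):
            _, state, _ = run_perceptron(algo, params, 300, seed=6)
            assert (state.w >= 0).all() and (state.v >= 0).all()

    def test_late_trials_cluster_at_the_reduced_fixed_point(self):
        """Below capacity each pattern settles where the corridor analysis
        says: |P - R| near A(1+q)/2 with the error estimate tracking it."""
        params = PerceptronParams(p=100)
        _, state, pattern = run_perceptron("sgdege", params, 4000, seed=8)
        x = pattern.x.astype(float)
        rates = np.clip(params.gamma * (x @ state.w - params.theta), 0, params.Pmax)
        est = np.maximum(x @ state.v - params.q * rates, 0.0)
        err = np.abs(rates - pattern.R)
        floor = params.A * (1 + params.q) / 2
        assert abs(err.mean() - floor) < 0.5 * floor
        assert np.abs(est - err).mean() < floor  # inhibition tracks the error


class TestCapacityScan:
    def test_trivial_single_pattern_grid(self):
        params = PerceptronParams(Nm=100)
        critical, table = capacity_scan("delta", params, [1], 500, 0.1, seed=0)
        assert critical == 1 and len(table) == 1

    def test_empty_or_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            capacity_scan("delta", PerceptronParams(), [], 10, 0.1, seed=0)
        with pytest.raises(ValueError):
            capacity_scan("delta", PerceptronParams(), [5, 3], 10, 0.1, seed=0)
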