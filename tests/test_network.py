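"""Microzone network: rate equations, plasticity updates, simulation loop."""

import numpy as np
import pytest

from conftest import naive_nuclear, naive_purkinje
from sgdege.network import (
    NetworkParams,
    ecs_sign,
    init_weights,
    movement_error,
    nuclear_rates,
    olive_inhibition,
    perturbation_eta,
    phi,
    purkinje_rates,
    run_simulation,
    sgdege_update,
)
from sgdege.patterns import ShapeParams, build_connectivity, generate_patterns, generate_targets


class TestPhi:
    @pytest.mark.parametrize("x,expected", [(-5.0, 0.0), (400.0, 300.0), (123.4, 123.4), (0.0, 0.0)])
    def test_threshold_linear_saturation(self, x, expected):
        assert phi(x, 300.0) == expected

    def test_elementwise(self):
        out = phi(np.array([-1.0, 10.0, 500.0]), 300.0)
        assert np.array_equal(out, [0.0, 10.0, 300.0])


class TestParams:
    def test_fixed_weights_match_printed_values(self):
        p = NetworkParams()
        assert p.u_M_PN == pytest.approx(2.4)
        assert p.u_PC_PN == pytest.approx(-0.06)
        assert p.u_PC_NO == pytest.approx(-0.03)

    def test_initial_weight_bounds(self):
        p = NetworkParams()
        assert p.w_init_max == pytest.approx(2.0)  # 8*10*50/2000
        assert p.v_init_max == pytest.approx(2.4)  # (15+0.5*30)*4*10*40/20000

    def test_rho_validation(self):
        with pytest.raises(ValueError):
            NetworkParams(rho=1.5)

    def test_default_network_optimises_400_outputs(self):
        assert NetworkParams().n_output_variables == 400


class TestInitWeights:
    def test_ranges_and_determinism(self, tiny_params):
        conn = build_connectivity(tiny_params.shape, seed=0)
        s1 = init_weights(tiny_params, conn, seed=4)
        s2 = init_weights(tiny_params, conn, seed=4)
        assert np.array_equal(s1.w, s2.w) and np.array_equal(s1.v, s2.v)
        assert s1.w.min() >= 0 and s1.w.max() <= tiny_params.w_init_max
        assert s1.v.min() >= 0 and s1.v.max() <= tiny_params.v_init_max


class TestRates:
    def test_zero_weights_silent(self, tiny_params):
        sh = tiny_params.shape
        conn = build_connectivity(sh, seed=1)
        state = init_weights(tiny_params, conn, seed=1)
        state.w[:] = 0.0
        m = generate_patterns(sh, seed=2).m[0]
        eta = np.zeros((sh.L, sh.T), dtype=np.uint8)
        assert (purkinje_rates(state, m, eta, tiny_params) == 0).all()

    def test_perturbation_alone_gives_amplitude_A(self, tiny_params):
        sh = tiny_params.shape
        conn = build_connectivity(sh, seed=1)
        state = init_weights(tiny_params, conn, seed=1)
        state.w[:] = 0.0
        m = np.zeros((sh.N, sh.S, sh.T), dtype=np.uint8)
        eta = np.zeros((sh.L, sh.T), dtype=np.uint8)
        eta[1, 2] = 1
        pc = purkinje_rates(state, m, eta, tiny_params)
        assert (pc[:, 1, 2] == tiny_params.A).all()
        pc[:, 1, 2] = 0.0
        assert (pc == 0).all()

    def test_single_fibre_drives_its_projection_neurone(self):
        sh = ShapeParams(S=2, L=3, T=2, N=4, p=1)
        params = NetworkParams(shape=sh)
        conn = build_connectivity(sh, seed=3)
        state = init_weights(params, conn, seed=3)
        state.w[:] = 0.0
        state.v[:] = 0.0
        m = np.zeros((sh.N, sh.S, sh.T), dtype=np.uint8)
        m[2, 1, 0] = 1
        pc = purkinje_rates(state, m, np.zeros((sh.L, sh.T), dtype=np.uint8), params)
        pn, no = nuclear_rates(state, m, pc, params)
        target_l = conn.pn_assign[2, 1]
        assert pn[target_l, 0] == pytest.approx(params.u_M_PN)
        pn[target_l, 0] = 0.0
        assert (pn == 0).all() and (no == 0).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_vectorized_rates_match_naive_loops(self, seed):
        sh = ShapeParams(S=2, L=2, T=3, N=4, p=1)
        params = NetworkParams(shape=sh, rho=0.5)
        conn = build_connectivity(sh, seed=seed)
        state = init_weights(params, conn, seed=seed)
        m = generate_patterns(sh, seed=seed + 50).m[0]
        rng = np.random.default_rng(seed)
        eta = perturbation_eta(rng.random(sh.L) < 0.5, rng.integers(0, sh.T, sh.L), sh.T)
        pc = purkinje_rates(state, m, eta, params)
        assert np.allclose(pc, naive_purkinje(state, m, eta, params), rtol=1e-12)
        pn, no = nuclear_rates(state, m, pc, params)
        pn_ref, no_ref = naive_nuclear(state, m, pc, params)
        assert np.allclose(pn, pn_ref, rtol=1e-12)
        assert np.allclose(no, no_ref, rtol=1e-12)


class TestErrorAndSign:
    def test_movement_error_examples(self):
        assert movement_error(np.array([[10.0, 20.0]]), np.array([[10.0, 20.0]])) == 0.0
        assert movement_error(np.array([[10.0, 20.0]]), np.array([[20.0, 40.0]])) == 15.0

    def test_movement_error_symmetric_under_relabelling(self):
        rng = np.random.default_rng(0)
        pn = rng.uniform(0, 60, (4, 5))
        r = rng.uniform(0, 60, (4, 5))
        perm = rng.permutation(20)
        assert movement_error(pn, r) == pytest.approx(
            movement_error(pn.ravel()[perm].reshape(4, 5), r.ravel()[perm].reshape(4, 5))
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            movement_error(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_olive_inhibition_is_mean_and_linear(self):
        no = np.array([[10.0], [30.0]])
        assert olive_inhibition(no) == 20.0
        assert olive_inhibition(3 * no) == 60.0

    @pytest.mark.parametrize("e,i,expected", [(5.0, 3.0, 1), (3.0, 5.0, -1), (4.0, 4.0, -1)])
    def test_ecs_sign_with_tie_silent(self, e, i, expected):
        assert ecs_sign(e, i) == expected


class TestSgdegeUpdate:
    def _setup(self):
        sh = ShapeParams(S=2, L=2, T=3, N=4, p=1)
        params = NetworkParams(shape=sh)
        conn = build_connectivity(sh, seed=0)
        state = init_weights(params, conn, seed=0)
        m = generate_patterns(sh, seed=1).m[0]
        return sh, params, state, m

    def test_no_perturbation_leaves_w_but_moves_v(self):
        sh, params, state, m = self._setup()
        w0, v0 = state.w.copy(), state.v.copy()
        sgdege_update(state, m, np.zeros((sh.L, sh.T), dtype=np.uint8), +1, params)
        assert np.array_equal(state.w, w0)
        active = m.sum(axis=2) > 0
        assert np.allclose(state.v[active], v0[active] + params.alpha_v)
        assert np.array_equal(state.v[~active], v0[~active])

    def test_perturbed_synapse_decrements_by_alpha_w(self):
        sh, params, state, m = self._setup()
        i, s, t = np.argwhere(m)[0]
        l = 1
        eta = np.zeros((sh.L, sh.T), dtype=np.uint8)
        eta[l, t] = 1
        w0 = state.w.copy()
        sgdege_update(state, m, eta, +1, params)
        assert state.w[i, s, l] == pytest.approx(w0[i, s, l] - params.alpha_w)
        # fibres not active in the perturbed bin are untouched
        others = m[:, :, t] == 0
        assert np.array_equal(state.w[others, l], w0[others, l])

    def test_v_positivity_clipped(self):
        sh, params, state, m = self._setup()
        i, s, _ = np.argwhere(m)[0]
        state.v[i, s] = 5e-5
        sgdege_update(state, m, np.zeros((sh.L, sh.T), dtype=np.uint8), -1, params)
        assert state.v[i, s] == 0.0
        assert (state.v >= 0).all()


class TestRunSimulation:
    def test_single_trial_record(self, tiny_params, tiny_shape):
        pats = generate_patterns(tiny_shape, seed=0)
        tg = generate_targets(tiny_shape.L, tiny_shape.T, tiny_shape.p, 30.0, seed=0)
        traj, _ = run_simulation(tiny_params, pats, tg, 1, seed=0)
        assert len(traj) == 1
        assert set(traj.columns) >= {"trial", "pattern", "error_hz", "inhibition_hz", "ecs"}

    def test_rho_zero_freezes_w(self, tiny_shape):
        params = NetworkParams(shape=tiny_shape, rho=0.0)
        pats = generate_patterns(tiny_shape, seed=0)
        tg = generate_targets(tiny_shape.L, tiny_shape.T, tiny_shape.p, 30.0, seed=0)
        from sgdege.patterns import substreams

        streams = substreams(3)
        conn = build_connectivity(tiny_shape, streams["connectivity"])
        state = init_weights(params, conn, rng_w=streams["init_w"], rng_v=streams["init_v"])
        w0 = state.w.copy()
        v0 = state.v.copy()
        _, final = run_simulation(
            params, pats, tg, 300, state=state, rng_pert=streams["perturbations"]
        )
        assert np.array_equal(final.w, w0)
        assert not np.array_equal(final.v, v0)  # v still drifts

    def test_v_stays_nonnegative_throughout(self, tiny_params, tiny_shape):
        pats = generate_patterns(tiny_shape, seed=5)
        tg = generate_targets(tiny_shape.L, tiny_shape.T, tiny_shape.p, 30.0, seed=5)
        _, final = run_simulation(tiny_params, pats, tg, 500, seed=5)
        assert (final.v >= 0).all()

    def test_deterministic_given_seed(self, tiny_params, tiny_shape):
        pats = generate_patterns(tiny_shape, seed=1)
        tg = generate_targets(tiny_shape.L, tiny_shape.T, tiny_shape.p, 30.0, seed=1)
        t1, s1 = run_simulation(tiny_params, pats, tg, 100, seed=9)
        t2, s2 = run_simulation(tiny_params, pats, tg, 100, seed=9)
        assert t1.equals(t2) and np.array_equal(s1.w, s2.w)

    def test_fast_and_reference_paths_agree(self, tiny_params, tiny_shape):
        pats = generate_patterns(tiny_shape, seed=2)
        tg = generate_targets(tiny_shape.L, tiny_shape.T, tiny_shape.p, 30.0, seed=2)
        t1, s1 = run_simulation(tiny_params, pats, tg, 200, seed=4, fast=True, refresh_every=31)
        t2, s2 = run_simulation(tiny_params, pats, tg, 200, seed=4, fast=False)
        assert np.allclose(t1.error_hz, t2.error_hz, rtol=1e-10)
        assert np.allclose(t1.inhibition_hz, t2.inhibition_hz, rtol=1e-10)
        assert (t1.ecs.to_numpy() == t2.ecs.to_numpy()).all()
        assert np.allclose(s1.w, s2.w, rtol=1e-10)
        assert np.allclose(s1.v.ravel(), s2.v.ravel(), rtol=1e-10)
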