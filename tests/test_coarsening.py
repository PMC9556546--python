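"""Unit and property tests of the single-SC coarsening solver."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import meiocross as mx
from meiocross.coarsening import SCState, stable_timestep


def make_state(L, positions, amounts, c0, n_grid=50):
    return SCState(
        sc_length=L,
        concentration=np.full(n_grid, float(c0)),
        positions=np.asarray(positions, dtype=float),
        amounts=np.asarray(amounts, dtype=float),
    )


class TestEquilibriumConcentration:
    def test_closed_form_value(self, params):
        p = params.replace(c0_eq=1.35, alpha=0.25)
        assert mx.equilibrium_concentration(1.0, p) == pytest.approx(1.35 / 2)

    def test_zero_at_zero(self, params):
        assert mx.equilibrium_concentration(0.0, params) == 0.0

    def test_decreasing_branch(self, params):
        p = params.replace(c0_eq=1.35, alpha=0.25)
        assert mx.equilibrium_concentration(10.0, p) < mx.equilibrium_concentration(2.0, p)

    def test_negative_amount_rejected(self, params):
        with pytest.raises(ValueError):
            mx.equilibrium_concentration(-0.1, params)

    @given(m=st.floats(0.0, 1e3), eps=st.floats(1e-9, 1e-6))
    def test_continuous_and_nonnegative(self, m, eps):
        p = mx.CoarseningParams()
        a, b = mx.equilibrium_concentration(m, p), mx.equilibrium_concentration(m + eps, p)
        assert a >= 0
        # locally Lipschitz: |dc_eq/dM| <= c0_eq everywhere
        assert abs(b - a) <= p.c0_eq * eps * 1.001 + 1e-12


class TestInitState:
    def test_focus_count_matches_density(self, params, rng):
        state = mx.init_state(30.0, params, rng)
        assert state.positions.size == 120  # 4 foci/um * 30 um

    def test_uniform_initial_concentration(self, params, rng):
        state = mx.init_state(20.0, params, rng)
        assert np.all(state.concentration == params.c_init)

    def test_truncation_bounds_scale_with_dosage(self, rng):
        p = mx.CoarseningParams(dosage_factor=2.0)
        state = mx.init_state(60.0, p, rng)
        assert state.amounts.min() >= 0.2 - 1e-12  # 2*3.4 - 3*2*1.1
        assert state.amounts.max() <= 13.4 + 1e-12

    def test_seed_determinism(self, params):
        a = mx.init_state(15.0, params, np.random.default_rng(7))
        b = mx.init_state(15.0, params, np.random.default_rng(7))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.amounts, b.amounts)

    def test_equally_spaced_option(self, params, rng):
        state = mx.init_state(10.0, params, rng, equally_spaced=True)
        assert np.allclose(np.diff(state.positions), state.positions[1] - state.positions[0])

    def test_invalid_length(self, params, rng):
        with pytest.raises(ValueError):
            mx.init_state(0.0, params, rng)


class TestSimulate:
    def test_uniform_no_foci_is_fixed_point(self, params):
        state = make_state(12.0, [], [], 2.8)
        out = mx.simulate(state, params, duration=50.0)
        assert np.allclose(out.concentration, 2.8, rtol=0, atol=1e-12)

    def test_mass_conservation_short_run(self, params, rng):
        state = mx.init_state(18.0, params, rng)
        out = mx.simulate(state, params, duration=200.0)
        drift = abs(out.total_hei10 - state.total_hei10) / state.total_hei10
        assert drift < 1e-10

    def test_nonnegative_state(self, params, rng):
        # amounts near zero force the clamped-flux path
        state = make_state(10.0, [1.0, 5.0, 9.0], [0.01, 0.02, 8.0], 0.05)
        out = mx.simulate(state, params, duration=300.0)
        assert np.all(out.amounts >= 0)
        assert np.all(out.concentration >= 0)

    def test_winner_takes_more(self, mc_params):
        # Two foci on the decreasing branch of c_eq: over 10 h the larger
        # grows and the smaller shrinks (coarsening).
        state = make_state(12.0, [3.0, 9.0], [8.0, 6.0], mc_params.c_init)
        out = mx.simulate(state, mc_params)  # full duration
        assert out.amounts[0] > 8.0
        assert out.amounts[1] < 6.0

    def test_negative_duration_rejected(self, params, rng):
        state = mx.init_state(10.0, params, rng)
        with pytest.raises(ValueError):
            mx.simulate(state, params, duration=-1.0)

    def test_zero_duration_is_identity(self, params, rng):
        state = mx.init_state(10.0, params, rng)
        out = mx.simulate(state, params, duration=0.0)
        assert np.array_equal(out.amounts, state.amounts)
        assert np.array_equal(out.concentration, state.concentration)

    def test_mirror_symmetry_exact(self, params):
        # distinct host nodes: reflecting positions about L/2 must produce
        # the bitwise-mirrored state
        L = 10.0
        positions = np.array([0.7, 2.3, 4.1, 6.6, 8.9])
        amounts = np.array([2.0, 7.0, 4.0, 6.5, 3.0])
        a = mx.simulate(make_state(L, positions, amounts, params.c_init), params, 400.0)
        b = mx.simulate(
            make_state(L, L - positions, amounts, params.c_init), params, 400.0
        )
        assert np.array_equal(a.amounts, b.amounts)
        assert np.array_equal(a.concentration, b.concentration[::-1])

    def test_mirror_symmetry_full_density(self, params, rng):
        # random full-density initial condition, shared nodes allowed
        state = mx.init_state(8.0, params, rng)
        mirrored = SCState(
            state.sc_length,
            state.concentration.copy(),
            state.sc_length - state.positions,
            state.amounts.copy(),
        )
        a = mx.simulate(state, params, 300.0)
        b = mx.simulate(mirrored, params, 300.0)
        assert np.allclose(np.sort(a.amounts), np.sort(b.amounts), rtol=1e-9)

    def test_ensemble_matches_single_runs(self, params):
        # batching contract: the ensemble path equals init_state+simulate
        seeds = np.random.SeedSequence(42).spawn(3)
        rngs = [np.random.default_rng(s) for s in seeds]
        pos, amt = mx.simulate_ensemble(9.0, 3, params, rngs, duration=150.0)
        for k, seed in enumerate(np.random.SeedSequence(42).spawn(3)):
            r = np.random.default_rng(seed)
            state = mx.init_state(9.0, params, r)
            out = mx.simulate(state, params, duration=150.0)
            assert np.array_equal(pos[k], state.positions)
            assert np.array_equal(amt[k], out.amounts)


class TestEulerOracle:
    def test_matches_brute_force_recomputation(self):
        """5-node grid, 2 foci, 10 steps vs an independent pure-Python Euler."""
        p = mx.CoarseningParams(n_grid=5, dosage_factor=1.0)
        L = 2.0
        dx = L / 4
        positions = [0.6, 1.4]  # nodes 1 and 3
        amounts = [2.0, 5.0]
        state = make_state(L, positions, amounts, 1.4, n_grid=5)
        dt = stable_timestep(state, p)
        nsteps = 10
        out = mx.simulate(state, p, duration=dt * nsteps)

        # --- independent recomputation from the model definition ---
        c = [1.4] * 5
        M = list(amounts)
        nodes = [round(x / dx) for x in positions]
        lam, D, c0 = p.exchange_rate, p.diffusivity, p.c0_eq
        beta = D * dt / (dx * dx)
        dtlam = dt * lam
        inv_dx = 1.0 / dx
        for _ in range(nsteps):
            new = [0.0] * 5
            new[0] = c[0] + beta * (c[1] - c[0])
            for j in (1, 2, 3):
                new[j] = c[j] + beta * ((c[j - 1] + c[j + 1]) - 2.0 * c[j])
            new[4] = c[4] + beta * (c[3] - c[4])
            for i in (0, 1):
                m = M[i]
                ceq = c0 * m / (1.0 + m * math.sqrt(math.sqrt(m)))
                dM = dtlam * (c[nodes[i]] - ceq)
                if dM < -m:
                    dM = -m
                M[i] = m + dM
                new[nodes[i]] -= dM * inv_dx
            c = new
        assert out.amounts.tolist() == M
        assert out.concentration.tolist() == c

    def test_designation_strict_threshold(self):
        state = make_state(10.0, [1.0, 5.0, 9.0], [5.0, 2.0, 3.0], 1.0)
        assert len(mx.designate_foci(state, 3.0)) == 1
        state0 = make_state(10.0, [1.0, 5.0], [0.0, 0.0], 1.0)
        assert mx.designate_foci(state0, 3.0) == []
        state_all = make_state(10.0, [9.0, 1.0], [1.0, 2.0], 1.0)
        out = mx.designate_foci(state_all, 0.0)
        assert len(out) == 2
        assert out[0][0] < out[1][0]  # ordered by position


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"diffusivity": 0.0},
            {"exchange_rate": -1.0},
            {"alpha": -0.1},
            {"n_grid": 2},
            {"dosage_factor": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            mx.CoarseningParams(**kwargs)

    def test_dosage_scaling(self):
        p = mx.CoarseningParams(dosage_factor=2.0)
        assert p.m_init == pytest.approx(6.8)
        assert p.sigma_init == pytest.approx(2.2)
        assert p.c_init == pytest.approx(2.8)
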