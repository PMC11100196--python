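import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcontract import (DomainError, ModelState, Parameters, ScenarioConfig,
                        adoption_from_mobilization, adoption_from_wom,
                        attractiveness, collaborative_effect, contract_rate,
                        driving_force, simulate, step)

GPSP = ScenarioConfig(hcs=1, wdp=1, hec=1)
ALL_ON = ScenarioConfig(hcs=1, wdp=1, hec=1, et=1, jtp=1, ii=1)


class TestAttractiveness:
    def test_all_off_is_baseline(self, default_params):
        assert attractiveness(ScenarioConfig(), default_params, 2025.0) \
            == default_params.base_attractiveness

    def test_additive_when_active(self, default_params):
        p = default_params
        expected = p.base_attractiveness + p.w_hcs + p.w_wdp + p.w_hec
        assert attractiveness(GPSP, p, 2025.0) == pytest.approx(expected)

    def test_step_gating_before_intervention_year(self, default_params):
        assert attractiveness(GPSP, default_params, 2019.99) \
            == default_params.base_attractiveness

    def test_trajectory_jumps_at_intervention_year(self, default_params):
        traj = simulate(default_params, GPSP)
        before = traj.beta[traj.time < 2020.0]
        after = traj.beta[traj.time >= 2020.0]
        assert np.all(before == default_params.base_attractiveness)
        assert np.all(after > default_params.base_attractiveness)


class TestDrivingForce:
    def test_baseline_term_only(self, default_params):
        p = default_params
        got = driving_force(ScenarioConfig(), 1e5, p)
        assert got == pytest.approx(p.gamma_min * p.drive_base)

    def test_additive_incentives(self, default_params):
        p = default_params
        got = driving_force(ScenarioConfig(et=1, jtp=1), 1e5, p)
        assert got == pytest.approx(p.gamma_min * (p.drive_base + p.w_et + p.w_jtp))

    def test_income_monotonicity_through_lookup(self, default_params):
        p = default_params
        s = ScenarioConfig(ii=1)
        xs = p.ii_lookup.x
        gammas = [driving_force(s, x, p) for x in xs]
        assert all(b >= a for a, b in zip(gammas, gammas[1:]))

    def test_negative_income_rejected(self, default_params):
        with pytest.raises(DomainError):
            driving_force(ScenarioConfig(ii=1), -1.0, default_params)


class TestCollaborativeEffect:
    def test_endpoint(self):
        p = Parameters(idr_gp_weight=0.501, delta_scale=1.0)
        # delta_scale pinned to 1: w*sqrt(0) + (1-w)*sqrt(1) = 1 - w
        assert collaborative_effect(0.0, p) == pytest.approx(1 - 0.501)

    def test_symmetry_point_independent_of_weight(self):
        for w in (0.51, 0.55, 0.65):
            p = Parameters(idr_gp_weight=w, delta_scale=1.0)
            assert collaborative_effect(0.5, p) == pytest.approx(math.sqrt(0.5))

    def test_normalized_to_one_at_reference_idr(self, default_params):
        got = collaborative_effect(default_params.reference_idr, default_params)
        assert got == pytest.approx(1.0)

    def test_unique_interior_maximum_between_half_and_seven_tenths(self):
        # argmax = w^2 / (w^2 + (1-w)^2), inside (0.5, 0.7) for w < ~0.604
        for w in (0.505, 0.55, 0.60):
            p = Parameters(idr_gp_weight=w)
            grid = np.linspace(0, 1, 2001)
            vals = [collaborative_effect(float(x), p) for x in grid]
            argmax = grid[int(np.argmax(vals))]
            assert 0.5 < argmax < 0.7

    def test_domain_error_outside_unit_interval(self, default_params):
        with pytest.raises(DomainError):
            collaborative_effect(1.2, default_params)


class TestFlows:
    def test_mobilization_direct_product(self):
        p = Parameters(mobilization_rate=0.05, population=2000.0)
        s = ModelState(time=2015, potential_contractors=1000.0,
                       contractors=1000.0, gp_count=10.0)
        assert adoption_from_mobilization(s, p) == pytest.approx(50.0)

    @pytest.mark.parametrize("pool, rate", [(0.0, 0.05), (1000.0, 0.0)])
    def test_mobilization_zero_cases(self, pool, rate):
        p = Parameters(mobilization_rate=rate, population=2000.0)
        s = ModelState(time=2015, potential_contractors=pool,
                       contractors=10.0, gp_count=10.0)
        assert adoption_from_mobilization(s, p) == 0.0

    def test_wom_zero_without_contractors(self, default_params):
        s = ModelState(time=2015,
                       potential_contractors=default_params.population,
                       contractors=0.0, gp_count=10.0)
        assert adoption_from_wom(s, 1.0, 1.0, 1.0, default_params) == 0.0

    def test_wom_direct_product(self):
        n = 1000.0
        p = Parameters(population=n, wom_base_coefficient=0.5)
        s = ModelState(time=2015, potential_contractors=n / 2,
                       contractors=n / 2, gp_count=10.0)
        assert adoption_from_wom(s, 1.0, 1.0, 1.0, p) == pytest.approx(0.125 * n)

    def test_wom_linear_in_beta(self, default_params):
        s = ModelState(time=2025, potential_contractors=5e6, contractors=5e6,
                       gp_count=100.0)
        one = adoption_from_wom(s, 1.0, 1.3, 0.9, default_params)
        two = adoption_from_wom(s, 2.0, 1.3, 0.9, default_params)
        assert two == pytest.approx(2 * one)


class TestStep:
    def test_euler_increment_matches_flow(self, default_params):
        s = ModelState(time=2015.0, potential_contractors=9e6, contractors=1e6,
                       gp_count=1000.0)
        nxt = step(s, ScenarioConfig(), default_params)
        dt = default_params.dt
        beta = attractiveness(ScenarioConfig(), default_params, 2015.0)
        from gpcontract import per_capita_income
        inc = per_capita_income(1e6, 1000.0, 0.5, default_params)
        gamma = driving_force(ScenarioConfig(), inc, default_params, time=2015.0)
        delta = collaborative_effect(default_params.reference_idr, default_params)
        flow = (adoption_from_mobilization(s, default_params)
                + adoption_from_wom(s, beta, gamma, delta, default_params))
        assert nxt.contractors - s.contractors == pytest.approx(flow * dt)

    def test_conservation(self, default_params):
        s = ModelState(time=2022.0, potential_contractors=4e6, contractors=6e6,
                       gp_count=5000.0)
        nxt = step(s, ALL_ON, default_params)
        assert nxt.potential_contractors + nxt.contractors \
            == pytest.approx(default_params.population)

    def test_cap_engaged_at_pool_exhaustion(self):
        p = Parameters(population=100.0, mobilization_rate=1.0,
                       wom_base_coefficient=5.0, dt=1.0)
        s = ModelState(time=2025.0, potential_contractors=0.5, contractors=99.5,
                       gp_count=10.0)
        nxt = step(s, ScenarioConfig(), p)
        assert nxt.contractors == pytest.approx(100.0)
        assert nxt.potential_contractors == 0.0

    def test_repeated_step_reproduces_simulate(self, default_params):
        traj = simulate(default_params, GPSP)
        state = ModelState(
            time=default_params.year_start,
            potential_contractors=float(traj.P[0]),
            contractors=float(traj.C[0]),
            gp_count=float(traj.gp_count[0]),
        )
        for _ in range(len(traj) - 1):
            state = step(state, GPSP, default_params)
        assert state.contractors == pytest.approx(float(traj.C[-1]), rel=1e-12)
        assert state.gp_count == pytest.approx(float(traj.gp_count[-1]), rel=1e-12)


def bass_closed_form(t, p, q, n=1.0):
    """Analytic Bass adoption curve F(t) with F(0) = 0."""
    e = math.exp(-(p + q) * t)
    return n * (1 - e) / (1 + (q / p) * e)


class TestSimulateOracles:
    def test_pure_mobilization_matches_exponential(self):
        # mu = 0: C(t) = N - (N - C0) exp(-alpha (t - 2015))
        params = Parameters(mobilization_rate=0.02, wom_base_coefficient=0.0,
                            initial_contract_rate=0.01)
        traj = simulate(params, ScenarioConfig())
        n = params.population
        exact = n - (n - 0.01 * n) * np.exp(-0.02 * (traj.time - 2015.0))
        np.testing.assert_allclose(traj.C, exact, rtol=1e-3)

    def test_constant_multiplier_bass_closed_form(self):
        # all multipliers 1, C0 = 0: Euler trajectory vs analytic Bass.
        # Forward-Euler truncation peaks near the inflection (~(p+q)^2 dt / 8
        # on the prevalence scale), so the whole trajectory is held to half a
        # percentage point and the horizon readout to 0.1% relative.
        p, q = 0.03, 0.3
        params = Parameters(mobilization_rate=p, wom_base_coefficient=q,
                            initial_contract_rate=0.0, base_attractiveness=1.0,
                            gamma_min=1.0, drive_base=1.0)
        traj = simulate(params, ScenarioConfig())
        exact = np.array([bass_closed_form(t - 2015.0, p, q) for t in traj.time])
        sim = traj.C / params.population
        assert np.max(np.abs(sim - exact)) < 5e-3
        assert abs(sim[-1] - exact[-1]) / exact[-1] < 1e-3

    def test_dt_halving_changes_2030_rate_by_less_than_tenth_point(
            self, reference_params):
        for scenario in (ScenarioConfig(), ALL_ON):
            coarse = simulate(reference_params, scenario)
            fine = simulate(reference_params.replace(dt=1.0 / 24.0), scenario)
            assert abs(contract_rate(coarse, 2030) - contract_rate(fine, 2030)) \
                < 0.1


class TestTrajectoryInvariants:
    @given(
        alpha=st.floats(0.0, 0.05),
        mu=st.floats(0.0, 0.6),
        cr0=st.floats(0.0, 0.2),
        idr=st.one_of(st.none(), st.floats(0.0, 1.0)),
        switches=st.tuples(*[st.integers(0, 1)] * 6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_and_monotone_prevalence(self, alpha, mu, cr0, idr,
                                                  switches):
        params = Parameters(mobilization_rate=alpha, wom_base_coefficient=mu,
                            initial_contract_rate=cr0)
        hcs, wdp, hec, et, jtp, ii = switches
        scenario = ScenarioConfig(hcs=hcs, wdp=wdp, hec=hec, et=et, jtp=jtp,
                                  ii=ii, idr=idr)
        traj = simulate(params, scenario)
        n = params.population
        assert np.max(np.abs(traj.P + traj.C - n)) <= 1e-9 * n
        assert np.all(np.diff(traj.contract_rate_pct) >= -1e-12)
        assert np.all(traj.contract_rate_pct >= 0)
        assert np.all(traj.contract_rate_pct <= 100 + 1e-9)
        assert np.all(traj.flow_mobilization >= 0)
        assert np.all(traj.flow_wom >= 0)

    def test_time_grid_uniform(self, default_params):
        traj = simulate(default_params, ScenarioConfig())
        assert np.allclose(np.diff(traj.time), default_params.dt)
        assert traj.time[0] == default_params.year_start
        assert traj.time[-1] == pytest.approx(default_params.year_end)

    def test_determinism_bit_identical(self, default_params):
        a = simulate(default_params, ALL_ON)
        b = simulate(default_params, ALL_ON)
        for name in ("C", "P", "gp_count", "beta", "gamma", "delta"):
            assert np.array_equal(getattr(a, name), getattr(b, name))


class TestContractRate:
    def test_full_and_empty_population(self, default_params):
        traj = simulate(default_params, ScenarioConfig())
        traj.contract_rate_pct[:] = 100.0
        assert contract_rate(traj, 2030) == 100.0
        traj.contract_rate_pct[:] = 0.0
        assert contract_rate(traj, 2020) == 0.0

    def test_reads_last_step_at_or_before_year(self, default_params):
        traj = simulate(default_params, ScenarioConfig())
        idx = int(np.searchsorted(traj.time, 2020.5 + 1e-9, side="right")) - 1
        assert contract_rate(traj, 2020.5) == traj.contract_rate_pct[idx]

    def test_outside_horizon_rejected(self, default_params):
        traj = simulate(default_params, ScenarioConfig())
        with pytest.raises(DomainError):
            contract_rate(traj, 2031.0)
        with pytest.raises(DomainError):
            contract_rate(traj, 2014.0)
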