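"""Time stepping, events and stopping behaviour of the explicit solver."""

import math

import numpy as np
import pytest

import gbmpop as g
from gbmpop.model import ModelParams, TumourState, initial_profile
from gbmpop.solver import (
    StabilityError,
    _euler_update,
    initial_state,
    introduce_population,
    step,
    total_population,
)

K = g.K_DEFAULT
DT = 1.0 / 1500.0
# negligible proliferation used where the scheme requires rho > 0 but the
# test needs pure transport
RHO_OFF = 1e-12


def _no_growth(**kw) -> ModelParams:
    return ModelParams(rho_E=RHO_OFF, rho_P=RHO_OFF, rho_N=RHO_OFF, **kw)


class TestStep:
    def test_uniform_capacity_is_fixed_point(self, mesh):
        n = mesh.n_nodes
        state = TumourState(np.zeros(n), np.zeros(n), np.full(n, K))
        new = step(state, ModelParams(), mesh, DT)
        np.testing.assert_array_equal(new.N, state.N)
        assert np.all(new.E == 0) and np.all(new.P == 0)
        assert new.t == pytest.approx(DT)

    def test_stability_guard(self, mesh):
        n = mesh.n_nodes
        state = TumourState(np.zeros(n), np.zeros(n), np.full(n, K))
        with pytest.raises(StabilityError):
            step(state, ModelParams(D_N=300.0), mesh, DT)
        with pytest.raises(StabilityError):
            g.SolverConfig(dt=0.01).check_stability(ModelParams(), mesh)
        # the clinical box (D up to 45 with the default step) is admissible
        g.SolverConfig().check_stability(ModelParams(D_E=45.0), mesh)

    def test_mass_conservation_without_proliferation(self, mesh):
        """Divergence-form transport conserves total mass to < 1e-8 relative."""
        x = mesh.x
        E = 0.3 * K * np.exp(-(((x - 80) / 5) ** 2))
        P = 0.2 * K * np.exp(-(((x - 110) / 4) ** 2))
        N = 0.3 * K * np.exp(-(((x - 100) / 6) ** 2))
        params = _no_growth(D_E=30.0, D_P=20.0, D_N=10.0)
        m0 = sum(total_population(f, mesh) for f in (E, P, N))
        for _ in range(1000):
            _euler_update(E, P, N, params, mesh.dx, DT)
        m1 = sum(total_population(f, mesh) for f in (E, P, N))
        assert abs(m1 - m0) / m0 < 1e-8

    def test_matches_heat_kernel_for_dilute_single_species(self, mesh):
        """One species with no growth diffuses exactly linearly; compare to
        the analytic Gaussian spreading law."""
        x = mesh.x
        D, sig0sq = 30.0, 0.5
        P = 1000.0 * np.exp(-((x - 100.0) ** 2) / (2 * sig0sq))
        E = np.zeros_like(x)
        N = np.zeros_like(x)
        params = _no_growth(D_P=D)
        nsteps = 15
        for _ in range(nsteps):
            _euler_update(E, P, N, params, mesh.dx, DT)
        sigsq = sig0sq + 2 * D * nsteps * DT
        exact = 1000.0 * math.sqrt(sig0sq / sigsq) * np.exp(
            -((x - 100.0) ** 2) / (2 * sigsq)
        )
        assert np.max(np.abs(P - exact)) / exact.max() < 0.01


class TestTotalPopulation:
    def test_seed_profile_mass(self, mesh):
        assert total_population(
            initial_profile(mesh.x, 100.0), mesh
        ) == pytest.approx(100.0, rel=1e-3)

    def test_zero_and_constant_fields(self, mesh):
        assert total_population(np.zeros(mesh.n_nodes), mesh) == 0.0
        assert total_population(
            np.full(mesh.n_nodes, K), mesh
        ) == pytest.approx(K * mesh.L)


class TestIntroduction:
    def test_adds_standard_mass_and_leaves_others(self, mesh):
        state = initial_state(ModelParams(), mesh)
        N_before = state.N.copy()
        introduce_population(state, "E", 100.0, mesh)
        assert state.introduced_E
        assert total_population(state.E, mesh) == pytest.approx(100.0, rel=1e-3)
        np.testing.assert_array_equal(state.N, N_before)
        assert np.all(state.P == 0)

    def test_double_introduction_rejected(self, mesh):
        state = initial_state(ModelParams(), mesh)
        introduce_population(state, "P", 100.0, mesh)
        with pytest.raises(g.SimulationError):
            introduce_population(state, "P", 100.0, mesh)

    def test_size_trigger_time_matches_exponential_growth(self, mesh):
        """At low density, d/dt int N = rho int N, so the 6x trigger fires
        near ln(6)/rho."""
        N_I = total_population(initial_profile(mesh.x, 100.0), mesh)
        params = ModelParams(N_E=6.0 * N_I, N_P=6.0 * N_I)
        trace = g.run(params, mesh, g.SolverConfig())
        expected = math.log(6.0) / 30.0
        assert trace.t_star_E == pytest.approx(expected, rel=0.10)
        assert trace.t_star_E == trace.t_star_P


class TestRun:
    def test_symmetric_construction_gives_identical_fields(self, fast_trace):
        s = fast_trace.final_state
        assert fast_trace.t_star_E == fast_trace.t_star_P
        assert np.max(np.abs(s.E - s.P)) < 1e-10 * K

    def test_stop_reason_and_width(self, fast_trace, mesh):
        assert fast_trace.stop_reason == "target_width"
        w = g.tumour_width(fast_trace.final_state, mesh)
        assert w >= 36.2
        assert w < 36.2 + 5.0  # did not overshoot wildly

    def test_widths_sampled_monotone_tail(self, fast_trace):
        """Sampled width series is non-decreasing once the tumour is established."""
        ws = [w for _, w in fast_trace.widths if w > 0]
        assert all(b >= a for a, b in zip(ws, ws[1:]))

    def test_max_time_is_reported_not_raised(self, mesh):
        cfg = g.SolverConfig(max_time=0.01)
        trace = g.run(ModelParams(), mesh, cfg)
        assert trace.stop_reason == "max_time"
        assert trace.stop_time == pytest.approx(0.01, abs=2 * DT)

    def test_front_speed_approaches_fisher_kpp_minimum(self):
        """Late-time front speed of a single population approaches
        2 sqrt(rho D) = 60 mm/year for rho = D = 30, within 5%."""
        mesh = g.Mesh(L=400.0)
        params = ModelParams(x_star_N=200.0)
        E, P, N = (np.zeros(mesh.n_nodes) for _ in range(3))
        N += initial_profile(mesh.x, 200.0)
        pos = {}
        for i in range(1, int(1.5 * 1500) + 1):
            _euler_update(E, P, N, params, mesh.dx, DT)
            t = i * DT
            for t_probe in (0.9, 1.5):
                if abs(t - t_probe) < DT / 2:
                    idx = np.where(N > 0.5 * K)[0][-1]
                    frac = (N[idx] - 0.5 * K) / (N[idx] - N[idx + 1])
                    pos[t_probe] = mesh.x[idx] + frac * mesh.dx
        speed = (pos[1.5] - pos[0.9]) / 0.6
        assert speed == pytest.approx(2 * math.sqrt(30.0 * 30.0), rel=0.05)

    def test_reduces_to_single_species_model(self, fast_trace, mesh):
        """With neutral interactions and identical rates, T = E+P+N evolves
        exactly as an independently stepped single-species model seeded with
        the same bumps at the realized introduction times."""
        prof = initial_profile(mesh.x, 100.0)
        T = prof.copy()
        nsteps = round(fast_trace.stop_time / DT)
        for i in range(1, nsteps + 1):
            grad = 30.0 * np.diff(T) / mesh.dx
            div = np.empty_like(T)
            div[0] = grad[0] / mesh.dx
            div[-1] = -grad[-1] / mesh.dx
            div[1:-1] = (grad[1:] - grad[:-1]) / mesh.dx
            T = np.maximum(T + DT * (div + 30.0 * T * (1 - T / K)), 0.0)
            t = i * DT
            if abs(t - fast_trace.t_star_E) < DT / 2:
                T = T + prof
            if abs(t - fast_trace.t_star_P) < DT / 2:
                T = T + prof
        assert np.max(np.abs(fast_trace.final_state.total - T)) < 1e-6 * K

    def test_swap_symmetry_is_exact(self, mesh):
        """Exchanging all E and P parameters mirrors the solution bitwise."""
        sc = g.Scenario(
            alpha_EP=-3.0, alpha_PE=2.0, v_rho_E=1.4, v_rho_P=1.1,
            v_D_E=1.2, v_D_P=1.05, trigger_multiple_E=4.0,
            trigger_multiple_P=7.0, offset_E=-0.75, offset_P=1.0,
        )
        p1 = g.build_params(sc, 30.0, 30.0, mesh)
        tr1 = g.run(p1, mesh, g.SolverConfig())
        tr2 = g.run(p1.swapped(), mesh, g.SolverConfig())
        np.testing.assert_array_equal(tr1.final_state.E, tr2.final_state.P)
        np.testing.assert_array_equal(tr1.final_state.P, tr2.final_state.E)
        np.testing.assert_array_equal(tr1.final_state.N, tr2.final_state.N)
        assert tr1.t_star_E == tr2.t_star_P

    def test_total_density_stays_below_capacity(self, fast_trace, asymmetric_trace):
        for trace in (fast_trace, asymmetric_trace):
            assert trace.final_state.total.max() <= K * (1 + 1e-3)

    def test_coexistence_under_all_interaction_types(self, mesh):
        """Both amplified populations persist alongside the founding one in
        a common interior region whether competing, cooperating or neutral."""
        cfg = g.SolverConfig(target_width=None, max_time=0.7)
        for a in (-5.0, 0.0, 5.0):
            params = ModelParams(
                rho_E=35.4, rho_P=33.0, rho_N=30.0,
                alpha_EP=a, alpha_PE=a,
                t_star_E=0.027, t_star_P=0.001,
            )
            s = g.run(params, mesh, cfg).final_state
            coexist = (s.E > 1.0) & (s.P > 1.0) & (s.N > 1.0)
            assert coexist.sum() > 0
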