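"""Hodgkin-Huxley kinetics, synapse latch, stimulus and j_all composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from neurocable3d import (
    GatingState,
    HHParameters,
    MembraneModel,
    Patch,
    StimulusSpec,
    SynapseSpec,
    advance_gating,
    e_l_for_rest,
    gating_rates,
    gating_steady_state,
    hh_current,
    synaptic_current,
)
from neurocable3d.membrane import simulate_space_clamped


class TestGatingRates:
    def test_removable_singularities(self):
        """alpha_m at V=25 and alpha_n at V=10 take their analytic limits."""
        _, _, am, _, _, _ = gating_rates(25.0)
        assert am == pytest.approx(1.0, abs=1e-9)
        an, _, _, _, _, _ = gating_rates(10.0)
        assert an == pytest.approx(0.1, abs=1e-10)
        # continuity across the singular points
        for v0 in (10.0, 25.0):
            below = np.array(gating_rates(v0 - 1e-6))
            above = np.array(gating_rates(v0 + 1e-6))
            assert np.allclose(below, above, rtol=1e-5)

    def test_steady_states_at_rest(self):
        """n/m/h steady states at V=0 match the classical values, computed
        independently by integrating the gating ODEs to equilibrium."""
        n_inf, m_inf, h_inf = gating_steady_state(0.0)
        assert n_inf == pytest.approx(0.3177, abs=2e-4)
        assert m_inf == pytest.approx(0.0529, abs=2e-4)
        assert h_inf == pytest.approx(0.5961, abs=2e-4)

        def rhs(_, x):
            an, bn, am, bm, ah, bh = gating_rates(0.0)
            return [
                an * (1 - x[0]) - bn * x[0],
                am * (1 - x[1]) - bm * x[1],
                ah * (1 - x[2]) - bh * x[2],
            ]

        sol = solve_ivp(rhs, (0.0, 200.0), [0.5, 0.5, 0.5], rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[:, -1], [n_inf, m_inf, h_inf], atol=1e-8)

    def test_rates_nonnegative(self):
        v = np.linspace(-50.0, 150.0, 2001)
        assert all(np.all(r >= 0.0) for r in gating_rates(v))


class TestHHCurrent:
    def test_reversal_potential_zeroes_sodium(self):
        p = HHParameters(g_k=0.0, g_l=0.0)
        assert hh_current(p.e_na, 0.3, 1.0, 1.0, p) == 0.0

    def test_closed_channels_no_current(self):
        p = HHParameters(g_l=0.0)
        for v in (-20.0, 0.0, 50.0, 115.0):
            assert hh_current(v, 0.0, 0.0, 0.7, p) == 0.0

    def test_rest_current_term_by_term(self):
        """Independent scalar evaluation of each channel term at V=0."""
        p = HHParameters()
        n, m, h = gating_steady_state(0.0)
        expected = (
            m**3 * h * 120.0 * (0.0 - 115.0)
            + n**4 * 36.0 * (0.0 + 12.0)
            + 0.3 * (0.0 - 10.6)
        )
        assert hh_current(0.0, n, m, h, p) == pytest.approx(expected, rel=1e-14)
        # and the balanced-leak variant is exactly stationary
        pb = e_l_for_rest(p)
        assert hh_current(0.0, n, m, h, pb) == pytest.approx(0.0, abs=1e-12)


class TestAdvanceGating:
    def test_stationary_at_steady_state(self):
        n, m, h = gating_steady_state(-5.0)
        g = GatingState(np.array([n]), np.array([m]), np.array([h]))
        g2 = advance_gating(g, -5.0, 0.5)
        for a, b in ((g.n, g2.n), (g.m, g2.m), (g.h, g2.h)):
            assert a == pytest.approx(b, rel=1e-12)

    def test_exact_relaxation_at_frozen_potential(self):
        """Repeated small steps at fixed V converge on the closed form
        x_inf + (x0 - x_inf) exp(-T / tau)."""
        v = 30.0
        an, bn, *_ = gating_rates(v)
        tau, x_inf = 1.0 / (an + bn), an / (an + bn)
        x0, T, steps = 0.1, 2.0, 4000
        g = GatingState(np.array([x0]), np.array([0.5]), np.array([0.5]))
        for _ in range(steps):
            g = advance_gating(g, v, T / steps)
        exact = x_inf + (x0 - x_inf) * np.exp(-T / tau)
        assert g.n[0] == pytest.approx(exact, abs=1e-4)
        g_rl = GatingState(np.array([x0]), np.array([0.5]), np.array([0.5]))
        g_rl = advance_gating(g_rl, v, T, scheme="rush_larsen")
        assert g_rl.n[0] == pytest.approx(exact, abs=1e-12)

    def test_single_step_against_reference_ode(self):
        """One 1-us implicit step matches a high-accuracy adaptive
        integration of the same ODE to better than 1e-6."""
        v, dt = 40.0, 1e-3
        x0 = [0.35, 0.1, 0.55]
        g = GatingState(*(np.array([x]) for x in x0))
        g1 = advance_gating(g, v, dt)

        def rhs(_, x):
            an, bn, am, bm, ah, bh = gating_rates(v)
            return [
                an * (1 - x[0]) - bn * x[0],
                am * (1 - x[1]) - bm * x[1],
                ah * (1 - x[2]) - bh * x[2],
            ]

        sol = solve_ivp(rhs, (0.0, dt), x0, rtol=1e-12, atol=1e-14)
        assert np.allclose([g1.n[0], g1.m[0], g1.h[0]], sol.y[:, -1], atol=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        v=st.lists(st.floats(-80.0, 200.0), min_size=1, max_size=30),
        dt=st.floats(1e-4, 5.0),
        x0=st.floats(0.0, 1.0),
    )
    def test_gating_stays_in_unit_interval(self, v, dt, x0):
        """Bounds hold for any potential trajectory and any step size."""
        g = GatingState(np.array([x0]), np.array([x0]), np.array([x0]))
        for scheme in ("implicit", "rush_larsen"):
            gg = g.copy()
            for vv in v:
                gg = advance_gating(gg, vv, dt, scheme=scheme)
                for x in (gg.n, gg.m, gg.h):
                    assert 0.0 <= x[0] <= 1.0


class TestSynapse:
    def test_below_threshold_never_fires(self):
        syn = SynapseSpec(pre_cell=0, post_cell=1, threshold=5.0,
                          post_current_amplitude=2.0, post_duration=1.0)
        for t in np.linspace(0.0, 5.0, 51):
            assert synaptic_current(syn, 4.9, t, 100.0) == 0.0
        assert not syn.fired

    def test_latch_persists_after_presynaptic_decay(self):
        """Once V_m|pre crosses 5 mV the rectangular pulse runs for the full
        duration even though the presynaptic potential falls back."""
        syn = SynapseSpec(pre_cell=0, post_cell=1, threshold=5.0,
                          post_current_amplitude=2.0, post_duration=1.0)
        area = 100.0
        assert synaptic_current(syn, 0.0, 0.5, area) == 0.0
        j = synaptic_current(syn, 6.0, 1.0, area)  # crossing fires the latch
        assert syn.latch_time == 1.0
        j_mid = synaptic_current(syn, -60.0, 1.5, area)  # pre back below
        expected = -2.0 / (area * 1e-5)
        assert j_mid == pytest.approx(expected)
        assert synaptic_current(syn, -60.0, 2.5, area) == 0.0  # pulse over

    def test_second_crossing_does_not_retrigger(self):
        syn = SynapseSpec(pre_cell=0, post_cell=1, post_duration=1.0)
        synaptic_current(syn, 10.0, 1.0, 100.0)
        synaptic_current(syn, -10.0, 1.2, 100.0)
        synaptic_current(syn, 10.0, 1.4, 100.0)  # within duration: no reset
        assert syn.latch_time == 1.0

    def test_alpha_form_peaks_inside_pulse(self):
        syn = SynapseSpec(pre_cell=0, post_cell=1, post_duration=2.0,
                          post_current_amplitude=1.0, alpha_form="alpha")
        synaptic_current(syn, 10.0, 0.0, 100.0)
        ts = np.linspace(0.01, 2.0, 100)
        js = [syn.current_density(t, 100.0) for t in ts]
        assert min(js) < 0.0 and js[-1] > min(js)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SynapseSpec(pre_cell=0, post_cell=1, post_duration=0.0)
        with pytest.raises(ValueError):
            StimulusSpec(t_on=1.0, t_off=1.0)


class TestTotalCurrent:
    def test_myelin_carries_only_capacitive_current(self):
        model = MembraneModel()
        g = (np.array([0.3]), np.array([0.1]), np.array([0.6]))
        j = model.total_current_density(Patch.MYELIN, np.array([60.0]), np.array([0.0]), g, 1.0)
        assert j == pytest.approx(0.0)
        j2 = model.total_current_density(Patch.MYELIN, np.array([60.0]), np.array([10.0]), g, 1.0)
        assert j2 == pytest.approx(model.params.c_m_myelin * 10.0)

    def test_dendrite_is_passive(self):
        model = MembraneModel()
        g = (np.array([0.9]), np.array([0.9]), np.array([0.9]))  # would be huge if active
        v = np.array([40.0])
        j = model.total_current_density(Patch.DENDRITE, v, np.array([0.0]), g, 1.0)
        assert j == pytest.approx(model.params.g_l * (40.0 - model.params.e_l))

    def test_active_patch_matches_term_by_term_composition(self):
        """j_all on an active patch = c_m dV/dt + j_HH, each term evaluated
        independently."""
        model = MembraneModel()
        n, m, h = gating_steady_state(0.0)
        g = (np.array([n]), np.array([m]), np.array([h]))
        v, dvdt = np.array([20.0]), np.array([5.0])
        j = model.total_current_density(Patch.ACTIVE, v, dvdt, g, 1.0)
        expected = 1.0 * 5.0 + hh_current(20.0, n, m, h, model.params)
        assert j == pytest.approx(expected, rel=1e-14)

    def test_unknown_patch_rejected(self):
        model = MembraneModel()
        g = (np.array([0.3]), np.array([0.1]), np.array([0.6]))
        with pytest.raises(ValueError, match="patch"):
            model.total_current_density(99, np.array([0.0]), np.array([0.0]), g, 0.0)


class TestSpaceClampedDynamics:
    def test_suprathreshold_current_elicits_action_potential(self):
        """A space-clamped active patch produces a spike: V_m exceeds 80 mV
        above rest and returns within 20 ms."""
        model = MembraneModel(params=e_l_for_rest(HHParameters()))
        t, v = simulate_space_clamped(
            model, t_end=20.0, dt=0.01,
            stimulus_density=lambda tt: -15.0 if tt <= 1.0 else 0.0,
        )
        assert v.max() > 80.0
        assert abs(v[-1]) < 15.0  # back near rest within 20 ms

    def test_subthreshold_current_stays_small(self):
        model = MembraneModel(params=e_l_for_rest(HHParameters()))
        t, v = simulate_space_clamped(
            model, t_end=10.0, dt=0.01,
            stimulus_density=lambda tt: -1.0 if tt <= 0.5 else 0.0,
        )
        assert v.max() < 20.0
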