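import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from pmfsim import (CRingConfig, IntegrationError, InvalidParameterError,
                    KineticParams, ModelState, ThermoParams, dark_equilibrate,
                    equilibrium_pmf, make_static)
from pmfsim.kinetics import (STATE_FIELDS, atp_synthase_flux,
                             b6f_rate_constant, counter_ion_flux, derivatives,
                             fluxes, qe_extent, recombination_rate,
                             singlet_o2_rate, solve_pka_reg,
                             zeaxanthin_steady_state)


class TestB6fControl:
    def test_tenfold_span_75_to_55(self, params, thermo, ring14):
        p = params.resolved(ring14, thermo)
        ratio = b6f_rate_constant(7.5, p) / b6f_rate_constant(5.5, p)
        assert ratio == pytest.approx(10.0, rel=0.02)

    def test_saturates_at_kmax(self, params):
        assert b6f_rate_constant(14.0, params) == pytest.approx(
            params.k_b6f_max, rel=1e-6)

    def test_half_max_at_pka(self, params, thermo, ring14):
        p = params.resolved(ring14, thermo)
        assert b6f_rate_constant(p.pka_reg, p) == pytest.approx(
            p.k_b6f_max / 2.0)

    def test_solved_pka_is_65_for_hill_1(self):
        assert solve_pka_reg(1.0) == pytest.approx(6.5, abs=1e-12)

    @given(ph=st.floats(4.0, 9.0), dph=st.floats(0.01, 1.0))
    def test_monotone_increasing_in_ph(self, ph, dph):
        p = KineticParams().resolved(CRingConfig(14), ThermoParams())
        assert b6f_rate_constant(ph + dph, p) > b6f_rate_constant(ph, p)

    def test_tenfold_unreachable_with_shallow_hill(self):
        with pytest.raises(InvalidParameterError):
            solve_pka_reg(0.4)


class TestRecombination:
    def test_zero_competent_pool(self, params):
        s = ModelState(qa_reduced=0.0, s23_donor_frac=0.5, delta_psi=0.2)
        assert recombination_rate(s, params) == 0.0

    def test_intrinsic_rate_at_zero_field(self, params):
        s = ModelState(qa_reduced=0.4, s23_donor_frac=0.5, delta_psi=0.0)
        assert recombination_rate(s, params) == pytest.approx(
            0.4 * 0.5 * params.k_r)

    def test_decade_per_006_over_f(self, params):
        base = ModelState(qa_reduced=0.4, s23_donor_frac=0.5, delta_psi=0.05)
        up = ModelState(qa_reduced=0.4, s23_donor_frac=0.5,
                        delta_psi=0.05 + params.psi_per_decade / params.f_dist)
        assert recombination_rate(up, params) == pytest.approx(
            10.0 * recombination_rate(base, params), rel=1e-9)

    @given(psi=st.floats(-0.1, 0.25), dpsi=st.floats(1e-4, 0.1))
    def test_strictly_increasing_in_delta_psi(self, psi, dpsi):
        params = KineticParams()
        lo = ModelState(qa_reduced=0.3, s23_donor_frac=0.5, delta_psi=psi)
        hi = ModelState(qa_reduced=0.3, s23_donor_frac=0.5, delta_psi=psi + dpsi)
        assert recombination_rate(hi, params) > recombination_rate(lo, params)

    def test_singlet_o2_yield(self, params):
        s = ModelState(qa_reduced=0.4, s23_donor_frac=0.5, delta_psi=0.1)
        assert singlet_o2_rate(s, params) == pytest.approx(
            params.phi_1o2 * recombination_rate(s, params))

    def test_s23_qa_never_exceeds_qa(self):
        s = ModelState(qa_reduced=0.3, s23_donor_frac=1.0)
        assert s.s23_qa_frac <= s.qa_reduced


class TestAtpSynthase:
    def test_zero_flux_at_equilibrium(self, params, thermo, ring14):
        pmf_eq = equilibrium_pmf(thermo, ring14)
        assert atp_synthase_flux(pmf_eq, ring14, thermo, params) == 0.0

    def test_ohmic_above_equilibrium(self, params, thermo, ring14):
        pmf_eq = equilibrium_pmf(thermo, ring14)
        assert atp_synthase_flux(pmf_eq + 0.01, ring14, thermo, params) == \
            pytest.approx(params.g_atpase * 0.01)

    def test_reverses_below_equilibrium(self, params, thermo, ring14):
        pmf_eq = equilibrium_pmf(thermo, ring14)
        assert atp_synthase_flux(pmf_eq - 0.02, ring14, thermo, params) < 0.0

    def test_inactive_enzyme(self, thermo, ring14):
        p = KineticParams(g_atpase=0.0)
        assert atp_synthase_flux(0.3, ring14, thermo, p) == 0.0


class TestQe:
    def test_near_zero_at_stromal_ph(self, params):
        assert qe_extent(7.8, None, params) < 1e-3

    def test_ordering_65_vs_70(self, params):
        # matched zeaxanthin: compare protonation-side response only
        zea = zeaxanthin_steady_state(6.5, params)
        s65 = ModelState(lumen_ph=6.5, psbs_protonated=0.5, zeaxanthin=zea)
        assert qe_extent(6.5, None, params) > qe_extent(7.0, None, params)
        assert s65.s23_qa_frac == 0.0  # sanity on unrelated fields

    def test_midpoint_protonation_factor(self):
        p = KineticParams(pka_psbs=6.2, pka_vde=6.2, n_psbs=1.0, n_vde=1.0)
        zea_ss = zeaxanthin_steady_state(6.2, p)
        assert qe_extent(6.2, None, p) == pytest.approx(0.5 * zea_ss, rel=1e-9)

    def test_appreciable_at_65(self, params):
        assert qe_extent(6.5, None, params) > 0.1


class TestCounterIon:
    def test_zero_at_ion_equilibrium(self):
        p = KineticParams(delta_psi_ion_eq=0.05)
        s = ModelState(delta_psi=0.05)
        assert counter_ion_flux(s, p) == 0.0

    def test_zero_conductance(self):
        p = KineticParams(g_ion=0.0, delta_psi_ion_eq=0.0)
        s = ModelState(delta_psi=0.2)
        assert counter_ion_flux(s, p) == 0.0

    def test_exponential_relaxation_closed_form(self, thermo, ring14):
        # frozen system: no light, no ATP synthase, no redox chemistry ->
        # d(psi)/dt = -c_m * g_ion * (psi - psi_eq), tau = 1/(g_ion * c_m)
        p = KineticParams(g_atpase=0.0, g_ion=20.0, delta_psi_ion_eq=0.0,
                          pka_reg=6.5)
        dark = make_static(0.0, 10.0)
        s0 = ModelState(qa_reduced=0.0, pq_reduced=0.0, p700_ox=0.0,
                        lumen_ph=7.8, delta_psi=0.1, s23_donor_frac=0.0,
                        psbs_protonated=0.0, zeaxanthin=0.0)

        def rhs(t, y):
            return derivatives(t, ModelState.from_array(y), ring14, thermo,
                               p, dark)

        tau = 1.0 / (p.g_ion * p.c_membrane)
        t_eval = np.linspace(0.0, 3.0 * tau, 20)
        sol = solve_ivp(rhs, (0.0, 3.0 * tau), s0.as_array(), method="BDF",
                        rtol=1e-10, atol=1e-12, t_eval=t_eval)
        psi = sol.y[STATE_FIELDS.index("delta_psi")]
        expected = 0.1 * np.exp(-t_eval / tau)
        assert np.allclose(psi, expected, rtol=1e-5, atol=1e-9)


class TestDerivatives:
    def test_dark_equilibrium_is_fixed_point(self, thermo, ring14, params):
        p = params.resolved(ring14, thermo)
        state = dark_equilibrate(ring14, thermo, p)
        d = derivatives(0.0, state, ring14, thermo, p, make_static(0.0, 1.0))
        assert np.max(np.abs(d)) < 1e-6

    def test_proton_bookkeeping_identity(self, thermo, ring14, params):
        p = params.resolved(ring14, thermo)
        s = ModelState(qa_reduced=0.3, pq_reduced=0.5, p700_ox=0.4,
                       lumen_ph=6.4, delta_psi=0.08, s23_donor_frac=0.4,
                       psbs_protonated=0.3, zeaxanthin=0.2)
        light = make_static(500.0, 10.0)
        fx = fluxes(1.0, s, ring14, thermo, p, light)
        d = derivatives(1.0, s, ring14, thermo, p, light)
        d_ph = d[STATE_FIELDS.index("lumen_ph")]
        assert fx["h_in"] - fx["h_out"] == pytest.approx(
            -p.beta_lumen * d_ph, rel=1e-12)

    def test_light_step_signs_at_dark_equilibrium(self, thermo, ring14, params):
        # at t = 0+ (just after onset, once the first stable turnovers have
        # begun) the membrane charges and the lumen acidifies
        p = params.resolved(ring14, thermo)
        state = dark_equilibrate(ring14, thermo, p)
        light = make_static(1000.0, 10.0)
        d0 = derivatives(0.0, state, ring14, thermo, p, light)
        assert d0[STATE_FIELDS.index("delta_psi")] > 0.0

        def rhs(t, y):
            return derivatives(t, ModelState.from_array(y), ring14, thermo,
                               p, light)

        sol = solve_ivp(rhs, (0.0, 0.01), state.as_array(), method="BDF",
                        rtol=1e-9, atol=1e-12)
        d = rhs(0.01, sol.y[:, -1])
        assert d[STATE_FIELDS.index("lumen_ph")] < 0.0
        assert sol.y[STATE_FIELDS.index("delta_psi"), -1] > state.delta_psi

    def test_non_finite_flux_reports_term(self, thermo, ring14, params):
        p = params.resolved(ring14, thermo)
        s = ModelState(delta_psi=float("inf"))
        with pytest.raises(IntegrationError) as err:
            derivatives(0.0, s, ring14, thermo, p, make_static(0.0, 1.0))
        assert err.value.term is not None

    def test_state_array_round_trip(self):
        s = ModelState(qa_reduced=0.1, lumen_ph=6.9, cumulative_lef=42.0)
        assert ModelState.from_array(s.as_array()) == s

    def test_validate_rejects_bad_fraction(self):
        with pytest.raises(IntegrationError):
            ModelState(qa_reduced=1.5).validate()


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        {"k_r": -1.0}, {"phi_1o2": 1.5}, {"f_dist": -0.2},
        {"pka_psbs": 3.0}, {"g_atpase": -5.0}, {"psi_per_decade": 0.0},
    ])
    def test_rejects_out_of_domain(self, kw):
        with pytest.raises(InvalidParameterError):
            KineticParams(**kw)

    def test_resolved_fills_pka_and_ion_eq(self, thermo, ring14, params):
        p = params.resolved(ring14, thermo, fraction_psi=0.5)
        assert p.pka_reg == pytest.approx(6.5)
        assert p.delta_psi_ion_eq == pytest.approx(
            0.5 * equilibrium_pmf(thermo, ring14))
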