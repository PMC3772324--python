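import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from msnsim import calcium_er as CE
from msnsim.config import generate_fixtures

#: parameters with the literature's printed magnitudes for the operations
#: whose worked examples quote them (pump half-max, rates at K values)
PRINTED = CE.CalciumParams(V_pump_uM_per_ms=0.1)


@pytest.fixture()
def params():
    return CE.CalciumParams()


class TestCICR:
    def test_zero_at_zero_calcium(self, params):
        assert CE.cicr_flux(0.0, params) == 0.0

    def test_half_maximal_at_k(self, params):
        # Ca = K_CICR -> Hill factor exactly 1/2
        ca = params.K_CICR_uM
        expect = 0.5 * params.V_CICR_per_ms * (params.Ca_ER_uM - ca)
        assert CE.cicr_flux(ca, params) == pytest.approx(expect)

    def test_zero_at_er_concentration(self, params):
        assert CE.cicr_flux(params.Ca_ER_uM, params) == pytest.approx(0.0)


class TestIP3RGates:
    def test_low_calcium_limits(self, params):
        m, h = CE.ip3r_gates(1.0, 1e-9, params)
        assert m == pytest.approx(0.0, abs=1e-6)
        assert h == pytest.approx(1.0, abs=1e-6)

    def test_half_activation_at_d_act_with_saturating_ip3(self, params):
        m, _ = CE.ip3r_gates(1e9, params.d_act_uM, params)
        assert m == pytest.approx(0.5, rel=1e-6)

    def test_gates_within_unit_interval(self, params):
        ca = np.logspace(-3, 2, 50)
        m, h = CE.ip3r_gates(0.5, ca, params)
        assert np.all((m >= 0) & (m <= 1)) and np.all((h >= 0) & (h <= 1))

    def test_release_curve_is_bell_shaped(self, params):
        """m^3 h^3 (Ca_ER - Ca) has a single interior maximum in Ca."""
        ca = np.linspace(1e-4, 2.0, 4000)
        m, h = CE.ip3r_gates(0.5, ca, params)
        y = m ** 3 * h ** 3 * (params.Ca_ER_uM - ca)
        k = int(np.argmax(y))
        assert 0 < k < len(ca) - 1
        d = np.diff(y)
        # single sign change of the derivative: rises then falls
        assert np.all(d[:k] > 0) and np.all(d[k:] < 0)
        # peak in the few-tenths-uM region
        assert 0.05 < ca[k] < 0.5


class TestIP3Dynamics:
    def test_fixed_point_without_glutamate(self, params):
        ip3 = CE.ip3_step(params.IP3_min_uM, np.inf, 1.0, params)
        assert ip3 == pytest.approx(params.IP3_min_uM)

    def test_production_peaks_at_tau_ip3(self, params):
        t = np.linspace(1.0, 1000.0, 2000)
        r = CE.ip3_production_rate(t, params)
        assert t[np.argmax(r)] == pytest.approx(params.tau_IP3_ms, rel=0.01)

    def test_relaxation_rate_is_beta(self, params):
        # after production has ceased, decay toward IP3_min at rate beta
        x0 = 2.0
        dt = 1.0
        x1 = CE.ip3_step(x0, np.inf, dt, params)
        expect = params.IP3_min_uM + (x0 - params.IP3_min_uM) * np.exp(
            -params.beta_IP3_per_ms * dt)
        assert x1 == pytest.approx(expect, rel=1e-12)


class TestERFluxes:
    def test_uptake_half_max_at_k(self, params):
        out = CE.er_exchange_fluxes(None, params, Ca_i_uM=params.K_uptake_uM,
                                    IP3_uM=params.IP3_min_uM)
        assert out["J_uptake"] == pytest.approx(params.V_uptake_uM_per_ms / 2)

    def test_zero_gradient_kills_release_and_leak(self, params):
        out = CE.er_exchange_fluxes(None, params, Ca_i_uM=params.Ca_ER_uM,
                                    IP3_uM=1.0)
        assert out["J_IP3"] == pytest.approx(0.0)
        assert out["J_leak"] == pytest.approx(0.0)

    def test_no_uptake_without_calcium(self, params):
        out = CE.er_exchange_fluxes(None, params, Ca_i_uM=0.0, IP3_uM=1.0)
        assert out["J_uptake"] == 0.0


class TestMembraneFlux:
    def test_inward_current_raises_calcium(self):
        assert CE.membrane_ca_flux(-0.001, 0.0, 1.0) > 0

    def test_doubling_volume_halves_flux(self):
        j1 = CE.membrane_ca_flux(-0.001, 0.0, 1.0)
        j2 = CE.membrane_ca_flux(-0.001, 0.0, 2.0)
        assert j2 == pytest.approx(j1 / 2)

    def test_one_picoamp_unit_conversion(self):
        # 1 pA into 1 um^3: 1e-12 C/s / (2*96489 C/mol) / 1e-15 L ~ 5.18 uM/ms
        j = CE.membrane_ca_flux(-0.001, 0.0, 1.0)
        assert j == pytest.approx(1e-12 / (2 * 96489.0) / 1e-15 * 1e-3 * 1e6,
                                  rel=1e-12)
        assert j == pytest.approx(5.182, rel=1e-3)

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            CE.membrane_ca_flux(0.0, 0.0, 0.0)


class TestPump:
    def test_half_max_at_k_with_printed_rate(self):
        # printed magnitudes: V_pump = 0.1 uM/ms, K_pump = 0.1 uM
        assert CE.pump_flux(0.1, PRINTED) == pytest.approx(0.05)

    def test_zero_at_zero(self, params):
        assert CE.pump_flux(0.0, params) == 0.0

    def test_saturates_at_v_pump(self, params):
        assert CE.pump_flux(1e9, params) == pytest.approx(
            params.V_pump_uM_per_ms, rel=1e-6)


class TestCalciumStep:
    def test_fixed_point_at_rest(self, params):
        pool = CE.CalciumPool(Ca_i_uM=params.Ca_inf_uM)
        f = CE.FluxSet(J_diff=float(CE.diffusion_flux(pool.Ca_i_uM, params)))
        out = CE.calcium_step(pool, f, 0.025)
        assert out.Ca_i_uM == pytest.approx(params.Ca_inf_uM)

    def test_pure_relaxation_decays_with_tau_diff(self, params):
        pool = CE.CalciumPool(Ca_i_uM=1.0)
        t, dt = 0.0, 0.01
        while t < params.tau_diff_ms:
            f = CE.FluxSet(J_diff=float(CE.diffusion_flux(pool.Ca_i_uM, params)))
            pool = CE.calcium_step(pool, f, dt)
            t += dt
        # after one time constant: Ca_inf + (1 - Ca_inf)/e
        expect = params.Ca_inf_uM + (1.0 - params.Ca_inf_uM) / np.e
        assert pool.Ca_i_uM == pytest.approx(expect, rel=2e-3)

    def test_trajectory_matches_adaptive_ode_oracle(self, params):
        """Full balance driven by a canned flux schedule vs scipy's solver."""
        fx = generate_fixtures("ca_flux_schedule", seed=3)
        t_grid, j_grid = fx["t_ms"], fx["J_uM_per_ms"]
        ip3 = 0.6  # frozen IP3 so both integrators see the same system

        def rhs(t, y):
            ca = y[0]
            er = CE.er_exchange_fluxes(None, params, Ca_i_uM=ca, IP3_uM=ip3)
            return (float(CE.cicr_flux(ca, params)) + float(er["J_IP3"])
                    - float(er["J_uptake"]) + float(er["J_leak"])
                    + float(np.interp(t, t_grid, j_grid))
                    - float(CE.pump_flux(ca, params))
                    + float(CE.diffusion_flux(ca, params)))

        sol = solve_ivp(rhs, (0, 500), [0.05], rtol=1e-9, atol=1e-12,
                        max_step=0.25)
        pool = CE.CalciumPool(Ca_i_uM=0.05, IP3_uM=ip3)
        dt = 0.01
        for k in range(50000):
            t = k * dt
            er = CE.er_exchange_fluxes(pool, params)
            f = CE.FluxSet(
                J_CICR=float(CE.cicr_flux(pool.Ca_i_uM, params)),
                J_IP3=float(er["J_IP3"]), J_uptake=float(er["J_uptake"]),
                J_leak=float(er["J_leak"]),
                J_cur=float(np.interp(t, t_grid, j_grid)),
                J_pump=float(CE.pump_flux(pool.Ca_i_uM, params)),
                J_diff=float(CE.diffusion_flux(pool.Ca_i_uM, params)),
            )
            pool = CE.calcium_step(pool, f, dt)
        assert pool.Ca_i_uM == pytest.approx(sol.y[0, -1], rel=0.01)

    def test_calcium_stays_positive_under_strong_efflux(self, params):
        pool = CE.CalciumPool(Ca_i_uM=0.01)
        pool = CE.calcium_step(pool, CE.FluxSet(J_pump=1e3), 1.0)
        assert pool.Ca_i_uM > 0
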