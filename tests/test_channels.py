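import numpy as np
import pytest
from scipy.integrate import solve_ivp

from msnsim import channels as C
from msnsim.kinetics import load_kinetics


@pytest.fixture(scope="module")
def kinetics():
    return load_kinetics()


@pytest.fixture(scope="module")
def specs(kinetics):
    channels, _ = kinetics
    # give every channel a uniform unit density so family sums are nontrivial
    for spec in channels.values():
        spec.density = {"all": 1e-4}
    return channels


class TestGateStep:
    def test_steady_state_is_fixed_point(self, specs):
        g = specs["NaF"].gates[0]
        x = float(g.steady_state(-40.0))
        assert C.gate_step(g, x, -40.0, dt_ms=0.5) == pytest.approx(x, abs=1e-12)

    def test_large_dt_reaches_steady_state(self, specs):
        g = specs["KIR"].gates[0]
        assert C.gate_step(g, 0.0, -60.0, dt_ms=1e6) == pytest.approx(
            float(g.steady_state(-60.0)), abs=1e-9)

    def test_halved_steps_match_ode_oracle(self, specs):
        """Exponential updates agree with adaptive ODE integration at fixed V."""
        g = specs["CaT"].gates[1]  # slow inactivation gate
        V, x0, T = -60.0, 0.9, 20.0
        xinf, tau = float(g.steady_state(V)), float(g.time_constant(V))
        sol = solve_ivp(lambda t, x: (xinf - x) / tau, (0, T), [x0],
                        rtol=1e-10, atol=1e-12)
        one = C.gate_step(g, x0, V, dt_ms=T)
        x = x0
        for _ in range(8):
            x = C.gate_step(g, x, V, dt_ms=T / 8)
        assert one == pytest.approx(sol.y[0, -1], rel=1e-9)
        assert x == pytest.approx(sol.y[0, -1], rel=1e-9)

    def test_bounded_for_random_voltage_trace(self, specs):
        rng = np.random.default_rng(7)
        V = np.clip(np.cumsum(rng.normal(0, 8, 500)) - 70, -100, 50)
        for spec in specs.values():
            for g in spec.gates:
                x = 0.5
                for v in V:
                    x = C.gate_step(g, x, v, Ca_uM=rng.uniform(0.01, 5.0),
                                    dt_ms=0.1)
                    assert 0.0 <= x <= 1.0

    def test_rejects_nonpositive_dt(self, specs):
        with pytest.raises(ValueError):
            C.gate_step(specs["NaF"].gates[0], 0.5, -60.0, dt_ms=0.0)


class TestOhmic:
    def test_zero_at_reversal(self, specs):
        spec = specs["KIR"]
        assert C.ohmic_current(spec, {"m": 1.0}, V_mV=-90.0) == 0.0

    def test_zero_when_closed(self, specs):
        assert C.ohmic_current(specs["KIR"], {"m": 0.0}, V_mV=0.0) == 0.0

    def test_kir_arithmetic(self, specs):
        # fully open KIR at its tabulated density, 20 mV above E_K
        i = C.ohmic_current(specs["KIR"], {"m": 1.0}, V_mV=-70.0,
                            gbar_S_cm2=4.18e-4)
        assert i == pytest.approx(4.18e-4 * 20.0)

    def test_sign_change_exactly_at_erev(self, specs):
        spec = specs["KIR"]
        below = C.ohmic_current(spec, {"m": 1.0}, -90.001, gbar_S_cm2=1e-3)
        above = C.ohmic_current(spec, {"m": 1.0}, -89.999, gbar_S_cm2=1e-3)
        assert below < 0 < above

    def test_ghk_spec_rejected(self, specs):
        with pytest.raises(TypeError):
            C.ohmic_current(specs["CaT"], {"m": 1.0, "h": 1.0}, -50.0)


def _ghk_reference(p, V_mV, ci_uM, co_mM, T):
    """Direct long-double evaluation of the GHK current equation."""
    F, R = np.longdouble(96489.0), np.longdouble(8.31)
    V = np.longdouble(V_mV) * np.longdouble(1e-3)
    ci = np.longdouble(ci_uM) * np.longdouble(1e-9)
    co = np.longdouble(co_mM) * np.longdouble(1e-6)
    u = 2 * F * V / (R * np.longdouble(T))
    num = ci - co * np.exp(-u)
    return float(np.longdouble(p) * 4 * F ** 2 * V / (R * np.longdouble(T))
                 * num / (1 - np.exp(-u))) * 1e3


class TestGHK:
    def test_v_zero_analytic_limit(self):
        # L'Hopital limit: I = 2*F*P*(ci - co), inward when ci < co
        p, ci, co = 1e-5, 0.01, 5.0
        i = C.ghk_current(p, 1.0, 0.0, ci, co)
        expect = 2 * 96489.0 * p * (ci * 1e-9 - co * 1e-6) * 1e3
        assert i == pytest.approx(expect, rel=1e-10)
        assert i < 0

    def test_null_point(self):
        V, T = 20.0, 303.15
        u = 2 * 96489.0 * V * 1e-3 / (8.31 * T)
        co = 5.0
        ci = co * 1e3 * np.exp(-u)  # uM
        i = C.ghk_current(1e-5, 1.0, V, ci, co, T)
        assert abs(i) < 1e-12
        # sign change across the null point
        assert C.ghk_current(1e-5, 1.0, V, ci * 0.99, co, T) < 0
        assert C.ghk_current(1e-5, 1.0, V, ci * 1.01, co, T) > 0

    @pytest.mark.parametrize("V", [-80.0, 80.0])
    def test_high_precision_reference(self, V):
        got = C.ghk_current(1e-5, 1.0, V, 0.01, 5.0, 303.15)
        ref = _ghk_reference(1e-5, V, 0.01, 5.0, 303.15)
        assert got == pytest.approx(ref, rel=1e-10)

    def test_series_branch_continuity(self):
        # the series expansion joins the exact branch smoothly near V = 0
        v_small = 1e-4 * 8.31 * 303.15 / (2 * 96489.0) * 1e3  # mV at |u|=1e-4
        lo = C.ghk_current(1e-5, 1.0, v_small * 0.99, 0.01, 5.0)
        hi = C.ghk_current(1e-5, 1.0, v_small * 1.01, 0.01, 5.0)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            C.ghk_current(1e-5, 1.0, 0.0, 0.01, Ca_o_mM=0.0)


class TestTotalChannelCurrent:
    def _states(self, specs, V=-70.0, Ca=0.05):
        return {name: {g.name: float(g.steady_state(V, Ca)) for g in s.gates}
                for name, s in specs.items()}

    def test_all_zero_densities(self, kinetics):
        channels, _ = kinetics
        import copy
        specs = copy.deepcopy(channels)
        for s in specs.values():
            s.density = {"all": 0.0}
        out = C.total_channel_current(specs, self._states(specs), -70.0, 0.05)
        assert out == {"I_NaChan": 0.0, "I_KChan": 0.0, "I_CaChan": 0.0}

    def test_single_kir_term(self, kinetics):
        channels, _ = kinetics
        import copy
        specs = copy.deepcopy(channels)
        for name, s in specs.items():
            s.density = {"all": 4.18e-4 if name == "KIR" else 0.0}
        states = self._states(specs)
        out = C.total_channel_current(specs, states, -70.0, 0.05)
        expect = C.ohmic_current(specs["KIR"], states["KIR"], -70.0,
                                 gbar_S_cm2=4.18e-4)
        assert out["I_KChan"] == pytest.approx(float(expect))
        assert out["I_NaChan"] == 0.0 and out["I_CaChan"] == 0.0

    def test_blockade_multipliers_scale_only_targets(self, specs):
        states = self._states(specs, V=-40.0)
        base = C.total_channel_current(specs, states, -40.0, 0.05)
        mult = {"KAf": 0.6, "KAs": 0.4, "KRP": 0.5, "NaF": 0.25}
        out = C.total_channel_current(specs, states, -40.0, 0.05, mu=mult)
        assert out["I_CaChan"] == pytest.approx(base["I_CaChan"])
        assert abs(out["I_KChan"]) < abs(base["I_KChan"])
        assert abs(out["I_NaChan"]) < abs(base["I_NaChan"])

    def test_unknown_channel_rejected(self, specs):
        bad = dict(specs)
        bad.pop("KIR")
        with pytest.raises(C.ChannelConfigError):
            C.total_channel_current(bad, self._states(specs), -70.0, 0.05)
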