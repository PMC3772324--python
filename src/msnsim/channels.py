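"""Voltage- and calcium-gated ionic currents.

Two conduction models are supported: ohmic Hodgkin-Huxley currents
``I = mu * gbar * x(t, V) * (V - E_rev)`` for the sodium and potassium
channels, and the Goldman-Hodgkin-Katz current equation for all calcium
channels, whose permeability is gated the same way
(``P = mu * pbar * x(t, V)``).

Gating kinetics are data, not code: they are loaded from a YAML stanza per
channel (see :mod:`msnsim.kinetics`), so corrected parameterizations can be
swapped in without touching the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FARADAY_C_PER_MOL = 96489.0
GAS_CONSTANT_J_PER_MOL_K = 8.31

CHANNEL_NAMES = (
    "NaF", "NaP", "KIR", "KAs", "KAf", "KRP", "SK", "BK",
    "CaN", "CaQ", "CaR", "CaT", "Cav1.2", "Cav1.3",
)
NA_CHANNELS = ("NaF", "NaP")
K_CHANNELS = ("KIR", "KAs", "KAf", "KRP", "SK", "BK")
CA_CHANNELS = ("CaN", "CaQ", "CaR", "CaT", "Cav1.2", "Cav1.3")

#: relative size of |2FV/RT| below which the GHK driving term switches to its
#: first-order series expansion (removable singularity at V = 0)
GHK_SERIES_THRESHOLD = 1e-4


class ChannelConfigError(ValueError):
    """Unknown channel name or inconsistent channel specification."""


@dataclass(frozen=True)
class GateScheme:
    """One Hodgkin-Huxley gate: steady-state curve + relaxation time."""

    name: str
    exponent: int
    vhalf_mV: float = 0.0
    k_mV: float = 1.0
    floor: float = 0.0           # incomplete (in)activation plateau
    tau0_ms: float = 1.0
    tau_amp_ms: float = 0.0
    tau_vt_mV: float = 0.0
    tau_ka_mV: float = 1.0
    tau_kb_mV: float = 1.0
    # calcium dependence: "", "hill" (SK) or "shift" (BK)
    ca_dependent: str = ""
    ca_half_uM: float = 0.35
    hill_coef: float = 4.0
    ca_ref_uM: float = 1.0
    shift_mV_per_efold: float = 0.0

    def steady_state(self, V_mV, Ca_uM=None):
        """x_inf at voltage ``V_mV`` (and calcium ``Ca_uM`` if Ca-dependent)."""
        V = np.asarray(V_mV, dtype=float)
        if self.ca_dependent == "hill":
            ca = np.maximum(np.asarray(Ca_uM if Ca_uM is not None else 0.0, float), 1e-12)
            r = ca ** self.hill_coef
            return r / (r + self.ca_half_uM ** self.hill_coef)
        if self.ca_dependent == "shift":
            ca = np.maximum(np.asarray(Ca_uM if Ca_uM is not None else self.ca_ref_uM, float), 1e-12)
            V = V - self.shift_mV_per_efold * np.log(ca / self.ca_ref_uM)
        s = 1.0 / (1.0 + np.exp(-(V - self.vhalf_mV) / self.k_mV))
        return self.floor + (1.0 - self.floor) * s

    def time_constant(self, V_mV):
        """tau(V) in ms; strictly positive over the physiological range."""
        V = np.asarray(V_mV, dtype=float)
        tau = np.full_like(V, self.tau0_ms, dtype=float)
        if self.tau_amp_ms:
            tau = tau + self.tau_amp_ms / (
                np.exp((V - self.tau_vt_mV) / self.tau_ka_mV)
                + np.exp(-(V - self.tau_vt_mV) / self.tau_kb_mV)
            )
        return tau


def gate_step(scheme: GateScheme, state, V_mV, Ca_uM=None, dt_ms: float = 0.025):
    """Advance a gate by ``dt_ms`` with the exact exponential update.

    First-order relaxation toward the steady state at the (frozen) voltage:
    unconditionally stable for any dt; result clamped to [0, 1].
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    xinf = scheme.steady_state(V_mV, Ca_uM)
    tau = scheme.time_constant(V_mV)
    x = xinf + (np.asarray(state, float) - xinf) * np.exp(-dt_ms / tau)
    return np.clip(x, 0.0, 1.0)


@dataclass
class ChannelSpec:
    """A channel type: conduction model, per-region magnitude, gates."""

    name: str
    conduction: str               # "ohmic" | "ghk"
    gates: list[GateScheme]
    erev_mV: float | None = None  # ohmic only
    density: dict[str, float] = field(default_factory=dict)  # region -> gbar/pbar

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ChannelConfigError(f"unknown channel: {self.name!r}")
        if self.conduction not in ("ohmic", "ghk"):
            raise ChannelConfigError(f"bad conduction model: {self.conduction!r}")
        if self.conduction == "ohmic" and self.erev_mV is None:
            raise ChannelConfigError(f"{self.name}: ohmic channel needs erev_mV")

    def open_fraction(self, state: dict[str, float]):
        x = 1.0
        for g in self.gates:
            x = x * np.asarray(state[g.name], float) ** g.exponent
        return x

    def steady_state_open(self, V_mV, Ca_uM=None):
        x = 1.0
        for g in self.gates:
            x = x * g.steady_state(V_mV, Ca_uM) ** g.exponent
        return x


def ohmic_current(spec: ChannelSpec, state: dict[str, float], V_mV, mu: float = 1.0,
                  gbar_S_cm2: float | None = None):
    """Ohmic current density (mA cm^-2): mu * gbar * x * (V - E_rev)."""
    if spec.conduction != "ohmic":
        raise TypeError(f"{spec.name} is not an ohmic channel")
    gbar = spec.density.get("all", 0.0) if gbar_S_cm2 is None else gbar_S_cm2
    x = spec.open_fraction(state)
    # S/cm2 * mV = mA/cm2
    return mu * gbar * x * (np.asarray(V_mV, float) - spec.erev_mV)


def ghk_driving(V_mV, Ca_i_uM, Ca_o_mM, T_K: float = 303.15):
    """The GHK flux factor 4F^2 V/(RT) * (ci - co e^-u)/(1 - e^-u).

    Concentrations converted to mol cm^-3; returns A s cm^-1 per unit
    permeability, i.e. multiply by P (cm/s) for A cm^-2.  The removable
    singularity at V = 0 is handled with a first-order series expansion.
    """
    V = np.asarray(V_mV, dtype=float) * 1e-3  # volts
    ci = np.asarray(Ca_i_uM, dtype=float) * 1e-9   # mol/cm3
    co = np.asarray(Ca_o_mM, dtype=float) * 1e-6   # mol/cm3
    F, R = FARADAY_C_PER_MOL, GAS_CONSTANT_J_PER_MOL_K
    u = 2.0 * F * V / (R * T_K)
    small = np.abs(u) < GHK_SERIES_THRESHOLD
    u_safe = np.where(small, 1.0, u)
    exact = u_safe * (ci - co * np.exp(-u_safe)) / (1.0 - np.exp(-u_safe))
    series = (ci - co) + u * (ci + co) / 2.0
    return 2.0 * F * np.where(small, series, exact)


def ghk_current(pbar_cm_s, x, V_mV, Ca_i_uM, Ca_o_mM=5.0, T_K: float = 303.15,
                mu: float = 1.0):
    """GHK calcium current density (mA cm^-2) with P = mu * pbar * x.

    Negative (inward) at physiological potentials whenever intracellular
    calcium is far below extracellular.
    """
    if np.any(np.asarray(Ca_o_mM) <= 0) or T_K <= 0:
        raise ValueError("Ca_o and T must be positive")
    P = mu * np.asarray(pbar_cm_s, float) * np.asarray(x, float)
    return P * ghk_driving(V_mV, Ca_i_uM, Ca_o_mM, T_K) * 1e3  # A->mA


def total_channel_current(
    specs: dict[str, ChannelSpec],
    states: dict[str, dict[str, float]],
    V_mV,
    Ca_i_uM,
    mu: dict[str, float] | None = None,
    region: str = "all",
    Ca_o_mM: float = 5.0,
    T_K: float = 303.15,
) -> dict[str, float]:
    """Family subtotals I_NaChan, I_KChan, I_CaChan (mA cm^-2).

    Every channel type must appear in ``specs`` (zero density is fine);
    unknown names raise.  ``mu`` maps channel name -> dopamine modulation
    factor (missing names default to 1).
    """
    mu = mu or {}
    for name in specs:
        if name not in CHANNEL_NAMES:
            raise ChannelConfigError(f"unknown channel: {name!r}")
    missing = set(CHANNEL_NAMES) - set(specs)
    if missing:
        raise ChannelConfigError(f"channels absent and not zeroed: {sorted(missing)}")
    out = {"I_NaChan": 0.0, "I_KChan": 0.0, "I_CaChan": 0.0}
    for name, spec in specs.items():
        m = mu.get(name, 1.0)
        dens = spec.density.get(region, spec.density.get("all", 0.0))
        if spec.conduction == "ohmic":
            i = ohmic_current(spec, states[name], V_mV, m, gbar_S_cm2=dens)
        else:
            x = spec.open_fraction(states[name])
            i = ghk_current(dens, x, V_mV, Ca_i_uM, Ca_o_mM, T_K, m)
        if name in NA_CHANNELS:
            out["I_NaChan"] += i
        elif name in K_CHANNELS:
            out["I_KChan"] += i
        else:
            out["I_CaChan"] += i
    return out
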