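"""Intracellular calcium dynamics with endoplasmic-reticulum exchange.

Per-compartment cytosolic calcium follows a signed flux balance:
ryanodine-receptor CICR and IP3-receptor release from the ER, SERCA uptake
into the ER, a passive ER leak, the membrane calcium current term, a
saturable extrusion pump, and a first-order diffusion/buffering relaxation
toward a resting level.  IP3 is produced after glutamate (an alpha-function
of the time since the last event, peaking at tau_IP3) and removed toward a
basal level.  ER calcium is held constant; explicit buffer species are not
modeled.

Units: concentrations in uM (ER store in mM in the parameter set, converted
here), fluxes in uM/ms, time in ms, membrane currents in nA, volumes in um^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .channels import FARADAY_C_PER_MOL

__all__ = [
    "CalciumParams",
    "CalciumPool",
    "FluxSet",
    "cicr_flux",
    "ip3r_gates",
    "ip3_production_rate",
    "ip3_step",
    "er_exchange_fluxes",
    "membrane_ca_flux",
    "pump_flux",
    "diffusion_flux",
    "total_flux",
    "calcium_step",
]

#: nA -> uM/ms conversion: 1e9 / (2 F) per um^3 of compartment volume
_CURRENT_TO_FLUX = 1e9 / (2.0 * FARADAY_C_PER_MOL)

CA_FLOOR_UM = 1e-6


@dataclass(frozen=True)
class CalciumParams:
    """Rate constants of the calcium balance (working per-ms scales)."""

    Ca_ER_mM: float = 0.20
    Ca_inf_uM: float = 0.01
    tau_diff_ms: float = 43.0
    V_CICR_per_ms: float = 3.0e-5
    K_CICR_uM: float = 0.2
    V_IP3_per_ms: float = 1.5e-3
    d_IP3_uM: float = 0.13
    d_act_uM: float = 0.082
    d_inh_uM: float = 1.05
    d_dis_uM: float = 0.94
    gamma_IP3_uM_per_ms2: float = 5.0e-3
    beta_IP3_per_ms: float = 0.2
    tau_IP3_ms: float = 220.0
    IP3_min_uM: float = 0.24
    V_uptake_uM_per_ms: float = 0.03
    K_uptake_uM: float = 0.2
    V_leak_per_ms: float = 1.35e-5
    V_pump_uM_per_ms: float = 0.02
    K_pump_uM: float = 0.1

    @property
    def Ca_ER_uM(self) -> float:
        return self.Ca_ER_mM * 1e3


@dataclass
class CalciumPool:
    """State of one compartment's calcium machinery."""

    Ca_i_uM: float = 0.01
    IP3_uM: float = 0.24
    t_glu_ms: float = math.inf      # time since last glutamate event
    volume_um3: float = 1.0

    def __post_init__(self) -> None:
        if self.Ca_i_uM <= 0 or self.volume_um3 <= 0:
            raise ValueError("Ca and volume must be positive")


@dataclass(frozen=True)
class FluxSet:
    """Signed flux components (uM/ms) of the calcium balance."""

    J_CICR: float = 0.0
    J_IP3: float = 0.0
    J_uptake: float = 0.0
    J_leak: float = 0.0
    J_cur: float = 0.0
    J_pump: float = 0.0
    J_diff: float = 0.0

    @property
    def net(self):
        return (self.J_CICR + self.J_IP3 - self.J_uptake + self.J_leak
                + self.J_cur - self.J_pump + self.J_diff)


def cicr_flux(Ca_i_uM, params: CalciumParams):
    """Ryanodine-receptor calcium-induced calcium release (uM/ms)."""
    ca = np.asarray(Ca_i_uM, dtype=float)
    return (params.V_CICR_per_ms * ca / (ca + params.K_CICR_uM)
            * (params.Ca_ER_uM - ca))


def ip3r_gates(IP3_uM, Ca_i_uM, params: CalciumParams):
    """IP3-receptor activation (m) and inactivation (h) gates, each in [0,1].

    m rises with IP3 and with calcium; h falls as calcium rises.  The
    product m^3 h^3 times the store gradient gives the bell-shaped release
    curve peaking near 0.2 uM cytosolic calcium.
    """
    ip3 = np.asarray(IP3_uM, dtype=float)
    ca = np.asarray(Ca_i_uM, dtype=float)
    m = (ip3 / (ip3 + params.d_IP3_uM)) * (ca / (ca + params.d_act_uM))
    num = params.d_inh_uM * (ip3 + params.d_IP3_uM)
    h = num / (num + ca * (ip3 + params.d_dis_uM))
    return m, h


def ip3_production_rate(t_glu_ms, params: CalciumParams):
    """IP3 production (uM/ms): alpha-function of time since glutamate.

    gamma * t * exp(-t/tau_IP3); zero when no glutamate has occurred.
    """
    t = np.asarray(t_glu_ms, dtype=float)
    rate = np.where(
        np.isfinite(t) & (t >= 0),
        params.gamma_IP3_uM_per_ms2 * np.where(np.isfinite(t), t, 0.0)
        * np.exp(-np.where(np.isfinite(t), t, 0.0) / params.tau_IP3_ms),
        0.0,
    )
    return rate


def ip3_step(IP3_uM, t_glu_ms, dt_ms: float, params: CalciumParams):
    """Advance intracellular IP3 by dt: production minus first-order removal.

    Removal is integrated exactly (exponential relaxation toward IP3_min);
    production explicitly.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    ip3 = np.asarray(IP3_uM, dtype=float)
    prod = ip3_production_rate(t_glu_ms, params)
    decay = math.exp(-params.beta_IP3_per_ms * dt_ms)
    return (params.IP3_min_uM + (ip3 - params.IP3_min_uM) * decay
            + prod * dt_ms)


def er_exchange_fluxes(pool: CalciumPool | None, params: CalciumParams,
                       Ca_i_uM=None, IP3_uM=None) -> dict:
    """IP3R release, SERCA uptake and passive leak fluxes (uM/ms)."""
    ca = np.asarray(pool.Ca_i_uM if pool is not None else Ca_i_uM, float)
    ip3 = np.asarray(pool.IP3_uM if pool is not None else IP3_uM, float)
    m, h = ip3r_gates(ip3, ca, params)
    grad = params.Ca_ER_uM - ca
    return {
        "J_IP3": params.V_IP3_per_ms * m ** 3 * h ** 3 * grad,
        "J_uptake": (params.V_uptake_uM_per_ms * ca ** 2
                     / (params.K_uptake_uM ** 2 + ca ** 2)),
        "J_leak": params.V_leak_per_ms * grad,
    }


def membrane_ca_flux(I_CaChan_nA, I_syn_ca_nA, volume_um3):
    """Membrane calcium flux J_cur (uM/ms) from currents in nA.

    J = -(I_CaChan + c_AMPA I_AMPA + c_NMDA I_NMDA) / (2 F v): an inward
    (negative) calcium current raises cytosolic calcium.  A 1 pA pure-calcium
    current into 1 um^3 gives about 5.18 uM/ms.
    """
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    total = np.asarray(I_CaChan_nA, float) + np.asarray(I_syn_ca_nA, float)
    return -total * _CURRENT_TO_FLUX / v


def pump_flux(Ca_i_uM, params: CalciumParams):
    """Michaelis-Menten extrusion pump (uM/ms), saturating at V_pump."""
    ca = np.asarray(Ca_i_uM, dtype=float)
    return params.V_pump_uM_per_ms * ca / (ca + params.K_pump_uM)


def diffusion_flux(Ca_i_uM, params: CalciumParams):
    """Diffusion/buffering relaxation toward the resting level (uM/ms)."""
    return (params.Ca_inf_uM - np.asarray(Ca_i_uM, float)) / params.tau_diff_ms


def total_flux(pool: CalciumPool, params: CalciumParams,
               I_CaChan_nA=0.0, I_syn_ca_nA=0.0) -> FluxSet:
    """Evaluate every flux component at the pool's current state."""
    er = er_exchange_fluxes(pool, params)
    return FluxSet(
        J_CICR=float(cicr_flux(pool.Ca_i_uM, params)),
        J_IP3=float(er["J_IP3"]),
        J_uptake=float(er["J_uptake"]),
        J_leak=float(er["J_leak"]),
        J_cur=float(membrane_ca_flux(I_CaChan_nA, I_syn_ca_nA, pool.volume_um3)),
        J_pump=float(pump_flux(pool.Ca_i_uM, params)),
        J_diff=float(diffusion_flux(pool.Ca_i_uM, params)),
    )


def calcium_step(pool: CalciumPool, fluxes: FluxSet, dt_ms: float) -> CalciumPool:
    """Advance cytosolic calcium by the signed flux sum over dt.

    The diffusion/relaxation term is included in ``fluxes``; calcium is
    floored at a tiny positive epsilon.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    ca = max(pool.Ca_i_uM + dt_ms * fluxes.net, CA_FLOOR_UM)
    return replace(pool, Ca_i_uM=float(ca))
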