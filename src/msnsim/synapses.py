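"""AMPAR and NMDAR synaptic conductances and currents.

Each glutamate event launches a normalized dual-exponential conductance
(peak equals the receptor's maximal conductance); events superpose linearly.
The NMDAR additionally carries the standard voltage-dependent magnesium
block, relieved by depolarization.  Both receptors reverse at 0 mV; their
calcium-carrying fractions (c_AMPA, c_NMDA) feed the spine calcium balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReceptorSpec",
    "SynapticEvent",
    "receptor_conductance",
    "nmda_block",
    "synaptic_current",
    "synaptic_ca_current",
]


@dataclass(frozen=True)
class ReceptorSpec:
    name: str                       # AMPA | NMDA
    gbar_pS: float
    tau_rise_ms: float
    tau_decay_ms: float
    erev_mV: float = 0.0
    ca_fraction: float = 0.0        # c_z: share of current carried by Ca2+
    mg_K0_mM: float = 3.57
    mg_slope_per_mV: float = 0.062
    has_mg_block: bool = False

    def __post_init__(self) -> None:
        if not (self.tau_decay_ms > self.tau_rise_ms > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.gbar_pS < 0 or not 0 <= self.ca_fraction <= 1:
            raise ValueError("gbar must be >= 0 and 0 <= ca_fraction <= 1")

    @property
    def peak_time_ms(self) -> float:
        """Analytic time-to-peak of the dual exponential."""
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def norm(self) -> float:
        """Peak value of exp(-t/tau_d) - exp(-t/tau_r) (normalization)."""
        tp = self.peak_time_ms
        return math.exp(-tp / self.tau_decay_ms) - math.exp(-tp / self.tau_rise_ms)


@dataclass(frozen=True)
class SynapticEvent:
    spine: int          # target spine compartment id
    onset_ms: float
    kind: str = "glutamate"

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise ValueError("event onset must be >= 0")


def receptor_conductance(spec: ReceptorSpec, event_times_ms, t_ms):
    """Conductance (pS) at time ``t_ms`` from past glutamate events.

    Zero before the first event; a single event peaks at exactly
    ``spec.gbar_pS``; multiple events superpose linearly.
    """
    t = np.asarray(t_ms, dtype=float)
    g = np.zeros_like(t)
    for t0 in np.atleast_1d(np.asarray(event_times_ms, dtype=float)):
        dt = t - t0
        active = dt >= 0
        g = g + np.where(
            active,
            (np.exp(-np.maximum(dt, 0.0) / spec.tau_decay_ms)
             - np.exp(-np.maximum(dt, 0.0) / spec.tau_rise_ms)) / spec.norm,
            0.0,
        )
    return spec.gbar_pS * g


def nmda_block(V_mV, mg_mM: float = 1.0, K0_mM: float = 3.57,
               slope_per_mV: float = 0.062):
    """Fraction of NMDAR conductance not blocked by magnesium, in [0, 1].

    Sigmoidal relief with depolarization; magnesium-free (mg = 0) gives 1 at
    any voltage.
    """
    if mg_mM < 0:
        raise ValueError("mg must be >= 0")
    V = np.asarray(V_mV, dtype=float)
    return 1.0 / (1.0 + (mg_mM / K0_mM) * np.exp(-slope_per_mV * V))


def synaptic_current(
    specs: dict[str, ReceptorSpec],
    event_times_ms,
    V_mV,
    t_ms,
    mu_AMPA: float = 1.0,
    mu_NMDA: float = 1.0,
    mg_mM: float = 1.0,
) -> dict[str, float]:
    """Synaptic currents (nA) at one site: I_AMPA, I_NMDA and their sum.

    I_z = g_z(t) * block_z(V) * (V - E_rev); only the NMDA term carries the
    magnesium block and only it is dopamine-modulated in the default model
    (mu_AMPA stays 1).  Components are returned separately because their
    calcium-carrying fractions differ.
    """
    V = np.asarray(V_mV, dtype=float)
    out: dict[str, float] = {}
    for name, mu in (("AMPA", mu_AMPA), ("NMDA", mu_NMDA)):
        spec = specs[name]
        g_pS = receptor_conductance(spec, event_times_ms, t_ms)
        block = nmda_block(V, mg_mM, spec.mg_K0_mM, spec.mg_slope_per_mV) \
            if spec.has_mg_block else 1.0
        # pS * mV = 1e-12 S * 1e-3 V = 1e-15 A = 1e-6 nA
        out[f"I_{name}"] = mu * g_pS * block * (V - spec.erev_mV) * 1e-6
    out["I_syn"] = out["I_AMPA"] + out["I_NMDA"]
    return out


def synaptic_ca_current(I_AMPA, I_NMDA, c_AMPA: float = 0.0005,
                        c_NMDA: float = 0.01):
    """Calcium-carrying part of the synaptic current: c_A*I_A + c_N*I_N."""
    return c_AMPA * np.asarray(I_AMPA, float) + c_NMDA * np.asarray(I_NMDA, float)
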