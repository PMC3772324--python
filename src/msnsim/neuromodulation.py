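"""Time-varying dopamine modulation of channel and receptor magnitudes.

A dopamine event launches a transient modulation factor mu_z(t) for each
target: rising from 1 toward its peak level over ~t_peak and decaying back
to 1 with tau_dec.  Targets with mu_peak > 1 (KIR, Cav1.2, NMDA) are
enhanced; those with mu_peak < 1 (NaF, CaN, CaQ) are reduced.  Dopamine
also shifts the activation half-voltage of Cav1.3 with the same temporal
profile.  The factors apply globally (all compartments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModulationSchedule", "modulation_factor", "unit_profile",
           "DEFAULT_MU_PEAK", "MODULATION_TARGETS", "ModulationConfigError"]

MODULATION_TARGETS = ("NaF", "KIR", "Cav1.2", "CaN", "CaQ", "NMDA")

DEFAULT_MU_PEAK = {
    "NaF": 0.95, "KIR": 1.25, "Cav1.2": 2.0, "CaN": 0.2, "CaQ": 0.5,
    "NMDA": 1.3,
}


class ModulationConfigError(ValueError):
    """Unknown modulation target."""


def modulation_factor(mu_peak: float, t_hat_ms, t_peak_ms: float = 60.0,
                      tau_inc_ms: float = 30.0, tau_dec_ms: float = 100.0,
                      continuous: bool = False):
    """Dopamine modulation factor at ``t_hat_ms`` after the last DA event.

    Piecewise transient: for t < t_peak the factor relaxes from 1 toward
    mu_peak with tau_inc; from t_peak on it decays from mu_peak back to 1
    with tau_dec.  ``t_hat = inf`` (no dopamine yet) gives exactly 1.

    The rising branch as published does not quite reach mu_peak at t_peak
    (it is discontinuous there); the default reproduces that form verbatim.
    ``continuous=True`` rescales the rising branch to land exactly on
    mu_peak at t_peak.
    """
    t = np.asarray(t_hat_ms, dtype=float)
    if np.any(t[np.isfinite(t)] < 0):
        raise ValueError("t_hat must be >= 0")
    if continuous:
        denom = 1.0 - math.exp(-t_peak_ms / tau_inc_ms)
        rising = 1.0 + (mu_peak - 1.0) * (1.0 - np.exp(-t / tau_inc_ms)) / denom
    else:
        rising = mu_peak + (1.0 - mu_peak) * np.exp(-t / tau_inc_ms)
    falling = 1.0 + (mu_peak - 1.0) * np.exp(-(t - t_peak_ms) / tau_dec_ms)
    out = np.where(t < t_peak_ms, rising, falling)
    return np.where(np.isfinite(t), out, 1.0)


def unit_profile(t_hat_ms, t_peak_ms: float = 60.0, tau_inc_ms: float = 30.0,
                 tau_dec_ms: float = 100.0, continuous: bool = False):
    """The mu transient mapped onto [0, 1] (0 at rest, 1 at full peak).

    Used for effects expressed as additive shifts rather than multiplicative
    factors (the Cav1.3 activation-voltage shift).
    """
    return modulation_factor(2.0, t_hat_ms, t_peak_ms, tau_inc_ms, tau_dec_ms,
                             continuous) - 1.0


@dataclass
class ModulationSchedule:
    """Dopamine event times plus per-target transient parameters."""

    event_times_ms: list[float] = field(default_factory=list)
    mu_peak: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MU_PEAK))
    t_peak_ms: float = 60.0
    tau_inc_ms: float = 30.0
    tau_dec_ms: float = 100.0
    cav13_shift_mV: float = -8.0
    continuous: bool = False

    def __post_init__(self) -> None:
        for z, mp in self.mu_peak.items():
            if z not in MODULATION_TARGETS:
                raise ModulationConfigError(f"unknown modulation target: {z!r}")
            if mp <= 0:
                raise ModulationConfigError("mu_peak must be positive")

    def t_hat(self, t_ms):
        """Time since the most recent dopamine event at or before ``t_ms``."""
        t = np.asarray(t_ms, dtype=float)
        out = np.full_like(t, np.inf)
        for ev in sorted(self.event_times_ms):
            out = np.where(t >= ev, t - ev, out)
        return out

    def factor(self, target: str, t_ms):
        """mu_z at absolute time ``t_ms`` (1 before any dopamine event)."""
        if target not in MODULATION_TARGETS:
            raise ModulationConfigError(f"unknown modulation target: {target!r}")
        return modulation_factor(
            self.mu_peak.get(target, 1.0), self.t_hat(t_ms),
            self.t_peak_ms, self.tau_inc_ms, self.tau_dec_ms, self.continuous,
        )

    def factors(self, t_ms) -> dict[str, float]:
        return {z: self.factor(z, t_ms) for z in MODULATION_TARGETS}

    def cav13_shift(self, t_ms):
        """Time-varying shift (mV) of the Cav1.3 activation half-voltage."""
        return self.cav13_shift_mV * unit_profile(
            self.t_hat(t_ms), self.t_peak_ms, self.tau_inc_ms,
            self.tau_dec_ms, self.continuous,
        )


def apply_modulation(gbar_or_pbar: dict[str, float], mu: dict[str, float]) -> dict[str, float]:
    """Scale the modulated targets' magnitudes; other entries untouched."""
    out = dict(gbar_or_pbar)
    for z, m in mu.items():
        if z not in MODULATION_TARGETS:
            raise ModulationConfigError(f"unknown modulation target: {z!r}")
        if z in out:
            out[z] = out[z] * m
    return out
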