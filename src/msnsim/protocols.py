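"""Named in-silico experiments: current steps, bAPs, glutamate inputs,
paired and triplet timing scans, and the leaky-integrator plasticity proxy.

Timing conventions: dt_glu > 0 means glutamate precedes the postsynaptic
spike (Post); dt_da > 0 means dopamine precedes Post.  The up-state is
emulated by a steady 0.2 nA somatic current, the down-state by none.  Post
is a 2 ms suprathreshold somatic step whose amplitude is auto-calibrated to
the smallest multiple of 0.1 nA that fires the resting (down-state) soma.

All scans exploit the engine's batch axis: every grid cell is one batch
element of a single vectorized run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import Engine, Model

__all__ = [
    "TimingScanSpec", "ScanResult", "calibrate_post_amplitude",
    "current_step_protocol", "bap_protocol", "glutamate_protocol",
    "paired_scan", "triplet_scan", "leaky_integrator",
    "UP_STATE_NA", "POST_WIDTH_MS",
]

UP_STATE_NA = 0.2
POST_WIDTH_MS = 2.0
DEFAULT_GRID = tuple(range(-100, 101, 10))

PROXIMAL, DISTAL = 0, 1  # spine indices (25 um and 100 um sites)


@dataclass
class TimingScanSpec:
    """Grid specification for paired/triplet timing scans."""

    dt_glu_ms: tuple = DEFAULT_GRID      # positive = Glu before Post
    dt_da_ms: tuple = DEFAULT_GRID       # positive = DA before Post
    state: str = "up"                    # "up" | "down"
    spine: int = PROXIMAL
    blockades: dict[str, float] = field(default_factory=dict)
    summary: str = "peak_Ca"             # "peak_Ca" | "peak_integrator"
    mu_peak_override: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.state not in ("up", "down"):
            raise ValueError("state must be 'up' or 'down'")
        if not len(self.dt_glu_ms) or not len(self.dt_da_ms):
            raise ValueError("timing grids must be nonempty")


@dataclass
class ScanResult:
    """Summary maps over (dt_da, dt_glu)."""

    dt_glu_ms: np.ndarray
    dt_da_ms: np.ndarray
    peak_Ca_uM: np.ndarray               # (n_da, n_glu)
    peak_x: np.ndarray | None = None     # leaky-integrator peaks, same shape

    def argmax(self, which: str = "peak_Ca") -> tuple[float, float]:
        """(dt_da, dt_glu) at the maximum of the chosen summary map."""
        m = self.peak_Ca_uM if which == "peak_Ca" else self.peak_x
        i, j = np.unravel_index(np.argmax(m), m.shape)
        return float(self.dt_da_ms[i]), float(self.dt_glu_ms[j])

    def to_frame(self):
        import pandas as pd
        da, glu = np.meshgrid(self.dt_da_ms, self.dt_glu_ms, indexing="ij")
        out = pd.DataFrame({
            "dt_da_ms": da.ravel(), "dt_glu_ms": glu.ravel(),
            "peak_Ca_uM": self.peak_Ca_uM.ravel(),
        })
        if self.peak_x is not None:
            out["peak_x"] = self.peak_x.ravel()
        return out


def _steady(state: str) -> float:
    return UP_STATE_NA if state == "up" else 0.0


def calibrate_post_amplitude(
    model: Model, state: str = "down", width_ms: float = POST_WIDTH_MS,
    dt_ms: float = 0.025, settle_ms: float = 500.0, max_nA: float = 5.0,
    margin_nA: float = 0.3,
) -> float:
    """Spike-evoking somatic step amplitude for the Post stimulus.

    The smallest multiple of 0.1 nA whose ``width_ms`` somatic step fires a
    spike (somatic voltage crossing 0 mV), plus a fixed suprathreshold
    margin so that the pulse stays suprathreshold when dopamine transiently
    reduces NaF and enhances KIR.
    """
    amps = np.arange(0.1, max_nA + 1e-9, 0.1)
    eng = Engine(model, dt_ms=dt_ms, batch=1)
    eng.add_step_current(0, _steady(state), 0.0, np.inf)
    eng.run(settle_ms)
    eng.tile(len(amps))
    eng.add_step_current(0, amps, eng.t, width_ms)
    rec = eng.run(40.0, record_every=2)
    spiking = (rec.V_mV[:, :, 0] > 0.0).any(axis=0)
    if not spiking.any():
        raise RuntimeError("no amplitude up to max_nA elicited a spike")
    return float(amps[int(np.argmax(spiking))]) + margin_nA


def current_step_protocol(
    model: Model, amplitudes_nA, width_ms: float = 500.0,
    blockades: dict[str, float] | None = None, dt_ms: float = 0.025,
    settle_ms: float = 500.0, tail_ms: float = 100.0,
):
    """Somatic step-current family; returns recording + per-step summaries.

    Summaries: spike count (upward 0 mV crossings) and steady-state voltage
    deflection for each amplitude.
    """
    amps = np.asarray(amplitudes_nA, dtype=float)
    eng = Engine(model, dt_ms=dt_ms, batch=1, blockades=blockades)
    eng.run(settle_ms)
    v_rest = float(eng.V[0, 0])
    eng.tile(len(amps))
    eng.add_step_current(0, amps, eng.t, width_ms)
    rec = eng.run(width_ms + tail_ms, record_every=max(1, int(0.1 / dt_ms)))
    v = rec.V_mV[:, :, 0]
    crossings = ((v[:-1] < 0.0) & (v[1:] >= 0.0)).sum(axis=0)
    in_step = rec.time_ms - rec.time_ms[0] <= width_ms
    v_end = v[in_step][-max(1, int(50 / 0.1)):].mean(axis=0)
    return {
        "recording": rec,
        "amplitudes_nA": amps,
        "v_rest_mV": v_rest,
        "spike_count": crossings,
        "deflection_mV": v_end - v_rest,
        "ca_soma_peak_uM": rec.Ca_uM[:, :, 0].max(axis=0),
    }


def bap_protocol(
    model: Model, pulse_width_ms: float = 2.0,
    blockades: dict[str, float] | None = None, dt_ms: float = 0.05,
    settle_ms: float = 500.0, post_amp_nA: float | None = None,
    follow_ms: float = 1000.0,
):
    """Back-propagating action potential into the spines, up vs down state.

    One batched run: cells = (down, up).  The pulse amplitude is the
    standard Post amplitude (calibrated for the 2 ms pulse) regardless of
    ``pulse_width_ms``, so wide-pulse variants change only the duration.
    Returns spine voltage/calcium peaks per state and the full recording.
    """
    if post_amp_nA is None:
        post_amp_nA = calibrate_post_amplitude(
            model, "down", POST_WIDTH_MS, dt_ms, settle_ms)
    eng = Engine(model, dt_ms=dt_ms, batch=2, blockades=blockades)
    eng.add_step_current(0, np.array([0.0, UP_STATE_NA]), 0.0, np.inf)
    eng.run(settle_ms)
    t0 = eng.t
    eng.add_step_current(0, post_amp_nA, t0, pulse_width_ms)
    eng.set_peak_window(t0 - 50.0, t0 + follow_ms)
    rec = eng.run(follow_ms + 50.0, record_every=max(1, int(0.1 / dt_ms)),
                  record_sources=True)
    sites = rec.site_names
    peaks = eng.peak_Ca()
    vpeak = rec.V_mV.max(axis=0)
    out = {"recording": rec, "post_amp_nA": post_amp_nA, "sites": sites}
    for b, state in enumerate(("down", "up")):
        out[state] = {
            "V_peak_mV": dict(zip(sites, vpeak[b])),
            "Ca_peak_uM": dict(zip(sites, peaks[b])),
        }
    return out


_RECEPTOR_CONDITIONS = {
    # (blockades, mg_mM override or None)
    "intact": ({}, None),
    # AMPAR-mediated response isolated: sodium, calcium and NMDAR currents
    # zeroed, magnesium-free bath
    "AMPAR_only_mgfree": ({"NaF": 0.0, "NaP": 0.0, "CaN": 0.0, "CaQ": 0.0,
                           "CaR": 0.0, "CaT": 0.0, "Cav1.2": 0.0,
                           "Cav1.3": 0.0, "NMDA": 0.0}, 0.0),
    # NMDAR-mediated response isolated: sodium, calcium and AMPAR currents
    # zeroed
    "NMDAR_only": ({"NaF": 0.0, "NaP": 0.0, "CaN": 0.0, "CaQ": 0.0,
                    "CaR": 0.0, "CaT": 0.0, "Cav1.2": 0.0, "Cav1.3": 0.0,
                    "AMPA": 0.0}, None),
}


def glutamate_protocol(
    model: Model, receptor_condition: str = "intact", dt_ms: float = 0.05,
    settle_ms: float = 500.0, follow_ms: float = 1000.0,
):
    """Single glutamate input onto each spine, up vs down state.

    One batched run with cells = (state x spine); the input lands on the
    spine in which the response is measured.  Returns EPSP and calcium peaks.
    """
    try:
        blockades, mg = _RECEPTOR_CONDITIONS[receptor_condition]
    except KeyError:
        raise ValueError(f"unknown receptor condition: {receptor_condition!r}")
    eng = Engine(model, dt_ms=dt_ms, batch=4, blockades=blockades, mg_mM=mg)
    # cells: 0 = down/prox, 1 = down/dist, 2 = up/prox, 3 = up/dist
    eng.add_step_current(0, np.array([0.0, 0.0, UP_STATE_NA, UP_STATE_NA]),
                         0.0, np.inf)
    eng.run(settle_ms)
    t0 = eng.t
    inf = np.inf
    eng.add_glutamate(PROXIMAL, np.array([t0, inf, t0, inf]))
    eng.add_glutamate(DISTAL, np.array([inf, t0, inf, t0]))
    eng.set_peak_window(t0 - 50.0, t0 + follow_ms)
    rec = eng.run(follow_ms + 50.0, record_every=max(1, int(0.1 / dt_ms)),
                  record_sources=True)
    sites = rec.site_names
    spine_site = {PROXIMAL: sites[1], DISTAL: sites[2]}
    peaks = eng.peak_Ca()
    out = {"recording": rec, "condition": receptor_condition}
    base_v = rec.V_mV[0]
    for b, (state, spine) in enumerate(
            (("down", PROXIMAL), ("down", DISTAL),
             ("up", PROXIMAL), ("up", DISTAL))):
        s = rec.site_index(spine_site[spine])
        out[(state, spine)] = {
            "epsp_mV": float(rec.V_mV[:, b, s].max() - base_v[b, s]),
            "Ca_peak_uM": float(peaks[b, s]),
        }
    return out


def _timing_scan(model: Model, spec: TimingScanSpec, include_glu: bool,
                 include_da: bool, dt_ms: float, settle_ms: float,
                 post_amp_nA: float | None, follow_ms: float,
                 integrator: tuple[float, float]) -> ScanResult:
    glu_grid = np.asarray(spec.dt_glu_ms, float) if include_glu else np.array([0.0])
    da_grid = np.asarray(spec.dt_da_ms, float) if include_da else np.array([0.0])
    da, glu = np.meshgrid(da_grid, glu_grid, indexing="ij")
    B = da.size
    if post_amp_nA is None:
        post_amp_nA = calibrate_post_amplitude(
            model, "down", POST_WIDTH_MS, dt_ms, settle_ms)
    eng = Engine(model, dt_ms=dt_ms, batch=1, blockades=spec.blockades,
                 mu_peak_override=spec.mu_peak_override)
    eng.add_step_current(0, _steady(spec.state), 0.0, np.inf)
    eng.run(settle_ms)
    eng.tile(B)
    margin = float(max(np.max(np.abs(glu_grid)), np.max(np.abs(da_grid)))) + 50.0
    t_post = eng.t + margin
    eng.add_step_current(0, post_amp_nA, t_post, POST_WIDTH_MS)
    if include_glu:
        eng.add_glutamate(spec.spine, t_post - glu.ravel())
    if include_da:
        eng.add_dopamine(t_post - da.ravel())
    eng.set_peak_window(t_post - margin - 40.0, t_post + follow_ms)
    eng.run(margin + follow_ms + 10.0, integrator=integrator)
    site = 1 + spec.spine  # sites: soma, proximal spine, distal spine
    peaks = eng.peak_Ca()[:, site].reshape(da.shape)
    xpeaks = eng.peak_integrator[:, site].reshape(da.shape)
    return ScanResult(dt_glu_ms=glu_grid, dt_da_ms=da_grid,
                      peak_Ca_uM=peaks, peak_x=xpeaks)


def paired_scan(
    model: Model, spec: TimingScanSpec, input_type: str = "glu",
    dt_ms: float = 0.05, settle_ms: float = 500.0,
    post_amp_nA: float | None = None, follow_ms: float = 1000.0,
    integrator: tuple[float, float] = (600.0, 20.0),
) -> ScanResult:
    """Peak spine calcium vs the timing of a single paired input and Post.

    ``input_type`` 'glu' scans dt_glu (no dopamine); 'da' scans dt_da (no
    glutamate).
    """
    if input_type not in ("glu", "da"):
        raise ValueError("input_type must be 'glu' or 'da'")
    return _timing_scan(model, spec, include_glu=input_type == "glu",
                        include_da=input_type == "da", dt_ms=dt_ms,
                        settle_ms=settle_ms, post_amp_nA=post_amp_nA,
                        follow_ms=follow_ms, integrator=integrator)


def triplet_scan(
    model: Model, spec: TimingScanSpec, dt_ms: float = 0.05,
    settle_ms: float = 500.0, post_amp_nA: float | None = None,
    follow_ms: float = 1000.0, integrator: tuple[float, float] = (600.0, 20.0),
) -> ScanResult:
    """Full (dt_da, dt_glu) peak-calcium map for Glu + DA + Post triplets."""
    return _timing_scan(model, spec, include_glu=True, include_da=True,
                        dt_ms=dt_ms, settle_ms=settle_ms,
                        post_amp_nA=post_amp_nA, follow_ms=follow_ms,
                        integrator=integrator)


def leaky_integrator(ca_trace_uM, dt_ms: float, tau_ms: float = 600.0,
                     a: float = 20.0, x0: float = 0.0):
    """First-order leaky integration of a calcium trace: tau x' = -x + a*Ca.

    Returns the x trace and its peak.  For constant calcium c the fixed
    point is a*c.
    """
    if tau_ms <= 0:
        raise ValueError("tau must be positive")
    ca = np.asarray(ca_trace_uM, dtype=float)
    f = math.exp(-dt_ms / tau_ms)
    x = np.empty_like(ca)
    prev = x0
    for i, c in enumerate(ca):
        prev = prev * f + a * c * (1.0 - f)
        x[i] = prev
    return x, float(x.max())
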