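"""Coupled time-stepping of membrane potential, gating, synapses and calcium.

The cable equation over the branched compartment graph is advanced with a
semi-implicit (backward-Euler) scheme: ohmic channel and synaptic terms enter
the linear system as conductances frozen at the current gate values, axial
coupling is solved exactly with a single Hines-style tree sweep per step, and
the nonlinear GHK calcium currents enter as explicit sources.  Gates use
exact exponential relaxation via precomputed voltage tables; calcium and IP3
advance by operator splitting within the same step.

The engine state carries a leading *batch* axis: a batch of B simulations
that share the morphology and parameters but may differ in stimulus timing
and amplitude runs vectorized in lock-step.  Timing scans and paired
up/down-state comparisons are single engine runs with B > 1.  The model is
fully deterministic: identical configurations produce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import morphology as morph
from .channels import (
    CHANNEL_NAMES, FARADAY_C_PER_MOL, GAS_CONSTANT_J_PER_MOL_K,
    ChannelConfigError, ChannelSpec,
)
from .calcium_er import CalciumParams, _CURRENT_TO_FLUX, CA_FLOOR_UM
from .kinetics import load_kinetics
from .neuromodulation import ModulationSchedule, modulation_factor, unit_profile
from .synapses import ReceptorSpec

__all__ = ["Model", "Engine", "Recording", "SimConfig", "IntegrationError",
           "run_simulation", "decompose_calcium_sources", "CALCIUM_SOURCES"]

CALCIUM_SOURCES = (
    "AMPA", "NMDA", "CaN", "CaQ", "CaR", "CaT", "Cav1.2", "Cav1.3",
    "ER", "diffusion",
)


class IntegrationError(RuntimeError):
    """Non-finite state encountered while stepping."""


@dataclass
class SimConfig:
    """Solver-level settings for one simulation run."""

    dt_ms: float = 0.025
    duration_ms: float = 1000.0
    settle_ms: float = 500.0
    record_every: int = 4
    record_sources: bool = True

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if self.duration_ms < 0:
            raise ValueError("duration must be >= 0")


@dataclass
class Model:
    """Morphology plus all biophysical parameters, ready to simulate."""

    graph: morph.CompartmentGraph
    channels: dict[str, ChannelSpec]
    receptors: dict[str, ReceptorSpec]
    densities: dict[str, object]
    ca_params: CalciumParams
    modulation: ModulationSchedule
    temperature_K: float = 303.15
    ca_external_mM: float = 5.0
    mg_mM: float = 1.0
    ca_fraction_scheme: str = "mu_scaled"
    v_table_mV: tuple[float, float, float] = (-120.0, 60.0, 0.05)

    @classmethod
    def from_config(cls, config: dict) -> "Model":
        """Assemble a model from a validated configuration dictionary."""
        mcfg = config["morphology"]
        if mcfg.get("swc"):
            tree = morph.read_swc(mcfg["swc"])
        else:
            tree = morph.build_synthetic_morphology(**mcfg["synthetic"])
        for sp in mcfg.get("spines", []):
            tree, _ = morph.attach_spine(
                tree, sp["site_um"], sp.get("diameter_um", 1.0),
                sp.get("length_um", 1.273), sp.get("dendrite", 0),
            )
        mem = config["membrane"]
        graph = morph.discretize(
            tree,
            f_lambda=mcfg.get("f_lambda", 0.1),
            freq_hz=mcfg.get("lambda_freq_Hz", 100.0),
            C_uF_cm2=mem["C_uF_cm2"],
            g_leak_S_cm2=mem["g_leak_S_cm2"],
            g_a=mem["g_a_Scm"],
            E_leak_mV=mem["E_leak_mV"],
            region_boundaries=tuple(mcfg.get("region_boundaries_um", (50.0, 100.0))),
        )
        graph = morph.apply_spine_correction(graph, dict(mcfg.get("spine_factors", {})) or None)
        channels, receptors = load_kinetics(config.get("kinetics_file"))
        for name, ov in config.get("receptors", {}).get("overrides", {}).items():
            base = receptors[name].__dict__ | ov
            receptors[name] = ReceptorSpec(**base)
        ca_keys = {f.name for f in CalciumParams.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        ca_params = CalciumParams(**{
            k: v for k, v in config["calcium"].items() if k in ca_keys
        })
        mod = config["modulation"]
        schedule = ModulationSchedule(
            event_times_ms=[],
            mu_peak=dict(mod["mu_peak"]),
            t_peak_ms=mod["t_peak_ms"],
            tau_inc_ms=mod["tau_inc_ms"],
            tau_dec_ms=mod["tau_dec_ms"],
            cav13_shift_mV=mod["cav13_shift_mV"],
            continuous=mod["continuous"],
        )
        sol = config["solver"]
        return cls(
            graph=graph, channels=channels, receptors=receptors,
            densities=dict(config["densities"]), ca_params=ca_params,
            modulation=schedule, temperature_K=config["temperature_K"],
            ca_external_mM=config["ca_external_mM"],
            mg_mM=config["receptors"]["mg_mM"],
            ca_fraction_scheme=config["receptors"]["ca_fraction_scheme"],
            v_table_mV=(sol["v_table_min_mV"], sol["v_table_max_mV"],
                        sol["v_table_step_mV"]),
        )

    def density_array(self, name: str) -> np.ndarray:
        """Per-compartment gbar (S/cm2) or pbar (cm/s) from the region tiers.

        Explicit spine compartments inherit the tier of the dendritic region
        they sit in.
        """
        spec = self.densities.get(name, 0.0)
        g = self.graph
        regions = []
        for i, c in enumerate(g.compartments):
            r = c.region
            if r == "spine":
                j = int(g.parent[i])
                while g.compartments[j].region == "spine":
                    j = int(g.parent[j])
                r = g.compartments[j].region
            regions.append(r)
        out = np.zeros(g.n)
        for i, r in enumerate(regions):
            if isinstance(spec, dict):
                if r in spec:
                    out[i] = spec[r]
                elif r != "soma" and "dend" in spec:
                    out[i] = spec["dend"]
                elif "all" in spec:
                    out[i] = spec["all"]
                else:
                    raise ChannelConfigError(
                        f"density for {name} lacks a value for region {r!r}")
            else:
                out[i] = float(spec)
        return out


# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Time series and summaries from one engine run (batch-aware)."""

    time_ms: np.ndarray                       # (nT,)
    sites: dict[str, int]                     # site name -> compartment index
    V_mV: np.ndarray                          # (nT, B, n_sites)
    Ca_uM: np.ndarray                         # (nT, B, n_sites)
    source_cum_uM: np.ndarray | None = None   # (nT, B, n_sites, n_sources)
    influx_cum_uM: np.ndarray | None = None   # (nT, B, n_sites) total positive flux
    source_names: tuple = CALCIUM_SOURCES
    peak_Ca_uM: np.ndarray | None = None      # (B, n_sites) baseline-subtracted
    peak_x: np.ndarray | None = None          # (B, n_sites) leaky-integrator peak

    @property
    def site_names(self) -> list[str]:
        return list(self.sites)

    def site_index(self, name: str) -> int:
        return self.site_names.index(name)

    def trace(self, quantity: str, site: str, cell: int = 0) -> np.ndarray:
        arr = {"V": self.V_mV, "Ca": self.Ca_uM}[quantity]
        return arr[:, cell, self.site_index(site)]

    def to_frame(self):
        """Tidy (time, cell, site, quantity, value) table."""
        import pandas as pd
        rows = []
        for q, arr in (("V_mV", self.V_mV), ("Ca_uM", self.Ca_uM)):
            nT, B, S = arr.shape
            for b in range(B):
                for s, name in enumerate(self.site_names):
                    rows.append(pd.DataFrame({
                        "time_ms": self.time_ms, "cell": b, "site": name,
                        "quantity": q, "value": arr[:, b, s],
                    }))
        return pd.concat(rows, ignore_index=True)


def decompose_calcium_sources(recording: Recording, window_ms=None,
                              cell: int = 0) -> dict[str, dict[str, float]]:
    """Per-site totals of each calcium source over a time window (uM).

    The totals are the increments of the cumulative per-source influx
    recorded during the run; their sum closes with the integral of the total
    positive influx.
    """
    if recording.source_cum_uM is None:
        raise ValueError("run was recorded without per-source fluxes")
    t = recording.time_ms
    if window_ms is None:
        i0, i1 = 0, len(t) - 1
    else:
        w0, w1 = window_ms
        if w0 < t[0] - 1e-9 or w1 > t[-1] + 1e-9:
            raise ValueError("window outside recording")
        i0 = int(np.searchsorted(t, w0))
        i1 = int(np.searchsorted(t, w1, side="right")) - 1
    out: dict[str, dict[str, float]] = {}
    for s, name in enumerate(recording.site_names):
        cum = recording.source_cum_uM[:, cell, s, :]
        totals = cum[i1] - cum[i0]
        d = {src: float(totals[k]) for k, src in enumerate(recording.source_names)}
        d["total"] = float(
            recording.influx_cum_uM[i1, cell, s] - recording.influx_cum_uM[i0, cell, s]
        )
        out[name] = d
    return out


# ---------------------------------------------------------------------------

class _GateTable:
    """Stacked voltage tables for the plain voltage-dependent gates."""

    def __init__(self, gates, vmin, vmax, dv, dt):
        self.vmin, self.dv = vmin, dv
        V = np.arange(vmin, vmax + dv / 2, dv)
        self.nV = len(V)
        self.xinf = np.empty((len(gates), self.nV))
        self.decay = np.empty((len(gates), self.nV))
        for i, g in enumerate(gates):
            self.xinf[i] = g.steady_state(V)
            self.decay[i] = np.exp(-dt / g.time_constant(V))

    def index(self, V):
        idx = np.rint((V - self.vmin) / self.dv).astype(np.int64)
        return np.clip(idx, 0, self.nV - 1)


class Engine:
    """Stepper for one model, one dt, and a batch of stimulus conditions."""

    def __init__(self, model: Model, dt_ms: float = 0.025, batch: int = 1,
                 blockades: dict[str, float] | None = None,
                 mg_mM: float | None = None,
                 mu_peak_override: dict[str, float] | None = None):
        self.model = model
        self.dt = float(dt_ms)
        self.B = int(batch)
        g = model.graph
        self.n = g.n
        self.parent = g.parent
        self.order = np.arange(self.n)
        self.gax_uS = g.g_axial_S * 1e6
        self.C_nF = g.C_nF
        self.gL_uS = g.g_leak_uS
        self.E_leak = g.E_leak_mV
        self.area_cm2 = g.area_cm2
        self.volume_um3 = g.array("volume_um3")
        self.blockades = dict(blockades or {})
        self.mg_mM = model.mg_mM if mg_mM is None else float(mg_mM)
        for k in self.blockades:
            if k not in CHANNEL_NAMES and k not in ("AMPA", "NMDA"):
                raise ChannelConfigError(f"unknown blockade target: {k!r}")
        mod = model.modulation
        self.mu_peak = dict(mod.mu_peak)
        if mu_peak_override:
            self.mu_peak.update(mu_peak_override)
        self._build_channel_arrays()
        self._build_synapses()
        self.reset()

    # -- construction -----------------------------------------------------
    def _build_channel_arrays(self):
        m = self.model
        vmin, vmax, dv = m.v_table_mV
        self.ohmic_names, self.ghk_names = [], []
        self.ohmic_g_uS, self.ohmic_E = [], []
        self.ghk_coef = []       # pbar*area*1e9: nA per (A s cm^-1) driving
        vgates = []              # plain voltage gates
        self.vgate_channel = []  # channel array index (family, slot)
        self.special = []        # (kind, channel slot, gate) for SK/BK/Cav1.3
        self.exponents = []
        ch_index: dict[str, tuple[str, int]] = {}
        for name in CHANNEL_NAMES:
            spec = m.channels[name]
            dens = m.density_array(name) * self.blockades.get(name, 1.0)
            if spec.conduction == "ohmic":
                slot = ("ohmic", len(self.ohmic_names))
                self.ohmic_names.append(name)
                self.ohmic_g_uS.append(dens * self.area_cm2 * 1e6)
                self.ohmic_E.append(spec.erev_mV)
            else:
                slot = ("ghk", len(self.ghk_names))
                self.ghk_names.append(name)
                self.ghk_coef.append(dens * self.area_cm2 * 1e9)
            ch_index[name] = slot
            for gate in spec.gates:
                if gate.ca_dependent == "hill":
                    self.special.append(("hill", slot, gate))
                elif gate.ca_dependent == "shift":
                    self.special.append(("shift", slot, gate))
                elif name == "Cav1.3" and gate.name == "m":
                    self.special.append(("cav13", slot, gate))
                else:
                    vgates.append(gate)
                    self.vgate_channel.append(slot)
        self.vgates = vgates
        self.tables = _GateTable(vgates, vmin, vmax, dv, self.dt)
        # special gates get their own small tables over V
        self.sp_tables = _GateTable([g for _, _, g in self.special],
                                    vmin, vmax, dv, self.dt)
        self.ohmic_g_uS = np.array(self.ohmic_g_uS)     # (nOhm, n)
        self.ohmic_E = np.array(self.ohmic_E)
        self.ghk_coef = np.array(self.ghk_coef)         # (nGhk, n)
        self.ghk_u_per_mV = (2.0 * FARADAY_C_PER_MOL * 1e-3
                             / (GAS_CONSTANT_J_PER_MOL_K * m.temperature_K))
        self.ca_o_mol_cm3 = m.ca_external_mM * 1e-6
        # which channels are dopamine targets
        self.mu_targets = {z: ch_index[z] for z in self.mu_peak if z in ch_index}

    def _build_synapses(self):
        m = self.model
        self.ampa = m.receptors["AMPA"]
        self.nmda = m.receptors["NMDA"]
        self.ampa_gbar = self.ampa.gbar_pS * self.blockades.get("AMPA", 1.0)
        self.nmda_gbar = self.nmda.gbar_pS * self.blockades.get("NMDA", 1.0)
        spine_idx = m.graph.spine_indices()
        dists = [m.graph.compartments[i].dist_um for i in spine_idx]
        order = np.argsort(dists)
        self.spine_comps = [spine_idx[i] for i in order]   # proximal first
        self.site_names = {"soma": 0}
        for k, i in enumerate(self.spine_comps):
            d = m.graph.compartments[i].dist_um
            self.site_names[f"spine_{d:.0f}um"] = i

    # -- state ------------------------------------------------------------
    def reset(self, V0: float | None = None):
        B, n = self.B, self.n
        self.t = 0.0
        self.V = np.full((B, n), self.E_leak if V0 is None else V0)
        ca0 = self.model.ca_params.Ca_inf_uM
        self.Ca = np.full((B, n), ca0)
        self.IP3 = np.full((B, n), self.model.ca_params.IP3_min_uM)
        idx = self.tables.index(self.V)
        self.X = self.tables.xinf[:, idx[0]][:, None, :].repeat(B, axis=1) \
            if n else np.zeros((0, B, n))
        spidx = self.sp_tables.index(self.V)
        self.Xs = np.empty((len(self.special), B, n))
        for i, (kind, _, gate) in enumerate(self.special):
            if kind == "hill":
                self.Xs[i] = gate.steady_state(self.V, self.Ca)
            else:
                self.Xs[i] = self.sp_tables.xinf[i][spidx]
        # synaptic dual-exponential state per spine: rise and decay terms
        ns = len(self.spine_comps)
        self.syn_A = np.zeros((2, B, ns))  # [AMPA, NMDA] rise
        self.syn_B = np.zeros((2, B, ns))  # [AMPA, NMDA] decay
        self.glu_onsets: list[tuple[int, np.ndarray]] = []
        self.da_onsets: list[np.ndarray] = []
        self.step_currents: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []
        # leaky integrator state and peak trackers
        self.x_int = np.zeros((B, len(self.site_names)))
        self.peak_window: tuple[float, float] | None = None
        self._peak_Ca = np.full((B, len(self.site_names)), -np.inf)
        self._base_Ca = np.zeros((B, len(self.site_names)))
        self._base_set = False
        self._peak_x = np.zeros((B, len(self.site_names)))

    def tile(self, batch: int):
        """Replicate the current (usually settled) state across a new batch."""
        if self.B != 1:
            raise ValueError("can only tile from a single-cell state")
        self.B = batch
        for name in ("V", "Ca", "IP3"):
            setattr(self, name, np.repeat(getattr(self, name), batch, axis=0))
        self.X = np.repeat(self.X, batch, axis=1)
        self.Xs = np.repeat(self.Xs, batch, axis=1)
        self.syn_A = np.repeat(self.syn_A, batch, axis=1)
        self.syn_B = np.repeat(self.syn_B, batch, axis=1)
        self.x_int = np.repeat(self.x_int, batch, axis=0)
        self._peak_Ca = np.repeat(self._peak_Ca, batch, axis=0)
        self._base_Ca = np.repeat(self._base_Ca, batch, axis=0)
        self._peak_x = np.repeat(self._peak_x, batch, axis=0)
        return self

    # -- stimuli ----------------------------------------------------------
    def add_step_current(self, comp: int, amp_nA, onset_ms, width_ms):
        """Injected current step; amp/onset may be scalars or (B,) arrays."""
        amp = np.broadcast_to(np.asarray(amp_nA, float), (self.B,)).copy()
        on = np.broadcast_to(np.asarray(onset_ms, float), (self.B,)).copy()
        w = np.broadcast_to(np.asarray(width_ms, float), (self.B,)).copy()
        self.step_currents.append((int(comp), amp, on, on + w))

    def add_glutamate(self, spine: int, onset_ms):
        """Glutamate event at spine index (0 = most proximal spine)."""
        on = np.broadcast_to(np.asarray(onset_ms, float), (self.B,)).copy()
        self.glu_onsets.append((int(spine), on))

    def add_dopamine(self, onset_ms):
        on = np.broadcast_to(np.asarray(onset_ms, float), (self.B,)).copy()
        self.da_onsets.append(on)

    def set_peak_window(self, t0_ms: float, t1_ms: float):
        """Track baseline-subtracted peak Ca and integrator peak in [t0, t1]."""
        self.peak_window = (t0_ms, t1_ms)
        self._peak_Ca[:] = -np.inf
        self._base_set = False

    # -- stepping ---------------------------------------------------------
    def _mu(self, t: float) -> dict[str, np.ndarray]:
        """Per-target modulation factors at time t, shape (B,)."""
        mod = self.model.modulation
        if not self.da_onsets:
            ones = np.ones(self.B)
            return {z: ones for z in self.mu_peak} | {"_shift": np.zeros(self.B)}
        t_hat = np.full(self.B, np.inf)
        for on in self.da_onsets:
            dt_ev = t - on
            t_hat = np.where((dt_ev >= 0) & (dt_ev < t_hat), dt_ev, t_hat)
        return {
            z: modulation_factor(self.mu_peak[z], t_hat, mod.t_peak_ms,
                                 mod.tau_inc_ms, mod.tau_dec_ms, mod.continuous)
            for z in self.mu_peak
        } | {"_shift": self.model.modulation.cav13_shift_mV * unit_profile(
            t_hat, mod.t_peak_ms, mod.tau_inc_ms, mod.tau_dec_ms, mod.continuous)}

    def step(self):
        dt, B, n = self.dt, self.B, self.n
        t = self.t
        V, Ca = self.V, self.Ca
        mu = self._mu(t)

        # --- synaptic event arrivals in [t, t+dt) then state decay -------
        decA = (math.exp(-dt / self.ampa.tau_rise_ms),
                math.exp(-dt / self.nmda.tau_rise_ms))
        decB = (math.exp(-dt / self.ampa.tau_decay_ms),
                math.exp(-dt / self.nmda.tau_decay_ms))
        for r in (0, 1):
            self.syn_A[r] *= decA[r]
            self.syn_B[r] *= decB[r]
        for spine, on in self.glu_onsets:
            hit = (on >= t) & (on < t + dt)
            if hit.any():
                self.syn_A[:, hit, spine] += 1.0
                self.syn_B[:, hit, spine] += 1.0

        # --- gate updates at frozen V, Ca --------------------------------
        idx = self.tables.index(V)
        xinf = self.tables.xinf[:, idx]
        dec = self.tables.decay[:, idx]
        self.X = xinf + (self.X - xinf) * dec
        for i, (kind, _, gate) in enumerate(self.special):
            if kind == "hill":
                xi = gate.steady_state(V, Ca)
                d = math.exp(-dt / gate.tau0_ms)
                self.Xs[i] = xi + (self.Xs[i] - xi) * d
            elif kind == "shift":
                vshift = gate.shift_mV_per_efold * np.log(
                    np.maximum(Ca, 1e-12) / gate.ca_ref_uM)
                j = self.sp_tables.index(V - vshift)
                self.Xs[i] = (self.sp_tables.xinf[i][j]
                              + (self.Xs[i] - self.sp_tables.xinf[i][j])
                              * self.sp_tables.decay[i][j])
            else:  # cav13: DA shifts the activation half-voltage
                shift = mu["_shift"][:, None]
                j = self.sp_tables.index(V - shift)
                self.Xs[i] = (self.sp_tables.xinf[i][j]
                              + (self.Xs[i] - self.sp_tables.xinf[i][j])
                              * self.sp_tables.decay[i][j])

        # --- open fractions per channel ----------------------------------
        open_ohmic = [np.ones((B, n)) for _ in self.ohmic_names]
        open_ghk = [np.ones((B, n)) for _ in self.ghk_names]
        def _slot_arr(slot):
            fam, k = slot
            return open_ohmic[k] if fam == "ohmic" else open_ghk[k]
        for gi, slot in enumerate(self.vgate_channel):
            x = self.X[gi]
            e = self.vgates[gi].exponent
            _slot_arr(slot)[...] *= x ** e if e != 1 else x
        for i, (kind, slot, gate) in enumerate(self.special):
            e = gate.exponent
            _slot_arr(slot)[...] *= self.Xs[i] ** e if e != 1 else self.Xs[i]

        # --- ohmic conductances and GHK currents -------------------------
        Gm = np.zeros((B, n))            # uS, total linear conductance
        rhsE = np.zeros((B, n))          # uS*mV source from reversal terms
        for k, name in enumerate(self.ohmic_names):
            g = self.ohmic_g_uS[k] * open_ohmic[k]
            if name in self.mu_targets:
                g = g * mu[name][:, None]
            Gm += g
            rhsE += g * self.ohmic_E[k]
        u = self.ghk_u_per_mV * V
        small = np.abs(u) < 1e-4
        usafe = np.where(small, 1.0, u)
        expu = np.exp(-usafe)
        ci = Ca * 1e-9
        co = self.ca_o_mol_cm3
        frac = np.where(
            small,
            (ci - co) + u * (ci + co) / 2.0,
            usafe * (ci - co * expu) / (1.0 - expu),
        )
        driving = 2.0 * FARADAY_C_PER_MOL * frac      # A s/cm per unit P
        I_ghk_each = []                                # nA, per Ca channel
        I_ghk = np.zeros((B, n))
        for k, name in enumerate(self.ghk_names):
            i_k = self.ghk_coef[k] * open_ghk[k] * driving
            if name in self.mu_targets:
                i_k = i_k * mu[name][:, None]
            I_ghk_each.append(i_k)
            I_ghk += i_k

        # --- synaptic conductances at spines ------------------------------
        g_syn = np.zeros((B, n))          # uS (E_rev = 0)
        I_nmda = np.zeros((B, len(self.spine_comps)))
        I_ampa = np.zeros((B, len(self.spine_comps)))
        g_ampa_sp = np.zeros((B, len(self.spine_comps)))
        g_nmda_sp = np.zeros((B, len(self.spine_comps)))
        if self.glu_onsets:
            Vsp = V[:, self.spine_comps]
            block = 1.0 / (1.0 + (self.mg_mM / self.nmda.mg_K0_mM)
                           * np.exp(-self.nmda.mg_slope_per_mV * Vsp))
            g_ampa_sp = (self.ampa_gbar / self.ampa.norm
                         * (self.syn_B[0] - self.syn_A[0])) * 1e-6  # pS->uS
            g_nmda_sp = (self.nmda_gbar / self.nmda.norm
                         * (self.syn_B[1] - self.syn_A[1])) * 1e-6 \
                * mu["NMDA"][:, None] * block
            for s, comp in enumerate(self.spine_comps):
                g_syn[:, comp] += g_ampa_sp[:, s] + g_nmda_sp[:, s]

        # --- stimulus currents -------------------------------------------
        I_inj = np.zeros((B, n))          # nA, depolarizing positive
        for comp, amp, on, off in self.step_currents:
            active = (t >= on) & (t < off)
            I_inj[:, comp] += np.where(active, amp, 0.0)

        # --- implicit tree solve -----------------------------------------
        d = self.C_nF / dt + self.gL_uS + Gm + g_syn
        rhs = self.C_nF / dt * V + self.gL_uS * self.E_leak + rhsE \
            - I_ghk + I_inj
        d = np.broadcast_to(d, (B, n)).copy() if d.ndim == 1 else d.copy()
        # add axial terms to diagonals
        for j in range(1, n):
            p = self.parent[j]
            d[:, j] += self.gax_uS[j]
            d[:, p] += self.gax_uS[j]
        # eliminate leaves toward the root, then back-substitute
        for j in range(n - 1, 0, -1):
            p = self.parent[j]
            f = self.gax_uS[j] / d[:, j]
            d[:, p] -= f * self.gax_uS[j]
            rhs[:, p] += f * rhs[:, j]
        Vn = np.empty_like(V)
        Vn[:, 0] = rhs[:, 0] / d[:, 0]
        for j in range(1, n):
            p = self.parent[j]
            Vn[:, j] = (rhs[:, j] + self.gax_uS[j] * Vn[:, p]) / d[:, j]

        # --- synaptic currents at the new voltage (for calcium) ----------
        if self.glu_onsets:
            Vsp_new = Vn[:, self.spine_comps]
            I_ampa = g_ampa_sp * Vsp_new          # uS*mV = nA
            I_nmda = g_nmda_sp * Vsp_new

        # --- calcium and IP3 ----------------------------------------------
        p = self.model.ca_params
        caER = p.Ca_ER_uM
        grad = caER - Ca
        J_cicr = p.V_CICR_per_ms * Ca / (Ca + p.K_CICR_uM) * grad
        mgate = (self.IP3 / (self.IP3 + p.d_IP3_uM)) * (Ca / (Ca + p.d_act_uM))
        hnum = p.d_inh_uM * (self.IP3 + p.d_IP3_uM)
        hgate = hnum / (hnum + Ca * (self.IP3 + p.d_dis_uM))
        J_ip3 = p.V_IP3_per_ms * mgate ** 3 * hgate ** 3 * grad
        J_upt = p.V_uptake_uM_per_ms * Ca ** 2 / (p.K_uptake_uM ** 2 + Ca ** 2)
        J_leak = p.V_leak_per_ms * grad
        J_pump = p.V_pump_uM_per_ms * Ca / (Ca + p.K_pump_uM)
        J_diff = (p.Ca_inf_uM - Ca) / p.tau_diff_ms
        J_cur = -I_ghk * _CURRENT_TO_FLUX / self.volume_um3
        # synaptic calcium enters only at the spines
        if self.glu_onsets:
            cA = self.ampa.ca_fraction
            cN = self.nmda.ca_fraction
            if self.model.ca_fraction_scheme == "mu_scaled":
                cN = cN * mu["NMDA"]
                cA = cA * 1.0
            I_syn_ca = cA * I_ampa + (cN[:, None] if np.ndim(cN) else cN) * I_nmda
            for s, comp in enumerate(self.spine_comps):
                J_cur[:, comp] += (-I_syn_ca[:, s] * _CURRENT_TO_FLUX
                                   / self.volume_um3[comp])
        Ca_new = Ca + dt * (J_cicr + J_ip3 - J_upt + J_leak + J_cur - J_pump
                            + J_diff)
        np.maximum(Ca_new, CA_FLOOR_UM, out=Ca_new)
        # IP3: exact removal + explicit alpha-function production at spines
        self.IP3 = (p.IP3_min_uM
                    + (self.IP3 - p.IP3_min_uM) * math.exp(-p.beta_IP3_per_ms * dt))
        for spine, on in self.glu_onsets:
            t_glu = t - on
            comp = self.spine_comps[spine]
            prod = np.where(
                t_glu >= 0,
                p.gamma_IP3_uM_per_ms2 * np.maximum(t_glu, 0.0)
                * np.exp(-np.maximum(t_glu, 0.0) / p.tau_IP3_ms),
                0.0,
            )
            self.IP3[:, comp] += prod * dt

        # --- per-source influx bookkeeping at the recorded sites ----------
        sites = list(self.site_names.values())
        src = self._src_step = np.zeros((B, len(sites), len(CALCIUM_SOURCES)))
        for si, comp in enumerate(sites):
            vfac = _CURRENT_TO_FLUX / self.volume_um3[comp]
            if self.glu_onsets and comp in self.spine_comps:
                s = self.spine_comps.index(comp)
                cA = self.ampa.ca_fraction
                cN = self.nmda.ca_fraction
                if self.model.ca_fraction_scheme == "mu_scaled":
                    cN = cN * mu["NMDA"]
                src[:, si, 0] = np.maximum(-cA * I_ampa[:, s] * vfac, 0.0) * dt
                src[:, si, 1] = np.maximum(-cN * I_nmda[:, s] * vfac, 0.0) * dt
            for k, name in enumerate(self.ghk_names):
                j = CALCIUM_SOURCES.index(name)
                src[:, si, j] = np.maximum(-I_ghk_each[k][:, comp] * vfac, 0.0) * dt
            er = (np.maximum(J_cicr[:, comp], 0.0) + np.maximum(J_ip3[:, comp], 0.0)
                  + np.maximum(J_leak[:, comp], 0.0))
            src[:, si, CALCIUM_SOURCES.index("ER")] = er * dt
            src[:, si, CALCIUM_SOURCES.index("diffusion")] = \
                np.maximum(J_diff[:, comp], 0.0) * dt

        # --- commit -------------------------------------------------------
        self.V = Vn
        self.Ca = Ca_new
        self.t = t + dt
        if not np.isfinite(Vn[:, 0]).all():
            bad = np.where(~np.isfinite(Vn).any(axis=1))[0]
            raise IntegrationError(
                f"non-finite voltage at t={self.t:.3f} ms (cells {bad[:5]})")

        # --- summaries ----------------------------------------------------
        ca_sites = Ca_new[:, sites]
        if self.peak_window is not None:
            w0, w1 = self.peak_window
            if self.t >= w0 and not self._base_set:
                self._base_Ca = ca_sites.copy()
                self._base_set = True
            if w0 <= self.t <= w1:
                np.maximum(self._peak_Ca, ca_sites - self._base_Ca,
                           out=self._peak_Ca)

    def run(self, duration_ms: float, record_every: int = 0,
            record_sources: bool = False,
            integrator: tuple[float, float] | None = None) -> Recording | None:
        """Advance by ``duration_ms``; optionally record traces.

        ``record_every`` 0 disables trace recording (summaries still track).
        ``integrator = (tau_ms, a)`` runs the leaky calcium integrator at the
        recorded sites and tracks its peak.
        """
        nsteps = int(round(duration_ms / self.dt))
        sites = list(self.site_names.values())
        rec = None
        if record_every:
            nT = nsteps // record_every + 1
            rec = Recording(
                time_ms=np.empty(nT), sites=dict(self.site_names),
                V_mV=np.empty((nT, self.B, len(sites))),
                Ca_uM=np.empty((nT, self.B, len(sites))),
            )
            if record_sources:
                rec.source_cum_uM = np.zeros(
                    (nT, self.B, len(sites), len(CALCIUM_SOURCES)))
                rec.influx_cum_uM = np.zeros((nT, self.B, len(sites)))
            rec.time_ms[0] = self.t
            rec.V_mV[0] = self.V[:, sites]
            rec.Ca_uM[0] = self.Ca[:, sites]
        cum_src = np.zeros((self.B, len(sites), len(CALCIUM_SOURCES)))
        if integrator is not None:
            tau_x, a_x = integrator
            fx = math.exp(-self.dt / tau_x)
        ptr = 1
        for k in range(nsteps):
            self.step()
            cum_src += self._src_step
            if integrator is not None:
                ca_sites = self.Ca[:, sites]
                self.x_int = self.x_int * fx + a_x * ca_sites * (1.0 - fx)
                np.maximum(self._peak_x, self.x_int, out=self._peak_x)
            if record_every and (k + 1) % record_every == 0 and ptr < rec.time_ms.shape[0]:
                rec.time_ms[ptr] = self.t
                rec.V_mV[ptr] = self.V[:, sites]
                rec.Ca_uM[ptr] = self.Ca[:, sites]
                if record_sources:
                    rec.source_cum_uM[ptr] = cum_src
                    rec.influx_cum_uM[ptr] = cum_src.sum(axis=-1)
                ptr += 1
        if rec is not None:
            rec.time_ms = rec.time_ms[:ptr]
            rec.V_mV = rec.V_mV[:ptr]
            rec.Ca_uM = rec.Ca_uM[:ptr]
            if record_sources:
                rec.source_cum_uM = rec.source_cum_uM[:ptr]
                rec.influx_cum_uM = rec.influx_cum_uM[:ptr]
            rec.peak_Ca_uM = self.peak_Ca()
            rec.peak_x = self._peak_x.copy()
        return rec

    def peak_Ca(self) -> np.ndarray:
        """Baseline-subtracted peak Ca per site tracked in the peak window."""
        return np.where(np.isfinite(self._peak_Ca), self._peak_Ca, 0.0)

    @property
    def peak_integrator(self) -> np.ndarray:
        return self._peak_x.copy()


def run_simulation(config: SimConfig, model: Model, batch: int = 1,
                   stimuli=None, blockades=None) -> Recording:
    """Settle the model, apply stimuli, and record a full trace set.

    ``stimuli`` is a list of dicts with ``kind`` in {current_step, glutamate,
    dopamine}; onsets are relative to the end of the settling period.
    """
    eng = Engine(model, dt_ms=config.dt_ms, batch=1, blockades=blockades)
    steady = [s for s in (stimuli or []) if s["kind"] == "current_step"
              and s.get("width_ms") is None]
    for s in steady:
        eng.add_step_current(s.get("comp", 0), s["amp_nA"], 0.0, np.inf)
    if config.settle_ms:
        eng.run(config.settle_ms)
    if batch > 1:
        eng.tile(batch)
    t0 = eng.t
    for s in (stimuli or []):
        if s["kind"] == "current_step" and s.get("width_ms") is not None:
            eng.add_step_current(s.get("comp", 0), s["amp_nA"],
                                 t0 + np.asarray(s["onset_ms"], float),
                                 s["width_ms"])
        elif s["kind"] == "glutamate":
            eng.add_glutamate(s.get("spine", 0), t0 + np.asarray(s["onset_ms"], float))
        elif s["kind"] == "dopamine":
            eng.add_dopamine(t0 + np.asarray(s["onset_ms"], float))
    rec = eng.run(config.duration_ms, record_every=config.record_every,
                  record_sources=config.record_sources)
    if rec is None:
        sites = list(eng.site_names.values())
        rec = Recording(
            time_ms=np.array([eng.t]), sites=dict(eng.site_names),
            V_mV=eng.V[None, :, sites], Ca_uM=eng.Ca[None, :, sites],
        )
    rec.time_ms = rec.time_ms - t0
    return rec
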