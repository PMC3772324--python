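"""Loading of the gating-kinetics parameter file.

The kinetics file is the single source for steady-state sigmoids, time
constants, gate exponents and receptor time courses.  The bundled default
(``data/kinetics.yaml``) is a Wolf/Moyer-derived reconstruction; point
``kinetics_file`` in the run configuration at a replacement to override it.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .channels import ChannelSpec, GateScheme, ChannelConfigError
from .synapses import ReceptorSpec


def _gate_from_dict(d: dict) -> GateScheme:
    inf = d.get("inf", {})
    tau = d.get("tau", {})
    return GateScheme(
        name=d["name"],
        exponent=int(d.get("exponent", 1)),
        vhalf_mV=float(inf.get("vhalf_mV", 0.0)),
        k_mV=float(inf.get("k_mV", 1.0)),
        floor=float(inf.get("floor", 0.0)),
        tau0_ms=float(tau.get("tau0_ms", 1.0)),
        tau_amp_ms=float(tau.get("amp_ms", 0.0)),
        tau_vt_mV=float(tau.get("vt_mV", 0.0)),
        tau_ka_mV=float(tau.get("ka_mV", 1.0)),
        tau_kb_mV=float(tau.get("kb_mV", 1.0)),
        ca_dependent=str(d.get("ca_dependent", "")),
        ca_half_uM=float(d.get("ca_half_uM", 0.35)),
        hill_coef=float(d.get("hill_coef", 4.0)),
        ca_ref_uM=float(d.get("ca_ref_uM", 1.0)),
        shift_mV_per_efold=float(d.get("shift_mV_per_efold", 0.0)),
    )


def load_kinetics(path=None) -> tuple[dict[str, ChannelSpec], dict[str, ReceptorSpec]]:
    """Parse a kinetics YAML into channel and receptor specifications.

    ``path=None`` loads the bundled defaults.
    """
    if path is None:
        text = resources.files("msnsim.data").joinpath("kinetics.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    channels: dict[str, ChannelSpec] = {}
    for name, cfg in raw.get("channels", {}).items():
        channels[name] = ChannelSpec(
            name=name,
            conduction=cfg["conduction"],
            erev_mV=cfg.get("erev_mV"),
            gates=[_gate_from_dict(g) for g in cfg.get("gates", [])],
        )
    receptors: dict[str, ReceptorSpec] = {}
    for name, cfg in raw.get("receptors", {}).items():
        if name not in ("AMPA", "NMDA"):
            raise ChannelConfigError(f"unknown receptor: {name!r}")
        mg = cfg.get("mg_block", {})
        receptors[name] = ReceptorSpec(
            name=name,
            gbar_pS=float(cfg["gbar_pS"]),
            tau_rise_ms=float(cfg["tau_rise_ms"]),
            tau_decay_ms=float(cfg["tau_decay_ms"]),
            erev_mV=float(cfg.get("erev_mV", 0.0)),
            ca_fraction=float(cfg.get("ca_fraction", 0.0)),
            mg_K0_mM=float(mg.get("K0_mM", 3.57)),
            mg_slope_per_mV=float(mg.get("slope_per_mV", 0.062)),
            has_mg_block=bool(mg),
        )
    return channels, receptors
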