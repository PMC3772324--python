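"""Configuration loading, validation, and fixture generation.

All model parameters live in one versioned defaults file
(``data/defaults.yaml``); a user configuration is a YAML file whose keys
override the defaults.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

__all__ = ["load_config", "default_config", "dump_config", "validate_config",
           "generate_fixtures", "ConfigError", "run_manifest"]


class ConfigError(ValueError):
    """Schema violation: names the offending key."""


def default_config() -> dict:
    text = resources.files("msnsim.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


#: keys whose sub-dicts accept free-form entries (channel names, overrides...)
_OPEN_KEYS = {
    ("densities",), ("modulation", "mu_peak"), ("receptors", "overrides"),
    ("blockades",), ("morphology", "spine_factors"), ("calcium", "verbatim"),
}


def _merge(base: dict, override: dict, path: tuple = ()) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base and path not in _OPEN_KEYS:
            dotted = ".".join(path + (str(key),))
            raise ConfigError(f"unknown configuration key: {dotted!r}")
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            out[key] = _merge(base[key], val, path + (key,))
        else:
            out[key] = val
    return out


def validate_config(config: dict) -> dict:
    """Range checks on the assembled configuration; returns it unchanged."""
    def bad(key, why):
        raise ConfigError(f"invalid value for {key}: {why}")

    sol = config["solver"]
    if sol["dt_ms"] <= 0:
        bad("solver.dt_ms", "must be > 0")
    if sol["settle_ms"] < 0:
        bad("solver.settle_ms", "must be >= 0")
    mem = config["membrane"]
    for k in ("C_uF_cm2", "g_leak_S_cm2", "g_a_Scm"):
        if mem[k] <= 0:
            bad(f"membrane.{k}", "must be > 0")
    if config["temperature_K"] <= 0:
        bad("temperature_K", "must be > 0")
    if config["ca_external_mM"] <= 0:
        bad("ca_external_mM", "must be > 0")
    if config["receptors"]["mg_mM"] < 0:
        bad("receptors.mg_mM", "must be >= 0")
    if config["receptors"]["ca_fraction_scheme"] not in ("mu_scaled", "constant"):
        bad("receptors.ca_fraction_scheme", "must be mu_scaled or constant")
    for name, val in config["densities"].items():
        vals = val.values() if isinstance(val, dict) else [val]
        if any(v < 0 for v in vals):
            bad(f"densities.{name}", "must be >= 0")
    for k, v in config["calcium"].items():
        if k != "verbatim" and isinstance(v, (int, float)) and v < 0:
            bad(f"calcium.{k}", "must be >= 0")
    bnds = config["morphology"]["region_boundaries_um"]
    if not (0 < bnds[0] < bnds[1]):
        bad("morphology.region_boundaries_um", "must be increasing and positive")
    for z, mp in config["modulation"]["mu_peak"].items():
        if mp <= 0:
            bad(f"modulation.mu_peak.{z}", "must be > 0")
    return config


def load_config(path=None) -> dict:
    """Load a run configuration: user YAML merged over the defaults.

    ``path=None`` (or an empty file) gives the full default model.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("configuration root must be a mapping")
        cfg = _merge(cfg, user)
    return validate_config(cfg)


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def run_manifest(config: dict, overrides: dict | None = None) -> dict:
    """Config echo plus provenance tags for a results directory."""
    from . import __version__
    import datetime

    defaults = default_config()

    def provenance(base, cfg, path=()):
        tags = {}
        for k, v in cfg.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                tags[k] = provenance(base[k], v, path + (k,))
            else:
                tags[k] = "default" if base.get(k) == v else "user-override"
        return tags

    return {
        "config": config,
        "provenance": provenance(defaults, config),
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "overrides": overrides or {},
    }


def generate_fixtures(kind: str, seed: int, outdir=None) -> dict:
    """Reproducible synthetic inputs for unit tests.

    kinds: ``morphology`` (a small random dendritic tree), ``voltage_trace``
    (a bounded random voltage trajectory spanning [-100, +40] mV), and
    ``ca_flux_schedule`` (a canned flux time course for calcium oracles).
    The model itself is deterministic; fixtures are the only stochastic
    component.
    """
    rng = np.random.default_rng(seed)
    if kind == "morphology":
        from .morphology import SegmentNode, SegmentTree, write_swc
        nodes = [SegmentNode(1, None, 0.0, 0.0, 0.0, rng.uniform(5, 10), "soma")]
        nid = 2
        for _ in range(int(rng.integers(2, 5))):
            parent = 1
            x = y = 0.0
            theta = rng.uniform(0, 2 * np.pi)
            for _ in range(int(rng.integers(3, 8))):
                step = rng.uniform(5, 20)
                x += np.cos(theta) * step
                y += np.sin(theta) * step
                nodes.append(SegmentNode(nid, parent, x, y, 0.0,
                                         rng.uniform(0.3, 1.5), "dendrite"))
                parent = nid
                nid += 1
        tree = SegmentTree(nodes)
        if outdir is not None:
            write_swc(tree, f"{outdir}/fixture_morphology_{seed}.swc")
        return {"tree": tree}
    if kind == "voltage_trace":
        t = np.arange(0.0, 200.0, 0.1)
        v = np.cumsum(rng.normal(0, 2.0, t.size))
        v = -30.0 + 70.0 * (v - v.min()) / max(np.ptp(v), 1e-9) - 70.0
        v[0], v[v.size // 2] = -100.0, 40.0  # guarantee the full span
        if outdir is not None:
            np.savetxt(f"{outdir}/fixture_voltage_{seed}.csv",
                       np.c_[t, v], delimiter=",", header="t_ms,V_mV")
        return {"t_ms": t, "V_mV": v}
    if kind == "ca_flux_schedule":
        t = np.arange(0.0, 500.0, 0.5)
        n_pulse = int(rng.integers(1, 4))
        J = np.zeros_like(t)
        for _ in range(n_pulse):
            t0 = rng.uniform(20, 400)
            amp = rng.uniform(0.05, 0.5)
            tau = rng.uniform(5, 40)
            J += amp * np.exp(-np.maximum(t - t0, 0) / tau) * (t >= t0)
        if outdir is not None:
            np.savetxt(f"{outdir}/fixture_flux_{seed}.csv",
                       np.c_[t, J], delimiter=",", header="t_ms,J_uM_per_ms")
        return {"t_ms": t, "J_uM_per_ms": J}
    raise ConfigError(f"unknown fixture kind: {kind!r}")
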