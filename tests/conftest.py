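import numpy as np
import pytest

from msnsim import load_config, Model


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def model(config):
    """The full default model (built once per session)."""
    return Model.from_config(config)


@pytest.fixture(scope="session")
def passive_blockades():
    """Multipliers silencing every active channel (passive cable)."""
    from msnsim.channels import CHANNEL_NAMES
    return {name: 0.0 for name in CHANNEL_NAMES}


@pytest.fixture(scope="session")
def bap_results(model):
    """bAP responses for 2 ms / 30 ms pulses and the T-type blockade variant.

    Computed once: these back several ordering tests.
    """
    from msnsim.protocols import bap_protocol, calibrate_post_amplitude
    amp = calibrate_post_amplitude(model, "down", dt_ms=0.05, settle_ms=400.0)
    out = {"amp": amp}
    for key, width, blockades in (
        ("2ms", 2.0, None),
        ("30ms", 30.0, None),
        ("30ms_noT", 30.0, {"CaT": 0.0}),
    ):
        out[key] = bap_protocol(model, pulse_width_ms=width,
                                blockades=blockades, dt_ms=0.05,
                                settle_ms=400.0, post_amp_nA=amp,
                                follow_ms=500.0)
    return out


@pytest.fixture(scope="session")
def glu_results(model):
    """Glutamate-input responses for the three receptor conditions."""
    from msnsim.protocols import glutamate_protocol
    return {
        cond: glutamate_protocol(model, cond, dt_ms=0.05, settle_ms=400.0,
                                 follow_ms=700.0)
        for cond in ("intact", "AMPAR_only_mgfree", "NMDAR_only")
    }


def rng(seed=0):
    return np.random.default_rng(seed)
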