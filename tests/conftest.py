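import numpy as np
import pytest

from epicardio import load_presets, prolate_spheroid_mesh


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def mesh200():
    """Default 200-node epicardial shell fixture."""
    return prolate_spheroid_mesh(200, seed=1)


@pytest.fixture(scope="session")
def mesh60():
    """Smaller shell for runtime-sensitive end-to-end checks."""
    return prolate_spheroid_mesh(60, seed=2, equatorial_radius=8.0,
                                 polar_radius=60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_canonical_traces(at_ms=40.0, rt_ms=290.0, polarity=1.0, beats=10,
                          rr_ms=600.0, noise=0.0, wander=0.0, seed=0,
                          t_width_ms=160.0):
    """One node's beat train with configurable noise, for unit tests."""
    from epicardio.synthetic_cohort import WaveformParams, synthesize_beat_train

    params = WaveformParams(noise_sd_frac=noise, wander_amp_frac=wander,
                            beats=beats, rr_jitter_frac=0.0,
                            t_width_ms=t_width_ms)
    rr = np.full(beats, rr_ms)
    trace = synthesize_beat_train(at_ms, rt_ms, polarity, params, rr, seed=seed)
    return trace, params
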