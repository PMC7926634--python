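import numpy as np
import pytest

from thermovitals.synthetic import ChestConfig, SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """A short breathing scene shared by read-only tests (15 bpm, 60 s)."""
    cfg = SceneConfig(
        width=96, height=72, duration=60.0, seed=7,
        chest=ChestConfig(rr_bpm=15.0, amplitude_px=1.0),
    )
    return cfg, *generate_scene(cfg)


@pytest.fixture
def tiny_sequence():
    """3-frame, 4x4 deterministic sequence for I/O round trips."""
    from thermovitals.irt_io import ThermalSequence

    rng = np.random.default_rng(0)
    stack = 25.0 + 10.0 * rng.random((3, 4, 4))
    return ThermalSequence.from_array(stack, fps=4.0, meta={"origin": "fixture"})
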