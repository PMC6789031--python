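import numpy as np
import pytest

from soctouch.session import RecordingBlock, Session, TouchEpisode


@pytest.fixture
def simple_session():
    """Two-block, four-partner session with two hand-placed units."""
    blocks = [
        RecordingBlock(0, 0.0, 30.0, frozenset(["f1"])),
        RecordingBlock(1, 30.0, 60.0, frozenset(["m1"])),
        RecordingBlock(2, 60.0, 90.0, frozenset(["f2"])),
        RecordingBlock(3, 90.0, 120.0, frozenset(["m2"])),
    ]
    episodes = [
        TouchEpisode(5.0, 7.0, "f1", "F"),
        TouchEpisode(10.0, 11.5, "f1", "F"),
        TouchEpisode(35.0, 36.0, "m1", "M"),
        TouchEpisode(40.0, 42.5, "m1", "M"),
        TouchEpisode(65.0, 66.0, "f2", "F"),
        TouchEpisode(95.0, 97.0, "m2", "M"),
    ]
    units = {
        "u0": np.sort(np.random.default_rng(0).uniform(0, 120, 600)),
        "u1": np.array([5.2, 5.4, 10.6, 35.5, 41.0, 65.5, 96.0]),
    }
    return Session(
        subject_id="r1", subject_sex="F", area="S1",
        blocks=blocks, episodes=episodes, units=units,
    )


@pytest.fixture(scope="session")
def glm_session():
    """Synthetic session with known GLM coefficients (shared, read-only)."""
    from soctouch.synth import GeneratorParams, generate_session, make_beta

    partners = (("f1", "F"), ("m1", "M"), ("f2", "F"), ("m2", "M"),
                ("f3", "F"), ("m3", "M"), ("f4", "F"), ("m4", "M"))
    params = GeneratorParams(seed=None, n_blocks=8, block_length=30.0,
                             partners=partners)
    betas = {
        "driven": make_beta(np.log(10.0), touch=0.6, sex=0.4,
                            h=[-1.5, -1.0, -0.5, 0, 0, 0, 0, 0, 0, 0, 0]),
        "null": make_beta(np.log(8.0)),
    }
    return generate_session(params, betas, seed=2024), betas
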