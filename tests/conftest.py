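import numpy as np
import pytest

from speckledemix.simulate import (
    EmitterMap,
    OpticalConfig,
    generate_emitters,
    simulate_dataset,
    synthesize_fingerprints,
)


@pytest.fixture(scope="session")
def base_optics() -> OpticalConfig:
    """Small, fast optical configuration shared across tests."""
    return OpticalConfig(
        frame_height=64, frame_width=64, grain_size=3.0, me_range=14.0, seed=0
    )


@pytest.fixture(scope="session")
def pair_factory(base_optics):
    """Factory producing two fingerprints separated by a given (dr, dc)."""

    def make(dr: float, dc: float, seed: int = 0, config: OpticalConfig | None = None):
        cfg = config or OpticalConfig(
            frame_height=base_optics.frame_height,
            frame_width=base_optics.frame_width,
            grain_size=base_optics.grain_size,
            me_range=base_optics.me_range,
            seed=seed,
        )
        em = EmitterMap(
            positions=np.array([[0.0, 0.0], [dr, dc]]), brightness=np.ones(2)
        )
        W = synthesize_fingerprints(em, cfg)
        shape = cfg.frame_shape
        return W[:, 0].reshape(shape), W[:, 1].reshape(shape)

    return make


@pytest.fixture(scope="session")
def small_dataset(base_optics):
    """3 well-separated emitters, noiseless, 300 frames."""
    emitters = generate_emitters(
        3, fov_radius=22, min_separation=14, seed=4
    )
    truth, stack = simulate_dataset(emitters, base_optics, 300)
    return truth, stack
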