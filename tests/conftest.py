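import numpy as np
import pytest

from vfpose.synth import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_records():
    """Small synthetic cohort at reduced resolution, shared across tests."""
    cfg = SynthConfig(
        n_patients=8, min_frames=1, max_frames=3, width=160, height=120, seed=3
    )
    return generate_dataset(cfg)


class ScriptedRng:
    """Stand-in generator that plays back queued values, used to force a
    specific augmentation path."""

    def __init__(self, randoms, uniforms=()):
        self._randoms = list(randoms)
        self._uniforms = list(uniforms)

    def random(self):
        return self._randoms.pop(0)

    def uniform(self, lo, hi, size=None):
        if self._uniforms:
            v = self._uniforms.pop(0)
        else:
            v = (lo + hi) / 2.0
        if size is not None:
            return np.full(size, v)
        return v
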