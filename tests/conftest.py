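import numpy as np
import pandas as pd
import pytest

from timbrefuse import (
    LatentPerceptModel,
    build_stimulus_set,
    synth_ratings,
)
from timbrefuse.synth import DyadSpec


SMALL_DESIGN = {
    "Chinese": {"S+S": 6, "S+N": 6, "N+N": 4},
    "Western": {"S+S": 6, "S+N": 6, "N+N": 4},
}


@pytest.fixture(scope="session")
def small_stimuli():
    """32 synthetic dyads with metadata (session-scoped: audio synthesis)."""
    return build_stimulus_set(SMALL_DESIGN, seed=7)


@pytest.fixture(scope="session")
def small_ratings(small_stimuli):
    _, metadata = small_stimuli
    latent = LatentPerceptModel()
    return synth_ratings(latent, metadata, n_raters=16, seed=11), metadata


@pytest.fixture
def sustained_dyad():
    return DyadSpec(f0_a=220.0, f0_b=440.0, n_harmonics=10,
                    noise_fraction=0.0, seed=5)


def make_sine(freq: float, sr: int = 44100, duration: float = 1.0,
              amp: float = 0.5) -> np.ndarray:
    t = np.arange(int(sr * duration)) / sr
    return amp * np.sin(2 * np.pi * freq * t)
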