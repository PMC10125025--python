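import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # naive_detector, stat oracles

from spikeseq import DetectionConfig, GeneratorSpec, gen_renewal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nowindow_config():
    """Default 1% relative tolerance, no analysis-window requirement."""
    return DetectionConfig(window=None)


@pytest.fixture
def worked_isis():
    """Small ISI series with a single 2-ISI family at indices 0, 2, 5."""
    return np.array([10, 20, 10.05, 20.1, 30, 10.02, 20.05, 40.0])


@pytest.fixture
def gamma_train():
    """Motif-free gamma-renewal train resembling a pallidal cell."""
    return gen_renewal(GeneratorSpec(n_isis=2000, rate=66.6, cv=1.13, seed=7))


def random_isi_series(rng, n, style=None):
    """Random positive ISI series of assorted marginal shapes (oracle tests)."""
    style = rng.integers(0, 4) if style is None else style
    if style == 0:  # exponential-like
        return rng.exponential(15.0, n) + 0.5
    if style == 1:  # regular with jitter: many near-matches
        return 10.0 * (1.0 + 0.02 * rng.standard_normal(n)).clip(0.5)
    if style == 2:  # coarse lattice: ties and exact repeats
        return rng.integers(1, 8, n).astype(float) * 5.0
    return rng.gamma(0.8, 20.0, n) + 0.1  # bursty, high CV
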