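import numpy as np
import pytest

from kernelspec import GeneratorConfig, Hypercube, ReferenceFrames, calibrate, generate_cube


@pytest.fixture
def small_cube():
    """Deterministic 4x5x6 raw cube with round wavelengths."""
    rng = np.random.default_rng(42)
    data = rng.uniform(100, 3000, size=(4, 5, 6)).astype(np.float32)
    return Hypercube(data, np.linspace(400, 1000, 6))


@pytest.fixture
def flat_refs():
    return ReferenceFrames(dark=np.full(6, 100.0), white=np.full(6, 3500.0))


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def one_batch():
    """One calibrated 8-kernel batch (two kernels per variety) + ground truth."""
    cfg = GeneratorConfig()
    raw, refs, truth = generate_cube(cfg, "germ_up", [0, 1, 2, 3, 0, 1, 2, 3], seed=11)
    return calibrate(raw, refs), truth, cfg
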