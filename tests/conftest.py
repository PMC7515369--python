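import numpy as np
import pytest

from entrosig import GeneratorSpec, benchmark_suite, generate_signal


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wgn(rng):
    """One fixed 10 s unit-variance white-noise window at 256 Hz."""
    return rng.normal(size=2560)


@pytest.fixture(scope="session")
def suite():
    """The ten default benchmark signals under one master seed."""
    return benchmark_suite(seed=7)


@pytest.fixture(scope="session")
def logistic_signal():
    return generate_signal(9, GeneratorSpec(seed=0))


@pytest.fixture
def ascii_file(tmp_path):
    """Write samples to a single-column ASCII file and return its path."""

    def _write(samples, name="segment.txt"):
        path = tmp_path / name
        path.write_text("\n".join(f"{v:.10g}" for v in samples) + "\n")
        return path

    return _write
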