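import numpy as np
import pytest

from dseqc.core import RawData, ScaledData, compute_dse_timeseries, scale_center


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def make_scaled(values: np.ndarray) -> ScaledData:
    """Wrap a plain matrix as ScaledData without centering or scaling.

    Used when a test needs exact control over the values entering the
    decomposition (e.g. hand-computed oracles on uncentered toys).
    """
    values = np.asarray(values, dtype=float)
    return ScaledData(
        values=values,
        voxel_means=np.zeros(values.shape[0]),
        overall_mean=1.0,
        scale_mode="none",
    )


def random_scaled(rng, I=None, T=None) -> ScaledData:
    I = I or int(rng.integers(1, 501))
    T = T or int(rng.integers(3, 101))
    scale = rng.uniform(0.1, 50)
    return make_scaled(rng.standard_normal((I, T)) * scale)


@pytest.fixture
def toy_dse():
    """Single voxel [1, 3]: all DSE quantities known by hand."""
    return compute_dse_timeseries(make_scaled([[1.0, 3.0]]))


@pytest.fixture
def centered_gaussian(rng):
    raw = RawData(rng.standard_normal((80, 50)) * 5 + 100)
    return scale_center(raw)
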