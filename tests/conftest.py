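import numpy as np
import pytest
from hypothesis import settings

from cnvpop.core import ProbeMap, RatioMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_probe_map() -> ProbeMap:
    """Ten probes on two chromosomes, 10 kb apart."""
    return ProbeMap(
        np.array([f"p{i}" for i in range(10)], dtype=object),
        np.array(["1"] * 6 + ["2"] * 4, dtype=object),
        np.array([10_000 * (i + 1) for i in range(6)] + [10_000 * (i + 1) for i in range(4)]),
    )


@pytest.fixture
def single_chrom_map() -> ProbeMap:
    return ProbeMap(
        np.array([f"p{i}" for i in range(50)], dtype=object),
        np.array(["1"] * 50, dtype=object),
        np.arange(1, 51) * 20_000,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_ratio_matrix(probe_map: ProbeMap, values: np.ndarray, smoothed=False) -> RatioMatrix:
    subjects = [f"S{i}" for i in range(values.shape[0])]
    return RatioMatrix(subjects, values, probe_map, smoothed=smoothed)
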