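import numpy as np
import pytest

from hrvkit import RRiSeries, TachogramSpec, make_tachogram


@pytest.fixture
def simple_rri() -> RRiSeries:
    """The small hand-computed series used in the worked index examples."""
    return RRiSeries([800.0, 810.0, 790.0, 805.0])


@pytest.fixture
def two_tone_tachogram():
    """900 ms mean with one LF (0.1 Hz, 30 ms) and one HF (0.25 Hz, 20 ms) tone."""
    spec = TachogramSpec(
        duration_s=300.0,
        mean_rri_ms=900.0,
        tones=((0.1, 30.0, 0.0), (0.25, 20.0, 1.0)),
        noise_sd_ms=0.0,
        seed=11,
    )
    return make_tachogram(spec)


def random_rri_values(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """A plausible random tachogram chunk: 400-1400 ms intervals."""
    if n is None:
        n = int(rng.integers(4, 60))
    return rng.uniform(400.0, 1400.0, size=n)
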