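import numpy as np
import pytest

from biflow.decay import DecayHistogram
from biflow.simulate import sample_truncated_exponential

WINDOW = 12.5  # ns, 80 MHz sync period
ADC_BINS = 256


def decay_histogram(
    rng: np.random.Generator,
    n_photons: int,
    lifetimes,
    fractions=None,
    window: float = WINDOW,
    adc_bins: int = ADC_BINS,
) -> DecayHistogram:
    """Histogram of truncated-exponential draws with known component mix."""
    lifetimes = np.atleast_1d(lifetimes).astype(float)
    if fractions is None:
        fractions = np.ones(lifetimes.size) / lifetimes.size
    counts_per = rng.multinomial(n_photons, fractions)
    times = np.concatenate(
        [
            sample_truncated_exponential(rng, tau, window, int(k))
            for tau, k in zip(lifetimes, counts_per)
        ]
    )
    edges = np.linspace(0.0, window, adc_bins + 1)
    counts, _ = np.histogram(times, bins=edges)
    return DecayHistogram(edges=edges, counts=counts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
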