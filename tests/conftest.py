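import numpy as np
import pytest

from phasealign import EpochSet, SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_synth() -> SynthConfig:
    """A small cohort configuration for fast end-to-end tests."""
    return SynthConfig(n_participants=4, n_trials_per_condition=12, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_synth):
    cohort, params = generate_cohort(small_synth)
    return cohort, params


@pytest.fixture()
def clean_synth() -> SynthConfig:
    """Noise-free configuration: every stochastic background component off."""
    return SynthConfig(noise_sigma=0.0, erp_amplitude=0.0, early_amp=0.0,
                       gamma_amp=0.0, seed=0)


def make_epochset(data: np.ndarray, sfreq: float = 100.0,
                  t0: float = -0.5, condition=None,
                  channels=("frontal",)) -> EpochSet:
    """Wrap a raw (epochs, channels, samples) array in an EpochSet."""
    n_ep, _, n_s = data.shape
    if condition is None:
        condition = np.array(["SE", "UE"] * (n_ep // 2 + 1))[:n_ep]
    return EpochSet(
        participant_id="T01", channels=channels, sampling_rate=sfreq,
        times=t0 + np.arange(n_s) / sfreq, data=data,
        condition=np.asarray(condition, dtype=object),
    )
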