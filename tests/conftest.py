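import numpy as np
import pytest

from fogturn import CohortConfig, PhenotypeParams, simulate_trial

FS = 128.0


@pytest.fixture(scope="session")
def freezer_params():
    return PhenotypeParams(is_freezer=True, episode_rate=1.5)


@pytest.fixture(scope="session")
def freezer_trial(freezer_params):
    """A seeded freezer trial with at least one episode."""
    trial, truth = simulate_trial(freezer_params, seed=1, subject_id="freezer")
    assert truth.episodes
    return trial, truth


@pytest.fixture(scope="session")
def nonfreezer_trial():
    trial, truth = simulate_trial(
        PhenotypeParams(is_freezer=False), seed=1, subject_id="control"
    )
    assert not truth.episodes
    return trial, truth


@pytest.fixture(scope="session")
def small_cohort_config():
    return CohortConfig(n_subjects=12, seed=42)


def oracle_psd(x, fs):
    """Independent one-sided periodogram: plain rectangular-window FFT.

    Used as the reference for band-power checks; deliberately avoids the
    implementation's tapered/detrended path.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    X = np.fft.rfft(x)
    psd = (np.abs(X) ** 2) * 2.0 / (fs * n)
    psd[0] /= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, psd


def oracle_band_fraction(x, fs, band):
    """Fraction of total (0..Nyquist) power inside a band, by direct FFT sums."""
    freqs, psd = oracle_psd(x, fs)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    return psd[inside].sum() / psd.sum()
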