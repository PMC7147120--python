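"""Shared fixtures: scaled-down synthetic subjects for fast end-to-end tests.

The generators default to a 512 Hz acquisition rate and 8 channels in unit
tests; the canonical 2048 Hz / 32-channel scale is exercised where a check
is specifically about that scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from envdecode.containers import BANDS, AnalysisConfig, Envelope, MultichannelRecording
from envdecode.preprocess import preprocess_band
from envdecode.synthetic import gen_eeg, gen_envelope, gen_kernel, pink_noise

SYN_FS = 512.0


def make_subject(duration: float = 120.0, n_channels: int = 8,
                 snr_db: float = -10.0, seed: int = 0, band: str = "wide",
                 fs: float = SYN_FS, null_eeg: bool = False):
    """One preprocessed (eeg, envelope) pair at the 64 Hz working rate.

    ``null_eeg=True`` replaces the forward-model EEG with pure pink noise
    independent of the envelope.
    """
    s_env, s_kern, s_eeg = np.random.SeedSequence(seed).spawn(3)
    env = gen_envelope(duration, fs, seed=np.random.default_rng(s_env))
    if null_eeg:
        rng = np.random.default_rng(s_eeg)
        n = int(round(duration * fs))
        labels = [f"ch{i}" for i in range(n_channels)]
        eeg = MultichannelRecording(pink_noise(n, rng, n_channels), fs, labels)
    else:
        kernel = gen_kernel(n_channels, fs, seed=np.random.default_rng(s_kern))
        eeg = gen_eeg(env, kernel, snr_db, seed=np.random.default_rng(s_eeg))
    spec = BANDS[band]
    return preprocess_band(eeg, spec), preprocess_band(env, spec)


@pytest.fixture(scope="session")
def small_cfg() -> AnalysisConfig:
    """Reduced 10-point penalty grid for fast cross-validation sweeps."""
    return AnalysisConfig(lambda_grid=np.logspace(-3, 7, 10))


@pytest.fixture(scope="session")
def entrained_subject():
    """200 s, 8 channels, -10 dB forward-model subject (wideband).

    200 s gives 4 ten-second scoring segments per fold, i.e. 20 pooled pairs,
    enough for the exact signed-rank tail to reach p < 1e-5.
    """
    return make_subject(duration=200.0, seed=11)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
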