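"""Filter design, zero-phase application, referencing, resampling, envelope."""

import numpy as np
import pytest
from scipy import signal as sps

from envdecode.containers import BANDS, BandSpec, Envelope, MultichannelRecording
from envdecode.preprocess import (apply_zero_phase, average_reference,
                                  design_fir, extract_envelope,
                                  preprocess_band, resample_to)


@pytest.mark.parametrize("band,expected_taps", [
    ("delta", 6759),   # 1 Hz minimum transition at 2048 Hz
    ("theta", 3379),   # 2 Hz minimum transition
    ("wide", 6759),    # 1 Hz minimum transition
])
def test_hamming_tap_count_at_2048(band, expected_taps):
    kernel = design_fir(BANDS[band], 2048.0)
    assert kernel.order == expected_taps


@pytest.mark.parametrize("band", list(BANDS))
def test_kernel_is_linear_phase(band):
    c = design_fir(BANDS[band], 512.0).coefficients
    assert len(c) % 2 == 1
    np.testing.assert_allclose(c, c[::-1], rtol=0, atol=1e-12 * np.abs(c).max())


def test_design_rejects_too_low_rate():
    with pytest.raises(ValueError):
        design_fir(BANDS["wide"], 30.0)


def test_kernel_tap_export_round_trips(tmp_path):
    import pandas as pd

    kernel = design_fir(BANDS["theta"], 256.0)
    path = tmp_path / "taps.csv"
    kernel.to_csv(path)
    back = pd.read_csv(path)["tap"].to_numpy()
    np.testing.assert_allclose(back, kernel.coefficients, atol=1e-16)


@pytest.mark.parametrize("band", list(BANDS))
def test_magnitude_response_passband_and_stopband(band):
    spec = BANDS[band]
    kernel = design_fir(spec, 512.0)
    passband = np.linspace(spec.f_lo, spec.f_hi, 40)
    gain_db = 20 * np.log10(np.abs(kernel.frequency_response(passband)))
    assert gain_db.min() > -1.0
    stop = np.array([spec.f_lo - spec.tbw_lo, spec.f_hi + spec.tbw_hi])
    stop_db = 20 * np.log10(np.abs(kernel.frequency_response(stop)))
    assert stop_db.max() < -40.0


def test_zero_phase_impulse_stays_put():
    kernel = design_fir(BANDS["theta"], 256.0)
    n, pos = 4096, 2000
    x = np.zeros(n)
    x[pos] = 1.0
    y = apply_zero_phase(kernel, x)
    assert y.size == n
    assert np.argmax(np.abs(y)) == pos


def test_zero_phase_kills_dc():
    kernel = design_fir(BANDS["delta"], 256.0)
    x = np.ones(6000)
    y = apply_zero_phase(kernel, x)
    edge = kernel.order // 2
    assert np.abs(y[edge:-edge]).max() < 1e-3


def test_zero_phase_preserves_passband_tone_per_frequency_response():
    fs = 512.0
    kernel = design_fir(BANDS["delta"], fs)
    gain = np.abs(kernel.frequency_response(np.array([2.5])))[0]
    assert gain == pytest.approx(1.0, abs=0.02)
    t = np.arange(int(20 * fs)) / fs
    x = np.sin(2 * np.pi * 2.5 * t)
    y = apply_zero_phase(kernel, x)
    center = slice(kernel.order, y.size - kernel.order)
    measured = np.abs(y[center]).max()
    assert measured == pytest.approx(gain, rel=0.02)


def test_zero_phase_output_peaks_at_zero_lag():
    # cross-correlation of band-limited input and its filtered copy peaks at 0
    rng = np.random.default_rng(0)
    fs = 256.0
    kernel = design_fir(BANDS["theta"], fs)
    x = sps.sosfiltfilt(sps.butter(4, [4, 8], btype="bandpass", fs=fs,
                                   output="sos"),
                        rng.standard_normal(int(60 * fs)))
    y = apply_zero_phase(kernel, x)
    edge = kernel.order
    xc, yc = x[edge:-edge], y[edge:-edge]
    lags = np.arange(-20, 21)
    corr = [np.corrcoef(xc[20 + k:len(xc) - 20 + k], yc[20:-20])[0, 1]
            for k in lags]
    assert lags[int(np.argmax(corr))] == 0


def test_zero_phase_requires_signal_longer_than_kernel():
    kernel = design_fir(BANDS["theta"], 256.0)
    with pytest.raises(ValueError):
        apply_zero_phase(kernel, np.zeros(kernel.order))


def test_zero_phase_filters_each_channel_of_a_matrix():
    kernel = design_fir(BANDS["theta"], 256.0)
    rng = np.random.default_rng(3)
    x = rng.standard_normal((3, 5000))
    y = apply_zero_phase(kernel, x)
    np.testing.assert_allclose(y[1], apply_zero_phase(kernel, x[1]), atol=1e-12)


@pytest.mark.parametrize("case", ["antisymmetric", "identical", "random"])
def test_average_reference(case):
    rng = np.random.default_rng(5)
    if case == "antisymmetric":
        v = rng.standard_normal(100)
        data = np.stack([v, -v])
    elif case == "identical":
        data = np.tile(rng.standard_normal(100), (3, 1))
    else:
        data = rng.standard_normal((4, 100))
    rec = MultichannelRecording(data, 64.0, [f"c{i}" for i in range(len(data))])
    out = average_reference(rec)
    np.testing.assert_allclose(out.data.mean(axis=0), 0, atol=1e-12)
    if case == "antisymmetric":
        np.testing.assert_allclose(out.data, data, atol=1e-12)
    if case == "identical":
        np.testing.assert_allclose(out.data, 0, atol=1e-12)


def test_resample_length_and_constant():
    assert resample_to(np.ones(2048), 2048, 64).size == 64
    np.testing.assert_allclose(resample_to(np.ones(2048), 2048, 64), 1.0,
                               rtol=1e-6)


def test_resample_preserves_slow_sinusoid():
    fs_in, fs_out = 2048.0, 64.0
    t_in = np.arange(int(30 * fs_in)) / fs_in
    y = resample_to(np.sin(2 * np.pi * 5 * t_in), fs_in, fs_out)
    t_out = np.arange(y.size) / fs_out
    ref = np.sin(2 * np.pi * 5 * t_out)
    sl = slice(64, y.size - 64)
    r = np.corrcoef(y[sl], ref[sl])[0, 1]
    assert r > 0.999


def test_resample_refuses_upsampling():
    with pytest.raises(ValueError):
        resample_to(np.ones(100), 64, 2048)


def test_envelope_of_pure_tone_is_its_amplitude():
    fs = 44100.0
    t = np.arange(int(0.5 * fs)) / fs
    env = extract_envelope(0.5 * np.sin(2 * np.pi * 1000 * t), fs=fs)
    core = env.samples[1000:-1000]
    assert np.all(np.abs(core - 0.5) < 0.005)
    assert env.samples.min() >= 0


def test_envelope_recovers_am_modulator():
    fs = 44100.0
    t = np.arange(int(2 * fs)) / fs
    modulator = 1 + 0.5 * np.sin(2 * np.pi * 4 * t)
    env = extract_envelope(modulator * np.sin(2 * np.pi * 1000 * t), fs=fs)
    sl = slice(2000, env.samples.size - 2000)
    r = np.corrcoef(env.samples[sl], modulator[sl])[0, 1]
    assert r > 0.99


def test_envelope_degenerate_inputs():
    env = extract_envelope(np.zeros(1000), fs=100.0)
    np.testing.assert_allclose(env.samples, 0)
    with pytest.raises(ValueError):
        extract_envelope(np.empty(0), fs=100.0)


def test_preprocess_band_length_arithmetic():
    env = Envelope(np.abs(np.random.default_rng(0).standard_normal(int(60 * 512))),
                   512.0)
    out = preprocess_band(env, BANDS["delta"])
    assert out.n_samples == round(60 * 64)
    assert out.fs == 64.0


def test_preprocess_band_concentrates_power_in_band():
    rng = np.random.default_rng(1)
    env = Envelope(np.abs(rng.standard_normal(int(120 * 512))), 512.0)
    out = preprocess_band(env, BANDS["delta"])
    # Hann-windowed Welch estimate: a boxcar periodogram would smear the
    # sharp band edges and understate the in-band fraction
    f, p = sps.welch(out.samples, fs=out.fs, nperseg=2048, window="hann")
    inband = p[(f >= 0.5) & (f <= 5)].sum()
    assert inband / p.sum() > 0.95


def test_processing_commutes_with_time_reversal():
    rng = np.random.default_rng(2)
    # length 1 mod 8 puts the reversed 512->64 Hz polyphase grid exactly one
    # output sample off the forward grid; align and compare
    env = Envelope(np.abs(rng.standard_normal(90 * 512 + 1)), 512.0)
    fwd_then_rev = preprocess_band(env, BANDS["delta"]).samples[::-1]
    rev_first = preprocess_band(Envelope(env.samples[::-1].copy(), 512.0),
                                BANDS["delta"]).samples
    m = 64
    a = fwd_then_rev[m - 1:fwd_then_rev.size - m - 1]
    b = rev_first[m:rev_first.size - m]
    scale = np.abs(a).max()
    np.testing.assert_allclose(b, a, atol=1e-9 * scale)


def test_eeg_and_envelope_share_one_code_path():
    # the same samples sent through the EEG path (minus referencing) and the
    # envelope path must come out identical
    rng = np.random.default_rng(4)
    x = np.abs(rng.standard_normal(int(60 * 512)))
    data = np.stack([x, -x])  # zero-mean across channels: referencing is a no-op
    rec = MultichannelRecording(data, 512.0, ["a", "b"])
    env = Envelope(x, 512.0)
    rec_out = preprocess_band(rec, BANDS["theta"])
    env_out = preprocess_band(env, BANDS["theta"])
    np.testing.assert_allclose(rec_out.data[0], env_out.samples, atol=1e-10)
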