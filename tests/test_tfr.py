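import numpy as np
import pytest

import betarebound as br
from betarebound.tfr import TFRError, kernel_sigma_s, ersp_from_power


SPEC = br.MorletSpec()


def test_cycle_ramp_anchors_and_midpoint():
    assert br.wavelet_cycles(4.0) == pytest.approx(3.0)
    assert br.wavelet_cycles(40.0) == pytest.approx(20.0)
    assert br.wavelet_cycles(22.0) == pytest.approx(11.5)
    with pytest.raises(TFRError):
        br.wavelet_cycles(3.0)
    with pytest.raises(TFRError):
        br.wavelet_cycles(41.0)


def test_frequency_grid_is_half_hz_73_rows():
    freqs = SPEC.freqs_hz
    assert len(freqs) == 73
    assert freqs[0] == 4.0 and freqs[-1] == 40.0
    assert np.allclose(np.diff(freqs), 0.5)
    # cycle count strictly increasing and linear in frequency
    n = br.wavelet_cycles(freqs)
    assert (np.diff(n) > 0).all()
    assert np.allclose(np.diff(n, 2), 0.0, atol=1e-12)


def test_spectral_transform_matches_direct_convolution():
    """FFT-based path equals brute-force time-domain convolution."""
    sfreq = 250.0
    rng = np.random.default_rng(12)
    n = int(2.0 * sfreq)
    x = rng.standard_normal(n)
    times = np.arange(n) / sfreq - 1.0
    spec = br.MorletSpec(output_window_ms=(-300.0, 300.0))
    coefs, out_times = br.morlet_transform(x, spec, sfreq, times_s=times)
    keep = (times >= out_times[0] - 1e-9) & (times <= out_times[-1] + 1e-9)
    worst = 0.0
    for i, f in enumerate(spec.freqs_hz):
        kern = br.morlet_kernel(f, br.wavelet_cycles(f, spec), sfreq,
                                spec.kernel_sigmas)
        direct = np.convolve(x, kern, mode="same")[keep]
        err = np.abs(direct - coefs[i]).max() / np.abs(direct).max()
        worst = max(worst, err)
    assert worst < 1e-9


def test_zero_input_gives_zero_coefficients():
    sfreq = 250.0
    x = np.zeros(1000)
    times = np.arange(1000) / sfreq - 1.5
    coefs, _ = br.morlet_transform(x, SPEC, sfreq, times_s=times)
    assert np.all(coefs == 0)


def test_pure_tone_power_peaks_at_its_frequency():
    sfreq = 250.0
    times = np.arange(1000) / sfreq - 1.5
    x = np.cos(2 * np.pi * 10.0 * times)
    coefs, _ = br.morlet_transform(x, SPEC, sfreq, times_s=times)
    power = (np.abs(coefs) ** 2).mean(axis=1)
    i_peak = int(np.argmax(power))
    assert SPEC.freqs_hz[i_peak] == pytest.approx(10.0, abs=0.5)
    # symmetric falloff around the peak
    assert power[i_peak - 4] == pytest.approx(power[i_peak + 4], rel=0.25)


def test_kernel_duration_strictly_decreasing():
    sig = kernel_sigma_s(SPEC.freqs_hz, SPEC)
    assert (np.diff(sig) < 0).all()


def test_epoch_too_short_raises_with_frequency():
    sfreq = 250.0
    x = np.zeros(300)
    times = np.arange(300) / sfreq - 0.6
    with pytest.raises(TFRError, match="4 Hz"):
        br.morlet_transform(x, br.MorletSpec(output_window_ms=(-500, 500)),
                            sfreq, times_s=times)


def _toy_epochs(n_trials, gen, sfreq=250.0, seed=0):
    """Build an EpochsArray from a per-trial generator ``gen(rng, times)``."""
    import mne

    rng = np.random.default_rng(seed)
    times = np.arange(int(4.0 * sfreq)) / sfreq - 1.5
    data = np.stack([gen(rng, times)[None, :] for _ in range(n_trials)])
    info = mne.create_info(["C3"], sfreq, ["eeg"])
    return mne.EpochsArray(data * 1e-6, info, tmin=-1.5, verbose="error")


def test_stationary_signal_reads_zero_db():
    epochs = _toy_epochs(100, lambda rng, t: rng.standard_normal(len(t)))
    m = br.compute_ersp(epochs, "C3")
    assert np.abs(m.values.mean()) < 0.2


def test_amplitude_halving_reads_minus_six_db():
    def gen(rng, t):
        amp = np.where(t < 0, 1.0, 0.5)
        return amp * np.cos(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))

    epochs = _toy_epochs(40, gen)
    m = br.compute_ersp(epochs, "C3")
    row = np.argmin(np.abs(m.freqs_hz - 10.0))
    window = (m.times_ms > 300) & (m.times_ms < 900)
    assert m.values[row][window].mean() == pytest.approx(-6.02, abs=0.3)


def test_ersp_invariant_to_constant_gain():
    epochs = _toy_epochs(20, lambda rng, t: rng.standard_normal(len(t)))
    m1 = br.compute_ersp(epochs, "C3")
    scaled = _toy_epochs(20, lambda rng, t: 37.5 * rng.standard_normal(len(t)))
    m2 = br.compute_ersp(scaled, "C3")
    np.testing.assert_allclose(m1.values, m2.values, atol=1e-9)


def test_zero_baseline_power_rejected():
    power = np.zeros((3, 5, 11))
    with pytest.raises(TFRError):
        ersp_from_power(power, np.linspace(-1000, 1000, 11), (-1000, -150))


def test_roi_average_requires_all_channels():
    m = br.TimeFreqMap(np.ones((3, 4)), [8, 9, 10], [0, 1, 2, 3], label="C1")
    out = br.roi_average({"C1": m, "C3": m}, ["C1", "C3"])
    np.testing.assert_allclose(out.values, m.values)
    with pytest.raises(TFRError, match="C5"):
        br.roi_average({"C1": m, "C3": m}, ["C1", "C3", "C5"])


def test_subject_and_roi_averaging_commute():
    rng = np.random.default_rng(3)
    grids = dict(freqs_hz=np.arange(8, 13.0), times_ms=np.arange(5.0))
    subj_ch = [
        {c: br.TimeFreqMap(rng.standard_normal((5, 5)), label=c, **grids)
         for c in ("C1", "C3")}
        for _ in range(4)
    ]
    roi_then_group = np.mean(
        [br.roi_average(m, ["C1", "C3"]).values for m in subj_ch], axis=0
    )
    group_then_roi = np.mean(
        [np.mean([subj_ch[s][c].values for s in range(4)], axis=0)
         for c in ("C1", "C3")], axis=0,
    )
    np.testing.assert_allclose(roi_then_group, group_then_roi, atol=1e-12)


def test_roi_voltage_first_mode_runs(preprocessed):
    _, epochs, _ = preprocessed
    sub = epochs[:6]
    m = br.compute_roi_ersp(sub, ("C1", "C3", "C5"), mode="average_voltage")
    assert m.values.shape == (73, 501)
    with pytest.raises(TFRError):
        br.compute_roi_ersp(sub, ("C1", "C9"))


def test_map_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    m = br.TimeFreqMap(rng.standard_normal((4, 6)), np.arange(8, 12.0),
                       np.linspace(-100, 100, 6), label="left")
    path = tmp_path / "map.tsv"
    m.to_tsv(path)
    back = br.TimeFreqMap.from_tsv(path)
    assert back.label == "left"
    np.testing.assert_allclose(back.values, m.values, rtol=1e-5)
    np.testing.assert_allclose(back.freqs_hz, m.freqs_hz)
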