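import numpy as np
import pytest

import betarebound as br
from betarebound.simulate import (
    SimulationError,
    _envelope_profile,
    pink_noise,
)


def _band_power(raw, design, channel, window_s, condition=None):
    """Mean squared analytic amplitude of one channel in a per-trial window.

    The Hilbert envelope tracks the oscillator's (deterministic) amplitude
    exactly on noise-free signals, unlike a short-window average of the
    squared voltage, which fluctuates with the oscillator phase.
    """
    from scipy.signal import hilbert

    sfreq = raw.info["sfreq"]
    x = raw.get_data(picks=[channel])[0]
    env = np.abs(hilbert(x))
    sel = design if condition is None else design.query(condition)
    vals = []
    for onset in sel["vowel_onset_s"]:
        i0 = int((onset + window_s[0]) * sfreq)
        i1 = int((onset + window_s[1]) * sfreq)
        vals.append(np.mean(env[i0:i1] ** 2))
    return float(np.mean(vals))


@pytest.fixture(scope="module")
def clean_cfg():
    """Deterministic-envelope configuration: single beta oscillator, no noise."""
    return br.SimConfig(
        noise_1f_amp=0.0, eog_noise_amp=0.0, mu_amp=0.0,
        trial_amp_sd=0.0, subject_sd=0.0,
    )


def test_marker_counts(simulated_subject, small_design):
    raw, design, _ = simulated_subject
    desc = list(raw.annotations.description)
    n_stim = (design.stimulation == "present").sum()
    assert desc.count("vowel") == len(design)
    assert desc.count("stimulation") == n_stim
    assert desc.count("question") == len(design)


def test_same_seed_bit_identical(small_design, sim_cfg):
    a = br.simulate_recording(small_design, sim_cfg, subject_seed=4)
    b = br.simulate_recording(small_design, sim_cfg, subject_seed=4)
    assert np.array_equal(a.get_data(), b.get_data())
    c = br.simulate_recording(small_design, sim_cfg, subject_seed=5)
    assert not np.array_equal(a.get_data(), c.get_data())


def test_ers_window_power_ratio_matches_squared_gain(small_design, clean_cfg):
    """Constant-envelope oscillator: ERS/baseline power ratio = ers_gain^2."""
    raw = br.simulate_recording(small_design, clean_cfg, subject_seed=9)
    # mid-plateau windows, clear of the raised-cosine ramps; dental trials
    # with stimulation carry the full (unattenuated) rebound gain
    ers = _band_power(raw, small_design, "C3", (0.575, 0.725),
                      "syllable == 'dental' and stimulation == 'present'")
    base = _band_power(raw, small_design, "C3", (-0.9, -0.4),
                       "syllable == 'dental' and stimulation == 'present'")
    assert ers / base == pytest.approx(clean_cfg.ers_gain**2, rel=0.01)


def test_no_attenuation_means_no_syllable_difference(small_design, clean_cfg):
    import dataclasses

    cfg = dataclasses.replace(clean_cfg, rebound_attenuation=0.0)
    raw = br.simulate_recording(small_design, cfg, subject_seed=9)
    p_bi = _band_power(raw, small_design, "C3", (0.575, 0.725),
                       "syllable == 'bilabial' and stimulation == 'present'")
    p_de = _band_power(raw, small_design, "C3", (0.575, 0.725),
                       "syllable == 'dental' and stimulation == 'present'")
    assert p_bi == pytest.approx(p_de, rel=0.01)


def test_attenuation_confined_to_left_roi(small_design, clean_cfg):
    """Zero right-hemisphere weights: syllable contrast exists only on the left."""
    raw = br.simulate_recording(small_design, clean_cfg, subject_seed=9)
    for ch in ("C1", "C3", "C5"):
        p_bi = _band_power(raw, small_design, ch, (0.575, 0.725),
                           "syllable == 'bilabial' and stimulation == 'present'")
        p_de = _band_power(raw, small_design, ch, (0.575, 0.725),
                           "syllable == 'dental' and stimulation == 'present'")
        assert p_bi < 0.8 * p_de
    for ch in ("C2", "C4", "C6"):
        p_bi = _band_power(raw, small_design, ch, (0.575, 0.725),
                           "syllable == 'bilabial' and stimulation == 'present'")
        p_de = _band_power(raw, small_design, ch, (0.575, 0.725),
                           "syllable == 'dental' and stimulation == 'present'")
        assert p_bi == pytest.approx(p_de, rel=0.01)


def test_envelope_profile_plateaus_and_baseline():
    t = np.linspace(-1.0, 1.5, 2501)
    g = _envelope_profile(t, (0.2, 0.4), 0.5, (0.5, 0.8), 1.8, 0.05)
    assert np.allclose(g[t < 0.1], 1.0)
    assert np.allclose(g[(t > 0.25) & (t < 0.35)], 0.5)
    assert np.allclose(g[(t > 0.55) & (t < 0.75)], 1.8)
    assert np.allclose(g[t > 0.9], 1.0)


def test_pink_noise_spectrum_slope():
    rng = np.random.default_rng(0)
    x = pink_noise(2**16, 500.0, rng)
    f = np.fft.rfftfreq(len(x), 1 / 500.0)
    psd = np.abs(np.fft.rfft(x)) ** 2
    lo = psd[(f > 1) & (f < 4)].mean()
    hi = psd[(f > 40) & (f < 160)].mean()
    # power ~ 1/f: a 40x frequency ratio gives roughly 40x power ratio
    assert 10 < lo / hi < 160


def test_missing_montage_channel_rejected():
    with pytest.raises(SimulationError):
        br.SimConfig(montage=("C1", "C3", "C5", "Cz", "EOGL", "EOGR"))
    with pytest.raises(SimulationError):
        br.SimConfig(rebound_attenuation=1.5)
    with pytest.raises(SimulationError):
        br.SimConfig(erd_gain=0.0)


def test_total_duration_tracks_generated_intervals(small_design, sim_cfg):
    raw = br.simulate_recording(small_design, sim_cfg, subject_seed=2)
    last_q = small_design.question_onset_s.iloc[-1]
    assert raw.times[-1] == pytest.approx(last_q + 4.0, abs=0.05)
    # and the final marker sits where the design says it should
    q_marks = [o for o, d in zip(raw.annotations.onset,
                                 raw.annotations.description)
               if d == "question"]
    assert max(q_marks) == pytest.approx(last_q, abs=1e-6)


def test_dataset_counterbalances_response_sides(small_design_cfg, sim_cfg):
    import dataclasses

    cfg = dataclasses.replace(sim_cfg, n_subjects=2)
    designs = [
        design for _, design, _ in br.simulate_dataset(
            small_design_cfg, cfg, master_seed=1
        )
    ]
    side0 = designs[0].query("question_polarity == 'positive'")
    side1 = designs[1].query("question_polarity == 'positive'")
    assert set(side0.true_response_side) == {"right"}
    assert set(side1.true_response_side) == {"left"}
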