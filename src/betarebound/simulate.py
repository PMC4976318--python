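"""Synthetic continuous EEG/EOG with event-locked mu/beta ERD-ERS dynamics.

The generator embodies the statistical structure the downstream analysis
assumes: 1/f background noise on every channel, narrowband mu (~10 Hz) and
beta (~20 Hz) oscillators over the six central electrodes whose envelopes
drop below baseline after the event (ERD) and then rebound above it (ERS),
a place-of-articulation-specific attenuation of the *beta* rebound on
bilabial trials with lip stimulation (weighted toward the left central
electrodes), and horizontal-EOG saccade responses to the identification
question.  Oscillators are narrowband via a slow random frequency drift,
hence non-phase-locked across trials: the ERD/ERS appears in induced power
only.

All amplitudes are in microvolts; the returned :class:`mne.io.Raw` holds
volts, as MNE expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import mne
import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from betarebound.design import DesignConfig, build_design

CENTRAL_CHANNELS = ("C1", "C3", "C5", "C2", "C4", "C6")
LEFT_ROI = ("C1", "C3", "C5")
RIGHT_ROI = ("C2", "C4", "C6")


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of the synthetic recording generator.

    Signal amplitudes are microvolt SDs.  ``erd_gain``/``ers_gain`` multiply
    the oscillator envelope inside the respective post-event windows
    (baseline gain is 1); ``rebound_attenuation`` shrinks the beta ERS
    excursion ``(ers_gain - 1)`` on bilabial+stimulation trials, scaled per
    channel by ``left_lateralization``.  Stimulation-absent trials receive
    the same ERD/ERS profile scaled by ``no_stim_effect_scale``, emulating
    the weaker modulation driven by the auditory event alone.
    """

    n_subjects: int = 12
    sfreq_hz: float = 500.0
    montage: tuple[str, ...] = (
        "C1", "C3", "C5", "C2", "C4", "C6", "Cz", "Pz", "EOGL", "EOGR",
    )
    eog_channels: tuple[str, str] = ("EOGL", "EOGR")
    noise_1f_amp: float = 8.0
    eog_noise_amp: float = 5.0
    mu_freq_hz: float = 10.0
    beta_freq_hz: float = 20.0
    mu_amp: float = 5.0
    beta_amp: float = 4.0
    #: SD (Hz) of the oscillator's slow frequency drift; sets the linewidth
    freq_drift_sd_hz: float = 0.75
    #: bandwidth (Hz) of the frequency drift (kept << the carrier so the
    #: oscillator stays narrowband with a constant unit envelope)
    freq_drift_bw_hz: float = 2.0
    erd_window_ms: tuple[float, float] = (200.0, 400.0)
    erd_gain: float = 0.6
    ers_window_ms: tuple[float, float] = (500.0, 800.0)
    ers_gain: float = 1.75
    rebound_attenuation: float = 0.8
    #: fraction of the ERD/ERS envelope excursion retained without stimulation
    no_stim_effect_scale: float = 0.4
    left_lateralization: Mapping[str, float] = field(
        default_factory=lambda: {
            "C1": 1.0, "C3": 1.0, "C5": 1.0, "C2": 0.0, "C4": 0.0, "C6": 0.0,
        }
    )
    #: raised-cosine ramp length for envelope transitions
    ramp_ms: float = 50.0
    #: lognormal SD of the per-trial oscillator amplitude jitter
    trial_amp_sd: float = 0.2
    #: SD of the per-subject scaling of all envelope excursions
    subject_sd: float = 0.25
    saccade_amp: float = 60.0
    saccade_amp_sd: float = 10.0
    saccade_latency_ms: float = 531.0
    saccade_latency_sd_ms: float = 80.0
    #: positive questions are answered faster by this many ms (+/- half each)
    saccade_polarity_effect_ms: float = 49.0
    #: stimulation speeds responses by this many ms (+/- half each)
    saccade_stim_effect_ms: float = 22.0
    saccade_hold_ms: float = 500.0
    incorrect_rate: float = 0.131
    line_noise_amp: float = 0.0
    line_freq_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in CENTRAL_CHANNELS if c not in self.montage]
        missing += [c for c in self.eog_channels if c not in self.montage]
        if missing:
            raise SimulationError(f"montage is missing channels: {missing}")
        if len(self.eog_channels) != 2:
            raise SimulationError("exactly two EOG channels are required")
        if self.erd_gain <= 0 or self.ers_gain <= 0:
            raise SimulationError("envelope gains must be strictly positive")
        if not 0.0 <= self.rebound_attenuation <= 1.0:
            raise SimulationError("rebound_attenuation must lie in [0, 1]")
        if any(w < 0 for w in self.left_lateralization.values()):
            raise SimulationError("lateralization weights must be non-negative")
        if not 0.0 <= self.incorrect_rate < 1.0:
            raise SimulationError("incorrect_rate must lie in [0, 1)")

    @property
    def eeg_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.montage if c not in self.eog_channels)


def _raised_cosine_step(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Smooth 0 -> 1 transition centred on ``t0`` over ``width`` seconds."""
    if width <= 0:
        return (t >= t0).astype(float)
    x = np.clip((t - (t0 - width / 2)) / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _envelope_profile(
    t: np.ndarray,
    erd_win: tuple[float, float],
    erd_gain: float,
    ers_win: tuple[float, float],
    ers_gain: float,
    ramp_s: float,
) -> np.ndarray:
    """Piecewise-constant envelope (1 / erd / ers / 1) with raised-cosine ramps.

    Plateaus span the stated windows exactly; each transition is centred on
    the window edge so the plateau value is reached half a ramp inside it.
    """
    g = np.ones_like(t)
    g += (erd_gain - 1.0) * (
        _raised_cosine_step(t, erd_win[0], ramp_s)
        - _raised_cosine_step(t, erd_win[1], ramp_s)
    )
    g += (ers_gain - 1.0) * (
        _raised_cosine_step(t, ers_win[0], ramp_s)
        - _raised_cosine_step(t, ers_win[1], ramp_s)
    )
    return g


def pink_noise(n_samples: int, sfreq: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise of unit variance, by spectral shaping of white noise."""
    m = sp_fft.next_fast_len(n_samples)  # pad to an FFT-friendly length
    white = rng.standard_normal(m)
    spec = sp_fft.rfft(white)
    f = np.fft.rfftfreq(m, d=1.0 / sfreq)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])  # amplitude ~ f^-1/2 => power ~ 1/f
    x = sp_fft.irfft(spec * shape, n=m)[:n_samples]
    sd = x.std()
    return x / sd if sd > 0 else x


def _drifting_oscillator(
    n_samples: int, sfreq: float, freq: float, drift_sd: float,
    drift_bw: float, rng: np.random.Generator,
) -> np.ndarray:
    """Unit-envelope cosine whose frequency wanders slowly around ``freq``.

    The instantaneous frequency is ``freq`` plus band-limited Gaussian noise
    (SD ``drift_sd`` Hz, bandwidth ``drift_bw`` Hz).  Integrating that drift
    decorrelates the phase across trials (non-phase-locked) while the
    amplitude stays exactly constant.
    """
    m = sp_fft.next_fast_len(n_samples)
    white = rng.standard_normal(m)
    if drift_sd > 0 and drift_bw > 0:
        spec = sp_fft.rfft(white)
        f = np.fft.rfftfreq(m, d=1.0 / sfreq)
        spec[f > drift_bw] = 0.0
        drift = sp_fft.irfft(spec, n=m)[:n_samples]
        sd = drift.std()
        drift = drift * (drift_sd / sd) if sd > 0 else drift
    else:
        drift = np.zeros(n_samples)
    phase = 2 * np.pi * np.cumsum(freq + drift) / sfreq
    phase += rng.uniform(0, 2 * np.pi)
    return np.cos(phase)


def _saccade_pulse(
    t: np.ndarray, onset: float, hold_s: float, rise_s: float = 0.03
) -> np.ndarray:
    """Unit step-and-return deflection: rise at onset, return after the hold."""
    return _raised_cosine_step(t, onset + rise_s / 2, rise_s) - _raised_cosine_step(
        t, onset + hold_s + rise_s / 2, rise_s
    )


def simulate_recording(
    design: pd.DataFrame,
    cfg: SimConfig,
    subject_seed: int,
    *,
    behavior_out: dict | None = None,
) -> mne.io.BaseRaw:
    """Simulate one subject's continuous recording for a given trial table.

    Event markers are written as annotations: ``vowel`` at each vowel onset,
    ``stimulation`` at vowel onset on stimulation-present trials, and
    ``question`` at question onset.  If ``behavior_out`` is a dict it
    receives the ground-truth executed saccade metadata (side, latency).
    """
    if len(design) == 0:
        raise SimulationError("design table is empty")
    rng = np.random.default_rng(subject_seed)
    sfreq = cfg.sfreq_hz
    t_end = float(design["question_onset_s"].max()) + 4.0
    n_samples = int(round(t_end * sfreq))
    t = np.arange(n_samples) / sfreq

    ch_names = list(cfg.montage)
    data = np.zeros((len(ch_names), n_samples))

    # subject-level scaling of every envelope excursion (effect heterogeneity)
    subj_scale = max(0.0, 1.0 + rng.standard_normal() * cfg.subject_sd)

    onsets = design["vowel_onset_s"].to_numpy(float)
    is_stim = (design["stimulation"] == "present").to_numpy()
    is_bilabial = (design["syllable"] == "bilabial").to_numpy()
    ramp_s = cfg.ramp_ms / 1000.0
    erd_win = (cfg.erd_window_ms[0] / 1000.0, cfg.erd_window_ms[1] / 1000.0)
    ers_win = (cfg.ers_window_ms[0] / 1000.0, cfg.ers_window_ms[1] / 1000.0)

    # per-trial oscillator amplitude jitter, shared across channels and bands
    amp_jitter = np.exp(rng.standard_normal(len(design)) * cfg.trial_amp_sd)

    seg_pre = 0.3  # envelope support before vowel onset, seconds
    seg_post = ers_win[1] + ramp_s + 0.3

    for ch_idx, name in enumerate(ch_names):
        if name in cfg.eog_channels:
            continue
        if name in CENTRAL_CHANNELS:
            w_lat = float(cfg.left_lateralization.get(name, 0.0))
            for band_amp, band_freq, attenuable in (
                (cfg.mu_amp, cfg.mu_freq_hz, False),
                (cfg.beta_amp, cfg.beta_freq_hz, True),
            ):
                if band_amp <= 0:
                    continue
                osc = _drifting_oscillator(
                    n_samples, sfreq, band_freq, cfg.freq_drift_sd_hz,
                    cfg.freq_drift_bw_hz, rng,
                )
                env = np.ones(n_samples)
                for k, onset in enumerate(onsets):
                    scale = subj_scale * (
                        1.0 if is_stim[k] else cfg.no_stim_effect_scale
                    )
                    erd_g = 1.0 + (cfg.erd_gain - 1.0) * scale
                    ers_excursion = (cfg.ers_gain - 1.0) * scale
                    if attenuable and is_stim[k] and is_bilabial[k]:
                        # the attenuated *fraction* of the rebound is a fixed
                        # property of the condition; its absolute size still
                        # scales with the subject's rebound via subj_scale
                        ers_excursion *= 1.0 - cfg.rebound_attenuation * w_lat
                    ers_g = 1.0 + ers_excursion
                    i0 = max(0, int((onset - seg_pre) * sfreq))
                    i1 = min(n_samples, int((onset + seg_post) * sfreq))
                    tt = t[i0:i1] - onset
                    profile = _envelope_profile(
                        tt, erd_win, erd_g, ers_win, ers_g, ramp_s
                    )
                    # per-trial amplitude jitter, faded in/out at the segment
                    # edges so it causes no envelope discontinuity
                    fade = _raised_cosine_step(
                        tt, tt[0] + ramp_s, ramp_s
                    ) - _raised_cosine_step(tt, tt[-1] - ramp_s, ramp_s)
                    env[i0:i1] = profile * (1.0 + (amp_jitter[k] - 1.0) * fade)
                data[ch_idx] += band_amp * env * osc
        if cfg.noise_1f_amp > 0:
            data[ch_idx] += cfg.noise_1f_amp * pink_noise(n_samples, sfreq, rng)
        if cfg.line_noise_amp > 0:
            data[ch_idx] += cfg.line_noise_amp * np.sin(
                2 * np.pi * cfg.line_freq_hz * t + rng.uniform(0, 2 * np.pi)
            )

    # --- EOG: saccadic step responses to the question -----------------------
    q_onsets = design["question_onset_s"].to_numpy(float)
    true_side = design["true_response_side"].to_numpy()
    is_positive = (design["question_polarity"] == "positive").to_numpy()
    flip = rng.random(len(design)) < cfg.incorrect_rate
    exec_side = np.where(
        flip, np.where(true_side == "left", "right", "left"), true_side
    )
    latency = (
        cfg.saccade_latency_ms
        + np.where(is_positive, -0.5, 0.5) * cfg.saccade_polarity_effect_ms
        + np.where(is_stim, -0.5, 0.5) * cfg.saccade_stim_effect_ms
        + rng.standard_normal(len(design)) * cfg.saccade_latency_sd_ms
    )
    latency = np.maximum(latency, 180.0) / 1000.0
    amp = np.maximum(
        cfg.saccade_amp + rng.standard_normal(len(design)) * cfg.saccade_amp_sd,
        cfg.saccade_amp * 0.3,
    )

    i_left = ch_names.index(cfg.eog_channels[0])
    i_right = ch_names.index(cfg.eog_channels[1])
    eog_diff = np.zeros(n_samples)  # right - left electrode
    hold_s = cfg.saccade_hold_ms / 1000.0
    for k in range(len(design)):
        onset = q_onsets[k] + latency[k]
        i0 = max(0, int((onset - 0.1) * sfreq))
        i1 = min(n_samples, int((onset + hold_s + 0.2) * sfreq))
        sign = 1.0 if exec_side[k] == "right" else -1.0
        eog_diff[i0:i1] += sign * amp[k] * _saccade_pulse(t[i0:i1], onset, hold_s)
    data[i_right] += eog_diff / 2
    data[i_left] -= eog_diff / 2
    if cfg.eog_noise_amp > 0:
        data[i_left] += cfg.eog_noise_amp * pink_noise(n_samples, sfreq, rng)
        data[i_right] += cfg.eog_noise_amp * pink_noise(n_samples, sfreq, rng)

    if behavior_out is not None:
        behavior_out["executed_side"] = exec_side
        behavior_out["latency_ms"] = latency * 1000.0
        behavior_out["flipped"] = flip

    ch_types = [
        "eog" if name in cfg.eog_channels else "eeg" for name in ch_names
    ]
    info = mne.create_info(ch_names, sfreq, ch_types)
    raw = mne.io.RawArray(data * 1e-6, info, verbose="error")

    ann_onset = np.concatenate([onsets, onsets[is_stim], q_onsets])
    ann_desc = (
        ["vowel"] * len(onsets)
        + ["stimulation"] * int(is_stim.sum())
        + ["question"] * len(q_onsets)
    )
    order = np.argsort(ann_onset, kind="stable")
    raw.set_annotations(
        mne.Annotations(
            onset=ann_onset[order],
            duration=np.zeros(len(ann_onset)),
            description=[ann_desc[i] for i in order],
        )
    )
    return raw


def derive_seed(*keys: int) -> int:
    """Deterministic sub-seed (< 2**31) from a tuple of integer keys.

    Hashing through :class:`numpy.random.SeedSequence` keeps the streams of
    nearby master seeds statistically independent (a plain ``master + index``
    sum would make adjacent master seeds share most subject streams).
    """
    return int(np.random.SeedSequence(keys).generate_state(1)[0] & 0x7FFFFFFF)


def subject_response_sides(subject: int) -> dict[str, str]:
    """Counterbalanced yes/no -> left/right mapping across subjects."""
    if subject % 2 == 0:
        return {"yes": "right", "no": "left"}
    return {"yes": "left", "no": "right"}


def simulate_dataset(
    design_cfg: DesignConfig,
    sim_cfg: SimConfig,
    master_seed: int | None = None,
):
    """Yield ``(subject, design, raw)`` for every subject of a simulated study.

    Each subject gets an independent pseudo-randomization of the same design
    and a counterbalanced response-side mapping; subject seeds derive
    deterministically from the master seed and the subject index.
    """
    seed0 = sim_cfg.seed if master_seed is None else master_seed
    for subject in range(sim_cfg.n_subjects):
        cfg_s = replace(
            design_cfg, response_sides=subject_response_sides(subject)
        )
        design = build_design(cfg_s, seed=derive_seed(seed0, subject, 1))
        raw = simulate_recording(
            design, sim_cfg, subject_seed=derive_seed(seed0, subject, 0)
        )
        yield subject, design, raw
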