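"""Morlet-wavelet time-frequency decomposition and ERSP maps.

The decomposition uses complex Morlet kernels whose cycle count rises
linearly from 3 cycles at 4 Hz to 20 cycles at 40 Hz on a 0.5 Hz grid, so
temporal resolution is traded for spectral resolution toward higher
frequencies.  Kernels are L2-normalized (Gaussian envelope SD
``n_cycles / (2 pi f)``, support truncated at +/-5 SD) and applied by
FFT-based convolution; a direct time-domain convolution gives identical
coefficients and serves as the test oracle.

The event-related spectral perturbation (ERSP) at frequency f and time t is

    ERSP(f, t) = 10 log10( mean_k |W_k(f, t)|^2 / P0(f) )

where the mean runs over trials k and ``P0(f)`` is the power averaged over
trials and baseline time points.  The ratio cancels any constant gain, so
ERSP is unit-free (dB relative to baseline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import mne
import numpy as np
from scipy import fft as sp_fft


class TFRError(ValueError):
    """Raised for invalid time-frequency requests."""


@dataclass(frozen=True)
class MorletSpec:
    """Frequency grid and cycle ramp of the wavelet set."""

    f_min_hz: float = 4.0
    f_max_hz: float = 40.0
    f_step_hz: float = 0.5
    cycles_at_fmin: float = 3.0
    cycles_at_fmax: float = 20.0
    output_window_ms: tuple[float, float] = (-1000.0, 1000.0)
    #: kernel support half-width, in Gaussian SDs
    kernel_sigmas: float = 5.0
    #: edge-safety margin, in Gaussian SDs, required inside the epoch
    edge_sigma: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.f_min_hz < self.f_max_hz:
            raise TFRError("invalid frequency range")
        if self.f_step_hz <= 0:
            raise TFRError("frequency step must be positive")
        if self.cycles_at_fmax <= self.cycles_at_fmin:
            raise TFRError("cycle count must increase with frequency")

    @property
    def freqs_hz(self) -> np.ndarray:
        n = int(round((self.f_max_hz - self.f_min_hz) / self.f_step_hz)) + 1
        return self.f_min_hz + self.f_step_hz * np.arange(n)


def wavelet_cycles(f_hz, spec: MorletSpec = MorletSpec()):
    """Cycle count at frequency ``f_hz``: linear ramp between the anchors."""
    f = np.asarray(f_hz, float)
    if np.any(f < spec.f_min_hz) or np.any(f > spec.f_max_hz):
        raise TFRError(
            f"frequency outside [{spec.f_min_hz}, {spec.f_max_hz}] Hz: {f_hz}"
        )
    n = spec.cycles_at_fmin + (spec.cycles_at_fmax - spec.cycles_at_fmin) * (
        (f - spec.f_min_hz) / (spec.f_max_hz - spec.f_min_hz)
    )
    return n if n.ndim else float(n)


def kernel_sigma_s(f_hz, spec: MorletSpec = MorletSpec()):
    """Gaussian-envelope SD in seconds: n_cycles / (2 pi f)."""
    return wavelet_cycles(f_hz, spec) / (2 * np.pi * np.asarray(f_hz, float))


def morlet_kernel(
    f_hz: float, n_cycles: float, sfreq: float, n_sigmas: float = 5.0
) -> np.ndarray:
    """Complex Morlet kernel, L2-normalized, truncated at +/- n_sigmas SD."""
    sigma_t = n_cycles / (2 * np.pi * f_hz)
    half = int(np.floor(n_sigmas * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    kernel = np.exp(2j * np.pi * f_hz * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return kernel / np.linalg.norm(kernel)


@dataclass
class TimeFreqMap:
    """ERSP (or power) matrix with explicit frequency and time grids."""

    values: np.ndarray  # (n_freqs, n_times)
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    level: str = "subject-condition"  # trial | subject-condition | group
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.freqs_hz = np.asarray(self.freqs_hz, float)
        self.times_ms = np.asarray(self.times_ms, float)
        if self.values.shape != (len(self.freqs_hz), len(self.times_ms)):
            raise TFRError("values shape does not match the grids")

    def same_grid(self, other: "TimeFreqMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.freqs_hz, other.freqs_hz)
            and np.allclose(self.times_ms, other.times_ms)
        )

    def to_tsv(self, path) -> None:
        """Write the map as TSV: header comments, then freq + one column/time."""
        header = json.dumps(
            {"level": self.level, "label": self.label,
             "times_ms": list(map(float, self.times_ms))}
        )
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            fh.write("freq_hz\t" + "\t".join(f"{t:g}" for t in self.times_ms) + "\n")
            for f, row in zip(self.freqs_hz, self.values):
                fh.write(f"{f:g}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "TimeFreqMap":
        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("# "))
            fh.readline()  # column header
            rows = [line.split("\t") for line in fh if line.strip()]
        freqs = np.array([float(r[0]) for r in rows])
        values = np.array([[float(v) for v in r[1:]] for r in rows])
        return cls(values, freqs, np.asarray(meta["times_ms"]),
                   level=meta["level"], label=meta["label"])

    def plot(self, ax=None, **imshow_kwargs):
        """Render the map as a spectrogram image (times x frequencies)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        extent = [self.times_ms[0], self.times_ms[-1],
                  self.freqs_hz[0], self.freqs_hz[-1]]
        im = ax.imshow(self.values, origin="lower", aspect="auto",
                       extent=extent, **imshow_kwargs)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("frequency (Hz)")
        return im


def _check_edges(spec: MorletSpec, times_s: np.ndarray,
                 out_window_s: tuple[float, float]) -> None:
    for f in spec.freqs_hz:
        margin = spec.edge_sigma * kernel_sigma_s(f, spec)
        if (out_window_s[0] - times_s[0] < margin
                or times_s[-1] - out_window_s[1] < margin):
            raise TFRError(
                f"epoch too short for edge-safe output at {f:g} Hz: needs "
                f"{margin:.3f} s margin beyond the output window"
            )


def morlet_transform(
    epoch_channel: np.ndarray,
    spec: MorletSpec,
    sfreq: float,
    times_s: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet coefficients of a single voltage series.

    ``times_s`` is the epoch time axis (seconds, same length as the data);
    when omitted the epoch is assumed to start at time 0.  Returns
    ``(coefficients, out_times_s)`` with coefficients of shape
    ``(n_freqs, n_out_times)`` cropped to ``spec.output_window_ms``.
    """
    x = np.asarray(epoch_channel, float)
    if x.ndim != 1:
        raise TFRError("epoch_channel must be one-dimensional")
    coefs, out_times = morlet_power(
        x[None, :], spec, sfreq, times_s=times_s, return_complex=True
    )
    return coefs[0], out_times


def morlet_power(
    data: np.ndarray,
    spec: MorletSpec,
    sfreq: float,
    times_s: np.ndarray | None = None,
    return_complex: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched wavelet transform of ``data`` with shape (..., n_samples).

    Returns ``(out, out_times_s)`` where ``out`` has shape
    ``(..., n_freqs, n_out_times)`` and holds power ``|W|^2`` (or complex
    coefficients when ``return_complex``).  Each kernel is applied as a
    'same'-aligned convolution via a single FFT of the data.
    """
    data = np.asarray(data, float)
    n = data.shape[-1]
    if times_s is None:
        times_s = np.arange(n) / sfreq
    times_s = np.asarray(times_s, float)
    if len(times_s) != n:
        raise TFRError("times_s length must match the data")
    out_window_s = (spec.output_window_ms[0] / 1000.0,
                    spec.output_window_ms[1] / 1000.0)
    if out_window_s[0] < times_s[0] or out_window_s[1] > times_s[-1]:
        raise TFRError("output window extends beyond the epoch time axis")
    _check_edges(spec, times_s, out_window_s)

    freqs = spec.freqs_hz
    kernels = [
        morlet_kernel(f, wavelet_cycles(f, spec), sfreq, spec.kernel_sigmas)
        for f in freqs
    ]
    max_len = max(len(k) for k in kernels)
    nfft = sp_fft.next_fast_len(n + max_len - 1)

    # place each kernel centred on index 0 (wrapped) so that multiplication in
    # the frequency domain directly yields the 'same'-aligned convolution
    kfd = np.zeros((len(freqs), nfft), complex)
    for i, k in enumerate(kernels):
        c = (len(k) - 1) // 2
        buf = np.zeros(nfft, complex)
        buf[: len(k) - c] = k[c:]
        buf[nfft - c:] = k[:c]
        kfd[i] = sp_fft.fft(buf)

    keep = (times_s >= out_window_s[0] - 1e-9) & (times_s <= out_window_s[1] + 1e-9)
    out_times = times_s[keep]
    lead_shape = data.shape[:-1]
    flat = data.reshape(-1, n)
    xf = sp_fft.fft(flat, nfft, axis=-1)
    dtype = complex if return_complex else float
    out = np.empty((flat.shape[0], len(freqs), keep.sum()), dtype)
    for i in range(len(freqs)):
        conv = sp_fft.ifft(xf * kfd[i], axis=-1)[:, :n][:, keep]
        out[:, i, :] = conv if return_complex else np.abs(conv) ** 2
    return out.reshape(lead_shape + out.shape[1:]), out_times


def _baseline_columns(times_ms: np.ndarray,
                      baseline_ms: tuple[float, float]) -> np.ndarray:
    cols = (times_ms >= baseline_ms[0] - 1e-9) & (times_ms <= baseline_ms[1] + 1e-9)
    if not cols.any():
        raise TFRError("baseline window contains no output time points")
    return cols


def single_trial_power(
    epochs: mne.Epochs, channel: str, spec: MorletSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial wavelet power of one channel: (n_trials, n_freqs, n_times)."""
    data = epochs.get_data(picks=[channel], copy=True)[:, 0, :]
    return morlet_power(data, spec, epochs.info["sfreq"], times_s=epochs.times)


def ersp_from_power(
    power: np.ndarray,
    times_ms: np.ndarray,
    baseline_ms: tuple[float, float],
) -> np.ndarray:
    """ERSP (dB) from per-trial power (n_trials, n_freqs, n_times).

    The baseline divisor ``P0(f)`` averages over trials and baseline time
    points, i.e. the normalization is common to all trials rather than
    per trial.
    """
    if power.ndim != 3 or power.shape[0] < 1:
        raise TFRError("power must be (n_trials, n_freqs, n_times), >= 1 trial")
    cols = _baseline_columns(times_ms, baseline_ms)
    p0 = power[:, :, cols].mean(axis=(0, 2))
    if np.any(p0 <= 0):
        raise TFRError("zero baseline power: degenerate input")
    mean_p = power.mean(axis=0)
    return 10.0 * np.log10(mean_p / p0[:, None])


def compute_ersp(
    epochs: mne.Epochs,
    channel: str,
    spec: MorletSpec = MorletSpec(),
    baseline_ms: tuple[float, float] = (-1000.0, -150.0),
) -> TimeFreqMap:
    """ERSP map of one channel across the trials of ``epochs``."""
    power, out_times = single_trial_power(epochs, channel, spec)
    times_ms = out_times * 1000.0
    values = ersp_from_power(power, times_ms, baseline_ms)
    return TimeFreqMap(values, spec.freqs_hz, times_ms, label=channel)


def roi_average(
    maps: Mapping[str, TimeFreqMap] | Sequence[TimeFreqMap],
    roi: Iterable[str] | None = None,
) -> TimeFreqMap:
    """Element-wise mean (in dB) of per-channel ERSP maps over an ROI."""
    if isinstance(maps, Mapping):
        roi = list(maps) if roi is None else list(roi)
        missing = [c for c in roi if c not in maps]
        if missing:
            raise TFRError(f"ROI channels missing from the map set: {missing}")
        selected = [maps[c] for c in roi]
    else:
        selected = list(maps)
        if roi is not None:
            by_label = {m.label: m for m in selected}
            missing = [c for c in roi if c not in by_label]
            if missing:
                raise TFRError(f"ROI channels missing from the map set: {missing}")
            selected = [by_label[c] for c in roi]
    if not selected:
        raise TFRError("no maps to average")
    first = selected[0]
    for m in selected[1:]:
        if not first.same_grid(m):
            raise TFRError("maps have mismatched grids")
    values = np.mean([m.values for m in selected], axis=0)
    return TimeFreqMap(values, first.freqs_hz, first.times_ms,
                       level=first.level, label="+".join(m.label for m in selected))


def compute_roi_ersp(
    epochs: mne.Epochs,
    roi: Sequence[str],
    spec: MorletSpec = MorletSpec(),
    baseline_ms: tuple[float, float] = (-1000.0, -150.0),
    mode: str = "average_power",
) -> TimeFreqMap:
    """ROI-level ERSP.

    ``mode="average_power"`` (default) computes one ERSP per electrode and
    averages the dB maps; ``mode="average_voltage"`` averages the voltage
    traces across the ROI first and decomposes the single virtual channel.
    """
    missing = [c for c in roi if c not in epochs.ch_names]
    if missing:
        raise TFRError(f"ROI channels absent from the recording: {missing}")
    if mode == "average_power":
        maps = {c: compute_ersp(epochs, c, spec, baseline_ms) for c in roi}
        out = roi_average(maps, roi)
    elif mode == "average_voltage":
        data = epochs.get_data(picks=list(roi), copy=True).mean(axis=1)
        power, out_times = morlet_power(
            data, spec, epochs.info["sfreq"], times_s=epochs.times
        )
        times_ms = out_times * 1000.0
        out = TimeFreqMap(
            ersp_from_power(power, times_ms, baseline_ms),
            spec.freqs_hz, times_ms, label="+".join(roi),
        )
    else:
        raise TFRError(f"unknown ROI mode: {mode!r}")
    return out
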