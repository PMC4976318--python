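"""Saccade detection on bipolar horizontal EOG and behavioural scoring.

A horizontal eye movement produces a dipolar deflection of opposite sign at
the two outer-canthi electrodes, so the differenced signal (right minus
left electrode) deflects positive for rightward and negative for leftward
saccades.  The detector low-passes the difference at 20 Hz, scans a 3 s
window from question onset, and accepts the first excursion exceeding 1.5
standard deviations from the window average provided it occurs at least
150 ms after the question; trials with no such excursion, or whose first
excursion is earlier than 150 ms (anticipation), are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import mne
import numpy as np
import pandas as pd
from scipy import signal

BEHAVIOR_COLUMNS = ["trial_id", "valid", "direction", "rt_ms", "correct"]


@dataclass(frozen=True)
class SaccadeDetection:
    valid: bool
    direction: str  # "left", "right" or "none"
    rt_ms: float  # NaN when invalid


def lowpass_eog(x: np.ndarray, sfreq: float, cutoff_hz: float = 20.0,
                order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass used for EOG traces."""
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def detect_saccade(
    eog_left: np.ndarray,
    eog_right: np.ndarray,
    question_onset_s: float,
    sfreq: float,
    *,
    window_s: float = 3.0,
    threshold_sd: float = 1.5,
    min_latency_ms: float = 150.0,
    stats_scope: str = "trial",
    session_stats: tuple[float, float] | None = None,
    prefiltered: bool = False,
) -> SaccadeDetection:
    """Detect the first saccade after the question on one trial.

    ``eog_left``/``eog_right`` are the full-length electrode series; the
    analysis window is ``[question_onset, question_onset + window_s]``.  The
    threshold statistics (mean and SD of the filtered difference signal) are
    computed over that same window (``stats_scope="trial"``, the default) or
    taken from ``session_stats`` (``stats_scope="session"``).  Adding a
    common offset to both electrodes leaves the result unchanged.

    Returns an invalid detection when the window extends past the recording
    end, when no excursion crosses the threshold, or when the first crossing
    is earlier than ``min_latency_ms`` (anticipated response).
    """
    diff = np.asarray(eog_right, float) - np.asarray(eog_left, float)
    i0 = int(round(question_onset_s * sfreq))
    i1 = i0 + int(round(window_s * sfreq))
    if i0 < 0 or i1 > diff.shape[-1]:
        return SaccadeDetection(False, "none", np.nan)
    filt = diff if prefiltered else lowpass_eog(diff, sfreq)
    seg = filt[i0:i1]
    if stats_scope == "session":
        if session_stats is None:
            raise ValueError("session_stats required with stats_scope='session'")
        mean, sd = session_stats
    elif stats_scope == "trial":
        mean, sd = float(seg.mean()), float(seg.std())
    else:
        raise ValueError(f"unknown stats_scope: {stats_scope!r}")
    if sd <= 0:
        return SaccadeDetection(False, "none", np.nan)
    dev = seg - mean
    above = np.abs(dev) > threshold_sd * sd
    if not above.any():
        return SaccadeDetection(False, "none", np.nan)
    first = int(np.argmax(above))
    rt_ms = first / sfreq * 1000.0
    if rt_ms < min_latency_ms:
        return SaccadeDetection(False, "none", np.nan)
    direction = "right" if dev[first] > 0 else "left"
    return SaccadeDetection(True, direction, rt_ms)


def score_trials(
    detections: list[SaccadeDetection] | pd.DataFrame,
    trials: pd.DataFrame,
    side_mapping: Mapping[str, str],
) -> pd.DataFrame:
    """Join detections with the trial table into a behaviour table.

    ``side_mapping`` maps ``yes``/``no`` to ``left``/``right``; a positive
    question polarity demands a "yes" response.  A detection is correct when
    its direction matches the demanded side; invalid detections are never
    correct and carry direction ``none`` and an undefined RT.
    """
    if set(side_mapping) != {"yes", "no"} or (
        side_mapping["yes"] == side_mapping["no"]
    ):
        raise ValueError("side_mapping must assign yes/no to distinct sides")
    if not set(side_mapping.values()) <= {"left", "right"}:
        raise ValueError(f"unmapped response side in {side_mapping!r}")
    if isinstance(detections, pd.DataFrame):
        det = detections[["valid", "direction", "rt_ms"]].reset_index(drop=True)
    else:
        det = pd.DataFrame(
            [(d.valid, d.direction, d.rt_ms) for d in detections],
            columns=["valid", "direction", "rt_ms"],
        )
    if len(det) != len(trials):
        raise ValueError("one detection per trial is required")
    answers = np.where(
        trials["question_polarity"].to_numpy() == "positive", "yes", "no"
    )
    expected = np.array([side_mapping[a] for a in answers])
    out = pd.DataFrame(
        {
            "trial_id": trials["trial_id"].to_numpy(),
            "valid": det["valid"].to_numpy(bool),
            "direction": det["direction"].to_numpy(),
            "rt_ms": det["rt_ms"].to_numpy(float),
        }
    )
    out["correct"] = out["valid"] & (out["direction"].to_numpy() == expected)
    return out[BEHAVIOR_COLUMNS]


def score_behavior(
    raw: mne.io.BaseRaw,
    trials: pd.DataFrame,
    side_mapping: Mapping[str, str],
    eog_channels: tuple[str, str] = ("EOGL", "EOGR"),
    **detect_kwargs,
) -> pd.DataFrame:
    """Detect and score every trial of a continuous recording.

    The EOG difference signal is low-pass filtered once for the whole
    session, then each trial's question window is scanned.
    """
    sfreq = raw.info["sfreq"]
    picks = [raw.ch_names.index(c) for c in eog_channels]
    data = raw.get_data(picks=picks)
    filt = lowpass_eog(data[1] - data[0], sfreq)
    zeros = np.zeros_like(filt)
    detections = [
        detect_saccade(
            zeros, filt, q, sfreq, prefiltered=True, **detect_kwargs
        )
        for q in trials["question_onset_s"].to_numpy(float)
    ]
    return score_trials(detections, trials, side_mapping)
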