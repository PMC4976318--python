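"""Continuous-recording preprocessing and epoching.

Band-pass (zero-phase Butterworth), resampling with anti-aliasing, common
average reference over the EEG channels (EOG excluded; EOG is also carried
through the band-pass untouched, since the behavioural module applies its
own 20 Hz low-pass), epoching around vowel onset and baseline correction
over the silent pre-stimulus window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import mne
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PreprocError(ValueError):
    """Raised for invalid preprocessing configurations."""


@dataclass
class PreprocConfig:
    bandpass_hz: tuple[float, float] = (0.5, 50.0)
    resample_hz: float = 250.0
    #: epoch window around vowel onset, seconds; half-open [start, end)
    epoch_window_s: tuple[float, float] = (-1.5, 2.5)
    baseline_window_ms: tuple[float, float] = (-1000.0, -150.0)
    reference: str = "common_average"
    #: zero-phase Butterworth order (applied forward-backward)
    filter_order: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.bandpass_hz
        if not 0 < lo < hi:
            raise PreprocError("invalid band-pass corner frequencies")
        b0, b1 = self.baseline_window_ms
        e0, e1 = self.epoch_window_s
        if not e0 < e1:
            raise PreprocError("invalid epoch window")
        if not (e0 * 1000.0 <= b0 < b1 <= e1 * 1000.0):
            raise PreprocError("baseline window must lie inside the epoch window")
        if self.reference != "common_average":
            raise PreprocError(f"unsupported reference: {self.reference!r}")

    @property
    def n_epoch_samples(self) -> int:
        """Samples per epoch under the half-open [start, end) convention."""
        return int(round((self.epoch_window_s[1] - self.epoch_window_s[0])
                         * self.resample_hz))


def preprocess_continuous(
    raw: mne.io.BaseRaw, cfg: PreprocConfig
) -> mne.io.BaseRaw:
    """Band-pass, resample and re-reference a continuous recording.

    EEG channels are band-pass filtered (zero-phase Butterworth of
    ``cfg.filter_order``, applied forward-backward), everything is resampled
    to ``cfg.resample_hz`` with anti-aliasing, and the EEG channels are
    re-referenced to their common average (EOG channels excluded from both
    the filter and the reference).  Annotation (marker) times are stored in
    seconds and therefore remain aligned after resampling.
    """
    nyq = raw.info["sfreq"] / 2.0
    if cfg.bandpass_hz[1] >= nyq:
        raise PreprocError(
            f"band-pass upper edge {cfg.bandpass_hz[1]} Hz reaches the Nyquist "
            f"frequency {nyq} Hz"
        )
    if cfg.resample_hz > raw.info["sfreq"]:
        raise PreprocError("resample rate exceeds the recording rate")
    out = raw.copy().load_data(verbose="error")
    out.filter(
        l_freq=cfg.bandpass_hz[0],
        h_freq=cfg.bandpass_hz[1],
        picks="eeg",
        method="iir",
        iir_params=dict(order=cfg.filter_order, ftype="butter"),
        phase="zero",
        verbose="error",
    )
    if cfg.resample_hz != out.info["sfreq"]:
        out.resample(cfg.resample_hz, verbose="error")
    out.set_eeg_reference("average", ch_type="eeg", projection=False,
                          verbose="error")
    return out


def epoch_and_baseline(
    raw: mne.io.BaseRaw, trials: pd.DataFrame, cfg: PreprocConfig
) -> mne.Epochs:
    """Cut one epoch per trial around vowel onset and baseline-correct it.

    Trials whose epoch would extend past either end of the recording are
    excluded with a logged warning.  The per-trial metadata (the surviving
    rows of ``trials``) rides along on the returned Epochs object.
    """
    sfreq = raw.info["sfreq"]
    e0, e1 = cfg.epoch_window_s
    onsets = trials["vowel_onset_s"].to_numpy(float)
    samples = np.round(onsets * sfreq).astype(int)
    # half-open convention: last sample is end - 1/sfreq
    tmax = e1 - 1.0 / sfreq
    ok = (samples + int(np.floor(e0 * sfreq)) >= 0) & (
        samples + int(np.ceil(tmax * sfreq)) < raw.n_times
    )
    if not ok.all():
        bad = trials.loc[~ok, "trial_id"].tolist()
        logger.warning(
            "excluding %d trial(s) too close to a recording edge: %s",
            len(bad), bad,
        )
    if not ok.any():
        raise PreprocError("no trial has enough data for the epoch window")
    events = np.column_stack(
        [samples[ok], np.zeros(ok.sum(), int), np.ones(ok.sum(), int)]
    )
    metadata = trials.loc[ok].reset_index(drop=True)
    baseline = (cfg.baseline_window_ms[0] / 1000.0,
                cfg.baseline_window_ms[1] / 1000.0)
    epochs = mne.Epochs(
        raw,
        events,
        event_id={"vowel": 1},
        tmin=e0,
        tmax=tmax,
        baseline=baseline,
        metadata=metadata,
        preload=True,
        proj=False,
        reject=None,
        reject_by_annotation=False,
        verbose="error",
    )
    return epochs


def select_valid_trials(
    epochs: mne.Epochs, behavior: pd.DataFrame
) -> mne.Epochs:
    """Keep only epochs whose trial was behaviourally valid and correct.

    ``behavior`` must contain ``trial_id``, ``valid`` and ``correct`` columns
    covering every trial in the epochs' metadata.  An empty selection is
    allowed (and logged).
    """
    meta = epochs.metadata
    if meta is None or "trial_id" not in meta:
        raise PreprocError("epochs carry no trial_id metadata")
    missing = set(meta["trial_id"]) - set(behavior["trial_id"])
    if missing:
        raise PreprocError(f"behavior table does not cover trials: {sorted(missing)}")
    good_ids = set(
        behavior.loc[
            behavior["valid"].astype(bool) & behavior["correct"].astype(bool),
            "trial_id",
        ]
    )
    mask = meta["trial_id"].isin(good_ids).to_numpy()
    if not mask.any():
        logger.warning("no valid+correct trials remain after selection")
    return epochs[mask]
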