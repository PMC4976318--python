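"""File formats: EDF+ writing, raw readers, trial/behaviour tables, epochs.

Continuous recordings are written as minimal EDF+C files (16-bit, one file
per subject, event markers in the annotations signal) and read back with
MNE's EDF/BrainVision readers.  Epochs are persisted in MNE's native FIF
container with a small JSON sidecar describing the time axis, channels and
trial metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import mne
import numpy as np
import pandas as pd

from betarebound.design import TRIAL_COLUMNS

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    for prec in range(6, -1, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {x} in {width} chars")


def write_edf(raw: mne.io.BaseRaw, path) -> Path:
    """Write a continuous recording as EDF+C with annotations.

    Signals are stored in microvolts with a per-channel symmetric physical
    range and 16-bit quantization; the sampling rate must be an integer
    (one data record per second).  All annotations of ``raw`` are written
    as standard EDF+ time-stamped annotation lists.
    """
    path = Path(path)
    sfreq = raw.info["sfreq"]
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1 s record per channel
    data_uv = raw.get_data() * 1e6
    n_sig, n_samples = data_uv.shape
    n_records = int(np.ceil(n_samples / spr))
    padded = np.zeros((n_sig, n_records * spr))
    padded[:, :n_samples] = data_uv

    # symmetric physical range per channel -> zero maps to digital zero;
    # the range is rounded to its header text first so the scale used for
    # quantization matches the header exactly (width 7 leaves room for the
    # minus sign of the physical minimum)
    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    phys_max_txt = [_fmt_float(np.ceil(p * 10) / 10, width=7) for p in phys_max]
    phys_max = np.array([float(s) for s in phys_max_txt])
    scale = _EDF_DIG_MAX / phys_max
    digital = np.clip(
        np.round(padded * scale[:, None]), _EDF_DIG_MIN, _EDF_DIG_MAX
    ).astype("<i2")

    ann = raw.annotations
    tals: list[list[bytes]] = [[] for _ in range(n_records)]
    for rec in range(n_records):
        tals[rec].append(f"+{rec}\x14\x14\x00".encode("ascii"))
    for onset, desc in zip(ann.onset, ann.description):
        rec = min(int(onset), n_records - 1)
        tals[rec].append(f"+{onset:.4f}\x14{desc}\x14\x00".encode("ascii"))
    ann_bytes_per_rec = max(max(sum(len(t) for t in rec) for rec in tals), 16)
    ann_spr = int(np.ceil(ann_bytes_per_rec / 2))  # 2-byte "samples"

    n_total_sig = n_sig + 1
    header_len = 256 * (n_total_sig + 1)
    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X X X X", 80))
        fh.write(_ascii("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(header_len, 8))
        fh.write(_ascii("EDF+C", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii("1", 8))  # record duration, seconds
        fh.write(_ascii(n_total_sig, 4))

        for name in raw.ch_names:
            fh.write(_ascii(name[:16], 16))
        fh.write(_ascii("EDF Annotations", 16))
        for _ in range(n_total_sig):
            fh.write(_ascii("", 80))  # transducer
        for _ in range(n_sig):
            fh.write(_ascii("uV", 8))
        fh.write(_ascii("", 8))
        for p in phys_max_txt:
            fh.write(_ascii(f"-{p}", 8))
        fh.write(_ascii(_EDF_DIG_MIN, 8))
        for p in phys_max_txt:
            fh.write(_ascii(p, 8))
        fh.write(_ascii(_EDF_DIG_MAX, 8))
        for _ in range(n_sig + 1):
            fh.write(_ascii(_EDF_DIG_MIN, 8))
        for _ in range(n_sig + 1):
            fh.write(_ascii(_EDF_DIG_MAX, 8))
        for _ in range(n_total_sig):
            fh.write(_ascii("", 80))  # prefiltering
        for _ in range(n_sig):
            fh.write(_ascii(spr, 8))
        fh.write(_ascii(ann_spr, 8))
        for _ in range(n_total_sig):
            fh.write(_ascii("", 32))

        for rec in range(n_records):
            fh.write(digital[:, rec * spr:(rec + 1) * spr].tobytes(order="C"))
            blob = b"".join(tals[rec])
            fh.write(blob.ljust(ann_spr * 2, b"\x00"))
    return path


def read_raw(path, preload: bool = True) -> mne.io.BaseRaw:
    """Read a continuous recording (EDF or BrainVision) by file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return mne.io.read_raw_edf(path, preload=preload, verbose="error")
    if suffix == ".vhdr":
        return mne.io.read_raw_brainvision(path, preload=preload,
                                           verbose="error")
    raise ValueError(f"unsupported recording format: {path.name}")


def write_trial_table(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    trials[TRIAL_COLUMNS].to_csv(path, index=False)
    return path


def read_trial_table(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    return trials[TRIAL_COLUMNS]


def write_behavior_table(behavior: pd.DataFrame, path) -> Path:
    path = Path(path)
    behavior.to_csv(path, index=False)
    return path


def read_behavior_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_epochs(epochs: mne.Epochs, path) -> Path:
    """Persist epochs as FIF plus a JSON sidecar with axes and metadata."""
    path = Path(path)
    if not path.name.endswith("-epo.fif"):
        path = path.with_name(path.stem + "-epo.fif")
    epochs.save(path, overwrite=True, verbose="error")
    sidecar = path.with_suffix(".json")
    meta = {
        "sfreq": epochs.info["sfreq"],
        "times_s": [float(epochs.times[0]), float(epochs.times[-1])],
        "n_epochs": len(epochs),
        "channels": list(epochs.ch_names),
        "metadata": (
            epochs.metadata.to_dict(orient="list")
            if epochs.metadata is not None else None
        ),
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def load_epochs(path) -> mne.Epochs:
    return mne.read_epochs(path, preload=True, verbose="error")


def write_mask_tsv(mask, path) -> Path:
    """Write a significance mask as TSV of 0/1 with freq/time axes."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("freq_hz\t" + "\t".join(f"{t:g}" for t in mask.times_ms) + "\n")
        for f, row in zip(mask.freqs_hz, mask.mask.astype(int)):
            fh.write(f"{f:g}\t" + "\t".join(str(v) for v in row) + "\n")
    return path
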