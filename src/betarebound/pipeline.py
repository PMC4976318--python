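"""End-to-end orchestration: simulate -> preprocess -> score -> ERSP -> stats.

A single :class:`PipelineConfig` drives every stage; all randomness derives
from its ``seed``, so a run is reproducible bit-for-bit from its manifest.
The per-subject ERSP stage (the slow one) can be cached on disk keyed by a
content hash of the stage configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import betarebound
from betarebound.design import DesignConfig
from betarebound.eog import score_behavior
from betarebound.preprocess import (
    PreprocConfig,
    epoch_and_baseline,
    preprocess_continuous,
    select_valid_trials,
)
from betarebound.simulate import SimConfig, simulate_dataset, subject_response_sides
from betarebound.stats import (
    BandWindowSpec,
    StatsError,
    canonical_band_windows,
    compare_maps_permutation,
    extract_band_window_means,
    posthoc_bonferroni,
    rm_anova_2x2x2,
)
from betarebound.tfr import MorletSpec, TimeFreqMap, ersp_from_power, morlet_power

logger = logging.getLogger(__name__)

CONDITIONS = [
    ("bilabial", "present"), ("dental", "present"),
    ("bilabial", "absent"), ("dental", "absent"),
]


class PipelineConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    morlet: MorletSpec = field(default_factory=MorletSpec)
    roi_left: tuple[str, ...] = ("C1", "C3", "C5")
    roi_right: tuple[str, ...] = ("C2", "C4", "C6")
    #: mu/beta band limits and their ERD / band-specific ERS windows
    band_windows: dict[str, BandWindowSpec] = field(
        default_factory=canonical_band_windows
    )
    n_perm: int = 1000
    alpha: float = 0.01
    #: compute the (slow) map-level permutation contrasts
    map_stats: bool = True
    seed: int = 0

    def validate(self) -> None:
        montage = set(self.sim.montage)
        for roi_name, roi in (("left", self.roi_left), ("right", self.roi_right)):
            missing = [c for c in roi if c not in montage]
            if missing:
                raise PipelineConfigError(
                    f"{roi_name} ROI channels absent from montage: {missing}"
                )
        b0, b1 = self.preproc.baseline_window_ms
        o0, o1 = self.morlet.output_window_ms
        if not (o0 <= b0 < b1 <= o1):
            raise PipelineConfigError(
                "baseline window must lie inside the wavelet output window"
            )
        for name, bw in self.band_windows.items():
            if not (self.morlet.f_min_hz <= bw.band_hz[0]
                    <= bw.band_hz[1] <= self.morlet.f_max_hz):
                raise PipelineConfigError(f"band {name} outside wavelet range")
            if not (o0 <= bw.window_ms[0] <= bw.window_ms[1] <= o1):
                raise PipelineConfigError(f"window {name} outside output window")
        if self.n_perm < 1:
            raise PipelineConfigError("n_perm must be >= 1")

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        def build(klass, sub):
            if sub is None:
                return klass()
            kwargs = dict(sub)
            for key, val in kwargs.items():
                if isinstance(val, list):
                    kwargs[key] = tuple(val)
            return klass(**kwargs)

        bw = {
            name: BandWindowSpec(tuple(v["band_hz"]), tuple(v["window_ms"]),
                                 v.get("label", name))
            for name, v in d.get("band_windows", {}).items()
        } or canonical_band_windows()
        return cls(
            design=build(DesignConfig, d.get("design")),
            sim=build(SimConfig, d.get("sim")),
            preproc=build(PreprocConfig, d.get("preproc")),
            morlet=build(MorletSpec, d.get("morlet")),
            roi_left=tuple(d.get("roi_left", ("C1", "C3", "C5"))),
            roi_right=tuple(d.get("roi_right", ("C2", "C4", "C6"))),
            band_windows=bw,
            n_perm=int(d.get("n_perm", 1000)),
            alpha=float(d.get("alpha", 0.01)),
            map_stats=bool(d.get("map_stats", True)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _subject_stage(cfg: PipelineConfig, subject: int, design, raw):
    """Preprocess, score and decompose one subject.

    Returns (maps, band_rows, rt_rows, counts) where ``maps`` is
    {(syllable, stimulation): {"left": map, "right": map}}.
    """
    rawp = preprocess_continuous(raw, cfg.preproc)
    behavior = score_behavior(
        rawp, design, subject_response_sides(subject),
        eog_channels=cfg.sim.eog_channels,
    )
    epochs = epoch_and_baseline(rawp, design, cfg.preproc)
    valid = select_valid_trials(epochs, behavior)
    counts = {
        "n_trials": len(design),
        "n_valid": int(behavior["valid"].sum()),
        "n_correct": int(behavior["correct"].sum()),
        "n_epochs": len(valid),
    }

    rois = {"left": cfg.roi_left, "right": cfg.roi_right}
    channels = sorted({c for roi in rois.values() for c in roi})
    data = valid.get_data(picks=channels, copy=True)
    power, out_times = morlet_power(
        data, cfg.morlet, valid.info["sfreq"], times_s=valid.times
    )  # (n_trials, n_ch, n_freqs, n_times)
    times_ms = out_times * 1000.0
    meta = valid.metadata.reset_index(drop=True)

    maps: dict = {}
    band_rows = []
    for syllable, stim in CONDITIONS:
        idx = np.flatnonzero(
            (meta["syllable"] == syllable) & (meta["stimulation"] == stim)
        )
        if idx.size == 0:
            logger.warning("subject %d: empty cell %s/%s", subject, syllable, stim)
            continue
        maps[(syllable, stim)] = {}
        for roi_name, roi in rois.items():
            ch_ix = [channels.index(c) for c in roi]
            per_ch = [
                ersp_from_power(power[idx][:, j], times_ms,
                                cfg.preproc.baseline_window_ms)
                for j in ch_ix
            ]
            tfmap = TimeFreqMap(
                np.mean(per_ch, axis=0), cfg.morlet.freqs_hz, times_ms,
                label=f"s{subject:02d}_{syllable}_{stim}_{roi_name}",
            )
            maps[(syllable, stim)][roi_name] = tfmap
            for bw_name, bw in cfg.band_windows.items():
                band, phase = bw_name.split("_", 1)
                band_rows.append({
                    "subject": subject, "roi": roi_name,
                    "syllable": syllable, "stimulation": stim,
                    "band": band, "window": phase,
                    "value": extract_band_window_means(tfmap, bw),
                })

    rt = behavior.merge(design[["trial_id", "syllable", "stimulation",
                                "question_polarity"]], on="trial_id")
    rt = rt[rt["valid"] & rt["correct"]]
    rt_rows = (
        rt.groupby(["syllable", "stimulation", "question_polarity"])["rt_ms"]
        .mean().reset_index()
    )
    rt_rows["subject"] = subject
    return maps, band_rows, rt_rows, counts


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path | None = None,
    cache_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis on a simulated dataset.

    Returns a result dict with group ERSP maps per condition and ROI,
    map-level significance masks for the syllable contrast (within each
    stimulation level and ROI), the per-subject band/window table, the mu
    and beta 2x2x2 ANOVAs with Bonferroni post-hocs, the reaction-time
    ANOVA, and a machine-readable manifest.
    """
    cfg.validate()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    subject_maps: list[dict] = []
    band_rows: list[dict] = []
    rt_tables = []
    counts_all = []
    for subject, design, raw in simulate_dataset(cfg.design, cfg.sim,
                                                 master_seed=cfg.seed):
        cached = None
        if cache_dir is not None:
            key = hashlib.sha1(
                (cfg.content_hash() + f"/subj{subject}").encode()
            ).hexdigest()[:16]
            cache_file = Path(cache_dir) / f"subject_{subject:02d}_{key}.npz"
            if cache_file.exists():
                cached = _load_subject_cache(cache_file)
        if cached is None:
            maps, rows, rt_rows, counts = _subject_stage(cfg, subject, design, raw)
            if cache_dir is not None:
                Path(cache_dir).mkdir(parents=True, exist_ok=True)
                _save_subject_cache(cache_file, maps, rows, rt_rows, counts)
        else:
            maps, rows, rt_rows, counts = cached
        logger.info("subject %d: %s", subject, counts)
        subject_maps.append(maps)
        band_rows.extend(rows)
        rt_tables.append(rt_rows)
        counts_all.append(counts)

    band_table = pd.DataFrame(band_rows)
    rt_table = pd.concat(rt_tables, ignore_index=True)

    # group maps and syllable contrasts per stimulation level and ROI
    group_maps: dict = {}
    masks: dict = {}
    for syllable, stim in CONDITIONS:
        for roi_name in ("left", "right"):
            per_subj = [m[(syllable, stim)][roi_name] for m in subject_maps
                        if (syllable, stim) in m]
            if not per_subj:
                logger.warning("no subject has condition %s/%s", syllable, stim)
                continue
            group_maps[(syllable, stim, roi_name)] = TimeFreqMap(
                np.mean([m.values for m in per_subj], axis=0),
                per_subj[0].freqs_hz, per_subj[0].times_ms, level="group",
                label=f"{syllable}_{stim}_{roi_name}",
            )
    if cfg.map_stats:
        for stim in ("present", "absent"):
            paired = all(
                ("dental", stim) in m and ("bilabial", stim) in m
                for m in subject_maps
            )
            if not paired:
                logger.warning(
                    "skipping %s-stimulation map contrast: a subject has an "
                    "empty condition cell", stim,
                )
                continue
            for roi_name in ("left", "right"):
                a = [m[("dental", stim)][roi_name] for m in subject_maps]
                b = [m[("bilabial", stim)][roi_name] for m in subject_maps]
                masks[(stim, roi_name)] = compare_maps_permutation(
                    a, b, n_perm=cfg.n_perm, alpha=cfg.alpha,
                    seed=cfg.seed + 17,
                )

    # band/window ANOVAs (left ROI, as the region of interest) + post-hocs
    anovas: dict = {}
    posthocs: dict = {}
    for band in sorted(band_table["band"].unique()):
        sub = band_table.query("band == @band and roi == 'left'")
        try:
            anovas[band] = rm_anova_2x2x2(
                sub, dv="value", within=("syllable", "stimulation", "window"),
                subject="subject",
            )
        except StatsError as exc:
            logger.warning("%s-band ANOVA skipped: %s", band, exc)
            anovas[band] = None
            continue
        ers = sub.query("window == 'ers'")
        wide = ers.pivot_table(index="subject", columns=["syllable", "stimulation"],
                               values="value")
        posthocs[band] = posthoc_bonferroni({
            "dental_vs_bilabial_stim": (
                wide[("dental", "present")].to_numpy(),
                wide[("bilabial", "present")].to_numpy(),
            ),
            "dental_vs_bilabial_nostim": (
                wide[("dental", "absent")].to_numpy(),
                wide[("bilabial", "absent")].to_numpy(),
            ),
        })

    try:
        rt_anova = rm_anova_2x2x2(
            rt_table, dv="rt_ms",
            within=("syllable", "stimulation", "question_polarity"),
            subject="subject",
        )
    except StatsError as exc:
        # small designs can leave a subject with an empty RT cell
        logger.warning("RT ANOVA skipped: %s", exc)
        rt_anova = None

    n_trials = sum(c["n_trials"] for c in counts_all)
    n_kept = sum(c["n_epochs"] for c in counts_all)
    manifest = {
        "package_version": betarebound.__version__,
        "python": sys.version.split()[0],
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "subject_counts": counts_all,
        "discard_rate": 1.0 - n_kept / n_trials if n_trials else float("nan"),
    }
    results = {
        "group_maps": group_maps,
        "masks": masks,
        "band_table": band_table,
        "anovas": anovas,
        "posthocs": posthocs,
        "rt_table": rt_table,
        "rt_anova": rt_anova,
        "manifest": manifest,
    }
    if out_path is not None:
        _write_outputs(results, out_path)
    return results


def _anova_to_dict(res) -> dict:
    return {
        "effects": res.effects.to_dict(orient="records"),
        "cell_stats": res.cell_stats.to_dict(orient="records"),
        "n_subjects": res.n_subjects,
    }


def _write_outputs(results: dict, out_path: Path) -> None:
    from betarebound.io import write_mask_tsv

    for key, tfmap in results["group_maps"].items():
        tfmap.to_tsv(out_path / ("ersp_" + "_".join(key) + ".tsv"))
    for key, mask in results["masks"].items():
        write_mask_tsv(mask, out_path / ("mask_" + "_".join(key) + ".tsv"))
    results["band_table"].to_csv(out_path / "band_window_table.csv", index=False)
    results["rt_table"].to_csv(out_path / "rt_table.csv", index=False)
    stats_blob = {
        "anovas": {k: _anova_to_dict(v) if v is not None else None
                   for k, v in results["anovas"].items()},
        "posthocs": {k: v.to_dict(orient="records")
                     for k, v in results["posthocs"].items()},
        "rt_anova": (
            _anova_to_dict(results["rt_anova"])
            if results["rt_anova"] is not None else None
        ),
    }
    (out_path / "statistics.json").write_text(json.dumps(stats_blob, indent=1))
    (out_path / "manifest.json").write_text(
        json.dumps(results["manifest"], indent=1)
    )


def _save_subject_cache(path, maps, rows, rt_rows, counts) -> None:
    arrays = {}
    keys = []
    for (syl, stim), rois in maps.items():
        for roi_name, tfmap in rois.items():
            tag = f"{syl}|{stim}|{roi_name}"
            keys.append(tag)
            arrays["values_" + tag] = tfmap.values
            arrays["freqs_" + tag] = tfmap.freqs_hz
            arrays["times_" + tag] = tfmap.times_ms
    np.savez_compressed(
        path,
        __keys=np.array(keys),
        __rows=json.dumps(rows),
        __rt=rt_rows.to_json(orient="split"),
        __counts=json.dumps(counts),
        **arrays,
    )


def _load_subject_cache(path):
    with np.load(path, allow_pickle=False) as z:
        maps: dict = {}
        for tag in z["__keys"]:
            syl, stim, roi_name = str(tag).split("|")
            maps.setdefault((syl, stim), {})[roi_name] = TimeFreqMap(
                z["values_" + tag], z["freqs_" + tag], z["times_" + tag],
                label=f"{syl}_{stim}_{roi_name}",
            )
        rows = json.loads(str(z["__rows"]))
        rt_rows = pd.read_json(StringIO(str(z["__rt"])), orient="split")
        counts = json.loads(str(z["__counts"]))
    return maps, rows, rt_rows, counts
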