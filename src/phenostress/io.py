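"""Plain-text readers/writers: per-channel CSV, beats CSV, EMA CSV,
profiles CSV, quality-mask CSV, and a YAML cohort manifest."""
from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from .types import (
    BeatSeries,
    Channel,
    ChannelRecording,
    EMAResponse,
    QualityMask,
    SubjectData,
)

__all__ = [
    "write_channel_csv", "read_channel_csv",
    "write_beats_csv", "read_beats_csv",
    "write_ema_csv", "read_ema_csv",
    "write_cohort", "write_masks_csv", "read_masks_csv",
]

_UNITS = {Channel.SC: "microsiemens", Channel.ST: "degrees Celsius",
          Channel.ACC_MAG: "g"}


def write_channel_csv(rec: ChannelRecording, path: str) -> None:
    pd.DataFrame({"time_s": rec.times(), "value": rec.samples}).to_csv(path, index=False)


def read_channel_csv(path: str, channel: Channel, sampling_rate: float) -> ChannelRecording:
    df = pd.read_csv(path)
    return ChannelRecording(channel=channel, sampling_rate=sampling_rate,
                            start_time=float(df["time_s"].iloc[0]),
                            samples=df["value"].to_numpy(float),
                            units=_UNITS.get(channel, ""))


def write_beats_csv(beats: BeatSeries, path: str) -> None:
    pd.DataFrame({"r_peak_time_s": beats.r_peak_times}).to_csv(path, index=False)


def read_beats_csv(path: str, duration: float | None = None) -> BeatSeries:
    df = pd.read_csv(path)
    return BeatSeries(r_peak_times=df["r_peak_time_s"].to_numpy(float), duration=duration)


def write_ema_csv(ema: list[EMAResponse], path: str) -> None:
    pd.DataFrame([{
        "prompt_time": r.prompt_time, "stress": r.stress_likert,
        "pleasure": r.pleasure, "arousal": r.arousal, "dominance": r.dominance,
        "activity": "|".join(sorted(r.activity)),
        "consumption": "|".join(sorted(r.consumption)),
    } for r in ema]).to_csv(path, index=False)


def read_ema_csv(path: str) -> list[EMAResponse]:
    df = pd.read_csv(path)
    return [EMAResponse(
        prompt_time=float(r.prompt_time), stress_likert=int(r.stress),
        pleasure=int(r.pleasure), arousal=int(r.arousal), dominance=int(r.dominance),
        activity=frozenset(str(r.activity).split("|")) if pd.notna(r.activity) else frozenset(),
        consumption=frozenset(str(r.consumption).split("|")) if pd.notna(r.consumption)
        else frozenset(),
    ) for r in df.itertuples()]


def write_cohort(cohort: list[SubjectData], out_dir: str, seed: int | None = None,
                 config_dict: dict | None = None) -> None:
    """One sub-directory per subject plus profiles.csv and manifest.yaml."""
    os.makedirs(out_dir, exist_ok=True)
    prof_rows = []
    for data in cohort:
        sid = data.profile.subject_id
        sdir = os.path.join(out_dir, sid)
        os.makedirs(sdir, exist_ok=True)
        write_beats_csv(data.beats, os.path.join(sdir, "beats.csv"))
        write_channel_csv(data.sc, os.path.join(sdir, "sc.csv"))
        write_channel_csv(data.st, os.path.join(sdir, "st.csv"))
        write_channel_csv(data.acc, os.path.join(sdir, "acc.csv"))
        write_ema_csv(data.ema, os.path.join(sdir, "ema.csv"))
        p = data.profile
        prof_rows.append({
            "subject_id": sid, "phenotype": p.phenotype.value,
            "baseline_hr": p.baseline_hr, "baseline_sc": p.baseline_sc,
            "baseline_st": p.baseline_st, "pss": p.pss,
            "dass_depression": p.dass_depression, "dass_anxiety": p.dass_anxiety,
            "dass_stress": p.dass_stress, "psqi": p.psqi, "age": p.age,
            "gender": p.gender,
        })
    pd.DataFrame(prof_rows).to_csv(os.path.join(out_dir, "profiles.csv"), index=False)
    manifest = {"n_subjects": len(cohort), "seed": seed,
                "config": config_dict or {}}
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)


def write_masks_csv(masks: dict[str, dict[Channel, QualityMask]], path: str) -> None:
    """Columns: subject, channel, seg_start_s, seg_end_s, good."""
    rows = []
    for sid, chmasks in masks.items():
        for ch, m in chmasks.items():
            rows.append(pd.DataFrame({
                "subject": sid, "channel": ch.value,
                "seg_start_s": m.seg_starts, "seg_end_s": m.seg_ends,
                "good": m.good.astype(int),
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_masks_csv(path: str) -> dict[str, dict[Channel, QualityMask]]:
    df = pd.read_csv(path)
    out: dict[str, dict[Channel, QualityMask]] = {}
    for (sid, ch), g in df.groupby(["subject", "channel"]):
        g = g.sort_values("seg_start_s")
        out.setdefault(str(sid), {})[Channel(ch)] = QualityMask(
            channel=Channel(ch), seg_starts=g["seg_start_s"].to_numpy(float),
            seg_ends=g["seg_end_s"].to_numpy(float),
            good=g["good"].to_numpy().astype(bool))
    return out
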