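"""Core in-memory containers shared across the pipeline.

Time convention: all timestamps are seconds of timezone-naive local clock
time, with t = 0 at 00:00 of the first recording day. Days start at
midnight; the nighttime baseline state N is the clock interval
[00:00, 06:00).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np

SECONDS_PER_DAY = 86_400
NIGHT_START_S = 0
NIGHT_END_S = 6 * 3600


class Phenotype(str, Enum):
    """Latent stress-reactivity phenotype of a simulated subject."""

    RESPONSIVE = "responsive"
    BLUNTED = "blunted"


class Channel(str, Enum):
    SC = "SC"
    ST = "ST"
    ACC_MAG = "ACC_MAG"
    ECG = "ECG"


#: Questionnaire instrument score ranges (inclusive).
INSTRUMENT_RANGES = {
    "pss": (0, 40),
    "dass_depression": (0, 21),
    "dass_anxiety": (0, 21),
    "dass_stress": (0, 21),
    "psqi": (0, 21),
}


@dataclass
class SubjectProfile:
    """Ground-truth description of a simulated subject.

    ``stress_effect`` maps effect names to the full-scale (latent level 1 →
    level 5) deltas that drive the physiology simulators:

    - ``hr_bpm``: mean heart-rate increase under maximal stress, beats/min
    - ``scr_rate_hz``: increase of the skin-conductance-response arrival rate
    - ``st_c``: skin-temperature shift under maximal stress (negative), °C
    - ``hrv_suppression``: fractional shrinkage of RR modulation amplitude
      under maximal stress, in [0, 1)
    """

    subject_id: str
    phenotype: Phenotype
    baseline_hr: float
    baseline_sc: float
    baseline_st: float
    stress_effect: dict[str, float]
    pss: int
    dass_depression: int
    dass_anxiety: int
    dass_stress: int
    psqi: int
    age: int
    gender: str

    def __post_init__(self) -> None:
        for name, (lo, hi) in INSTRUMENT_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside instrument range [{lo}, {hi}]")


@dataclass
class LatentStressSchedule:
    """Piecewise-constant latent stress level over the simulation horizon.

    ``bounds`` has one more element than ``levels``; segment i covers
    [bounds[i], bounds[i+1]) with latent level ``levels[i]`` in 1..5.
    ``activity_bounds``/``activity`` describe the physical-activity
    intensity trace (arbitrary units in [0, 1]) the same way.
    """

    bounds: np.ndarray
    levels: np.ndarray
    activity_bounds: np.ndarray
    activity: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.bounds[-1])

    def level_at(self, t: float | np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.bounds, t, side="right") - 1, 0, len(self.levels) - 1)
        return self.levels[idx]

    def activity_at(self, t: float | np.ndarray) -> np.ndarray:
        idx = np.clip(
            np.searchsorted(self.activity_bounds, t, side="right") - 1, 0, len(self.activity) - 1
        )
        return self.activity[idx]


@dataclass
class ChannelRecording:
    """Uniformly sampled single-channel recording."""

    channel: Channel
    sampling_rate: float
    start_time: float
    samples: np.ndarray
    units: str
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.sampling_rate

    def slice(self, start: float, end: float) -> np.ndarray:
        """Samples with timestamps in [start, end)."""
        i0 = int(np.ceil((start - self.start_time) * self.sampling_rate - 1e-9))
        i1 = int(np.ceil((end - self.start_time) * self.sampling_rate - 1e-9))
        return self.samples[max(i0, 0) : max(i1, 0)]


@dataclass
class BeatSeries:
    """R-peak event times (seconds, strictly increasing)."""

    r_peak_times: np.ndarray
    start_time: float = 0.0
    duration: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.r_peak_times, dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("r_peak_times must be strictly increasing")
        self.r_peak_times = t

    @property
    def rr_intervals(self) -> np.ndarray:
        """Successive RR intervals in milliseconds."""
        return np.diff(self.r_peak_times) * 1000.0

    def slice(self, start: float, end: float) -> np.ndarray:
        """Beat times in [start, end)."""
        i0, i1 = np.searchsorted(self.r_peak_times, [start, end], side="left")
        return self.r_peak_times[i0:i1]


@dataclass
class EMAResponse:
    """One smartphone stress self-report."""

    prompt_time: float
    stress_likert: int
    pleasure: int
    arousal: int
    dominance: int
    activity: frozenset[str]
    consumption: frozenset[str]

    def __post_init__(self) -> None:
        if not 1 <= self.stress_likert <= 5:
            raise ValueError("stress_likert must be in 1..5")
        for f in ("pleasure", "arousal", "dominance"):
            if not 1 <= getattr(self, f) <= 9:
                raise ValueError(f"{f} must be in 1..9")


@dataclass
class QualityMask:
    """Per-segment good/bad verdicts tiling one channel's recording.

    Segment i covers [seg_starts[i], seg_ends[i]); segments are contiguous
    and non-overlapping and jointly cover [seg_starts[0], seg_ends[-1]).
    """

    channel: Channel
    seg_starts: np.ndarray
    seg_ends: np.ndarray
    good: np.ndarray

    def __post_init__(self) -> None:
        self.seg_starts = np.asarray(self.seg_starts, dtype=float)
        self.seg_ends = np.asarray(self.seg_ends, dtype=float)
        self.good = np.asarray(self.good, dtype=bool)
        if not (len(self.seg_starts) == len(self.seg_ends) == len(self.good)):
            raise ValueError("mask arrays must have equal length")
        if len(self.seg_starts) > 1 and not np.allclose(self.seg_ends[:-1], self.seg_starts[1:]):
            raise ValueError("segments must tile the recording without gaps or overlap")

    @property
    def coverage(self) -> tuple[float, float]:
        return float(self.seg_starts[0]), float(self.seg_ends[-1])


@dataclass
class SubjectData:
    """Everything simulated for one subject."""

    profile: SubjectProfile
    schedule: LatentStressSchedule
    beats: BeatSeries
    sc: ChannelRecording
    st: ChannelRecording
    acc: ChannelRecording
    ema: list[EMAResponse]


def is_night(t: float | np.ndarray) -> np.ndarray:
    """True for clock times in the nighttime baseline interval [00:00, 06:00)."""
    tod = np.asarray(t) % SECONDS_PER_DAY
    return (tod >= NIGHT_START_S) & (tod < NIGHT_END_S)
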