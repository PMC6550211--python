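"""Rule-based per-channel signal-quality indicators.

Three channel-specific indicators, each yielding a binary good/bad verdict
per segment:

- ECG (beat series), 10-s segments: mean HR within [40, 180] bpm, no
  inter-beat gap above 3 s, max/min RR ratio below 2.2, and an adaptive
  beat-interval template match.
- Skin conductance, 5-s segments: signal deemed lost below 0.001 µS; bad if
  the lost fraction exceeds 0.9, or if any per-second relative change rises
  more than 20% or falls more than 10%.
- Skin temperature, per sample: good iff within [20, 40] °C.

Verdicts aggregate to window-level quality fractions (time-weighted share
of good coverage); downstream inclusion requires a fraction strictly
above 0.8.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import QCConfig
from .types import BeatSeries, Channel, ChannelRecording, QualityMask

__all__ = [
    "QrsTemplate",
    "ecg_segment_quality",
    "sc_window_quality",
    "st_sample_quality",
    "aggregate_window_quality",
    "build_ecg_mask",
    "build_sc_mask",
    "build_st_mask",
]

_N_QUANTILES = 8
_QUANTILE_GRID = np.linspace(0.05, 0.95, _N_QUANTILES)


def _rr_profile(rr_ms: np.ndarray) -> np.ndarray:
    """8-point RR quantile profile (linear-interpolated order statistics)."""
    s = np.sort(rr_ms)
    return np.interp(_QUANTILE_GRID * (len(s) - 1), np.arange(len(s)), s)


@dataclass
class QrsTemplate:
    """Running beat-interval template over the last k accepted segments.

    The template is the mean of the 8-point RR quantile profiles of the
    last ``k`` segments that passed all rules; the match statistic is
    ``1 − mean|profile − template| / mean(template)``, a scale-normalized
    similarity that is 1 for identical profiles. A segment matches when the
    statistic reaches ``threshold``. The first segment passing the three
    explicit rules seeds the template and is accepted; the template updates
    only from accepted segments.
    """

    k: int = 5
    threshold: float = 0.66
    profiles: list[np.ndarray] = field(default_factory=list)

    @property
    def template(self) -> np.ndarray | None:
        if not self.profiles:
            return None
        return np.mean(self.profiles, axis=0)

    def match(self, rr_ms: np.ndarray, profile: np.ndarray | None = None) -> float:
        tmpl = self.template
        prof = _rr_profile(rr_ms) if profile is None else profile
        if tmpl is None:
            return 1.0
        denom = max(float(np.mean(tmpl)), 1e-9)
        return 1.0 - float(np.mean(np.abs(prof - tmpl))) / denom

    def accept(self, rr_ms: np.ndarray, profile: np.ndarray | None = None) -> None:
        self.profiles.append(_rr_profile(rr_ms) if profile is None else profile)
        if len(self.profiles) > self.k:
            self.profiles = self.profiles[-self.k :]


def ecg_segment_quality(beat_times: np.ndarray, seg_start: float, seg_end: float,
                        template: QrsTemplate | None = None,
                        config: QCConfig | None = None) -> tuple[bool, QrsTemplate]:
    """Good/bad verdict for one 10-s beat segment; updates the template.

    Inter-beat gaps include the leads from the segment edges to the first
    and last beat, so an empty or sparsely covered segment fails the 3-s
    gap rule.
    """
    config = config or QCConfig()
    template = template if template is not None else QrsTemplate(
        k=config.template_k, threshold=config.template_threshold)
    t = np.asarray(beat_times, dtype=float)

    # Rule (ii) first: it is the only rule defined for < 2 beats.
    gaps = np.diff(t)
    max_gap = max(
        float(np.max(gaps)) if len(gaps) else 0.0,
        float(t[0] - seg_start) if len(t) else seg_end - seg_start,
        float(seg_end - t[-1]) if len(t) else seg_end - seg_start,
    )
    if max_gap > config.max_rr_gap_s:
        return False, template
    if len(t) < 2:
        return False, template

    rr_ms = np.diff(t) * 1000.0
    mean_hr = 60_000.0 / float(np.mean(rr_ms))
    if not config.hr_min_bpm <= mean_hr <= config.hr_max_bpm:
        return False, template
    if float(np.max(rr_ms) / np.min(rr_ms)) >= config.max_rr_ratio:
        return False, template
    prof = _rr_profile(rr_ms)
    if template.match(rr_ms, profile=prof) < template.threshold:
        return False, template
    template.accept(rr_ms, profile=prof)
    return True, template


def sc_window_quality(values: np.ndarray, sampling_rate: float,
                      config: QCConfig | None = None) -> bool:
    """Good/bad verdict for one 5-s skin-conductance segment."""
    config = config or QCConfig()
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return False
    lost = float(np.mean(v < config.sc_lost_threshold_us))
    if lost > config.sc_lost_ratio:
        return False
    # Slew rule on consecutive 1-s means: relative change per second.
    per_sec = max(int(round(sampling_rate)), 1)
    n_sec = len(v) // per_sec
    if n_sec >= 2:
        means = v[: n_sec * per_sec].reshape(n_sec, per_sec).mean(axis=1)
        denom = np.maximum(means[:-1], config.sc_lost_threshold_us)
        rel = (means[1:] - means[:-1]) / denom
        if np.any(rel > config.sc_max_rise) or np.any(rel < -config.sc_max_fall):
            return False
    return True


def st_sample_quality(value: float, config: QCConfig | None = None) -> bool:
    """Good iff the skin-temperature sample is finite and within [20, 40] °C."""
    config = config or QCConfig()
    if not np.isfinite(value):
        return False
    return config.st_min_c <= value <= config.st_max_c


def _segment_grid(duration: float, seg_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Full segments tiling [0, duration); a trailing partial segment covers
    the remainder but is always marked bad (conservative)."""
    n_full = int(np.floor(duration / seg_s + 1e-9))
    starts = np.arange(n_full) * seg_s
    ends = starts + seg_s
    if n_full * seg_s < duration - 1e-9:
        starts = np.append(starts, n_full * seg_s)
        ends = np.append(ends, duration)
    return starts, ends


def build_ecg_mask(beats: BeatSeries, duration: float | None = None,
                   config: QCConfig | None = None) -> QualityMask:
    """Sequential 10-s segment verdicts with the adaptive template."""
    config = config or QCConfig()
    duration = duration if duration is not None else (
        beats.duration if beats.duration is not None else float(beats.r_peak_times[-1]))
    starts, ends = _segment_grid(duration, config.ecg_segment_s)
    good = np.zeros(len(starts), dtype=bool)
    template = QrsTemplate(k=config.template_k, threshold=config.template_threshold)
    t = beats.r_peak_times
    idx = np.searchsorted(t, starts, side="left")
    idx_end = np.searchsorted(t, ends, side="left")
    full = ends - starts >= config.ecg_segment_s - 1e-9
    for i in range(len(starts)):
        if not full[i]:
            continue  # partial trailing segment: bad
        verdict, template = ecg_segment_quality(
            t[idx[i]:idx_end[i]], starts[i], ends[i], template, config)
        good[i] = verdict
    return QualityMask(channel=Channel.ECG, seg_starts=starts, seg_ends=ends, good=good)


def build_sc_mask(rec: ChannelRecording, config: QCConfig | None = None) -> QualityMask:
    config = config or QCConfig()
    if rec.channel is not Channel.SC:
        raise ValueError("build_sc_mask expects an SC recording")
    starts, ends = _segment_grid(rec.duration, config.sc_segment_s)
    good = np.zeros(len(starts), dtype=bool)
    per_seg = int(round(config.sc_segment_s * rec.sampling_rate))
    n_full = int(len(rec.samples) // per_seg)
    if n_full:
        segs = rec.samples[: n_full * per_seg].reshape(n_full, per_seg)
        for i in range(n_full):
            good[i] = sc_window_quality(segs[i], rec.sampling_rate, config)
    return QualityMask(channel=Channel.SC, seg_starts=starts, seg_ends=ends, good=good)


def build_st_mask(rec: ChannelRecording, config: QCConfig | None = None) -> QualityMask:
    """Per-sample verdicts: each sample is its own 1/rate-second segment."""
    config = config or QCConfig()
    if rec.channel is not Channel.ST:
        raise ValueError("build_st_mask expects an ST recording")
    dt = 1.0 / rec.sampling_rate
    starts = np.arange(len(rec.samples)) * dt
    ends = starts + dt
    v = rec.samples
    good = np.isfinite(v) & (v >= config.st_min_c) & (v <= config.st_max_c)
    return QualityMask(channel=Channel.ST, seg_starts=starts, seg_ends=ends, good=good)


def window_quality_fractions(mask: QualityMask, starts: np.ndarray, window_s: float) -> np.ndarray:
    """Vectorized :func:`aggregate_window_quality` for many aligned windows.

    Uses the cumulative good-coverage integral over the segment grid; exact
    for any window within the mask's coverage.
    """
    starts = np.asarray(starts, dtype=float)
    ends = starts + window_s
    lo, hi = mask.coverage
    if len(starts) and (starts.min() < lo - 1e-9 or ends.max() > hi + 1e-9):
        raise ValueError("window extends beyond mask coverage")
    seg_len = mask.seg_ends - mask.seg_starts
    cum = np.concatenate([[0.0], np.cumsum(seg_len * mask.good)])

    def _integral(t: np.ndarray) -> np.ndarray:
        i = np.clip(np.searchsorted(mask.seg_starts, t, side="right") - 1, 0, len(seg_len) - 1)
        return cum[i] + mask.good[i] * np.clip(t - mask.seg_starts[i], 0.0, seg_len[i])

    return (_integral(ends) - _integral(starts)) / window_s


def aggregate_window_quality(mask: QualityMask, start: float, end: float) -> float:
    """Time-weighted fraction of [start, end) covered by good segments."""
    if end <= start:
        raise ValueError("window must have positive length")
    lo, hi = mask.coverage
    if start < lo - 1e-9 or end > hi + 1e-9:
        raise ValueError("window extends beyond mask coverage")
    overlap = np.minimum(mask.seg_ends, end) - np.maximum(mask.seg_starts, start)
    overlap = np.clip(overlap, 0.0, None)
    return float(np.sum(overlap * mask.good) / (end - start))
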