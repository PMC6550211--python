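"""Windowed physiological feature extraction.

Eighteen features per 5-min window (60-s hop → one row per minute of
interior recording): six ECG/HRV features (mean HR, RMSSD, SDNN, LF, HF,
LF/HF), eight skin-conductance features (tonic mean, phasic power, SCR
area, SCR count, first/second absolute differences, tonic slope, SD) and
four skin-temperature features (mean, median, slope, SD), plus the
accelerometer-magnitude SD used as the physical-activity proxy.

Frequency-domain HRV uses the RR tachogram cubic-interpolated to 4 Hz,
linearly detrended, with a single-segment Hann periodogram; LF is band
power in 0.04–0.15 Hz and HF in 0.15–0.40 Hz (ms²).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, interp1d
from scipy.signal import butter, filtfilt, find_peaks, periodogram

from .config import FeatureConfig, WindowSpec
from .quality import window_quality_fractions
from .types import BeatSeries, Channel, ChannelRecording, QualityMask

__all__ = [
    "FEATURE_COLUMNS",
    "sliding_windows",
    "ecg_time_domain",
    "band_powers",
    "ecg_features",
    "sc_decompose",
    "detect_scrs",
    "scr_area",
    "sc_features",
    "st_features",
    "acc_sd",
    "extract_all",
]

#: Canonical feature order; correlation pruning drops the *later* feature of
#: a redundant pair, so this order doubles as the pruning tie-break.
FEATURE_COLUMNS = [
    "ecg_mean_hr", "ecg_rmssd", "ecg_sdnn", "ecg_lf", "ecg_hf", "ecg_lfhf",
    "sc_mean", "sc_phasic", "sc_area", "sc_scr_count",
    "sc_diff1", "sc_diff2", "sc_slope", "sc_sd",
    "st_mean", "st_median", "st_slope", "st_sd",
]


def sliding_windows(duration: float, spec: WindowSpec | None = None) -> np.ndarray:
    """Start times of full [start, start+window) windows at the hop cadence.

    count = floor((duration − window)/hop) + 1; empty for duration < window.
    """
    spec = spec or WindowSpec()
    if duration < spec.window_s:
        return np.empty(0)
    n = int(np.floor((duration - spec.window_s) / spec.hop_s + 1e-9)) + 1
    return np.arange(n) * spec.hop_s


def ecg_time_domain(rr_ms: np.ndarray) -> tuple[float, float, float]:
    """(mean HR bpm, RMSSD ms, SDNN ms) from RR intervals in ms."""
    rr = np.asarray(rr_ms, dtype=float)
    mean_hr = 60_000.0 / float(np.mean(rr))
    d = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(d**2))) if len(d) else 0.0
    sdnn = float(np.std(rr, ddof=0))
    return mean_hr, rmssd, sdnn


def _interp_tachogram(beat_times: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """RR(t) in ms sampled uniformly at ``rate_hz`` over the beat span.

    Cubic interpolation when at least 4 beats are available, else linear.
    RR at time t[i] is attributed to the interval ending at beat i.
    """
    t = np.asarray(beat_times, dtype=float)
    rr = np.diff(t) * 1000.0
    x = t[1:]
    if len(x) < 2:
        raise ValueError("need at least 3 beats for a tachogram")
    kind = CubicSpline if len(x) >= 4 else None
    grid = np.arange(x[0], x[-1], 1.0 / rate_hz)
    if kind is not None:
        vals = CubicSpline(x, rr)(grid)
    else:
        vals = interp1d(x, rr)(grid)
    return grid, vals


def band_powers(tach_ms: np.ndarray, rate_hz: float,
                config: FeatureConfig | None = None) -> tuple[float, float]:
    """(LF, HF) band power (ms²) of a uniformly sampled tachogram slice.

    Linear detrend, single-segment Hann periodogram, trapezoidal band
    integration.
    """
    config = config or FeatureConfig()
    x = np.asarray(tach_ms, dtype=float)
    t = np.arange(len(x)) / rate_hz
    coef = np.polyfit(t, x, 1)
    x = x - np.polyval(coef, t)
    f, p = periodogram(x, fs=rate_hz, window="hann", detrend=False)
    out = []
    for lo, hi in (config.lf_band, config.hf_band):
        m = (f >= lo) & (f <= hi)
        out.append(float(np.trapezoid(p[m], f[m])) if m.sum() > 1 else 0.0)
    return out[0], out[1]


def ecg_features(beat_times: np.ndarray, config: FeatureConfig | None = None) -> dict[str, float]:
    """Six ECG features for one window's beats; NaNs when under-determined.

    Fewer than 2 beats → all features missing; HF = 0 → LF/HF missing.
    Spectral features need enough beats to span ≥ 60 s of tachogram.
    """
    config = config or FeatureConfig()
    nan = float("nan")
    out = {k: nan for k in FEATURE_COLUMNS[:6]}
    t = np.asarray(beat_times, dtype=float)
    if len(t) < 2:
        return out
    rr = np.diff(t) * 1000.0
    out["ecg_mean_hr"], out["ecg_rmssd"], out["ecg_sdnn"] = ecg_time_domain(rr)
    if len(t) >= 4 and t[-1] - t[1] >= 60.0:
        _, tach = _interp_tachogram(t, config.tachogram_rate_hz)
        lf, hf = band_powers(tach, config.tachogram_rate_hz, config)
        out["ecg_lf"], out["ecg_hf"] = lf, hf
        out["ecg_lfhf"] = lf / hf if hf > 0 else nan
    return out


def _tonic_filter(sc: np.ndarray, rate: float, cutoff_hz: float) -> np.ndarray:
    nyq = rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError("tonic cutoff must be below the Nyquist frequency")
    b, a = butter(2, cutoff_hz / nyq, btype="low")
    padlen = min(3 * (max(len(b), len(a)) - 1) * 10, len(sc) - 1)
    return filtfilt(b, a, sc, padlen=padlen)


def sc_decompose(sc: np.ndarray, sampling_rate: float,
                 config: FeatureConfig | None = None):
    """Split SC into tonic (0.05-Hz low-pass) + phasic residual, detect SCRs.

    Returns ``(tonic, phasic, events)`` with ``tonic + phasic`` equal to the
    input by construction. ``events`` is a DataFrame with columns
    ``onset_idx, peak_idx, amplitude, rise_s``.
    """
    config = config or FeatureConfig()
    sc = np.asarray(sc, dtype=float)
    if len(sc) < 8:
        raise ValueError("SC slice too short to decompose")
    tonic = _tonic_filter(sc, sampling_rate, config.tonic_cutoff_hz)
    phasic = sc - tonic
    events = detect_scrs(phasic, sampling_rate, config)
    return tonic, phasic, events


def detect_scrs(phasic: np.ndarray, sampling_rate: float,
                config: FeatureConfig | None = None) -> pd.DataFrame:
    """Trough-to-peak SCR detection on the phasic trace.

    An event is a local-minimum → local-maximum rise of at least 0.01 µS
    completed within 5 s.
    """
    config = config or FeatureConfig()
    min_dist = max(int(0.5 * sampling_rate), 1)
    peaks, _ = find_peaks(phasic, distance=min_dist,
                          prominence=config.scr_min_amplitude_us * 0.5)
    onsets, amps, rises, keep = [], [], [], []
    max_rise_n = int(config.scr_max_rise_s * sampling_rate)
    for p in peaks:
        lo = max(p - max_rise_n, 0)
        onset = lo + int(np.argmin(phasic[lo : p + 1]))
        amp = phasic[p] - phasic[onset]
        rise = (p - onset) / sampling_rate
        if amp >= config.scr_min_amplitude_us and 0 < rise <= config.scr_max_rise_s:
            onsets.append(onset)
            amps.append(float(amp))
            rises.append(float(rise))
            keep.append(int(p))
    return pd.DataFrame({"onset_idx": onsets, "peak_idx": keep,
                         "amplitude": amps, "rise_s": rises})


def _event_areas(phasic: np.ndarray, events: pd.DataFrame, sampling_rate: float,
                 support_s: float = 10.0) -> np.ndarray:
    """Per-event trapezoidal area (µS·s) of phasic deviation above onset.

    Each event is integrated from its onset over at most ``support_s``
    seconds, truncated at the next event's onset.
    """
    if len(events) == 0:
        return np.empty(0)
    onsets = events["onset_idx"].to_numpy()
    n_support = int(support_s * sampling_rate)
    areas = np.zeros(len(onsets))
    for j, o in enumerate(onsets):
        end = min(o + n_support, len(phasic) - 1)
        if j + 1 < len(onsets):
            end = min(end, int(onsets[j + 1]))
        if end <= o:
            continue
        seg = phasic[o : end + 1] - phasic[o]
        areas[j] = float(np.trapezoid(np.clip(seg, 0.0, None), dx=1.0 / sampling_rate))
    return areas


def scr_area(phasic: np.ndarray, events: pd.DataFrame, sampling_rate: float,
             support_s: float = 10.0) -> float:
    """Σ trapezoidal area (µS·s) of phasic deviation above each SCR's onset."""
    return float(np.sum(_event_areas(phasic, events, sampling_rate, support_s)))


def sc_features(sc: np.ndarray, tonic: np.ndarray, phasic: np.ndarray,
                events: pd.DataFrame, sampling_rate: float) -> dict[str, float]:
    """Eight SC features for one window given its decomposition."""
    t = np.arange(len(sc)) / sampling_rate
    slope = float(np.polyfit(t, tonic, 1)[0]) if len(sc) > 1 else 0.0
    d1 = np.diff(sc)
    d2 = np.diff(sc, n=2)
    return {
        "sc_mean": float(np.mean(tonic)),
        "sc_phasic": float(np.mean(phasic**2)),
        "sc_area": scr_area(phasic, events, sampling_rate),
        "sc_scr_count": float(len(events)),
        "sc_diff1": float(np.mean(np.abs(d1))) if len(d1) else 0.0,
        "sc_diff2": float(np.mean(np.abs(d2))) if len(d2) else 0.0,
        "sc_slope": slope,
        "sc_sd": float(np.std(sc, ddof=0)),
    }


def st_features(st: np.ndarray, sampling_rate: float) -> dict[str, float]:
    """Four ST features; slope is the least-squares trend in °C/s."""
    st = np.asarray(st, dtype=float)
    t = np.arange(len(st)) / sampling_rate
    slope = float(np.polyfit(t, st, 1)[0]) if len(st) > 1 else 0.0
    return {
        "st_mean": float(np.mean(st)),
        "st_median": float(np.median(st)),
        "st_slope": slope,
        "st_sd": float(np.std(st, ddof=0)),
    }


def acc_sd(acc: np.ndarray) -> float:
    """Standard deviation of the accelerometer magnitude in the window."""
    return float(np.std(np.asarray(acc, dtype=float), ddof=0))


@dataclass
class _GlobalSc:
    tonic: np.ndarray
    phasic: np.ndarray
    events: pd.DataFrame


def _rolling_sd(x: np.ndarray, win: int, hop: int, n_out: int) -> np.ndarray:
    """Windowed SD via cumulative sums (population convention)."""
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x.astype(float) ** 2)])
    starts = np.arange(n_out) * hop
    ends = starts + win
    s1 = c1[ends] - c1[starts]
    s2 = c2[ends] - c2[starts]
    var = s2 / win - (s1 / win) ** 2
    return np.sqrt(np.clip(var, 0.0, None))


def extract_all(beats: BeatSeries, sc: ChannelRecording, st: ChannelRecording,
                acc: ChannelRecording, masks: dict[Channel, QualityMask],
                spec: WindowSpec | None = None,
                config: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature table: one row per 5-min window at the 60-s hop.

    Channels must share the time origin and duration (within one hop).
    Windows whose per-channel quality fraction does not exceed the gate get
    missing values for that channel's features only; quality fractions and
    ACC SD are reported for every row regardless.

    The SC tonic component and the 4-Hz tachogram are estimated once on the
    full recording and sliced per window (avoids filter edge transients at
    window borders); all other features are computed window-locally.
    """
    spec = spec or WindowSpec()
    config = config or FeatureConfig()
    durations = [sc.duration, st.duration, acc.duration]
    if beats.duration is not None:
        durations.append(beats.duration)
    starts_err = [sc.start_time, st.start_time, acc.start_time, beats.start_time]
    if max(starts_err) - min(starts_err) > 1e-6:
        raise ValueError("channels must share a common time origin")
    if max(durations) - min(durations) > spec.hop_s:
        raise ValueError("channel durations are misaligned by more than one hop")
    duration = min(durations)
    win_starts = sliding_windows(duration, spec)
    n = len(win_starts)
    nan = float("nan")

    # --- global SC decomposition
    tonic = _tonic_filter(sc.samples, sc.sampling_rate, config.tonic_cutoff_hz)
    phasic = sc.samples - tonic
    events = detect_scrs(phasic, sc.sampling_rate, config)
    ev_onset_t = events["onset_idx"].to_numpy() / sc.sampling_rate if len(events) else np.empty(0)

    # --- global tachogram
    bt = beats.r_peak_times
    tach_grid = tach_vals = None
    if len(bt) >= 4:
        tach_grid, tach_vals = _interp_tachogram(bt, config.tachogram_rate_hz)

    # --- per-window quality fractions
    q = {ch: window_quality_fractions(masks[ch], win_starts, spec.window_s)
         for ch in (Channel.ECG, Channel.SC, Channel.ST)}

    # --- ACC SD for all windows (vectorized)
    acc_win = int(round(spec.window_s * acc.sampling_rate))
    acc_hop = int(round(spec.hop_s * acc.sampling_rate))
    n_acc = min(n, (len(acc.samples) - acc_win) // acc_hop + 1) if len(acc.samples) >= acc_win else 0
    acc_sds = np.full(n, nan)
    if n_acc > 0:
        acc_sds[:n_acc] = _rolling_sd(acc.samples, acc_win, acc_hop, n_acc)

    out = pd.DataFrame({"window_start": win_starts})
    gate = config.quality_gate

    # --- ECG (sequential: per-window time-domain + tachogram slice spectra)
    ecg_cols = {k: np.full(n, nan) for k in FEATURE_COLUMNS[:6]}
    bi0 = np.searchsorted(bt, win_starts, side="left")
    bi1 = np.searchsorted(bt, win_starts + spec.window_s, side="left")
    ok_ecg = q[Channel.ECG] > gate
    for i in np.flatnonzero(ok_ecg):
        seg = bt[bi0[i]:bi1[i]]
        if len(seg) < 2:
            continue
        rr = np.diff(seg) * 1000.0
        (ecg_cols["ecg_mean_hr"][i], ecg_cols["ecg_rmssd"][i],
         ecg_cols["ecg_sdnn"][i]) = ecg_time_domain(rr)
        if tach_grid is not None:
            ws = win_starts[i]
            j0, j1 = np.searchsorted(tach_grid, [ws, ws + spec.window_s])
            if (j1 - j0) / config.tachogram_rate_hz >= 60.0:
                lf, hf = band_powers(tach_vals[j0:j1], config.tachogram_rate_hz, config)
                ecg_cols["ecg_lf"][i], ecg_cols["ecg_hf"][i] = lf, hf
                ecg_cols["ecg_lfhf"][i] = lf / hf if hf > 0 else nan
    for k, v in ecg_cols.items():
        out[k] = v

    # --- SC (vectorized over windows via cumulative sums)
    sc_rate = sc.sampling_rate
    sc_win = int(round(spec.window_s * sc_rate))
    sc_hop = int(round(spec.hop_s * sc_rate))
    w0 = np.arange(n) * sc_hop
    w1 = w0 + sc_win
    x = sc.samples

    def _winsum(arr: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(arr)])
        return c[b] - c[a]

    sc_mean_t = _winsum(tonic, w0, w1) / sc_win
    phasic_pow = _winsum(phasic**2, w0, w1) / sc_win
    sc_m1 = _winsum(x, w0, w1) / sc_win
    sc_m2 = _winsum(x**2, w0, w1) / sc_win
    sc_sd_ = np.sqrt(np.clip(sc_m2 - sc_m1**2, 0.0, None))
    ad1 = np.abs(np.diff(x))
    ad2 = np.abs(np.diff(x, n=2))
    sc_d1 = _winsum(ad1, w0, np.minimum(w1 - 1, len(ad1))) / (sc_win - 1)
    sc_d2 = _winsum(ad2, w0, np.minimum(w1 - 2, len(ad2))) / (sc_win - 2)
    # tonic least-squares slope: dot with centered-time weights
    tw = np.arange(sc_win) / sc_rate
    tw = (tw - tw.mean()) / np.sum((tw - tw.mean()) ** 2)
    sc_slope_ = np.array([float(tonic[a:b] @ tw) for a, b in zip(w0, w1)])
    # per-event SCR areas computed once globally, summed per window by onset
    ev_areas = _event_areas(phasic, events, sc_rate)
    e0 = np.searchsorted(ev_onset_t, win_starts, side="left")
    e1 = np.searchsorted(ev_onset_t, win_starts + spec.window_s, side="left")
    ca = np.concatenate([[0.0], np.cumsum(ev_areas)])
    sc_area_ = ca[e1] - ca[e0]
    sc_count_ = (e1 - e0).astype(float)

    ok_sc = q[Channel.SC] > gate
    for k, v in zip(FEATURE_COLUMNS[6:14],
                    [sc_mean_t, phasic_pow, sc_area_, sc_count_, sc_d1, sc_d2,
                     sc_slope_, sc_sd_]):
        out[k] = np.where(ok_sc, v, nan)

    # --- ST (vectorized)
    st_rate = st.sampling_rate
    st_win = int(round(spec.window_s * st_rate))
    st_hop = int(round(spec.hop_s * st_rate))
    s0 = np.arange(n) * st_hop
    s1 = s0 + st_win
    y = st.samples
    st_m1 = _winsum(y, s0, s1) / st_win
    st_m2 = _winsum(y**2, s0, s1) / st_win
    st_sd_ = np.sqrt(np.clip(st_m2 - st_m1**2, 0.0, None))
    view = np.lib.stride_tricks.sliding_window_view(y, st_win)[::st_hop][:n]
    st_med_ = np.median(view, axis=1)
    tws = np.arange(st_win) / st_rate
    tws = (tws - tws.mean()) / np.sum((tws - tws.mean()) ** 2)
    st_slope_ = view @ tws
    ok_st = q[Channel.ST] > gate
    for k, v in zip(FEATURE_COLUMNS[14:], [st_m1, st_med_, st_slope_, st_sd_]):
        out[k] = np.where(ok_st, v, nan)

    out["acc_sd"] = acc_sds
    out["ecg_quality"] = q[Channel.ECG]
    out["sc_quality"] = q[Channel.SC]
    out["st_quality"] = q[Channel.ST]
    cols = ["window_start", *FEATURE_COLUMNS, "acc_sd", "ecg_quality", "sc_quality", "st_quality"]
    return out[cols]
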