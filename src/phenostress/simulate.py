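"""Synthetic multi-day wearable cohort generator.

Simulates, per subject: a latent piecewise-constant stress level driving
R-peak times (heart rate + LF/HF sinusoidal RR modulation), skin
conductance (tonic level + Poisson-arriving phasic responses), skin
temperature, accelerometer magnitude, and stress self-reports (EMA).
Ground-truth phenotypes and effect sizes are retained on the
:class:`~phenostress.types.SubjectProfile` so downstream recovery is
testable without external data.
"""
from __future__ import annotations

import bisect
import math

import numpy as np

from .config import SimConfig
from .types import (
    SECONDS_PER_DAY,
    BeatSeries,
    Channel,
    ChannelRecording,
    EMAResponse,
    LatentStressSchedule,
    Phenotype,
    SubjectData,
    SubjectProfile,
    is_night,
)

__all__ = [
    "generate_cohort",
    "generate_profile",
    "simulate_subject",
    "simulate_latent_schedule",
    "simulate_beats",
    "simulate_sc",
    "simulate_st",
    "simulate_acc",
    "simulate_ema",
    "inject_artifacts",
    "ARTIFACT_TYPES",
]


def _stress_scale(level: float | np.ndarray) -> np.ndarray:
    """Map latent level 1..5 to a 0..1 effect multiplier."""
    return (np.asarray(level, dtype=float) - 1.0) / 4.0


def _draw_score(rng: np.random.Generator, mean_sd: tuple[float, float], lo: int, hi: int) -> int:
    return int(np.clip(round(rng.normal(*mean_sd)), lo, hi))


def generate_profile(rng: np.random.Generator, subject_id: str, phenotype: Phenotype,
                     config: SimConfig) -> SubjectProfile:
    """Draw one subject profile; questionnaire scores depend on phenotype."""
    key = phenotype.value
    effects = dict(config.responsive_effects if phenotype is Phenotype.RESPONSIVE
                   else config.blunted_effects)
    return SubjectProfile(
        subject_id=subject_id,
        phenotype=phenotype,
        baseline_hr=float(rng.normal(config.baseline_hr_mean, config.baseline_hr_sd)),
        baseline_sc=float(max(rng.normal(config.baseline_sc_mean, config.baseline_sc_sd), 0.3)),
        baseline_st=float(rng.normal(config.baseline_st_mean, config.baseline_st_sd)),
        stress_effect=effects,
        pss=_draw_score(rng, config.pss_by_phenotype[key], 0, 40),
        dass_depression=_draw_score(rng, config.dass_depression_by_phenotype[key], 0, 21),
        dass_anxiety=_draw_score(rng, config.dass_anxiety_by_phenotype[key], 0, 21),
        dass_stress=_draw_score(rng, config.dass_stress_by_phenotype[key], 0, 21),
        psqi=_draw_score(rng, config.psqi_by_phenotype[key], 0, 21),
        age=int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 22, 65)),
        gender=str(rng.choice(["female", "male"])),
    )


def simulate_latent_schedule(days: int, seed: int | np.random.Generator,
                             config: SimConfig | None = None) -> LatentStressSchedule:
    """Piecewise-constant latent stress level plus an activity trace.

    Nighttime (clock 00:00–06:00) is forced to level 1 (no stress) and zero
    activity; daytime levels are drawn i.i.d. per segment from
    ``config.day_level_probs``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    horizon = days * SECONDS_PER_DAY
    levels_list: list[int] = []
    bounds: list[float] = [0.0]
    t = 0.0
    while t < horizon:
        day_start = math.floor(t / SECONDS_PER_DAY) * SECONDS_PER_DAY
        night_end = day_start + 6 * 3600
        if t < night_end:  # night: level 1 until 06:00
            seg_end = min(night_end, horizon)
            level = 1
        else:
            dur = rng.uniform(config.segment_minutes_min, config.segment_minutes_max) * 60.0
            seg_end = min(t + dur, horizon)
            # clip segments at the next midnight so night always restarts at 1
            next_midnight = day_start + SECONDS_PER_DAY
            seg_end = min(seg_end, next_midnight)
            level = int(rng.choice(np.arange(1, 6), p=config.day_level_probs))
        levels_list.append(level)
        bounds.append(seg_end)
        t = seg_end

    # Activity bouts: Poisson arrivals in daytime, zero intensity otherwise.
    a_bounds: list[float] = [0.0]
    a_vals: list[float] = []
    t = 0.0
    bout_len = config.activity_bout_minutes * 60.0
    while t < horizon:
        if is_night(t):
            day_start = math.floor(t / SECONDS_PER_DAY) * SECONDS_PER_DAY
            seg_end = min(day_start + 6 * 3600, horizon)
            a_vals.append(0.0)
            a_bounds.append(seg_end)
            t = seg_end
            continue
        gap = rng.exponential(3600.0 / max(config.activity_bout_rate_per_hour, 1e-9))
        next_midnight = (math.floor(t / SECONDS_PER_DAY) + 1) * SECONDS_PER_DAY
        bout_start = t + gap
        if bout_start >= min(next_midnight, horizon):
            a_vals.append(0.0)
            a_bounds.append(min(next_midnight, horizon))
            t = min(next_midnight, horizon)
            continue
        a_vals.append(0.0)
        a_bounds.append(bout_start)
        bout_end = min(bout_start + bout_len, next_midnight, horizon)
        a_vals.append(float(rng.uniform(*config.activity_intensity_range)))
        a_bounds.append(bout_end)
        t = bout_end

    return LatentStressSchedule(
        bounds=np.asarray(bounds),
        levels=np.asarray(levels_list, dtype=int),
        activity_bounds=np.asarray(a_bounds),
        activity=np.asarray(a_vals),
    )


def simulate_beats(profile: SubjectProfile, schedule: LatentStressSchedule,
                   seed: int | np.random.Generator,
                   config: SimConfig | None = None) -> BeatSeries:
    """R-peak times from an instantaneous-heart-rate model.

    HR(t) = baseline + stress effect · scale(level(t)) + circadian night dip;
    each RR interval additionally carries LF (0.1 Hz) and HF (0.3 Hz)
    sinusoidal modulation — shrunk under stress by the phenotype's
    ``hrv_suppression`` — plus white noise.
    """
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    horizon = schedule.duration
    d_hr = profile.stress_effect.get("hr_bpm", 0.0)
    supp = profile.stress_effect.get("hrv_suppression", 0.0)
    bounds = schedule.bounds.tolist()
    levels = schedule.levels
    two_pi_lf = 2 * math.pi * config.lf_freq_hz
    two_pi_hf = 2 * math.pi * config.hf_freq_hz
    a_lf, a_hf = config.lf_amplitude_ms, config.hf_amplitude_ms
    noise = rng.normal(0.0, config.rr_noise_ms, size=int(horizon / 0.3) + 16)

    beats = [0.0]
    t = 0.0
    i = 0
    n_levels = len(levels)
    while True:
        idx = bisect.bisect_right(bounds, t) - 1
        if idx >= n_levels:
            idx = n_levels - 1
        s = (levels[idx] - 1.0) / 4.0
        hr = profile.baseline_hr + d_hr * s
        if (t % SECONDS_PER_DAY) < 6 * 3600:
            hr += config.circadian_hr_dip_bpm
        shrink = 1.0 - supp * s
        rr_ms = (60_000.0 / max(hr, 20.0)
                 + shrink * (a_lf * math.sin(two_pi_lf * t) + a_hf * math.sin(two_pi_hf * t))
                 + noise[i])
        rr_ms = max(rr_ms, 300.0)
        t += rr_ms / 1000.0
        i += 1
        if t >= horizon:
            break
        beats.append(t)
    return BeatSeries(r_peak_times=np.asarray(beats), duration=horizon)


def _scr_kernel(rate: float, rise_s: float, tau_s: float, length_s: float = 30.0) -> np.ndarray:
    """Unit-amplitude canonical SCR: linear rise over ``rise_s``, exp decay."""
    n = int(length_s * rate)
    t = np.arange(n) / rate
    k = np.where(t < rise_s, t / rise_s, np.exp(-(t - rise_s) / tau_s))
    return k


def simulate_sc(profile: SubjectProfile, schedule: LatentStressSchedule,
                seed: int | np.random.Generator,
                config: SimConfig | None = None) -> ChannelRecording:
    """Skin conductance = tonic level + Poisson-arriving SCRs + noise.

    The SCR arrival rate rises with latent stress by the phenotype's
    ``scr_rate_hz`` effect. Ground-truth event times/amplitudes are stored
    in ``meta["scr_times"]`` / ``meta["scr_amps"]``.
    """
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = config.sc_rate
    horizon = schedule.duration
    n = int(round(horizon * rate))
    t = np.arange(n) / rate

    tonic = (profile.baseline_sc
             + config.sc_night_offset * is_night(t).astype(float)
             + config.sc_drift_amplitude * np.sin(2 * np.pi * t / config.sc_drift_period_s))

    d_rate = profile.stress_effect.get("scr_rate_hz", 0.0)
    ev_times: list[float] = []
    ev_amps: list[float] = []
    for i in range(len(schedule.levels)):
        a, b = schedule.bounds[i], schedule.bounds[i + 1]
        lam = config.scr_base_rate_hz + d_rate * float(_stress_scale(schedule.levels[i]))
        k = rng.poisson(lam * (b - a))
        if k:
            ev_times.extend(rng.uniform(a, b, size=k).tolist())
            ev_amps.extend((config.scr_amp_median
                            * np.exp(rng.normal(0.0, config.scr_amp_log_sd, size=k))).tolist())

    sc = tonic.copy()
    kernel = _scr_kernel(rate, config.scr_rise_s, config.scr_decay_tau_s)
    for et, amp in zip(ev_times, ev_amps):
        i0 = int(round(et * rate))
        i1 = min(i0 + len(kernel), n)
        if i0 < n:
            sc[i0:i1] += amp * kernel[: i1 - i0]
    sc += rng.normal(0.0, config.sc_noise_sd, size=n)
    np.clip(sc, 0.0, None, out=sc)
    order = np.argsort(ev_times)
    return ChannelRecording(
        channel=Channel.SC, sampling_rate=rate, start_time=0.0, samples=sc,
        units="microsiemens",
        meta={"scr_times": np.asarray(ev_times)[order], "scr_amps": np.asarray(ev_amps)[order]},
    )


def simulate_st(profile: SubjectProfile, schedule: LatentStressSchedule,
                seed: int | np.random.Generator,
                config: SimConfig | None = None) -> ChannelRecording:
    """Skin temperature at 1 Hz: higher at night, lower under stress."""
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = config.st_rate
    n = int(round(schedule.duration * rate))
    t = np.arange(n) / rate
    d_st = profile.stress_effect.get("st_c", 0.0)
    phase = rng.uniform(0, 2 * np.pi)
    st = (profile.baseline_st
          + config.st_night_offset * is_night(t).astype(float)
          + d_st * _stress_scale(schedule.level_at(t))
          + config.st_drift_sd * np.sin(2 * np.pi * t / config.st_drift_period_s + phase)
          + rng.normal(0.0, config.st_noise_sd, size=n))
    return ChannelRecording(channel=Channel.ST, sampling_rate=rate, start_time=0.0,
                            samples=st, units="degrees Celsius")


def simulate_acc(profile: SubjectProfile, schedule: LatentStressSchedule,
                 seed: int | np.random.Generator,
                 config: SimConfig | None = None) -> ChannelRecording:
    """Accelerometer magnitude: 1 g mean, variance tracking the activity trace."""
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = config.acc_rate
    n = int(round(schedule.duration * rate))
    t = np.arange(n) / rate
    sd = config.acc_base_sd + config.acc_activity_sd_gain * schedule.activity_at(t)
    samples = 1.0 + rng.standard_normal(n) * sd
    np.clip(samples, 0.0, None, out=samples)
    return ChannelRecording(channel=Channel.ACC_MAG, sampling_rate=rate, start_time=0.0,
                            samples=samples, units="g")


def simulate_ema(profile: SubjectProfile, schedule: LatentStressSchedule,
                 seed: int | np.random.Generator,
                 config: SimConfig | None = None) -> list[EMAResponse]:
    """Stress self-reports: 12/day at random waking-hour times ≥30 min apart.

    The reported Likert level equals the latent level at the prompt time,
    perturbed by ±1 with probability ``ema_misreport_prob``. Pleasure is
    negatively coupled to reported stress.
    """
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = int(round(schedule.duration / SECONDS_PER_DAY))
    k = config.ema_per_day
    gap = config.ema_min_gap_s
    wake_start = config.ema_wake_start_h * 3600
    wake_len = (config.ema_wake_end_h - config.ema_wake_start_h) * 3600
    slack = wake_len - (k - 1) * gap
    if slack <= 0:
        raise ValueError("waking window too short for the prompt schedule")
    activities_low = ["lying", "sitting", "standing"]
    activities_high = ["walking", "running", "biking", "driving"]
    consumptions = ["caffeine", "alcohol", "soft_drink", "breakfast", "lunch",
                    "dinner", "snack", "none"]
    out: list[EMAResponse] = []
    for d in range(days):
        offsets = np.sort(rng.uniform(0, slack, size=k))
        times = d * SECONDS_PER_DAY + wake_start + offsets + np.arange(k) * gap
        for pt in times:
            level = int(schedule.level_at(pt))
            if rng.random() < config.ema_misreport_prob:
                level = int(np.clip(level + rng.choice([-1, 1]), 1, 5))
            pleasure = int(np.clip(round(7.5 - 1.1 * level + rng.normal(0, 1.0)), 1, 9))
            arousal = int(np.clip(round(2.0 + 1.2 * level + rng.normal(0, 1.0)), 1, 9))
            dominance = int(np.clip(round(5.0 + rng.normal(0, 1.5)), 1, 9))
            pool = activities_high if schedule.activity_at(pt) > 0.2 else activities_low
            act = frozenset([str(rng.choice(pool))])
            cons = frozenset([str(rng.choice(consumptions))])
            out.append(EMAResponse(prompt_time=float(pt), stress_likert=level,
                                   pleasure=pleasure, arousal=arousal, dominance=dominance,
                                   activity=act, consumption=cons))
    return out


def simulate_subject(subject_id: str, phenotype: Phenotype, seed: int | np.random.SeedSequence,
                     config: SimConfig | None = None) -> SubjectData:
    """Simulate one subject end to end (profile, recordings, EMA)."""
    config = config or SimConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    profile = generate_profile(rngs[0], subject_id, phenotype, config)
    schedule = simulate_latent_schedule(config.days, rngs[1], config)
    return SubjectData(
        profile=profile,
        schedule=schedule,
        beats=simulate_beats(profile, schedule, rngs[2], config),
        sc=simulate_sc(profile, schedule, rngs[3], config),
        st=simulate_st(profile, schedule, rngs[4], config),
        acc=simulate_acc(profile, schedule, rngs[5], config),
        ema=simulate_ema(profile, schedule, np.random.default_rng(ss.spawn(1)[0]), config),
    )


def cohort_phenotypes(n_subjects: int, responsive_fraction: float) -> list[Phenotype]:
    """Deterministic phenotype assignment: first ``round(n·f)`` responsive."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (leave-one-subject-out needs >= 2)")
    if not 0.0 <= responsive_fraction <= 1.0:
        raise ValueError("responsive_fraction must be in [0, 1]")
    n_resp = int(round(n_subjects * responsive_fraction))
    return [Phenotype.RESPONSIVE] * n_resp + [Phenotype.BLUNTED] * (n_subjects - n_resp)


def generate_cohort(n_subjects: int, responsive_fraction: float, seed: int,
                    config: SimConfig | None = None) -> list[SubjectData]:
    """Simulate a full cohort. Deterministic given (args, config)."""
    config = config or SimConfig()
    phenos = cohort_phenotypes(n_subjects, responsive_fraction)
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_subjects)
    return [
        simulate_subject(f"S{i:03d}", ph, child, config)
        for i, (ph, child) in enumerate(zip(phenos, children))
    ]


ARTIFACT_TYPES = ("sc_flatline", "sc_slew", "st_out_of_range", "rr_gap", "rr_ectopic")


def inject_artifacts(data: ChannelRecording | BeatSeries, artifact_spec: dict[str, dict],
                     seed: int | np.random.Generator):
    """Corrupt a recording with named artifact types; return ground truth.

    ``artifact_spec`` maps an artifact type to parameters, e.g.
    ``{"sc_flatline": {"count": 2, "duration_s": 10.0}}``. Returns
    ``(corrupted, truth)`` where ``truth`` is a list of
    ``(artifact_type, start_s, end_s)`` intervals. A spec with zero counts
    returns data equal to the input.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for name in artifact_spec:
        if name not in ARTIFACT_TYPES:
            raise ValueError(f"unknown artifact type: {name!r}")

    truth: list[tuple[str, float, float]] = []
    if isinstance(data, BeatSeries):
        times = data.r_peak_times.copy()
        duration = data.duration or float(times[-1])
        for name, params in artifact_spec.items():
            if name not in ("rr_gap", "rr_ectopic"):
                raise ValueError(f"artifact {name!r} does not apply to a beat series")
            count = int(params.get("count", 0))
            for _ in range(count):
                if name == "rr_gap":
                    gap = float(params.get("gap_s", 3.5))
                    start = params.get("at_s")
                    start = float(start) if start is not None else rng.uniform(0, duration - gap)
                    times = times[(times < start) | (times >= start + gap)]
                    truth.append((name, start, start + gap))
                else:  # rr_ectopic: move one beat to create a short/long RR pair
                    at = params.get("at_s")
                    at = float(at) if at is not None else rng.uniform(1.0, duration - 1.0)
                    i = int(np.searchsorted(times, at))
                    if 1 <= i < len(times) - 1:
                        rr_prev = times[i] - times[i - 1]
                        times[i] = times[i - 1] + 0.25 * rr_prev
                        truth.append((name, float(times[i - 1]), float(times[i + 1])))
        return BeatSeries(r_peak_times=np.sort(times), duration=duration), truth

    samples = data.samples.copy()
    rate = data.sampling_rate
    duration = data.duration
    for name, params in artifact_spec.items():
        applies = {"sc_flatline": Channel.SC, "sc_slew": Channel.SC,
                   "st_out_of_range": Channel.ST}
        if name not in applies:
            raise ValueError(f"artifact {name!r} does not apply to a sampled channel")
        if applies[name] is not data.channel:
            raise ValueError(f"artifact {name!r} does not apply to channel {data.channel}")
        count = int(params.get("count", 0))
        dur = float(params.get("duration_s", 10.0))
        for _ in range(count):
            start = params.get("at_s")
            start = float(start) if start is not None else rng.uniform(0, duration - dur)
            i0, i1 = int(start * rate), int((start + dur) * rate)
            if name == "sc_flatline":
                samples[i0:i1] = float(params.get("value", 0.0005))
            elif name == "sc_slew":
                samples[i0:i1] = samples[i0:i1] * float(params.get("factor", 1.6))
            else:  # st_out_of_range
                samples[i0:i1] = float(params.get("value", 45.0))
            truth.append((name, start, start + dur))
    return (
        ChannelRecording(channel=data.channel, sampling_rate=rate, start_time=data.start_time,
                         samples=samples, units=data.units, meta=dict(data.meta)),
        truth,
    )
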