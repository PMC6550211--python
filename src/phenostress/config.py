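"""Tunable parameters, grouped per pipeline stage.

Simulation defaults encode the study conditions the pipeline is designed
for: 5-day recordings, 12 stress prompts/day at least 30 min apart on a
5-point Likert scale, a daytime stress distribution dominated by
"no stress", and a cohort split between physiologically responsive and
blunted subjects. See docs/methods.md for the rationale behind each value.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SimConfig:
    """Synthetic-cohort generator parameters."""

    days: int = 5

    # Sampling rates, Hz. Skin conductance is nominally acquired at 256 Hz by
    # the wrist device; it is simulated/processed at a configurable rate
    # (default 8 Hz) since every SC rule here is rate-parameterized and the
    # signal band of interest is < 1 Hz.
    sc_rate: float = 8.0
    st_rate: float = 1.0
    acc_rate: float = 32.0

    # Latent stress schedule. Daytime levels 1..5; probabilities follow the
    # observed self-report imbalance (~50% no stress, ~0.3% extreme stress).
    day_level_probs: tuple[float, ...] = (0.504, 0.353, 0.10, 0.04, 0.003)
    segment_minutes_min: float = 30.0
    segment_minutes_max: float = 90.0
    # Physical-activity bouts (daytime only).
    activity_bout_rate_per_hour: float = 0.8
    activity_bout_minutes: float = 15.0
    activity_intensity_range: tuple[float, float] = (0.3, 1.0)

    # Heart rate / HRV.
    baseline_hr_mean: float = 72.0
    baseline_hr_sd: float = 5.0
    circadian_hr_dip_bpm: float = -10.0
    lf_amplitude_ms: float = 25.0
    hf_amplitude_ms: float = 20.0
    rr_noise_ms: float = 8.0
    lf_freq_hz: float = 0.1
    hf_freq_hz: float = 0.3

    # Skin conductance.
    baseline_sc_mean: float = 1.7
    baseline_sc_sd: float = 0.4
    sc_night_offset: float = 1.1
    sc_drift_amplitude: float = 0.2
    sc_drift_period_s: float = 10_800.0
    scr_base_rate_hz: float = 1.0 / 60.0
    scr_amp_median: float = 0.3
    scr_amp_log_sd: float = 0.5
    scr_rise_s: float = 1.0
    scr_decay_tau_s: float = 4.0
    sc_noise_sd: float = 0.01

    # Skin temperature.
    baseline_st_mean: float = 31.4
    baseline_st_sd: float = 0.8
    st_night_offset: float = 1.7
    st_noise_sd: float = 0.05
    st_drift_sd: float = 0.3
    st_drift_period_s: float = 7200.0

    # Accelerometer magnitude: 1 g mean; SD tracks the activity trace.
    acc_base_sd: float = 0.015
    acc_activity_sd_gain: float = 0.12

    # Full-scale (level 1 → 5) stress effects per phenotype. The responsive
    # margin over blunted is strictly positive for every channel.
    responsive_effects: dict[str, float] = field(
        default_factory=lambda: {
            "hr_bpm": 10.0,
            "scr_rate_hz": 3.0 / 60.0,
            "st_c": -1.0,
            "hrv_suppression": 0.5,
        }
    )
    blunted_effects: dict[str, float] = field(
        default_factory=lambda: {
            "hr_bpm": 1.0,
            "scr_rate_hz": 0.3 / 60.0,
            "st_c": -0.1,
            "hrv_suppression": 0.05,
        }
    )

    # EMA schedule.
    ema_per_day: int = 12
    ema_min_gap_s: float = 1800.0
    ema_wake_start_h: float = 8.0
    ema_wake_end_h: float = 22.0
    ema_misreport_prob: float = 0.05

    # Phenotype-conditional questionnaire score distributions (mean, sd):
    # blunted subjects report poorer sleep and higher depression/anxiety/
    # stress than responsive ones.
    pss_by_phenotype: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"responsive": (10.5, 5.5), "blunted": (17.1, 5.6)}
    )
    dass_depression_by_phenotype: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"responsive": (1.4, 2.1), "blunted": (3.5, 3.4)}
    )
    dass_anxiety_by_phenotype: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"responsive": (1.0, 1.7), "blunted": (2.6, 2.9)}
    )
    dass_stress_by_phenotype: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"responsive": (3.1, 3.2), "blunted": (6.5, 3.9)}
    )
    psqi_by_phenotype: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"responsive": (4.1, 2.3), "blunted": (5.3, 2.5)}
    )
    age_mean: float = 39.4
    age_sd: float = 9.8


@dataclass
class QCConfig:
    """Rule-based quality-indicator thresholds."""

    ecg_segment_s: float = 10.0
    hr_min_bpm: float = 40.0
    hr_max_bpm: float = 180.0
    max_rr_gap_s: float = 3.0
    max_rr_ratio: float = 2.2
    template_k: int = 5
    template_threshold: float = 0.66

    sc_segment_s: float = 5.0
    sc_lost_threshold_us: float = 0.001
    sc_lost_ratio: float = 0.9
    sc_max_rise: float = 0.20
    sc_max_fall: float = 0.10

    st_min_c: float = 20.0
    st_max_c: float = 40.0


@dataclass
class WindowSpec:
    """Sliding analysis window: 5 min long, 4 min overlap (60-s hop)."""

    window_s: float = 300.0
    overlap_s: float = 240.0

    @property
    def hop_s(self) -> float:
        return self.window_s - self.overlap_s


@dataclass
class FeatureConfig:
    """Feature-extraction parameters."""

    tachogram_rate_hz: float = 4.0
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    tonic_cutoff_hz: float = 0.05
    scr_min_amplitude_us: float = 0.01
    scr_max_rise_s: float = 5.0
    quality_gate: float = 0.8


@dataclass
class AssemblyConfig:
    """Inclusion rules for the labeled analysis dataset."""

    quality_gate: float = 0.8          # strict: quality fraction must exceed this
    acc_sd_max: float = 0.04           # inclusive: ACC SD ≤ threshold retained
    min_rows_per_hour: int = 10        # ≥10 min of retained rows per EMA hour
    lookback_s: float = 3600.0         # label propagation window before each prompt
    prune_r_max: float = 0.7
    night_start_h: float = 0.0
    night_end_h: float = 6.0


@dataclass
class ModelConfig:
    """LOSO random-forest configuration."""

    n_estimators: int = 200
    max_features: str = "sqrt"
    min_samples_leaf: int = 10
    max_samples: float | None = 0.3
    fdr_alpha: float = 0.05
    f1_average: str = "macro"          # or "weighted"


@dataclass
class StayConfig:
    """Stay-location clustering thresholds."""

    radius_m: float = 1000.0
    min_dwell_s: float = 3600.0
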