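"""Labeled analysis-dataset assembly.

Joins windowed feature tables to stress self-reports and applies the
inclusion rules: each report labels the 60 one-minute rows of the hour
preceding its prompt; five Likert levels collapse to three states
(S1 = no stress, S2 = light, S3 = high, merging levels 3–5); rows in
[00:00, 06:00) form the nighttime baseline state N regardless of reports.
Retained rows must have window quality fraction strictly above 0.8 and
ACC SD ≤ 0.04; a labeled hour must keep at least 10 rows; subjects whose
retained day labels contain a single state are discarded. Features are then
z-normalized per subject and redundant features pruned at |Spearman r| > 0.7.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AssemblyConfig
from .features import FEATURE_COLUMNS
from .types import SECONDS_PER_DAY, EMAResponse

__all__ = [
    "merge_stress_levels",
    "propagate_labels",
    "day_night_states",
    "filter_rows",
    "zscore_per_subject",
    "prune_correlated",
    "assemble_dataset",
]

STATE_ORDER = ["N", "S1", "S2", "S3"]


def merge_stress_levels(likert: int) -> str:
    """Collapse the 5-point Likert report: 1→S1, 2→S2, {3,4,5}→S3."""
    if likert not in (1, 2, 3, 4, 5):
        raise ValueError(f"stress level must be in 1..5, got {likert!r}")
    return "S1" if likert == 1 else ("S2" if likert == 2 else "S3")


def propagate_labels(ema: list[EMAResponse] | pd.DataFrame, features: pd.DataFrame,
                     config: AssemblyConfig | None = None) -> pd.DataFrame:
    """Attach each report's stress level to the hour of rows preceding it.

    A report at prompt time T labels rows with ``window_start`` in
    [T − 3600, T). When two prompts' hours overlap, the later prompt
    overwrites the overlap. Adds ``stress_likert`` and ``prompt_id``
    columns (NaN where no report covers the row).
    """
    config = config or AssemblyConfig()
    out = features.copy()
    out["stress_likert"] = np.nan
    out["prompt_id"] = np.nan
    if isinstance(ema, pd.DataFrame):
        prompts = list(zip(ema["prompt_time"].to_numpy(), ema["stress_likert"].to_numpy()))
    else:
        prompts = [(r.prompt_time, r.stress_likert) for r in ema]
    ws = out["window_start"].to_numpy()
    for pid, (pt, lvl) in enumerate(sorted(prompts, key=lambda p: p[0])):
        sel = (ws >= pt - config.lookback_s) & (ws < pt)
        out.loc[sel, "stress_likert"] = lvl
        out.loc[sel, "prompt_id"] = pid
    return out


def day_night_states(rows: pd.DataFrame, config: AssemblyConfig | None = None) -> pd.DataFrame:
    """Assign the state column: N in [00:00, 06:00), else the merged label.

    Daytime rows without a label get state NaN (unlabeled).
    """
    config = config or AssemblyConfig()
    out = rows.copy()
    tod_h = (out["window_start"].to_numpy() % SECONDS_PER_DAY) / 3600.0
    night = (tod_h >= config.night_start_h) & (tod_h < config.night_end_h)
    states = np.full(len(out), None, dtype=object)
    lab = out["stress_likert"].to_numpy()
    for i in np.flatnonzero(~np.isnan(lab)):
        states[i] = merge_stress_levels(int(lab[i]))
    states[night] = "N"
    out["state"] = states
    return out


def filter_rows(rows: pd.DataFrame, config: AssemblyConfig | None = None) -> pd.DataFrame:
    """Apply the inclusion rules; idempotent.

    1. quality fraction (min across channels) strictly > 0.8 and
       ACC SD ≤ 0.04;
    2. drop labeled hours retaining fewer than 10 rows;
    3. drop unlabeled daytime rows;
    4. drop subjects whose retained day labels cover a single state.
    """
    config = config or AssemblyConfig()
    df = rows.copy()
    if "subject_id" not in df.columns:
        df["subject_id"] = "S000"
    quality = df[["ecg_quality", "sc_quality", "st_quality"]].min(axis=1)
    keep = (quality > config.quality_gate) & (df["acc_sd"] <= config.acc_sd_max)
    df = df[keep]

    is_day_label = df["state"].isin(["S1", "S2", "S3"])
    # 10-min rule per (subject, prompt) hour
    labeled = df[is_day_label & df["prompt_id"].notna()]
    counts = labeled.groupby(["subject_id", "prompt_id"]).size()
    bad_hours = set(counts[counts < config.min_rows_per_hour].index)
    if bad_hours:
        key = pd.MultiIndex.from_arrays([df["subject_id"], df["prompt_id"]])
        in_bad = pd.Series(key.isin(list(bad_hours)), index=df.index)
        df = df[~(is_day_label & in_bad)]
        is_day_label = df["state"].isin(["S1", "S2", "S3"])

    df = df[is_day_label | (df["state"] == "N")]

    day_states = df[df["state"].isin(["S1", "S2", "S3"])].groupby("subject_id")["state"].nunique()
    single = set(day_states[day_states < 2].index)
    all_subjects = set(df["subject_id"])
    no_day = all_subjects - set(day_states.index)
    df = df[~df["subject_id"].isin(single | no_day)]
    return df.reset_index(drop=True)


def zscore_per_subject(rows: pd.DataFrame,
                       feature_cols: list[str] | None = None) -> pd.DataFrame:
    """Center/scale each feature by the subject's retained-row mean and SD.

    Zero-variance (or all-missing) features for a subject map to 0.
    """
    feature_cols = feature_cols or [c for c in FEATURE_COLUMNS if c in rows.columns]
    out = rows.copy()

    def _z(g: pd.DataFrame) -> pd.DataFrame:
        mu = g.mean()
        sd = g.std(ddof=0)
        z = (g - mu) / sd.replace(0.0, np.nan)
        degenerate = [c for c in g.columns if not sd.get(c, 0) > 0]
        z[degenerate] = 0.0
        return z

    out[feature_cols] = out.groupby("subject_id", group_keys=False)[feature_cols].apply(_z)
    return out


def prune_correlated(rows: pd.DataFrame, feature_cols: list[str] | None = None,
                     r_max: float = 0.7) -> list[str]:
    """Greedy redundancy pruning at |Spearman r| > ``r_max``.

    Features are visited in the canonical order; a feature is dropped if it
    correlates above the threshold with any already-kept feature. Depends
    only on the pooled correlation matrix and the documented order.
    """
    feature_cols = feature_cols or [c for c in FEATURE_COLUMNS if c in rows.columns]
    corr = rows[feature_cols].corr(method="spearman").abs()
    kept: list[str] = []
    for col in feature_cols:
        if rows[col].notna().sum() < 2:
            continue
        if all(not (corr.loc[col, k] > r_max) for k in kept):
            kept.append(col)
    return kept


def assemble_dataset(feature_tables: dict[str, pd.DataFrame],
                     ema_tables: dict[str, list[EMAResponse] | pd.DataFrame],
                     config: AssemblyConfig | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Full assembly: label, state-tag, filter, z-score, prune.

    Returns ``(dataset, reduced_feature_names)``; the dataset contains both
    nighttime baseline rows (state N) and labeled day rows (S1–S3).
    """
    config = config or AssemblyConfig()
    parts = []
    for sid, feats in feature_tables.items():
        df = propagate_labels(ema_tables[sid], feats, config)
        df = day_night_states(df, config)
        df.insert(0, "subject_id", sid)
        parts.append(df)
    pooled = pd.concat(parts, ignore_index=True)
    pooled = filter_rows(pooled, config)
    pooled = zscore_per_subject(pooled)
    reduced = prune_correlated(pooled, r_max=config.prune_r_max)
    return pooled, reduced
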