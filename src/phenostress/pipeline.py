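"""End-to-end study runner: simulate → QC → features → assemble → model.

Subjects are processed one at a time (raw recordings are discarded once the
feature table is extracted) so multi-day cohorts fit comfortably in memory.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemble import assemble_dataset
from .config import AssemblyConfig, FeatureConfig, ModelConfig, QCConfig, SimConfig, WindowSpec
from .features import FEATURE_COLUMNS, extract_all
from .modeling import ModelResult, assign_groups, compare_groups, dynamic_range, loso_train_eval
from .quality import build_ecg_mask, build_sc_mask, build_st_mask
from .reporting import population_summary, state_median_matrix
from .simulate import cohort_phenotypes, simulate_subject
from .types import Channel, SubjectData

__all__ = ["StudyResult", "extract_subject_features", "run_study"]


@dataclass
class StudyResult:
    profiles: pd.DataFrame
    dataset: pd.DataFrame
    reduced_features: list[str]
    model: ModelResult
    groups: pd.Series
    dynamic_ranges: pd.DataFrame
    state_matrix: pd.DataFrame
    summary: pd.DataFrame
    comparisons: dict


def extract_subject_features(data: SubjectData, qc: QCConfig | None = None,
                             spec: WindowSpec | None = None,
                             feat: FeatureConfig | None = None) -> pd.DataFrame:
    """QC masks + windowed features for one subject."""
    qc = qc or QCConfig()
    duration = data.sc.duration
    masks = {
        Channel.ECG: build_ecg_mask(data.beats, duration=duration, config=qc),
        Channel.SC: build_sc_mask(data.sc, config=qc),
        Channel.ST: build_st_mask(data.st, config=qc),
    }
    return extract_all(data.beats, data.sc, data.st, data.acc, masks,
                       spec=spec, config=feat)


def _profile_row(data: SubjectData) -> dict:
    p = data.profile
    return {
        "subject_id": p.subject_id, "phenotype": p.phenotype.value,
        "baseline_hr": p.baseline_hr, "baseline_sc": p.baseline_sc,
        "baseline_st": p.baseline_st, "pss": p.pss,
        "dass_depression": p.dass_depression, "dass_anxiety": p.dass_anxiety,
        "dass_stress": p.dass_stress, "psqi": p.psqi, "age": p.age, "gender": p.gender,
    }


def run_study(n_subjects: int, responsive_fraction: float, seed: int,
              sim: SimConfig | None = None, qc: QCConfig | None = None,
              assembly: AssemblyConfig | None = None,
              model: ModelConfig | None = None,
              progress: bool = False) -> StudyResult:
    """Simulate a cohort and run the complete analysis."""
    sim = sim or SimConfig()
    phenos = cohort_phenotypes(n_subjects, responsive_fraction)
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_subjects)

    profiles, feat_tables, ema_tables = [], {}, {}
    for i, (ph, child) in enumerate(zip(phenos, children)):
        data = simulate_subject(f"S{i:03d}", ph, child, sim)
        profiles.append(_profile_row(data))
        feat_tables[data.profile.subject_id] = extract_subject_features(data, qc=qc)
        ema_tables[data.profile.subject_id] = data.ema
        if progress:
            print(f"  simulated+extracted {data.profile.subject_id} ({ph.value})")

    profiles_df = pd.DataFrame(profiles)
    dataset, reduced = assemble_dataset(feat_tables, ema_tables, config=assembly)

    result = loso_train_eval(dataset, reduced, seed=seed, config=model)
    f1 = result.per_subject.set_index("subject_id")["f1"]
    groups = assign_groups(f1)
    dr = dynamic_range(dataset, groups, reduced)
    matrix = state_median_matrix(dataset, reduced)
    summary = population_summary(dataset, reduced)
    comparisons = compare_groups(groups, profiles_df, dataset=dataset)

    return StudyResult(profiles=profiles_df, dataset=dataset, reduced_features=reduced,
                       model=result, groups=groups, dynamic_ranges=dr,
                       state_matrix=matrix, summary=summary, comparisons=comparisons)
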