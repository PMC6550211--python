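"""Leave-one-subject-out stress classification and digital phenotyping.

A random forest is trained per fold on all subjects but one (after
fold-internal FDR-supervised feature selection at α = 0.05) and evaluated
on the held-out subject's rows with the F1 score. Per-subject F1 scores
then define phenotype groups (low < 0.33 ≤ medium ≤ 0.66 < high), which are
characterized by per-feature dynamic range (mean S3 − S1 contrast) and
compared on questionnaire scores and demographics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectFdr, f_classif
from sklearn.metrics import confusion_matrix, f1_score as _sk_f1

from .config import ModelConfig
from .reporting import bh_adjust

__all__ = [
    "ModelResult",
    "fdr_feature_selection",
    "loso_train_eval",
    "f1_score",
    "majority_baseline_f1",
    "assign_groups",
    "dynamic_range",
    "compare_groups",
]

STRESS_STATES = ["S1", "S2", "S3"]


def f1_score(y_true, y_pred, average: str = "macro") -> float:
    """Multi-class F1 averaged over the classes present in ``y_true``.

    Per-class F1 = 2PR/(P+R) with the 0 convention when P + R = 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    labels = np.unique(y_true)
    return float(_sk_f1(y_true, y_pred, labels=labels, average=average, zero_division=0))


def majority_baseline_f1(y_true, majority_label=None, average: str = "macro") -> float:
    """F1 obtained by predicting one class (the majority) for every sample."""
    y_true = np.asarray(y_true)
    if majority_label is None:
        vals, counts = np.unique(y_true, return_counts=True)
        majority_label = vals[np.argmax(counts)]
    return f1_score(y_true, np.full(len(y_true), majority_label), average=average)


def fdr_feature_selection(X: np.ndarray, y: np.ndarray, feature_names: list[str],
                          alpha: float = 0.05) -> list[str]:
    """FDR-supervised univariate selection (ANOVA F + BH step-up at α).

    Falls back to all features when the procedure rejects everything.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs at least 2 classes")
    sel = SelectFdr(f_classif, alpha=alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        sel.fit(X, y)
    mask = sel.get_support()
    if not mask.any():
        return list(feature_names)
    return [f for f, m in zip(feature_names, mask) if m]


@dataclass
class ModelResult:
    """Per-subject LOSO evaluation artifacts."""

    per_subject: pd.DataFrame                 # subject_id, f1, baseline_f1, n_test
    confusions: dict[str, np.ndarray]
    selected_features: dict[str, list[str]]
    importances: dict[str, pd.Series]
    feature_names: list[str] = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return float(self.per_subject["f1"].mean())


def loso_train_eval(dataset: pd.DataFrame, feature_cols: list[str],
                    seed: int, config: ModelConfig | None = None) -> ModelResult:
    """Leave-one-subject-out random-forest evaluation on S1–S3 rows.

    Each fold imputes missing features with the training-fold median,
    selects features by the FDR procedure on training rows only, fits the
    forest, and scores the held-out subject. Deterministic given ``seed``.
    """
    config = config or ModelConfig()
    df = dataset[dataset["state"].isin(STRESS_STATES)]
    subjects = sorted(df["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")

    rows, confs, sel_map, imp_map = [], {}, {}, {}
    rng = np.random.default_rng(seed)
    for sid in subjects:
        train = df[df["subject_id"] != sid]
        test = df[df["subject_id"] == sid]
        med = train[feature_cols].median()
        Xtr = train[feature_cols].fillna(med).to_numpy()
        Xte = test[feature_cols].fillna(med).to_numpy()
        ytr = train["state"].to_numpy()
        yte = test["state"].to_numpy()

        selected = fdr_feature_selection(Xtr, ytr, feature_cols, alpha=config.fdr_alpha)
        idx = [feature_cols.index(f) for f in selected]
        clf = RandomForestClassifier(
            n_estimators=config.n_estimators, max_features=config.max_features,
            min_samples_leaf=config.min_samples_leaf, max_samples=config.max_samples,
            random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1)
        clf.fit(Xtr[:, idx], ytr)
        pred = clf.predict(Xte[:, idx])

        maj = pd.Series(ytr).mode().iloc[0]
        rows.append({
            "subject_id": sid,
            "f1": f1_score(yte, pred, average=config.f1_average),
            "baseline_f1": majority_baseline_f1(yte, majority_label=maj,
                                                average=config.f1_average),
            "n_test": len(yte),
        })
        confs[sid] = confusion_matrix(yte, pred, labels=STRESS_STATES)
        sel_map[sid] = selected
        imp_map[sid] = pd.Series(clf.feature_importances_, index=selected)

    return ModelResult(per_subject=pd.DataFrame(rows), confusions=confs,
                       selected_features=sel_map, importances=imp_map,
                       feature_names=list(feature_cols))


def assign_groups(f1_by_subject: pd.Series) -> pd.Series:
    """Map per-subject F1 to phenotype groups.

    F1 < 0.33 → low; 0.33 ≤ F1 ≤ 0.66 → medium; F1 > 0.66 → high (interval
    boundaries go to medium).
    """
    f = f1_by_subject.astype(float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError("F1 scores must lie in [0, 1]")
    return pd.Series(np.where(f < 0.33, "low", np.where(f > 0.66, "high", "medium")),
                     index=f.index, name="group")


def dynamic_range(dataset: pd.DataFrame, groups: pd.Series,
                  feature_cols: list[str]) -> pd.DataFrame:
    """Per-group per-feature mean S3 − S1 contrast.

    Each subject contributes mean(feature | S3) − mean(feature | S1);
    subjects lacking either state for a feature are excluded from that
    feature's group mean.
    """
    per_subj = {}
    for sid, g in dataset[dataset["state"].isin(["S1", "S3"])].groupby("subject_id"):
        s1 = g[g["state"] == "S1"][feature_cols].mean()
        s3 = g[g["state"] == "S3"][feature_cols].mean()
        per_subj[sid] = s3 - s1
    contrasts = pd.DataFrame(per_subj).T          # subjects × features
    contrasts["group"] = groups.reindex(contrasts.index)
    return contrasts.groupby("group")[feature_cols].mean()


def compare_groups(groups: pd.Series, profiles: pd.DataFrame,
                   dataset: pd.DataFrame | None = None,
                   score_cols: tuple[str, ...] = ("pss", "dass_depression", "dass_anxiety",
                                                  "dass_stress", "psqi", "age"),
                   alpha: float = 0.05) -> dict:
    """Group characterization: score tests, gender χ², label imbalance.

    Per questionnaire score: Kruskal–Wallis across the three groups and a
    Wilcoxon rank-sum low vs high; p-values are BH-adjusted across the
    whole family.
    """
    prof = profiles.set_index("subject_id") if "subject_id" in profiles.columns else profiles
    prof = prof.join(groups.rename("group"))
    present = [g for g in ("low", "medium", "high") if (prof["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("need at least 2 nonempty groups to compare")

    tests = []
    for col in score_cols:
        if col not in prof.columns:
            continue
        by_group = [prof.loc[prof["group"] == g, col].dropna() for g in present]
        if len(present) >= 3 and all(len(v) > 0 for v in by_group):
            kw = stats.kruskal(*by_group)
            tests.append({"score": col, "test": "kruskal", "stat": float(kw.statistic),
                          "p": float(kw.pvalue)})
        if "low" in present and "high" in present:
            lo = prof.loc[prof["group"] == "low", col].dropna()
            hi = prof.loc[prof["group"] == "high", col].dropna()
            if len(lo) and len(hi):
                mw = stats.mannwhitneyu(lo, hi, alternative="two-sided", method="auto")
                tests.append({"score": col, "test": "ranksum_low_vs_high",
                              "stat": float(mw.statistic), "p": float(mw.pvalue)})
    tests_df = pd.DataFrame(tests)
    if len(tests_df):
        adj, rej = bh_adjust(tests_df["p"].to_numpy(), q=alpha)
        tests_df["p_adj"] = adj
        tests_df["significant"] = rej

    chi2 = None
    if "gender" in prof.columns:
        tab = pd.crosstab(prof["group"], prof["gender"])
        if tab.shape[0] >= 2 and tab.shape[1] >= 2 and (tab.to_numpy() > 0).all():
            c = stats.chi2_contingency(tab)
            chi2 = {"stat": float(c.statistic), "p": float(c.pvalue)}

    label_share = None
    if dataset is not None:
        day = dataset[dataset["state"].isin(STRESS_STATES)].copy()
        day["group"] = groups.reindex(day["subject_id"]).to_numpy()
        label_share = (day.groupby(["group", "state"]).size()
                       / day.groupby("group").size()).unstack(fill_value=0.0)

    sizes = prof["group"].value_counts().to_dict()
    return {"tests": tests_df, "gender_chi2": chi2, "label_share": label_share,
            "group_sizes": sizes}
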