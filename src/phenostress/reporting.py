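"""Descriptive statistics: state-wise median differences, population
summaries, and multiple-testing correction.

For each feature, the population median of the per-subject-normalized
values is computed per state (N, S1, S2, S3) and the six pairwise
differences N–S1, N–S2, N–S3, S1–S2, S2–S3, S1–S3 are tested with the
Wilcoxon rank-sum test; p-values are Benjamini–Hochberg-adjusted across the
full feature × pair family at FDR 0.05, with significance tiers at
p < 0.05 / 0.005 / 0.0005.

The per-state "95% CI" columns of the population summary are population
distribution quantiles (2.5th–97.5th percentiles), not standard-error
intervals — they describe the spread of pooled window values.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "state_median_matrix",
    "population_summary",
    "spearman",
    "STATE_PAIRS",
]

STATE_PAIRS = [("N", "S1"), ("N", "S2"), ("N", "S3"),
               ("S1", "S2"), ("S2", "S3"), ("S1", "S3")]
SIG_TIERS = (0.05, 0.005, 0.0005)


def bh_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def _tier(p_adj: float) -> int:
    """Number of significance stars (tiers are nested)."""
    return int(sum(p_adj < t for t in SIG_TIERS))


def state_median_matrix(rows: pd.DataFrame, feature_cols: list[str],
                        q: float = 0.05) -> pd.DataFrame:
    """Signed median differences + BH-adjusted rank-sum tests per state pair.

    Expects normalized rows with a ``state`` column in {N, S1, S2, S3}.
    Rows should already satisfy the quality/activity inclusion rules.
    Pairs involving an empty state are reported with NaN difference and
    p-value. Differences are antisymmetric by construction:
    diff(A, B) = median(A) − median(B).
    """
    recs = []
    by_state = {s: rows[rows["state"] == s] for s in ("N", "S1", "S2", "S3")}
    for feat in feature_cols:
        for a, b in STATE_PAIRS:
            va = by_state[a][feat].dropna().to_numpy()
            vb = by_state[b][feat].dropna().to_numpy()
            if len(va) == 0 or len(vb) == 0:
                recs.append({"feature": feat, "pair": f"{a}-{b}", "diff": np.nan, "p": np.nan})
                continue
            mw = stats.mannwhitneyu(va, vb, alternative="two-sided", method="auto")
            recs.append({"feature": feat, "pair": f"{a}-{b}",
                         "diff": float(np.median(va) - np.median(vb)),
                         "p": float(mw.pvalue)})
    out = pd.DataFrame(recs)
    avail = out["p"].notna()
    p_adj = np.full(len(out), np.nan)
    if avail.any():
        adj, _ = bh_adjust(out.loc[avail, "p"].to_numpy(), q=q)
        p_adj[avail.to_numpy()] = adj
    out["p_adj"] = p_adj
    out["stars"] = [(_tier(p) if np.isfinite(p) else 0) for p in p_adj]
    return out


def population_summary(rows: pd.DataFrame, feature_cols: list[str]) -> pd.DataFrame:
    """Per state per feature: mean and central 95% population interval.

    The interval is the 2.5th–97.5th percentile of the pooled per-window
    values (NaN when fewer than 2 values).
    """
    recs = []
    for state, g in rows.groupby("state"):
        for feat in feature_cols:
            v = g[feat].dropna().to_numpy()
            rec = {"state": state, "feature": feat, "n": len(v),
                   "mean": float(np.mean(v)) if len(v) else np.nan}
            if len(v) >= 2:
                lo, hi = np.percentile(v, [2.5, 97.5])
                rec["ci_low"], rec["ci_high"] = float(lo), float(hi)
            else:
                rec["ci_low"] = rec["ci_high"] = np.nan
            recs.append(rec)
    return pd.DataFrame(recs)


def spearman(x, y) -> float:
    """Spearman rank correlation (midrank ties)."""
    r = stats.spearmanr(x, y).statistic
    return float(r)


def state_matrix_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Optional heatmap of the median-difference matrix (blue = positive,
    red = negative); requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = matrix.pivot(index="feature", columns="pair", values="diff")
    pairs = [f"{a}-{b}" for a, b in STATE_PAIRS]
    pivot = pivot[[p for p in pairs if p in pivot.columns]]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(pivot) + 2))
    vmax = np.nanmax(np.abs(pivot.to_numpy())) or 1.0
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    stars = matrix.pivot(index="feature", columns="pair", values="stars")[pivot.columns]
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            s = int(stars.iloc[i, j]) if np.isfinite(stars.iloc[i, j]) else 0
            if s:
                ax.text(j, i, "*" * s, ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="median difference (z units)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
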