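"""Cohort-level statistics: change tables, within/between-group tests,
change-change correlations.

All tests are normality-gated: a Shapiro-Wilk test at alpha 0.05 decides
between the parametric test (paired/independent t, Pearson) and its rank
analogue (Wilcoxon signed-rank, Mann-Whitney U, Spearman). Within-group
families are Bonferroni-adjusted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .responder import SubjectRecord

SHAPIRO_ALPHA = 0.05


def change_table(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Per-subject change scores (T10-T0, T1M-T0) and improvement rate.

    Long-lived convention: clinical scores decrease with improvement, so a
    negative delta is a better outcome. EEG/TEP-derived metrics can be
    merged in afterwards by subject id.
    """
    rows = []
    for s in subjects:
        row = {
            "id": s.id,
            "group": s.group,
            "updrs_t0": s.updrs_t0,
            "d_updrs_t10": None if s.updrs_t10 is None else s.updrs_t10 - s.updrs_t0,
            "d_updrs_t1m": None if s.updrs_t1m is None else s.updrs_t1m - s.updrs_t0,
            "improvement_rate": s.improvement_rate,
            "responder": s.responder,
            "frontal_delta_rel": s.frontal_delta_rel,
            "f2f7_delta_pli": s.f2f7_delta_pli,
        }
        tremor = s.subscores.get("tremor")
        if tremor and "t0" in tremor and "t10" in tremor:
            row["d_tremor_t10"] = tremor["t10"] - tremor["t0"]
        rows.append(row)
    return pd.DataFrame(rows)


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > SHAPIRO_ALPHA


def paired_change_test(
    values_t0: np.ndarray, values_t1: np.ndarray, family_size: int = 1
) -> dict:
    """Normality-gated paired test with Bonferroni adjustment.

    Returns the statistic, raw p, and adjusted p = min(1, p * family_size).
    All-zero differences are a degenerate case reported with p = 1.
    """
    a = np.asarray(values_t0, float)
    b = np.asarray(values_t1, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired samples with n >= 3")
    diff = b - a
    if np.all(diff == 0):
        return {"test": "degenerate", "statistic": 0.0, "p": 1.0,
                "p_adjusted": 1.0, "note": "all paired differences are zero"}
    if _is_normal(diff):
        res = stats.ttest_rel(a, b)
        name = "paired_t"
    else:
        res = stats.wilcoxon(a, b)
        name = "wilcoxon"
    p = float(res.pvalue)
    return {"test": name, "statistic": float(res.statistic), "p": p,
            "p_adjusted": min(1.0, p * family_size)}


def between_group_change(delta_a: np.ndarray, delta_b: np.ndarray) -> dict:
    """Normality-gated independent t / Mann-Whitney U on change scores."""
    a = np.asarray(delta_a, float)
    b = np.asarray(delta_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 subjects per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return {"test": "degenerate", "statistic": 0.0, "p": p}
    if _is_normal(a) and _is_normal(b):
        res = stats.ttest_ind(a, b)
        return {"test": "independent_t", "statistic": float(res.statistic),
                "p": float(res.pvalue)}
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "mannwhitneyu", "statistic": float(res.statistic),
            "p": float(res.pvalue)}


def correlate_changes(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson if both variables pass Shapiro-Wilk, else Spearman."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError("need n >= 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("correlation undefined for a constant variable")
    if _is_normal(x) and _is_normal(y):
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return {"method": method, "r": float(r), "p": float(p), "n": int(x.size)}
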