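"""Responder labeling and the baseline-EEG responder classifier.

A subject is a treatment responder if their UPDRS-III motor score improved
by at least 30% of baseline, or dropped by more than 5 points, after the
10-session course. The classifier predicts that label from two baseline
resting-EEG features — frontal delta relative power and F2-F7 delta PLI —
with a linear support-vector machine evaluated by stratified 5-fold nested
cross-validation repeated over many random fold draws; the inner loop
selects the margin penalty C, the outer loop supplies pooled decision
scores for ROC/AUC and balanced accuracy.

Feature standardisation is computed from training folds only, inside both
CV levels, so no test information leaks into scaling or model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import balanced_accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

#: UPDRS-III subscore item mapping (motor examination item numbers)
UPDRS_SUBSCORE_ITEMS = {
    "upper_limb": (20, 21, 22, 23, 24, 25),
    "lower_limb": (20, 22, 26, 29),
    "axial": (27, 28, 29, 30),
    "tremor": (20, 21),
    "rigidity": (22,),
    "postural_instability": (30,),
    "akinesia": (23, 24, 25, 26),
    "bradykinesia": (31,),
}

DEFAULT_C_GRID = tuple(10.0 ** k for k in range(-3, 4))  # 1e-3 .. 1e3


@dataclass
class SubjectRecord:
    """One study subject: clinical scores, EEG features, responder labels."""

    id: str
    group: str                    # "iTBS" or "rTMS10"
    affected_side: str            # more affected upper limb: "left"/"right"
    updrs_t0: float
    updrs_t10: float | None = None
    updrs_t1m: float | None = None
    subscores: dict[str, dict[str, float]] = field(default_factory=dict)
    tug_seconds: float | None = None
    frontal_delta_rel: float | None = None
    f2f7_delta_pli: float | None = None
    true_responder: bool | None = None   # generator ground truth, if synthetic
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for score in (self.updrs_t0, self.updrs_t10, self.updrs_t1m):
            if score is not None and score < 0:
                raise ValueError("UPDRS-III scores must be non-negative")

    @property
    def responder(self) -> bool | None:
        """Rule-derived responder label; None if T10 is missing."""
        if self.updrs_t10 is None:
            return None
        return label_responder(self.updrs_t0, self.updrs_t10) == "responder"

    @property
    def improvement_rate(self) -> float | None:
        if self.updrs_t10 is None:
            return None
        return (self.updrs_t0 - self.updrs_t10) / self.updrs_t0


def label_responder(updrs_t0: float, updrs_t10: float) -> str:
    """Responder rule: improvement rate >= 30% OR absolute drop > 5 points.

    Improvement is a decrease; the rate clause is inclusive at 30% and the
    absolute clause strict at 5 points.
    """
    if updrs_t0 <= 0:
        raise ZeroDivisionError("improvement rate undefined for baseline score 0")
    change = updrs_t0 - updrs_t10
    if change / updrs_t0 >= 0.30 or change > 5:
        return "responder"
    return "non-responder"


def updrs_subscores(items: dict[int, float]) -> dict[str, float]:
    """Clinical subscores from per-item UPDRS-III scores (items 18-31)."""
    out = {}
    for name, members in UPDRS_SUBSCORE_ITEMS.items():
        missing = [m for m in members if m not in items]
        if missing:
            raise KeyError(f"subscore {name!r} needs missing items {missing}")
        out[name] = float(sum(items[m] for m in members))
    return out


def extract_features(subjects: list[SubjectRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Baseline feature matrix [frontal delta rel power, F2-F7 delta PLI] and labels.

    Returns raw (un-scaled) features; standardisation happens inside the CV
    using training-fold statistics only. Subjects without a rule-derived
    label (missing T10) are dropped.
    """
    rows, labels = [], []
    for s in subjects:
        if s.responder is None:
            continue
        if s.frontal_delta_rel is None or s.f2f7_delta_pli is None:
            raise ValueError(f"subject {s.id}: baseline EEG features missing")
        rows.append([s.frontal_delta_rel, s.f2f7_delta_pli])
        labels.append(int(s.responder))
    return np.asarray(rows, dtype=float), np.asarray(labels, dtype=int)


def _fold_zscore(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both arrays with the training-fold mean/sd; constant columns -> 0."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("constant feature column z-scored to zeros", stacklevel=3)
        sd = np.where(degenerate, 1.0, sd)
    zt = (train - mu) / sd
    zo = (other - mu) / sd
    zt[:, degenerate] = 0.0
    zo[:, degenerate] = 0.0
    return zt, zo


@dataclass
class ClassifierReport:
    balanced_accuracy: float
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    sensitivity: float
    specificity: float
    threshold: float
    per_repetition_bal_acc: np.ndarray
    per_repetition_auc: np.ndarray
    c_trace: list[list[float]]
    seed: int


def _stratified_folds(y, n_folds, rng, max_attempts=100):
    """Shuffled stratified folds; re-draw if any fold lacks a class."""
    for _ in range(max_attempts):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise RuntimeError(f"could not draw {n_folds} folds with both classes "
                       f"in every training set after {max_attempts} attempts")


def nested_cv_classify(
    features: np.ndarray,
    labels: np.ndarray,
    outer_folds: int = 5,
    inner_folds: int = 5,
    repetitions: int = 1000,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    seed: int = 0,
) -> ClassifierReport:
    """Linear-SVM nested CV, metrics averaged over repeated fold draws.

    Each repetition re-draws the stratified outer partition; the inner
    5-fold loop picks C from ``c_grid`` by balanced accuracy; outer-fold
    decision scores are pooled within a repetition for the AUC. The ROC
    curve and its Youden-optimal operating point are computed on scores
    pooled across all repetitions.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be n_subjects x n_features aligned with labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need at least two subjects in each of two classes")
    rng = np.random.default_rng(seed)

    rep_bal_acc = np.empty(repetitions)
    rep_auc = np.empty(repetitions)
    c_trace: list[list[float]] = []
    all_scores = np.zeros(len(y))

    for rep in range(repetitions):
        folds = _stratified_folds(y, outer_folds, rng)
        scores = np.empty(len(y))
        preds = np.empty(len(y), dtype=int)
        rep_cs = []
        for train_idx, test_idx in folds:
            Xtr_raw, ytr = X[train_idx], y[train_idx]
            best_c, best_acc = c_grid[0], -np.inf
            inner = _stratified_folds(ytr, inner_folds, rng)
            inner_sets = []
            for itr, ite in inner:
                Zi, Zv = _fold_zscore(Xtr_raw[itr], Xtr_raw[ite])
                inner_sets.append((Zi, ytr[itr], Zv, ytr[ite]))
            for c in c_grid:
                accs = [
                    balanced_accuracy_score(
                        yv, SVC(kernel="linear", C=c).fit(Zi, yi).predict(Zv))
                    for Zi, yi, Zv, yv in inner_sets
                ]
                mean_acc = float(np.mean(accs))
                if mean_acc > best_acc:
                    best_acc, best_c = mean_acc, c
            rep_cs.append(best_c)
            Ztr, Zte = _fold_zscore(Xtr_raw, X[test_idx])
            clf = SVC(kernel="linear", C=best_c).fit(Ztr, ytr)
            scores[test_idx] = clf.decision_function(Zte)
            preds[test_idx] = clf.predict(Zte)
        rep_bal_acc[rep] = balanced_accuracy_score(y, preds)
        rep_auc[rep] = roc_auc_score(y, scores)
        all_scores += scores
        c_trace.append(rep_cs)

    pooled = all_scores / repetitions
    fpr, tpr, thr = roc_curve(y, pooled)
    youden = int(np.argmax(tpr - fpr))
    return ClassifierReport(
        balanced_accuracy=float(rep_bal_acc.mean()),
        auc=float(rep_auc.mean()),
        roc_fpr=fpr, roc_tpr=tpr,
        sensitivity=float(tpr[youden]),
        specificity=float(1.0 - fpr[youden]),
        threshold=float(thr[youden]),
        per_repetition_bal_acc=rep_bal_acc,
        per_repetition_auc=rep_auc,
        c_trace=c_trace, seed=seed,
    )


def roc_report(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Empirical ROC, trapezoid AUC (midrank ties) and Youden point."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    auc = roc_auc_score(y, s)
    fpr, tpr, thr = roc_curve(y, s)
    youden = int(np.argmax(tpr - fpr))
    return {
        "auc": float(auc),
        "fpr": fpr, "tpr": tpr, "thresholds": thr,
        "sensitivity": float(tpr[youden]),
        "specificity": float(1.0 - fpr[youden]),
        "threshold": float(thr[youden]),
    }


def group_difference_tests(
    feature_table: dict[str, tuple[np.ndarray, np.ndarray]],
    fdr_features: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Responder vs non-responder comparisons per feature.

    Each entry of ``feature_table`` maps a feature name to (group_a values,
    group_b values). A Shapiro-Wilk gate (alpha 0.05 per group) selects a
    two-sample t-test when both groups look normal, otherwise a
    Mann-Whitney U test. Features named in ``fdr_features`` (e.g. the PLI
    pairwise family) get Benjamini-Hochberg adjusted p-values.
    """
    out: dict[str, dict] = {}
    for name, (a, b) in feature_table.items():
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"feature {name!r}: need >= 2 per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            out[name] = {"test": "skipped", "note": "zero variance in both groups",
                         "p": np.nan, "statistic": np.nan}
            continue
        normal = (stats.shapiro(a).pvalue > alpha and
                  stats.shapiro(b).pvalue > alpha)
        if normal:
            res = stats.ttest_ind(a, b)
            out[name] = {"test": "t", "statistic": float(res.statistic),
                         "p": float(res.pvalue)}
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            out[name] = {"test": "mannwhitneyu", "statistic": float(res.statistic),
                         "p": float(res.pvalue)}
    if fdr_features:
        ps = [out[n]["p"] for n in fdr_features]
        reject, adj, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
        for n, r, q in zip(fdr_features, reject, adj):
            out[n]["p_fdr"] = float(q)
            out[n]["reject_fdr"] = bool(r)
    return out
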