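"""Classifier evaluation: ROC/AUC, DeLong paired comparison, Youden cutoffs.

Mirrors the evaluation pipeline used to validate the fixation-instability
score: per-parameter maximum-margin classifiers on a stratified 70/30 split,
one-vs-one multiclass ROC with the macro-mean AUC, standard errors via the
AUC's equivalence to the Wilcoxon statistic (Hanley-McNeil), nonparametric
paired comparison of correlated AUCs via DeLong structural components,
Youden-index cutoff selection, and the Spearman rank-correlation matrix
with a significance-filtered variant.

Ties are handled consistently everywhere with the midrank convention
(concordance kernel 1 / 1/2 / 0), so the AUC computed from DeLong components
equals the Mann-Whitney AUC exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class AUCEstimate:
    auc: float
    se: float
    positive_class: object
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class DeLongResult:
    delta_auc: float
    se_delta: float
    z: float
    p: float
    ci95: tuple[float, float]
    auc_a: float
    auc_b: float
    degenerate: bool = False


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split: 70% train by default."""

    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def split(self, n: int, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.arange(n)
        train, test = train_test_split(
            idx,
            train_size=self.train_fraction,
            stratify=labels if self.stratified else None,
            random_state=self.seed,
        )
        return train, test


def _check_binary(labels: np.ndarray, positive) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    return pos, ~pos


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of the AUC via its Wilcoxon-statistic equivalence."""
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(scores, labels, positive=1) -> AUCEstimate:
    """AUC as the normalized Mann-Whitney statistic, ties counted 1/2.

    Equals the probability that a random positive outscores a random
    negative (ties worth 1/2); computed with midranks in O(n log n).
    A constant score gives 0.5 by this convention.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_binary(labels, positive)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    ranks = stats.rankdata(scores)  # midranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))
    return AUCEstimate(
        auc=auc,
        se=hanley_mcneil_se(auc, n_pos, n_neg),
        positive_class=positive,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def roc_curve_points(scores, labels, positive=1) -> pd.DataFrame:
    """(FPR, TPR, threshold) coordinates of the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    pos, _neg = _check_binary(labels, positive)
    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order].astype(float)
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(1.0 - sorted_pos)
    # collapse ties: keep the last point of each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / pos.sum()]
    fpr = np.r_[0.0, fps[distinct] / (~pos).sum()]
    thr = np.r_[np.inf, scores[order][distinct]]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


class MarginScorer:
    """Soft-margin linear SVM over a single standardized scalar feature.

    The decision function is affine in the feature, hence a monotone score;
    training is deterministic for a fixed split.
    """

    def __init__(self, positive_class):
        self.positive_class = positive_class
        self._pipe = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))

    def fit(self, feature, labels) -> "MarginScorer":
        feature = np.asarray(feature, dtype=float).reshape(-1, 1)
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            raise ValueError("training partition contains a single class")
        y = (labels == self.positive_class).astype(int)
        self._pipe.fit(feature, y)
        return self

    def decision(self, feature) -> np.ndarray:
        feature = np.asarray(feature, dtype=float).reshape(-1, 1)
        return np.asarray(self._pipe.decision_function(feature), dtype=float)

    def predict(self, feature) -> np.ndarray:
        return (self.decision(feature) > 0).astype(int)

    @property
    def threshold_in_feature_units(self) -> float:
        """Feature value where the decision function crosses zero."""
        scaler: StandardScaler = self._pipe.named_steps["standardscaler"]
        svc: SVC = self._pipe.named_steps["svc"]
        w = float(svc.coef_[0, 0])
        b = float(svc.intercept_[0])
        if w == 0:
            return float("nan")
        z = -b / w
        return float(z * np.sqrt(scaler.var_[0]) + scaler.mean_[0])


def train_margin_classifier(feature, labels, split: SplitSpec, positive_class=1):
    """Fit a 1-D margin classifier on the train partition of a split.

    Returns ``(scorer, train_idx, test_idx)``; the scorer's decision
    function is a monotone transform of the feature.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    train_idx, test_idx = split.split(len(feature), labels)
    scorer = MarginScorer(positive_class).fit(feature[train_idx], labels[train_idx])
    return scorer, train_idx, test_idx


def one_vs_one_auc(scores, labels, classes=None) -> dict:
    """Per-pair AUCs of a scalar score under the one-vs-one scheme.

    For each unordered class pair the AUC is reported once per positive
    class (with a single shared monotone score the two directions coincide);
    the macro-mean averages one AUC per pair.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(np.unique(labels).tolist())
    if any((labels == c).sum() == 0 for c in classes):
        raise ValueError("all classes must be present")
    pairs = {}
    pair_aucs = []
    for a, b in combinations(classes, 2):
        sel = (labels == a) | (labels == b)
        s, l = scores[sel], labels[sel]
        est_b = roc_auc(s, l, positive=b)  # more severe class positive
        est_a = roc_auc(-s, l, positive=a)
        pairs[(a, b)] = {a: est_a, b: est_b}
        pair_aucs.append(est_b.auc)
    return {"pairs": pairs, "macro_mean_auc": float(np.mean(pair_aucs))}


def _delong_components(scores, pos_mask) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components V10 (per positive), V01 (per negative)."""
    x = np.asarray(scores, dtype=float)[pos_mask]  # positives
    y = np.asarray(scores, dtype=float)[~pos_mask]  # negatives
    # psi(x_i, y_j) = 1 if x>y, 1/2 if tie, 0 if x<y
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def delong_compare(scores_a, scores_b, labels, positive=1) -> DeLongResult:
    """Paired comparison of two correlated AUCs on the same subjects.

    Uses the DeLong structural-component estimator of the covariance of the
    two AUCs; reports |dAUC|, its SE, the z statistic and a two-sided normal
    p-value with a symmetric 95% CI.  Identical score vectors (or zero
    variance of the difference) are flagged degenerate with p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    pos, _ = _check_binary(labels, positive)
    m, n = int(pos.sum()), int((~pos).sum())

    auc_a, v10_a, v01_a = _delong_components(scores_a, pos)
    auc_b, v10_b, v01_b = _delong_components(scores_b, pos)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = auc_a - auc_b
    if var_delta <= 0:
        return DeLongResult(
            delta_auc=abs(delta),
            se_delta=0.0,
            z=0.0,
            p=1.0,
            ci95=(abs(delta), abs(delta)),
            auc_a=auc_a,
            auc_b=auc_b,
            degenerate=True,
        )
    se = float(np.sqrt(var_delta))
    z = float(delta / se)
    p = float(2 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    return DeLongResult(
        delta_auc=abs(delta),
        se_delta=se,
        z=z,
        p=p,
        ci95=(abs(delta) - half, abs(delta) + half),
        auc_a=auc_a,
        auc_b=auc_b,
    )


def youden_cutoff(scores, labels, positive=1) -> CutoffResult:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct sorted scores plus
    sentinels below the minimum and above the maximum; subjects score
    positive when strictly above the threshold.  Ties in J break toward the
    lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_binary(labels, positive)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    distinct = np.unique(scores)
    candidates = np.r_[-np.inf, (distinct[:-1] + distinct[1:]) / 2.0, np.inf]
    best = None
    for thr in candidates:
        pred = scores > thr
        sens = float((pred & pos).sum() / n_pos)
        spec = float((~pred & neg).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(
                threshold=float(thr), youden_j=j, sensitivity=sens, specificity=spec
            )
    return best


def spearman_matrix(table: pd.DataFrame, alpha: float = 0.05):
    """Pairwise Spearman rank correlations with p-values and a filtered view.

    Returns ``(r, p, filtered)`` DataFrames; ``filtered`` masks entries with
    p > alpha as NaN.  A constant column correlates with nothing: its
    entries are NaN (masked), not an error.
    """
    if table.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 numeric columns")
    cols = table.columns
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    values = [table[c].to_numpy(dtype=float) for c in cols]
    for i in range(k):
        for j in range(i, k):
            xi, xj = values[i], values[j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue  # undefined for a constant column
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = stats.spearmanr(xi, xj)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    filtered = r_df.where(p_df <= alpha)
    return r_df, p_df, filtered


PARAMETER_COLUMNS = ("sa", "sp", "acd", "fis_raw")


def evaluate_all(
    cohort: pd.DataFrame,
    split: SplitSpec,
    class_order: tuple = ("normal", "borderline", "case"),
    label_column: str = "hads_class",
) -> dict:
    """Run the full evaluation pipeline on a scored cohort table.

    For each of the four parameters (SA, SP, ACD, FIS) a margin classifier
    is trained per class pair on the 70% stratified train partition and its
    decision scores on the 30% test partition drive the one-vs-one AUC
    table.  All six parameter pairs are then compared per class pair with
    the DeLong test on the shared test subjects, and Youden cutoffs for
    normal-vs-borderline and borderline-vs-case are selected on the raw FIS.
    """
    missing = [c for c in PARAMETER_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing parameter columns: {missing}")
    labels = cohort[label_column].to_numpy()
    for cls in class_order:
        if (labels == cls).sum() == 0:
            raise ValueError(f"class {cls!r} absent from cohort")
    train_idx, test_idx = split.split(len(cohort), labels)

    report: dict = {
        "split": {
            "train_fraction": split.train_fraction,
            "seed": split.seed,
            "n_train": len(train_idx),
            "n_test": len(test_idx),
        },
        "auc": {},
        "delong": {},
        "youden": {},
    }

    # per parameter, per class pair: train on train partition, score test
    test_scores: dict[str, dict[tuple, np.ndarray]] = {}
    for param in PARAMETER_COLUMNS:
        feature = cohort[param].to_numpy(dtype=float)
        param_entry = {"pairs": {}, "macro_mean_auc": None}
        pair_aucs = []
        test_scores[param] = {}
        for a, b in combinations(class_order, 2):
            tr = train_idx[np.isin(labels[train_idx], (a, b))]
            te = test_idx[np.isin(labels[test_idx], (a, b))]
            scorer = MarginScorer(positive_class=b).fit(feature[tr], labels[tr])
            s = scorer.decision(feature[te])
            test_scores[param][(a, b)] = s
            est_b = roc_auc(s, labels[te], positive=b)
            est_a = roc_auc(-s, labels[te], positive=a)
            param_entry["pairs"][f"{a}_vs_{b}"] = {
                a: {"auc": est_a.auc, "se": est_a.se},
                b: {"auc": est_b.auc, "se": est_b.se},
            }
            pair_aucs.append(est_b.auc)
        param_entry["macro_mean_auc"] = float(np.mean(pair_aucs))
        report["auc"][param] = param_entry

    # DeLong: all six parameter pairs, per class pair, on shared test subjects
    for a, b in combinations(class_order, 2):
        te = test_idx[np.isin(labels[test_idx], (a, b))]
        pair_labels = labels[te]
        entry = {}
        for pa, pb in combinations(PARAMETER_COLUMNS, 2):
            res = delong_compare(
                test_scores[pa][(a, b)], test_scores[pb][(a, b)], pair_labels, positive=b
            )
            entry[f"{pa}_vs_{pb}"] = {
                "delta_auc": res.delta_auc,
                "se": res.se_delta,
                "z": res.z,
                "p": res.p,
                "ci95": list(res.ci95),
                "auc_a": res.auc_a,
                "auc_b": res.auc_b,
            }
        report["delong"][f"{a}_vs_{b}"] = entry

    # Youden cutoffs on raw FIS for the two adjacent class pairs
    fis = cohort["fis_raw"].to_numpy(dtype=float)
    for a, b in (class_order[:2], class_order[1:]):
        sel = np.isin(labels, (a, b))
        cut = youden_cutoff(fis[sel], labels[sel], positive=b)
        report["youden"][f"{a}_vs_{b}"] = {
            "threshold": cut.threshold,
            "youden_j": cut.youden_j,
            "sensitivity": cut.sensitivity,
            "specificity": cut.specificity,
        }
    return report
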