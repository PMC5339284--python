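"""Evaluation protocol: splits, confusion metrics, ROC/AUROC, one-way
ANOVA with Tukey-Kramer HSD, and the multi-classifier comparison harness.

Fatigue is the positive class throughout:

    sensitivity (TPR) = TP / (TP + FN)
    specificity (TNR) = TN / (TN + FP)
    accuracy          = (TP + TN) / (TP + TN + FP + FN)

all reported as percentages (full precision internally, one decimal for
display).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .ann import ANNConfig, train_ann, predict_ann
from .containers import FeatureMatrix
from .dbn import TrainConfig, predict as dbn_predict, train_dbn
from .features import scale_minmax01


# ---------------------------------------------------------------------------
# splits

def holdout_split(
    n: int, seed: int, groups: Optional[Sequence] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled train/validation/test partition of ``range(n)``.

    Sizes are ``ceil(n/3)``, ``ceil((n - train)/2)`` and the remainder
    (train >= valid >= test); with n = 6278 this gives (2093, 2093, 2092).
    When ``groups`` is given (one group id per sample, e.g. subject), all
    samples of a group land in the same subset.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 to form three subsets, got {n}")
    n_train = ceil(n / 3)
    n_valid = ceil((n - n_train) / 2)
    rng = np.random.default_rng(seed)
    if groups is None:
        perm = rng.permutation(n)
        return perm[:n_train], perm[n_train : n_train + n_valid], perm[n_train + n_valid :]
    groups = np.asarray(groups)
    if len(groups) != n:
        raise ValueError("groups must have one entry per sample")
    uniq = rng.permutation(np.unique(groups))
    parts: list[list[int]] = [[], [], []]
    targets = [n_train, n_valid, n - n_train - n_valid]
    for g in uniq:
        members = np.flatnonzero(groups == g)
        # place into the subset with the largest remaining deficit
        deficits = [targets[i] - len(parts[i]) for i in range(3)]
        parts[int(np.argmax(deficits))].extend(members.tolist())
    return tuple(np.asarray(p, dtype=int) for p in parts)  # type: ignore[return-value]


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint covering folds with sizes differing by at most one."""
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    return list(np.array_split(rng.permutation(n), k))


# ---------------------------------------------------------------------------
# metrics

@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalReport:
    """Confusion counts plus rates (percent), optional ROC curve/AUROC."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    roc: Optional[list[tuple[float, float]]] = None
    auroc: Optional[float] = None
    per_fold: Optional[list["EvalReport"]] = None

    def to_dict(self) -> dict:
        d = {
            "TP": self.counts.TP, "FP": self.counts.FP,
            "TN": self.counts.TN, "FN": self.counts.FN,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
        }
        if self.auroc is not None:
            d["auroc"] = self.auroc
        if self.roc is not None:
            d["roc"] = [[float(a), float(b)] for a, b in self.roc]
        if self.per_fold is not None:
            d["per_fold"] = [r.to_dict() for r in self.per_fold]
        return d


def confusion_metrics(y_true: Sequence[int], y_pred: Sequence[int]) -> EvalReport:
    """Counts and the three rates from binary labels (1 = fatigue)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if not (set(np.unique(y_true)) <= {0, 1} and set(np.unique(y_pred)) <= {0, 1}):
        raise ValueError("labels must be binary (0 alert / 1 fatigue)")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    counts = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    pos, neg = tp + fn, tn + fp
    return EvalReport(
        counts=counts,
        sensitivity=100.0 * tp / pos if pos else float("nan"),
        specificity=100.0 * tn / neg if neg else float("nan"),
        accuracy=100.0 * (tp + tn) / counts.total,
    )


def roc_curve(scores: Sequence[float], y_true: Sequence[int]) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) and trapezoidal AUROC.

    Thresholds sweep the distinct score values from high to low (ties
    grouped at one threshold); the curve runs from (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative sample")
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # group tied scores
            tp += int(yy[j] == 1)
            fp += int(yy[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auroc = float(np.trapezoid(ys, xs))
    return points, auroc


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey-Kramer HSD

# Critical values of the studentized range statistic q(alpha; k groups,
# df error), k = 2..10, df = 2..30, as tabulated in the standard HSD
# reference tables (four-decimal precision).  Index: _Q_xx[k][df - 2].
_Q_05 = {
    2: [6.0849, 4.5007, 3.9265, 3.6354, 3.4605, 3.3441, 3.2612, 3.1992, 3.1511, 3.1127, 3.0813, 3.0552, 3.0332, 3.0143, 2.998, 2.9837, 2.9712, 2.96, 2.95, 2.941, 2.9329, 2.9255, 2.9188, 2.9126, 2.907, 2.9017, 2.8969, 2.8924, 2.8882],
    3: [8.3308, 5.9096, 5.0402, 4.6017, 4.3392, 4.1649, 4.041, 3.9485, 3.8768, 3.8196, 3.7729, 3.7341, 3.7014, 3.6734, 3.6491, 3.628, 3.6093, 3.5927, 3.5779, 3.5646, 3.5526, 3.5417, 3.5317, 3.5226, 3.5142, 3.5064, 3.4993, 3.4926, 3.4864],
    4: [9.798, 6.8245, 5.7571, 5.2183, 4.8956, 4.6813, 4.5293, 4.4149, 4.3266, 4.2561, 4.1987, 4.1509, 4.1105, 4.076, 4.0461, 4.02, 3.997, 3.9766, 3.9583, 3.9419, 3.927, 3.9136, 3.9013, 3.89, 3.8796, 3.8701, 3.8612, 3.853, 3.8454],
    5: [10.8811, 7.5017, 6.287, 5.6731, 5.3049, 5.0601, 4.8858, 4.7554, 4.6543, 4.5736, 4.5077, 4.4529, 4.4066, 4.367, 4.3327, 4.3027, 4.2763, 4.2528, 4.2319, 4.213, 4.1959, 4.1805, 4.1663, 4.1534, 4.1415, 4.1305, 4.1203, 4.1109, 4.1021],
    6: [11.7343, 8.0371, 6.7064, 6.0329, 5.6284, 5.3591, 5.1672, 5.0235, 4.912, 4.823, 4.7502, 4.6897, 4.6385, 4.5947, 4.5568, 4.5237, 4.4944, 4.4685, 4.4452, 4.4244, 4.4055, 4.3883, 4.3727, 4.3583, 4.3451, 4.3329, 4.3217, 4.3112, 4.3015],
    7: [12.4349, 8.4783, 7.0526, 6.3299, 5.8953, 5.6057, 5.3991, 5.2444, 5.1242, 5.0281, 4.9496, 4.8842, 4.829, 4.7816, 4.7406, 4.7048, 4.6731, 4.645, 4.6199, 4.5973, 4.5769, 4.5583, 4.5413, 4.5258, 4.5115, 4.4983, 4.4861, 4.4747, 4.4642],
    8: [13.0273, 8.8525, 7.3465, 6.5823, 6.1222, 5.8153, 5.5962, 5.4319, 5.3042, 5.2021, 5.1187, 5.0491, 4.9903, 4.9399, 4.8962, 4.858, 4.8243, 4.7944, 4.7676, 4.7435, 4.7217, 4.7018, 4.6838, 4.6672, 4.6519, 4.6378, 4.6248, 4.6127, 4.6014],
    9: [13.539, 9.1766, 7.6015, 6.8014, 6.3192, 5.9973, 5.7673, 5.5947, 5.4605, 5.3531, 5.2653, 5.1921, 5.1301, 5.077, 5.031, 4.9907, 4.9552, 4.9236, 4.8954, 4.8699, 4.8469, 4.826, 4.8069, 4.7894, 4.7733, 4.7584, 4.7446, 4.7318, 4.7199],
    10: [13.9885, 9.462, 7.8263, 6.9947, 6.4931, 6.1579, 5.9183, 5.7384, 5.5984, 5.4863, 5.3946, 5.3181, 5.2534, 5.1979, 5.1498, 5.1077, 5.0705, 5.0375, 5.0079, 4.9813, 4.9572, 4.9353, 4.9152, 4.8969, 4.88, 4.8644, 4.85, 4.8366, 4.8241],
}
_Q_01 = {
    2: [14.0358, 8.2603, 6.5112, 5.7023, 5.2431, 4.949, 4.7452, 4.596, 4.482, 4.3923, 4.3198, 4.26, 4.2099, 4.1673, 4.1306, 4.0987, 4.0707, 4.046, 4.0239, 4.0041, 3.9863, 3.9702, 3.9555, 3.942, 3.9297, 3.9183, 3.9078, 3.8981, 3.8891],
    3: [19.0189, 10.6185, 8.1198, 6.9757, 6.3305, 5.9193, 5.6354, 5.428, 5.2702, 5.146, 5.0459, 4.9635, 4.8945, 4.8359, 4.7855, 4.7418, 4.7034, 4.6694, 4.6392, 4.6122, 4.5878, 4.5657, 4.5456, 4.5272, 4.5104, 4.4948, 4.4805, 4.4672, 4.4549],
    4: [22.2937, 12.1695, 9.1729, 7.8042, 7.0333, 6.5424, 6.2044, 5.9567, 5.7686, 5.6208, 5.5016, 5.4036, 5.3215, 5.2518, 5.1919, 5.1399, 5.0942, 5.0539, 5.018, 4.9859, 4.9569, 4.9307, 4.9068, 4.885, 4.865, 4.8466, 4.8296, 4.8138, 4.7992],
    5: [24.7172, 13.3243, 9.9583, 8.4215, 7.556, 7.005, 6.6248, 6.3473, 6.1361, 5.9701, 5.8363, 5.7262, 5.634, 5.5558, 5.4885, 5.4301, 5.3788, 5.3336, 5.2933, 5.2572, 5.2246, 5.1952, 5.1684, 5.1439, 5.1215, 5.1008, 5.0817, 5.064, 5.0476],
    6: [26.629, 14.2407, 10.5832, 8.9131, 7.9723, 7.373, 6.9594, 6.6574, 6.4275, 6.2468, 6.1011, 5.9812, 5.8808, 5.7956, 5.7223, 5.6586, 5.6028, 5.5535, 5.5095, 5.4702, 5.4348, 5.4027, 5.3735, 5.3468, 5.3223, 5.2998, 5.279, 5.2597, 5.2418],
    7: [28.2006, 14.9978, 11.1009, 9.3209, 8.3177, 7.6784, 7.2369, 6.9145, 6.669, 6.4759, 6.3202, 6.192, 6.0847, 5.9936, 5.9152, 5.8471, 5.7874, 5.7346, 5.6876, 5.6455, 5.6076, 5.5733, 5.542, 5.5135, 5.4873, 5.4632, 5.4409, 5.4203, 5.4012],
    8: [29.5301, 15.641, 11.5418, 9.6687, 8.6125, 7.939, 7.4738, 7.1339, 6.8749, 6.6713, 6.5069, 6.3717, 6.2583, 6.1621, 6.0793, 6.0074, 5.9443, 5.8886, 5.8389, 5.7944, 5.7544, 5.7181, 5.685, 5.6549, 5.6272, 5.6017, 5.5782, 5.5564, 5.5361],
    9: [30.6794, 16.199, 11.9251, 9.9715, 8.8693, 8.1662, 7.6803, 7.3251, 7.0544, 6.8414, 6.6696, 6.528, 6.4095, 6.3087, 6.2221, 6.1468, 6.0807, 6.0223, 5.9703, 5.9238, 5.8818, 5.8438, 5.8092, 5.7775, 5.7485, 5.7218, 5.6972, 5.6743, 5.6531],
    10: [31.6894, 16.6908, 12.2637, 10.2393, 9.0966, 8.3674, 7.8632, 7.4945, 7.2133, 6.9921, 6.8136, 6.6664, 6.5432, 6.4384, 6.3483, 6.27, 6.2013, 6.1406, 6.0865, 6.038, 5.9943, 5.9547, 5.9187, 5.8858, 5.8556, 5.8278, 5.8021, 5.7784, 5.7563],
}


def q_critical(n_groups: int, df_error: int, alpha: float) -> float:
    """Studentized-range critical value from the embedded table.

    Covers n_groups 2..10, df 2..30 at alpha in {0.05, 0.01}.  A df above
    30 is clamped to 30 (conservative for significance claims).
    """
    table = {0.05: _Q_05, 0.01: _Q_01}.get(alpha)
    if table is None:
        raise ValueError(f"alpha must be 0.05 or 0.01, got {alpha}")
    if n_groups not in table:
        raise ValueError(f"n_groups must be in 2..10, got {n_groups}")
    if df_error < 2:
        raise ValueError(f"df_error must be >= 2, got {df_error}")
    return table[n_groups][min(df_error, 30) - 2]


@dataclass
class TukeyResult:
    F: float
    p_anova: float
    pairwise: list[tuple[tuple[str, str], float, str]]  # (pair, Q, tier)
    q_crit_05: float
    q_crit_01: float
    df_error: int
    msw: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"group_1": a, "group_2": b, "Q": q, "inference": tier}
             for (a, b), q, tier in self.pairwise]
        )


def anova_tukey(per_group: dict[str, Sequence[float]]) -> TukeyResult:
    """One-way ANOVA over groups plus Tukey-Kramer pairwise Q statistics.

    ``Q_{i,j} = |mean_i - mean_j| / sqrt(MSW / n)`` with the within-group
    mean square MSW and common group size n; significance tiers compare Q
    with the studentized-range critical values at alpha 0.05 and 0.01.
    Requires >= 2 groups of equal size >= 2.
    """
    names = list(per_group)
    groups = [np.asarray(per_group[g], dtype=float) for g in names]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = {len(g) for g in groups}
    if len(sizes) != 1:
        raise ValueError(f"groups must be equal-sized, got sizes {sorted(len(g) for g in groups)}")
    n = sizes.pop()
    if n < 2:
        raise ValueError("each group needs at least two observations")
    k = len(groups)
    df_error = k * (n - 1)
    F, p = _st.f_oneway(*groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msw = ss_within / df_error
    if msw == 0:
        F, p = 0.0, 1.0  # identical groups: no variance to compare
    q05 = q_critical(k, df_error, 0.05)
    q01 = q_critical(k, df_error, 0.01)
    se = np.sqrt(msw / n)
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(groups[i].mean() - groups[j].mean())
            Q = diff / se if se > 0 else 0.0
            tier = "p<0.01" if Q > q01 else ("p<0.05" if Q > q05 else "ns")
            pairwise.append(((names[i], names[j]), float(Q), tier))
    return TukeyResult(F=float(F), p_anova=float(p), pairwise=pairwise,
                       q_crit_05=q05, q_crit_01=q01, df_error=df_error, msw=float(msw))


# ---------------------------------------------------------------------------
# classifier comparison harness

class _DBNClassifier:
    """train/predict adapter over the sparse-DBN (or plain DBN, lambda=0)."""

    def __init__(self, hidden: Sequence[int], cfg: TrainConfig):
        self.hidden = list(hidden)
        self.cfg = cfg
        self.model = None

    def train(self, train: FeatureMatrix, valid: FeatureMatrix) -> None:
        arch = [train.n_features, *self.hidden, 2]
        self.model = train_dbn(train, valid, arch, self.cfg)

    def predict(self, X: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        return dbn_predict(self.model, X)


class _ANNClassifier:
    def __init__(self, cfg: ANNConfig):
        self.cfg = cfg
        self.model = None

    def train(self, train: FeatureMatrix, valid: FeatureMatrix) -> None:
        self.model = train_ann(train, valid, self.cfg)

    def predict(self, X: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        return predict_ann(self.model, X)


def make_classifier(kind: str, seed: int = 0, hidden: Optional[Sequence[int]] = None, **overrides):
    """Factory for the built-in classifiers: 'ann', 'dbn', 'sparse-dbn'.

    Any object exposing ``train(train_fm, valid_fm)`` and
    ``predict(fm) -> (scores, labels)`` can stand in for an external
    classifier in :func:`compare_classifiers`.
    """
    if kind == "ann":
        n_hidden = hidden[0] if hidden else 15
        return _ANNClassifier(ANNConfig(n_hidden=n_hidden, seed=seed, **overrides))
    if kind in ("dbn", "sparse-dbn"):
        lam = overrides.pop("lambda_", 1.0 if kind == "sparse-dbn" else 0.0)
        if kind == "dbn":
            lam = 0.0
        cfg = TrainConfig(seed=seed, lambda_=lam, **overrides)
        return _DBNClassifier(hidden or [15, 15], cfg)
    raise ValueError(f"unknown classifier kind {kind!r}; expected ann, dbn or sparse-dbn")


@dataclass
class ComparisonReport:
    """Outcome of the multi-classifier comparison."""

    protocol: str
    reports: dict[str, EvalReport]
    table: pd.DataFrame
    tukey: Optional[TukeyResult] = None
    errors: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "protocol": self.protocol,
            "classifiers": {k: r.to_dict() for k, r in self.reports.items()},
            "errors": self.errors,
        }
        if self.tukey is not None:
            d["tukey"] = {
                "F": self.tukey.F,
                "p_anova": self.tukey.p_anova,
                "q_crit_05": self.tukey.q_crit_05,
                "q_crit_01": self.tukey.q_crit_01,
                "df_error": self.tukey.df_error,
                "pairwise": [
                    {"pair": list(pair), "Q": q, "inference": tier}
                    for pair, q, tier in self.tukey.pairwise
                ],
            }
        return d


def _evaluate_on(clf, train: FeatureMatrix, valid: FeatureMatrix, test: FeatureMatrix) -> EvalReport:
    tr_s, (va_s, te_s) = scale_minmax01(train, [valid, test])
    clf.train(tr_s, va_s)
    scores, labels = clf.predict(te_s)
    report = confusion_metrics(te_s.y, labels)
    if len(np.unique(te_s.y)) == 2:
        report.roc, report.auroc = roc_curve(scores, te_s.y)
    return report


def compare_classifiers(
    features: FeatureMatrix,
    classifiers: dict[str, object],
    protocol: str = "holdout",
    seed: int = 0,
    k: int = 3,
    repeats: int = 1,
    groups: Optional[Sequence] = None,
) -> ComparisonReport:
    """Run several classifiers under a shared split and compare them.

    ``classifiers`` maps display name -> classifier object (see
    :func:`make_classifier`).  For the hold-out protocol each classifier
    is trained on the train subset with early stopping on the validation
    subset and scored on the test subset.  For k-fold, each fold serves
    once as the test set while the remaining folds are split 2:1 into
    train/validation (the early-stopping contract needs a validation set);
    ``repeats`` reruns each fold with a derived seed, and fold accuracies
    feed the one-way ANOVA + Tukey-Kramer comparison when every classifier
    produced the same number of fold results (>= 2).  A classifier failure
    is recorded and the run continues.
    """
    if protocol not in ("holdout", "kfold"):
        raise ValueError(f"protocol must be 'holdout' or 'kfold', got {protocol!r}")
    n = features.n_samples
    reports: dict[str, EvalReport] = {}
    errors: dict[str, str] = {}
    rows = []
    fold_acc: dict[str, list[float]] = {}

    if protocol == "holdout":
        tr, va, te = holdout_split(n, seed, groups=groups)
        for name, clf in classifiers.items():
            try:
                rep = _evaluate_on(clf, features.subset(tr), features.subset(va), features.subset(te))
                reports[name] = rep
                rows.append({"classifier": name, "TP": rep.counts.TP, "FN": rep.counts.FN,
                             "TN": rep.counts.TN, "FP": rep.counts.FP,
                             "sensitivity_pct": rep.sensitivity, "specificity_pct": rep.specificity,
                             "accuracy_pct": rep.accuracy, "auroc": rep.auroc})
            except Exception as exc:  # noqa: BLE001 — per-cell failure policy
                errors[name] = str(exc)
        return ComparisonReport("holdout", reports, pd.DataFrame(rows), errors=errors)

    folds = kfold_split(n, k, seed)
    for name, clf in classifiers.items():
        per_fold: list[EvalReport] = []
        try:
            for fi, test_idx in enumerate(folds):
                rest = np.concatenate([f for fj, f in enumerate(folds) if fj != fi])
                for rep_i in range(repeats):
                    rng = np.random.default_rng([seed, fi, rep_i])
                    perm = rng.permutation(rest)
                    n_tr = ceil(2 * len(perm) / 3)
                    per_fold.append(
                        _evaluate_on(
                            clf,
                            features.subset(perm[:n_tr]),
                            features.subset(perm[n_tr:]),
                            features.subset(test_idx),
                        )
                    )
            accs = [r.accuracy for r in per_fold]
            mean_rep = per_fold[0]
            summary = EvalReport(
                counts=ConfusionCounts(
                    TP=int(np.mean([r.counts.TP for r in per_fold])),
                    FP=int(np.mean([r.counts.FP for r in per_fold])),
                    TN=int(np.mean([r.counts.TN for r in per_fold])),
                    FN=int(np.mean([r.counts.FN for r in per_fold])),
                ),
                sensitivity=float(np.mean([r.sensitivity for r in per_fold])),
                specificity=float(np.mean([r.specificity for r in per_fold])),
                accuracy=float(np.mean(accs)),
                auroc=float(np.mean([r.auroc for r in per_fold if r.auroc is not None]))
                if any(r.auroc is not None for r in per_fold) else None,
                per_fold=per_fold,
            )
            reports[name] = summary
            fold_acc[name] = accs
            rows.append({
                "classifier": name,
                "sensitivity_pct_mean": summary.sensitivity,
                "sensitivity_pct_sd": float(np.std([r.sensitivity for r in per_fold], ddof=1)),
                "specificity_pct_mean": summary.specificity,
                "specificity_pct_sd": float(np.std([r.specificity for r in per_fold], ddof=1)),
                "accuracy_pct_mean": summary.accuracy,
                "accuracy_pct_sd": float(np.std(accs, ddof=1)),
                "auroc_mean": summary.auroc,
            })
        except Exception as exc:  # noqa: BLE001
            errors[name] = str(exc)

    tukey = None
    lens = {len(v) for v in fold_acc.values()}
    if len(fold_acc) >= 2 and len(lens) == 1 and lens.pop() >= 2:
        tukey = anova_tukey(fold_acc)
    return ComparisonReport("kfold", reports, pd.DataFrame(rows), tukey=tukey, errors=errors)
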