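"""Model validation: diagnostic panel, double cross-validation, permutation test.

The diagnostic panel follows common PLS-DA practice for food-authenticity
models: per class (one-versus-rest) the cross-validated regression errors
RMSECV, Q2 and the discriminant DQ2, the confusion-matrix rates accuracy,
sensitivity, specificity, efficiency (geometric mean of sensitivity and
specificity), precision, the Matthews correlation coefficient, and AUROC.

Performance is estimated by double (nested) cross-validation: the outer
loop measures held-out performance, the inner loop picks the number of
latent variables, and autoscaling is refit inside every training
partition so no held-out sample influences scaling, complexity selection
or fitting for its own fold.

The permutation test shuffles class labels, re-runs the cross-validated
classifier and counts misclassified samples; with no class structure the
count is binomial(n, 0.5)-like, which serves as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .chemometrics import PLSDAClassifier
from .exceptions import DataError

METRIC_NAMES = (
    "rmsecv",
    "q2",
    "dq2",
    "accuracy",
    "sensitivity",
    "specificity",
    "efficiency",
    "precision",
    "matthews",
    "auroc",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; reals, so means over repetitions are valid."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.total == 0:
            raise DataError("confusion counts sum to zero")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


def confusion(true_labels, predicted_labels, positive) -> ConfusionCounts:
    """Standard 2x2 counts for the one-vs-rest dichotomy on ``positive``."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise DataError("label vectors differ in length")
    if positive not in set(t) | set(p):
        raise DataError(f"positive class {positive!r} absent from labels")
    tpos = t == positive
    ppos = p == positive
    return ConfusionCounts(
        tp=float(np.sum(tpos & ppos)),
        tn=float(np.sum(~tpos & ~ppos)),
        fp=float(np.sum(~tpos & ppos)),
        fn=float(np.sum(tpos & ~ppos)),
    )


def efficiency(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity, in [0, 1]."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise DataError("sensitivity and specificity must lie in [0, 1]")
    return float(np.sqrt(sensitivity * specificity))


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN (undefined, never 0) when nothing was called positive."""
    denom = counts.tp + counts.fp
    return float(counts.tp / denom) if denom > 0 else float("nan")


def matthews(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; NaN when any marginal is zero."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return float("nan")
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


def classification_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); per-metric NaN on zero denominators."""
    acc = (counts.tp + counts.tn) / counts.total
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sens = counts.tp / pos if pos > 0 else float("nan")
    spec = counts.tn / neg if neg > 0 else float("nan")
    return float(acc), sens, spec


def regression_cv_metrics(y, y_hat) -> tuple[float, float, float]:
    """(RMSECV, Q2, DQ2) of cross-validated predictions of a 0/1 indicator.

    DQ2 is the discriminant Q2: residuals are zeroed when the prediction
    lies beyond its class label (y_hat > 1 for y = 1, y_hat < 0 for
    y = 0) — overshooting the correct side of the decision boundary is
    not an error for classification purposes, so DQ2 >= Q2 always.
    """
    y = np.asarray(y, dtype=float)
    yh = np.asarray(y_hat, dtype=float)
    if y.shape != yh.shape:
        raise DataError("y and y_hat differ in length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("y must be coded 0/1")
    resid = y - yh
    press = float(np.sum(resid**2))
    rmsecv = float(np.sqrt(press / len(y)))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return rmsecv, float("nan"), float("nan")
    q2 = 1.0 - press / tss
    overshoot = ((y == 1) & (yh > 1)) | ((y == 0) & (yh < 0))
    dresid = np.where(overshoot, 0.0, resid)
    dq2 = 1.0 - float(np.sum(dresid**2)) / tss
    return rmsecv, q2, dq2


def auroc(y_true, scores) -> float:
    """Pairwise concordance probability (Mann-Whitney), ties counted 1/2."""
    y = np.asarray(y_true)
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def binomial_reference(n: int, p: float = 0.5):
    """Exact binomial pmf over 0..n and its mean n*p."""
    if n < 1:
        raise DataError("n must be >= 1")
    if not 0 < p < 1:
        raise DataError("p must lie in (0, 1)")
    k = np.arange(n + 1)
    return stats.binom.pmf(k, n, p), float(n * p)


# ---------------------------------------------------------------------------
# double cross-validation


def _panel(
    y_bin: np.ndarray,
    y_hat: np.ndarray,
    hard_pos: np.ndarray,
    rank_scores: np.ndarray | None = None,
) -> dict:
    """Full metric panel for one class contrast from pooled CV predictions.

    ``rank_scores`` is the classifier's per-sample ranking score for the
    class (higher = more class-like), used for AUROC; regression metrics
    are always computed on the continuous indicator predictions. Defaults
    to the indicator predictions themselves.
    """
    if rank_scores is None:
        rank_scores = y_hat
    counts = ConfusionCounts(
        tp=float(np.sum((y_bin == 1) & hard_pos)),
        tn=float(np.sum((y_bin == 0) & ~hard_pos)),
        fp=float(np.sum((y_bin == 0) & hard_pos)),
        fn=float(np.sum((y_bin == 1) & ~hard_pos)),
    )
    acc, sens, spec = classification_metrics(counts)
    rmsecv, q2, dq2 = regression_cv_metrics(y_bin, y_hat)
    eff = (
        efficiency(sens, spec)
        if np.isfinite(sens) and np.isfinite(spec)
        else float("nan")
    )
    return {
        "rmsecv": rmsecv,
        "q2": q2,
        "dq2": dq2,
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "efficiency": eff,
        "precision": precision(counts),
        "matthews": matthews(counts),
        "auroc": auroc(y_bin, rank_scores),
    }


@dataclass
class CVReport:
    """Double-CV diagnostics aggregated over repetitions.

    ``mean``/``median`` are metric x class DataFrames; ``per_repetition``
    maps class -> (repetitions x metrics) DataFrame; ``chosen_lv`` records
    the inner-CV-selected latent-variable count of every outer fold.
    """

    mean: pd.DataFrame
    median: pd.DataFrame
    per_repetition: dict[object, pd.DataFrame]
    chosen_lv: list[int]
    n_repetitions: int

    def to_csv(self, path) -> None:
        """Table-3-style layout: metric rows, class x {mean, median} columns."""
        blocks = []
        for stat, df in (("mean", self.mean), ("median", self.median)):
            d = df.copy()
            d.columns = [f"{c}_{stat}" for c in d.columns]
            blocks.append(d)
        out = pd.concat(blocks, axis=1)
        out.index.name = "metric"
        out.to_csv(path)


def _inner_select_lv(
    X: np.ndarray,
    y: np.ndarray,
    classes: np.ndarray,
    inner_k: int,
    max_lv: int,
    rng: np.random.Generator,
) -> int:
    """Pick the LV count maximizing pooled inner-CV Q2 across classes."""
    skf = StratifiedKFold(
        n_splits=inner_k, shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    fit_classes = classes[1:] if len(classes) == 2 else classes
    press = np.zeros(max_lv)
    tss = 0.0
    for tr, te in skf.split(X, y):
        model = PLSDAClassifier(n_components=max_lv, scale=True).fit(
            X[tr], y[tr]
        )
        a_max = model.n_components_
        cols = {cls: list(model.classes_).index(cls) for cls in fit_classes}
        for a in range(1, max_lv + 1):
            scores = model.decision_function(X[te], n_components=min(a, a_max))
            for cls in fit_classes:
                y_bin = (y[te] == cls).astype(float)
                press[a - 1] += float(np.sum((y_bin - scores[:, cols[cls]]) ** 2))
        for cls in fit_classes:
            y_bin = (y[te] == cls).astype(float)
            tss += float(np.sum((y_bin - (y[tr] == cls).mean()) ** 2))
    q2 = 1.0 - press / max(tss, 1e-300)
    return int(np.argmax(q2)) + 1


def double_cross_validate(
    X,
    labels,
    outer_k: int = 5,
    inner_k: int = 5,
    n_repetitions: int = 20,
    max_lv: int = 5,
    seed: int | None = None,
    outer_splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVReport:
    """Repeated stratified double CV of one-vs-rest PLS-DA.

    Per repetition: a stratified outer split; for each outer fold the
    inner CV (on outer-training data only) selects the latent-variable
    count maximizing inner Q2; the model is refit on the outer-training
    set — including its autoscaling — and applied to the held-out fold.
    The per-class metric panel is computed on the pooled outer
    predictions of the repetition, then aggregated as mean and median
    across repetitions. ``outer_splits`` overrides the outer folds of a
    single repetition (used for leakage diagnostics).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < outer_k]
    if len(too_small):
        raise DataError(
            f"class(es) {list(too_small)} have fewer than outer_k={outer_k} members"
        )
    rng = np.random.default_rng(seed)
    if outer_splits is not None:
        n_repetitions = 1

    per_rep: dict[object, list[dict]] = {cls: [] for cls in classes}
    chosen_lv: list[int] = []
    for _ in range(n_repetitions):
        if outer_splits is None:
            skf = StratifiedKFold(
                n_splits=outer_k, shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            splits = list(skf.split(X, y))
        else:
            splits = [(np.asarray(tr), np.asarray(te)) for tr, te in outer_splits]
        y_hat = np.zeros((len(y), len(classes)))
        rank = np.zeros((len(y), len(classes)))
        hard = np.empty(len(y), dtype=object)
        covered = np.zeros(len(y), dtype=bool)
        for tr, te in splits:
            a_star = _inner_select_lv(X[tr], y[tr], classes, inner_k, max_lv, rng)
            chosen_lv.append(a_star)
            model = PLSDAClassifier(n_components=a_star, scale=True).fit(
                X[tr], y[tr]
            )
            y_hat[te] = model.decision_function(X[te])
            rank[te] = -model.class_distances(X[te])
            hard[te] = model.predict(X[te])
            covered[te] = True
        for j, cls in enumerate(classes):
            y_bin = (y[covered] == cls).astype(float)
            per_rep[cls].append(
                _panel(
                    y_bin,
                    y_hat[covered, j],
                    hard[covered] == cls,
                    rank_scores=rank[covered, j],
                )
            )

    per_repetition = {
        cls: pd.DataFrame(rows, columns=list(METRIC_NAMES))
        for cls, rows in per_rep.items()
    }
    mean = pd.DataFrame(
        {cls: df.mean() for cls, df in per_repetition.items()}
    )
    median = pd.DataFrame(
        {cls: df.median() for cls, df in per_repetition.items()}
    )
    return CVReport(
        mean=mean,
        median=median,
        per_repetition=per_repetition,
        chosen_lv=chosen_lv,
        n_repetitions=n_repetitions,
    )


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationResult:
    """Null distribution of misclassified counts under label permutation."""

    misclassified: np.ndarray
    n_iterations: int
    n_samples: int
    observed: int
    reference_pmf: np.ndarray
    reference_mean: float
    p_value: float

    @property
    def mean_misclassified_fraction(self) -> float:
        return float(self.misclassified.mean() / self.n_samples)

    def to_frame(self) -> pd.DataFrame:
        """Histogram of null counts with the binomial reference overlay."""
        k = np.arange(self.n_samples + 1)
        hist = np.bincount(self.misclassified, minlength=self.n_samples + 1)
        return pd.DataFrame(
            {
                "misclassified": k,
                "empirical_fraction": hist / self.n_iterations,
                "binomial_reference": self.reference_pmf,
            }
        )


def _cv_misclassified(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int,
    n_components: int,
    random_state: int,
) -> int:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    wrong = 0
    for tr, te in skf.split(X, y):
        model = PLSDAClassifier(n_components=n_components, scale=True).fit(
            X[tr], y[tr]
        )
        wrong += int(np.sum(model.predict(X[te]) != y[te]))
    return wrong


def permutation_test(
    X,
    labels,
    n_iterations: int = 1000,
    n_folds: int = 5,
    n_components: int = 2,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation null of the cross-validated misclassification count.

    Each iteration permutes the labels uniformly, re-runs the stratified
    k-fold cross-validated PLS-DA (autoscaling refit per training fold, a
    fixed latent-variable count for tractability) and records how many
    samples were misclassified. The unpermuted model's count is compared
    against this null with the (b + 1)/(m + 1) left-tail empirical
    p-value; the binomial(n, 0.5) mass function is attached as the
    theoretical no-structure reference.
    """
    if n_iterations < 1:
        raise DataError("need at least one permutation iteration")
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n = len(y)

    observed = _cv_misclassified(
        X, y, n_folds, n_components, int(rng.integers(2**31 - 1))
    )
    counts = np.empty(n_iterations, dtype=int)
    for i in range(n_iterations):
        perm = rng.permutation(y)
        counts[i] = _cv_misclassified(
            X, perm, n_folds, n_components, int(rng.integers(2**31 - 1))
        )
    pmf, ref_mean = binomial_reference(n, 0.5)
    p = (int(np.sum(counts <= observed)) + 1) / (n_iterations + 1)
    return PermutationResult(
        misclassified=counts,
        n_iterations=n_iterations,
        n_samples=n,
        observed=observed,
        reference_pmf=pmf,
        reference_mean=ref_mean,
        p_value=float(p),
    )
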