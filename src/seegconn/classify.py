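"""Linear outcome classification in the (mean, SD) connectivity plane.

Each patient is a point whose x coordinate is the mean and y coordinate the
standard deviation of the off-diagonal connectivity entries; the label is the
surgical outcome (True = seizure-free).  A straight separating line is fitted
either as a soft-margin linear support-vector classifier or as a
pooled-covariance linear discriminant; performance is estimated with the
leave-one-out method and its significance with a label-permutation test.
Group differences in either coordinate are assessed with the two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import _libsvm

_libsvm.set_verbosity_wrap(0)

__all__ = [
    "LabeledPoint",
    "SeparatingLine",
    "ClassifierReport",
    "PermutationResult",
    "SingleClassError",
    "SingularCovarianceError",
    "fit_linear_svc",
    "fit_lda",
    "loo_evaluate",
    "permutation_test",
    "rank_sum_test",
]

Fitter = Callable[[np.ndarray, np.ndarray], "SeparatingLine"]


class SingleClassError(ValueError):
    """Raised when a fit is requested with only one outcome label present."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """Raised when the pooled covariance of the discriminant is not invertible."""


@dataclass(frozen=True)
class LabeledPoint:
    """A patient in the feature plane: (mean, SD) of connectivity + outcome."""

    patient_id: str
    x: float
    y: float
    label: bool

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")


@dataclass
class SeparatingLine:
    """2-D linear decision rule: predict positive iff w·(x, y) + offset ≥ 0."""

    weights: np.ndarray
    offset: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float).ravel()
        if w.shape != (2,):
            raise ValueError("weights must be a 2-vector")
        if np.all(w == 0.0):
            raise ValueError("weights must not both be zero")
        self.weights = w
        self.offset = float(self.offset)

    def decision_values(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, float)) @ self.weights + self.offset

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Boolean predictions; a point exactly on the line counts positive."""
        return self.decision_values(points) >= 0.0


@dataclass
class ClassifierReport:
    """Leave-one-out confusion counts and the derived performance metrics.

    Positive = seizure-free.  ``sensitivity = TP/(TP+FN)``,
    ``specificity = TN/(TN+FP)``, ``accuracy = (TP+TN)/(TP+FP+TN+FN)``.
    """

    predictions: list[bool]
    labels: list[bool]
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.predictions) != len(self.labels):
            raise ValueError("one prediction per label required")
        p = np.asarray(self.predictions, bool)
        y = np.asarray(self.labels, bool)
        self.tp = int(np.sum(p & y))
        self.fp = int(np.sum(p & ~y))
        self.tn = int(np.sum(~p & ~y))
        self.fn = int(np.sum(~p & y))

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "ClassifierReport":
        preds = [True] * tp + [True] * fp + [False] * tn + [False] * fn
        labels = [True] * tp + [False] * fp + [False] * tn + [True] * fn
        return cls(preds, labels)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def metrics(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


@dataclass
class PermutationResult:
    """Exceedance p-values from random relabelings of the cohort.

    Each p-value is the fraction of permutations whose metric is equal to or
    higher than the observed one (plain count/n estimator; set
    ``add_one=True`` in :func:`permutation_test` for the (count+1)/(n+1)
    variant).
    """

    n_permutations: int
    p_sensitivity: float
    p_specificity: float
    p_accuracy: float
    seed: int
    observed: ClassifierReport | None = None


def _as_xy(points) -> np.ndarray:
    if isinstance(points, (list, tuple)) and points and isinstance(points[0], LabeledPoint):
        return np.array([[p.x, p.y] for p in points], dtype=float)
    return np.asarray(points, dtype=float).reshape(-1, 2)


def fit_linear_svc(
    points, labels: Sequence[bool], C: float = 1000.0, tol: float = 1e-3
) -> SeparatingLine:
    """Soft-margin linear support-vector fit on raw (unstandardised) features.

    Minimises ``½‖w‖² + C·Σ hinge`` and returns the separating line; on
    linearly separable data a sufficiently large ``C`` yields zero training
    error.  Deterministic given the inputs.

    The default ``C`` is large because the connectivity features are used raw:
    they live on a ~0.1 scale, and the soft-margin trade-off that C = 1 strikes
    for unit-variance features requires C of order 1/scale² here (a small C
    degenerates into majority voting).  ``tol`` is the solver's KKT tolerance;
    tighten it (e.g. 1e-10) when decision values are compared numerically.
    """
    x = _as_xy(points)
    y = np.asarray(labels, dtype=bool)
    if C <= 0:
        raise ValueError("C must be positive")
    if len(set(y.tolist())) < 2:
        raise SingleClassError("both outcome labels must be present to fit")
    # libsvm through its low-level entry point: leave-one-out permutation
    # testing performs thousands of tiny fits, where the public estimator's
    # per-call validation dominates.  Labels are encoded {False: 0, True: 1}
    # and the binary solution negated, exactly as sklearn.svm.SVC does;
    # equality with the public estimator is asserted in the test suite.
    xs = np.ascontiguousarray(x, dtype=np.float64)
    out = _libsvm.fit(
        xs, y.astype(np.float64), svm_type=0, kernel="linear",
        C=float(C), tol=float(tol),
    )
    weights = -(out[3][0] @ out[1])
    offset = -float(out[4][0])
    return SeparatingLine(weights, offset)


def fit_lda(points, labels: Sequence[bool]) -> SeparatingLine:
    """Closed-form pooled-covariance linear discriminant with equal priors.

    ``w = Σ_pooled⁻¹ (μ₊ − μ₋)`` and the boundary passes through the midpoint
    of the class means.
    """
    x = _as_xy(points)
    y = np.asarray(labels, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise SingleClassError("each class needs at least 2 points")
    xp, xn = x[y], x[~y]
    mp, mn = xp.mean(axis=0), xn.mean(axis=0)
    sp = np.cov(xp, rowvar=False, ddof=1) * (len(xp) - 1)
    sn = np.cov(xn, rowvar=False, ddof=1) * (len(xn) - 1)
    pooled = (sp + sn) / (len(x) - 2)
    if np.linalg.cond(pooled) > 1e12:
        raise SingularCovarianceError("pooled covariance is singular")
    w = np.linalg.solve(pooled, mp - mn)
    offset = -float(w @ (mp + mn) / 2.0)
    return SeparatingLine(w, offset)


def loo_evaluate(
    points,
    labels: Sequence[bool],
    fitter: Fitter = fit_linear_svc,
    patient_ids: Sequence[str] | None = None,
) -> ClassifierReport:
    """Leave-one-out evaluation of a separating-line fitter.

    For each patient the line is refitted on the remaining patients and the
    held-out point is classified; confusion counts accumulate over all folds.
    A fold whose training set contains a single class (possible under
    permuted labels in tiny cohorts) falls back to predicting the training
    majority label.
    """
    x = _as_xy(points)
    y = np.asarray(labels, dtype=bool)
    if len(x) < 3:
        raise ValueError("leave-one-out needs at least 3 points")
    if len(set(y.tolist())) < 2:
        raise SingleClassError("both outcome labels must be present")
    preds: list[bool] = []
    for i in range(len(x)):
        keep = np.arange(len(x)) != i
        ytr = y[keep]
        if ytr.all() or not ytr.any():
            preds.append(bool(ytr[0]))
            continue
        line = fitter(x[keep], ytr)
        preds.append(bool(line.predict(x[i : i + 1])[0]))
    ids = list(patient_ids) if patient_ids is not None else []
    return ClassifierReport(preds, y.tolist(), ids)


def permutation_test(
    points,
    labels: Sequence[bool],
    n_permutations: int = 10_000,
    seed: int = 0,
    fitter: Fitter = fit_linear_svc,
    add_one: bool = False,
) -> PermutationResult:
    """Label-permutation significance of the leave-one-out metrics.

    Each permutation uniformly rearranges the observed label multiset (label
    counts are preserved, not resampled), the full leave-one-out evaluation
    is recomputed, and each p-value is the probability of a permuted metric
    equal to or higher than the observed one.  Reproducible given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be ≥ 1")
    x = _as_xy(points)
    y = np.asarray(labels, dtype=bool)
    observed = loo_evaluate(x, y, fitter)
    obs = observed.metrics()
    rng = np.random.default_rng(seed)
    counts = {k: 0 for k in obs}
    eps = 1e-12
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        rep = loo_evaluate(x, perm, fitter).metrics()
        for k in counts:
            if rep[k] >= obs[k] - eps:
                counts[k] += 1
    if add_one:
        p = {k: (c + 1) / (n_permutations + 1) for k, c in counts.items()}
    else:
        p = {k: c / n_permutations for k, c in counts.items()}
    return PermutationResult(
        n_permutations=n_permutations,
        p_sensitivity=p["sensitivity"],
        p_specificity=p["specificity"],
        p_accuracy=p["accuracy"],
        seed=seed,
        observed=observed,
    )


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two samples.

    Uses exact null enumeration when both groups have ≤ 12 observations and
    there are no ties, otherwise the normal approximation with continuity and
    tie corrections.  Returns ``(W, p)`` where W is the rank-sum statistic of
    ``group_a``.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if a.size <= 12 and b.size <= 12 and not ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return w, float(res.pvalue)
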