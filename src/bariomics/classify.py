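"""Linear-SVM group classification in PC space with permutation significance.

Separates sample groups (lean vs obese; pre- vs post-surgery) using the
projections onto the leading principal components.  Evaluation is a ROC
curve whose AUC equals the normalized Mann-Whitney U statistic, and its
significance is calibrated by label scrambling: the whole train+evaluate
path is re-run on each of ``n_perm`` relabelings and the observed AUC is
ranked among the scrambled ones with the add-one rule, so p is never
exactly zero.

Two evaluation modes are provided because the appropriate one depends on
the question: ``cv="stratified5"`` (default) pools decision values from
held-out stratified folds and measures out-of-sample separability;
``cv="resubstitution"`` scores the training data itself and measures
in-sample separability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .decompose import ScoreMatrix

PRE_TIMEPOINTS = ("A", "B")
POST_TIMEPOINTS = ("C", "D", "E")


def contrast_labels(meta: pd.DataFrame, contrast: str,
                    pre=PRE_TIMEPOINTS, post=POST_TIMEPOINTS) -> pd.Series:
    """Binary labels for a named contrast; samples outside the contrast are NaN.

    ``lean_vs_obese``: lean controls (H) are 0, all obese time points are 1.
    ``pre_vs_post``: presurgery points (A, B by default) are 0, postsurgery
    (C, D, E) are 1; lean samples are excluded.
    """
    tp = meta["timepoint"]
    labels = pd.Series(np.nan, index=meta.index, dtype=float)
    if contrast == "lean_vs_obese":
        labels[tp == "H"] = 0
        labels[tp != "H"] = 1
    elif contrast == "pre_vs_post":
        labels[tp.isin(pre)] = 0
        labels[tp.isin(post)] = 1
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return labels


def train_linear_svm(scores: ScoreMatrix | np.ndarray, labels,
                     regularization: float = 1.0) -> tuple[np.ndarray, float]:
    """Maximum-margin linear separator (hinge loss, L2 penalty).

    Returns ``(w, b)`` with decision value ``w·score + b``; positive values
    vote for the positive class.
    """
    X = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train a classifier")
    svm = SVC(kernel="linear", C=regularization)
    svm.fit(X, y)
    return svm.coef_.ravel().copy(), float(svm.intercept_[0])


def roc_auc(decision_values, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC of decision values against binary labels.

    The AUC equals the Mann-Whitney U statistic divided by
    ``n_pos * n_neg``; tied decision values contribute half a concordant
    pair.  The returned curve starts at (0, 0) and ends at (1, 1) with both
    coordinates non-decreasing.
    """
    y = np.asarray(labels, dtype=float)
    d = np.asarray(decision_values, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y, d)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, auc


def _evaluate(X: np.ndarray, y: np.ndarray, regularization: float,
              cv: str, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    """Train+evaluate once; returns (decision values, roc points, auc)."""
    if cv == "resubstitution":
        w, b = train_linear_svm(X, y, regularization)
        decision = X @ w + b
    elif cv == "stratified5":
        n_splits = min(5, int(np.min(np.bincount(y.astype(int)))))
        if n_splits < 2:
            raise ValueError("too few samples in the minority class for CV")
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                   random_state=int(rng.integers(2**31)))
        decision = np.empty_like(y, dtype=float)
        for train_idx, test_idx in splitter.split(X, y):
            w, b = train_linear_svm(X[train_idx], y[train_idx], regularization)
            decision[test_idx] = X[test_idx] @ w + b
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")
    points, auc = roc_auc(decision, y)
    return decision, points, auc


def permutation_pvalue(scores: ScoreMatrix | np.ndarray, labels,
                       n_perm: int = 1000, seed: int = 0,
                       regularization: float = 1.0,
                       cv: str = "resubstitution") -> float:
    """Label-scrambling p-value for the classifier AUC.

    Each permutation redraws the labels (class multiset preserved) and
    re-runs the entire train+evaluate path; ``p = (1 + #{AUC_perm >=
    AUC_obs}) / (n_perm + 1)``.
    """
    X = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    _, _, observed = _evaluate(X, y, regularization, cv, rng)
    hits = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        _, _, auc_perm = _evaluate(X, y_perm, regularization, cv, rng)
        if auc_perm >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


@dataclass
class ClassificationResults:
    """Fitted classifier with its evaluation; returned by GroupClassifier.fit."""

    weights: np.ndarray           # per-PC weight of the full-data separator
    bias: float
    auc: float
    roc_points: np.ndarray
    decision_values: np.ndarray
    cv_scheme: str
    regularization: float
    n_permutations: int | None = None
    p_perm: float | None = None
    component_names: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Linear SVM group classification",
            f"  evaluation: {self.cv_scheme}",
            f"  AUC: {self.auc:.3f}",
        ]
        if self.p_perm is not None:
            lines.append(
                f"  permutation p: {self.p_perm:.4g} ({self.n_permutations} scrambles)")
        lines.append("  weights:")
        names = self.component_names or [f"PC{i+1}" for i in range(len(self.weights))]
        for name, w in zip(names, self.weights):
            lines.append(f"    {name:>6}: {w:+.4f}")
        return "\n".join(lines)


class GroupClassifier:
    """Model object: linear SVM over PC scores for a binary group contrast.

    Parameters
    ----------
    scores
        ScoreMatrix (or plain array) of the samples to classify.
    labels
        Binary labels aligned with the score rows; NaN rows are dropped.
    """

    def __init__(self, scores: ScoreMatrix | np.ndarray, labels):
        if isinstance(scores, ScoreMatrix):
            X = scores.scores
            self.component_names = [f"PC{i+1}" for i in range(scores.n_components)]
        else:
            X = np.asarray(scores, dtype=float)
            self.component_names = [f"PC{i+1}" for i in range(X.shape[1])]
        y = np.asarray(labels, dtype=float)
        keep = ~np.isnan(y)
        self.X = X[keep]
        self.y = y[keep]
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")

    def fit(self, regularization: float = 1.0, cv: str = "stratified5",
            n_perm: int | None = None, seed: int = 0) -> ClassificationResults:
        """Train, evaluate, and (optionally) permutation-calibrate.

        The reported per-PC weights come from the full-data fit (the
        cross-validated folds only supply held-out decision values).
        """
        rng = np.random.default_rng(seed)
        decision, points, auc = _evaluate(self.X, self.y, regularization, cv, rng)
        w, b = train_linear_svm(self.X, self.y, regularization)
        result = ClassificationResults(
            weights=w, bias=b, auc=auc, roc_points=points,
            decision_values=decision, cv_scheme=cv,
            regularization=regularization,
            component_names=self.component_names,
        )
        if n_perm:
            result.n_permutations = n_perm
            result.p_perm = permutation_pvalue(
                self.X, self.y, n_perm=n_perm, seed=seed,
                regularization=regularization, cv=cv)
        return result
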