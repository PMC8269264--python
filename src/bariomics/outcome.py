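"""Predicting post-surgery BMI change from the presurgery microbiome.

Each obese subject contributes one enrollment (time-point A) sample; its PC
score vector predicts the BMI change at a follow-up horizon (6, 12 or 18
months) through an L1-penalized linear regression, validated leave-one-out:
every subject is predicted by a model that never saw them.  The fold
coefficient vectors are averaged, so the reported support is the set of PCs
the LASSO kept across folds.

Sign convention everywhere: ``delta = BMI(follow-up) − BMI(A)``, negative
means weight loss.  The binary target for the ROC is "more than median
loss": observed delta strictly below the median of observed deltas.  Since
lower predicted delta should rank such subjects first, the ROC score is the
negated prediction.

The penalty, when not fixed, is chosen per fold by an inner leave-one-out
grid search with the one-standard-error parsimony rule — no information
from the held-out subject leaks into its own penalty or coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, lasso_path

from .classify import roc_auc
from .decompose import ScoreMatrix
from .tables import FOLLOWUP_COLUMNS


def assemble_outcome_table(scores: ScoreMatrix, meta: pd.DataFrame,
                           horizon: str = "6m",
                           duplicate_policy: str = "error"
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """One row per subject: point-A PC scores (X) and BMI delta (y).

    Subjects lacking an enrollment (A) sample or the follow-up BMI for the
    chosen horizon are excluded.  A subject with two A samples is ambiguous
    and rejected unless ``duplicate_policy='first'``.
    """
    if horizon not in FOLLOWUP_COLUMNS:
        raise ValueError(f"unknown horizon {horizon!r}; expected one of "
                         f"{sorted(FOLLOWUP_COLUMNS)}")
    col = FOLLOWUP_COLUMNS[horizon]
    frame = scores.to_frame()
    meta = meta.loc[meta.index.intersection(frame.index)]
    at_a = meta[meta["timepoint"] == "A"]
    if at_a["subject_id"].duplicated().any():
        dup = at_a.loc[at_a["subject_id"].duplicated(), "subject_id"].iloc[0]
        if duplicate_policy != "first":
            raise ValueError(f"subject {dup!r} has multiple point-A samples; "
                             "pass duplicate_policy='first' to keep the first")
        at_a = at_a[~at_a["subject_id"].duplicated()]
    eligible = at_a[at_a[col].notna()]
    if eligible.empty:
        raise ValueError(f"no subject has both a point-A sample and {col}")
    X = frame.loc[eligible.index].copy()
    X.index = pd.Index(eligible["subject_id"], name="subject_id")
    y = pd.Series(
        (eligible[col] - eligible["bmi"]).to_numpy(),
        index=X.index, name=f"delta_bmi_{horizon}",
    )
    return X, y


def _lasso_fit(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    model = Lasso(alpha=alpha, fit_intercept=True, max_iter=50_000, tol=1e-8)
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)

def _alpha_grid(X: np.ndarray, y: np.ndarray, n_alphas: int = 20) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alpha_max = np.max(np.abs(Xc.T @ yc)) / len(y)
    alpha_max = max(alpha_max, 1e-8)
    return np.geomspace(alpha_max, alpha_max * 1e-3, n_alphas)

def _choose_alpha_loo(X: np.ndarray, y: np.ndarray) -> float:
    """Inner leave-one-out over a log grid, one-SE rule.

    Picks the largest penalty whose mean LOO squared error is within one
    standard error of the minimum — favouring sparse, stable supports.
    """
    alphas = _alpha_grid(X, y)
    n = len(y)
    errors = np.empty((len(alphas), n))
    for i in range(n):
        mask = np.arange(n) != i
        Xt, yt = X[mask], y[mask]
        xm, ym = Xt.mean(axis=0), yt.mean()
        # lasso_path has no intercept: fit on centered data, path in one call
        _, coefs, _ = lasso_path(Xt - xm, yt - ym, alphas=alphas, tol=1e-8)
        preds = (X[i] - xm) @ coefs + ym
        errors[:, i] = (preds - y[i]) ** 2
    mean_err = errors.mean(axis=1)
    se = errors.std(axis=1, ddof=1) / np.sqrt(n)
    best = int(np.argmin(mean_err))
    threshold = mean_err[best] + se[best]
    # alphas are descending from alpha_max: first (largest) one under threshold
    for j in range(len(alphas)):
        if mean_err[j] <= threshold:
            return float(alphas[j])
    return float(alphas[best])


def loo_lasso(X, y, penalty: float | None = None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out L1 regression.

    Returns ``(predictions, coef_matrix, mean_coefficients)`` where
    ``coef_matrix`` stacks one coefficient vector per fold and
    ``mean_coefficients`` is their average — the quantity reported as the
    model's regression weights.  ``penalty=None`` triggers the nested inner
    LOO selection per fold; a float fixes the penalty (deterministic mode).
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if not np.isfinite(ya).all():
        raise ValueError("non-finite outcome values")
    n = len(ya)
    if n < 3:
        raise ValueError("leave-one-out regression needs at least 3 subjects")
    predictions = np.empty(n)
    coef_matrix = np.empty((n, Xa.shape[1]))
    for i in range(n):
        mask = np.arange(n) != i
        Xt, yt = Xa[mask], ya[mask]
        alpha = penalty if penalty is not None else _choose_alpha_loo(Xt, yt)
        coef, intercept = _lasso_fit(Xt, yt, alpha)
        coef_matrix[i] = coef
        predictions[i] = Xa[i] @ coef + intercept
    return predictions, coef_matrix, coef_matrix.mean(axis=0)


def evaluate_prediction(predictions, observed, n_perm: int = 1000, seed: int = 0
                        ) -> dict:
    """Median-split ROC/AUC and Spearman agreement, with permutation p.

    Positive class: observed delta strictly below the median (more than
    median loss); subjects exactly at the median fall in the "less change"
    class.  The permutation p scrambles the *predicted* values and
    recomputes the AUC, add-one rule.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if len(obs) < 4:
        raise ValueError("evaluation needs at least 4 subjects")
    if np.all(obs == obs[0]):
        raise ValueError("all observed deltas identical; median split undefined")
    truth = (obs < np.median(obs)).astype(float)
    if truth.min() == truth.max():
        raise ValueError("median split produced a single class")
    points, auc = roc_auc(-pred, truth)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, auc_perm = roc_auc(-rng.permutation(pred), truth)
        if auc_perm >= auc:
            hits += 1
    p_perm = (1 + hits) / (n_perm + 1)
    rho, p_rho = stats.spearmanr(pred, obs)
    return {
        "auc_median_split": auc,
        "roc_points": points,
        "p_perm_auc": p_perm,
        "spearman_rho": float(rho),
        "p_spearman": float(p_rho),
        "n_permutations": n_perm,
    }


@dataclass
class OutcomePredictionResults:
    """Out-of-fold predictions, averaged coefficients and their evaluation."""

    horizon: str
    subjects: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    coef_matrix: np.ndarray
    mean_coefficients: np.ndarray
    component_names: list[str]
    auc_median_split: float
    roc_points: np.ndarray
    p_perm_auc: float
    spearman_rho: float
    p_spearman: float
    n_permutations: int
    penalty: float | None

    @property
    def support(self) -> list[str]:
        """Components the averaged-coefficient report counts as nonzero.

        The raw fold average is nonzero as soon as a single fold selects a
        variable, so the support of the averaged weights is operationalized
        the way stability selection reads it: a component belongs to the
        support iff the LASSO kept it in a strict majority of the
        leave-one-out fits.
        """
        kept = (self.coef_matrix != 0.0).mean(axis=0)
        return [n for n, frac in zip(self.component_names, kept) if frac > 0.5]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"observed_delta_bmi": self.observed,
             "predicted_delta_bmi": self.predicted},
            index=pd.Index(self.subjects, name="subject_id"),
        )

    def summary(self) -> str:
        lines = [
            f"BMI-change prediction, horizon {self.horizon} "
            f"(delta = follow-up − baseline; negative = loss)",
            f"  subjects: {len(self.subjects)}",
            f"  median-split AUC: {self.auc_median_split:.3f} "
            f"(permutation p = {self.p_perm_auc:.4g}, "
            f"{self.n_permutations} scrambles)",
            f"  Spearman rho(predicted, observed): {self.spearman_rho:.3f} "
            f"(p = {self.p_spearman:.4g})",
            "  mean LOO coefficients:",
        ]
        for name, c in zip(self.component_names, self.mean_coefficients):
            lines.append(f"    {name:>6}: {c:+.4f}")
        return "\n".join(lines)


class OutcomeModel:
    """Model object: LOO-validated LASSO from point-A PC scores to BMI change."""

    def __init__(self, X: pd.DataFrame, y: pd.Series, horizon: str = "6m"):
        self.X = X
        self.y = y
        self.horizon = horizon

    @classmethod
    def from_scores(cls, scores: ScoreMatrix, meta: pd.DataFrame,
                    horizon: str = "6m",
                    duplicate_policy: str = "error") -> "OutcomeModel":
        X, y = assemble_outcome_table(scores, meta, horizon, duplicate_policy)
        return cls(X, y, horizon)

    def fit(self, penalty: float | None = None, n_perm: int = 1000,
            seed: int = 0) -> OutcomePredictionResults:
        predictions, coef_matrix, mean_coef = loo_lasso(self.X, self.y, penalty)
        metrics = evaluate_prediction(predictions, self.y.to_numpy(),
                                      n_perm=n_perm, seed=seed)
        return OutcomePredictionResults(
            horizon=self.horizon,
            subjects=list(self.X.index),
            observed=self.y.to_numpy(),
            predicted=predictions,
            coef_matrix=coef_matrix,
            mean_coefficients=mean_coef,
            component_names=list(self.X.columns),
            penalty=penalty,
            auc_median_split=metrics["auc_median_split"],
            roc_points=metrics["roc_points"],
            p_perm_auc=metrics["p_perm_auc"],
            spearman_rho=metrics["spearman_rho"],
            p_spearman=metrics["p_spearman"],
            n_permutations=metrics["n_permutations"],
        )
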