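"""Principal-component decomposition of the whitened abundance table.

The decomposition is fitted once, on every sample available (all obese time
points plus the lean controls), giving a single score space in which group
classification, outcome prediction and metadata screening all operate.
Downstream analyses then select rows of the score matrix (e.g. only
enrollment samples for outcome prediction) rather than refitting.

Determinism: eigenvector signs are arbitrary, so each loading column is
oriented to make its largest-magnitude entry positive — the same input
yields bit-identical loadings across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable

SCREEN_COVARIATES = ("bmi", "age", "gender", "a1c")


@dataclass
class PCModel:
    """A fitted decomposition: loadings, variance fractions and fit context.

    ``loadings`` has one row per feature and one orthonormal column per
    component; ``explained_variance_fraction`` are eigenvalue shares of the
    total variance; ``mean_`` is the per-feature mean of the training data,
    subtracted before projecting (z-scored input makes it ~0, but unseen
    samples are centered with the *training* mean).
    """

    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    feature_ids: list[str]
    mean_: np.ndarray
    fitted_on: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings,
            index=self.feature_ids,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )


@dataclass
class ScoreMatrix:
    """Per-sample projections onto the fitted components."""

    sample_ids: list[str]
    scores: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )

    def subset(self, sample_ids) -> "ScoreMatrix":
        frame = self.to_frame().loc[list(sample_ids)]
        return ScoreMatrix(sample_ids=list(frame.index), scores=frame.to_numpy())


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-|value| entry is positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca(table: FeatureTable, n_components: int = 8) -> PCModel:
    """Fit the top principal components of a z-scored feature table.

    Loadings are the leading eigenvectors of the feature covariance of the
    (explicitly re-centered) data, computed by full SVD.
    """
    if table.stage != "zscored":
        raise ValueError(f"PCA expects a zscored table, got stage {table.stage!r}")
    n, p = table.data.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)"
            f"={min(n - 1, p)}"
        )
    X = table.values
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    loadings = _fix_signs(pca.components_.T)
    return PCModel(
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        feature_ids=table.feature_ids,
        mean_=pca.mean_.copy(),
        fitted_on=table.sample_ids,
    )


def project(table: FeatureTable, model: PCModel) -> ScoreMatrix:
    """Project (possibly unseen) samples onto the fitted components.

    The table may contain extra features and any feature order; it is
    reindexed to the model's feature list, and a feature the model knows but
    the table lacks is an error.
    """
    missing = [f for f in model.feature_ids if f not in set(table.feature_ids)]
    if missing:
        raise ValueError(f"table lacks feature {missing[0]!r} required by the model")
    X = table.data[model.feature_ids].to_numpy()
    scores = (X - model.mean_) @ model.loadings
    return ScoreMatrix(sample_ids=table.sample_ids, scores=scores)


def top_loadings(model: PCModel, component: int, fraction: float = 0.15) -> pd.DataFrame:
    """Features ranked by |loading| on one component, truncated to a fraction.

    ``component`` is zero-based.  Returns ``ceil(fraction * n_features)``
    rows with the signed weights, largest magnitude first.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not 0 <= component < model.n_components:
        raise ValueError(f"component index {component} out of range")
    weights = model.loadings[:, component]
    order = np.argsort(-np.abs(weights), kind="stable")
    k = int(np.ceil(fraction * len(weights)))
    idx = order[:k]
    return pd.DataFrame(
        {"feature_id": [model.feature_ids[i] for i in idx],
         "weight": weights[idx]}
    ).set_index("feature_id")


def screen_pcs(scores: ScoreMatrix, meta: pd.DataFrame,
               covariates=SCREEN_COVARIATES) -> pd.DataFrame:
    """Spearman screen of every PC against clinical covariates, BH-corrected.

    Missing covariate values are dropped pairwise.  The BH family is the set
    of per-PC tests within one covariate.  A covariate that is constant (or
    observed fewer than 3 times) yields NaN statistics rather than an error.

    Returns a tidy frame with columns pc, covariate, spearman_rho, p_raw,
    p_bh.
    """
    frame = scores.to_frame()
    meta = meta.loc[frame.index]
    rows = []
    for cov in covariates:
        values = pd.to_numeric(meta[cov], errors="coerce")
        mask = values.notna().to_numpy()
        rhos, ps = [], []
        for j in range(scores.n_components):
            x = frame.iloc[:, j].to_numpy()[mask]
            y = values.to_numpy()[mask]
            if len(y) < 3 or np.all(y == y[0]):
                rhos.append(np.nan)
                ps.append(np.nan)
                continue
            rho, p = stats.spearmanr(x, y)
            rhos.append(rho)
            ps.append(p)
        ps_arr = np.asarray(ps, dtype=float)
        p_bh = np.full_like(ps_arr, np.nan)
        ok = ~np.isnan(ps_arr)
        if ok.any():
            p_bh[ok] = multipletests(ps_arr[ok], method="fdr_bh")[1]
        for j in range(scores.n_components):
            rows.append({"pc": f"PC{j + 1}", "covariate": cov,
                         "spearman_rho": rhos[j], "p_raw": ps[j], "p_bh": p_bh[j]})
    return pd.DataFrame(rows)
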