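"""PCA decomposition, projection, loadings ranking and the metadata screen."""

import numpy as np
import pandas as pd
import pytest

import bariomics as bm
from bariomics.decompose import ScoreMatrix

from conftest import make_table


def zscored(values):
    table = make_table(values, stage="logged")
    return bm.zscore(table)


@pytest.fixture(scope="module")
def random_ztable():
    rng = np.random.default_rng(11)
    return zscored(rng.normal(size=(50, 20)))


class TestFitPCA:
    def test_rank_one_data_explains_everything_on_first_pc(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=30)
        direction = np.array([1.0, -2.0, 0.5, 3.0])
        table = zscored(np.outer(t, direction))
        model = bm.fit_pca(table, 2)
        np.testing.assert_allclose(model.explained_variance_fraction, [1.0, 0.0],
                                   atol=1e-9)

    def test_duplicating_every_sample_leaves_loadings_unchanged(self, random_ztable):
        model = bm.fit_pca(random_ztable, 4)
        doubled = pd.concat([random_ztable.data,
                             random_ztable.data.set_axis(
                                 [s + "_b" for s in random_ztable.sample_ids])])
        table2 = bm.FeatureTable(data=doubled, taxonomy=random_ztable.taxonomy,
                                 stage="zscored")
        model2 = bm.fit_pca(table2, 4)
        np.testing.assert_allclose(model.loadings, model2.loadings, atol=1e-9)

    def test_matches_dense_eigendecomposition_oracle(self, random_ztable):
        """Loadings equal the top eigenvectors of the covariance matrix."""
        model = bm.fit_pca(random_ztable, 6)
        X = random_ztable.values
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / len(Xc)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(6):
            u, v = model.loadings[:, j], evecs[:, j]
            sign = np.sign(u @ v)
            np.testing.assert_allclose(u, sign * v, atol=1e-8)
        np.testing.assert_allclose(model.explained_variance_fraction,
                                   evals[:6] / evals.sum(), atol=1e-8)

    def test_deterministic_bit_identical_across_runs(self, random_ztable):
        a = bm.fit_pca(random_ztable, 5)
        b = bm.fit_pca(random_ztable, 5)
        assert (a.loadings == b.loadings).all()

    def test_sign_convention_largest_entry_positive(self, random_ztable):
        model = bm.fit_pca(random_ztable, 6)
        for j in range(6):
            k = np.argmax(np.abs(model.loadings[:, j]))
            assert model.loadings[k, j] > 0

    def test_orthonormal_columns(self, random_ztable):
        model = bm.fit_pca(random_ztable, 6)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_too_many_components_rejected(self, random_ztable):
        with pytest.raises(ValueError, match="n_components"):
            bm.fit_pca(random_ztable, 21)

    def test_requires_zscored_stage(self):
        table = make_table(np.random.default_rng(1).normal(size=(10, 3)) ** 2)
        with pytest.raises(ValueError, match="zscored"):
            bm.fit_pca(table, 2)


class TestProject:
    def test_score_variance_proportional_to_explained_variance(self, random_ztable):
        model = bm.fit_pca(random_ztable, 6)
        scores = bm.project(random_ztable, model)
        var = scores.scores.var(axis=0)
        total = random_ztable.values.var(axis=0).sum()
        np.testing.assert_allclose(var / total,
                                   model.explained_variance_fraction, atol=1e-8)

    def test_mean_sample_projects_to_zero(self, random_ztable):
        model = bm.fit_pca(random_ztable, 4)
        mean_row = random_ztable.data.mean(axis=0).to_frame().T
        mean_row.index = ["mean_sample"]
        table = bm.FeatureTable(data=mean_row, taxonomy=random_ztable.taxonomy,
                                stage="logged")
        scores = bm.project(table, model)
        np.testing.assert_allclose(scores.scores, 0.0, atol=1e-9)

    def test_permuted_feature_order_gives_identical_scores(self, random_ztable):
        model = bm.fit_pca(random_ztable, 4)
        rng = np.random.default_rng(2)
        perm = rng.permutation(random_ztable.feature_ids)
        shuffled = bm.FeatureTable(data=random_ztable.data[perm],
                                   taxonomy=random_ztable.taxonomy,
                                   stage="zscored")
        a = bm.project(random_ztable, model)
        b = bm.project(shuffled, model)
        np.testing.assert_allclose(a.scores, b.scores)

    def test_missing_feature_named_in_error(self, random_ztable):
        model = bm.fit_pca(random_ztable, 3)
        dropped = random_ztable.feature_ids[2]
        sub = bm.FeatureTable(
            data=random_ztable.data.drop(columns=[dropped]),
            taxonomy=random_ztable.taxonomy, stage="zscored")
        with pytest.raises(ValueError, match=dropped):
            bm.project(sub, model)

    def test_reconstruction_error_decreases_with_components(self, random_ztable):
        X = random_ztable.values
        Xc = X - X.mean(axis=0)
        errors = []
        for k in (2, 5, 10, 20):
            model = bm.fit_pca(random_ztable, k)
            scores = bm.project(random_ztable, model)
            recon = scores.scores @ model.loadings.T
            errors.append(np.linalg.norm(Xc - recon))
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] < 1e-8  # zero error at full rank


class TestTopLoadings:
    def _model(self, weights):
        weights = np.asarray(weights, dtype=float)[:, None]
        return bm.PCModel(loadings=weights / np.linalg.norm(weights),
                          explained_variance_fraction=np.array([1.0]),
                          feature_ids=[f"F{i}" for i in range(len(weights))],
                          mean_=np.zeros(len(weights)))

    def test_fraction_one_returns_all_sorted(self):
        out = bm.top_loadings(self._model([0.1, -0.9, 0.5]), 0, fraction=1.0)
        assert list(out.index) == ["F1", "F2", "F0"]

    def test_ceil_arithmetic_fifteen_percent_of_forty(self):
        model = self._model(np.linspace(1, 0.1, 40))
        out = bm.top_loadings(model, 0, fraction=0.15)
        assert len(out) == 6

    def test_hand_built_ordering_with_signs(self):
        out = bm.top_loadings(self._model([0.9, -0.8, 0.1]), 0, fraction=1.0)
        assert list(out.index) == ["F0", "F1", "F2"]
        assert out.loc["F1", "weight"] < 0

    def test_bad_component_rejected(self):
        with pytest.raises(ValueError, match="component"):
            bm.top_loadings(self._model([1.0]), 3, fraction=0.5)


class TestScreen:
    def _meta(self, n, **cols):
        base = {"subject_id": [f"P{i}" for i in range(n)],
                "timepoint": ["A"] * n, "bmi": [40.0] * n}
        base.update(cols)
        return bm.validate_metadata(pd.DataFrame(
            base, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id")))

    def test_perfect_monotone_gives_rho_one(self):
        n = 12
        scores = ScoreMatrix(sample_ids=[f"S{i}" for i in range(n)],
                             scores=np.arange(n, dtype=float)[:, None])
        meta = self._meta(n, bmi=np.linspace(30, 50, n))
        screen = bm.screen_pcs(scores, meta, covariates=("bmi",))
        assert screen.loc[0, "spearman_rho"] == pytest.approx(1.0)

    def test_bh_never_below_raw_and_within_covariate(self):
        rng = np.random.default_rng(5)
        n = 40
        scores = ScoreMatrix(sample_ids=[f"S{i}" for i in range(n)],
                             scores=rng.normal(size=(n, 8)))
        meta = self._meta(n, bmi=rng.normal(40, 5, n),
                          age=rng.normal(50, 10, n))
        screen = bm.screen_pcs(scores, meta, covariates=("bmi", "age"))
        assert (screen["p_bh"] >= screen["p_raw"] - 1e-12).all()
        assert len(screen) == 16

    def test_constant_covariate_reported_missing(self):
        n = 10
        scores = ScoreMatrix(sample_ids=[f"S{i}" for i in range(n)],
                             scores=np.random.default_rng(0).normal(size=(n, 2)))
        meta = self._meta(n, gender=[1] * n)
        screen = bm.screen_pcs(scores, meta, covariates=("gender",))
        assert screen["spearman_rho"].isna().all()

    def test_rho_antisymmetric_under_covariate_negation(self):
        rng = np.random.default_rng(9)
        n = 30
        scores = ScoreMatrix(sample_ids=[f"S{i}" for i in range(n)],
                             scores=rng.normal(size=(n, 3)))
        age = rng.normal(50, 8, n)
        a = bm.screen_pcs(scores, self._meta(n, age=age), covariates=("age",))
        b = bm.screen_pcs(scores, self._meta(n, age=-age + 120),
                          covariates=("age",))
        np.testing.assert_allclose(a["spearman_rho"], -b["spearman_rho"],
                                   atol=1e-12)
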