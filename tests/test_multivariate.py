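"""Intensity-matrix assembly, preprocessing, NIPALS PCA, Q2 and projection."""

import numpy as np
import pandas as pd
import pytest

from somatlas import (
    IntensityMatrix,
    apply_preprocessing,
    assemble_matrix,
    assign_peaklist,
    fit_pca,
    fit_work_predict,
    preprocess,
    project,
    q2_cv,
    top_loadings,
)
from somatlas.synth import (
    PopulationConfig,
    generate_population,
    generate_two_class_study,
    simulate_peaklist,
)


def _tables(n_samples=3, n_formulas=40, seed=0):
    pop = generate_population(PopulationConfig(n_formulas=n_formulas, seed=seed))
    tables = []
    for i in range(n_samples):
        sim = simulate_peaklist(pop, ppm_sigma=0.02, seed=seed + 10 + i,
                                sample_id=f"s{i}")
        tables.append(assign_peaklist(sim.peaklist))
    return pop, tables


class TestAssembleMatrix:
    def test_shared_and_private_formulas(self):
        pop, tables = _tables(2, 30, seed=1)
        m = assemble_matrix(tables)
        assert m.data.shape[0] == 2
        union = {a.formula.hill for t in tables for a in t.primaries}
        assert set(m.formula_index) == union

    def test_same_table_twice_gives_identical_rows(self):
        pop, tables = _tables(1, 25, seed=2)
        t = tables[0]
        import copy

        t2 = copy.deepcopy(t)
        t2.sample_id = "other"
        m = assemble_matrix([t, t2])
        assert np.allclose(m.data.iloc[0].values, m.data.iloc[1].values)

    def test_duplicate_sample_id_rejected(self):
        _, tables = _tables(2, 20, seed=3)
        tables[1].sample_id = tables[0].sample_id
        with pytest.raises(ValueError, match="duplicate sample_id"):
            assemble_matrix(tables)

    def test_no_all_zero_columns(self):
        _, tables = _tables(3, 30, seed=4)
        m = assemble_matrix(tables)
        assert (m.data.values != 0).any(axis=0).all()


class TestPreprocess:
    def _matrix(self, seed=5, n=8, p=20):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.lognormal(10, 1.5, size=(n, p)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"F{j}" for j in range(p)],
        )
        return IntensityMatrix(data)

    def test_columns_centered_and_unit_variance(self):
        xt, rec = preprocess(self._matrix())
        assert np.allclose(xt.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(xt.std(axis=0, ddof=1), 1.0, atol=1e-10)
        assert rec.log_applied

    def test_constant_column_dropped_and_recorded(self):
        m = self._matrix()
        m.data["const"] = 7.0
        xt, rec = preprocess(m)
        assert "const" not in xt.columns
        assert rec.dropped_columns == ["const"]

    def test_record_reproduces_transform_on_new_rows(self):
        m = self._matrix(seed=6, n=10)
        train = IntensityMatrix(m.data.iloc[:7])
        xt, rec = preprocess(train)
        held = m.data.iloc[7:]
        got = apply_preprocessing(rec, held)
        want = (np.log10(1 + held[rec.kept_columns]) - rec.column_means) / rec.column_scales
        assert np.allclose(got.values, want.values)

    def test_missing_formulas_treated_as_zero(self):
        m = self._matrix(seed=7)
        xt, rec = preprocess(m)
        new = m.data.iloc[:1].drop(columns=m.data.columns[:3])
        got = apply_preprocessing(rec, new)
        zeros = (np.log10(1.0) - rec.column_means[m.data.columns[:3]]) / rec.column_scales[m.data.columns[:3]]
        assert np.allclose(got[m.data.columns[:3]].values.ravel(), zeros.values)


def _preprocessed(seed=8, n=5, p=8):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.lognormal(8, 1.0, size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"F{j}" for j in range(p)],
    )
    m = IntensityMatrix(data)
    return m, *preprocess(m)


class TestFitPCA:
    def test_full_rank_explains_everything(self):
        m, xt, rec = _preprocessed()
        model = fit_pca(xt, n_components=4)  # n - 1 components
        assert model.r2x_cum[-1] == pytest.approx(1.0, abs=1e-8)

    def test_reconstruction_identity(self):
        m, xt, rec = _preprocessed(seed=9)
        model = fit_pca(xt, 4)
        recon = model.scores.values @ model.loadings
        assert np.allclose(recon, xt.values, atol=1e-6)

    def test_loadings_orthonormal(self):
        m, xt, rec = _preprocessed(seed=10, n=12, p=30)
        model = fit_pca(xt, 5)
        gram = model.loadings @ model.loadings.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_r2x_matches_svd_oracle(self):
        """NIPALS explained-variance fractions agree with an independent
        SVD-based PCA on the same matrix."""
        from sklearn.decomposition import PCA

        m, xt, rec = _preprocessed(seed=11, n=15, p=40)
        model = fit_pca(xt, 4)
        # sklearn centers internally; columns are already centered
        sk = PCA(n_components=4, svd_solver="full").fit(xt.values)
        total = np.sum(xt.values**2)
        sk_r2x = sk.explained_variance_ * (xt.shape[0] - 1) / total
        assert np.allclose(model.r2x, sk_r2x, atol=1e-8)
        # scores agree up to the fixed sign convention
        sk_scores = sk.transform(xt.values)
        for a in range(4):
            s = np.sign(np.dot(sk_scores[:, a], model.scores.values[:, a]))
            assert np.allclose(s * sk_scores[:, a], model.scores.values[:, a], atol=1e-6)

    def test_component_count_validated(self):
        m, xt, rec = _preprocessed()
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(xt, xt.shape[0])  # > samples - 1

    def test_two_class_structure_separates_on_pc1(self):
        study = generate_two_class_study(effect=4.0, noise_sigma=0.2, seed=12)
        m = study.to_intensity_matrix()
        xt, rec = preprocess(m)
        model = fit_pca(xt, 2)
        pc1 = model.scores["PC1"]
        a = pc1[[s for s, c in study.class_assignments.items() if c == "A"]]
        b = pc1[[s for s, c in study.class_assignments.items() if c == "B"]]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or (
            a.max() < b.min() or b.max() < a.min()
        )


class TestProject:
    def test_training_rows_project_to_own_scores(self):
        m, xt, rec = _preprocessed(seed=13)
        model = fit_pca(xt, 3, preprocessing=rec)
        got = project(model, m.data)
        assert np.allclose(got.values, model.scores.values, atol=1e-8)

    def test_profile_at_column_means_projects_to_origin(self):
        m, xt, rec = _preprocessed(seed=14)
        model = fit_pca(xt, 3, preprocessing=rec)
        center_raw = (10.0 ** rec.column_means - 1.0).to_frame().T
        center_raw.index = ["center"]
        got = project(model, center_raw)
        assert np.allclose(got.values, 0.0, atol=1e-8)

    def test_heldout_samples_land_in_correct_class_region(self):
        study = generate_two_class_study(effect=4.0, noise_sigma=0.25, seed=15)
        m = study.to_intensity_matrix()
        model, cv, scores, predicted = fit_work_predict(
            m, study.work_ids, study.prediction_ids
        )
        assert predicted is not None
        correct = [
            predicted[s] == study.class_assignments[s] for s in study.prediction_ids
        ]
        assert all(correct)


class TestQ2:
    def test_noise_only_matrix_has_no_predictive_power(self):
        rng = np.random.default_rng(16)
        xt = pd.DataFrame(rng.standard_normal((20, 60)))
        xt = (xt - xt.mean()) / xt.std(ddof=1)
        cv = q2_cv(xt, 2, n_folds=7)
        assert cv.q2_cum[-1] <= 0.05

    def test_planted_rank_one_signal_is_predicted(self):
        rng = np.random.default_rng(17)
        t = rng.standard_normal(24)[:, None]
        p = rng.standard_normal(50)[None, :]
        xt = pd.DataFrame(t @ p + 0.1 * rng.standard_normal((24, 50)))
        xt = (xt - xt.mean()) / xt.std(ddof=1)
        cv = q2_cv(xt, 2, n_folds=7)
        assert cv.q2[0] > 0.5

    def test_q2_never_exceeds_r2x(self):
        for seed in (18, 19, 20):
            m, xt, rec = _preprocessed(seed=seed, n=14, p=25)
            model = fit_pca(xt, 3)
            cv = q2_cv(xt, 3, n_folds=7)
            assert np.all(cv.q2_cum <= model.r2x_cum + 1e-9)

    def test_fold_count_validated(self):
        m, xt, rec = _preprocessed()
        with pytest.raises(ValueError, match="n_folds"):
            q2_cv(xt, 2, n_folds=1)
        with pytest.raises(ValueError, match="n_folds"):
            q2_cv(xt, 2, n_folds=50)


class TestTopLoadings:
    def test_k_all_returns_full_ordering(self):
        m, xt, rec = _preprocessed(seed=21, n=10, p=12)
        model = fit_pca(xt, 2)
        full = top_loadings(model, 1, 12)
        loads = [v for _, v in full]
        assert loads == sorted(loads, reverse=True)
        assert len(full) == 12

    def test_sign_lists_are_mirror_images(self):
        m, xt, rec = _preprocessed(seed=22, n=10, p=12)
        model = fit_pca(xt, 2)
        pos = top_loadings(model, 1, 12, sign="positive")
        neg = top_loadings(model, 1, 12, sign="negative")
        assert [f for f, _ in pos] == [f for f, _ in reversed(neg)]

    def test_oversized_k_warns_and_truncates(self):
        m, xt, rec = _preprocessed(seed=23)
        model = fit_pca(xt, 2)
        with pytest.warns(UserWarning, match="truncat"):
            got = top_loadings(model, 1, 999)
        assert len(got) == xt.shape[1]

    def test_discriminating_formulas_dominate_pc1(self):
        study = generate_two_class_study(effect=4.0, noise_sigma=0.2, seed=24)
        m = study.to_intensity_matrix()
        xt, rec = preprocess(m)
        model = fit_pca(xt, 2)
        k = len(study.discriminating_formulas)
        pc1 = np.abs(model.loadings[0])
        order = np.argsort(pc1)[::-1][:k]
        top = {model.formula_index[i] for i in order}
        overlap = len(top & study.discriminating_formulas) / k
        assert overlap >= 0.9


def test_identical_seeds_give_identical_models():
    runs = []
    for _ in range(2):
        study = generate_two_class_study(effect=4.0, seed=25)
        m = study.to_intensity_matrix()
        xt, rec = preprocess(m)
        model = fit_pca(xt, 2)
        runs.append(model.scores.values.copy())
    assert np.array_equal(runs[0], runs[1])
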