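"""Native NIPALS PLS-DA / OPLS-DA, VIP, Q² and permutation validation."""

import numpy as np
import pandas as pd
import pytest

from metabofuse import mvda
from metabofuse.mvda import (
    ClassDesign,
    fit_oplsda,
    fit_plsda,
    inner_relation,
    pareto_scale,
    permutation_test,
    q2_crossval,
    vip_scores,
    biplot_data,
)


def random_design(n, classes=("A", "B"), seed=0):
    rng = np.random.default_rng(seed)
    labels = [classes[i % len(classes)] for i in range(n)]
    return ClassDesign([f"s{i}" for i in range(n)], labels)


def centered(X):
    return X - X.mean(axis=0)


class TestParetoScale:
    def test_hand_computed_column(self):
        X = pd.DataFrame({"v": [1.0, 3.0]})
        scaled, means, divisors = pareto_scale(X)
        assert means["v"] == 2.0
        assert divisors["v"] == pytest.approx(2 ** 0.25)
        assert np.allclose(scaled["v"], [-0.8409, 0.8409], atol=5e-5)

    def test_unit_sd_centered_column_unchanged(self):
        x = np.array([-1.0, 0.0, 1.0]) / np.sqrt(1.0)
        x = x / x.std(ddof=1)  # sd exactly 1
        X = pd.DataFrame({"v": x})
        scaled, _, _ = pareto_scale(X)
        assert np.allclose(scaled["v"], x)

    def test_constant_column_becomes_zero(self):
        X = pd.DataFrame({"v": [5.0, 5.0, 5.0], "w": [1.0, 2.0, 3.0]})
        scaled, _, _ = pareto_scale(X)
        assert np.allclose(scaled["v"], 0.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pareto_scale(pd.DataFrame({"v": [1.0]}))


class TestNipalsPlsda:
    def _fixture(self, n=10, p=8, n_classes=2, seed=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, p))
        classes = [f"C{i}" for i in range(n_classes)]
        design = ClassDesign(
            [f"s{i}" for i in range(n)], [classes[i % n_classes] for i in range(n)]
        )
        return X, design

    @pytest.mark.parametrize("n_classes", [2, 4])
    def test_first_weight_is_dominant_eigenvector(self, n_classes):
        """Oracle: dense eigendecomposition of X'YY'X on a 10x8 fixture."""
        X, design = self._fixture(n_classes=n_classes)
        model = fit_plsda(X, design, n_components=1)
        Xc = centered(X)
        Yc = centered(design.Y.to_numpy())
        M = Xc.T @ Yc @ Yc.T @ Xc
        eigvals, eigvecs = np.linalg.eigh(M)
        dominant = eigvecs[:, -1]
        w = model.W[:, 0]
        if np.dot(dominant, w) < 0:
            dominant = -dominant
        assert np.allclose(w, dominant, atol=1e-8)

    def test_agrees_with_sklearn_first_component(self):
        """Cross-check against an independent PLS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        X, design = self._fixture(n=14, p=9, seed=11)
        model = fit_plsda(X, design, n_components=2)
        sk = PLSRegression(n_components=2, scale=False).fit(X, design.Y.to_numpy())
        for a in range(2):
            w_sk = sk.x_weights_[:, a]
            w = model.W[:, a]
            if np.dot(w_sk, w) < 0:
                w_sk = -w_sk
            assert np.allclose(w, w_sk, atol=1e-6)

    def test_rank_one_signal_fully_explained(self):
        rng = np.random.default_rng(4)
        t = np.repeat([1.0, -1.0], 6) + rng.normal(0, 0.01, 12)
        p = rng.normal(0, 1, 20)
        X = np.outer(t, p)
        design = ClassDesign(
            [f"s{i}" for i in range(12)], ["A"] * 6 + ["B"] * 6
        )
        model = fit_plsda(X, design, n_components=1)
        assert model.r2x[0] >= 0.999

    def test_r2y_non_decreasing_and_scores_orthogonal(self):
        X, design = self._fixture(n=16, p=10, n_classes=4, seed=9)
        model = fit_plsda(X, design, n_components=3)
        assert all(b >= a - 1e-12 for a, b in zip(model.r2y, model.r2y[1:]))
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (6, 4))
        design = ClassDesign([f"s{i}" for i in range(6)], ["A"] * 6)
        with pytest.raises(ValueError):
            fit_plsda(X, design, 1)

    def test_deterministic_given_input(self):
        X, design = self._fixture(n_classes=4)
        m1 = fit_plsda(X, design, 2)
        m2 = fit_plsda(X, design, 2)
        assert np.array_equal(m1.T, m2.T) and np.array_equal(m1.W, m2.W)


class TestOplsda:
    def _two_class(self, n=12, p=20, ortho_scale=1.0, seed=5, noise=0.01):
        rng = np.random.default_rng(seed)
        y = np.array([1.0, 0.0] * (n // 2))
        w_true = rng.normal(0, 1, p)
        w_true /= np.linalg.norm(w_true)
        w_orth = rng.normal(0, 1, p)
        w_orth -= (w_orth @ w_true) * w_true
        w_orth /= np.linalg.norm(w_orth)
        t_orth = rng.normal(0, 1, n)
        t_orth -= (t_orth @ (y - y.mean())) / ((y - y.mean()) @ (y - y.mean())) * (y - y.mean())
        X = np.outer(y - y.mean(), w_true) + ortho_scale * np.outer(t_orth, w_orth)
        if noise:
            X = X + rng.normal(0, noise, (n, p))
        return X, y

    def test_no_orthogonal_structure_degenerates_to_pls(self):
        X, y = self._two_class(ortho_scale=0.0, noise=0.0)
        opls = fit_oplsda(X, y, n_ortho=1)
        design = ClassDesign([f"s{i}" for i in range(len(y))], [str(v) for v in y])
        pls = fit_plsda(X, design, n_components=1)
        assert opls.r2x_ortho == pytest.approx(0.0, abs=1e-8)
        t_o, t_p = opls.T[:, 0], pls.T[:, 0]
        if np.dot(t_o, t_p) < 0:
            t_p = -t_p
        assert np.allclose(t_o, t_p, atol=1e-8)

    def test_energy_decomposition_bounded(self):
        X, y = self._two_class(ortho_scale=2.0)
        m = fit_oplsda(X, y, n_ortho=2)
        assert 0 <= m.r2x_pred <= 1 and 0 <= m.r2x_ortho <= 1
        assert m.r2x_pred + m.r2x_ortho <= 1 + 1e-9

    def test_predictive_scores_match_projection_route(self):
        """Oracle: remove the t_o subspace by explicit projection instead of
        rank-one deflation; predictive scores must agree up to sign/scale."""
        X, y = self._two_class(ortho_scale=1.5, seed=8)
        m = fit_oplsda(X, y, n_ortho=1)
        Xc = centered(X)
        T_o = m.T_o
        proj = Xc - T_o @ np.linalg.lstsq(T_o, Xc, rcond=None)[0]
        yc = y - y.mean()
        w = proj.T @ yc / (yc @ yc)
        w /= np.linalg.norm(w)
        t_alt = proj @ w
        t = m.T[:, 0]
        t_alt *= np.sign(t_alt @ t) * (np.linalg.norm(t) / np.linalg.norm(t_alt))
        assert np.allclose(t, t_alt, atol=1e-6 * np.linalg.norm(t))

    def test_score_and_weight_orthogonality(self):
        X, y = self._two_class(ortho_scale=2.0, seed=13)
        m = fit_oplsda(X, y, n_ortho=2)
        assert abs(m.T[:, 0] @ m.T_o[:, 0]) < 1e-8 * np.linalg.norm(m.T) * np.linalg.norm(m.T_o)
        assert abs(m.W[:, 0] @ m.W_o[:, 0]) < 1e-8

    def test_multiclass_without_contrast_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (9, 5))
        with pytest.raises(ValueError, match="contrast"):
            fit_oplsda(X, np.array([0, 1, 2] * 3), 1)


class TestDiagnostics:
    def test_inner_relation_exact_line(self):
        rng = np.random.default_rng(1)
        n = 10
        t = rng.normal(0, 1, n)
        model = mvda.LatentModel(
            kind="PLS-DA", T=t.reshape(-1, 1), P=np.ones((3, 1)), W=np.ones((3, 1)),
            C=np.ones((1, 1)), U=(2 * t).reshape(-1, 1), x_mean=np.zeros(3),
            y_mean=np.zeros(1), r2x=[1.0], r2y=[1.0], ssy_explained=[1.0],
            variable_ids=["a", "b", "c"], sample_ids=[str(i) for i in range(n)],
        )
        res = inner_relation(model)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_inner_relation_orthogonal_scores(self):
        t = np.array([1.0, -1.0, 1.0, -1.0])
        u = np.array([1.0, 1.0, -1.0, -1.0])
        model = mvda.LatentModel(
            kind="PLS-DA", T=t.reshape(-1, 1), P=np.ones((2, 1)), W=np.ones((2, 1)),
            C=np.ones((1, 1)), U=u.reshape(-1, 1), x_mean=np.zeros(2),
            y_mean=np.zeros(1), r2x=[1.0], r2y=[1.0], ssy_explained=[1.0],
            variable_ids=["a", "b"], sample_ids=["1", "2", "3", "4"],
        )
        assert inner_relation(model)["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_inner_relation_constant_scores_rejected(self):
        model = mvda.LatentModel(
            kind="PLS-DA", T=np.ones((4, 1)), P=np.ones((2, 1)), W=np.ones((2, 1)),
            C=np.ones((1, 1)), U=np.ones((4, 1)), x_mean=np.zeros(2),
            y_mean=np.zeros(1), r2x=[1.0], r2y=[1.0], ssy_explained=[1.0],
            variable_ids=["a", "b"], sample_ids=list("abcd"),
        )
        with pytest.raises(ValueError):
            inner_relation(model)

    def test_vip_mean_square_is_one(self, fitted_model):
        vip = vip_scores(fitted_model["model"])
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-9)

    def test_vip_dominant_variable_wins(self):
        rng = np.random.default_rng(2)
        n = 20
        y = np.array([1.0, 0.0] * (n // 2))
        X = rng.normal(0, 0.05, (n, 6))
        X[:, 3] += 3 * (y - y.mean())
        design = ClassDesign([f"s{i}" for i in range(n)], [str(v) for v in y])
        model = fit_plsda(X, design, 1)
        vip = vip_scores(model)
        assert vip.idxmax() == "3"

    def test_vip_ranking_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (12, 8))
        design = random_design(12, seed=6)
        r1 = vip_scores(fit_plsda(X, design, 2)).rank()
        r2 = vip_scores(fit_plsda(X * 5.0, design, 2)).rank()
        assert (r1 == r2).all()

    def test_biplot_coordinates_and_bounds(self, fitted_model):
        model = fitted_model["model"]
        coords = biplot_data(model, fitted_model["fused"].block_of)
        assert coords["x"].abs().max() <= 1.0 and coords["y"].abs().max() <= 1.0
        samples = coords[coords["kind"] == "sample"]
        scale = np.max(np.abs(model.T[:, :2]))
        assert np.allclose(samples[["x", "y"]].to_numpy(), model.T[:, :2] / scale)
        assert (coords["kind"] == "variable").sum() == len(model.variable_ids)
        assert set(coords.loc[coords.kind == "variable", "block"]) == {"NMR", "MS"}

    def test_biplot_requires_two_components(self):
        X = np.random.default_rng(0).normal(0, 1, (8, 5))
        model = fit_plsda(X, random_design(8), 1)
        with pytest.raises(ValueError):
            biplot_data(model)


class TestValidation:
    def _strong(self, n=28, p=15, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([1.0, 0.0] * (n // 2))
        X = np.outer(y - y.mean(), rng.normal(0, 1, p)) + rng.normal(0, 0.05, (n, p))
        Y = np.column_stack([y, 1 - y])
        return X, Y

    def test_strong_signal_high_q2(self):
        X, Y = self._strong()
        assert q2_crossval(X, Y, n_components=1, folds=7, seed=0) >= 0.9

    def test_pure_noise_low_q2(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (24, 10))
            y = np.array([1.0, 0.0] * 12)
            Y = np.column_stack([y, 1 - y])
            vals.append(q2_crossval(X, Y, n_components=2, folds=7, seed=seed))
        assert np.mean(vals) <= 0.2

    def test_q2_bounded_by_r2y(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (20, 12))
            design = random_design(20, seed=seed)
            model = fit_plsda(X, design, 2)
            q2 = q2_crossval(X, design.Y.to_numpy(), 2, folds=5, seed=seed)
            assert q2 <= model.r2y[-1] + 1e-9

    def test_fold_missing_class_rejected(self):
        # a lone member of one class always leaves the opposite training
        # fold without that class when only 2 folds are used
        X = np.random.default_rng(0).normal(0, 1, (4, 4))
        y = np.array([1.0, 0.0, 0.0, 0.0])
        Y = np.column_stack([y, 1 - y])
        with pytest.raises(ValueError, match="fold"):
            q2_crossval(X, Y, 1, folds=2, seed=0)

    def test_permutation_original_point_matches_direct_fit(self):
        X, Y = self._strong(n=20, p=8, seed=4)
        design = ClassDesign(
            [f"s{i}" for i in range(20)], ["A" if v else "B" for v in Y[:, 0]]
        )
        rep = permutation_test(X, design, n=12, seed=1, n_components=1)
        model = fit_plsda(X, design, 1)
        q2 = q2_crossval(X, design.Y.to_numpy(), 1, folds=7, seed=1)
        assert rep.correlations[-1] == 1.0
        assert rep.r2[-1] == pytest.approx(model.r2y[-1], abs=1e-12)
        assert rep.q2[-1] == pytest.approx(q2, abs=1e-12)

    def test_permutation_structured_data_valid(self):
        X, Y = self._strong(n=24, p=12, seed=7)
        design = ClassDesign(
            [f"s{i}" for i in range(24)], ["A" if v else "B" for v in Y[:, 0]]
        )
        rep = permutation_test(X, design, n=30, seed=2, n_components=1)
        assert rep.valid
        assert rep.q2_intercept < 0
        assert rep.r2_intercept > rep.q2_intercept

    def test_pure_noise_usually_invalid(self):
        flags = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(0, 1, (20, 30))
            design = random_design(20, seed=seed)
            rep = permutation_test(X, design, n=20, seed=seed, n_components=1)
            flags.append(rep.valid)
        assert sum(flags) <= 2

    def test_too_few_permutations_rejected(self):
        X, Y = self._strong(n=12, p=5)
        design = ClassDesign(
            [f"s{i}" for i in range(12)], ["A" if v else "B" for v in Y[:, 0]]
        )
        with pytest.raises(ValueError):
            permutation_test(X, design, n=5)

    def test_permutation_deterministic_given_seed(self):
        X, Y = self._strong(n=16, p=6, seed=9)
        design = ClassDesign(
            [f"s{i}" for i in range(16)], ["A" if v else "B" for v in Y[:, 0]]
        )
        a = permutation_test(X, design, n=11, seed=3, n_components=1)
        b = permutation_test(X, design, n=11, seed=3, n_components=1)
        assert np.array_equal(a.q2, b.q2) and a.q2_intercept == b.q2_intercept


class TestSeasonalClustering:
    def test_same_season_samples_cluster_in_score_space(self, fitted_model):
        model = fitted_model["model"]
        labels = np.asarray(fitted_model["labels"])
        T = model.T[:, :2]
        within, between = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                d = np.linalg.norm(T[i] - T[j])
                (within if labels[i] == labels[j] else between).append(d)
        assert np.mean(within) < np.mean(between)
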