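import numpy as np
import pytest
from scipy import optimize

from petpattern.glm_classify import (
    ClassifierSpec,
    LabeledFeatures,
    LinearModel,
    decision_value,
    default_svm_grid,
    fit_linear_svm,
    fit_logistic_elasticnet,
    fit_pca,
    lambda_max,
    pca_transform,
    predict_proba,
    svm_primal_objective,
    tune_hyperparameters,
)


def solve_svm_dual_qp(X, t, C):
    """Generic QP solve of the SVM dual: an independent oracle.

    max sum(a) - 1/2 a' Q a  s.t. 0 <= a <= C, sum(a t) = 0,
    with Q_ij = t_i t_j x_i.x_j. Returns the optimal dual objective,
    which by strong duality equals the primal optimum.
    """
    n = X.shape[0]
    Q = (t[:, None] * X) @ (t[:, None] * X).T

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    cons = [{"type": "eq", "fun": lambda a: a @ t, "jac": lambda a: t.astype(float)}]
    best = None
    for x0_scale in (0.0, 0.5):
        res = optimize.minimize(
            neg_dual, np.full(n, x0_scale * C), jac=grad, method="SLSQP",
            bounds=[(0.0, C)] * n, constraints=cons,
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


class TestPCA:
    def test_points_on_line(self):
        u = np.array([1.0, 1.0]) / np.sqrt(2.0)
        X = np.outer([-2.0, -1.0, 1.0, 2.0], u)
        model = fit_pca(X)
        assert abs(abs(model.components[0] @ u) - 1.0) < 1e-12
        assert model.k == 1  # second eigenvalue is 0, below threshold

    def test_rank_bound(self, rng):
        X = rng.normal(size=(5, 100))
        model = fit_pca(X)
        assert model.k <= 4

    def test_dense_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(6, 3))
        model = fit_pca(X)
        cov = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(model.eigenvalues, evals[: model.k], atol=1e-8)
        for i in range(model.k):
            assert abs(abs(model.components[i] @ evecs[:, i]) - 1.0) < 1e-8

    def test_orthonormal_rows(self, rng):
        model = fit_pca(rng.normal(size=(10, 50)))
        G = model.components @ model.components.T
        np.testing.assert_allclose(G, np.eye(model.k), atol=1e-8)

    def test_eigenvalues_nonincreasing(self, rng):
        model = fit_pca(rng.normal(size=(12, 30)))
        assert (np.diff(model.eigenvalues) <= 1e-12).all()

    def test_rank0_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_pca(np.ones((4, 5)))

    def test_transform_of_mean_is_zero(self, rng):
        model = fit_pca(rng.normal(size=(8, 20)))
        np.testing.assert_allclose(pca_transform(model, model.mean), 0.0, atol=1e-12)

    def test_transform_recovers_unit_vector(self, rng):
        model = fit_pca(rng.normal(size=(8, 20)))
        e1 = np.zeros(model.k)
        e1[0] = 1.0
        x = model.mean + model.components.T @ e1
        np.testing.assert_allclose(pca_transform(model, x), e1, atol=1e-10)

    def test_isometry_on_span(self, rng):
        model = fit_pca(rng.normal(size=(8, 20)))
        a = model.components.T @ rng.normal(size=model.k)
        b = model.components.T @ rng.normal(size=model.k)
        d_feat = np.linalg.norm(pca_transform(model, model.mean + a)
                                - pca_transform(model, model.mean + b))
        assert abs(d_feat - np.linalg.norm(a - b)) < 1e-10


class TestSVM:
    def test_1d_maximum_margin(self):
        data = LabeledFeatures(np.array([[-1.0], [1.0]]), [-1, 1])
        model = fit_linear_svm(data, C=1e6)
        assert abs(model.w[0] - 1.0) < 1e-6
        assert abs(model.b) < 1e-6

    def test_inseparable_pair_symmetry(self):
        X = np.array([[0.5], [0.5], [0.5], [0.5]])
        data = LabeledFeatures(X, [1, -1, 1, -1])
        model = fit_linear_svm(data, C=10.0)
        obj = svm_primal_objective(model, data)
        assert np.isfinite(obj)
        assert abs(decision_value(model, np.array([0.5]))) < 1e-6

    def test_qp_dual_oracle(self, rng):
        X = rng.normal(size=(6, 2))
        t = np.array([1, 1, 1, -1, -1, -1])
        C = 2.0
        model = fit_linear_svm(LabeledFeatures(X, t), C=C)
        primal = svm_primal_objective(model, LabeledFeatures(X, t))
        dual = solve_svm_dual_qp(X, t, C)
        assert abs(primal - dual) / abs(dual) < 1e-5

    def test_kernel_scale_divides_features(self, rng):
        X = rng.normal(size=(10, 3))
        t = np.array([1] * 5 + [-1] * 5)
        a = fit_linear_svm(LabeledFeatures(X, t), C=1.0, scale=2.0)
        b = fit_linear_svm(LabeledFeatures(X / 2.0, t), C=1.0, scale=1.0)
        np.testing.assert_allclose(a.w, b.w, atol=1e-8)
        # decision_value applies the stored scale to raw inputs
        np.testing.assert_allclose(decision_value(a, X), decision_value(b, X / 2.0),
                                   atol=1e-8)

    def test_non_support_vector_removal(self, rng):
        X, t = _separated_blobs(rng, margin=3.0)
        data = LabeledFeatures(X, t)
        model = fit_linear_svm(data, C=1.0)
        margins = data.t * decision_value(model, X)
        far = int(np.argmax(margins))  # clearly outside the margin
        assert margins[far] > 1.0 + 1e-3
        keep = np.arange(len(t)) != far
        model2 = fit_linear_svm(LabeledFeatures(X[keep], t[keep]), C=1.0)
        np.testing.assert_allclose(model.w, model2.w, atol=1e-5)
        assert abs(model.b - model2.b) < 1e-5

    def test_invalid_hyperparams(self):
        data = LabeledFeatures(np.array([[0.0], [1.0]]), [-1, 1])
        with pytest.raises(ValueError):
            fit_linear_svm(data, C=-1.0)
        with pytest.raises(ValueError):
            fit_linear_svm(data, C=1.0, scale=0.0)


def _separated_blobs(rng, margin=3.0, n=8, p=2):
    X = rng.normal(size=(2 * n, p))
    t = np.array([1] * n + [-1] * n)
    X[:, 0] += t * margin
    return X, t


class TestLogisticElasticNet:
    def test_intercept_only_limit(self):
        rngl = np.random.default_rng(7)
        X = rngl.normal(size=(30, 4))
        t = np.array([1] * 20 + [-1] * 10)
        model = fit_logistic_elasticnet(LabeledFeatures(X, t), alpha=0.5, lam=1e4)
        np.testing.assert_allclose(model.w, 0.0, atol=1e-6)
        assert abs(model.b - np.log(20 / 10)) < 1e-2

    def test_unpenalized_mle_oracle(self, rng):
        # non-separable data so the unpenalized MLE exists
        X = rng.normal(size=(40, 3))
        t = np.where(rng.random(40) < 0.5, 1, -1)
        model = fit_logistic_elasticnet(LabeledFeatures(X, t), alpha=0.0, lam=0.0)

        def nll(wb):
            z = t * (X @ wb[:3] + wb[3])
            return np.mean(np.logaddexp(0.0, -z))

        res = optimize.minimize(nll, np.zeros(4), method="BFGS",
                                options={"gtol": 1e-12})
        assert nll(np.r_[model.w, model.b]) - res.fun < 1e-5
        np.testing.assert_allclose(model.w, res.x[:3], atol=1e-4)

    def test_ridge_matches_convex_solver(self, rng):
        X = rng.normal(size=(30, 3))
        t = np.where(rng.random(30) < 0.5, 1, -1)
        lam = 0.1
        model = fit_logistic_elasticnet(LabeledFeatures(X, t), alpha=0.0, lam=lam)

        def obj(wb):
            z = t * (X @ wb[:3] + wb[3])
            return np.mean(np.logaddexp(0.0, -z)) + lam / 2.0 * wb[:3] @ wb[:3]

        res = optimize.minimize(obj, np.zeros(4), method="BFGS",
                                options={"gtol": 1e-12})
        assert obj(np.r_[model.w, model.b]) - res.fun < 1e-5

    def test_lambda_max_zeroes_lasso(self, rng):
        X = rng.normal(size=(50, 5))
        t = np.where(rng.random(50) < 0.5, 1, -1)
        lmax = lambda_max(X, t, alpha=1.0)
        model = fit_logistic_elasticnet(LabeledFeatures(X, t), alpha=1.0,
                                        lam=lmax * 1.05)
        np.testing.assert_array_equal(model.w, 0.0)

    def test_l1_norm_monotone_in_lambda(self, rng):
        X = rng.normal(size=(40, 5))
        t = np.array([1] * 20 + [-1] * 20)
        X[:, 0] += t * 1.0
        norms = []
        for lam in [0.3, 0.1, 0.03, 0.01]:
            m = fit_logistic_elasticnet(LabeledFeatures(X, t), alpha=0.5, lam=lam)
            norms.append(np.abs(m.w).sum())
        assert all(a <= b + 1e-8 for a, b in zip(norms, norms[1:]))

    def test_invalid_params(self):
        data = LabeledFeatures(np.array([[0.0], [1.0]]), [-1, 1])
        with pytest.raises(ValueError):
            fit_logistic_elasticnet(data, alpha=1.5, lam=0.1)
        with pytest.raises(ValueError):
            fit_logistic_elasticnet(data, alpha=0.5, lam=-0.1)


class TestDecisionValue:
    def test_constant_model(self):
        m = LinearModel(w=np.zeros(3), b=0.3, loss_spec="hinge_l2")
        assert decision_value(m, np.array([5.0, -2.0, 1.0])) == pytest.approx(0.3)

    def test_sigmoid_midpoint(self):
        m = LinearModel(w=np.array([1.0]), b=0.0, loss_spec="logistic_elasticnet")
        assert predict_proba(m, np.array([0.0])) == pytest.approx(0.5)

    def test_antisymmetry(self, rng):
        m = LinearModel(w=rng.normal(size=4), b=0.7, loss_spec="hinge_l2")
        x = rng.normal(size=4)
        assert decision_value(m, -x) == pytest.approx(-decision_value(m, x) + 2 * m.b)

    def test_dimension_mismatch(self):
        m = LinearModel(w=np.ones(3), b=0.0, loss_spec="hinge_l2")
        with pytest.raises(ValueError, match="dimension"):
            decision_value(m, np.ones(4))


class TestTuning:
    def test_single_grid_point(self, rng):
        X, t = _separated_blobs(rng)
        best = tune_hyperparameters(LabeledFeatures(X, t), "svm",
                                    [{"C": 0.5, "scale": 1.0}], inner_k=4)
        assert best == {"C": 0.5, "scale": 1.0}

    def test_tie_break_deterministic(self, rng):
        X, t = _separated_blobs(rng)
        grid = [{"C": 1.0, "scale": 1.0}, {"C": 1.0, "scale": 1.0}]
        best = tune_hyperparameters(LabeledFeatures(X, t), "svm", grid, inner_k=4)
        assert best == grid[0]

    def test_selected_point_wins_exhaustively(self, rng):
        from sklearn.metrics import roc_auc_score
        from sklearn.model_selection import StratifiedKFold

        X, t = _separated_blobs(rng, margin=2.0, n=15)
        grid = [{"C": 1e-3, "scale": 1.0}, {"C": 1.0, "scale": 1.0}]
        seed = 5
        best = tune_hyperparameters(LabeledFeatures(X, t), "svm", grid,
                                    inner_k=5, seed=seed)
        # independent exhaustive evaluation over the same folds
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        totals = np.zeros(2)
        for tr, te in skf.split(X, t):
            for gi, g in enumerate(grid):
                m = fit_linear_svm(LabeledFeatures(X[tr], t[tr]), **g)
                totals[gi] += roc_auc_score(t[te], decision_value(m, X[te]))
        assert totals[[g == best for g in grid].index(True)] == totals.max()

    def test_small_class_reduces_folds(self, rng):
        X = rng.normal(size=(8, 2))
        t = np.array([1, 1, 1, 1, 1, -1, -1, -1])
        with pytest.warns(UserWarning, match="reducing"):
            tune_hyperparameters(LabeledFeatures(X, t), "svm",
                                 [{"C": 1.0, "scale": 1.0}], inner_k=10)

    def test_default_grid_shapes(self, rng):
        grid = default_svm_grid(16)
        assert len(grid) == 21
        assert grid[0]["C"] == pytest.approx(1e-3)
        spec = ClassifierSpec("pca_lr")
        X, t = _separated_blobs(rng)
        lr_grid = spec.build_grid(X, t)
        assert len(lr_grid) == 75
        # each alpha's path spans 4 decades down from its lambda_max
        for a in (0.1, 0.5, 0.9):
            lams = sorted((g["lambda"] for g in lr_grid if g["alpha"] == a),
                          reverse=True)
            assert len(lams) == 25
            assert lams[0] / lams[-1] == pytest.approx(1e4, rel=1e-6)
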