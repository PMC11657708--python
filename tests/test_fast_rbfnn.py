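import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from usplane.fast_rbfnn import (
    FCMResult,
    FastRBFConfig,
    RBFLayer,
    build_dual_kernel,
    fcm_fit,
    fit_multiclass,
    hidden_map,
    project_simplex,
    rbf_parameters,
    solve_dual,
)
from usplane.texture import FeatureTable


def slsqp_dual_objective(Ktilde, y, lam):
    """Generic-QP oracle for the dual objective value."""
    n = y.size
    c = (2.0 / lam) * np.concatenate([y, -y])
    res = minimize(
        lambda z: z @ Ktilde @ z - c @ z,
        np.full(2 * n, 1.0 / (2 * n)),
        jac=lambda z: 2 * Ktilde @ z - c,
        method="SLSQP",
        bounds=[(0, None)] * (2 * n),
        constraints={"type": "eq", "fun": lambda z: z.sum() - 1.0},
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return -res.fun


def two_blob_table(n_per_class=100, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0.0, 1.0, (n_per_class, 2)), rng.normal(sep, 1.0, (n_per_class, 2))]
    )
    y = np.repeat([0, 1], n_per_class)
    return FeatureTable(X, y, ["f0", "f1"])


class TestFCM:
    def test_single_cluster_closed_form(self, rng):
        X = rng.normal(size=(40, 3))
        res = fcm_fit(X, M=1, seed=0)
        np.testing.assert_allclose(res.centers[0], X.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(res.memberships, 1.0)

    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal([0, 0], 0.1, (100, 2))
        b = rng.normal([10, 10], 0.1, (100, 2))
        res = fcm_fit(np.vstack([a, b]), M=2, seed=1)
        got = res.centers[np.argsort(res.centers[:, 0])]
        assert np.linalg.norm(got[0] - a.mean(axis=0)) < 0.2
        assert np.linalg.norm(got[1] - b.mean(axis=0)) < 0.2

    def test_membership_rows_sum_to_one_and_objective_decreases(self, rng):
        X = rng.normal(size=(60, 4))
        res = fcm_fit(X, M=5, seed=2)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
        hist = res.objective_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_duplicate_points_warn(self):
        X = np.zeros((10, 2))
        with pytest.warns(UserWarning, match="distinct"):
            fcm_fit(X, M=3, seed=0)


class TestRBFLayer:
    def test_hand_computed_center_and_width(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        fcm = FCMResult(np.array([[0.5], [0.5]]), np.zeros((1, 2)), [])
        layer = rbf_parameters(X, fcm)
        np.testing.assert_allclose(layer.centers[0], [1.0, 0.0])
        assert layer.widths[0] == pytest.approx(1.0)  # mean squared distance

    def test_identical_points_width_floored(self):
        X = np.zeros((5, 2))
        fcm = FCMResult(np.ones((5, 1)), np.zeros((1, 2)), [])
        layer = rbf_parameters(X, fcm)
        np.testing.assert_allclose(layer.centers[0], 0.0)
        assert layer.widths[0] == pytest.approx(1e-8)

    def test_widths_strictly_positive_on_random_data(self, rng):
        X = rng.normal(size=(30, 3))
        res = fcm_fit(X, M=4, seed=3)
        layer = rbf_parameters(X, res)
        assert np.all(layer.widths > 0)


class TestHiddenMap:
    def test_known_values(self):
        layer = RBFLayer(centers=np.array([[0.0, 0.0]]), widths=np.array([2.0]))
        out = hidden_map(np.array([[0.0, 0.0], [1.0, 0.0], [np.sqrt(2), 0.0]]), layer)
        np.testing.assert_allclose(
            out.ravel(), [1.0, np.exp(-0.5), np.exp(-1.0)], atol=1e-12
        )

    def test_bounded_in_unit_interval_and_one_only_at_center(self, rng):
        X = rng.normal(size=(20, 3))
        res = fcm_fit(X, M=3, seed=1)
        layer = rbf_parameters(X, res)
        H = hidden_map(X, layer)
        assert np.all(H > 0) and np.all(H <= 1)
        H2 = hidden_map(layer.centers, layer)
        np.testing.assert_allclose(np.diag(H2), 1.0)


class TestDualKernel:
    def test_single_sample_block_form(self):
        Kt = build_dual_kernel(np.array([[0.5]]), lam=1.0, mu=0.1, gamma=1.0)
        np.testing.assert_allclose(Kt, [[1.1, -1.0], [-1.0, 1.1]])

    def test_symmetric_positive_semidefinite(self, rng):
        Xh = rng.random((12, 5))
        Kt = build_dual_kernel(Xh, lam=2.0, mu=0.3, gamma=0.7)
        np.testing.assert_allclose(Kt, Kt.T)
        assert np.linalg.eigvalsh(Kt).min() >= -1e-8

    def test_duplicated_rows_force_unit_off_diagonal(self):
        Xh = np.array([[0.2, 0.8], [0.2, 0.8]])
        Kt = build_dual_kernel(Xh, lam=1.0, mu=0.1, gamma=1.0)
        assert Kt[0, 1] == pytest.approx(1.0)  # K of equal points
        assert Kt[0, 2] == pytest.approx(-1.0)


class TestSolveDual:
    def test_simplex_projection_is_euclidean_projection(self, rng):
        v = rng.normal(size=30)
        z = project_simplex(v)
        assert z.min() >= 0 and z.sum() == pytest.approx(1.0, abs=1e-12)
        # projection optimality: no feasible direction improves the distance
        w = project_simplex(rng.normal(size=30))
        assert np.dot(v - z, w - z) <= 1e-9

    @pytest.mark.parametrize("trial", range(10))
    def test_objective_matches_generic_qp_oracle(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(2, 21))
        Xh = rng.random((n, 4))
        Kt = build_dual_kernel(Xh, lam=1.0, mu=0.1, gamma=0.5)
        y = rng.choice([-1.0, 1.0], n)
        sol = solve_dual(Kt, y, lam=1.0, mu=0.1)
        assert sol.objective == pytest.approx(
            slsqp_dual_objective(Kt, y, 1.0), abs=1e-6
        )
        assert sol.kkt_residual < 1e-6

    def test_constraint_contract(self, rng):
        Xh = rng.random((8, 3))
        Kt = build_dual_kernel(Xh, lam=1.0, mu=0.1, gamma=1.0)
        y = np.array([1.0, -1, 1, -1, 1, 1, -1, -1])
        sol = solve_dual(Kt, y, lam=1.0, mu=0.1)
        assert sol.alpha.min() >= 0 and sol.alpha_star.min() >= 0
        assert sol.alpha.sum() + sol.alpha_star.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(sol.xi, sol.alpha * 0.1 * 8)

    def test_single_sample_matches_grid_search(self):
        Kt = build_dual_kernel(np.array([[0.3]]), lam=1.0, mu=0.1, gamma=1.0)
        y = np.array([1.0])
        sol = solve_dual(Kt, y, lam=1.0)
        grid = np.linspace(0, 1, 200001)
        c = 2.0
        vals = c * (2 * grid - 1) - (
            1.1 * grid**2 + 1.1 * (1 - grid) ** 2 - 2 * grid * (1 - grid)
        )
        best = grid[np.argmax(vals)]
        assert sol.alpha[0] == pytest.approx(best, abs=1e-4)
        assert sol.alpha[0] > 0.9  # the linear term dominates at default lam, mu


class TestModel:
    def test_separable_blobs_high_training_accuracy(self):
        table = two_blob_table()
        model = fit_multiclass(table, None, FastRBFConfig(M=10, seed=0))
        acc = np.mean(model.predict(table.X) == table.y)
        assert acc >= 0.98

    def test_deterministic_given_seed(self):
        table = two_blob_table(n_per_class=40)
        cfg = FastRBFConfig(M=8, seed=5)
        a = fit_multiclass(table, None, cfg)
        b = fit_multiclass(table, None, cfg)
        for da, db in zip(a.duals, b.duals):
            np.testing.assert_allclose(da.alpha, db.alpha, atol=1e-10)
            np.testing.assert_allclose(da.alpha_star, db.alpha_star, atol=1e-10)

    def test_decision_value_matches_manual_kernel_sum(self):
        table = two_blob_table(n_per_class=20)
        model = fit_multiclass(table, None, FastRBFConfig(M=5, seed=1))
        x = table.X[3]
        xh = model._hidden(x[None, :])
        K = np.exp(-model.gamma * cdist(model.Xh_train, xh, "sqeuclidean")).ravel()
        for k, dual in enumerate(model.duals):
            manual = model.config.lam * np.sum((dual.alpha - dual.alpha_star) * K)
            assert model.decision_value(k, x) == pytest.approx(manual, abs=1e-12)

    def test_equal_duals_cancel_to_zero_decision(self):
        table = two_blob_table(n_per_class=15)
        model = fit_multiclass(table, None, FastRBFConfig(M=4, seed=2))
        d = model.duals[0]
        d.alpha_star = d.alpha.copy()  # alpha == alpha* -> identical cancellation
        assert model.decision_value(0, table.X[0]) == pytest.approx(0.0, abs=1e-15)

    def test_flipping_dual_difference_flips_decision_sign(self):
        table = two_blob_table(n_per_class=15)
        model = fit_multiclass(table, None, FastRBFConfig(M=4, seed=3))
        before = model.decision_value(0, table.X[0])
        d = model.duals[0]
        d.alpha, d.alpha_star = d.alpha_star.copy(), d.alpha.copy()
        assert model.decision_value(0, table.X[0]) == pytest.approx(-before, abs=1e-12)

    def test_exact_tie_broken_toward_lower_class_index(self):
        table = two_blob_table(n_per_class=15)
        model = fit_multiclass(table, None, FastRBFConfig(M=4, seed=4))
        model.duals[1] = model.duals[0]  # identical machines -> exact ties
        pred = model.predict(table.X)
        assert np.all(pred == 0)

    def test_feature_dimension_mismatch_rejected(self):
        table = two_blob_table(n_per_class=10)
        model = fit_multiclass(table, None, FastRBFConfig(M=4, seed=0))
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((3, 7)))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        table = FeatureTable(X, np.zeros(20, int), ["a", "b"])
        with pytest.raises(ValueError, match="two classes"):
            fit_multiclass(table)

    def test_json_round_trip_is_bit_exact(self, tmp_path):
        table = two_blob_table(n_per_class=25)
        model = fit_multiclass(table, None, FastRBFConfig(M=6, seed=7))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = model.from_json(path)
        np.testing.assert_array_equal(back.layer.centers, model.layer.centers)
        np.testing.assert_array_equal(back.layer.widths, model.layer.widths)
        for da, db in zip(model.duals, back.duals):
            np.testing.assert_array_equal(da.alpha, db.alpha)
        np.testing.assert_array_equal(back.predict(table.X), model.predict(table.X))

    def test_looser_slack_penalty_never_reduces_active_slacks(self):
        # larger mu cheapens slack usage, so the count of samples with
        # materially nonzero slack must not decrease
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(2, 1, (30, 3))])
        table = FeatureTable(X, np.repeat([0, 1], 30), ["a", "b", "c"])
        counts = []
        for mu in (0.01, 0.1, 1.0):
            model = fit_multiclass(table, None, FastRBFConfig(M=8, mu=mu, seed=0))
            d = model.duals[0]
            counts.append(int(np.sum((d.xi > 1e-6) | (d.xi_star > 1e-6))))
        assert counts == sorted(counts)
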