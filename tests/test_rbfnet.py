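"""Deep RBF network: activations, k-means, gradients, pretraining, fit."""

import json
import math
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonguedx.errors import ConfigError, DataError, NotFittedError
from tonguedx.rbfnet import (
    DeepRBFClassifier,
    DeepRBFNet,
    NetworkConfig,
    class_order,
    fit,
    gaussian_phi,
    kmeans_centers,
    predict,
    pretrain_autoencoder,
    rbf_widths,
)

DATA_DIR = Path(__file__).parent / "data"


class TestGaussianPhi:
    def test_center_value_is_one(self):
        assert gaussian_phi(0.0, 1.3) == pytest.approx(1.0)

    def test_closed_form_at_two_sigma_squared(self):
        sigma = 0.7
        assert gaussian_phi(2 * sigma**2, sigma) == pytest.approx(math.exp(-1))

    @given(
        grid=st.lists(st.integers(0, 400), min_size=2, max_size=20, unique=True),
        sigma=st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_squared_distance(self, grid, sigma):
        d2 = np.sort(np.array(grid, dtype=float)) / 10.0
        vals = gaussian_phi(d2, sigma)
        expected = np.exp(-d2 / (2 * sigma**2))
        assert np.allclose(vals, expected)
        assert np.all(vals <= 1)
        # strict decrease wherever the value has not underflowed to zero
        representable = vals[:-1] > 1e-300
        assert np.all(np.diff(vals)[representable] < 0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ConfigError):
            gaussian_phi(1.0, 0.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ConfigError):
            gaussian_phi(-0.5, 1.0)


class TestKMeans:
    def test_single_center_is_coordinate_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        centers, assign = kmeans_centers(X, 1, seed=0)
        assert np.allclose(centers[0], X.mean(axis=0))
        assert np.all(assign == 0)

    def test_recovers_well_separated_blob_means(self):
        rng = np.random.default_rng(1)
        means = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.vstack([m + rng.normal(scale=0.01, size=(30, 2)) for m in means])
        centers, _ = kmeans_centers(X, 3, seed=2)
        for m in means:
            assert np.min(np.linalg.norm(centers - m, axis=1)) < 0.05

    def test_k_equals_n_gives_zero_wcss(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 2))
        centers, assign = kmeans_centers(X, 6, seed=0)
        wcss = sum(
            np.sum((X[assign == j] - centers[j]) ** 2) for j in range(6)
        )
        assert wcss == pytest.approx(0.0, abs=1e-20)

    def test_matches_sklearn_on_separated_data(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(3)
        means = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 0], [0, 0, 8]], dtype=float)
        X = np.vstack([m + rng.normal(scale=0.1, size=(25, 3)) for m in means])
        ours, assign = kmeans_centers(X, 4, seed=1)
        ref = sklearn_cluster.KMeans(n_clusters=4, n_init=10, random_state=0).fit(X)
        our_wcss = sum(np.sum((X[assign == j] - ours[j]) ** 2) for j in range(4))
        assert our_wcss == pytest.approx(ref.inertia_, rel=1e-6)

    @pytest.mark.parametrize("bad_k", [0, 100])
    def test_invalid_k_rejected(self, bad_k):
        with pytest.raises(ConfigError):
            kmeans_centers(np.zeros((5, 2)) + np.arange(5)[:, None], bad_k)

    def test_empty_data_rejected(self):
        with pytest.raises(ConfigError):
            kmeans_centers(np.empty((0, 2)), 1)


def test_width_rules_positive_and_distinct():
    centers = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    rng = np.random.default_rng(0)
    data = np.repeat(centers, 10, axis=0) + rng.normal(scale=0.05, size=(30, 2))
    assign = np.repeat(np.arange(3), 10)
    near = rbf_widths(centers, "nearest-center")
    spread = rbf_widths(centers, "cluster-spread", data=data, assignments=assign)
    assert np.all(near > 0) and np.all(spread > 0)
    # nearest-center: mean of the two nearest other-center distances
    assert near[0] == pytest.approx((1.0 + 2.0) / 2)
    # cluster-spread tracks the much smaller within-cluster radius
    assert np.all(spread < near)


def _small_net(seed, sizes=(3,), input_dim=2, **kw):
    cfg = NetworkConfig(
        input_dim=input_dim, hidden_layer_sizes=sizes, output_dim=2, seed=seed, **kw
    )
    net = DeepRBFNet(cfg)
    rng = np.random.default_rng(seed + 50)
    for L in net.layers:
        L.centers = rng.normal(size=L.centers.shape)
        L.widths = rng.uniform(0.5, 2.0, size=L.widths.shape)
    return net


def _finite_difference_check(net, X, T, h=1e-6):
    grads = net.backprop(X, T)
    worst = 0.0
    for li, layer in enumerate(net.layers):
        for arr, g in ((layer.W, grads[li][0]), (layer.b, grads[li][1])):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                lp = net.loss(X, T)
                arr[idx] = orig - h
                lm = net.loss(X, T)
                arr[idx] = orig
                fd = (lp - lm) / (2 * h)
                denom = max(abs(fd), abs(g[idx]), 1e-6)
                worst = max(worst, abs(fd - g[idx]) / denom)
    return worst


class TestForwardBackward:
    def test_forward_matches_straight_line_oracle(self):
        """Independent evaluation of the two-layer radial chain without the
        layer abstraction: u = x W + b per unit; a_i = exp(-||u - r_i||^2 /
        (2 s_i^2)); output identically."""
        net = _small_net(0, sizes=(3,))
        x = np.array([0.3, -0.7])
        (y,) = net.forward(x[None, :])
        h = x
        for L in net.layers:
            u = h @ L.W + L.b
            a = np.array(
                [
                    math.exp(-np.sum((u - L.centers[i]) ** 2) / (2 * L.widths[i] ** 2))
                    for i in range(L.units)
                ]
            )
            h = a
        assert np.allclose(y, h, atol=1e-12)

    def test_zero_map_at_center_gives_unit_activation(self):
        net = _small_net(1, sizes=(3,))
        for L in net.layers:
            L.W[:] = 0.0
            L.b[:] = 0.0
            L.centers[:] = 0.0
        (y,) = net.forward(np.array([[5.0, -3.0]]))
        assert np.allclose(y, 1.0)

    def test_batch_forward_equals_single_forwards(self):
        net = _small_net(2, sizes=(4, 3))
        X = np.random.default_rng(9).normal(size=(7, 2))
        batch = net.forward(X)
        singles = np.vstack([net.forward(x[None, :]) for x in X])
        # BLAS summation order differs with row count; agreement to float
        # round-off is the batching-consistency contract
        assert np.allclose(batch, singles, rtol=0, atol=1e-13)

    def test_outputs_in_unit_interval(self):
        net = _small_net(3, sizes=(5, 4))
        X = np.random.default_rng(4).normal(size=(20, 2), scale=3)
        Y = net.forward(X)
        assert np.all((Y > 0) & (Y <= 1))

    def test_shape_mismatch_rejected(self):
        net = _small_net(0)
        with pytest.raises(ConfigError):
            net.forward(np.zeros((2, 5)))

    def test_perfect_prediction_gives_zero_gradients(self):
        net = _small_net(5, sizes=(3,))
        X = np.random.default_rng(5).normal(size=(4, 2))
        T = net.forward(X)  # targets equal to predictions
        for dW, db in net.backprop(X, T):
            assert np.allclose(dW, 0.0) and np.allclose(db, 0.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_gradients_match_finite_differences(self, trial):
        net = _small_net(trial, sizes=(3,))
        rng = np.random.default_rng(trial + 100)
        X = rng.normal(size=(4, 2))
        T = rng.random((4, 2))
        assert _finite_difference_check(net, X, T) < 1e-6

    def test_doubling_residual_doubles_linear_output_gradient(self):
        net = _small_net(6, sizes=(3,), linear_output=True)
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 2))
        Y = net.forward(X)
        T1 = Y - 0.1
        T2 = Y - 0.2  # doubled residual
        g1 = net.backprop(X, T1)[-1]
        g2 = net.backprop(X, T2)[-1]
        assert np.allclose(2 * g1[0], g2[0]) and np.allclose(2 * g1[1], g2[1])


class TestUpdate:
    def test_zero_gradients_leave_network_unchanged(self):
        net = _small_net(0)
        before = [L.W.copy() for L in net.layers]
        zeros = [(np.zeros_like(L.W), np.zeros_like(L.b)) for L in net.layers]
        net.apply_gradients(zeros, alpha=0.2)
        assert all(np.array_equal(b, L.W) for b, L in zip(before, net.layers))

    def test_zero_learning_rate_leaves_network_unchanged(self):
        net = _small_net(1)
        before = [L.W.copy() for L in net.layers]
        grads = [(np.ones_like(L.W), np.ones_like(L.b)) for L in net.layers]
        net.apply_gradients(grads, alpha=0.0)
        assert all(np.array_equal(b, L.W) for b, L in zip(before, net.layers))

    def test_scalar_quadratic_toy_matches_hand_derived_update(self):
        """One linear unit, one weight: E = 1/2 (t - w x)^2 so the step is
        w <- w + alpha (t - w x) x."""
        cfg = NetworkConfig(
            input_dim=1, hidden_layer_sizes=(), output_dim=1,
            linear_output=True, grad_clip=0.0, seed=0,
        )
        net = DeepRBFNet(cfg)
        L = net.layers[0]
        L.b[:] = 0.0
        w0, x, t, alpha = float(L.W[0, 0]), 1.7, 0.9, 0.2
        grads = net.backprop(np.array([[x]]), np.array([[t]]))
        net.apply_gradients(grads, alpha)
        assert L.W[0, 0] == pytest.approx(w0 + alpha * (t - w0 * x) * x)


class TestPretraining:
    def test_identical_vectors_reconstructed_and_collapsed(self):
        X = np.tile(np.linspace(0, 1, 8), (20, 1))
        net = DeepRBFNet(NetworkConfig(hidden_layer_sizes=(3, 3), seed=0))
        traces = pretrain_autoencoder(net, X)
        assert traces[0][-1] < 1e-6
        H = X
        for L in net.layers[:-1]:
            H = L.forward(H)
        assert np.all(H.std(axis=0) < 1e-9)

    def test_identity_sized_layer_descends(self):
        rng = np.random.default_rng(6)
        X = rng.random((60, 5))
        net = DeepRBFNet(NetworkConfig(input_dim=5, hidden_layer_sizes=(5,), seed=1))
        traces = pretrain_autoencoder(net, X)
        assert traces[0][-1] < traces[0][0]

    def test_every_layer_final_loss_not_above_initial(self):
        rng = np.random.default_rng(7)
        X = rng.random((80, 8))
        net = DeepRBFNet(NetworkConfig(seed=2))
        traces = pretrain_autoencoder(net, X)
        assert len(traces) == 7
        for trace in traces:
            assert trace[-1] <= trace[0] + 1e-12

    def test_line_embedded_in_8d_beats_variance_bound(self):
        """Data on a 1-D affine subspace of R^8: with a bottleneck >= 2 the
        reconstruction loss must fall below 10% of the total variance (the
        PCA bound for any >=1-component linear code is 0)."""
        rng = np.random.default_rng(3)
        t = rng.uniform(-1, 1, size=(150, 1))
        direction = rng.normal(size=(1, 8))
        direction /= np.linalg.norm(direction)
        X = 0.5 + t * direction
        # eigendecomposition oracle: total variance = sum of eigenvalues
        cov = np.cov(X.T)
        total_var = float(np.sum(np.linalg.eigvalsh(cov)))
        data_var = np.sum((X - X.mean(0)) ** 2, axis=1).mean()
        assert data_var == pytest.approx(total_var * (len(X) - 1) / len(X), rel=1e-9)
        net = DeepRBFNet(
            NetworkConfig(hidden_layer_sizes=(4,), seed=0, pretrain_epochs=150)
        )
        traces = pretrain_autoencoder(net, X)
        assert traces[0][-1] < 0.1 * data_var

    def test_empty_data_rejected(self):
        net = DeepRBFNet(NetworkConfig(seed=0))
        with pytest.raises(DataError):
            pretrain_autoencoder(net, np.empty((0, 8)))


class TestFit:
    def test_separable_blobs_train_to_perfect_accuracy_and_converge(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(200, 8))
        b = rng.normal(size=(200, 8))
        b[:, 0] += 10.0
        X = np.vstack([a, b])
        y = np.array(["non_DM"] * 200 + ["DM"] * 200, dtype=object)
        cfg = NetworkConfig(seed=4, max_epochs=2500, refresh_output_centers=True)
        net, report = fit(cfg, X, y)
        labels, _ = predict(net, X)
        assert np.mean(labels == y) == 1.0
        assert report.converged
        assert report.final_train_mse <= cfg.convergence_criterion
        assert report.epochs_run < cfg.max_epochs

    def test_shuffled_labels_stay_at_chance(self, blob_data):
        """Labels shuffled independently of features: held-out accuracy on
        freshly shuffled data stays in the chance band over 10 seeds."""
        X, y = blob_data
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed + 400)
            y_shuf = y.copy()
            rng.shuffle(y_shuf)
            cfg = NetworkConfig(
                hidden_layer_sizes=(4,), max_epochs=15, pretrain_epochs=5, seed=seed
            )
            net, _ = fit(cfg, X, y_shuf)
            y_new = y.copy()
            rng.shuffle(y_new)
            labels, _ = predict(net, X)
            accs.append(np.mean(labels == y_new))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_refit_is_bitwise_identical(self, blob_data):
        X, y = blob_data
        cfg = NetworkConfig(hidden_layer_sizes=(4, 3), max_epochs=10, seed=3)
        net1, _ = fit(cfg, X, y)
        net2, _ = fit(cfg, X, y)
        for L1, L2 in zip(net1.layers, net2.layers):
            assert np.array_equal(L1.W, L2.W)
            assert np.array_equal(L1.b, L2.b)
            assert np.array_equal(L1.centers, L2.centers)

    def test_single_class_rejected(self, blob_data):
        X, _ = blob_data
        y = np.array(["DM"] * len(X), dtype=object)
        with pytest.raises(DataError):
            fit(NetworkConfig(seed=0), X, y)

    def test_training_log_recorded(self, blob_data):
        X, y = blob_data
        cfg = NetworkConfig(hidden_layer_sizes=(4,), max_epochs=12, seed=0)
        net, report = fit(cfg, X, y)
        assert len(report.mse_trace) == report.epochs_run
        assert net.training_log == report.mse_trace


class TestPredict:
    def test_class_is_argmax_of_scores(self, blob_data):
        X, y = blob_data
        cfg = NetworkConfig(hidden_layer_sizes=(4,), max_epochs=20, seed=1)
        net, _ = fit(cfg, X, y)
        labels, scores = predict(net, X)
        assert net.classes_ == ("non_DM", "DM")
        expect = np.where(scores[:, 1] > scores[:, 0], "DM", "non_DM")
        assert np.array_equal(labels, expect.astype(object))

    def test_exact_ties_resolve_to_non_dm(self):
        cfg = NetworkConfig(
            input_dim=2, hidden_layer_sizes=(), output_dim=2,
            linear_output=True, seed=0,
        )
        net = DeepRBFNet(cfg)
        net.classes_ = ("non_DM", "DM")
        net.layers[0].W = np.eye(2)
        net.layers[0].b = np.zeros(2)
        labels, scores = predict(net, np.array([[0.4, 0.4]]))
        assert scores[0, 0] == scores[0, 1]
        assert labels[0] == "non_DM"

    def test_unfitted_network_rejected(self):
        net = DeepRBFNet(NetworkConfig(seed=0))
        with pytest.raises(NotFittedError):
            predict(net, np.zeros((1, 8)))

    def test_golden_fixture_regression(self):
        """A fitted small blob model reproduces frozen predictions/scores."""
        doc = json.loads((DATA_DIR / "blob_golden.json").read_text())
        rng = np.random.default_rng(21)
        a = rng.normal(size=(60, 8)) * 0.5
        b = rng.normal(size=(60, 8)) * 0.5
        b[:, 0] += 6.0
        X = np.vstack([a, b])
        y = np.array(["non_DM"] * 60 + ["DM"] * 60, dtype=object)
        cfg = NetworkConfig(
            hidden_layer_sizes=(4, 3), max_epochs=200, pretrain_epochs=10,
            refresh_output_centers=True, seed=5,
        )
        net, _ = fit(cfg, X, y)
        labels, scores = predict(net, np.array(doc["query_points"]))
        assert labels.tolist() == doc["labels"]
        assert np.allclose(scores, np.array(doc["scores"]), atol=1e-10)


class TestSerialization:
    def test_round_trip_is_lossless(self, blob_data, tmp_path):
        X, y = blob_data
        cfg = NetworkConfig(hidden_layer_sizes=(4,), max_epochs=10, seed=2)
        net, _ = fit(cfg, X, y)
        p = tmp_path / "model.json"
        net.save(p)
        back = DeepRBFNet.load(p)
        assert back.config == net.config
        assert back.classes_ == net.classes_
        for L1, L2 in zip(net.layers, back.layers):
            assert np.array_equal(L1.W, L2.W)
            assert np.array_equal(L1.widths, L2.widths)
        l1, s1 = predict(net, X)
        l2, s2 = predict(back, X)
        assert np.array_equal(l1, l2)
        assert np.array_equal(s1, s2)

    def test_unsupported_schema_version_rejected(self):
        with pytest.raises(ConfigError):
            DeepRBFNet.from_json(json.dumps({"schema_version": 99}))


def test_class_order_puts_non_dm_first():
    assert class_order(["DM", "non_DM", "DM"]) == ("non_DM", "DM")
    assert class_order(["a", "b"]) == ("a", "b")


def test_classifier_wrapper_guards_unfitted_state():
    clf = DeepRBFClassifier(NetworkConfig(seed=0))
    with pytest.raises(NotFittedError):
        clf.predict(np.zeros((1, 8)))
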