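"""Deep radial basis function network with autoencoder pretraining.

Architecture.  Every layer (hidden and output) applies an affine map to
its input, ``u = x W + b``, then a Gaussian radial unit response
relative to per-unit centers ``r_i`` living in the mapped space:

    a_i = c_i * exp(-||u - r_i||^2 / (2 sigma_i^2))

The affine map realises the norm-side linear transform of the radial
functional connection f(x) = sum_i c_i phi(||x w - r_i||^2); the mixing
coefficients ``c_i`` default to 1 and are not trained.  Centers come
from k-means (k-means++ seeding, Lloyd iterations) on the layer's mapped
input; widths follow one of two documented rules.  Only the affine
parameters (W, b) of each layer are trained — centers and widths stay
fixed after initialisation, as in classical RBF practice.

Training.  (1) Greedy layer-wise autoencoder pretraining: each hidden
layer, in order, is trained with a linear decoder to reconstruct its own
input (mean squared reconstruction loss); the encoder is then frozen
and its encodings feed the next layer.  (2) Supervised fine-tuning by
mini-batch gradient descent (batch-averaged gradients, learning rate
alpha, default 0.2, batch 40) on the squared error
E = 1/2 sum_k (t_k - y_k)^2 against one-hot targets over the two output
units, until the epoch-mean error falls below the convergence criterion
(default 1e-6) or ``max_epochs`` is reached.

Everything is deterministic given (config, data, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError, NotFittedError, TrainingError

WIDTH_RULES = ("nearest-center", "cluster-spread")
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class NetworkConfig:
    input_dim: int = 8
    hidden_layer_sizes: tuple[int, ...] = (3, 5, 7, 5, 3, 4, 3)
    output_dim: int = 2
    learning_rate: float = 0.2
    convergence_criterion: float = 1e-6
    batch_size: int = 40
    max_epochs: int = 500
    width_rule: str = "nearest-center"
    center_strategy: str = "per-layer"  # or "input-once"
    pretrain_epochs: int = 40
    pretrain_learning_rate: float = 0.1
    refresh_output_centers: bool = False
    grad_clip: float = 0.2  # max L2 norm per parameter block; 0 disables
    restarts: int = 1  # seeded re-initialisations; best train MSE kept
    linear_output: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = (self.input_dim, *self.hidden_layer_sizes, self.output_dim)
        if any(int(s) < 1 for s in sizes):
            raise ConfigError("all layer sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.convergence_criterion <= 0:
            raise ConfigError("convergence_criterion must be positive")
        if self.width_rule not in WIDTH_RULES:
            raise ConfigError(f"unknown width_rule: {self.width_rule!r}")
        if self.center_strategy not in ("per-layer", "input-once"):
            raise ConfigError(f"unknown center_strategy: {self.center_strategy!r}")
        object.__setattr__(self, "hidden_layer_sizes", tuple(int(s) for s in self.hidden_layer_sizes))


class RBFLayer:
    """One radial layer: affine map (trained) + fixed Gaussian units."""

    def __init__(self, fan_in: int, units: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(fan_in)
        self.W = rng.uniform(-bound, bound, size=(fan_in, units))
        self.b = np.zeros(units)
        self.centers = np.zeros((units, units))
        self.widths = np.ones(units)
        self.mixing = np.ones(units)
        self.gaussian = True  # linear-output mode turns this off

    @property
    def fan_in(self) -> int:
        return self.W.shape[0]

    @property
    def units(self) -> int:
        return self.W.shape[1]

    def map_input(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W + self.b

    def forward(self, X: np.ndarray, cache: Optional[dict] = None) -> np.ndarray:
        if X.shape[1] != self.fan_in:
            raise ConfigError(
                f"layer expects fan-in {self.fan_in}, got {X.shape[1]}"
            )
        U = self.map_input(X)
        if not self.gaussian:
            if cache is not None:
                cache.update(X=X, U=U, A=U)
            return U
        D2 = (
            np.sum(U * U, axis=1, keepdims=True)
            - 2.0 * U @ self.centers.T
            + np.sum(self.centers * self.centers, axis=1)
        )
        np.maximum(D2, 0.0, out=D2)
        A = self.mixing * np.exp(-D2 / (2.0 * self.widths**2))
        if cache is not None:
            cache.update(X=X, U=U, A=A)
        return A

    def backward(self, cache: dict, dA: np.ndarray):
        """Gradients of the cached forward pass.

        Returns (dW, db, dX): gradients w.r.t. the affine parameters and
        the layer input, for the upstream sensitivity ``dA`` w.r.t. the
        layer's activations.
        """
        if not self.gaussian:
            dU = dA
        else:
            M = dA * cache["A"] / self.widths**2
            dU = M @ self.centers - np.sum(M, axis=1, keepdims=True) * cache["U"]
        if not np.all(np.isfinite(dU)):
            raise TrainingError("non-finite gradient in radial layer")
        dW = cache["X"].T @ dU
        db = dU.sum(axis=0)
        dX = dU @ self.W.T
        return dW, db, dX


def gaussian_phi(squared_distance, width):
    """Gaussian radial basis phi(d^2) = exp(-d^2 / (2 sigma^2)).

    Strictly decreasing in the squared distance, equal to 1 at the
    center; ``width`` must be positive.
    """
    d2 = np.asarray(squared_distance, dtype=float)
    sig = np.asarray(width, dtype=float)
    if np.any(sig <= 0):
        raise ConfigError("width sigma must be positive")
    if not (np.all(np.isfinite(d2)) and np.all(np.isfinite(sig))):
        raise ConfigError("gaussian_phi requires finite inputs")
    if np.any(d2 < 0):
        raise ConfigError("squared distance must be nonnegative")
    out = np.exp(-d2 / (2.0 * sig**2))
    return float(out) if out.ndim == 0 else out


def kmeans_centers(
    data: np.ndarray, k: int, seed: int = 0, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's algorithm from a seeded k-means++ start.

    Iterates until the assignment fixpoint or ``max_iter``; the
    within-cluster sum of squares is non-increasing across iterations.
    Returns (centers, assignments).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ConfigError("k-means needs a nonempty 2-D data array")
    n_distinct = len(np.unique(X, axis=0))
    if k < 1 or k > n_distinct:
        raise ConfigError(f"k must be in [1, {n_distinct} (distinct points)], got {k}")
    rng = np.random.default_rng(seed)

    # k-means++ seeding
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(len(X))]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        p = d2 / d2.sum() if d2.sum() > 0 else np.full(len(X), 1.0 / len(X))
        centers[j] = X[rng.choice(len(X), p=p)]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))

    assign = np.full(len(X), -1)
    for _ in range(max_iter):
        dist = (
            np.sum(X * X, axis=1, keepdims=True)
            - 2.0 * X @ centers.T
            + np.sum(centers * centers, axis=1)
        )
        new_assign = np.argmin(dist, axis=1)
        # re-seed empty clusters at the farthest point
        for j in range(k):
            if not np.any(new_assign == j):
                far = np.argmax(np.min(dist, axis=1))
                centers[j] = X[far]
                new_assign[far] = j
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            centers[j] = X[assign == j].mean(axis=0)
    return centers, assign


def rbf_widths(
    centers: np.ndarray,
    rule: str = "nearest-center",
    data: Optional[np.ndarray] = None,
    assignments: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-unit Gaussian widths.

    ``nearest-center``: mean distance to the two nearest other centers
    (to the single other center when k = 2; data spread when k = 1).
    ``cluster-spread``: RMS radius of the unit's k-means cluster.
    Degenerate zero widths fall back to the mean positive width, or 1.
    """
    if rule not in WIDTH_RULES:
        raise ConfigError(f"unknown width_rule: {rule!r}")
    k = len(centers)
    sig = np.zeros(k)
    if rule == "cluster-spread" and data is not None and assignments is not None:
        for j in range(k):
            pts = data[assignments == j]
            if len(pts):
                sig[j] = np.sqrt(np.mean(np.sum((pts - centers[j]) ** 2, axis=1)))
    else:
        if k == 1:
            if data is not None and len(data):
                sig[0] = np.sqrt(np.mean(np.sum((data - centers[0]) ** 2, axis=1)))
        else:
            dist = np.sqrt(
                np.maximum(
                    np.sum(centers * centers, axis=1, keepdims=True)
                    - 2.0 * centers @ centers.T
                    + np.sum(centers * centers, axis=1),
                    0.0,
                )
            )
            np.fill_diagonal(dist, np.inf)
            m = min(2, k - 1)
            sig = np.sort(dist, axis=1)[:, :m].mean(axis=1)
    positive = sig[sig > 0]
    fallback = positive.mean() if len(positive) else 1.0
    sig = np.where(sig > 0, sig, fallback)
    return sig


class DeepRBFNet:
    """Layer stack plus training bookkeeping; build via :func:`fit`."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = (config.input_dim, *config.hidden_layer_sizes, config.output_dim)
        self.layers = [
            RBFLayer(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)
        ]
        if config.linear_output:
            self.layers[-1].gaussian = False
        self.autoencoder_losses: list[list[float]] = []
        self.training_log: list[float] = []
        self.classes_: Optional[tuple[str, str]] = None
        self._rng = rng

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, caches: Optional[list] = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.input_dim:
            raise ConfigError(
                f"expected input dim {self.config.input_dim}, got {X.shape[1]}"
            )
        H = X
        for layer in self.layers:
            cache: dict = {}
            H = layer.forward(H, cache)
            if caches is not None:
                caches.append(cache)
        return H

    def loss(self, X: np.ndarray, T: np.ndarray) -> float:
        """Mean per-sample squared error E = 1/2 sum_k (t_k - y_k)^2."""
        Y = self.forward(X)
        return float(0.5 * np.sum((T - Y) ** 2) / len(Y))

    def backprop(self, X: np.ndarray, T: np.ndarray):
        """Batch-mean gradients of E w.r.t. every layer's (W, b)."""
        caches: list[dict] = []
        Y = self.forward(X, caches)
        G = (Y - np.atleast_2d(T)) / len(Y)
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dW, db, G = layer.backward(cache, G)
            grads.append((dW, db))
        return list(reversed(grads))

    def apply_gradients(self, grads, alpha: float, clip: float = 0.0) -> None:
        """Gradient-descent update new = old - alpha * dE/dparam.

        With ``clip`` > 0 each parameter block's gradient is rescaled to at
        most that L2 norm.  The chained 1/sigma^2 factors of deep Gaussian
        layers can make raw early-stage gradients orders of magnitude too
        large for a fixed step; clipping bounds the step without altering
        the small-gradient regime near convergence.
        """
        if alpha < 0:
            raise ConfigError("learning rate must be nonnegative")
        for layer, (dW, db) in zip(self.layers, grads):
            if clip > 0:
                nW = np.linalg.norm(dW)
                if nW > clip:
                    dW = dW * (clip / nW)
                nb = np.linalg.norm(db)
                if nb > clip:
                    db = db * (clip / nb)
            layer.W -= alpha * dW
            layer.b -= alpha * db

    # -- initialisation -----------------------------------------------------

    def _set_layer_centers(self, layer: RBFLayer, H: np.ndarray, seed: int) -> None:
        U = layer.map_input(H)
        k = min(layer.units, len(np.unique(U, axis=0)))
        centers, assign = kmeans_centers(U, k, seed=seed)
        if k < layer.units:  # fewer distinct points than units: tile
            reps = -(-layer.units // k)
            centers = np.tile(centers, (reps, 1))[: layer.units]
            assign = assign  # widths fall back on duplicates
        layer.centers = centers
        layer.widths = rbf_widths(
            centers, self.config.width_rule, data=U, assignments=assign
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "config": asdict(self.config),
            "classes": self.classes_,
            "layers": [
                {
                    "W": layer.W.tolist(),
                    "b": layer.b.tolist(),
                    "centers": layer.centers.tolist(),
                    "widths": layer.widths.tolist(),
                    "mixing": layer.mixing.tolist(),
                    "gaussian": layer.gaussian,
                }
                for layer in self.layers
            ],
            "autoencoder_losses": self.autoencoder_losses,
            "training_log": self.training_log,
        }
        return json.dumps(doc)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "DeepRBFNet":
        doc = json.loads(text)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ConfigError(f"unsupported model schema: {doc.get('schema_version')}")
        cfg = doc["config"]
        cfg["hidden_layer_sizes"] = tuple(cfg["hidden_layer_sizes"])
        net = cls(NetworkConfig(**cfg))
        for layer, ld in zip(net.layers, doc["layers"]):
            layer.W = np.array(ld["W"])
            layer.b = np.array(ld["b"])
            layer.centers = np.array(ld["centers"])
            layer.widths = np.array(ld["widths"])
            layer.mixing = np.array(ld["mixing"])
            layer.gaussian = ld["gaussian"]
        net.autoencoder_losses = doc["autoencoder_losses"]
        net.training_log = doc["training_log"]
        net.classes_ = tuple(doc["classes"]) if doc["classes"] else None
        return net

    @classmethod
    def load(cls, path) -> "DeepRBFNet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


@dataclass
class TrainReport:
    epochs_run: int
    final_train_mse: float
    converged: bool
    mse_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# autoencoder pretraining


def pretrain_autoencoder(
    net: DeepRBFNet,
    X: np.ndarray,
    epochs: Optional[int] = None,
    tol: float = 0.0,
) -> list[list[float]]:
    """Greedy layer-wise pretraining of the hidden stack.

    Each hidden layer is paired with a linear decoder and trained to
    minimise the mean squared reconstruction error of its own input;
    the best-so-far encoder parameters are kept, so the final loss of a
    layer never exceeds its initial loss.  Returns the per-layer loss
    traces (also stored on the net).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(X) == 0:
        raise DataError("pretraining requires nonempty data")
    cfg = net.config
    n_epochs = cfg.pretrain_epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed + 1)
    traces: list[list[float]] = []

    raw = X
    H = X
    for li, layer in enumerate(net.layers[:-1]):
        if cfg.center_strategy == "input-once":
            # centers = image of raw-input k-means centroids under the prefix
            k = min(layer.units, len(np.unique(raw, axis=0)))
            c_raw, _ = kmeans_centers(raw, k, seed=cfg.seed + 101)
            Himg = c_raw
            for prev in net.layers[:li]:
                Himg = prev.forward(Himg)
            U = layer.map_input(Himg)
            if k < layer.units:
                U = np.tile(U, (-(-layer.units // k), 1))[: layer.units]
            layer.centers = U
            layer.widths = rbf_widths(
                U, cfg.width_rule, data=layer.map_input(H), assignments=None
            )
        else:
            net._set_layer_centers(layer, H, seed=cfg.seed + 101 + li)

        D = rng.uniform(-0.1, 0.1, size=(layer.units, layer.fan_in))
        d0 = H.mean(axis=0).copy()
        trace = []
        best = (np.inf, layer.W.copy(), layer.b.copy(), D.copy(), d0.copy())

        def recon_loss() -> float:
            A = layer.forward(H)
            R = A @ D + d0
            return float(np.mean(np.sum((H - R) ** 2, axis=1)))

        loss0 = recon_loss()
        trace.append(loss0)
        best = (loss0, layer.W.copy(), layer.b.copy(), D.copy(), d0.copy())
        n = len(H)
        bs = min(cfg.batch_size, n)
        for _ in range(n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                Hb = H[idx]
                cache: dict = {}
                A = layer.forward(Hb, cache)
                R = A @ D + d0
                dR = 2.0 * (R - Hb) / len(Hb)
                dD = A.T @ dR
                dd0 = dR.sum(axis=0)
                dA = dR @ D.T
                dW, db, _ = layer.backward(cache, dA)
                if not np.all(np.isfinite(dW)):
                    raise TrainingError(f"divergent pretraining loss at layer {li}")
                lr = cfg.pretrain_learning_rate
                if cfg.grad_clip > 0:
                    for g in (dW, db, dD, dd0):
                        n_g = np.linalg.norm(g)
                        if n_g > cfg.grad_clip:
                            g *= cfg.grad_clip / n_g
                layer.W -= lr * dW
                layer.b -= lr * db
                D -= lr * dD
                d0 -= lr * dd0
            cur = recon_loss()
            if not np.isfinite(cur):
                raise TrainingError(f"divergent pretraining loss at layer {li}")
            trace.append(cur)
            if cur < best[0]:
                best = (cur, layer.W.copy(), layer.b.copy(), D.copy(), d0.copy())
            if cur <= tol:
                break
        _, layer.W, layer.b, D, d0 = best
        traces.append(trace)
        H = layer.forward(H)
    net.autoencoder_losses = traces
    return traces


# ---------------------------------------------------------------------------
# supervised fit / predict


def _one_hot(y: np.ndarray, classes: tuple[str, str]) -> np.ndarray:
    T = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        T[y == c, j] = 1.0
    return T


def class_order(labels: Sequence[str]) -> tuple[str, ...]:
    """Output-unit order: non_DM first (the tie-break class), else sorted."""
    uniq = sorted(set(labels))
    if set(uniq) == {"DM", "non_DM"}:
        return ("non_DM", "DM")
    return tuple(uniq)


def fit(
    config: NetworkConfig, X: np.ndarray, y: Sequence[str], pretrain: bool = True
) -> tuple[DeepRBFNet, TrainReport]:
    """Train a deep RBF classifier.

    Pipeline: per-layer k-means centers and widths, greedy autoencoder
    pretraining, then supervised mini-batch gradient descent on one-hot
    targets until the epoch-mean error reaches the convergence criterion
    or ``max_epochs``.  With ``restarts`` > 1 the whole pipeline runs from
    that many derived seeds and the model with the lowest final training
    error is kept (deep Gaussian stacks can occasionally fall into a
    constant-output saddle; restarts filter those runs out).
    Deterministic given (config, data).
    """
    import dataclasses as _dc

    if config.restarts < 1:
        raise ConfigError("restarts must be >= 1")
    if config.restarts == 1:
        return _fit_once(config, X, y, pretrain)
    best = None
    for r in range(config.restarts):
        sub = _dc.replace(config, seed=config.seed + 7919 * r, restarts=1)
        net, report = _fit_once(sub, X, y, pretrain)
        if best is None or report.final_train_mse < best[1].final_train_mse:
            best = (net, report)
        if report.converged:
            break
    return best


def _fit_once(
    config: NetworkConfig, X: np.ndarray, y: Sequence[str], pretrain: bool = True
) -> tuple[DeepRBFNet, TrainReport]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=object)
    classes = class_order(list(y))
    if len(classes) < 2:
        raise DataError("training data must contain at least 2 classes")
    if len(classes) != config.output_dim:
        raise DataError(
            f"{len(classes)} classes but output_dim={config.output_dim}"
        )
    net = DeepRBFNet(config)
    net.classes_ = classes
    T = _one_hot(y, classes)

    if pretrain:
        pretrain_autoencoder(net, X)
    else:
        H = X
        for li, layer in enumerate(net.layers[:-1]):
            net._set_layer_centers(layer, H, seed=config.seed + 101 + li)
            H = layer.forward(H)

    # output layer centers/widths from its mapped input
    H = X
    for layer in net.layers[:-1]:
        H = layer.forward(H)
    out = net.layers[-1]
    if out.gaussian:
        net._set_layer_centers(out, H, seed=config.seed + 997)

    rng = np.random.default_rng(config.seed + 2)
    n = len(X)
    bs = min(config.batch_size, n)
    trace: list[float] = []
    converged = False
    epochs_run = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            grads = net.backprop(X[idx], T[idx])
            net.apply_gradients(grads, config.learning_rate, config.grad_clip)
        if out.gaussian and config.refresh_output_centers:
            _refresh_centers(net, X, out)
        mse = net.loss(X, T)
        trace.append(mse)
        epochs_run = epoch + 1
        if not np.isfinite(mse):
            raise TrainingError(f"training loss diverged at epoch {epochs_run}")
        if mse <= config.convergence_criterion:
            converged = True
            break
    net.training_log = trace
    report = TrainReport(
        epochs_run=epochs_run,
        final_train_mse=trace[-1] if trace else float("nan"),
        converged=converged,
        mse_trace=trace,
    )
    return net, report


def _refresh_centers(net: DeepRBFNet, X: np.ndarray, out: RBFLayer) -> None:
    """One Lloyd step on the output layer's mapped input: reassign points
    to their nearest center and move each center to its cluster mean.

    Widths stay fixed, so as fine-tuning contracts the class clusters the
    output activations can approach their one-hot targets instead of
    saturating at the width scale.  Empty clusters keep their center.
    """
    H = X
    for layer in net.layers[:-1]:
        H = layer.forward(H)
    U = out.map_input(H)
    d2 = (
        np.sum(U * U, axis=1, keepdims=True)
        - 2.0 * U @ out.centers.T
        + np.sum(out.centers * out.centers, axis=1)
    )
    assign = np.argmin(d2, axis=1)
    for j in range(out.units):
        pts = U[assign == j]
        if len(pts):
            out.centers[j] = pts.mean(axis=0)


def predict(net: DeepRBFNet, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and per-class scores (output activations).

    The class is the argmax of the scores; exact ties resolve to the
    first output unit, which is non_DM by construction.
    """
    if net.classes_ is None:
        raise NotFittedError("predict called on an unfitted network")
    scores = net.forward(X)
    idx = np.argmax(scores, axis=1)  # argmax takes the first maximum: non_DM on ties
    labels = np.array([net.classes_[i] for i in idx], dtype=object)
    return labels, scores


class DeepRBFClassifier:
    """Thin stateful wrapper around :func:`fit` / :func:`predict`."""

    def __init__(self, config: Optional[NetworkConfig] = None, pretrain: bool = True):
        self.config = config or NetworkConfig()
        self.pretrain = pretrain
        self.net: Optional[DeepRBFNet] = None
        self.report: Optional[TrainReport] = None

    def fit(self, X, y) -> "DeepRBFClassifier":
        self.net, self.report = fit(self.config, X, y, pretrain=self.pretrain)
        return self

    def predict(self, X) -> np.ndarray:
        if self.net is None:
            raise NotFittedError("classifier is not fitted")
        return predict(self.net, X)[0]

    def scores(self, X) -> np.ndarray:
        if self.net is None:
            raise NotFittedError("classifier is not fitted")
        return predict(self.net, X)[1]

    def positive_scores(self, X, positive: str = "DM") -> np.ndarray:
        if self.net is None:
            raise NotFittedError("classifier is not fitted")
        s = predict(self.net, X)[1]
        j = self.net.classes_.index(positive)
        # normalised positive-class score for thresholding / ROC
        tot = s.sum(axis=1)
        return np.where(tot > 0, s[:, j] / np.maximum(tot, 1e-300), 0.5)
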