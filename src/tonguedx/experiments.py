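"""Reproducible studies: structure recovery, gradient check, type-I error.

These functions define the package's standard experiments at fixed
problem sizes so that tests and reporting scripts run the identical
computation.  All randomness derives from explicit integer seeds.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import (
    CohortSpec,
    null_effects,
    scaled_spec,
    simulate_cohort,
    split_cohort,
    strong_effects,
)
from .rbfnet import DeepRBFClassifier, DeepRBFNet, NetworkConfig, fit, predict
from .schema import encode_records
from .significance import five_by_two_cv

#: network used for the cohort experiments: equal-width deep stack (six
#: hidden layers of 8 units, the input-neuron count), 3 restarts
RECOVERY_NETWORK = NetworkConfig(
    hidden_layer_sizes=(8,) * 6, max_epochs=200, restarts=3
)

RECOVERY_ENCODING = "severity-scaled"


def recovery_study(
    effects: Optional[Mapping[str, Mapping[str, float]]] = None,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    network: Optional[NetworkConfig] = None,
    encoding: str = RECOVERY_ENCODING,
    train_fraction: float = 0.7,
) -> dict:
    """Held-out accuracy of the deep RBF classifier on synthetic cohorts.

    For each seed: draw a full-size quota cohort under ``effects``
    (default: the strong +/-2 log-odds model), split 70/30 stratified,
    train on the 70%, measure accuracy on the held-out 30%.
    """
    effects = strong_effects() if effects is None else effects
    network = RECOVERY_NETWORK if network is None else network
    accs = []
    for seed in seeds:
        spec = CohortSpec(effects=effects, seed=seed)
        records = simulate_cohort(spec)
        train, test = split_cohort(records, train_fraction, seed=seed)
        Xtr, ytr = encode_records(train, encoding)
        Xte, yte = encode_records(test, encoding)
        net, _ = fit(dataclasses.replace(network, seed=seed), Xtr, ytr)
        labels, _ = predict(net, Xte)
        accs.append(float(np.mean(labels == yte)))
    return {
        "per_seed_accuracy": accs,
        "mean_accuracy": float(np.mean(accs)),
        "n_test": len(yte),
        "seeds": list(seeds),
    }


def gradient_check_study(n_networks: int = 100, seed: int = 0, h: float = 1e-5) -> dict:
    """Worst relative disagreement between analytic and central
    finite-difference gradients over randomized small networks.

    The relative error uses denominator max(|fd|, |g|, 1e-4): entries
    below 1e-4 in magnitude are effectively compared absolutely, since
    central differences on a loss of order 1 carry ~1e-11 round-off
    noise and cannot certify relative error on smaller entries.
    """
    worst = 0.0
    master = np.random.default_rng(seed)
    for trial in range(n_networks):
        net_seed = int(master.integers(2**31 - 1))
        cfg = NetworkConfig(
            input_dim=2, hidden_layer_sizes=(3,), output_dim=2, seed=net_seed
        )
        net = DeepRBFNet(cfg)
        rng = np.random.default_rng(net_seed + 1)
        for layer in net.layers:
            layer.centers = rng.normal(size=layer.centers.shape)
            layer.widths = rng.uniform(0.5, 2.0, size=layer.widths.shape)
        X = rng.normal(size=(4, 2))
        T = rng.random((4, 2))
        grads = net.backprop(X, T)
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
                    denom = max(abs(fd), abs(g[idx]), 1e-4)
                    worst = max(worst, abs(fd - g[idx]) / denom)
    return {"worst_relative_error": worst, "n_networks": n_networks}


#: deliberately small model for the null study: only the equality of the
#: two classifiers matters under the null
NULL_TEST_NETWORK = NetworkConfig(
    hidden_layer_sizes=(4,), max_epochs=8, pretrain_epochs=4, seed=0
)


def type_i_error_study(
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    n_records: int = 120,
    network: Optional[NetworkConfig] = None,
) -> dict:
    """Empirical type-I error of the 5x2 CV t test under the null.

    Each replicate draws a small zero-effect cohort (labels independent
    of features) and compares two deep RBF classifiers that differ only
    in their initialisation seed, so the true accuracy gap is zero.
    """
    network = NULL_TEST_NETWORK if network is None else network
    n_dm = round(n_records * 1658 / 2675)
    rejects = 0
    for rep in range(n_replicates):
        rep_seed = (seed * 100003 + rep) % (2**31 - 1)
        spec = scaled_spec(
            n_records, n_dm, seed=rep_seed,
            sampling_mode="multinomial", effects=null_effects(),
        )
        records = simulate_cohort(spec)
        X, y = encode_records(records)
        factory = lambda s: DeepRBFClassifier(
            dataclasses.replace(network, seed=s), pretrain=False
        )
        comp = five_by_two_cv(factory, factory, X, y, seed=rep_seed, alpha=alpha)
        rejects += comp.p_value < alpha
    return {
        "rejection_rate": rejects / n_replicates,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }
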