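"""5x2 cross-validation paired t test for comparing two classifiers.

Five seeded random 50/50 splits of the data; on each split both models
are trained on half A and tested on half B and vice versa, giving two
per-fold accuracy differences per iteration.  With per-iteration mean
d_avg = (d_A + d_B)/2 and variance s_i^2 = (d_A - d_avg)^2 +
(d_B - d_avg)^2, the statistic is Dietterich's

    t = d_{A,1} / sqrt((1/5) sum_i s_i^2)

(the numerator is the first fold difference of the first iteration),
referred to a t distribution with 5 degrees of freedom, two-sided.

Degeneracy: when the pooled variance is exactly zero (e.g. both models
are identical) the statistic is undefined; the comparison is flagged
``no-difference`` with p = 1 and no rejection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import DataError
from .metrics import confusion, metrics

DECISION_REJECT = "Null hypothesis rejection"
DECISION_RETAIN = "Null hypothesis retention"
DECISION_NO_DIFFERENCE = "No difference (degenerate variance)"


@dataclass
class CVComparison:
    acc_1: np.ndarray  # (5, 2) fold accuracies, model 1
    acc_2: np.ndarray  # (5, 2) fold accuracies, model 2
    diffs: np.ndarray  # (5, 2) per-fold accuracy differences
    means: np.ndarray  # (5,) per-iteration mean differences
    variances: np.ndarray  # (5,) per-iteration variances
    t: float
    p_value: float
    alpha: float
    degenerate: bool = False

    @property
    def decision(self) -> str:
        if self.degenerate:
            return DECISION_NO_DIFFERENCE
        return DECISION_REJECT if self.p_value < self.alpha else DECISION_RETAIN

    def to_json(self) -> str:
        return json.dumps(
            {
                "fold_accuracies_model_1": self.acc_1.tolist(),
                "fold_accuracies_model_2": self.acc_2.tolist(),
                "differences": self.diffs.tolist(),
                "iteration_means": self.means.tolist(),
                "iteration_variances": self.variances.tolist(),
                "t": None if math.isnan(self.t) else self.t,
                "p_value": self.p_value,
                "alpha": self.alpha,
                "decision": self.decision,
            }
        )


def p_value(t: float, df: int = 5) -> float:
    """Two-sided tail probability of the t distribution; symmetric in
    +/-t, equal to 1 at t = 0, strictly decreasing in |t|."""
    if df < 1:
        raise DataError("degrees of freedom must be >= 1")
    if math.isnan(t):
        return 1.0
    return float(2.0 * stats.t.sf(abs(t), df))


def cv_statistic(diffs: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """(t, p, degenerate) from a (5, 2) array of fold accuracy differences."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.shape != (5, 2):
        raise DataError(f"expected a (5, 2) difference array, got {diffs.shape}")
    means = diffs.mean(axis=1)
    variances = np.sum((diffs - means[:, None]) ** 2, axis=1)
    pooled = variances.mean()
    if pooled == 0.0:
        return float("nan"), 1.0, True
    t = diffs[0, 0] / math.sqrt(pooled)
    return t, p_value(t, df=5), False


def compare_from_differences(diffs: np.ndarray, alpha: float = 0.05) -> CVComparison:
    """Build a comparison directly from fold accuracy differences
    (accuracies themselves unknown; used for injected-difference
    studies and arithmetic checks)."""
    diffs = np.asarray(diffs, dtype=float)
    t, p, degen = cv_statistic(diffs, alpha)
    means = diffs.mean(axis=1)
    variances = np.sum((diffs - means[:, None]) ** 2, axis=1)
    nan = np.full_like(diffs, np.nan)
    return CVComparison(
        acc_1=nan, acc_2=nan, diffs=diffs, means=means,
        variances=variances, t=t, p_value=p, alpha=alpha, degenerate=degen,
    )


def _half_split(
    rng: np.random.Generator, y: np.ndarray, max_attempts: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    n = len(y)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        a, b = perm[: n // 2], perm[n // 2 :]
        if len(set(y[a])) > 1 and len(set(y[b])) > 1:
            return a, b
    raise DataError("could not obtain two-class halves in 20 seeded attempts")


def five_by_two_cv(
    model_factory_1: Callable[[int], object],
    model_factory_2: Callable[[int], object],
    X: np.ndarray,
    y: Sequence[str],
    seed: int = 0,
    alpha: float = 0.05,
) -> CVComparison:
    """Run the full 5x2 CV comparison of two model factories.

    A factory maps an integer seed to an unfitted model exposing
    ``fit(X, y)`` and ``predict(X)``.  Each (iteration, fold, model)
    gets a distinct derived seed, so two copies of the same factory
    still produce independently initialised models.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    acc = np.zeros((2, 5, 2))
    for it in range(5):
        a, b = _half_split(rng, y)
        for fold, (tr, te) in enumerate(((a, b), (b, a))):
            for mi, factory in enumerate((model_factory_1, model_factory_2)):
                model = factory(seed * 1000 + it * 10 + fold * 2 + mi)
                model.fit(X[tr], y[tr])
                preds = model.predict(X[te])
                acc[mi, it, fold] = metrics(confusion(preds, y[te])).accuracy
    diffs = acc[0] - acc[1]
    t, p, degen = cv_statistic(diffs, alpha)
    means = diffs.mean(axis=1)
    variances = np.sum((diffs - means[:, None]) ** 2, axis=1)
    return CVComparison(
        acc_1=acc[0], acc_2=acc[1], diffs=diffs, means=means,
        variances=variances, t=t, p_value=p, alpha=alpha, degenerate=degen,
    )
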