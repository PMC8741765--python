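"""Published benchmark numbers used as arithmetic inputs.

These tables hold the study's printed per-model evaluation metrics and
cohort phase composition.  They are inputs for consistency arithmetic
(metric identities, improvement deltas, phase sums) — nothing here is a
measurement produced by this package.
"""

from __future__ import annotations

#: per-model metrics (accuracy, precision, sensitivity, specificity, f1, error_rate)
MODEL_METRICS: dict[str, dict[str, float]] = {
    "ResNet50": {
        "accuracy": 0.929, "precision": 0.961, "sensitivity": 0.956,
        "specificity": 0.776, "f1": 0.958, "error_rate": 0.071,
    },
    "ResNet50-RBFNN": {
        "accuracy": 0.944, "precision": 0.968, "sensitivity": 0.965,
        "specificity": 0.819, "f1": 0.967, "error_rate": 0.056,
    },
    "ResNet50-DeepRBFNN": {
        "accuracy": 0.984, "precision": 0.989, "sensitivity": 0.991,
        "specificity": 0.943, "f1": 0.990, "error_rate": 0.016,
    },
}

#: comparison baselines (same metric keys plus computational time, minutes)
COMPARISON_METRICS: dict[str, dict[str, float]] = {
    "PCA-GA-SVM": {
        "accuracy": 0.670, "precision": 0.669, "sensitivity": 0.769,
        "specificity": 0.555, "f1": 0.715, "error_rate": 0.329, "time_min": 2.01,
    },
    "Non-invasive": {
        "accuracy": 0.763, "precision": 0.691, "sensitivity": 0.728,
        "specificity": 0.607, "f1": 0.774, "error_rate": 0.317, "time_min": 3.46,
    },
    "GreedySnake": {
        "accuracy": 0.801, "precision": 0.760, "sensitivity": 0.803,
        "specificity": 0.669, "f1": 0.792, "error_rate": 0.258, "time_min": 3.19,
    },
    "ResNet34": {
        "accuracy": 0.875, "precision": 0.890, "sensitivity": 0.907,
        "specificity": 0.826, "f1": 0.898, "error_rate": 0.125, "time_min": 3.24,
    },
    "SqueezeNet": {
        "accuracy": 0.856, "precision": 0.865, "sensitivity": 0.899,
        "specificity": 0.793, "f1": 0.882, "error_rate": 0.143, "time_min": 3.31,
    },
    "AlexNet": {
        "accuracy": 0.863, "precision": 0.870, "sensitivity": 0.905,
        "specificity": 0.801, "f1": 0.887, "error_rate": 0.137, "time_min": 3.27,
    },
    "RandomForest": {
        "accuracy": 0.877, "precision": 0.881, "sensitivity": 0.893,
        "specificity": 0.829, "f1": 0.890, "error_rate": 0.133, "time_min": 3.07,
    },
    "Stacking": {
        "accuracy": 0.892, "precision": 0.894, "sensitivity": 0.912,
        "specificity": 0.850, "f1": 0.917, "error_rate": 0.119, "time_min": 3.61,
    },
    "GA-XGBT": {
        "accuracy": 0.906, "precision": 0.911, "sensitivity": 0.899,
        "specificity": 0.872, "f1": 0.934, "error_rate": 0.103, "time_min": 3.57,
    },
    "SVM": {
        "accuracy": 0.927, "precision": 0.932, "sensitivity": 0.945,
        "specificity": 0.917, "f1": 0.955, "error_rate": 0.085, "time_min": 3.41,
    },
    "ResNet50-DeepRBFNN": {
        "accuracy": 0.984, "precision": 0.989, "sensitivity": 0.991,
        "specificity": 0.943, "f1": 0.990, "error_rate": 0.016, "time_min": 3.50,
    },
}


def improvement_over(baseline: str, metric: str, model: str = "ResNet50-DeepRBFNN") -> float:
    """Percentage-point improvement of ``model`` over ``baseline`` on
    ``metric`` (differences of the published table entries, x100)."""
    return round(
        (COMPARISON_METRICS[model][metric] - COMPARISON_METRICS[baseline][metric]) * 100, 10
    )
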