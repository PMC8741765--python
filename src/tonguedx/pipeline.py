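"""Experiment orchestration: splits, fivefold cross-validation, full runs.

``run_experiment`` drives the whole pipeline — optional cohort
simulation, encoding, stratified 70/30 split, pretraining + supervised
fine-tuning, held-out evaluation, ROC, fivefold cross-validation on the
training portion and an optional 5x2 CV comparison — and writes every
artifact (cohort table, split report, model JSON, metric JSON, fold
table, ROC points, structured log) into one output directory.

The held-out test portion never enters the cross-validation loop.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import cohort as cohort_mod
from . import schema
from .errors import ConfigError, DataError, TongueDxError
from .metrics import METRIC_NAMES, MetricReport, confusion, metrics, roc_curve, report_table
from .rbfnet import DeepRBFClassifier, NetworkConfig
from .significance import five_by_two_cv

log = logging.getLogger("tonguedx")

ARTIFACTS = (
    "cohort.csv",
    "split.json",
    "model.json",
    "metrics.json",
    "folds.csv",
    "roc.csv",
    "run.log",
)


@dataclass
class RunConfig:
    """Configuration of one experiment run (JSON or YAML on disk)."""

    cohort_path: Optional[str] = None  # read this table instead of simulating
    cohort: Optional[cohort_mod.CohortSpec] = None  # simulate when no path given
    network: NetworkConfig = field(default_factory=NetworkConfig)
    encoding_scheme: str = "ordinal"
    train_fraction: float = 0.7
    n_folds: int = 5
    run_crossval: bool = True
    compare_seeds: Optional[tuple[int, int]] = None  # run 5x2 CV of two net seeds
    out_dir: str = "run_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ConfigError(f"run config {path} is not a mapping")
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        if "network" in doc and isinstance(doc["network"], dict):
            net = dict(doc["network"])
            if "hidden_layer_sizes" in net:
                net["hidden_layer_sizes"] = tuple(net["hidden_layer_sizes"])
            doc["network"] = NetworkConfig(**net)
        if "cohort" in doc and isinstance(doc["cohort"], dict):
            doc["cohort"] = cohort_mod.CohortSpec(**doc["cohort"])
        if "compare_seeds" in doc and doc["compare_seeds"] is not None:
            doc["compare_seeds"] = tuple(doc["compare_seeds"])
        try:
            return cls(**doc)
        except TypeError as e:
            raise ConfigError(str(e)) from None

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stratified_folds(labels: Sequence[str], k: int, seed: int = 0) -> list[list[int]]:
    """Seeded stratified k-fold partition: disjoint, exhaustive; within
    each class the remainder records go to the lowest-index folds, so
    overall fold sizes differ by at most the number of classes."""
    labels = list(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    rng = np.random.default_rng(seed)
    for lab in sorted(set(labels)):
        idx = np.array([i for i, l in enumerate(labels) if l == lab])
        if len(idx) < k:
            raise DataError(f"class {lab!r} has fewer than {k} records")
        rng.shuffle(idx)
        base, extra = divmod(len(idx), k)
        start = 0
        for f in range(k):
            size = base + (1 if f < extra else 0)
            folds[f].extend(int(i) for i in idx[start : start + size])
            start += size
    return folds


def fivefold_cv(
    X: np.ndarray,
    y: Sequence[str],
    config: NetworkConfig,
    n_folds: int = 5,
    seed: int = 0,
    pretrain: bool = True,
) -> tuple[list[MetricReport], dict[str, tuple[float, float]]]:
    """Stratified k-fold cross-validation of the deep RBF classifier.

    Returns the per-fold validation reports and per-metric
    (mean, sd) aggregates (population sd over the folds).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    folds = stratified_folds(list(y), n_folds, seed=seed)
    reports: list[MetricReport] = []
    for f, val_idx in enumerate(folds):
        val = np.array(val_idx)
        tr = np.array([i for i in range(len(y)) if i not in set(val_idx)])
        clf = DeepRBFClassifier(
            dataclasses.replace(config, seed=config.seed + f), pretrain=pretrain
        )
        clf.fit(X[tr], y[tr])
        preds = clf.predict(X[val])
        rep = metrics(confusion(preds, y[val]))
        reports.append(rep)
        log.info("fold=%d accuracy=%.4f", f, rep.accuracy)
    agg = {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        agg[m] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    return reports, agg


def _stage(name: str, cfg_hash: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage=%s config=%s start", name, cfg_hash)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, TongueDxError):
                raise type(exc)(f"stage {name} (config {cfg_hash}): {exc}") from None
            log.info("stage=%s config=%s done", name, cfg_hash)
            return False

    return _Ctx()


def run_experiment(config: RunConfig) -> Path:
    """Execute the full pipeline and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.digest()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        with _stage("cohort", cfg_hash):
            if config.cohort_path:
                records = schema.read_feature_table(config.cohort_path)
            else:
                spec = config.cohort or cohort_mod.CohortSpec(seed=config.seed)
                records = cohort_mod.simulate_cohort(spec)
            schema.write_feature_table(records, out / "cohort.csv")

        with _stage("split", cfg_hash):
            train, test = cohort_mod.split_cohort(
                records, config.train_fraction, seed=config.seed
            )
            split_report = {
                "train": _class_counts(train),
                "test": _class_counts(test),
                "train_fraction": config.train_fraction,
            }
            (out / "split.json").write_text(json.dumps(split_report, indent=1))

        with _stage("encode", cfg_hash):
            Xtr, ytr = schema.encode_records(train, config.encoding_scheme)
            Xte, yte = schema.encode_records(test, config.encoding_scheme)

        with _stage("fit", cfg_hash):
            clf = DeepRBFClassifier(config.network)
            clf.fit(Xtr, ytr)
            assert clf.net is not None and clf.report is not None
            clf.net.save(out / "model.json")
            for ep, mse in enumerate(clf.report.mse_trace, start=1):
                log.debug("epoch=%d mse=%.8g", ep, mse)
            log.info(
                "epochs=%d final_mse=%.8g converged=%s",
                clf.report.epochs_run, clf.report.final_train_mse, clf.report.converged,
            )

        with _stage("evaluate", cfg_hash):
            preds = clf.predict(Xte)
            rep = metrics(confusion(preds, yte))
            payload = json.loads(rep.to_json())
            payload["epochs_run"] = clf.report.epochs_run
            payload["converged"] = clf.report.converged

        with _stage("roc", cfg_hash):
            pos = clf.positive_scores(Xte)
            points, auc = roc_curve(pos, yte)
            payload["auc"] = auc
            lines = ["fpr,tpr"] + [f"{p[0]:.6f},{p[1]:.6f}" for p in points]
            (out / "roc.csv").write_text("\n".join(lines) + "\n")

        if config.run_crossval:
            with _stage("crossval", cfg_hash):
                reports, agg = fivefold_cv(
                    Xtr, ytr, config.network, n_folds=config.n_folds, seed=config.seed
                )
                rows = {f"fold_{i}": r for i, r in enumerate(reports)}
                (out / "folds.csv").write_text(report_table(rows))
                payload["crossval"] = {m: {"mean": a[0], "sd": a[1]} for m, a in agg.items()}
        else:
            (out / "folds.csv").write_text(report_table({}))

        if config.compare_seeds is not None:
            with _stage("compare", cfg_hash):
                s1, s2 = config.compare_seeds
                f1 = lambda s: DeepRBFClassifier(dataclasses.replace(config.network, seed=s1))
                f2 = lambda s: DeepRBFClassifier(dataclasses.replace(config.network, seed=s2))
                comp = five_by_two_cv(f1, f2, Xtr, ytr, seed=config.seed)
                (out / "comparison.json").write_text(comp.to_json())

        (out / "metrics.json").write_text(json.dumps(payload, indent=1))
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _class_counts(records) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in records:
        counts[r.label] = counts.get(r.label, 0) + 1
    return dict(sorted(counts.items()))
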