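"""End-to-end experiment: simulate -> preprocess -> fit -> features ->
normalize -> train the plain and the Walsh-coded Bi-LSTM -> evaluate.

Both classifiers see identical splits, identical training-noise streams and
identically seeded initializations, so their comparison isolates the label
codec.  Normalization statistics are fitted on the training partition only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bilstm, features as feat, preprocess, synthetic
from .hyperfit import fit_hyperbolic
from .signal import DLSignal
from .walsh import Codebook

__all__ = [
    "ExperimentConfig",
    "EvaluationReport",
    "stratified_split",
    "confusion_and_accuracy",
    "build_feature_table",
    "run_experiment",
]

log = logging.getLogger("lumigrain")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one full comparison run."""

    profiles: tuple[synthetic.ClassProfile, ...] = synthetic.DEFAULT_PROFILES
    acquisition: synthetic.AcquisitionConfig = synthetic.AcquisitionConfig()
    feature_config: feat.FeatureConfig = feat.FeatureConfig()
    train_config: bilstm.TrainConfig = bilstm.TrainConfig()
    n_per_class: int = 100
    train_fraction: float = 0.8
    test_fraction: float = 0.2
    walsh_order: int = 8
    noise_on_test: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1 and 0 < self.test_fraction < 1):
            raise ValueError("split fractions must lie in (0, 1)")
        if abs(self.train_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.n_per_class < 2:
            raise ValueError("need at least 2 samples per class to split")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "profiles" in raw:
            kwargs["profiles"] = tuple(
                synthetic.ClassProfile(**p) for p in raw.pop("profiles")
            )
        for key, ctor in (("acquisition", synthetic.AcquisitionConfig),
                          ("feature_config", feat.FeatureConfig),
                          ("train_config", bilstm.TrainConfig)):
            if key in raw:
                kwargs[key] = ctor(**raw.pop(key))
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvaluationReport:
    """Confusion counts and accuracies for one trained model."""

    model_name: str
    class_labels: list[str]
    confusion: np.ndarray  # rows: true, cols: predicted
    train_accuracy: float
    test_accuracy: float
    history: bilstm.TrainHistory = field(default_factory=bilstm.TrainHistory)

    @property
    def per_class_recall(self) -> np.ndarray:
        totals = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, np.diag(self.confusion) / totals, np.nan)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "class_labels": self.class_labels,
            "confusion": self.confusion.tolist(),
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "per_class_recall": self.per_class_recall.tolist(),
            "history_loss": self.history.loss,
            "history_accuracy": self.history.accuracy,
        }


def stratified_split(
    labels: np.ndarray, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled index split; disjoint and exhaustive."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        cut = int(round(train_fraction * idx.size))
        train_idx.append(idx[:cut])
        test_idx.append(idx[cut:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def confusion_and_accuracy(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int
) -> tuple[np.ndarray, float]:
    """counts[i, j] = samples with true class i predicted as j."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label sequences must have equal length")
    if t.size == 0:
        raise ValueError("label sequences must be non-empty")
    if t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
        raise ValueError("label out of range")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    return counts, float(np.trace(counts) / t.size)


def _preprocess_signal(sig: DLSignal, background: float, window: int = 5) -> DLSignal:
    return preprocess.moving_average(preprocess.subtract_background(sig, background), window)


def build_feature_table(
    signals: list[DLSignal],
    cfg: feat.FeatureConfig,
    background: float,
    smoothing_window: int = 5,
) -> tuple[np.ndarray, list[str]]:
    """Preprocess, fit and featurize every signal; returns (matrix, labels)."""
    rows = []
    labels = []
    for sig in signals:
        clean = _preprocess_signal(sig, background, smoothing_window)
        fit = fit_hyperbolic(clean)
        fv = feat.extract_features(clean, fit, cfg)
        rows.append(fv.values)
        labels.append(sig.meta.get("label", ""))
    return np.vstack(rows), labels


def _train_and_evaluate(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    train_cfg: bilstm.TrainConfig,
    codebook: Codebook | None,
    class_labels: list[str],
    test_noise_rng: np.random.Generator | None,
) -> EvaluationReport:
    t0 = time.perf_counter()
    model, history = bilstm.train(X_train, y_train, train_cfg, codebook)
    train_preds = bilstm.predict(model, X_train, codebook)
    X_eval = X_test
    if test_noise_rng is not None and train_cfg.feature_noise_sd > 0:
        X_eval = X_test + test_noise_rng.normal(
            0.0, train_cfg.feature_noise_sd, X_test.shape
        )
    test_preds = bilstm.predict(model, X_eval, codebook)
    n_classes = len(class_labels)
    _, train_acc = confusion_and_accuracy(y_train, train_preds, n_classes)
    confusion, test_acc = confusion_and_accuracy(y_test, test_preds, n_classes)
    log.info("model %s trained in %.1f s: train acc %.3f, test acc %.3f",
             name, time.perf_counter() - t0, train_acc, test_acc)
    return EvaluationReport(
        model_name=name,
        class_labels=class_labels,
        confusion=confusion,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        history=history,
    )


def run_experiment(config: ExperimentConfig) -> dict[str, EvaluationReport]:
    """Execute the full chain and return reports for both classifiers.

    A master seed spawns independent streams for data generation, the split,
    model training and test-time noise, so the whole run is deterministic and
    the two classifiers share every stochastic input.
    """
    ss = np.random.SeedSequence(config.seed)
    seed_data, seed_split, seed_train, seed_noise = (
        int(s.generate_state(1)[0]) for s in ss.spawn(4)
    )

    stage = "simulate"
    try:
        signals = synthetic.generate_dataset(
            config.profiles, config.n_per_class, config.acquisition, seed_data
        )
        stage = "featurize"
        X, str_labels = build_feature_table(
            signals, config.feature_config, config.acquisition.background
        )
        class_labels = sorted(set(str_labels))
        label_to_idx = {lbl: i for i, lbl in enumerate(class_labels)}
        y = np.array([label_to_idx[lbl] for lbl in str_labels])

        stage = "split"
        train_idx, test_idx = stratified_split(y, config.train_fraction, seed_split)

        stage = "normalize"
        stats = feat.zscore_fit(X[train_idx])
        X_train = feat.zscore_apply(X[train_idx], stats)
        X_test = feat.zscore_apply(X[test_idx], stats)
        y_train, y_test = y[train_idx], y[test_idx]

        stage = "train"
        train_cfg = replace(config.train_config, seed=seed_train)
        codebook = Codebook(num_classes=len(class_labels), order=config.walsh_order)
        reports = {}
        for name, codec in (("onehot", None), ("walsh", codebook)):
            noise_rng = (np.random.default_rng(seed_noise)
                         if config.noise_on_test else None)
            reports[name] = _train_and_evaluate(
                name, X_train, y_train, X_test, y_test, train_cfg, codec,
                class_labels, noise_rng,
            )
        return reports
    except Exception:
        log.error("experiment failed during stage %r", stage)
        raise


def write_reports(reports: dict[str, EvaluationReport], out_dir: str | Path,
                  seed: int) -> None:
    """Serialize reports as JSON plus confusion/history CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, report in reports.items():
        payload = report.to_dict()
        payload["seed"] = seed
        (out / f"report_{name}.json").write_text(json.dumps(payload, indent=2))
        pd.DataFrame(
            report.confusion, index=report.class_labels, columns=report.class_labels
        ).to_csv(out / f"confusion_{name}.csv")
        pd.DataFrame(
            {"loss": report.history.loss, "accuracy": report.history.accuracy}
        ).to_csv(out / f"history_{name}.csv", index_label="epoch")
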