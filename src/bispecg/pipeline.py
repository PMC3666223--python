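"""End-to-end experiment driver: signals -> features -> split -> ELM -> report.

For each record, the bispectrum is estimated over 1-second segments of the
whole record (record-level averaging), QPC peaks are detected in the
principal region, and the five-feature summary becomes the record's input
vector. Records are split 50/50 into train and test sets, stratified by
class and always at the record level — episodes of one record are strongly
dependent and must never straddle the split (the leakage guard asserts
this). Feature standardization is fit on the training records only. The
ELM (sigmoid hidden layer, linear outputs) is trained in one shot and
evaluated on the held-out records; accuracy is the headline metric, with
per-class recall and the full confusion matrix always attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .bispectrum import estimate_bispectrum, bicoherence
from .elm import ELMModel, LabeledFeatures, one_hot, predict, train_elm
from .exceptions import ConfigurationError, DataError, SplitError
from .qpc import FEATURE_NAMES, detect_qpc, extract_features
from .signal_io import Signal, demean

__all__ = [
    "ExperimentConfig",
    "EvaluationReport",
    "features_for_signals",
    "stratified_split",
    "run_experiment",
]

TASKS = ("af_classes", "af_vs_normal")
AF_LABELS = ("N", "S", "T")


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunables of one experiment; round-trips through a flat
    ``key = value`` text file."""

    task: str = "af_vs_normal"
    split_fraction: float = 0.5  # train fraction
    nfft: int = 128
    segment_seconds: float = 1.0
    overlap_fraction: float = 0.0
    window_name: str = "rao-gabr"
    rel_threshold: float = 0.1
    bicoh_floor: float = 0.3
    hidden: int = 20
    activation: str = "sigmoid"
    weight_scale: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.task not in TASKS:
            raise ConfigurationError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigurationError(
                f"split_fraction must be in (0, 1), got {self.split_fraction}"
            )

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str,
                 "bool": lambda s: s.strip().lower() in ("1", "true", "yes")}
        for i, raw in enumerate(Path(path).read_text().splitlines()):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}: line {i + 1} is not 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ConfigurationError(f"{path}: unknown key {key!r}")
            kwargs[key] = casts[types[key]](val)
        return cls(**kwargs)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class EvaluationReport:
    """Test-set evaluation of one experiment."""

    accuracy: float  # percent
    per_class_recall: dict[str, float]
    confusion: np.ndarray  # rows = true class, cols = predicted
    class_names: list[str]
    n_train: int
    n_test: int
    config_hash: str

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_recall": self.per_class_recall,
            "confusion_matrix": self.confusion.tolist(),
            "class_names": self.class_names,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "config_hash": self.config_hash,
        }


def record_features(signal: Signal, config: ExperimentConfig) -> tuple:
    """Five-feature vector (and peak count) for one record."""
    seg = int(round(config.segment_seconds * signal.fs))
    est = estimate_bispectrum(
        demean(signal),
        nfft=config.nfft,
        segment_samples=seg,
        overlap_fraction=config.overlap_fraction,
        window_name=config.window_name,
    )
    qpcs = detect_qpc(
        est,
        bicoherence(est),
        rel_threshold=config.rel_threshold,
        bicoh_floor=config.bicoh_floor,
    )
    return extract_features(qpcs)


def features_for_signals(
    signals: list[Signal], config: ExperimentConfig | None = None
) -> pd.DataFrame:
    """Feature table with columns record_id, label, energy, min, max, mean,
    std, n_peaks (the CSV schema of the feature export)."""
    config = config or ExperimentConfig()
    rows = []
    for sig in signals:
        fv = record_features(sig, config)
        rows.append(
            {
                "record_id": sig.record_id,
                "label": sig.label,
                **dict(zip(FEATURE_NAMES, fv.as_array())),
                "n_peaks": fv.n_peaks,
            }
        )
    return pd.DataFrame(rows)


def stratified_split(
    labels: list[str], train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Record-level stratified split; every class needs >= 2 records so both
    sides are non-empty."""
    labels = np.asarray(labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size < 2:
            raise SplitError(f"class {c!r} has {members.size} record(s); need >= 2")
        perm = rng.permutation(members)
        k = int(round(train_fraction * members.size))
        k = min(max(k, 1), members.size - 1)
        train_idx.extend(perm[:k])
        test_idx.extend(perm[k:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def _task_label(label: str | None, task: str) -> str | None:
    if label is None:
        return None
    if task == "af_vs_normal":
        return "AF" if label in AF_LABELS else "NORMAL"
    return label if label in AF_LABELS else None  # af_classes drops NORMAL


def run_experiment(
    config: ExperimentConfig,
    signals: list[Signal],
    out_dir: str | Path | None = None,
    features: pd.DataFrame | None = None,
) -> EvaluationReport:
    """Run the full experiment and return the evaluation report.

    ``features`` may carry a precomputed table from
    :func:`features_for_signals` (it is re-labeled for the task); otherwise
    features are extracted here. With ``out_dir`` set, the feature table,
    per-record predictions, JSON report, config and a parameter log are
    written there.
    """
    if features is None:
        features = features_for_signals(signals, config)
    feats = features.copy()
    feats["label"] = [_task_label(l, config.task) for l in feats["label"]]
    feats = feats[feats["label"].notna()].reset_index(drop=True)
    labels = feats["label"].tolist()
    if len(set(labels)) < 2:
        raise DataError(f"task {config.task!r} needs >= 2 classes, got {set(labels)}")

    rng = np.random.default_rng(config.seed)
    train_idx, test_idx = stratified_split(labels, config.split_fraction, rng)
    # leakage guard: no record id on both sides of the split
    ids = feats["record_id"].to_numpy()
    overlap = set(ids[train_idx]) & set(ids[test_idx])
    assert not overlap, f"split leakage: {sorted(overlap)[:5]}"

    X = feats[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    Y, class_names = one_hot(labels)
    data_train = LabeledFeatures(X[train_idx], Y[train_idx], class_names)
    model = train_elm(
        data_train,
        hidden=config.hidden,
        activation=config.activation,
        seed=config.seed,
        weight_scale=config.weight_scale,
        standardize=config.standardize,
    )
    pred_idx, raw = predict(model, X[test_idx])
    true_idx = Y[test_idx].argmax(axis=1)

    conf = _sk_confusion(true_idx, pred_idx, labels=np.arange(len(class_names)))
    n_test = len(test_idx)
    accuracy = 100.0 * np.trace(conf) / n_test
    recall = {}
    for c, name in enumerate(class_names):
        total = conf[c].sum()
        recall[name] = float(conf[c, c] / total) if total else float("nan")
    report = EvaluationReport(
        accuracy=float(accuracy),
        per_class_recall=recall,
        confusion=conf,
        class_names=class_names,
        n_train=len(train_idx),
        n_test=n_test,
        config_hash=config.hash(),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        pred_rows = pd.DataFrame(
            {
                "record_id": ids[test_idx],
                "true": [class_names[i] for i in true_idx],
                "predicted": [class_names[i] for i in pred_idx],
                **{f"raw_{name}": raw[:, c] for c, name in enumerate(class_names)},
            }
        )
        pred_rows.to_csv(out / "predictions.csv", index=False)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        config.to_file(out / "config.txt")
        (out / "run.log").write_text(
            "effective parameters\n"
            + "\n".join(
                f"{f.name} = {getattr(config, f.name)}"
                for f in dataclasses.fields(config)
            )
            + f"\nn_train = {report.n_train}\nn_test = {report.n_test}\n"
            + f"accuracy = {report.accuracy:.4f}\n"
        )
    return report
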