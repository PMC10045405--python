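"""Stratified 3-fold cross-validation and confusion-matrix metrics.

The positive class is *abnormal*, so sensitivity measures abnormal-sound
detection.  Reported metrics are accuracy, sensitivity (TPR), precision
(PPV), and specificity (TNR), each averaged over folds, plus balanced
accuracy (macro-averaged recall) as an auxiliary field.  A metric with a
zero denominator is reported as 0 together with an ``undefined`` flag —
never NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io_audio import Recording
from .model import HeadSpec, TrainConfig, build_model
from .selection import (
    SelectionResult,
    select_by_duration,
    select_by_gmm,
    select_by_snr,
    select_none,
)
from .signal_stats import SignalStats, stats_from_recordings
from .spectrogram import recording_to_image
from .io_audio import Manifest, ManifestEntry

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "stratified_kfold",
    "compute_metrics",
    "run_experiment",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "abnormal"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_from_predictions(
    labels, probabilities, threshold: float = 0.5
) -> ConfusionMatrix:
    """Count a confusion matrix from string labels and P(abnormal) scores."""
    tp = fn = tn = fp = 0
    for lab, p in zip(labels, probabilities):
        predicted_positive = p >= threshold
        actual_positive = lab == POSITIVE_LABEL
        if actual_positive and predicted_positive:
            tp += 1
        elif actual_positive:
            fn += 1
        elif predicted_positive:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def _safe_ratio(num: int, den: int, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, sensitivity, precision, specificity (+ balanced accuracy)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    sensitivity = _safe_ratio(cm.tp, cm.tp + cm.fn, "sensitivity", flags)
    precision = _safe_ratio(cm.tp, cm.tp + cm.fp, "precision", flags)
    specificity = _safe_ratio(cm.tn, cm.tn + cm.fp, "specificity", flags)
    metrics = {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "sensitivity": sensitivity,
        "precision": precision,
        "specificity": specificity,
        "balanced_accuracy": 0.5 * (sensitivity + specificity),
        "undefined": flags,
    }
    if flags:
        logger.warning("metrics with zero denominator reported as 0: %s", flags)
    return metrics


@dataclass
class EvalReport:
    """Per-fold confusion matrices and fold-averaged metrics."""

    per_fold: list[ConfusionMatrix]
    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    balanced_accuracy: float
    config: dict = field(default_factory=dict)

    @classmethod
    def from_folds(cls, folds: list[ConfusionMatrix], config: dict | None = None) -> "EvalReport":
        per_fold_metrics = [compute_metrics(cm) for cm in folds]
        mean = lambda key: float(np.mean([m[key] for m in per_fold_metrics]))
        return cls(
            per_fold=folds,
            accuracy=mean("accuracy"),
            sensitivity=mean("sensitivity"),
            precision=mean("precision"),
            specificity=mean("specificity"),
            balanced_accuracy=mean("balanced_accuracy"),
            config=config or {},
        )

    def as_row(self) -> dict:
        """Flat row in the benchmark column order."""
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
        }


def stratified_kfold(ids, labels, k: int = 3, seed: int = 42) -> list[tuple[list, list]]:
    """Seeded stratified partition; returns k (train_ids, test_ids) pairs."""
    ids = list(ids)
    labels = list(labels)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    too_small = {lab: c for lab, c in counts.items() if c < k}
    if too_small:
        raise ValueError(f"classes with fewer than k={k} examples: {too_small}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in splitter.split(np.zeros(len(ids)), labels):
        folds.append(([ids[i] for i in train_idx], [ids[i] for i in test_idx]))
    return folds


_SELECTORS = {
    "none": lambda stats, manifest, **kw: select_none(stats, manifest),
    "duration": select_by_duration,
    "snr": select_by_snr,
    "gmm": select_by_gmm,
}


def run_experiment(
    recordings: list[Recording],
    selection: str = "none",
    backbone: str = "tinycnn",
    cfg: TrainConfig | None = None,
    k: int = 3,
    pipeline_rate: int = 44100,
    selection_kwargs: dict | None = None,
    image_cache: dict | None = None,
) -> EvalReport:
    """Full pipeline: select -> image -> k-fold train/predict -> averaged report.

    ``recordings`` must carry labels.  ``image_cache`` (id -> raster) lets
    callers share the imaging step across experiment arms; missing entries
    are computed and stored.
    """
    cfg = cfg or TrainConfig(backbone=backbone)
    if selection not in _SELECTORS:
        raise ValueError(f"unknown selection {selection!r}; choose from {sorted(_SELECTORS)}")
    by_id = {rec.id: rec for rec in recordings}
    manifest = Manifest(
        entries=[ManifestEntry(id=r.id, path="", label=r.label) for r in recordings]
    )
    try:
        stats = stats_from_recordings(recordings)
    except Exception as exc:
        raise RuntimeError(f"stats stage failed: {exc}") from exc
    try:
        result: SelectionResult = _SELECTORS[selection](
            stats, manifest, **(selection_kwargs or {})
        )
    except Exception as exc:
        raise RuntimeError(f"selection stage failed: {exc}") from exc

    kept = result.kept_ids
    labels = {rec_id: by_id[rec_id].label for rec_id in kept}
    if image_cache is None:
        image_cache = {}
    try:
        for rec_id in kept:
            if rec_id not in image_cache:
                image_cache[rec_id] = recording_to_image(
                    by_id[rec_id], pipeline_rate=pipeline_rate
                ).pixels
    except Exception as exc:
        raise RuntimeError(f"imaging stage failed: {exc}") from exc

    folds: list[ConfusionMatrix] = []
    for train_ids, test_ids in stratified_kfold(
        kept, [labels[i] for i in kept], k=k, seed=cfg.seed
    ):
        model = build_model(backbone, HeadSpec(), cfg)
        model.fit([image_cache[i] for i in train_ids], [labels[i] for i in train_ids])
        probs = model.predict_proba([image_cache[i] for i in test_ids])
        folds.append(confusion_from_predictions([labels[i] for i in test_ids], probs))
    config = {
        "selection": selection,
        "backbone": backbone,
        "k": k,
        "pipeline_rate": pipeline_rate,
        "seed": cfg.seed,
        "epochs": cfg.epochs,
        "batch_size": cfg.batch_size,
        "learning_rate": cfg.learning_rate,
        "selection_params": result.params,
        "kept": len(kept),
        "per_class_kept": result.per_class_kept,
    }
    return EvalReport.from_folds(folds, config)
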