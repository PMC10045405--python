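"""Data-selection procedures: curate a corpus from its stats table.

Three selectors, each a pure function of (stats, manifest) that partitions
the manifest ids into kept and dropped sets:

* ``select_by_duration`` — keep recordings whose duration falls in a window
  around a per-class target (the most common duration per class, typically
  taken from the KDE mode: ~20 s for normal, ~35 s for abnormal corpora);
* ``select_by_snr`` — keep recordings with SNR >= threshold (inclusive;
  default 0 dB);
* ``select_by_gmm`` — fit a 2-component Gaussian mixture to the
  standardized (duration, SNR) features and keep the denser cluster,
  discarding the smaller "noise" cluster.

Selectors never re-read audio; they operate on the stats table alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .gmm import em_fit, hard_assign
from .io_audio import LABELS, Manifest
from .signal_stats import SignalStats

__all__ = [
    "SelectionResult",
    "select_none",
    "select_by_duration",
    "select_by_snr",
    "select_by_gmm",
    "chain_report",
]


@dataclass
class SelectionResult:
    """Outcome of one selection rule: a partition of the input ids."""

    method: str
    kept_ids: list[str]
    dropped_ids: list[str]
    per_class_kept: dict[str, int]
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "kept_ids": self.kept_ids,
                "dropped_ids": self.dropped_ids,
                "per_class_kept": self.per_class_kept,
                "params": self.params,
            },
            indent=2,
        )


def _stats_map(stats: list[SignalStats], manifest: Manifest) -> dict[str, SignalStats]:
    by_id = {s.id: s for s in stats}
    missing = [e.id for e in manifest.entries if e.id not in by_id]
    if missing:
        raise ValueError(f"missing stats for manifest ids: {missing}")
    return by_id


def _result(method: str, manifest: Manifest, keep: dict[str, bool], params: dict) -> SelectionResult:
    kept = [e.id for e in manifest.entries if keep[e.id]]
    dropped = [e.id for e in manifest.entries if not keep[e.id]]
    per_class = {label: 0 for label in LABELS}
    for e in manifest.entries:
        if keep[e.id]:
            per_class[e.label] += 1
    return SelectionResult(
        method=method, kept_ids=kept, dropped_ids=dropped, per_class_kept=per_class, params=params
    )


def select_none(stats: list[SignalStats], manifest: Manifest) -> SelectionResult:
    """Identity selector (the uncurated baseline arm)."""
    _stats_map(stats, manifest)
    return _result("none", manifest, {e.id: True for e in manifest.entries}, {})


def select_by_duration(
    stats: list[SignalStats],
    manifest: Manifest,
    target_normal_s: float,
    target_abnormal_s: float,
    tolerance_s: float = 2.5,
) -> SelectionResult:
    """Keep recordings within ``tolerance_s`` of their class's target duration."""
    by_id = _stats_map(stats, manifest)
    targets = {"normal": target_normal_s, "abnormal": target_abnormal_s}
    keep = {
        e.id: abs(by_id[e.id].duration_s - targets[e.label]) <= tolerance_s
        for e in manifest.entries
    }
    params = {
        "target_normal_s": target_normal_s,
        "target_abnormal_s": target_abnormal_s,
        "tolerance_s": tolerance_s,
    }
    return _result("kde_duration", manifest, keep, params)


def select_by_snr(
    stats: list[SignalStats], manifest: Manifest, threshold_db: float | None = 0.0
) -> SelectionResult:
    """Keep recordings with SNR >= threshold (inclusive); ``None`` keeps all."""
    by_id = _stats_map(stats, manifest)
    if threshold_db is None:
        keep = {e.id: True for e in manifest.entries}
    else:
        keep = {e.id: by_id[e.id].snr_db >= threshold_db for e in manifest.entries}
    return _result("snr_threshold", manifest, keep, {"threshold_db": threshold_db})


def select_by_gmm(
    stats: list[SignalStats],
    manifest: Manifest,
    seed: int = 42,
    tol: float = 1e-6,
    max_iter: int = 200,
    features: tuple[str, ...] = ("duration_s", "snr_db"),
) -> SelectionResult:
    """Keep the denser of two mixture components in standardized feature space.

    Cluster size is the number of hard-assigned members; a tie goes to the
    component with the larger mixture weight.
    """
    if len(manifest) < 2:
        raise ValueError("GMM selection needs at least 2 recordings")
    by_id = _stats_map(stats, manifest)
    ids = [e.id for e in manifest.entries]
    X = np.array([[getattr(by_id[i], f) for f in features] for i in ids])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant feature carries no cluster information
    Z = (X - mu) / sd
    model, resp = em_fit(Z, n_components=2, seed=seed, tol=tol, max_iter=max_iter)
    labels = hard_assign(resp)
    sizes = np.bincount(labels, minlength=2)
    if sizes[0] == sizes[1]:
        big = int(np.argmax(model.weights))
    else:
        big = int(np.argmax(sizes))
    keep = {rec_id: bool(labels[j] == big) for j, rec_id in enumerate(ids)}
    params = {
        "seed": seed,
        "features": list(features),
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "variances": model.variances.tolist(),
        "kept_component": big,
        "converged": model.converged,
    }
    return _result("gmm_cluster", manifest, keep, params)


def chain_report(results: list[SelectionResult]) -> dict:
    """Per-method kept counts, JSON-serializable."""
    return {
        r.method: {
            "kept_total": len(r.kept_ids),
            "dropped_total": len(r.dropped_ids),
            "per_class_kept": r.per_class_kept,
            "params": r.params,
        }
        for r in results
    }
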