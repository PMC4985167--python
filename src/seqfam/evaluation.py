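"""Confusion-matrix metrics and the staged tune/retrain/evaluate protocol.

Metrics are sensitivity SE = TP/(TP+FN), specificity SP = TN/(TN+FP) and
precision PR = TP/(TP+FP); an undefined ratio is reported as None
(not-applicable), never coerced to 0.

The protocol: hyperparameters are tuned on the testing partition, the model
is retrained on train+test, evaluated on the independent partition, and a
final model is retrained on all three partitions with the same
hyperparameters. Platt posterior calibration is attached to the final model
for the SVM method only; kNN and PNN report their native normalized scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix

from . import classifiers
from .classifiers import TrainedClassifier
from .dataset_builder import PARTITIONS, DatasetSplit
from .descriptors import (
    DescriptorConfig,
    PropertyGrouping,
    PropertyScale,
    feature_matrix,
    load_groupings,
    load_scales,
)
from .sequence_io import ProteinSequence


@dataclass
class EvaluationReport:
    """Independent-partition performance of one family x method model."""

    family_id: str
    method: str
    TP: int
    TN: int
    FP: int
    FN: int
    SE: float | None
    SP: float | None
    PR: float | None
    chosen_hyperparameters: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "family_id": self.family_id,
            "method": self.method,
            "TP": self.TP,
            "TN": self.TN,
            "FP": self.FP,
            "FN": self.FN,
            "SE": self.SE,
            "SP": self.SP,
            "PR": self.PR,
            "hyperparameters": _plain(self.chosen_hyperparameters),
        }


def _plain(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> tuple[int, int, int, int]:
    """Exact (TP, TN, FP, FN) counts for +/-1 labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.shape[0]}, y_pred has {y_pred.shape[0]}"
        )
    cm = confusion_matrix(y_true, y_pred, labels=[1, -1])
    tp, fn = int(cm[0, 0]), int(cm[0, 1])
    fp, tn = int(cm[1, 0]), int(cm[1, 1])
    return tp, tn, fp, fn


def metrics(counts: tuple[int, int, int, int]) -> tuple[float | None, float | None, float | None]:
    """(SE, SP, PR) from (TP, TN, FP, FN); undefined ratios are None."""
    tp, tn, fp, fn = counts
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    se = tp / (tp + fn) if (tp + fn) > 0 else None
    sp = tn / (tn + fp) if (tn + fp) > 0 else None
    pr = tp / (tp + fp) if (tp + fp) > 0 else None
    return se, sp, pr


def _partition_matrices(
    split: DatasetSplit,
    sequences: Mapping[str, ProteinSequence],
    config: DescriptorConfig,
    groupings: Mapping[str, PropertyGrouping] | None,
    scales: Mapping[str, PropertyScale] | None,
) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
    out = {}
    for part in PARTITIONS:
        pos = split.positives[part]
        neg = split.negatives[part]
        if not pos or not neg:
            raise ValueError(
                f"partition {part!r} of family {split.family_id!r} is missing a class "
                f"({len(pos)} positives, {len(neg)} negatives)"
            )
        ids = list(pos) + list(neg)
        X = feature_matrix([sequences[i] for i in ids], config, groupings, scales)
        y = np.array([1] * len(pos) + [-1] * len(neg), dtype=int)
        out[part] = (X, y, ids)
    return out


def run_protocol(
    split: DatasetSplit,
    sequences: Mapping[str, ProteinSequence],
    method: str,
    grid: Sequence[Mapping[str, Any]] | None = None,
    config: DescriptorConfig = DescriptorConfig(),
    groupings: Mapping[str, PropertyGrouping] | None = None,
    scales: Mapping[str, PropertyScale] | None = None,
    seed: int = 0,
) -> tuple[TrainedClassifier, EvaluationReport]:
    """Run the staged protocol and return (final model, report).

    Stages: (1) grid search on train vs test; (2) retrain on train+test
    with the chosen hyperparameters; (3) evaluate on the independent
    partition; (4) retrain the final model on all three partitions with the
    same hyperparameters. The report carries the independent-set metrics.
    """
    parts = _partition_matrices(split, sequences, config, groupings, scales)
    X_tr, y_tr, _ = parts["train"]
    X_te, y_te, _ = parts["test"]
    X_ind, y_ind, _ = parts["independent"]

    if grid is None:
        grid = classifiers.default_grid(method, y_tr)
    best, _ = classifiers.grid_search(method, X_tr, y_tr, X_te, y_te, grid)

    X_tt = np.vstack([X_tr, X_te])
    y_tt = np.concatenate([y_tr, y_te])
    stage2 = classifiers.train(method, X_tt, y_tt, **best)
    preds = classifiers.predict(stage2, X_ind)
    y_pred = np.array([p.label for p in preds])
    counts = confusion(y_ind, y_pred)
    se, sp, pr = metrics(counts)
    report = EvaluationReport(
        family_id=split.family_id,
        method=method,
        TP=counts[0],
        TN=counts[1],
        FP=counts[2],
        FN=counts[3],
        SE=se,
        SP=sp,
        PR=pr,
        chosen_hyperparameters=dict(best),
    )

    X_all = np.vstack([X_tt, X_ind])
    y_all = np.concatenate([y_tt, y_ind])
    final_params = dict(best)
    if method == "svm":
        final_params.update(platt=True, seed=seed)
    final = classifiers.train(method, X_all, y_all, **final_params)
    final.family_id = split.family_id
    final.config_digest = config.digest(
        groupings if groupings is not None else load_groupings(),
        scales if scales is not None else load_scales(),
    )
    return final, report


def write_reports_tsv(reports: Sequence[EvaluationReport], path: str | Path) -> None:
    """One row per family x method; columns per the report schema."""
    cols = ["family_id", "method", "TP", "TN", "FP", "FN", "SE", "SP", "PR", "hyperparameters"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            d = r.to_dict()
            row = [
                str(d["family_id"]),
                str(d["method"]),
                str(d["TP"]),
                str(d["TN"]),
                str(d["FP"]),
                str(d["FN"]),
                "NA" if d["SE"] is None else f"{d['SE']:.6f}",
                "NA" if d["SP"] is None else f"{d['SP']:.6f}",
                "NA" if d["PR"] is None else f"{d['PR']:.6f}",
                json.dumps(d["hyperparameters"], sort_keys=True),
            ]
            fh.write("\t".join(row) + "\n")


def write_reports_json(reports: Sequence[EvaluationReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)
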