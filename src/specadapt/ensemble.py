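"""Deep-ensemble confidence scoring and misclassification reports.

An ensemble of N independently seeded networks (default 5) predicts by
majority vote; the vote share of the winning class is the confidence score.
With five models a score of 0.6 means three of five agreed, 1.0 means all
did.  The reports reproduce the shape of the study's uncertainty tables:
per-confidence-bin correct/incorrect counts with within-bin percentages,
and a per-material breakdown of the errors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import TrainConfig
from .spectra_io import ALLERGEN_CLASSES, DomainSplit, SpectralDataset
from .training import TrainedModel

__all__ = [
    "EnsemblePrediction",
    "train_ensemble",
    "predict_with_confidence",
    "confidence_report",
    "ConfidenceReport",
    "misclassification_breakdown",
]


@dataclass(frozen=True)
class EnsemblePrediction:
    """Majority class, its vote share, and the raw per-model votes."""

    predicted_class: str
    confidence: float
    votes: tuple[str, ...]


def train_ensemble(
    trainer,
    split: DomainSplit,
    config: TrainConfig | None = None,
    n_models: int = 5,
) -> list[TrainedModel]:
    """Train ``n_models`` copies differing only by derived seeds.

    Model ``i`` uses ``config.seed + i``; data and every other
    hyperparameter are shared, so ensemble diversity comes purely from
    random initialization (and the batch/latent draws that follow from it).
    """
    if n_models < 2:
        raise ValueError(f"an ensemble needs at least 2 models, got {n_models}")
    config = config or TrainConfig()
    return [trainer(split, replace(config, seed=config.seed + i)) for i in range(n_models)]


def predict_with_confidence(
    models: list[TrainedModel], ds: SpectralDataset
) -> list[EnsemblePrediction]:
    """Majority-vote predictions with vote-share confidence per spectrum.

    Ties are broken toward the alphabetically first class name among the
    tied classes (deterministic; real five-model ensembles rarely tie).
    """
    dims = {m.suite.input_dim for m in models}
    if len(dims) != 1 or next(iter(dims)) != ds.intensities.shape[1]:
        raise ValueError(
            f"model input dims {sorted(dims)} do not all match the dataset "
            f"grid length {ds.intensities.shape[1]}"
        )
    all_votes = np.stack([m.predict(ds)[0] for m in models])  # (N, n) class names
    n_models = len(models)
    out = []
    for j in range(all_votes.shape[1]):
        votes = tuple(all_votes[:, j])
        # ALLERGEN_CLASSES is alphabetical, so first-max is the tie-break
        counts = [votes.count(c) for c in ALLERGEN_CLASSES]
        best = int(np.argmax(counts))
        out.append(
            EnsemblePrediction(
                predicted_class=ALLERGEN_CLASSES[best],
                confidence=counts[best] / n_models,
                votes=votes,
            )
        )
    return out


@dataclass
class ConfidenceReport:
    """Per-confidence-bin tallies of ensemble predictions.

    ``counts``/``percentages`` have rows correct/incorrect/total and one
    column per occupied confidence bin plus a ``total`` column; within-bin
    percentages are 100 * count / bin total.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    overall_accuracy: float
    flagged: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """Interleaved count/percentage table (the published layout)."""
        cols = {}
        for bin_col in self.counts.columns:
            cols[(str(bin_col), "count")] = self.counts[bin_col]
            if bin_col != "total":
                cols[(str(bin_col), "percentage")] = self.percentages[bin_col]
        return pd.DataFrame(cols)


def confidence_report(
    preds: list[EnsemblePrediction],
    truths,
    flag_threshold: float | None = None,
) -> ConfidenceReport:
    """Tabulate prediction correctness per occupied confidence bin.

    ``flag_threshold`` optionally attaches the indices of predictions at or
    above a confidence level (e.g. 0.8), the alerting rule an in-line
    deployment would act on.
    """
    truths = np.asarray(truths, dtype=object)
    if len(preds) != len(truths):
        raise ValueError(
            f"got {len(preds)} predictions but {len(truths)} true labels"
        )
    correct = np.array([p.predicted_class == t for p, t in zip(preds, truths)])
    confidence = np.array([p.confidence for p in preds])
    bins = sorted(set(confidence))
    counts = pd.DataFrame(
        0, index=["correct", "incorrect", "total"], columns=bins + ["total"]
    )
    for b in bins:
        in_bin = confidence == b
        counts.loc["correct", b] = int((correct & in_bin).sum())
        counts.loc["incorrect", b] = int((~correct & in_bin).sum())
        counts.loc["total", b] = int(in_bin.sum())
    counts["total"] = counts[bins].sum(axis=1)
    totals = counts.loc["total"].replace(0, np.nan)
    percentages = (100.0 * counts / totals).round(1)
    overall = round(
        100.0 * counts.loc["correct", "total"] / counts.loc["total", "total"], 2
    )
    flagged = None
    if flag_threshold is not None:
        idx = np.nonzero(confidence >= flag_threshold)[0]
        flagged = pd.DataFrame(
            {
                "index": idx,
                "predicted_class": [preds[i].predicted_class for i in idx],
                "confidence": confidence[idx],
                "correct": correct[idx],
            }
        )
    return ConfidenceReport(
        counts=counts,
        percentages=percentages,
        overall_accuracy=float(overall),
        flagged=flagged,
    )


def misclassification_breakdown(
    preds: list[EnsemblePrediction], truths, material_ids
) -> pd.DataFrame:
    """One row per (material, predicted class) among the errors.

    Columns: material, true class, predicted class, frequency, and the
    confidence scores of those errors sorted descending.
    """
    truths = np.asarray(truths, dtype=object)
    material_ids = np.asarray(material_ids, dtype=object)
    if not (len(preds) == len(truths) == len(material_ids)):
        raise ValueError("predictions, truths and material ids differ in length")
    rows: dict[tuple[str, str], dict] = {}
    for p, truth, material in zip(preds, truths, material_ids):
        if p.predicted_class == truth:
            continue
        key = (material, p.predicted_class)
        entry = rows.setdefault(
            key,
            {
                "material_id": material,
                "true_class": truth,
                "predicted_class": p.predicted_class,
                "frequency": 0,
                "confidences": [],
            },
        )
        entry["frequency"] += 1
        entry["confidences"].append(p.confidence)
    records = []
    for key in sorted(rows):
        entry = rows[key]
        entry["confidences"] = tuple(sorted(entry["confidences"], reverse=True))
        records.append(entry)
    return pd.DataFrame(
        records,
        columns=[
            "material_id",
            "true_class",
            "predicted_class",
            "frequency",
            "confidences",
        ],
    )
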