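"""Functional training interface over :class:`DomainAdaptationModel`.

Each trainer takes a :class:`~specadapt.spectra_io.DomainSplit` and a
:class:`~specadapt.model.TrainConfig` and returns a fitted
:class:`TrainedModel` (alias of
:class:`~specadapt.model.DomainAdaptationResults`).
"""

from __future__ import annotations

import numpy as np

from .model import (
    DomainAdaptationModel,
    DomainAdaptationResults,
    TrainConfig,
    adversarial_transform,
)
from .spectra_io import DomainSplit, SpectralDataset

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "adversarial_transform",
    "train_transfer_baseline",
    "train_dann",
    "train_sgan",
    "train_combined",
    "predict",
    "TRAINERS",
]

TrainedModel = DomainAdaptationResults


def train_transfer_baseline(
    split: DomainSplit, config: TrainConfig | None = None
) -> TrainedModel:
    """Cross-entropy training on labelled data only (no domain adaptation)."""
    return DomainAdaptationModel(split, "TL", config).fit()


def train_dann(split: DomainSplit, config: TrainConfig | None = None) -> TrainedModel:
    """Domain-adversarial training (three sequential steps per iteration)."""
    return DomainAdaptationModel(split, "DANN", config).fit()


def train_sgan(split: DomainSplit, config: TrainConfig | None = None) -> TrainedModel:
    """Semisupervised GAN training (classification plus three real/fake
    steps per iteration)."""
    return DomainAdaptationModel(split, "SGAN", config).fit()


def train_combined(
    split: DomainSplit, config: TrainConfig | None = None
) -> TrainedModel:
    """DANN and SGAN schedules around a single classification step."""
    return DomainAdaptationModel(split, "SGAN+DANN", config).fit()


#: Method tag -> trainer, in the column order used by the experiment grid.
TRAINERS = {
    "SGAN+DANN": train_combined,
    "SGAN": train_sgan,
    "DANN": train_dann,
    "TL": train_transfer_baseline,
}


def predict(
    model: TrainedModel, ds: SpectralDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spectrum predicted class names and probability rows."""
    return model.predict(ds)
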