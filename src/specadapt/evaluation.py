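"""Experiment grid: method x speed x sensor x labelled-instance count.

Reproduces the study's benchmark layout: for every requested combination a
domain split is built, a model is trained by the requested method and its
accuracy on the held-out moving-condition test set is recorded.  Cells are
independently reproducible from their recorded per-cell seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TrainConfig
from .spectra_io import SpectralDataset, make_domain_split
from .training import TRAINERS

__all__ = ["accuracy", "run_experiment_grid", "ExperimentGrid"]


def accuracy(preds, truths) -> float:
    """Percentage of correct predictions, reported to 2 decimals."""
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    if len(preds) == 0:
        raise ValueError("cannot compute accuracy of zero predictions")
    if len(preds) != len(truths):
        raise ValueError(
            f"got {len(preds)} predictions but {len(truths)} true labels"
        )
    return round(100.0 * float(np.mean(preds == truths)), 2)


@dataclass
class ExperimentGrid:
    """Result container: one row per requested cell.

    ``cells`` columns: method, speed, sensor, labelled, accuracy, seed,
    status ("ok"/"failed"), reason.
    """

    cells: pd.DataFrame
    base_seed: int
    config: TrainConfig = field(default_factory=TrainConfig)

    def pivot(self) -> pd.DataFrame:
        """Accuracy matrix with (sensor, speed) rows and (method, labelled)
        columns — the published benchmark layout."""
        ok = self.cells[self.cells["status"] == "ok"]
        return ok.pivot_table(
            index=["sensor", "speed"],
            columns=["method", "labelled"],
            values="accuracy",
            sort=False,
        )

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.pivot().to_csv(path)
        return path

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "base_seed": self.base_seed,
            "cells": self.cells.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _cell_seed(base_seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, index]).generate_state(1)[0] & 0x7FFFFFFF
    )


def run_experiment_grid(
    datasets: dict[tuple[str, str], tuple[SpectralDataset, SpectralDataset]],
    methods=("SGAN+DANN", "SGAN", "DANN", "TL"),
    speeds=("slow", "medium", "fast"),
    sensors=("both", "S2.0", "S2.5"),
    labelled=("none", "single"),
    config: TrainConfig | None = None,
    base_seed: int = 0,
    trainers=None,
) -> ExperimentGrid:
    """Train and evaluate every requested (method, speed, sensor, labelled)
    cell.

    ``datasets`` maps ``(speed, sensor)`` to a (static, moving) dataset
    pair.  A missing pair marks the affected cells as failed and the run
    continues.  Each cell derives its own seed from ``base_seed`` and its
    position in the request, so any cell can be re-run alone.  ``trainers``
    may override the method registry (useful for smoke tests with stub
    trainers).
    """
    config = config or TrainConfig()
    trainers = trainers or TRAINERS
    unknown = [m for m in methods if m not in trainers]
    if unknown:
        raise ValueError(f"unknown methods {unknown}")
    if any(l not in ("none", "single") for l in labelled):
        raise ValueError("labelled options must be 'none' or 'single'")

    rows = []
    index = 0
    for sensor in sensors:
        for speed in speeds:
            for method in methods:
                for lab in labelled:
                    seed = _cell_seed(base_seed, index)
                    index += 1
                    cell = {
                        "method": method,
                        "speed": speed,
                        "sensor": sensor,
                        "labelled": lab,
                        "seed": seed,
                        "accuracy": np.nan,
                        "status": "ok",
                        "reason": "",
                    }
                    pair = datasets.get((speed, sensor))
                    if pair is None:
                        cell["status"] = "failed"
                        cell["reason"] = f"no dataset for ({speed}, {sensor})"
                        rows.append(cell)
                        continue
                    try:
                        static_ds, moving_ds = pair
                        split = make_domain_split(
                            static_ds,
                            moving_ds,
                            n_labelled_per_unit=1 if lab == "single" else 0,
                            seed=seed,
                        )
                        result = trainers[method](split, replace(config, seed=seed))
                        truth = split.target_test.meta["allergen_class"].to_numpy()
                        preds, _ = result.predict(split.target_test)
                        cell["accuracy"] = accuracy(preds, truth)
                    except Exception as exc:  # keep the grid running
                        cell["status"] = "failed"
                        cell["reason"] = f"{type(exc).__name__}: {exc}"
                    rows.append(cell)
    return ExperimentGrid(cells=pd.DataFrame(rows), base_seed=base_seed, config=config)
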