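"""Global interpretability: per-wavelength permutation importance.

Shuffling one wavelength's intensity values across samples destroys any
information that wavelength carries while leaving its marginal distribution
intact; the resulting drop in classification accuracy is that wavelength's
importance.  Contiguous runs of high-importance wavelengths are then merged
into ranked ranges, the form in which NIR practitioners read the result
(absorption bands, not single nanometres).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import ALLERGEN_CLASSES, SpectralDataset
from .training import TrainedModel

__all__ = [
    "ImportanceProfile",
    "ImportantRange",
    "permutation_importance",
    "extract_important_ranges",
    "plot_importance",
]


@dataclass(frozen=True)
class ImportantRange:
    """A contiguous wavelength range (inclusive, nm) and its mean accuracy
    drop in percentage points."""

    start: int
    end: int
    mean_importance: float

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class ImportanceProfile:
    """Per-wavelength permutation-importance results.

    ``importance`` is the baseline accuracy minus the mean accuracy over
    ``n_repeats`` column shuffles, in percentage points; negative values
    are permutation noise.
    """

    wavelengths: np.ndarray
    baseline_accuracy: float
    permuted_accuracy: np.ndarray
    importance: np.ndarray
    n_repeats: int
    ranges: list[ImportantRange] = field(default_factory=list)


def _as_label_fn(predictor):
    """Normalize the predictor argument to a ``X -> class-index`` function.

    Accepts a single fitted model, a list of models (majority vote with
    alphabetical tie-break), or any callable mapping an intensity matrix to
    integer class indices or class-name strings.
    """
    lut = {c: i for i, c in enumerate(ALLERGEN_CLASSES)}

    def normalize(labels):
        labels = np.asarray(labels)
        if labels.dtype.kind in "OU":
            return np.array([lut[l] for l in labels])
        return labels.astype(int)

    if isinstance(predictor, TrainedModel):
        predictor = [predictor]
    if isinstance(predictor, (list, tuple)):
        models = list(predictor)

        def vote(x):
            counts = np.zeros((len(x), len(ALLERGEN_CLASSES)), dtype=int)
            for m in models:
                p = m.predict_proba(x)
                counts[np.arange(len(x)), p.argmax(axis=1)] += 1
            return counts.argmax(axis=1)

        return vote, models
    if callable(predictor):
        return (lambda x: normalize(predictor(x))), None
    raise TypeError(f"cannot use {type(predictor).__name__} as a predictor")


def permutation_importance(
    predictor,
    ds: SpectralDataset,
    n_repeats: int = 10,
    seed: int = 0,
) -> ImportanceProfile:
    """Accuracy drop caused by shuffling each wavelength column.

    For every wavelength the column is shuffled across spectra
    ``n_repeats`` times (a fresh permutation each repeat), predictions are
    recomputed and the importance is the baseline accuracy minus the mean
    permuted accuracy, in percentage points.  For the fitted networks used
    here only the first dense layer touches the input, so each shuffle is
    evaluated through a rank-one update of the first-layer pre-activation
    rather than a full forward pass.
    """
    if len(ds) < 2:
        raise ValueError(
            "permutation importance needs at least 2 spectra (shuffling a "
            "single row is the identity)"
        )
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    label_fn, models = _as_label_fn(predictor)
    rng = np.random.default_rng(seed)
    x = ds.intensities
    truth = np.array(
        [dict(zip(ALLERGEN_CLASSES, range(5)))[c] for c in ds.meta["allergen_class"]]
    )
    n, p = x.shape

    def acc(pred_idx):
        return 100.0 * float(np.mean(pred_idx == truth))

    if models is not None:
        # fast path: cache standardized inputs and first-layer pre-activations
        caches = []
        for m in models:
            xs = ((x - m.mu) / m.sd).astype(np.float32)
            z1 = m.suite.feature_extractor.first_preact(xs)
            caches.append((m, xs, z1))

        def predict_permuted(j, perm):
            counts = np.zeros((n, len(ALLERGEN_CLASSES)), dtype=int)
            for m, xs, z1 in caches:
                delta = xs[perm, j] - xs[:, j]
                w1j = m.suite.feature_extractor.params[0][j]
                feats = m.suite.feature_extractor.forward_from_preact(
                    z1 + np.outer(delta, w1j)
                )
                logits, _ = m.suite.classifier_head.forward(feats)
                counts[np.arange(n), logits.argmax(axis=1)] += 1
            return counts.argmax(axis=1)

        baseline = acc(predict_permuted(0, np.arange(n)))
    else:

        def predict_permuted(j, perm):
            xp = x.copy()
            xp[:, j] = xp[perm, j]
            return label_fn(xp)

        baseline = acc(label_fn(x))

    permuted = np.zeros(p)
    for j in range(p):
        total = 0.0
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            total += acc(predict_permuted(j, perm))
        permuted[j] = total / n_repeats

    return ImportanceProfile(
        wavelengths=ds.grid.copy(),
        baseline_accuracy=baseline,
        permuted_accuracy=permuted,
        importance=baseline - permuted,
        n_repeats=n_repeats,
    )


def extract_important_ranges(
    profile: ImportanceProfile,
    threshold_sd: float = 2.0,
    min_width: int = 5,
) -> list[ImportantRange]:
    """Merge high-importance wavelengths into ranked contiguous ranges.

    Grid points whose importance exceeds ``mean + threshold_sd * sd`` (over
    all points) are merged into maximal runs of consecutive nanometres at
    least ``min_width`` nm wide, ranked by descending mean importance.
    Runs never bridge the physical gap between the two sensor grids
    (1950 -> 2000 nm) because contiguity is measured in nm.
    """
    imp = profile.importance
    wl = profile.wavelengths
    cut = imp.mean() + threshold_sd * imp.std()
    mask = imp > cut
    ranges = []
    i = 0
    while i < len(wl):
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(wl) and mask[j + 1] and wl[j + 1] == wl[j] + 1:
            j += 1
        width = int(wl[j] - wl[i] + 1)
        if width >= min_width:
            ranges.append(
                ImportantRange(
                    start=int(wl[i]),
                    end=int(wl[j]),
                    mean_importance=float(imp[i : j + 1].mean()),
                )
            )
        i = j + 1
    ranges.sort(key=lambda r: r.mean_importance, reverse=True)
    return ranges


def plot_importance(profile: ImportanceProfile, ax=None):
    """Plot the importance profile with any extracted ranges shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    # break the line at the inter-sensor gap
    gaps = np.nonzero(np.diff(profile.wavelengths) != 1)[0]
    start = 0
    for g in list(gaps) + [len(profile.wavelengths) - 1]:
        ax.plot(
            profile.wavelengths[start : g + 1],
            profile.importance[start : g + 1],
            color="C0",
        )
        start = g + 1
    for r in profile.ranges:
        ax.axvspan(r.start, r.end, color="C1", alpha=0.3)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("accuracy drop (pp)")
    ax.set_title("Permutation wavelength importance")
    return ax
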