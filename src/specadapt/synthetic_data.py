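"""Synthetic paired stationary/moving NIR spectra.

Real production-line data for this problem are not publicly released, so the
toolkit ships a generator that emulates their structure: 19 food-powder
materials (three of them in three brands, 25 material-brand units in total)
spanning five allergen classes, five physical samples per unit and ten
replicate spectra per sample, measured both stationary and at conveyor
speeds.  Each unit's template spectrum is a Gaussian band mixture over a
linear baseline, with band positions tied to the compositional motifs NIR
actually sees: carbohydrate O-H first overtone near 1569-1604 nm, long-chain
fatty-acid CH2 first overtone near 1725-1750 nm, water O-H bands near
1931-1951 nm and a protein band near 2111-2132 nm.  Units of the same
allergen class share class-motif band amplitudes and differ by unit-specific
perturbations; brands differ by a baseline offset.

Motion is modelled as a multiplicative gain, an additive baseline offset and
inflated measurement noise — the phenomenology reported for moving samples
(peak-intensity changes and increased spectral noise):

    intensity(lambda) = g_s * [baseline(lambda) + sum_b A_b *
                         exp(-(lambda - c_b)^2 / (2 w_b^2))] + o_s + eps,
    eps ~ Normal(0, (sigma0 * m_s)^2) i.i.d. per grid point.

Randomness is organized as a splittable seed hierarchy
(library -> unit -> sample -> replicate) so any subset regenerates
independently from one global integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import (
    ALLERGEN_CLASSES,
    MATERIAL_ALLERGEN,
    META_COLUMNS,
    SpectralDataset,
    material_units,
    sensor_grid,
)

__all__ = [
    "Band",
    "UnitTemplate",
    "MaterialLibrary",
    "MotionShiftParams",
    "default_material_library",
    "default_motion_shift",
    "simulate_spectrum",
    "simulate_domain_pair",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: center and width in nm, amplitude in
    arbitrary intensity units."""

    center: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class UnitTemplate:
    """Noise-free template spectrum of one material-brand unit."""

    material_id: str
    brand_id: int
    allergen_class: str
    bands: tuple[Band, ...]
    baseline_intercept: float
    baseline_slope: float

    def template(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate baseline + band mixture on a wavelength grid (nm)."""
        grid = np.asarray(grid, dtype=float)
        y = self.baseline_intercept + self.baseline_slope * (grid - 2000.0)
        for b in self.bands:
            y = y + b.amplitude * np.exp(-((grid - b.center) ** 2) / (2 * b.width**2))
        return y

    def to_dict(self) -> dict:
        return {
            "material_id": self.material_id,
            "brand_id": self.brand_id,
            "allergen_class": self.allergen_class,
            "bands": [[b.center, b.width, b.amplitude] for b in self.bands],
            "baseline_intercept": self.baseline_intercept,
            "baseline_slope": self.baseline_slope,
        }


@dataclass
class MaterialLibrary:
    """The 25 unit templates plus the seed they were generated from."""

    units: list[UnitTemplate]
    seed: int

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted({u.allergen_class for u in self.units}))

    def to_dict(self) -> dict:
        return {"seed": self.seed, "units": [u.to_dict() for u in self.units]}


# Class-motif band amplitudes (a.u.) at the four compositional band centers.
# Rows are allergen classes; the relative pattern is what makes classes
# separable (flours are carbohydrate-rich, nut powders fat-rich, egg powders
# protein-rich, gluten vs gluten-free flours differ mainly in protein).
_MOTIF_CENTERS = {"carbohydrate": 1586.0, "fat": 1737.0, "water": 1941.0, "protein": 2121.0}
_MOTIF_WIDTHS = {"carbohydrate": 14.0, "fat": 10.0, "water": 9.0, "protein": 9.0}
_CLASS_MOTIFS = {
    "egg": {"carbohydrate": 0.05, "fat": 0.40, "water": 0.50, "protein": 0.80},
    "gluten": {"carbohydrate": 0.90, "fat": 0.12, "water": 0.40, "protein": 0.50},
    "gluten-free": {"carbohydrate": 1.00, "fat": 0.18, "water": 0.45, "protein": 0.12},
    "peanut": {"carbohydrate": 0.30, "fat": 0.90, "water": 0.25, "protein": 0.45},
    "tree nut": {"carbohydrate": 0.45, "fat": 0.80, "water": 0.30, "protein": 0.28},
}


def default_material_library(seed: int = 0, separation: float = 1.0) -> MaterialLibrary:
    """Build the 25-unit library deterministically from ``seed``.

    ``separation`` scales how far each class's motif amplitudes sit from the
    across-class mean: 0 collapses all classes onto one template family
    (classification impossible), 1 is the default, larger values make
    classes easier to separate.
    """
    ss = np.random.SeedSequence(seed)
    unit_seeds = ss.spawn(len(material_units()))
    grand_mean = {
        m: float(np.mean([v[m] for v in _CLASS_MOTIFS.values()]))
        for m in _MOTIF_CENTERS
    }
    units = []
    for (material, brand), child in zip(material_units(), unit_seeds):
        rng = np.random.default_rng(child)
        cls = MATERIAL_ALLERGEN[material]
        bands = []
        for motif, center in _MOTIF_CENTERS.items():
            base_amp = grand_mean[motif] + separation * (
                _CLASS_MOTIFS[cls][motif] - grand_mean[motif]
            )
            amp = max(base_amp * (1.0 + rng.normal(0.0, 0.08)), 0.0)
            bands.append(
                Band(
                    center=center + rng.normal(0.0, 3.0),
                    width=_MOTIF_WIDTHS[motif] * (1.0 + rng.normal(0.0, 0.10)),
                    amplitude=amp,
                )
            )
        # one unit-specific minor band so units within a class are not clones
        bands.append(
            Band(
                center=float(rng.uniform(1560.0, 2440.0)),
                width=float(rng.uniform(8.0, 20.0)),
                amplitude=float(abs(rng.normal(0.0, 0.06))),
            )
        )
        intercept = float(rng.uniform(0.35, 0.55)) + 0.015 * (brand - 1)
        slope = float(rng.normal(0.0, 2e-4))
        units.append(
            UnitTemplate(
                material_id=material,
                brand_id=brand,
                allergen_class=cls,
                bands=tuple(bands),
                baseline_intercept=intercept,
                baseline_slope=slope,
            )
        )
    return MaterialLibrary(units=units, seed=seed)


@dataclass
class MotionShiftParams:
    """Speed-dependent distortion of moving spectra relative to stationary.

    Per speed: multiplicative gain ``g``, additive baseline offset ``o``
    (a.u.) and a noise multiplier ``m`` applied to the base noise level
    ``sigma0``.  The static condition is fixed at (1, 0, 1).  ``unit_jitter_sd``
    optionally perturbs the gain per material-brand unit (off by default).
    """

    gain: dict = field(
        default_factory=lambda: {
            "static": 1.0, "slow": 0.87, "medium": 0.845, "fast": 0.825,
        }
    )
    offset: dict = field(
        default_factory=lambda: {
            "static": 0.0, "slow": 0.11, "medium": 0.135, "fast": 0.155,
        }
    )
    noise_mult: dict = field(
        default_factory=lambda: {
            "static": 1.0, "slow": 2.5, "medium": 3.0, "fast": 3.3,
        }
    )
    sigma0: float = 0.035
    unit_jitter_sd: float = 0.0

    def __post_init__(self):
        speeds = ["slow", "medium", "fast"]
        ms = [self.noise_mult[s] for s in speeds]
        if any(m2 < m1 for m1, m2 in zip(ms, ms[1:])):
            raise ValueError("noise multiplier must be nondecreasing with speed")
        if any(m < 1.0 for m in ms) or self.sigma0 < 0:
            raise ValueError("noise parameters must be >= their static values")

    def for_speed(self, speed: str) -> tuple[float, float, float]:
        if speed not in self.gain:
            raise ValueError(f"unknown speed tag {speed!r}")
        return self.gain[speed], self.offset[speed], self.noise_mult[speed]

    @staticmethod
    def null() -> "MotionShiftParams":
        """No distortion at any speed (moving == static in distribution)."""
        one = {"static": 1.0, "slow": 1.0, "medium": 1.0, "fast": 1.0}
        zero = {"static": 0.0, "slow": 0.0, "medium": 0.0, "fast": 0.0}
        return MotionShiftParams(gain=dict(one), offset=dict(zero), noise_mult=dict(one))

    def to_dict(self) -> dict:
        return {
            "gain": dict(self.gain),
            "offset": dict(self.offset),
            "noise_mult": dict(self.noise_mult),
            "sigma0": self.sigma0,
            "unit_jitter_sd": self.unit_jitter_sd,
        }


def default_motion_shift() -> MotionShiftParams:
    """The frozen default shift magnitudes used throughout the test-bench."""
    return MotionShiftParams()


def simulate_spectrum(
    unit: UnitTemplate,
    speed: str,
    shift: MotionShiftParams,
    rng: np.random.Generator,
    sensor: str = "both",
    sample_offset: float = 0.0,
) -> np.ndarray:
    """Draw one noisy spectrum of ``unit`` under a motion condition.

    ``sample_offset`` is an intercept perturbation shared by all replicates
    of one physical sample; it sits inside the gain (a property of the
    sample, not of the motion).  Returns the intensity vector on the grid of
    ``sensor``.
    """
    g, o, m = shift.for_speed(speed)
    grid = sensor_grid(sensor)
    clean = unit.template(grid) + sample_offset
    noise = rng.normal(0.0, shift.sigma0 * m, size=grid.shape)
    return g * clean + o + noise


def simulate_domain_pair(
    library: MaterialLibrary,
    speed: str,
    n_samples: int = 5,
    n_replicates: int = 10,
    shift: MotionShiftParams | None = None,
    sensor: str = "both",
    seed: int = 0,
    sample_offset_sd: float = 0.015,
) -> tuple[SpectralDataset, SpectralDataset]:
    """Simulate matched stationary and moving datasets.

    Every material-brand unit contributes ``n_samples * n_replicates``
    spectra per condition.  Each physical sample carries a random intercept
    offset shared by its replicates and by both conditions (the same sample
    is measured stationary and moving); replicate noise is i.i.d.  The whole
    draw is deterministic from ``seed``.
    """
    if len(library) == 0:
        raise ValueError("empty material library")
    if n_samples < 1 or n_replicates < 1:
        raise ValueError("n_samples and n_replicates must be >= 1")
    if shift is None:
        shift = default_motion_shift()
    if speed not in ("slow", "medium", "fast"):
        raise ValueError(f"moving speed must be slow/medium/fast, got {speed!r}")

    grid = sensor_grid(sensor)
    rows_static, rows_moving = [], []
    int_static, int_moving = [], []
    unit_seeds = np.random.SeedSequence(seed).spawn(len(library))
    for unit, unit_ss in zip(library, unit_seeds):
        unit_shift = shift
        jitter_ss, *sample_seeds = unit_ss.spawn(n_samples + 1)
        if shift.unit_jitter_sd > 0:
            jrng = np.random.default_rng(jitter_ss)
            factor = 1.0 + jrng.normal(0.0, shift.unit_jitter_sd)
            unit_shift = MotionShiftParams(
                gain={k: v * factor if k != "static" else v for k, v in shift.gain.items()},
                offset=dict(shift.offset),
                noise_mult=dict(shift.noise_mult),
                sigma0=shift.sigma0,
                unit_jitter_sd=0.0,
            )
        for sample_id, sample_ss in enumerate(sample_seeds, start=1):
            off_ss, static_ss, moving_ss = sample_ss.spawn(3)
            offset = float(
                np.random.default_rng(off_ss).normal(0.0, sample_offset_sd)
            )
            rng_s = np.random.default_rng(static_ss)
            rng_m = np.random.default_rng(moving_ss)
            for replicate_id in range(1, n_replicates + 1):
                int_static.append(
                    simulate_spectrum(unit, "static", unit_shift, rng_s, sensor, offset)
                )
                int_moving.append(
                    simulate_spectrum(unit, speed, unit_shift, rng_m, sensor, offset)
                )
                for rows, tag in ((rows_static, "static"), (rows_moving, speed)):
                    rows.append(
                        {
                            "material_id": unit.material_id,
                            "brand_id": unit.brand_id,
                            "allergen_class": unit.allergen_class,
                            "domain_tag": tag,
                            "sensor_tag": sensor,
                            "sample_id": sample_id,
                            "replicate_id": replicate_id,
                        }
                    )

    def build(rows, intensities):
        meta = pd.DataFrame(rows, columns=list(META_COLUMNS))
        return SpectralDataset(grid.copy(), np.array(intensities), meta)

    return build(rows_static, int_static), build(rows_moving, int_moving)
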