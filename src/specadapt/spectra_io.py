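"""Spectral tables, sensor grids and source/target domain splits.

The toolkit works on wide-format tables of 1D near-infrared spectra from two
sensor grids (S2.0: 1550-1950 nm, S2.5: 2000-2450 nm, both at 1 nm
resolution).  Each record carries the food-powder material it was measured
from, the brand, the allergen class of the material, and the motion
condition (static or one of three conveyor speeds) under which it was
acquired.  The :class:`DomainSplit` built here drives every trainer: static
spectra are the labelled source domain, moving spectra are split into an
unlabelled training pool and a held-out test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ALLERGEN_CLASSES",
    "MATERIAL_ALLERGEN",
    "MULTI_BRAND_MATERIALS",
    "DOMAIN_TAGS",
    "SPEED_MS",
    "META_COLUMNS",
    "sensor_grid",
    "Spectrum",
    "SpectralDataset",
    "DomainSplit",
    "read_spectra_table",
    "write_spectra_table",
    "combine_sensors",
    "make_domain_split",
]

#: The five allergen classes, in the fixed (alphabetical) label order used
#: for class indices and for deterministic tie-breaking everywhere.
ALLERGEN_CLASSES = ("egg", "gluten", "gluten-free", "peanut", "tree nut")

#: The 19 food-powder materials and the allergen class each belongs to.
MATERIAL_ALLERGEN: dict[str, str] = {
    "spelt flour": "gluten",
    "rye flour": "gluten",
    "buckwheat flour": "gluten",
    "oat flour": "gluten",
    "barley flour": "gluten",
    "brown flour": "gluten",
    "wheat flour": "gluten",
    "wheat gluten flour": "gluten",
    "gluten-free white flour": "gluten-free",
    "coconut flour": "gluten-free",
    "tapioca flour": "gluten-free",
    "corn flour": "gluten-free",
    "rice flour": "gluten-free",
    "peanut flour": "peanut",
    "peanut butter powder": "peanut",
    "almond flour": "tree nut",
    "whole egg powder": "egg",
    "egg yolk powder": "egg",
    "egg white powder": "egg",
}

#: Materials sourced from three brands; all others have a single brand.
MULTI_BRAND_MATERIALS = ("wheat flour", "gluten-free white flour", "almond flour")

DOMAIN_TAGS = ("static", "slow", "medium", "fast")

#: Conveyor speeds in m/s for the three moving conditions.
SPEED_MS = {"slow": 0.017, "medium": 0.036, "fast": 0.068}

META_COLUMNS = (
    "material_id",
    "brand_id",
    "allergen_class",
    "domain_tag",
    "sensor_tag",
    "sample_id",
    "replicate_id",
)

_GRIDS = {
    "S2.0": np.arange(1550, 1951),
    "S2.5": np.arange(2000, 2451),
}
_GRIDS["both"] = np.concatenate([_GRIDS["S2.0"], _GRIDS["S2.5"]])


class SpectraFormatError(ValueError):
    """Malformed spectral table (grid, header or row-shape problems)."""


class SpectraValidationError(ValueError):
    """Metadata inconsistent with the material/allergen vocabulary."""


def sensor_grid(sensor_tag: str) -> np.ndarray:
    """Wavelength grid (nm) for a sensor tag: S2.0 (401 pts), S2.5 (451 pts)
    or their 852-point concatenation for ``"both"``."""
    try:
        return _GRIDS[sensor_tag].copy()
    except KeyError:
        raise ValueError(f"unknown sensor_tag {sensor_tag!r}") from None


def material_units() -> list[tuple[str, int]]:
    """All 25 (material, brand) units: 19 materials, three of them in three
    brands."""
    units = []
    for material in MATERIAL_ALLERGEN:
        n_brands = 3 if material in MULTI_BRAND_MATERIALS else 1
        units.extend((material, b) for b in range(1, n_brands + 1))
    return units


@dataclass(frozen=True)
class Spectrum:
    """One intensity vector on a named wavelength grid, with provenance."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    material_id: str
    brand_id: int
    allergen_class: str
    domain_tag: str
    sensor_tag: str
    sample_id: int
    replicate_id: int

    def __post_init__(self):
        if len(self.wavelengths) != len(self.intensities):
            raise SpectraFormatError("wavelengths and intensities differ in length")
        expected = _GRIDS.get(self.sensor_tag)
        if expected is None or not np.array_equal(self.wavelengths, expected):
            raise SpectraFormatError(
                f"grid does not match sensor_tag {self.sensor_tag!r}"
            )
        _validate_meta_row(
            self.material_id, self.brand_id, self.allergen_class, self.domain_tag
        )


def _validate_meta_row(material_id, brand_id, allergen_class, domain_tag) -> None:
    if material_id not in MATERIAL_ALLERGEN:
        raise SpectraValidationError(f"unknown material {material_id!r}")
    expected_class = MATERIAL_ALLERGEN[material_id]
    if allergen_class != expected_class:
        raise SpectraValidationError(
            f"material {material_id!r} is {expected_class!r}, "
            f"not {allergen_class!r}"
        )
    max_brand = 3 if material_id in MULTI_BRAND_MATERIALS else 1
    if not 1 <= int(brand_id) <= max_brand:
        raise SpectraValidationError(
            f"brand_id {brand_id} out of range for {material_id!r}"
        )
    if domain_tag not in DOMAIN_TAGS:
        raise SpectraValidationError(f"unknown domain_tag {domain_tag!r}")


@dataclass
class SpectralDataset:
    """An ordered collection of spectra sharing one wavelength grid.

    Intensities are stored as an ``(n_spectra, n_wavelengths)`` array and
    metadata as a DataFrame with one row per spectrum (columns
    :data:`META_COLUMNS`).
    """

    grid: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise SpectraFormatError("wavelength grid must be strictly increasing")
        if self.intensities.ndim != 2 or self.intensities.shape[1] != len(self.grid):
            raise SpectraFormatError(
                f"intensity matrix shape {self.intensities.shape} does not "
                f"match grid length {len(self.grid)}"
            )
        if len(self.meta) != len(self.intensities):
            raise SpectraFormatError("metadata and intensity row counts differ")
        self.meta = self.meta.reset_index(drop=True)
        tags = self.meta["sensor_tag"].unique()
        if len(tags) > 1:
            raise SpectraFormatError(f"mixed sensor tags in one dataset: {tags}")
        for row in self.meta.itertuples(index=False):
            _validate_meta_row(
                row.material_id, row.brand_id, row.allergen_class, row.domain_tag
            )

    def __len__(self) -> int:
        return len(self.intensities)

    def __iter__(self):
        for i in range(len(self)):
            yield self.spectrum(i)

    @property
    def sensor_tag(self) -> str:
        return str(self.meta["sensor_tag"].iloc[0]) if len(self.meta) else "S2.0"

    @property
    def labels(self) -> np.ndarray:
        """Integer class labels in the fixed :data:`ALLERGEN_CLASSES` order."""
        lut = {c: i for i, c in enumerate(ALLERGEN_CLASSES)}
        return self.meta["allergen_class"].map(lut).to_numpy()

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        return Spectrum(
            wavelengths=self.grid.copy(),
            intensities=self.intensities[i].copy(),
            material_id=row["material_id"],
            brand_id=int(row["brand_id"]),
            allergen_class=row["allergen_class"],
            domain_tag=row["domain_tag"],
            sensor_tag=row["sensor_tag"],
            sample_id=int(row["sample_id"]),
            replicate_id=int(row["replicate_id"]),
        )

    def subset(self, indices) -> "SpectralDataset":
        indices = np.asarray(indices, dtype=int)
        return SpectralDataset(
            self.grid.copy(),
            self.intensities[indices],
            self.meta.iloc[indices].reset_index(drop=True),
        )

    def record_keys(self) -> list[tuple[str, int, int, int]]:
        """(material, brand, sample, replicate) key per spectrum."""
        return [
            (r.material_id, int(r.brand_id), int(r.sample_id), int(r.replicate_id))
            for r in self.meta.itertuples(index=False)
        ]

    @staticmethod
    def empty(grid: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(
            np.asarray(grid),
            np.empty((0, len(grid))),
            pd.DataFrame(columns=list(META_COLUMNS)),
        )

    @staticmethod
    def concat(datasets: list["SpectralDataset"]) -> "SpectralDataset":
        if not datasets:
            raise ValueError("nothing to concatenate")
        grid = datasets[0].grid
        for ds in datasets[1:]:
            if not np.array_equal(ds.grid, grid):
                raise SpectraFormatError("cannot concatenate datasets on mixed grids")
        return SpectralDataset(
            grid.copy(),
            np.vstack([ds.intensities for ds in datasets]),
            pd.concat([ds.meta for ds in datasets], ignore_index=True),
        )


@dataclass
class DomainSplit:
    """The four subsets that drive every trainer.

    ``source_labelled`` holds the static spectra; the moving spectra are
    partitioned into ``target_unlabelled`` (labels hidden during training),
    ``target_test`` and, optionally, one labelled instance per
    material-brand unit in ``target_labelled``.
    """

    source_labelled: SpectralDataset
    target_labelled: SpectralDataset
    target_unlabelled: SpectralDataset
    target_test: SpectralDataset
    seed: int = 0

    def manifest(self) -> dict:
        """JSON-serializable record-key listing per subset, plus the seed."""
        return {
            "seed": self.seed,
            "subsets": {
                name: [list(k) for k in getattr(self, name).record_keys()]
                for name in (
                    "source_labelled",
                    "target_labelled",
                    "target_unlabelled",
                    "target_test",
                )
            },
        }

    def write_manifest(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.manifest(), indent=1))
        return path


def read_spectra_table(path) -> SpectralDataset:
    """Read a wide-format spectral CSV (metadata columns, then one intensity
    column per integer wavelength in nm)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise SpectraFormatError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"missing metadata columns {missing} in {path}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        grid = np.array([int(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(
            f"non-numeric wavelength column among {wl_cols[:5]}..."
        ) from exc
    if np.any(np.diff(grid) <= 0):
        raise SpectraFormatError("wavelength columns are not strictly increasing")
    intensities = df[wl_cols].to_numpy(dtype=float)
    if np.isnan(intensities).any():
        raise SpectraFormatError(f"missing intensity values in {path}")
    return SpectralDataset(grid, intensities, df[list(META_COLUMNS)].copy())


def write_spectra_table(ds: SpectralDataset, path) -> Path:
    """Write the dataset as a wide CSV with integer-nm wavelength headers."""
    if len(ds) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    wide = pd.concat(
        [
            ds.meta[list(META_COLUMNS)].reset_index(drop=True),
            pd.DataFrame(ds.intensities, columns=[str(int(w)) for w in ds.grid]),
        ],
        axis=1,
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    wide.to_csv(path, index=False, float_format="%.10g")
    return path


def combine_sensors(
    ds_s20: SpectralDataset, ds_s25: SpectralDataset
) -> SpectralDataset:
    """Concatenate matched S2.0 and S2.5 measurements into 852-feature
    spectra (sensor_tag ``"both"``).

    Records are matched on (material, brand, sample, replicate, domain);
    a missing or duplicated key on either side is an error naming the key.
    """
    if ds_s20.sensor_tag != "S2.0" or ds_s25.sensor_tag != "S2.5":
        raise ValueError(
            f"expected sensor tags ('S2.0', 'S2.5'), got "
            f"({ds_s20.sensor_tag!r}, {ds_s25.sensor_tag!r})"
        )

    def keyed(ds):
        out = {}
        for i, r in enumerate(ds.meta.itertuples(index=False)):
            key = (
                r.material_id,
                int(r.brand_id),
                int(r.sample_id),
                int(r.replicate_id),
                r.domain_tag,
            )
            if key in out:
                raise ValueError(f"duplicate record key {key}")
            out[key] = i
        return out

    k20, k25 = keyed(ds_s20), keyed(ds_s25)
    for key in k20:
        if key not in k25:
            raise ValueError(f"S2.5 dataset is missing record {key}")
    for key in k25:
        if key not in k20:
            raise ValueError(f"S2.0 dataset is missing record {key}")

    order = list(k20)  # S2.0 record order defines the output order
    idx20 = np.array([k20[k] for k in order])
    idx25 = np.array([k25[k] for k in order])
    intensities = np.hstack(
        [ds_s20.intensities[idx20], ds_s25.intensities[idx25]]
    )
    meta = ds_s20.meta.iloc[idx20].reset_index(drop=True).copy()
    meta["sensor_tag"] = "both"
    return SpectralDataset(sensor_grid("both"), intensities, meta)


def make_domain_split(
    static_ds: SpectralDataset,
    moving_ds: SpectralDataset,
    n_labelled_per_unit: int = 0,
    seed: int = 0,
) -> DomainSplit:
    """Build the labelled/unlabelled/test domain split.

    Per material-brand unit the moving spectra are split half into the
    unlabelled pool and half into the test set, stratified by sample so both
    halves see every physical sample, deterministically from ``seed``.  With
    ``n_labelled_per_unit=1`` one moving spectrum per unit is moved from the
    unlabelled pool into ``target_labelled`` (a single labelled target
    instance per material category).
    """
    if n_labelled_per_unit not in (0, 1):
        raise ValueError(
            f"n_labelled_per_unit must be 0 or 1, got {n_labelled_per_unit}"
        )
    rng = np.random.default_rng(seed)
    groups = moving_ds.meta.groupby(["material_id", "brand_id"], sort=True)
    unlab_idx: list[int] = []
    test_idx: list[int] = []
    lab_idx: list[int] = []
    for (material, brand), unit_df in groups:
        if len(unit_df) < 2:
            raise ValueError(
                f"unit ({material!r}, {brand}) has fewer than 2 moving spectra"
            )
        unit_unlab: list[int] = []
        for _, sample_df in unit_df.groupby("sample_id", sort=True):
            idx = sample_df.index.to_numpy()
            perm = rng.permutation(len(idx))
            half = len(idx) // 2
            unit_unlab.extend(idx[perm[:half]])
            test_idx.extend(idx[perm[half:]])
        if n_labelled_per_unit == 1:
            pick = int(rng.integers(len(unit_unlab)))
            lab_idx.append(unit_unlab.pop(pick))
        unlab_idx.extend(unit_unlab)

    grid = moving_ds.grid
    return DomainSplit(
        source_labelled=static_ds,
        target_labelled=(
            moving_ds.subset(lab_idx) if lab_idx else SpectralDataset.empty(grid)
        ),
        target_unlabelled=moving_ds.subset(sorted(unlab_idx)),
        target_test=moving_ds.subset(sorted(test_idx)),
        seed=seed,
    )
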