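"""Synthetic spectra generator: templates, motion shift, seed hierarchy."""

import numpy as np
import pytest

from specadapt import (
    default_material_library,
    make_domain_split,
    simulate_domain_pair,
    simulate_spectrum,
)
from specadapt.spectra_io import sensor_grid
from specadapt.synthetic_data import MotionShiftParams, default_motion_shift


class TestLibrary:
    def test_library_structure(self, library):
        assert len(library) == 25
        assert library.classes == ("egg", "gluten", "gluten-free", "peanut", "tree nut")
        # three-brand materials appear three times
        from collections import Counter

        counts = Counter(u.material_id for u in library)
        assert counts["wheat flour"] == 3
        assert counts["almond flour"] == 3
        assert counts["gluten-free white flour"] == 3

    def test_gluten_units_carry_carbohydrate_band(self, library):
        for unit in library:
            if unit.allergen_class == "gluten":
                centers = [b.center for b in unit.bands if b.amplitude > 0.1]
                assert any(1569 <= c <= 1604 for c in centers)

    def test_same_seed_same_library(self):
        a = default_material_library(42)
        b = default_material_library(42)
        assert a.to_dict() == b.to_dict()

    def test_separation_scales_class_contrast(self):
        collapsed = default_material_library(0, separation=0.0)
        templates = {}
        grid = sensor_grid("both")
        for u in collapsed:
            templates.setdefault(u.allergen_class, []).append(u.template(grid))
        class_means = {c: np.mean(t, axis=0) for c, t in templates.items()}
        spread0 = np.std(list(class_means.values()), axis=0).mean()
        wide = default_material_library(0, separation=2.0)
        templates = {}
        for u in wide:
            templates.setdefault(u.allergen_class, []).append(u.template(grid))
        class_means = {c: np.mean(t, axis=0) for c, t in templates.items()}
        spread2 = np.std(list(class_means.values()), axis=0).mean()
        # unit-level perturbations keep a floor under the spread at
        # separation 0; doubling the separation must still widen it clearly
        assert spread2 > 1.5 * spread0


class TestSimulateSpectrum:
    def test_zero_noise_static_reproduces_template(self, library):
        unit = library.units[0]
        shift = MotionShiftParams(sigma0=0.0)
        rng = np.random.default_rng(0)
        y = simulate_spectrum(unit, "static", shift, rng, sensor="S2.0")
        np.testing.assert_array_equal(y, unit.template(sensor_grid("S2.0")))

    def test_monte_carlo_mean_matches_closed_form(self, library):
        # mean of n draws at fast speed ~ g*template + o within 3 SEs per point
        unit = library.units[3]
        shift = default_motion_shift()
        g, o, m = shift.for_speed("fast")
        rng = np.random.default_rng(123)
        n = 10_000
        draws = np.stack(
            [simulate_spectrum(unit, "fast", shift, rng, "S2.0") for _ in range(n)]
        )
        expected = g * unit.template(sensor_grid("S2.0")) + o
        se = shift.sigma0 * m / np.sqrt(n)
        frac_inside = np.mean(np.abs(draws.mean(axis=0) - expected) < 3 * se)
        assert frac_inside > 0.99

    def test_monte_carlo_variance_matches_closed_form(self, library):
        # chi-square 99% band for the per-point sample variance at n draws
        from scipy import stats

        unit = library.units[3]
        shift = default_motion_shift()
        _, _, m = shift.for_speed("fast")
        rng = np.random.default_rng(321)
        n = 10_000
        draws = np.stack(
            [simulate_spectrum(unit, "fast", shift, rng, "S2.0") for _ in range(n)]
        )
        sigma2 = (shift.sigma0 * m) ** 2
        s2 = draws.var(axis=0, ddof=1)
        lo = sigma2 * stats.chi2.ppf(0.005, n - 1) / (n - 1)
        hi = sigma2 * stats.chi2.ppf(0.995, n - 1) / (n - 1)
        assert np.mean((s2 > lo) & (s2 < hi)) > 0.98

    def test_unknown_speed_rejected(self, library):
        with pytest.raises(ValueError, match="speed"):
            simulate_spectrum(
                library.units[0],
                "warp",
                default_motion_shift(),
                np.random.default_rng(0),
            )


class TestSimulateDomainPair:
    def test_full_scale_counts(self, library):
        static, moving = simulate_domain_pair(
            library, "slow", n_samples=5, n_replicates=10, sensor="S2.0", seed=0
        )
        assert len(static) == len(moving) == 1250
        per_unit = static.meta.groupby(["material_id", "brand_id"]).size()
        assert (per_unit == 50).all()

    def test_minimal_counts(self, library):
        static, moving = simulate_domain_pair(
            library, "slow", n_samples=1, n_replicates=1, sensor="S2.5", seed=0
        )
        assert len(static) == len(moving) == 25

    def test_null_shift_zero_noise_pairs_are_identical(self, library):
        # sample offsets are shared between conditions, so a null shift with
        # no noise makes moving spectra equal their static counterparts
        shift = MotionShiftParams.null()
        shift.sigma0 = 0.0
        static, moving = simulate_domain_pair(
            library, "fast", n_samples=2, n_replicates=2, shift=shift,
            sensor="S2.0", seed=5,
        )
        np.testing.assert_allclose(static.intensities, moving.intensities)

    def test_null_shift_distributionally_identical(self, library):
        # two-sample t-test per wavelength should almost never reject
        from scipy import stats

        static, moving = simulate_domain_pair(
            library, "medium", n_samples=3, n_replicates=10,
            shift=MotionShiftParams.null(), sensor="S2.5", seed=8,
        )
        _, p = stats.ttest_ind(static.intensities, moving.intensities, axis=0)
        assert np.mean(p > 0.01) >= 0.95

    def test_deterministic_from_seed(self, library):
        a = simulate_domain_pair(library, "fast", 1, 2, sensor="S2.0", seed=11)
        b = simulate_domain_pair(library, "fast", 1, 2, sensor="S2.0", seed=11)
        np.testing.assert_array_equal(a[0].intensities, b[0].intensities)
        np.testing.assert_array_equal(a[1].intensities, b[1].intensities)

    def test_outputs_satisfy_grid_invariants(self, domain_pair):
        static, moving = domain_pair
        # SpectralDataset construction validates grids; spot-check a spectrum
        spec = static.spectrum(0)
        assert spec.sensor_tag == "S2.0"
        assert len(spec.wavelengths) == len(spec.intensities) == 401

    def test_class_separation_drives_static_accuracy(self):
        # a fixed simple classifier gets monotonically better as inter-class
        # band-amplitude differences grow
        from sklearn.linear_model import LogisticRegression

        accs = []
        for sep in (0.02, 0.3, 1.0):
            seed_accs = []
            for seed in (0, 1, 2):
                lib = default_material_library(seed, separation=sep)
                static, _ = simulate_domain_pair(
                    lib, "slow", n_samples=2, n_replicates=2, sensor="S2.0",
                    seed=seed,
                )
                x, y = static.intensities, static.labels
                rng = np.random.default_rng(seed)
                idx = rng.permutation(len(x))
                train, test = idx[: len(x) // 2], idx[len(x) // 2 :]
                clf = LogisticRegression(max_iter=2000).fit(x[train], y[train])
                seed_accs.append(clf.score(x[test], y[test]))
            accs.append(np.mean(seed_accs))
        assert accs[0] < accs[1] <= accs[2]

    def test_empty_library_rejected(self):
        from specadapt.synthetic_data import MaterialLibrary

        with pytest.raises(ValueError, match="empty"):
            simulate_domain_pair(MaterialLibrary(units=[], seed=0), "slow")
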