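"""Training schedules: adversarial transform, reduction to the baseline,
determinism, bookkeeping and prediction contracts."""

import math

import numpy as np
import pytest

from specadapt import (
    DomainAdaptationModel,
    TrainConfig,
    adversarial_transform,
    make_domain_split,
    predict,
    train_combined,
    train_dann,
    train_sgan,
    train_transfer_baseline,
)
from specadapt.spectra_io import DomainSplit, SpectralDataset


class TestAdversarialTransform:
    def test_reciprocal_values(self):
        assert adversarial_transform(1.0, eps=1e-12) == pytest.approx(-1.0)
        assert adversarial_transform(2.0, mode="negation") == -2.0

    def test_negative_loss_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            adversarial_transform(-0.5)

    def test_monotone_increasing_with_decreasing_gradient(self):
        # -1/(L+eps) rises with L; its slope 1/(L+eps)^2 falls with L
        grid = np.linspace(0.01, 10, 200)
        vals = np.array([adversarial_transform(l, eps=1e-9) for l in grid])
        assert (np.diff(vals) > 0).all()
        slopes = np.gradient(vals, grid)
        assert (np.diff(slopes) < 0).all()

    def test_gradient_ratio_hundredfold(self):
        # finite-difference slope at L=0.1 is ~100x the slope at L=1.0:
        # small discriminator loss (an accurate adversary) => big step
        h = 1e-6

        def slope(l):
            return (
                adversarial_transform(l + h, eps=0.0)
                - adversarial_transform(l - h, eps=0.0)
            ) / (2 * h)

        assert slope(0.1) / slope(1.0) == pytest.approx(100.0, rel=1e-3)


def _two_blob_split(n_per_class=48, seed=0):
    """A linearly separable static set: two materials from different
    classes, far apart in intensity."""
    import pandas as pd

    from specadapt.spectra_io import META_COLUMNS, sensor_grid

    rng = np.random.default_rng(seed)
    grid = sensor_grid("S2.0")
    rows, intens = [], []
    for material, cls, level in (
        ("oat flour", "gluten", 0.2),
        ("peanut flour", "peanut", 1.2),
    ):
        for i in range(n_per_class):
            rows.append(
                {
                    "material_id": material,
                    "brand_id": 1,
                    "allergen_class": cls,
                    "domain_tag": "static",
                    "sensor_tag": "S2.0",
                    "sample_id": 1 + i % 5,
                    "replicate_id": 1 + i // 5,
                }
            )
            intens.append(rng.normal(level, 0.02, len(grid)))
    ds = SpectralDataset(grid, np.array(intens), pd.DataFrame(rows, columns=list(META_COLUMNS)))
    return DomainSplit(
        source_labelled=ds,
        target_labelled=SpectralDataset.empty(grid),
        target_unlabelled=SpectralDataset.empty(grid),
        target_test=SpectralDataset.empty(grid),
    )


class TestTransferBaseline:
    def test_reaches_100_percent_on_separable_data(self):
        split = _two_blob_split()
        model = train_transfer_baseline(split, TrainConfig(epochs=40, seed=1))
        assert model.accuracy(split.source_labelled) == 100.0

    def test_one_epoch_logs_one_step_per_batch(self, small_split):
        cfg = TrainConfig(epochs=1, seed=2)
        model = train_transfer_baseline(small_split, cfg)
        n = len(small_split.source_labelled)
        assert len(model.loss_history) == math.ceil(n / cfg.batch_size)
        assert set(model.loss_history[0]) == {"classification"}

    def test_same_seed_identical_weights(self, small_split, fast_config):
        a = train_transfer_baseline(small_split, fast_config)
        b = train_transfer_baseline(small_split, fast_config)
        for pa, pb in zip(
            a.suite.feature_extractor.params, b.suite.feature_extractor.params
        ):
            np.testing.assert_array_equal(pa, pb)

    def test_empty_source_rejected(self, small_split):
        from specadapt.spectra_io import sensor_grid

        empty = SpectralDataset.empty(sensor_grid("S2.0"))
        bad = DomainSplit(empty, empty, small_split.target_unlabelled, empty)
        with pytest.raises(ValueError, match="non-empty"):
            train_transfer_baseline(bad)


class TestAdversarialTrainers:
    def test_dann_logs_three_named_losses(self, small_split, fast_config):
        model = train_dann(small_split, fast_config)
        record = model.loss_history[0]
        assert {
            "classification",
            "domain_disc_labelled",
            "domain_disc_unlabelled",
        } <= set(record)

    def test_sgan_logs_realfake_and_generator_losses(self, small_split, fast_config):
        model = train_sgan(small_split, fast_config)
        record = model.loss_history[0]
        assert {
            "classification",
            "realfake_labelled",
            "realfake_generated",
            "generator_confusion",
            "realfake_unlabelled",
        } <= set(record)

    def test_combined_logs_at_least_five_losses(self, small_split, fast_config):
        model = train_combined(small_split, fast_config)
        assert len(model.loss_history[0]) >= 5

    def test_unlabelled_required(self, small_split):
        from specadapt.spectra_io import sensor_grid

        empty = SpectralDataset.empty(sensor_grid("S2.0"))
        bad = DomainSplit(small_split.source_labelled, empty, empty, empty)
        for trainer in (train_dann, train_sgan, train_combined):
            with pytest.raises(ValueError, match="transfer baseline"):
                trainer(bad)

    @pytest.mark.parametrize("trainer", [train_dann, train_sgan, train_combined])
    def test_disabled_adversarial_reduces_to_baseline(
        self, small_split, trainer
    ):
        # with every adversarial branch off, all schedules are the same
        # sequence of classification updates => identical weights
        cfg = TrainConfig(epochs=3, seed=8, enable_adversarial=False)
        baseline = train_transfer_baseline(small_split, cfg)
        other = trainer(small_split, cfg)
        for pa, pb in zip(
            baseline.suite.feature_extractor.params,
            other.suite.feature_extractor.params,
        ):
            np.testing.assert_array_equal(pa, pb)
        for pa, pb in zip(
            baseline.suite.classifier_head.params,
            other.suite.classifier_head.params,
        ):
            np.testing.assert_array_equal(pa, pb)

    def test_determinism_of_adversarial_training(self, small_split, fast_config):
        a = train_combined(small_split, fast_config)
        b = train_combined(small_split, fast_config)
        for pa, pb in zip(
            a.suite.feature_extractor.params, b.suite.feature_extractor.params
        ):
            np.testing.assert_array_equal(pa, pb)
        assert a.loss_history == b.loss_history


class TestDannFeatureAlignment:
    def test_dann_features_less_domain_discriminative_than_baseline(
        self, domain_pair
    ):
        # train a probe classifier on frozen features to tell static from
        # moving; DANN features should be harder to separate than TL's
        from sklearn.linear_model import LogisticRegression

        static, moving = domain_pair
        split = make_domain_split(static, moving, 0, seed=0)
        gaps = {}
        for name, trainer in (("TL", train_transfer_baseline), ("DANN", train_dann)):
            probe_gap = []
            for seed in (0, 1, 2):
                model = trainer(split, TrainConfig(epochs=60, seed=seed))
                feats_s = model.suite.features(
                    ((static.intensities - model.mu) / model.sd).astype(np.float32)
                )
                feats_m = model.suite.features(
                    ((split.target_test.intensities - model.mu) / model.sd).astype(
                        np.float32
                    )
                )
                x = np.vstack([feats_s, feats_m])
                y = np.r_[np.zeros(len(feats_s)), np.ones(len(feats_m))]
                rng = np.random.default_rng(seed)
                idx = rng.permutation(len(x))
                half = len(x) // 2
                clf = LogisticRegression(max_iter=500).fit(
                    x[idx[:half]], y[idx[:half]]
                )
                probe_gap.append(abs(clf.score(x[idx[half:]], y[idx[half:]]) - 0.5))
            gaps[name] = np.mean(probe_gap)
        assert gaps["DANN"] <= gaps["TL"]


class TestSganGenerator:
    def test_generated_batch_shape(self, small_split, fast_config):
        model = train_sgan(small_split, fast_config)
        out = model.suite.generate(32, np.random.default_rng(0))
        assert out.shape == (32, model.suite.input_dim)

    def test_training_pulls_generator_toward_target_mean(self, domain_pair):
        # compare L2 distance of the mean generated (standardized) spectrum
        # to the mean unlabelled target spectrum, before vs after training
        from specadapt.networks import build_network_suite

        static, moving = domain_pair
        split = make_domain_split(static, moving, 0, seed=1)
        dists = {"trained": [], "untrained": []}
        for seed in (0, 1, 2):
            model = train_sgan(split, TrainConfig(epochs=60, seed=seed))
            target = (
                (split.target_unlabelled.intensities - model.mu) / model.sd
            ).mean(axis=0)
            gen_mean = model.suite.generate(500, np.random.default_rng(99)).mean(
                axis=0
            )
            fresh = build_network_suite(
                model.suite.input_dim,
                latent_dim=model.config.latent_dim,
                seed=model.suite.seed,
            )
            fresh_mean = fresh.generate(500, np.random.default_rng(99)).mean(axis=0)
            dists["trained"].append(np.linalg.norm(gen_mean - target))
            dists["untrained"].append(np.linalg.norm(fresh_mean - target))
        assert np.mean(dists["trained"]) < np.mean(dists["untrained"])

    def test_realfake_discriminator_recognizes_real_target(
        self, small_split
    ):
        model = train_sgan(small_split, TrainConfig(epochs=60, seed=3))
        x = (
            (small_split.target_test.intensities - model.mu) / model.sd
        ).astype(np.float32)
        p = model.suite.realfake_probabilities(x)
        # class 0 is "real"; most held-out real spectra should score real
        assert (p.argmax(axis=1) == 0).mean() > 0.5


class TestPredict:
    def test_probability_rows_sum_to_one(self, small_split, fast_config):
        model = train_transfer_baseline(small_split, fast_config)
        labels, proba = predict(model, small_split.target_test)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= {
            "egg", "gluten", "gluten-free", "peanut", "tree nut",
        }

    def test_row_permutation_equivariance(self, small_split, fast_config):
        model = train_transfer_baseline(small_split, fast_config)
        ds = small_split.target_test
        perm = np.random.default_rng(0).permutation(len(ds))
        labels, proba = predict(model, ds)
        labels_p, proba_p = predict(model, ds.subset(perm))
        np.testing.assert_array_equal(labels[perm], labels_p)
        # single-precision forward passes: equality up to float32 round-off
        np.testing.assert_allclose(proba[perm], proba_p, rtol=1e-4, atol=1e-6)

    def test_grid_mismatch_rejected(self, small_split, fast_config):
        model = train_transfer_baseline(small_split, fast_config)
        with pytest.raises(ValueError, match="wavelengths"):
            model.predict(np.zeros((3, 451)))

    def test_summary_mentions_method_and_steps(self, small_split, fast_config):
        model = train_dann(small_split, fast_config)
        text = model.summary()
        assert "DANN" in text and "Optimization steps" in text

    def test_results_checkpoint_round_trip(self, tmp_path, small_split, fast_config):
        from specadapt.training import TrainedModel

        model = train_transfer_baseline(small_split, fast_config)
        path = model.save(tmp_path / "m.npz")
        back = TrainedModel.load(path)
        np.testing.assert_allclose(
            model.predict_proba(small_split.target_test),
            back.predict_proba(small_split.target_test),
        )
        assert back.method_tag == "TL"
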