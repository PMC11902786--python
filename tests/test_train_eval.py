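"""Training protocol, cross-validation harness, ablation/baseline runners,
checkpoints."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from burnspec.data import SpectralDataset
from burnspec.metrics import MetricsReport
from burnspec.synthetic import SyntheticConfig, generate
from burnspec.train_eval import (BASELINES, Conv1DClassifier, CVResult,
                                 MBNetClassifier, TrainConfig,
                                 TransformerClassifier, _Pipeline,
                                 ablation_table, baseline_table, crossvalidate,
                                 fold_hash, fold_indices, load_checkpoint,
                                 lr_schedule, make_estimator, run_ablation,
                                 run_baselines, save_checkpoint, train)

from conftest import DESK_MODEL

FAST = dict(epochs=3, batch_size=64, model=DESK_MODEL)


class TestSchedule:
    def test_stepped_exponential_decay_values(self):
        cfg = TrainConfig()
        assert lr_schedule(0, cfg) == pytest.approx(1e-3, abs=0)
        assert lr_schedule(10, cfg) == pytest.approx(9e-4)
        assert lr_schedule(25, cfg) == pytest.approx(8.1e-4)

    def test_closed_form_everywhere(self):
        cfg = TrainConfig(lr0=0.02, decay_step=7, decay_rate=0.5)
        for e in (0, 3, 7, 13, 50):
            assert lr_schedule(e, cfg) == pytest.approx(0.02 * 0.5 ** (e // 7))
        with pytest.raises(ValueError):
            lr_schedule(-1, cfg)

    def test_history_matches_schedule(self, tiny_dataset):
        cfg = TrainConfig(seed=5, **FAST)
        _, history = train(tiny_dataset, cfg)
        assert history["lr"] == [lr_schedule(e, cfg) for e in range(cfg.epochs)]


class TestTrain:
    def test_same_seed_gives_identical_loss_curves(self, tiny_dataset):
        cfg = TrainConfig(seed=9, **FAST)
        _, h1 = train(tiny_dataset, cfg)
        _, h2 = train(tiny_dataset, cfg)
        assert h1["loss"] == h2["loss"]

    def test_different_seed_gives_different_curve(self, tiny_dataset):
        _, h1 = train(tiny_dataset, TrainConfig(seed=1, **FAST))
        _, h2 = train(tiny_dataset, TrainConfig(seed=2, **FAST))
        assert h1["loss"] != h2["loss"]

    def test_loss_decreases(self, clean_tiny_dataset):
        cfg = TrainConfig(seed=0, epochs=10, batch_size=64, model=DESK_MODEL)
        _, history = train(clean_tiny_dataset, cfg)
        assert history["loss"][-1] < history["loss"][0]

    def test_two_separable_classes_reach_high_training_accuracy(self):
        # the most distant temperature classes at zero noise
        ds = generate(SyntheticConfig(n_bands=40, samples_per_class=30,
                                      noise_sd=0.0, illum_scale_sd=0.0,
                                      interference_sd=0.0, seed=4))
        keep = np.isin(ds.labels, [0, 5])
        two = SpectralDataset(ds.spectra[keep],
                              (ds.labels[keep] == 5).astype(int),
                              ds.wavelengths, class_names=["a", "b"])
        pipe, _ = train(two, TrainConfig(seed=0, epochs=25, batch_size=32,
                                         model=DESK_MODEL))
        assert np.mean(pipe.predict(two.spectra) == two.labels) >= 0.99

    def test_single_class_rejected(self, tiny_dataset):
        ds = tiny_dataset.subset(tiny_dataset.labels == 2)
        with pytest.raises(ValueError, match="two classes"):
            train(ds, TrainConfig(**FAST))


class TestFolds:
    def test_stratified_partition(self, tiny_dataset):
        folds = fold_indices(tiny_dataset.labels, 5, seed=3)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(tiny_dataset.n_samples))
        for tr, te in folds:
            assert set(tr) & set(te) == set()
            counts = np.bincount(tiny_dataset.labels[te], minlength=6)
            assert counts.min() >= 3  # 20 per class / 5 folds, stratified

    def test_reproducible_hash(self, tiny_dataset):
        h1 = fold_hash(fold_indices(tiny_dataset.labels, 5, seed=3))
        h2 = fold_hash(fold_indices(tiny_dataset.labels, 5, seed=3))
        h3 = fold_hash(fold_indices(tiny_dataset.labels, 5, seed=4))
        assert h1 == h2 != h3

    def test_small_class_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="fewer than k"):
            fold_indices(np.array([0, 0, 0, 1]), 3, seed=0)


class TestCrossValidate:
    def test_mean_report_is_arithmetic_mean_of_folds(self, tiny_dataset):
        res = crossvalidate(tiny_dataset, TrainConfig(seed=1), k=4, model="lda")
        assert isinstance(res, CVResult)
        assert len(res.per_fold) == 4
        assert res.mean_report.OA == pytest.approx(
            np.mean([r.OA for r in res.per_fold]), abs=1e-12)
        assert res.mean_report.Kappa == pytest.approx(
            np.mean([r.Kappa for r in res.per_fold]), abs=1e-12)

    def test_pooled_confusion_counts_every_sample_once(self, tiny_dataset):
        res = crossvalidate(tiny_dataset, TrainConfig(seed=1), k=4, model="knn")
        assert res.pooled_confusion.sum() == tiny_dataset.n_samples

    def test_standardizer_fitted_on_training_folds_only(self, rng):
        """Leakage canary: the scaler statistics must come from the train
        split, not the full data."""
        Xtr = rng.normal(0.0, 1.0, size=(40, 6))
        Xte = rng.normal(50.0, 1.0, size=(10, 6))   # wildly different scale
        ytr = np.tile([0, 1], 20)
        pipe = _Pipeline(KNeighborsClassifier(1), standardize=True)
        pipe.fit(Xtr, ytr)
        np.testing.assert_allclose(pipe.scaler.mean_, Xtr.mean(0), atol=1e-12)
        assert np.abs(pipe.scaler.mean_).max() < 5  # untouched by test scale
        pipe.predict(Xte)


class TestAblation:
    def test_four_variants_on_identical_folds(self, tiny_dataset):
        cfg = TrainConfig(seed=2, epochs=2, batch_size=64, model=DESK_MODEL)
        results = run_ablation(tiny_dataset, cfg, k=2)
        assert set(results) == {"bidirectional", "sequential_only",
                                "reverse_only", "no_mamba"}
        assert len({r.folds_hash for r in results.values()}) == 1
        table = ablation_table(results)
        assert table.shape == (3, 4)
        assert list(table.index) == ["OA (%)", "AA (%)", "Kappa"]


class TestBaselines:
    def test_registry_covers_all_methods(self):
        cfg = TrainConfig()
        for name in BASELINES + ("mbnet",):
            assert hasattr(make_estimator(name, cfg), "fit")
        with pytest.raises(KeyError):
            make_estimator("quantum", cfg)

    def test_identical_folds_and_combined_table(self, tiny_dataset):
        cfg = TrainConfig(seed=3, epochs=2, batch_size=64, model=DESK_MODEL)
        results = run_baselines(tiny_dataset, cfg, k=2,
                                names=("knn", "lda", "mbnet"))
        cvs = [r for r in results.values() if isinstance(r, CVResult)]
        assert len({r.folds_hash for r in cvs}) == 1
        table = baseline_table(results, tiny_dataset.class_names)
        assert table.shape == (9, 3)   # 6 per-class rows + OA/AA/Kappa

    def test_failing_estimator_is_reported_not_fatal(self, tiny_dataset,
                                                     monkeypatch):
        cfg = TrainConfig(seed=3)
        import burnspec.train_eval as te

        def broken(name, cfg):
            raise RuntimeError("did not converge")

        monkeypatch.setattr(te, "make_estimator", broken)
        results = te.run_baselines(tiny_dataset, cfg, k=2, names=("knn",))
        assert isinstance(results["knn"], str) and "converge" in results["knn"]

    def test_nearest_neighbor_memorizes_training_set(self, tiny_dataset):
        est = KNeighborsClassifier(1).fit(tiny_dataset.spectra,
                                          tiny_dataset.labels)
        assert np.mean(est.predict(tiny_dataset.spectra)
                       == tiny_dataset.labels) == 1.0

    @pytest.mark.parametrize("cls", [Conv1DClassifier, TransformerClassifier])
    def test_autodiff_baselines_learn_an_easy_task(self, cls,
                                                   clean_tiny_dataset):
        ds = clean_tiny_dataset
        cfg = TrainConfig(seed=0, epochs=30, batch_size=32)
        est = _Pipeline(cls(cfg), standardize=True)
        est.fit(ds.spectra, ds.labels)
        assert np.mean(est.predict(ds.spectra) == ds.labels) > 0.5


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tiny_dataset, tmp_path):
        cfg = TrainConfig(seed=6, **FAST)
        pipe, _ = train(tiny_dataset, cfg)
        path = save_checkpoint(pipe.estimator, tmp_path / "ck.npz",
                               scaler=pipe.scaler)
        clf = load_checkpoint(path)
        X = clf.scaler.transform(tiny_dataset.spectra)
        np.testing.assert_array_equal(
            clf.model.predict(X.astype(np.float32)),
            pipe.predict(tiny_dataset.spectra))

    def test_mismatched_geometry_fails_loudly(self, tiny_dataset, tmp_path):
        cfg = TrainConfig(seed=6, **FAST)
        pipe, _ = train(tiny_dataset, cfg)
        path = save_checkpoint(pipe.estimator, tmp_path / "ck.npz")
        with pytest.raises(ValueError, match="bands"):
            load_checkpoint(path, expect_bands=99)
        with pytest.raises(ValueError, match="classes"):
            load_checkpoint(path, expect_classes=2)
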