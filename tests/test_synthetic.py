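"""Synthetic burn-spectra generator: determinism, template structure,
class separability, noise behavior."""

import dataclasses

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import cross_val_score
from sklearn.neighbors import KNeighborsClassifier

from burnspec.synthetic import (SyntheticConfig, class_template,
                                difficulty_sweep, generate)


class TestTemplates:
    def test_default_template_length_and_range(self):
        cfg = SyntheticConfig()
        t = class_template(cfg, 0)
        assert t.shape == (260,)
        assert np.all((t >= 0) & (t <= 1.2))
        assert cfg.wavelengths[0] == 400.0 and cfg.wavelengths[-1] == 1000.0

    def test_distinct_classes_have_distinct_templates(self):
        cfg = SyntheticConfig()
        templates = [class_template(cfg, c) for c in range(6)]
        for i in range(6):
            for j in range(i + 1, 6):
                assert np.linalg.norm(templates[i] - templates[j]) > 0

    def test_absorption_dip_depth_decreases_with_temperature(self):
        cfg = SyntheticConfig()
        window = (cfg.wavelengths >= 600) & (cfg.wavelengths <= 700)
        # dip magnitude relative to the class's own albedo-scaled baseline
        depths = []
        for c in range(6):
            t = class_template(cfg, c)
            base = np.interp(cfg.wavelengths[window],
                             cfg.wavelengths[~window], t[~window])
            depths.append((base - t[window]).max())
        assert all(a > b for a, b in zip(depths, depths[1:]))

    def test_zero_depth_template_has_no_dip_minimum(self):
        cfg = SyntheticConfig(
            dip_depth_by_class=(0.4, 0.3, 0.2, 0.15, 0.1, 0.0))
        t = class_template(cfg, 5)
        wl = cfg.wavelengths
        inside = (wl > 600) & (wl < 700)
        idx = np.flatnonzero(inside)[1:-1]
        assert not np.any((t[idx] < t[idx - 1]) & (t[idx] < t[idx + 1]))

    def test_adjacent_mid_temperatures_are_closest_pair(self):
        cfg = SyntheticConfig()
        templates = np.array([class_template(cfg, c) for c in range(6)])
        dists = {(i, j): np.linalg.norm(templates[i] - templates[j])
                 for i in range(6) for j in range(i + 1, 6)}
        assert min(dists, key=dists.get) == (2, 3)  # 150 vs 200 degC

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError, match="class_index"):
            class_template(SyntheticConfig(), 6)


class TestGenerate:
    def test_determinism_bit_identical(self):
        cfg = SyntheticConfig(n_bands=60, samples_per_class=15, seed=11)
        a, b = generate(cfg), generate(cfg)
        np.testing.assert_array_equal(a.spectra, b.spectra)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_shape_and_balanced_labels(self):
        ds = generate(SyntheticConfig(n_bands=60, samples_per_class=9, seed=0))
        assert ds.spectra.shape == (54, 60)
        np.testing.assert_array_equal(np.bincount(ds.labels), [9] * 6)
        assert ds.class_names[0] == "50 degC" and ds.class_names[-1] == "300 degC"

    def test_zero_noise_reproduces_templates_exactly(self):
        cfg = SyntheticConfig(n_bands=80, samples_per_class=4, noise_sd=0.0,
                              illum_scale_sd=0.0, interference_sd=0.0, seed=5)
        ds = generate(cfg)
        for c in range(6):
            block = ds.spectra[ds.labels == c]
            np.testing.assert_array_equal(block, np.tile(class_template(cfg, c),
                                                         (4, 1)))

    def test_zero_noise_is_nearest_neighbor_separable(self):
        cfg = SyntheticConfig(samples_per_class=30, noise_sd=0.0,
                              illum_scale_sd=0.0, interference_sd=0.0, seed=2)
        ds = generate(cfg)
        scores = cross_val_score(KNeighborsClassifier(1), ds.spectra,
                                 ds.labels, cv=10)
        assert scores.mean() == 1.0

    def test_class_means_converge_to_templates(self):
        """At large n the class-conditional sample mean approaches the
        template: the band-averaged deviation stays within 3 standard
        errors and nearly all bands individually within 4."""
        cfg = SyntheticConfig(samples_per_class=10_000, seed=13)
        ds = generate(cfg)
        for c in range(6):
            block = ds.spectra[ds.labels == c]
            tmpl = class_template(cfg, c)
            dev = block.mean(axis=0) - tmpl
            se = block.std(axis=0, ddof=1) / np.sqrt(block.shape[0])
            # band-averaged deviation: its SE must respect the cross-band
            # correlation of the illumination terms, so compute it from the
            # per-sample band averages directly
            row_means = block.mean(axis=1)
            se_avg = row_means.std(ddof=1) / np.sqrt(block.shape[0])
            assert abs(dev.mean()) < 3 * se_avg
            assert np.mean(np.abs(dev) < 4 * se) > 0.98

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SyntheticConfig(noise_sd=-0.1)
        with pytest.raises(ValueError, match="decrease"):
            SyntheticConfig(dip_depth_by_class=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6))
        with pytest.raises(ValueError, match="samples_per_class"):
            generate(SyntheticConfig(samples_per_class=0))


class TestDifficultySweep:
    LEVELS = (0.0, 0.02, 0.05, 0.12)

    def test_level_matching_config_reproduces_generate(self):
        cfg = SyntheticConfig(n_bands=50, samples_per_class=10, seed=3,
                              noise_sd=0.02)
        sweep = difficulty_sweep(cfg, self.LEVELS)
        np.testing.assert_array_equal(sweep[1].spectra, generate(cfg).spectra)

    def test_templates_fixed_across_levels(self):
        cfg = SyntheticConfig(n_bands=50, samples_per_class=10, seed=3)
        for lv in self.LEVELS:
            c = dataclasses.replace(cfg, noise_sd=lv)
            np.testing.assert_array_equal(class_template(c, 2),
                                          class_template(cfg, 2))

    def test_accuracy_non_increasing_with_noise(self):
        """Median LDA cross-validated accuracy over 5 generator seeds must
        not improve as additive noise grows."""
        levels = (0.0, 0.05, 0.25)
        medians = []
        for lv in levels:
            accs = []
            for seed in range(5):
                cfg = SyntheticConfig(n_bands=60, samples_per_class=40,
                                      seed=seed, noise_sd=lv)
                ds = generate(cfg)
                accs.append(cross_val_score(LinearDiscriminantAnalysis(),
                                            ds.spectra, ds.labels, cv=3).mean())
            medians.append(np.median(accs))
        assert all(a >= b - 1e-9 for a, b in zip(medians, medians[1:]))

    def test_rejects_bad_levels(self):
        cfg = SyntheticConfig(n_bands=40, samples_per_class=5)
        with pytest.raises(ValueError, match="non-negative"):
            difficulty_sweep(cfg, [-0.1, 0.0])
        with pytest.raises(ValueError, match="non-decreasing"):
            difficulty_sweep(cfg, [0.1, 0.0])
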