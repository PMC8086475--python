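"""Preprocessing, SNR, SVM classification, cross-validation partitions."""

import numpy as np
import pytest

from fastraman.library import WAVENUMBERS, spectral_library
from fastraman.phantom import training_set
from fastraman.spectra import (
    RamanClassifier,
    cross_validate_5fold,
    lopo_partition,
    preprocess,
    robust_noise_sd,
    snr,
    train_classifier,
)


class TestPreprocess:
    def test_output_has_unit_norm(self, make_spectrum):
        rng = np.random.default_rng(0)
        s = make_spectrum(rng.normal(1.0, 0.2, WAVENUMBERS.size))
        out = preprocess(s)
        assert np.linalg.norm(out.intensities) == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(out.wavenumbers, s.wavenumbers)

    def test_idempotent(self, make_spectrum, library):
        s = make_spectrum(library["bcc"] + 0.3)
        once = preprocess(s)
        twice = preprocess(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-9)

    def test_linear_ramp_invariance(self, make_spectrum, library):
        base = make_spectrum(library["dermis"])
        ramp = make_spectrum(
            library["dermis"] + 0.5 + 0.001 * (WAVENUMBERS - WAVENUMBERS[0])
        )
        np.testing.assert_allclose(
            preprocess(ramp).intensities, preprocess(base).intensities, atol=1e-9
        )

    def test_zero_spectrum_rejected(self, make_spectrum):
        with pytest.raises(ValueError, match="no signal"):
            preprocess(make_spectrum(np.zeros(WAVENUMBERS.size)))

    def test_short_axis_rejected(self):
        from fastraman.phantom import Spectrum

        s = Spectrum(np.arange(8.0), np.ones(8), (0, 0), 2.0)
        with pytest.raises(ValueError, match="too short"):
            preprocess(s)


class TestSnr:
    def test_pure_noise_below_contact_threshold(self, make_spectrum):
        rng = np.random.default_rng(0)
        vals = [
            snr(make_spectrum(rng.normal(0, 0.02, WAVENUMBERS.size)))
            for _ in range(1000)
        ]
        assert np.mean(np.asarray(vals) < 7) >= 0.99

    def test_noiseless_template_effectively_infinite(self, make_spectrum, library):
        for cls in ("dermis", "bcc", "epidermis", "fat", "blood"):
            u = np.linspace(-1, 1, WAVENUMBERS.size)
            s = make_spectrum(library[cls] + 0.2 + 0.1 * u - 0.1 * u * u)
            assert snr(s) >= 1e6

    def test_constant_spectrum_gives_zero(self, make_spectrum):
        assert snr(make_spectrum(np.full(WAVENUMBERS.size, 3.0))) == 0.0

    def test_calibration_at_nominal_ratio_seven(self, make_spectrum, library):
        # Monte-Carlo calibration: peak/sigma = 7 by construction
        rng = np.random.default_rng(1)
        vals = np.array(
            [
                snr(make_spectrum(library["dermis"] + rng.normal(0, 1 / 7, WAVENUMBERS.size)))
                for _ in range(300)
            ]
        )
        assert 5.0 <= np.median(vals) <= 9.0
        assert vals.min() > 4.5 and vals.max() < 9.5

    def test_noise_sd_estimator_is_calibrated(self, library):
        rng = np.random.default_rng(2)
        for true_sd in (0.01, 0.02, 0.028):
            est = np.mean(
                [
                    robust_noise_sd(library["bcc"] + rng.normal(0, true_sd, WAVENUMBERS.size))
                    for _ in range(200)
                ]
            )
            assert est == pytest.approx(true_sd, rel=0.08)


class TestClassifier:
    def test_separable_classes_reach_perfect_training_accuracy(self):
        X, y = training_set(30, seed=0, classes=("bcc", "fat"), raman_noise_sd=0.005)
        clf = train_classifier(X, y, wavenumbers=WAVENUMBERS)
        assert (clf.predict(X) == y).all()

    def test_cross_validation_high_accuracy_at_default_separability(self):
        X, y = training_set(100, seed=1)
        rep = cross_validate_5fold(X, y, seed=0, wavenumbers=WAVENUMBERS)
        assert rep.accuracy >= 95.0
        # row sums conserved
        assert rep.class_matrix.sum(axis=1).tolist() == [100] * len(rep.class_matrix)

    def test_shuffled_balanced_labels_score_at_chance(self):
        X, y = training_set(150, seed=2, classes=("bcc", "dermis"))
        rng = np.random.default_rng(3)
        rep = cross_validate_5fold(X, rng.permutation(y), seed=0, wavenumbers=WAVENUMBERS)
        assert 40.0 <= rep.accuracy <= 60.0

    def test_missing_required_class_reported_by_name(self):
        X, y = training_set(25, seed=3, classes=("bcc", "dermis"))
        with pytest.raises(ValueError, match="blood"):
            train_classifier(X, y, required_classes=("bcc", "dermis", "blood"))

    def test_too_few_spectra_per_class_rejected(self):
        X, y = training_set(10, seed=4, classes=("bcc", "dermis"))
        with pytest.raises(ValueError, match=">= 20"):
            train_classifier(X, y)

    def test_single_class_rejected(self):
        X, y = training_set(30, seed=5, classes=("bcc",))
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(X, y)
        with pytest.raises(ValueError, match="2 classes"):
            cross_validate_5fold(X, y)

    def test_too_few_for_stratification_rejected(self):
        X, y = training_set(30, seed=6, classes=("bcc", "dermis"))
        X = np.vstack([X, X[:2]])
        y = np.concatenate([y, ["fat", "fat"]])
        with pytest.raises(ValueError, match="stratify"):
            cross_validate_5fold(X, y)

    def test_deterministic_given_seed(self):
        X, y = training_set(30, seed=7, classes=("bcc", "dermis", "fat"))
        a = cross_validate_5fold(X, y, seed=5, wavenumbers=WAVENUMBERS)
        b = cross_validate_5fold(X, y, seed=5, wavenumbers=WAVENUMBERS)
        assert a.class_matrix.equals(b.class_matrix)

    def test_margin_shrinks_with_shorter_exposure(self, model):
        # noisier (1 s) spectra sit closer to the decision boundary
        X2, _ = training_set(80, seed=8, exposure=2.0)
        X1, _ = training_set(80, seed=8, exposure=1.0)
        assert np.median(model.predict_margin(X1)) < np.median(
            model.predict_margin(X2)
        )

    def test_sklearn_params_roundtrip(self):
        clf = RamanClassifier(C=2.0, kernel="rbf")
        params = clf.get_params()
        assert params["C"] == 2.0 and params["kernel"] == "rbf"
        clf2 = RamanClassifier(**params)
        assert clf2.get_params() == params


class TestLopoPartition:
    def test_three_patients_three_partitions(self):
        parts = lopo_partition(["a", "a", "b", "c", "c"])
        assert len(parts) == 3
        for train, test in parts:
            assert set(train) & set(test) == set()

    def test_held_out_sets_cover_everything_once(self):
        pid = np.repeat([f"p{i}" for i in range(112)], 3)
        parts = lopo_partition(pid)
        assert len(parts) == 112
        covered = np.concatenate([test for _, test in parts])
        assert sorted(covered.tolist()) == list(range(pid.size))
        for train, test in parts:
            assert len(set(pid[train])) == 111
            assert len(set(pid[test])) == 1

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError, match="2 patients"):
            lopo_partition(["only", "only"])
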