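"""Stain-physics simulator: determinism, class structure, patient effects."""

import numpy as np
import pytest

from hsinuclei.cube_io import calibrate_transmittance
from hsinuclei.simulate import (
    SceneSpec,
    StainModel,
    generate_patch_dataset,
    generate_patient_set,
    generate_scene,
    generate_spectrum_records,
    sample_nucleus_counts,
)
from hsinuclei.spectra import normalize_spectrum


class TestStainModel:
    def test_absorbance_curves_unit_peak_nonnegative(self):
        stains = StainModel()
        for curve in (stains.eosin_absorbance, stains.hematoxylin_absorbance):
            assert curve.max() == pytest.approx(1.0, abs=1e-6)
            assert (curve >= 0).all()

    def test_peaks_at_configured_wavelengths(self):
        stains = StainModel()
        lam = stains.wavelengths
        assert abs(lam[stains.eosin_absorbance.argmax()] - 525) < 3
        assert abs(lam[stains.hematoxylin_absorbance.argmax()] - 600) < 3


class TestGenerateScene:
    def test_same_seed_bit_identical(self):
        spec = SceneSpec(shape=(96, 96), n_nuclei=6, seed=5)
        a, b = generate_scene(spec), generate_scene(spec)
        np.testing.assert_array_equal(a.raw.data, b.raw.data)
        np.testing.assert_array_equal(a.truth_labels, b.truth_labels)

    def test_different_seeds_differ(self):
        a = generate_scene(SceneSpec(shape=(96, 96), n_nuclei=6, seed=1))
        b = generate_scene(SceneSpec(shape=(96, 96), n_nuclei=6, seed=2))
        assert not np.array_equal(a.truth_labels, b.truth_labels)

    def test_empty_scene_is_background_spectrum(self):
        spec = SceneSpec(shape=(64, 64), n_nuclei=0, n_lymphocytes=0,
                         background_fraction=0.0, noise_sd=0.001, seed=3)
        bundle = generate_scene(spec)
        assert bundle.truth_labels.max() == 0
        assert len(bundle.truth_centroids) == 0
        cal = calibrate_transmittance(bundle.raw, bundle.references)
        # cytoplasm-only field: every pixel close to the mean spectrum,
        # up to the smooth staining texture and shot noise
        mean_spec = cal.data.reshape(-1, 87).mean(axis=0)
        dev = np.abs(cal.data - mean_spec).mean()
        assert dev < 0.05

    def test_unplaceable_nuclei_reported(self):
        spec = SceneSpec(shape=(80, 80), n_nuclei=200, seed=4, max_retries=5)
        bundle = generate_scene(spec)
        assert bundle.n_placed < bundle.n_requested
        assert bundle.truth_labels.max() == bundle.n_placed

    def test_calibration_closes_loop_within_noise(self):
        spec = SceneSpec(shape=(96, 96), n_nuclei=5, noise_sd=0.01,
                         blur_fraction=0.0, seed=6)
        bundle = generate_scene(spec)
        cal = calibrate_transmittance(bundle.raw, bundle.references)
        err = cal.data - np.clip(bundle.truth.data, 0, 1.5)
        assert np.sqrt((err**2).mean()) < 2 * spec.noise_sd

    def test_class_mean_spectra_cross_once_near_645(self):
        lam = StainModel().wavelengths
        means = {}
        for label in ("cancerous", "normal"):
            spec = SceneSpec(shape=(160, 160), n_nuclei=12, label=label,
                             noise_sd=0.0, blur_fraction=0.0,
                             equalize_morphology=True, seed=9)
            bundle = generate_scene(spec)
            nuc = bundle.truth_labels > 0
            means[label] = bundle.truth.data[nuc].mean(axis=0)
        diff = means["cancerous"] - means["normal"]
        signs = np.sign(diff)
        crossings = np.nonzero(np.diff(signs))[0]
        assert len(crossings) == 1
        crossing_wavelength = (lam[crossings[0]] + lam[crossings[0] + 1]) / 2
        assert 640 <= crossing_wavelength <= 650


class TestPatientSet:
    def test_reversed_fraction_count_exact(self):
        tiny = SceneSpec(shape=(72, 72), n_nuclei=3, n_lymphocytes=0)
        cohort = generate_patient_set(6, images_per_patient=1,
                                      reversed_fraction=1 / 6,
                                      base_spec=tiny, seed=2)
        assert sum(p.reversed_trend for p in cohort) == 1

    def test_each_patient_contributes_both_classes(self):
        tiny = SceneSpec(shape=(72, 72), n_nuclei=3, n_lymphocytes=0)
        cohort = generate_patient_set(2, images_per_patient=2,
                                      base_spec=tiny, seed=3)
        for p in cohort:
            assert {s.label for s in p.scenes} == {"cancerous", "normal"}

    def test_invalid_reversed_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_patient_set(3, reversed_fraction=1.5)


class TestSpectrumRecords:
    def test_thickness_changes_amplitude_not_normalized_shape(self):
        """Doubling section thickness darkens spectra; sum-normalization
        removes the effect (the stated rationale for Eq-style scaling)."""
        base = generate_spectrum_records(2, 20, tilt_amplitude=0.05,
                                         noise_sd=0.0, seed=4)
        # rebuild the same records with an explicit thickness change:
        # thickness enters as a power on transmittance, so normalized
        # shapes change only through the power law, not amplitude.
        raw = base[0].raw
        thicker = raw**2  # Beer-Lambert: doubled thickness squares T
        assert thicker.sum() < raw.sum()  # uniformly darker
        n1, n2 = normalize_spectrum(raw), normalize_spectrum(thicker)
        # amplitude information is gone from both (each sums to 1)
        assert n1.sum() == pytest.approx(1.0) and n2.sum() == pytest.approx(1.0)

    def test_balanced_classes_per_patient(self):
        recs = generate_spectrum_records(3, 10, seed=5)
        for pid in {r.patient_id for r in recs}:
            labels = [r.label for r in recs if r.patient_id == pid]
            assert labels.count("cancerous") == labels.count("normal")

    def test_null_simulator_has_no_class_difference(self):
        recs = generate_spectrum_records(2, 50, tilt_amplitude=0.0,
                                         noise_sd=0.0, seed=6)
        by_label = {}
        for lab in ("cancerous", "normal"):
            sel = [r.normalized for r in recs
                   if r.label == lab and r.patient_id == "P01"]
            by_label[lab] = np.mean(sel, axis=0)
        np.testing.assert_allclose(by_label["cancerous"], by_label["normal"],
                                   atol=5e-4)


class TestPatchDataset:
    def test_shapes_and_balance(self):
        ds = generate_patch_dataset(n_patients=2, patches_per_class=3,
                                    patch_size=31, seed=7)
        assert ds["hsi"].shape == (12, 31, 31, 87)
        assert ds["rgb"].shape == (12, 31, 31, 3)
        assert ds["labels"].sum() == 6
        assert set(ds["patients"]) == {"P01", "P02"}

    def test_deterministic(self):
        a = generate_patch_dataset(2, 2, patch_size=31, seed=8)
        b = generate_patch_dataset(2, 2, patch_size=31, seed=8)
        np.testing.assert_array_equal(a["hsi"], b["hsi"])


def test_nucleus_count_distribution_matches_field_mix():
    """Counts reproduce the observed 21-50 / 51-100 / >100 field mix."""
    counts = sample_nucleus_counts(20000, np.random.default_rng(0))
    assert counts.min() >= 21
    p_low = ((counts >= 21) & (counts <= 50)).mean()
    p_mid = ((counts >= 51) & (counts <= 100)).mean()
    p_high = (counts > 100).mean()
    assert p_low == pytest.approx(90 / 197, abs=0.05)
    assert p_mid == pytest.approx(88 / 197, abs=0.05)
    assert p_high == pytest.approx(19 / 197, abs=0.04)
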