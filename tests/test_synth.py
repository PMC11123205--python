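"""HRF model, dynamic absorption, dataset generation and MAC validation."""

import numpy as np
import pytest

from sfsmac import (
    ArtifactSchedule,
    HemodynamicModel,
    canonical_hrf,
    figure4_experiment,
    generate_dynamic_dataset,
    mu_a_dynamic,
    physiological_response,
)
from sfsmac.optics import load_extinction_table


class TestCanonicalHRF:
    def test_zero_at_origin(self):
        assert canonical_hrf(np.array([0.0]))[0] == 0.0

    def test_peak_in_physiological_window(self):
        t = np.arange(0.0, 30.0, 0.1)
        h = canonical_hrf(t)
        assert 4.0 <= t[np.argmax(h)] <= 6.0

    def test_single_sign_change_with_undershoot(self):
        t = np.arange(0.1, 30.0, 0.1)
        h = canonical_hrf(t)
        signs = np.sign(h[np.abs(h) > 1e-12])
        assert (np.diff(signs) != 0).sum() == 1
        assert h[5] > 0 and h.min() < 0  # positive lobe then undershoot

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(np.array([1.0]), alpha1=0.0)


class TestPhysiologicalResponse:
    def test_dc_only_response(self):
        m = HemodynamicModel(p_hrf=0.0, p_cardiac=0.0, p_resp=0.0, p_mayer=0.0,
                             p_dc=3.0)
        resp = physiological_response(m)
        np.testing.assert_allclose(resp.response, 3.0)
        np.testing.assert_allclose(resp.normalized, 0.0)

    def test_pure_cardiac_spectrum_peaks_at_one_hertz(self):
        m = HemodynamicModel(p_hrf=0.0, p_cardiac=1.0, p_resp=0.0, p_mayer=0.0,
                             duration=30.0)
        resp = physiological_response(m)
        spec = np.abs(np.fft.rfft(resp.response))
        freqs = np.fft.rfftfreq(resp.response.size, 0.1)
        assert freqs[np.argmax(spec[1:]) + 1] == pytest.approx(1.0, abs=0.05)

    def test_impulse_stimulus_recovers_impulse_response(self):
        dt = 0.1
        m = HemodynamicModel(stimulus=[(2.0, 2.0 + dt)], p_cardiac=0.0,
                             p_resp=0.0, p_mayer=0.0, duration=20.0)
        resp = physiological_response(m)
        t = m.times
        shifted = canonical_hrf(np.maximum(t - 2.0, 0.0)) * dt
        mask = t > 2.0
        np.testing.assert_allclose(resp.response[mask], shifted[mask], atol=1e-12)

    def test_normalization_attains_unit_maximum(self):
        resp = physiological_response(HemodynamicModel())
        assert resp.normalized.min() == 0.0
        assert resp.normalized.max() == 1.0

    def test_identically_zero_response_rejected(self):
        m = HemodynamicModel(p_hrf=0.0, p_cardiac=0.0, p_resp=0.0, p_mayer=0.0)
        with pytest.raises(ValueError, match="zero"):
            physiological_response(m)

    def test_oscillation_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            HemodynamicModel(f_cardiac=6.0)


class TestDynamicAbsorption:
    model = HemodynamicModel()

    def test_baseline_value_at_zero_response(self):
        table = load_extinction_table()
        lam = 545.0
        mu = mu_a_dynamic(self.model, np.zeros(3), lam)
        expected = table.mu_from_concentration(lam, 25.0, 25.0)  # C_HbT/2 each
        np.testing.assert_allclose(mu, expected)

    def test_monotone_in_normalized_response(self):
        y = np.linspace(0.0, 1.0, 11)
        for lam in (545.0, 680.0):
            mu = mu_a_dynamic(self.model, y, lam)
            assert np.all(np.diff(mu) > 0)

    def test_isosbestic_collapse_is_affine_in_y(self):
        # at an isosbestic wavelength with equal concentration excursions the
        # formula collapses to a single scaled copy of y plus a constant
        m = HemodynamicModel(dc_hbo_uM=5.0, dc_hbr_uM=5.0)
        y = np.linspace(0.0, 1.0, 9)
        mu = mu_a_dynamic(m, y, 545.0)
        fitted = np.polynomial.polynomial.polyfit(y, mu, 1)
        np.testing.assert_allclose(
            np.polynomial.polynomial.polyval(y, fitted), mu, rtol=1e-12
        )

    def test_wavelength_outside_table_rejected(self):
        with pytest.raises(ValueError):
            mu_a_dynamic(self.model, np.zeros(2), 3000.0)

    def test_y_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            mu_a_dynamic(self.model, np.array([1.2]), 545.0)


class TestArtifactSchedule:
    def test_transmission_profile_half_open(self):
        sched = ArtifactSchedule([(2.0, 3.5, 0.96)])
        t = np.arange(0.0, 7.0, 0.1)
        tau = sched.transmission(t)
        assert tau[t == 2.0][0] == 0.96
        assert tau[np.isclose(t, 3.5)][0] == 1.0
        assert tau[t < 2.0].min() == 1.0

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            ArtifactSchedule([(0.0, 1.0, 0.0)])


class TestGenerateDynamicDataset:
    kwargs = dict(n_photons=4_000, seed=13)

    def test_empty_schedule_reproduces_ideal_bit_exactly(self):
        ds = generate_dynamic_dataset(schedule=ArtifactSchedule(), **self.kwargs)
        np.testing.assert_array_equal(
            ds.ideal_frame.intensities, ds.corrupted_frame.intensities
        )

    def test_same_seed_is_deterministic(self):
        a = generate_dynamic_dataset(schedule=ArtifactSchedule.paper_default(),
                                     **self.kwargs)
        b = generate_dynamic_dataset(schedule=ArtifactSchedule.paper_default(),
                                     **self.kwargs)
        np.testing.assert_array_equal(
            a.corrupted_frame.intensities, b.corrupted_frame.intensities
        )

    def test_artifact_scales_tissue_return_by_tau_squared(self):
        tau = 0.96
        ds = generate_dynamic_dataset(schedule=ArtifactSchedule([(2.0, 3.5, tau)]),
                                      **self.kwargs)
        t = ds.ideal_frame.times
        in_event = (t >= 2.0) & (t < 3.5)
        for j in range(2):
            ideal = ds.ideal_frame.intensities[:, j]
            corrupt = ds.corrupted_frame.intensities[:, j]
            spec = ds.truth["specular"][j]
            ratio = (corrupt[in_event] - spec) / (ideal[in_event] - spec)
            np.testing.assert_allclose(ratio, tau**2, rtol=1e-12)
            np.testing.assert_array_equal(corrupt[~in_event], ideal[~in_event])

    def test_flat_channels_without_stimulus_or_oscillations(self):
        m = HemodynamicModel(p_cardiac=0.0, p_resp=0.0, p_mayer=0.0, p_dc=1.0,
                             p_hrf=0.0)
        ds = generate_dynamic_dataset(m, ArtifactSchedule(), **self.kwargs)
        assert np.ptp(ds.ideal_frame.intensities, axis=0) == pytest.approx(0.0)

    def test_artifact_confined_to_event_and_680_untouched_by_stimulus(self):
        ds = generate_dynamic_dataset(schedule=ArtifactSchedule.paper_default(),
                                      n_photons=20_000, seed=2)
        t = ds.corrupted_frame.times
        i680 = ds.corrupted_frame.column(680.0)
        in_event = (t >= 2.0) & (t < 3.5)
        step = i680[in_event].mean() / i680[~in_event].mean()
        assert step < 0.95  # clear step down during the event
        # outside the event the 680 channel is flat to well under the step size
        outside = i680[~in_event]
        assert np.ptp(outside) / outside.mean() < 0.01

    def test_full_mc_engine_consistency(self):
        m = HemodynamicModel(duration=1.0, stimulus=[(0.2, 0.4)])
        ds = generate_dynamic_dataset(
            m, ArtifactSchedule(), engine="full-mc", n_photons=800, seed=3
        )
        np.testing.assert_array_equal(
            ds.ideal_frame.intensities, ds.corrupted_frame.intensities
        )
        assert ds.ideal_frame.intensities.shape == (10, 2)


class TestFigureFourExperiment:
    @pytest.mark.parametrize("tau", [0.96, 0.9, 0.8])
    def test_correction_reduces_during_artifact_error(self, tau):
        ds = generate_dynamic_dataset(
            schedule=ArtifactSchedule([(2.0, 3.5, tau)]),
            n_photons=30_000, seed=17, independent_reference=True,
        )
        rep = figure4_experiment(ds)
        assert rep.mse_corrected_vs_ideal[1] < rep.mse_corrupted_vs_ideal[1]

    def test_artifact_free_dataset_unchanged_by_correction(self):
        # per-sample MC (the two-series procedure): with no artifact the 680 nm
        # proxy is noise-dominated, the fitted scale stays small, and correction
        # leaves the perfusion trace at the corrupted trace's noise floor
        ds = generate_dynamic_dataset(
            schedule=ArtifactSchedule([(2.0, 3.5, 1.0 - 1e-9)]),
            engine="full-mc", n_photons=3_000, seed=19,
            independent_reference=True,
        )
        rep = figure4_experiment(ds)
        for k in range(3):
            assert rep.mse_corrected_vs_ideal[k] == pytest.approx(
                rep.mse_corrupted_vs_ideal[k], rel=2.0
            )

    def test_during_artifact_error_dominates(self):
        ds = generate_dynamic_dataset(
            schedule=ArtifactSchedule.paper_default(),
            n_photons=30_000, seed=23, independent_reference=True,
        )
        rep = figure4_experiment(ds)
        m = rep.mse_corrupted_vs_ideal
        assert m[1] > 100.0 * max(m[0], m[2])
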