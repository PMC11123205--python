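"""Interface intensity model, artifact proxy, and the regression correction."""

import numpy as np
import pytest
from sklearn.base import clone

from sfsmac import (
    InterfacePathModel,
    MacModel,
    MotionArtifactCorrector,
    apply_mac,
    artifact_proxy,
    fit_mac,
    forward_intensity,
)

from conftest import make_frame


def path_model(**overrides):
    base = dict(
        incident_spectrum=np.array([100.0, 80.0]),
        near_reflection=np.array([0.03, 0.03]),
        near_transmission_in=np.array([0.97, 0.97]),
        near_transmission_out=np.array([0.97, 0.97]),
        far_reflection_brain=np.array([0.001, 0.001]),
        far_transmission_in=np.array([0.99, 0.99]),
        far_transmission_out=np.array([0.99, 0.99]),
        fiber_transmission=np.array([1.0, 1.0]),
        tissue_reflectance=np.array([0.5, 0.4]),
    )
    base.update(overrides)
    return InterfacePathModel(**base)


class TestForwardIntensity:
    def test_specular_only_when_no_tissue_or_far_return(self):
        m = path_model(
            tissue_reflectance=np.zeros(2), far_reflection_brain=np.zeros(2)
        )
        total, terms = forward_intensity(m)
        np.testing.assert_allclose(total, m.incident_spectrum * m.near_reflection)
        np.testing.assert_allclose(terms["far_fresnel"], 0.0)

    def test_lossless_path_returns_tissue_reflectance(self):
        ones = np.ones(2)
        m = path_model(
            near_reflection=np.zeros(2),
            near_transmission_in=ones, near_transmission_out=ones,
            far_reflection_brain=np.zeros(2),
            far_transmission_in=ones, far_transmission_out=ones,
            fiber_transmission=ones, tissue_reflectance=np.array([0.5, 0.4]),
        )
        total, _ = forward_intensity(m)
        np.testing.assert_allclose(total, m.incident_spectrum * m.tissue_reflectance)

    def test_far_transmission_scales_tissue_term_quadratically(self):
        tau = 0.9
        m0 = path_model()
        m1 = path_model(
            far_transmission_in=tau * m0.far_transmission_in,
            far_transmission_out=tau * m0.far_transmission_out,
        )
        _, t0 = forward_intensity(m0)
        _, t1 = forward_intensity(m1)
        np.testing.assert_allclose(
            t1["tissue_backscatter"], tau**2 * t0["tissue_backscatter"]
        )
        np.testing.assert_allclose(t1["near_specular"], t0["near_specular"])

    def test_coefficient_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            path_model(far_transmission_in=np.array([1.2, 0.9]))


class TestArtifactProxy:
    def test_constant_band_gives_zero(self):
        frame = make_frame(np.full((5, 2), 4.0), [675.0, 680.0])
        np.testing.assert_allclose(artifact_proxy(frame), 0.0)

    def test_mean_removal(self):
        frame = make_frame([[4.0], [6.0]], [680.0])
        np.testing.assert_allclose(artifact_proxy(frame), [-1.0, 1.0])

    def test_additive_constant_invariance(self):
        frame = make_frame([[4.0], [6.0], [5.0]], [680.0])
        shifted = make_frame(frame.intensities + 11.0, [680.0])
        np.testing.assert_allclose(
            artifact_proxy(frame), artifact_proxy(shifted), atol=1e-12
        )


def common_mode_frame(n=60, seed=0, noise=0.0, m_true=(0.8, 1.3, 1.0), scale=1.0):
    """Frame where every channel is c + m * x(t), with x the 680 nm proxy."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, scale, n)
    x -= x.mean()
    wavelengths = [545.0, 600.0, 680.0]
    base = np.array([50.0, 40.0, 30.0])
    intensities = base + np.outer(x, np.asarray(m_true))
    if noise:
        intensities = intensities + rng.normal(0.0, noise, intensities.shape)
    return make_frame(intensities, wavelengths), np.asarray(m_true), x


class TestFitMac:
    def test_exact_common_mode_recovery(self):
        frame, m_true, _ = common_mode_frame()
        model = fit_mac(frame, band=(680.0, 680.0))
        np.testing.assert_allclose(model.m, m_true, rtol=1e-10)

    def test_independent_channel_slope_within_three_standard_errors(self):
        rng = np.random.default_rng(3)
        n = 1000
        x = rng.normal(0.0, 1.0, n)
        y = rng.normal(0.0, 1.0, n)  # independent of the proxy
        frame = make_frame(
            np.column_stack([10.0 + y, 20.0 + x]), [545.0, 680.0]
        )
        model = fit_mac(frame, band=(680.0, 680.0))
        se = y.std() / (np.sqrt(n) * x.std())
        assert abs(model.m[0]) < 3.0 * se

    def test_recovery_within_five_percent_at_one_percent_noise(self):
        # artifact excursions ~10 counts on a 30-50 count baseline, 1% noise
        frame, m_true, x = common_mode_frame(n=500, seed=11, noise=0.4, scale=5.0)
        model = fit_mac(frame, band=(680.0, 680.0))
        assert model.m[0] == pytest.approx(m_true[0], rel=0.05)

    def test_zero_variance_proxy_rejected(self):
        frame = make_frame(np.full((10, 2), 5.0), [545.0, 680.0])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_mac(frame)

    def test_diagnostics_r2_is_one_for_exact_fit(self):
        frame, _, _ = common_mode_frame()
        model = fit_mac(frame, band=(680.0, 680.0))
        np.testing.assert_allclose(model.fit_diagnostics["r2"], 1.0, atol=1e-9)


class TestApplyMac:
    def test_exact_common_mode_correction_flattens_everything(self):
        frame, _, _ = common_mode_frame()
        model = fit_mac(frame, band=(680.0, 680.0))
        corrected = apply_mac(frame, model)
        assert np.ptp(corrected.intensities, axis=0) == pytest.approx(0.0, abs=1e-9)

    def test_zero_m_is_identity(self):
        frame, _, _ = common_mode_frame()
        model = fit_mac(frame, band=(680.0, 680.0))
        model.m = np.zeros_like(model.m)
        corrected = apply_mac(frame, model)
        np.testing.assert_array_equal(corrected.intensities, frame.intensities)

    def test_corrected_proxy_has_zero_variance(self):
        frame, _, _ = common_mode_frame()
        model = fit_mac(frame, band=(680.0, 680.0))
        corrected = apply_mac(frame, model)
        assert np.var(artifact_proxy(corrected, model.band)) == pytest.approx(0.0, abs=1e-18)

    def test_temporal_mean_preserved_exactly(self):
        frame, _, _ = common_mode_frame(noise=0.5, seed=5)
        model = fit_mac(frame, band=(680.0, 680.0))
        corrected = apply_mac(frame, model)
        np.testing.assert_allclose(
            corrected.intensities.mean(axis=0),
            frame.intensities.mean(axis=0),
            rtol=1e-13,
        )

    def test_second_pass_fit_is_null(self):
        """Refitting on the corrected exact common-mode frame gives m ~ 0."""
        frame, _, _ = common_mode_frame()
        model = fit_mac(frame, band=(680.0, 680.0))
        corrected = apply_mac(frame, model)
        # corrected band channel is constant -> proxy variance vanishes
        with pytest.raises(ValueError, match="zero-variance"):
            fit_mac(corrected, band=(680.0, 680.0))

    def test_grid_mismatch_rejected(self):
        frame, _, _ = common_mode_frame()
        model = fit_mac(frame, band=(680.0, 680.0))
        other = make_frame(frame.intensities[:, :2], [545.0, 600.0])
        with pytest.raises(ValueError, match="grid"):
            apply_mac(other, model)

    def test_no_artifact_change_bounded_by_proxy_excursion(self):
        rng = np.random.default_rng(9)
        intensities = 50.0 + rng.normal(0.0, 0.01, (200, 3))
        frame = make_frame(intensities, [545.0, 600.0, 680.0])
        model = fit_mac(frame, band=(680.0, 680.0))
        corrected = apply_mac(frame, model)
        n_hat = artifact_proxy(frame, model.band)
        bound = np.abs(model.m).max() * np.abs(n_hat).max()
        assert np.abs(corrected.intensities - frame.intensities).max() <= bound + 1e-12


class TestEstimatorInterface:
    def test_get_set_params_and_clone(self):
        est = MotionArtifactCorrector(band=(670.0, 680.0), robust=True)
        params = est.get_params()
        assert params["robust"] is True
        twin = clone(est)
        assert twin.get_params()["band"] == (670.0, 680.0)

    def test_fit_transform_matrix_api(self):
        frame, m_true, x = common_mode_frame()
        est = MotionArtifactCorrector(
            wavelengths=frame.wavelengths, band=(680.0, 680.0)
        )
        out = est.fit_transform(frame.intensities)
        assert est.m_ == pytest.approx(m_true, rel=1e-9)
        assert np.ptp(out, axis=0) == pytest.approx(0.0, abs=1e-9)

    def test_column_index_band_without_wavelengths(self):
        frame, m_true, _ = common_mode_frame()
        est = MotionArtifactCorrector(band=(2, 2)).fit(frame.intensities)
        np.testing.assert_allclose(est.m_, m_true, rtol=1e-9)

    def test_robust_option_recovers_slope_under_spikes(self):
        frame, m_true, x = common_mode_frame(n=200, seed=21, noise=0.05)
        corrupted = frame.intensities.copy()
        corrupted[::37, 0] += 25.0  # gross spike outliers off the common mode
        est_plain = MotionArtifactCorrector(band=(2, 2)).fit(corrupted)
        est_robust = MotionArtifactCorrector(band=(2, 2), robust=True).fit(corrupted)
        assert abs(est_robust.m_[0] - m_true[0]) < abs(est_plain.m_[0] - m_true[0])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            MotionArtifactCorrector(band=(0, 0)).fit(np.ones((2, 2)))


class TestMacModelSerialization:
    def test_json_round_trip(self, tmp_path):
        frame, _, _ = common_mode_frame()
        model = fit_mac(frame, band=(670.0, 680.0))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MacModel.from_json(path)
        np.testing.assert_allclose(back.m, model.m)
        assert back.band == model.band
        assert back.proxy_mean == pytest.approx(model.proxy_mean)
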