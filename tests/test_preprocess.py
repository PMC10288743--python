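"""Optical-density conversion, Beer-Lambert inversion, filtering, CBSI,
artifact scoring and z-normalisation."""

import numpy as np
import pytest
from dataclasses import replace

from hypothesis import given, settings
from hypothesis import strategies as st

from nirsdoc import preprocess as pp
from nirsdoc.io_formats import HbTimeSeries, OpticalRecording, ValidationError, \
    default_montage
from nirsdoc.preprocess import PreprocessConfig, RejectionConfig
from nirsdoc.synthetic_data import CohortSpec, forward_mbll, generate_cohort


def _recording(intensity):
    intensity = np.asarray(intensity, dtype=float)
    montage = default_montage()
    if intensity.shape[0] != 5:
        intensity = np.broadcast_to(intensity, (5,) + intensity.shape[1:]).copy()
    return OpticalRecording("s", "HC", intensity, montage)


def _hb(hbo, hbr, fs=10.0):
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    hbr = np.atleast_2d(np.asarray(hbr, dtype=float))
    chans = [f"c{i}" for i in range(hbo.shape[0])]
    return HbTimeSeries("s", "HC", fs, chans, hbo, hbr)


class TestIntensityToOD:
    def test_constant_intensity_gives_zero_od(self):
        od = pp.intensity_to_od(_recording(np.full((5, 2, 100), 3.7)))
        np.testing.assert_allclose(od, 0.0, atol=1e-15)

    def test_tenfold_drop_gives_unit_od(self):
        intensity = np.ones((5, 2, 100))
        intensity[:, :, 50] = 0.1
        od = pp.intensity_to_od(_recording(intensity), i0=1.0)
        assert od[0, 0, 50] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(np.delete(od, 50, axis=2), 0.0, atol=1e-15)

    def test_matches_direct_log_ratio(self, rng):
        intensity = np.exp(rng.normal(0, 0.1, (5, 2, 80)))
        rec = _recording(intensity)
        od = pp.intensity_to_od(rec, i0=2.0)
        np.testing.assert_allclose(od, -np.log10(rec.intensity / 2.0), atol=1e-14)

    @pytest.mark.parametrize("definition,window", [("mean", slice(None)),
                                                   ("baseline60", slice(0, 600))])
    def test_od_averages_to_zero_over_reference_window(self, rng, definition, window):
        intensity = np.exp(rng.normal(0, 0.1, (5, 2, 1000)))
        od = pp.intensity_to_od(_recording(intensity), definition)
        np.testing.assert_allclose(od[:, :, window].mean(axis=2), 0.0, atol=1e-12)


class TestODToHb:
    def test_zero_od_gives_zero_concentration(self, default_config):
        hb = pp.od_to_hb(np.zeros((5, 2, 40)), default_config, (760.0, 830.0))
        np.testing.assert_allclose(hb.hbo, 0.0)
        np.testing.assert_allclose(hb.hbr, 0.0)
        assert hb.units == "uM"

    def test_solution_matches_cramers_rule(self, rng, default_config):
        od = rng.normal(0, 0.05, (3, 2, 60))
        hb = pp.od_to_hb(od, default_config, (760.0, 830.0))
        a = pp.extinction_matrix(default_config, (760.0, 830.0))
        det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
        hbo = (a[1, 1] * od[:, 0] - a[0, 1] * od[:, 1]) / det
        hbr = (-a[1, 0] * od[:, 0] + a[0, 0] * od[:, 1]) / det
        np.testing.assert_allclose(hb.hbo, hbo, rtol=1e-12)
        np.testing.assert_allclose(hb.hbr, hbr, rtol=1e-12)

    def test_forward_inverse_round_trip(self, rng, default_config):
        hb = _hb(rng.normal(0, 0.5, (5, 200)), rng.normal(0, 0.2, (5, 200)))
        rec = forward_mbll(hb, default_config, i0=1.0)
        od = pp.intensity_to_od(rec, i0=1.0)
        back = pp.od_to_hb(od, default_config, rec.wavelengths_nm)
        np.testing.assert_allclose(back.hbo, hb.hbo, rtol=1e-9, atol=1e-12)


class TestBandpass:
    fs = 10.0

    def _tone(self, freq, seconds=600):
        t = np.arange(0, seconds, 1 / self.fs)
        return _hb(np.sin(2 * np.pi * freq * t)[None, :],
                   np.zeros((1, t.size)) + 1e-9 * np.sin(t))

    def test_cardiac_band_tone_strongly_attenuated(self, default_config):
        hb = self._tone(1.1)
        out = pp.bandpass(hb, default_config)
        assert np.sqrt((out.hbo ** 2).mean()) < 0.01 * np.sqrt((hb.hbo ** 2).mean())

    def test_passband_tone_preserved(self, default_config):
        hb = self._tone(0.05)
        out = pp.bandpass(hb, default_config)
        ratio = np.sqrt((out.hbo ** 2).mean()) / np.sqrt((hb.hbo ** 2).mean())
        assert abs(ratio - 1.0) < 0.12

    def test_zero_series_maps_to_zero(self, default_config):
        out = pp.bandpass(_hb(np.zeros((2, 500)), np.zeros((2, 500))), default_config)
        np.testing.assert_allclose(out.hbo, 0.0, atol=1e-12)

    def test_too_short_series_rejected(self, default_config):
        with pytest.raises(ValidationError, match="too short"):
            pp.bandpass(_hb(np.ones((1, 10)), np.ones((1, 10))), default_config)

    def test_linearity(self, rng, default_config):
        hb = _hb(rng.normal(size=(2, 800)), rng.normal(size=(2, 800)))
        scaled = hb.copy_with(3.0 * hb.hbo, 3.0 * hb.hbr)
        # tolerance reflects the numerical conditioning of the narrow band
        np.testing.assert_allclose(pp.bandpass(scaled, default_config).hbo,
                                   3.0 * pp.bandpass(hb, default_config).hbo,
                                   rtol=1e-5, atol=1e-6)


class TestCBSI:
    def test_output_exactly_anticorrelated(self, rng):
        hb = _hb(rng.normal(0, 1, (3, 400)), rng.normal(0, 0.5, (3, 400)))
        out = pp.cbsi_correct(hb)
        for c in range(3):
            r = np.corrcoef(out.hbo[c], out.hbr[c])[0, 1]
            assert r == pytest.approx(-1.0, abs=1e-10)

    def test_fixed_point_left_unchanged(self, rng):
        hbo = rng.normal(0, 1, (2, 300))
        alpha = 1.7
        hb = _hb(hbo, -hbo / alpha)
        out = pp.cbsi_correct(hb)
        np.testing.assert_allclose(out.hbo, hb.hbo, atol=1e-12)
        np.testing.assert_allclose(out.hbr, hb.hbr, atol=1e-12)

    def test_shared_step_artifact_attenuated(self, rng):
        base_o = rng.normal(0, 1.0, 600)
        base_r = rng.normal(0, 0.5, 600)
        alpha = base_o.std() / base_r.std()
        step = np.zeros(600)
        step[300:] = 8.0
        hb = _hb((base_o + step)[None, :], (base_r + step / alpha)[None, :])
        out = pp.cbsi_correct(hb)
        raw_jump = np.abs(np.mean(hb.hbo[0, 300:]) - np.mean(hb.hbo[0, :300]))
        cor_jump = np.abs(np.mean(out.hbo[0, 300:]) - np.mean(out.hbo[0, :300]))
        assert cor_jump < raw_jump

    def test_zero_variance_hbr_rejected(self):
        with pytest.raises(ValidationError, match="zero-variance"):
            pp.cbsi_correct(_hb(np.random.default_rng(0).normal(size=(1, 50)),
                                np.zeros((1, 50))))

    def test_homogeneous_in_scale(self, rng):
        hb = _hb(rng.normal(size=(2, 200)), rng.normal(size=(2, 200)))
        scaled = hb.copy_with(2.5 * hb.hbo, 2.5 * hb.hbr)
        np.testing.assert_allclose(pp.cbsi_correct(scaled).hbo,
                                   2.5 * pp.cbsi_correct(hb).hbo, rtol=1e-12)


class TestArtifactScore:
    def test_zero_series_retained_with_zero_score(self):
        score, reject = pp.artifact_score(np.zeros(100))
        assert score == 0.0 and not reject

    def test_ten_z_spike_scores_two_and_rejects(self):
        z = np.zeros(200)
        z[100] = 10.0
        score, reject = pp.artifact_score(z, RejectionConfig(max_abs_z=5.0,
                                                             max_jump_z=100.0))
        assert score == pytest.approx(2.0)
        assert reject

    def test_jump_criterion_fires_on_steps(self):
        z = np.zeros(100)
        z[50:] = 4.0  # |z| max 4 < 5, but the one-sample jump is 4 > 3
        score, reject = pp.artifact_score(z)
        assert reject and score == pytest.approx(4.0 / 3.0)

    def test_scale_normalises_raw_input(self):
        raw = np.zeros(50)
        raw[10] = 12.0
        score, reject = pp.artifact_score(raw, RejectionConfig(max_abs_z=5.0,
                                                               max_jump_z=1e9),
                                          scale=2.0)
        assert score == pytest.approx(1.2) and reject


class TestZScore:
    def test_standardises_each_channel(self, rng):
        hb = _hb(rng.normal(3, 7, (4, 500)), rng.normal(-2, 0.3, (4, 500)))
        out = pp.zscore(hb)
        assert out.units == "z"
        np.testing.assert_allclose(out.hbo.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.hbo.std(axis=1), 1.0, atol=1e-10)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(2, 300))
        y = rng.normal(size=(2, 300))
        out1 = pp.zscore(_hb(x, y))
        out2 = pp.zscore(_hb(4.2 * x + 3.0, 4.2 * y + 3.0))
        np.testing.assert_allclose(out1.hbo, out2.hbo, atol=1e-10)

    @given(scale=st.floats(0.1, 100.0), offset=st.floats(-50.0, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_property(self, scale, offset):
        rng = np.random.default_rng(99)
        x = rng.normal(size=(1, 100))
        out1 = pp.zscore(_hb(x, x + 1.0))
        out2 = pp.zscore(_hb(scale * x + offset, scale * (x + 1.0) + offset))
        np.testing.assert_allclose(out1.hbo, out2.hbo, atol=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            pp.zscore(_hb(np.ones((1, 50)), np.zeros((1, 50)) + 0.5))


class TestFullChain:
    def test_processing_log_proves_stage_order(self, tiny_cohort, default_config):
        rec = tiny_cohort.subjects[0].recording
        hb = pp.preprocess_recording(rec, default_config)
        stages = [e["stage"] for e in hb.processing_log]
        assert stages == ["od", "mbll", "bandpass", "cbsi", "zscore"]
        assert hb.units == "z"

    def test_cbsi_can_be_disabled(self, tiny_cohort):
        cfg = PreprocessConfig(cbsi_enabled=False)
        hb = pp.preprocess_recording(tiny_cohort.subjects[0].recording, cfg)
        assert "cbsi" not in [e["stage"] for e in hb.processing_log]

    def test_noise_free_sign_recovery_without_cbsi(self, noise_free_subject):
        """End-to-end: block-averaged preprocessed HbO keeps the sign of the
        injected (negative, healthy-control) amplitude in every channel."""
        from nirsdoc import epochs_features as ef
        cfg = PreprocessConfig(cbsi_enabled=False)
        hb = pp.preprocess_recording(noise_free_subject.recording, cfg)
        sets = ef.segment(hb, noise_free_subject.schedule)
        for channel in hb.channels:
            es = ef.baseline_correct(sets[("SON", channel, "HbO")])
            avg, _ = ef.block_average(es)
            feat = ef.mean_feature(avg, es.times_s)
            assert np.sign(feat) == np.sign(
                noise_free_subject.ground_truth.amplitudes[("SON", "HbO")]
            )

    def test_chain_linear_before_zscore(self, rng, default_config):
        """OD → MBLL → filter → CBSI is homogeneous: scaling the underlying
        concentrations scales the cleaned output."""
        hb = _hb(rng.normal(0, 0.5, (5, 700)), rng.normal(0, 0.2, (5, 700)))
        big = hb.copy_with(2.0 * hb.hbo, 2.0 * hb.hbr)

        def chain(x):
            rec = forward_mbll(x, default_config, i0=1.0)
            od = pp.intensity_to_od(rec, i0=1.0)
            y = pp.od_to_hb(od, default_config, rec.wavelengths_nm)
            return pp.cbsi_correct(pp.bandpass(y, default_config))

        np.testing.assert_allclose(chain(big).hbo, 2.0 * chain(hb).hbo,
                                   rtol=1e-5, atol=1e-6)
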