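"""Epoching geometry, baseline correction, block averaging and the two
scalar response features."""

import numpy as np
import pandas as pd
import pytest

from hypothesis import given, settings
from hypothesis import strategies as st

from nirsdoc import epochs_features as ef
from nirsdoc import preprocess as pp
from nirsdoc.epochs_features import EpochWindows
from nirsdoc.io_formats import EventSchedule, HbTimeSeries, ValidationError
from nirsdoc.synthetic_data import CohortSpec, build_paradigm, generate_cohort, \
    ParadigmSpec


FS = 10.0


def _hb_from(hbo_row, n_ch=1):
    hbo = np.tile(np.asarray(hbo_row, dtype=float), (n_ch, 1))
    return HbTimeSeries("s", "HC", FS, [f"c{i}" for i in range(n_ch)],
                        hbo, -0.5 * hbo + 0.01)


def _schedule(onsets, duration=30.0, condition="SON"):
    return EventSchedule.from_blocks([(condition, o, duration) for o in onsets])


class TestWindows:
    def test_defaults_are_nested(self):
        w = EpochWindows()
        assert w.segment == (-5.0, 45.0) and w.analysis == (-3.0, 40.0)

    @pytest.mark.parametrize("kwargs", [
        {"analysis": (-6.0, 40.0)},          # outside segment
        {"baseline": (-4.0, 0.0)},           # outside analysis
        {"mean_window": (2.0, 41.0)},
        {"slope_window": (-4.0, 15.0)},
    ])
    def test_nesting_violations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            EpochWindows(**kwargs)


class TestSegment:
    def test_epoch_has_500_samples_at_10_hz(self):
        t = np.arange(0, 700, 1 / FS)
        sets = ef.segment(_hb_from(np.sin(t)), _schedule([60.0 + 70 * k for k in range(8)]))
        es = sets[("SON", "c0", "HbO")]
        assert es.epochs.shape == (8, 500)
        assert es.valid.all()

    def test_onset_on_sample_boundary_start_index(self):
        n = 2000
        data = np.arange(n, dtype=float)
        hb = _hb_from(data)
        sets = ef.segment(hb, _schedule([100.0]))
        es = sets[("SON", "c0", "HbO")]
        # onset index 1000, segment starts 5 s (50 samples) earlier
        assert es.epochs[0, 0] == data[1000 - 50]

    def test_window_past_recording_flagged_invalid(self):
        hb = _hb_from(np.zeros(800))  # 80 s of data
        sets = ef.segment(hb, _schedule([20.0, 50.0]))  # 50+45 > 80 s
        es = sets[("SON", "c0", "HbO")]
        assert es.valid.tolist() == [True, False]
        assert np.isnan(es.epochs[1]).all()


class TestBaselineCorrect:
    def _epochs(self, values):
        times = (np.arange(500) - 50) / FS
        return ef.EpochSet("s", "HC", "SON", "c0", "HbO",
                           np.atleast_2d(values), times, np.array([5.0]), FS)

    def test_constant_epoch_becomes_zero(self):
        out = ef.baseline_correct(self._epochs(np.full(500, 3.3)))
        np.testing.assert_allclose(out.epochs, 0.0, atol=1e-12)
        assert out.epochs[:, :30].mean() == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_shifts_by_baseline_mean(self):
        times = (np.arange(500) - 50) / FS
        out = ef.baseline_correct(self._epochs(times.copy()))
        # baseline samples are −3.0 … −0.1 s; their mean is −1.55 on the grid
        np.testing.assert_allclose(out.epochs[0], times + 1.55, atol=1e-12)

    def test_idempotent(self, rng):
        out1 = ef.baseline_correct(self._epochs(rng.normal(size=500)))
        out2 = ef.baseline_correct(out1)
        np.testing.assert_allclose(out1.epochs, out2.epochs, atol=1e-14)


class TestBlockAverage:
    def _set(self, epochs, retained=None):
        times = (np.arange(epochs.shape[1]) - 50) / FS
        es = ef.EpochSet("s", "HC", "SON", "c0", "HbO", epochs, times,
                         np.arange(len(epochs), dtype=float), FS)
        if retained is not None:
            es.retained = np.asarray(retained, dtype=bool)
        return es

    def test_identical_epochs_average_to_one_of_them(self, rng):
        row = rng.normal(size=500)
        avg, n = ef.block_average(self._set(np.tile(row, (8, 1))))
        assert n == 8
        np.testing.assert_allclose(avg, row, atol=1e-14)

    def test_average_over_exactly_the_retained_epochs(self):
        epochs = np.arange(8, dtype=float)[:, None] * np.ones((8, 500))
        keep = [True, False, True, False, False, False, True, False]
        avg, n = ef.block_average(self._set(epochs, retained=keep))
        assert n == 3
        np.testing.assert_allclose(avg, (0 + 2 + 6) / 3.0)

    def test_zero_retained_is_flagged_missing(self):
        avg, n = ef.block_average(self._set(np.ones((4, 500)), retained=[False] * 4))
        assert avg is None and n == 0

    def test_averaging_shrinks_noise_variance_eightfold(self):
        rng = np.random.default_rng(7)
        signal = np.sin(np.linspace(0, 3, 500))
        ratios = []
        for _ in range(200):
            noise = rng.normal(0, 1, (8, 500))
            avg, _ = ef.block_average(self._set(signal + noise))
            ratios.append(np.var(avg - signal) / np.var(noise))
        assert np.mean(ratios) == pytest.approx(1 / 8, rel=0.3)


class TestFeatures:
    times = (np.arange(500) - 50) / FS

    def test_constant_curve_mean_is_the_constant(self):
        assert ef.mean_feature(np.full(500, 2.5), self.times) == pytest.approx(2.5)

    def test_ramp_mean_matches_grid_sum(self):
        # mean of t over grid samples 2.0, 2.1, …, 19.9 s
        assert ef.mean_feature(self.times.copy(), self.times) == pytest.approx(10.95)

    def test_exact_line_slope(self):
        curve = 2.0 * self.times + 7.0
        assert ef.slope_feature(curve, self.times) == pytest.approx(2.0, abs=1e-12)
        assert ef.slope_feature(np.full(500, 3.0), self.times) == pytest.approx(0.0,
                                                                                abs=1e-12)

    def test_slope_matches_polyfit_oracle(self, rng):
        curve = rng.normal(size=500)
        mask = ef.window_mask(self.times, (5.0, 15.0), FS)
        expected = np.polyfit(self.times[mask], curve[mask], 1)[0]
        assert ef.slope_feature(curve, self.times) == pytest.approx(expected, rel=1e-10)

    def test_short_slope_window_rejected(self):
        times = np.arange(2) / FS
        with pytest.raises(ValidationError):
            ef.slope_feature(np.ones(2), times)

    @given(scale=st.floats(-5.0, 5.0), shift=st.floats(-10.0, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_and_shift_equivariance(self, scale, shift):
        rng = np.random.default_rng(123)
        curve = rng.normal(size=500)
        m0 = ef.mean_feature(curve, self.times)
        s0 = ef.slope_feature(curve, self.times)
        transformed = scale * curve + shift
        assert ef.mean_feature(transformed, self.times) == pytest.approx(
            scale * m0 + shift, abs=1e-8)
        assert ef.slope_feature(transformed, self.times) == pytest.approx(
            scale * s0, abs=1e-8)


class TestFeatureTable:
    @pytest.fixture()
    def subject(self, tiny_cohort):
        subj = tiny_cohort.subjects[0]
        cfg = pp.PreprocessConfig()
        hb = pp.preprocess_recording(subj.recording, cfg)
        return hb, subj.schedule

    def test_block_avg_mode_row_count(self, subject):
        hb, sched = subject
        table = ef.subject_features(hb, sched, mode="block-avg")
        assert len(table) == 2 * 5 * 2  # condition × channel × chromophore
        assert set(table["epoch_index"]) == {"block-avg"}

    def test_per_epoch_mode_row_count(self, subject):
        hb, sched = subject
        table = ef.subject_features(hb, sched, mode="per-epoch")
        assert len(table) == 2 * 5 * 2 * 8

    def test_rejected_epochs_flagged_not_zeroed(self, subject):
        hb, sched = subject
        table = ef.subject_features(hb, sched, mode="per-epoch")
        dropped = table[~table["retained"]]
        assert dropped["mean_conc"].isna().all()
        assert dropped["slope"].isna().all()

    def test_empty_table_has_schema(self):
        table = ef.build_feature_table([])
        assert list(table.columns)[:5] == ["subject_id", "group", "condition",
                                           "channel", "chromophore"]


class TestRejectionOnCohort:
    def test_uncorrected_steps_rejected_clean_epochs_kept(self):
        """With motion steps far above the noise floor and CBSI disabled,
        step-containing trials are rejected and artifact-free ones kept."""
        cfg = pp.PreprocessConfig(cbsi_enabled=False)
        n_step = [0, 0]
        n_free = [0, 0]
        for seed in range(6):
            cohort = generate_cohort(
                CohortSpec(n_per_group={"HC": 2, "MCS": 0, "VS": 2}, seed=seed))
            for subj in cohort.subjects:
                hb = pp.preprocess_recording(subj.recording, cfg)
                sets = ef.reject_epochs(ef.segment(hb, subj.schedule), cfg.rejection)
                steps = np.asarray(subj.ground_truth.step_times_s)
                spikes = np.asarray(subj.ground_truth.spike_times_s)
                for (cond, ch, chrom), es in sets.items():
                    if chrom != "HbO":
                        continue
                    for k, onset in enumerate(es.onsets_s):
                        in_epoch = lambda a, lo, hi: bool(
                            a.size and np.any((a >= onset + lo) & (a < onset + hi)))
                        rejected = not es.retained[k]
                        if in_epoch(steps, -5, 45):
                            n_step[0] += rejected
                            n_step[1] += 1
                        elif not (in_epoch(steps, -65, 105) or in_epoch(spikes, -5, 45)):
                            n_free[0] += rejected
                            n_free[1] += 1
        assert n_step[1] > 20  # enough artifact trials to judge
        assert n_step[0] / n_step[1] >= 0.9
        assert n_free[0] / n_free[1] <= 0.1
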