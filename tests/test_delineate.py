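"""Beat detection, delineation accuracy and series cleaning."""

import numpy as np
import pytest

import ecgdelta as e
from conftest import match_beats


def beat_train(n_beats=10, hr_bpm=75.0, fs=500.0, noise_sd=0.0, seed=0,
               morphology=None):
    """A short constant-RR train rendered from the default morphology."""
    m = morphology or e.BeatMorphology.default()
    rr_ms = 60000.0 / hr_bpm
    cycle, fid = e.generate_beat(m, rr_ms, fs)
    n_cycle = len(cycle)
    pad = int(0.5 * fs)
    samples = np.zeros(2 * pad + n_beats * n_cycle)
    r_true = []
    for k in range(n_beats):
        start = pad + k * n_cycle
        samples[start:start + n_cycle] += cycle
        r_true.append(start + fid["R"])
    if noise_sd > 0:
        samples += np.random.default_rng(seed).normal(0.0, noise_sd, len(samples))
    return e.ECGRecord(samples, fs), np.array(r_true)


class TestDetectRPeaks:
    def test_all_zero_trace_yields_no_peaks(self):
        record = e.ECGRecord(np.zeros(5000), 500.0)
        assert len(e.detect_r_peaks(record)) == 0

    def test_constant_trace_yields_no_peaks(self):
        record = e.ECGRecord(np.full(5000, 0.7), 500.0)
        assert len(e.detect_r_peaks(record)) == 0

    def test_record_shorter_than_integration_window_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            e.detect_r_peaks(e.ECGRecord(np.zeros(30), 500.0))

    def test_noise_free_train_recovers_every_peak(self):
        record, r_true = beat_train(n_beats=10, hr_bpm=75.0, fs=500.0)
        peaks = e.detect_r_peaks(record)
        assert len(peaks) == 10
        assert np.max(np.abs(peaks - r_true)) <= 2

    def test_noisy_train_recovers_peaks_in_most_replicates(self):
        hits = 0
        for seed in range(20):
            record, r_true = beat_train(n_beats=10, noise_sd=0.05, seed=seed)
            peaks = e.detect_r_peaks(record)
            if len(peaks) == 10 and np.max(np.abs(peaks - r_true)) <= 3:
                hits += 1
        assert hits >= 19

    def test_detection_is_deterministic(self):
        record, _ = beat_train(noise_sd=0.05, seed=3)
        assert np.array_equal(e.detect_r_peaks(record), e.detect_r_peaks(record))


class TestDelineate:
    def test_noise_free_session_fiducials_within_tolerance(self, null_pair):
        _, ng = null_pair
        record = e.ECGRecord(ng.samples_mV, ng.sampling_rate_hz)
        fid = e.delineate(record, e.detect_r_peaks(record))
        gt = ng.truth
        beat = match_beats(fid.R, gt)
        tol = 5e-3 * ng.sampling_rate_hz          # +-5 ms in samples
        n_ok = 0
        for j in range(fid.n_beats):
            i = beat[j]
            errs = [abs(getattr(fid, name)[j] - gt.fiducials[name][i])
                    for name in ("R", "Q", "S", "P_onset", "P_peak",
                                 "T_onset", "T_peak", "T_end")]
            if max(errs) <= tol:
                n_ok += 1
        assert n_ok / fid.n_beats >= 0.99

    def test_boundary_beats_are_dropped(self):
        record, r_true = beat_train(n_beats=6)
        # crop so the first R has no room for its P-search window
        cropped = e.ECGRecord(record.samples_mV[r_true[0] - 50:],
                              record.sampling_rate_hz)
        peaks = e.detect_r_peaks(cropped)
        fid = e.delineate(cropped, peaks)
        assert fid.n_beats < len(peaks)
        assert fid.drop_reasons["boundary"] >= 2    # cropped first + final beat

    def test_fewer_than_two_peaks_raises(self):
        record, _ = beat_train(n_beats=3)
        with pytest.raises(ValueError, match="2 R peaks"):
            e.delineate(record, np.array([100]))

    def test_absent_p_wave_drops_only_p_dependent_series(self):
        m = e.BeatMorphology.default()
        flat_p = e.BeatMorphology(P=e.WaveShape(0.0, m.P.width_ms, m.P.offset_ms),
                                  Q=m.Q, R=m.R, S=m.S, T=m.T)
        record, _ = beat_train(n_beats=8, morphology=flat_p)
        fid = e.delineate(record, e.detect_r_peaks(record))
        assert fid.n_beats > 0
        assert np.all(np.isnan(fid.P_peak))
        series = e.extract_segments(fid, record)
        assert len(series["P-H"]) == 0
        assert len(series["PRQ"]) == 0
        assert len(series["QT"]) == fid.n_beats

    def test_delineation_is_deterministic(self, null_pair):
        _, ng = null_pair
        record = e.ECGRecord(ng.samples_mV, ng.sampling_rate_hz)
        peaks = e.detect_r_peaks(record)
        a = e.delineate(record, peaks)
        b = e.delineate(record, peaks)
        assert np.array_equal(a.R, b.R)
        assert np.array_equal(a.T_end, b.T_end, equal_nan=True)


class TestExtractSegments:
    def test_rr_and_hr_from_two_peaks(self):
        record, _ = beat_train(n_beats=4, hr_bpm=75.0)
        fid = e.delineate(record, e.detect_r_peaks(record))
        series = e.extract_segments(fid, record)
        assert series["RR-I"].values[0] == pytest.approx(800.0, abs=2.0)
        assert series["HR"].values[0] == pytest.approx(75.0, abs=0.2)

    def test_hr_equals_60000_over_rr_exactly(self, null_pair):
        _, ng = null_pair
        record = e.ECGRecord(ng.samples_mV, ng.sampling_rate_hz)
        fid = e.delineate(record, e.detect_r_peaks(record))
        series = e.extract_segments(fid, record)
        np.testing.assert_allclose(series["HR"].values,
                                   60000.0 / series["RR-I"].values, rtol=1e-12)

    @pytest.mark.parametrize("qt_ms,rr_ms,expected", [
        (400.0, 1000.0, 400.0),        # divisor sqrt(1)
        (400.0, 640.0, 500.0),         # 400 / sqrt(0.64)
    ])
    def test_bazett_correction(self, qt_ms, rr_ms, expected):
        qtc = qt_ms / np.sqrt(rr_ms / 1000.0)
        assert qtc == pytest.approx(expected)

    def test_extracted_intervals_match_ground_truth(self, null_pair):
        """Noise-free extraction agrees with truth within 2 sample periods."""
        _, ng = null_pair
        record = e.ECGRecord(ng.samples_mV, ng.sampling_rate_hz)
        fid = e.delineate(record, e.detect_r_peaks(record))
        series = e.extract_segments(fid, record)
        gt = ng.truth
        beat = match_beats(fid.R, gt)
        tol_ms = 2.0 / ng.sampling_rate_hz * 1000.0
        for seg in ("RR-I", "QRS", "PRQ", "QT", "ST", "QTC"):
            s = series[seg]
            gt_vals = gt.segments[seg][beat[s.beat_index]]
            ok = np.isfinite(gt_vals)
            assert np.max(np.abs(s.values[ok] - gt_vals[ok])) <= tol_ms, seg
        for seg, tol_mV in (("R-H", 0.02), ("P-H", 0.01)):
            s = series[seg]
            gt_vals = gt.segments[seg][beat[s.beat_index]]
            assert np.max(np.abs(s.values - gt_vals)) <= tol_mV, seg

    def test_single_beat_raises(self):
        record, _ = beat_train(n_beats=4)
        fid = e.delineate(record, e.detect_r_peaks(record))
        fid_one = e.FiducialSet(
            R=fid.R[:1], Q=fid.Q[:1], S=fid.S[:1], P_onset=fid.P_onset[:1],
            P_peak=fid.P_peak[:1], T_onset=fid.T_onset[:1],
            T_peak=fid.T_peak[:1], T_end=fid.T_end[:1],
            timestamp_s=fid.timestamp_s[:1],
            sampling_rate_hz=fid.sampling_rate_hz)
        with pytest.raises(ValueError, match="RR undefined"):
            e.extract_segments(fid_one, record)


class TestCleanSeries:
    @staticmethod
    def series(values, segment="RR-I"):
        values = np.asarray(values, dtype=float)
        n = len(values)
        return e.SegmentSeries(segment_id=segment, values=values,
                               beat_index=np.arange(n),
                               timestamp_s=np.arange(n, dtype=float))

    def test_clean_synthetic_series_no_removals(self, null_pair):
        _, ng = null_pair
        from ecgdelta.pipeline import truth_to_series
        for seg, s in truth_to_series(ng.truth).items():
            assert e.clean_series(s).n_removed == 0, seg

    def test_injected_outlier_is_removed_exactly(self):
        rng = np.random.default_rng(0)
        values = rng.normal(800.0, 20.0, 500)
        values[123] = 10000.0
        cleaned = e.clean_series(self.series(values))
        assert cleaned.n_removed == 1
        assert 123 not in cleaned.beat_index

    def test_constant_series_untouched_despite_zero_mad(self):
        cleaned = e.clean_series(self.series(np.full(50, 800.0)))
        assert cleaned.n_removed == 0

    def test_impossible_heart_rates_removed(self):
        values = np.full(50, 70.0)
        values[[3, 7]] = [10.0, 300.0]
        cleaned = e.clean_series(self.series(values, segment="HR"))
        assert cleaned.n_removed == 2

    def test_excess_removal_logs_warning(self, caplog):
        values = np.concatenate([np.full(10, 800.0), np.full(5, -1.0)])
        with caplog.at_level("WARNING", logger="ecgdelta.delineate"):
            e.clean_series(self.series(values))
        assert any("removed" in rec.message for rec in caplog.records)
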