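"""Signal preprocessing: peak detection, phases, RVT, cleaning, syncing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import physiofmri as pf
from physiofmri.physio import (
    PhysioRecording,
    PupilRecording,
    cardiac_phase,
    compute_rvt,
    detect_cardiac_peaks,
    preprocess_pupil,
    preprocess_sc,
    read_physio_tsv,
    read_pupil_tsv,
    respiratory_phase,
    sync_to_scan,
    write_physio_tsv,
    write_pupil_tsv,
)
from physiofmri.synthetic import gen_physio


class TestCardiacPeaks:
    def test_peaks_match_hidden_beat_times(self):
        truth = pf.GroundTruth(seed=4, hr_bpm=72.0, hr_sd=0.02, noise_sd=0.0)
        rec = gen_physio(truth, duration_s=120.0)
        detected = detect_cardiac_peaks(rec.channels["ppg"], rec.fs)
        beats = rec.meta["beat_times"]
        beats = beats[(beats > detected[0] - 0.5) & (beats < detected[-1] + 0.5)]
        assert abs(len(detected) - len(beats)) <= 1
        for d in detected:
            assert np.min(np.abs(beats - d)) < 0.02

    def test_rate_times_duration_gives_count(self):
        truth = pf.GroundTruth(seed=0, hr_bpm=90.0, hr_sd=0.0, noise_sd=0.0)
        rec = gen_physio(truth, duration_s=60.0)
        detected = detect_cardiac_peaks(rec.channels["ppg"], rec.fs)
        assert abs(len(detected) - 90) <= 1

    def test_flat_signal_is_an_error(self):
        with pytest.raises(ValueError, match="pulsatile"):
            detect_cardiac_peaks(np.zeros(5000), 500.0)


class TestCardiacPhase:
    def test_phase_zero_at_peaks_pi_at_midpoints(self):
        peaks = np.arange(0.0, 10.0, 1.0)
        ps = cardiac_phase(peaks, np.array([3.0]))
        assert ps.phase[0] == pytest.approx(0.0, abs=1e-12)
        ps = cardiac_phase(peaks, np.array([3.5]))
        assert ps.phase[0] == pytest.approx(np.pi, abs=1e-12)

    def test_linear_interpolation_quarter_beat(self):
        peaks = np.arange(0.0, 5.0, 1.0)
        ps = cardiac_phase(peaks, np.array([0.25]))
        assert ps.phase[0] == pytest.approx(np.pi / 2, abs=1e-12)

    def test_range_invariant(self):
        rng = np.random.default_rng(0)
        peaks = np.cumsum(rng.uniform(0.6, 1.2, 50))
        t = rng.uniform(peaks[0], peaks[-1], 500)
        ps = cardiac_phase(peaks, t)
        assert np.all(ps.phase >= 0) and np.all(ps.phase < 2 * np.pi)

    def test_eval_outside_span_rejected(self):
        with pytest.raises(ValueError):
            cardiac_phase(np.array([0.0, 1.0]), np.array([100.0]))


class TestRespiratoryPhase:
    def test_sinusoid_extremes_and_mean(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        resp = np.sin(2 * np.pi * t / 4.0)
        # at a maximum the amplitude CDF is 1 -> |phase| = pi
        ps = respiratory_phase(resp, fs, np.array([1.0]))
        assert abs(ps.phase[0]) == pytest.approx(np.pi, rel=0.02)
        # rising through the mean -> phase near +pi/2; falling -> negative
        ps_up = respiratory_phase(resp, fs, np.array([4.0]))
        ps_down = respiratory_phase(resp, fs, np.array([2.0]))
        assert ps_up.phase[0] == pytest.approx(np.pi / 2, rel=0.05)
        assert ps_down.phase[0] < 0

    def test_amplitude_scale_invariance(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        resp = np.sin(2 * np.pi * t / 5.0) + 0.2 * np.sin(2 * np.pi * t / 17.0)
        te = np.linspace(5, 55, 40)
        p1 = respiratory_phase(resp, fs, te).phase
        p2 = respiratory_phase(3.7 * resp, fs, te).phase
        assert np.allclose(p1, p2)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            respiratory_phase(np.ones(1000), 100.0, np.array([5.0]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_phase_ranges_hold_for_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        fs = 50.0
        t = np.arange(0, 30, 1 / fs)
        freq = rng.uniform(0.1, 0.5)
        resp = rng.uniform(0.5, 3.0) * np.sin(2 * np.pi * freq * t)
        resp += 0.1 * rng.standard_normal(len(t))
        te = np.linspace(2, 28, 30)
        phase = respiratory_phase(resp, fs, te).phase
        assert np.all(phase > -np.pi - 1e-12) and np.all(phase <= np.pi + 1e-12)


class TestRvt:
    @pytest.mark.parametrize("A,T", [(1.0, 4.0), (2.5, 3.0), (0.3, 6.0)])
    def test_sinusoid_equals_2a_over_t(self, A, T):
        fs = 100.0
        t = np.arange(0, 30 * T, 1 / fs)
        resp = A * np.sin(2 * np.pi * t / T)
        te = np.linspace(2 * T, 28 * T, 50)
        rvt = compute_rvt(resp, fs, te)
        assert np.max(np.abs(rvt.rvt / (2 * A / T) - 1)) < 0.01

    def test_amplitude_linearity(self):
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        resp = np.sin(2 * np.pi * t / 4.0)
        te = np.linspace(10, 110, 20)
        r1 = compute_rvt(resp, fs, te).rvt
        r2 = compute_rvt(2 * resp, fs, te).rvt
        assert np.allclose(r2, 2 * r1, rtol=1e-9)

    def test_worked_value_half(self):
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        resp = np.sin(2 * np.pi * t / 4.0)
        rvt = compute_rvt(resp, fs, np.array([60.0]))
        assert rvt.rvt[0] == pytest.approx(0.5, rel=0.01)

    def test_too_few_breaths_rejected(self):
        with pytest.raises(ValueError):
            compute_rvt(np.sin(np.linspace(0, np.pi, 200)), 100.0, np.array([1.0]))


class TestPupilPreprocessing:
    def test_linear_interpolation_of_invalid_run(self):
        rec = PupilRecording(pd=[2.0, 0.0, 0.0, 4.0],
                            valid=[True, False, False, True],
                            fs=120.0, trigger_times=[0.0])
        out = preprocess_pupil(rec, smooth_samples=1)
        assert np.allclose(out.pd, [2.0, 8 / 3, 10 / 3, 4.0])

    @pytest.mark.parametrize("frac,expect_rejected", [
        (0.12, True), (0.10, True), (0.0999, False), (0.05, False)])
    def test_rejection_rule_boundary(self, frac, expect_rejected):
        n = 10_000
        n_bad = int(round(frac * n))
        valid = np.ones(n, dtype=bool)
        valid[100:100 + n_bad] = False
        rec = PupilRecording(pd=np.full(n, 3.0), valid=valid, fs=120.0,
                            trigger_times=[0.0])
        out = preprocess_pupil(rec)
        assert out.rejected is expect_rejected
        assert out.meta["artifact_fraction"] == pytest.approx(frac, abs=1e-6)

    def test_constant_valid_signal_unchanged(self):
        rec = PupilRecording(pd=np.full(500, 2.5), valid=np.ones(500, bool),
                            fs=120.0, trigger_times=[0.0])
        out = preprocess_pupil(rec)
        assert np.allclose(out.pd, 2.5)

    def test_reprocessing_never_unrejects(self):
        valid = np.ones(1000, dtype=bool)
        valid[:200] = False
        rec = PupilRecording(pd=np.full(1000, 3.0), valid=valid, fs=120.0,
                            trigger_times=[0.0])
        once = preprocess_pupil(rec)
        assert once.rejected
        twice = preprocess_pupil(once)
        assert twice.rejected

    def test_all_invalid_rejected_with_error(self):
        rec = PupilRecording(pd=np.zeros(100), valid=np.zeros(100, bool),
                            fs=120.0, trigger_times=[0.0])
        with pytest.raises(ValueError):
            preprocess_pupil(rec)


class TestSkinConductance:
    def test_constant_input_preserved(self):
        out = preprocess_sc(np.full(1000, 4.2), 500.0)
        assert np.allclose(out, 4.2)
        assert len(out) == 1000

    def test_single_spike_removed_by_median(self):
        sc = np.full(2000, 1.0)
        sc[1000] = 50.0
        out = preprocess_sc(sc, 500.0)
        assert np.max(np.abs(out - 1.0)) < 1e-9

    def test_step_becomes_monotone_ramp_without_overshoot(self):
        sc = np.concatenate([np.zeros(1500), np.ones(1500)])
        out = preprocess_sc(sc, 500.0)
        assert np.all(np.diff(out) >= -1e-12)
        assert out.min() >= -1e-12 and out.max() <= 1 + 1e-12

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            preprocess_sc(np.ones(100), 500.0)


class TestSync:
    def _rec(self, fs=100.0, n_vol=220, tr=2.04, extra_s=2.0):
        n = int((n_vol * tr + extra_s) * fs)
        return PhysioRecording(
            channels={"ppg": np.arange(n, dtype=float),
                      "respiration": np.zeros(n), "sc": np.zeros(n)},
            fs=fs, trigger_times=np.arange(n_vol) * tr)

    def test_retained_duration_is_216_volumes(self):
        rec = self._rec()
        out = sync_to_scan(rec, 220, 2.04)
        assert out.duration == pytest.approx(216 * 2.04, abs=1 / rec.fs)
        assert len(out.trigger_times) == 216
        assert out.trigger_times[0] == pytest.approx(0.0)

    def test_recording_started_at_trigger_keeps_alignment(self):
        rec = self._rec()
        out = sync_to_scan(rec, 220, 2.04, n_discard=0)
        assert out.channels["ppg"][0] == rec.channels["ppg"][0]

    def test_short_recording_padded_with_edge_value(self, caplog):
        rec = self._rec(extra_s=-1.0)  # ends 1 s before the scan does
        out = sync_to_scan(rec, 220, 2.04)
        assert out.duration == pytest.approx(216 * 2.04, abs=1 / rec.fs)
        assert out.channels["ppg"][-1] == rec.channels["ppg"][-1]

    def test_trigger_train_inconsistent_with_volumes_rejected(self):
        rec = self._rec()
        with pytest.raises(ValueError, match="trigger"):
            sync_to_scan(rec, 100, 2.04)


class TestRoundTripIO:
    def test_physio_tsv_round_trip(self, tmp_path):
        truth = pf.GroundTruth(seed=9)
        rec = gen_physio(truth, duration_s=20.0, trigger_times=np.arange(8) * 2.04)
        write_physio_tsv(rec, tmp_path / "p.tsv")
        back = read_physio_tsv(tmp_path / "p.tsv")
        assert back.fs == rec.fs
        for name in rec.channels:
            assert np.allclose(back.channels[name], rec.channels[name])

    def test_pupil_tsv_round_trip(self, tmp_path):
        rec = PupilRecording(pd=np.linspace(3, 4, 50),
                            valid=np.arange(50) % 7 != 0,
                            fs=120.0, trigger_times=[0.0, 2.04])
        write_pupil_tsv(rec, tmp_path / "pup.tsv")
        back = read_pupil_tsv(tmp_path / "pup.tsv")
        assert np.allclose(back.pd, rec.pd)
        assert np.array_equal(back.valid, rec.valid)
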