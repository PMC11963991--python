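"""Fiducial detection and cardiac timing metrics."""

import warnings

import numpy as np
import pytest

import pentacardio as pc
from pentacardio.fiducials import (
    BeatFiducials,
    compute_metrics,
    detect_ecg_fiducials,
    detect_r_peaks,
    detect_scg_fiducials,
    detect_trimodal_fiducials,
    segment_metrics,
)


class TestEcg:
    def test_all_r_peaks_found_within_one_sample(self, noiseless_rest):
        rec = noiseless_rest
        fid = detect_ecg_fiducials(rec.channel("ECG"), rec.sampling_rate)
        truth = [b["R"] for b in rec.annotations.beats]
        found = [b["R"] for b in fid.beats]
        assert len(found) == len(truth)
        assert max(abs(a - b) for a, b in zip(found, truth)) <= 1

    def test_flat_signal_gives_zero_beats(self):
        fid = detect_ecg_fiducials(np.zeros(2000), 200.0)
        assert fid.n_beats == 0

    def test_too_short_or_slow_sampling_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(100), 200.0)
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(2000), 50.0)

    def test_constant_rr_gives_expected_hr(self):
        """RR = 0.75 s everywhere => HR = 80 bpm."""
        fs = 200.0
        beats = [{"R": int(i * 0.75 * fs)} for i in range(10)]
        fid = BeatFiducials(fs, beats, [{"R": True}] * 10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(fid)
        assert m.hr == pytest.approx(80.0)
        assert m.sdrr == pytest.approx(0.0, abs=1e-9)

    def test_refractory_prevents_double_detection(self, noiseless_rest):
        rec = noiseless_rest
        r = detect_r_peaks(rec.channel("ECG"), 200.0)
        assert np.all(np.diff(r) >= 0.2 * 200.0)


class TestMechanical:
    def test_scg_ao_detected_within_two_samples(self, noiseless_rest):
        rec = noiseless_rest
        r = np.array([b["R"] for b in rec.annotations.beats])
        fid = detect_scg_fiducials(rec.channel("Pad5.Acc.Z"), 200.0, r)
        for beat, v, truth in zip(fid.beats, fid.valid, rec.annotations.beats):
            if v.get("AO"):
                assert abs(beat["AO"] - truth["AO"]) <= 2

    def test_missing_r_times_rejected(self, noiseless_rest):
        with pytest.raises(ValueError):
            detect_scg_fiducials(
                noiseless_rest.channel("Pad5.Acc.Z"), 200.0, np.array([])
            )

    def test_noise_only_window_flagged_invalid(self):
        rng = np.random.default_rng(0)
        fs = 200.0
        n = 4000
        x = np.zeros(n)
        r = np.array([400, 800, 1200, 1600, 2000, 2400])
        # genuine peaks on most beats, nothing on the third
        for ri in r:
            if ri != 1200:
                x[ri + 16] = 1.0  # AO-like peak at R+80 ms
        x += 0.001 * rng.standard_normal(n)
        fid = detect_scg_fiducials(x, fs, r)
        flags = [v["AO"] for v in fid.valid]
        assert flags.count(True) >= 4
        assert fid.valid[2]["AO"] is False

    def test_end_to_end_running_valid_fraction(self, running_recording):
        """Compensated+filtered running recording keeps >= 95% valid beats."""
        comp, _ = pc.compensate(running_recording, (0.0, 30.0))
        bank = pc.build_filter_bank(fs=200.0)
        x = pc.filters.filter_recording_channels(
            comp.channel("Pad5.Acc.Z"), pc.MotionStateProbs.one_hot("running"), bank
        )
        from pentacardio.recording import TrimodalRecording

        data = comp.data.copy()
        data[comp.layout.channel_index("Pad5.Acc.Z")] = x
        rec2 = TrimodalRecording(data, 200.0, comp.layout, annotations=None)
        fid = detect_trimodal_fiducials(rec2)
        ao_valid = [v.get("AO", False) for v in fid.valid]
        assert np.mean(ao_valid) >= 0.95
        # and AO lands within 2 samples of truth on valid beats
        truth = {b["R"]: b["AO"] for b in running_recording.annotations.beats}
        errs = [
            abs(beat["AO"] - truth[beat["R"]])
            for beat, v in zip(fid.beats, fid.valid)
            if v.get("AO") and beat["R"] in truth
        ]
        assert errs and np.median(errs) <= 2


class TestMetrics:
    def test_constructed_beat_arithmetic(self):
        """Q at 0, AO at 80 ms, AC at 380 ms => PEP .08, LVET .30, ratio .2667."""
        fs = 1000.0
        beats, valid = [], []
        for i in range(5):
            off = int(i * 0.8 * fs)
            beats.append(
                {"Q": off, "R": off + 40, "AO": off + 80, "AC": off + 380}
            )
            valid.append({k: True for k in beats[-1]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(BeatFiducials(fs, beats, valid))
        assert m.pep == pytest.approx(0.080)
        assert m.lvet == pytest.approx(0.300)
        assert m.pep_over_lvet == pytest.approx(0.2667, abs=1e-4)

    def test_fewer_than_two_beats_warns_and_nans(self):
        fid = BeatFiducials(200.0, [{"R": 100}], [{"R": True}])
        with pytest.warns(RuntimeWarning):
            m = compute_metrics(fid)
        assert np.isnan(m.hr) and np.isnan(m.sdrr)

    def test_noiseless_recovery_within_5_ms(self, noiseless_rest):
        rec = noiseless_rest
        fid = detect_trimodal_fiducials(rec)
        m = compute_metrics(fid)
        ann = rec.annotations.beats
        fs = rec.sampling_rate
        rr = np.diff([b["R"] for b in ann]) / fs
        truth = {
            "hr": 60.0 / rr.mean(),
            "qt": np.mean([(b["T"] - b["Q"]) / fs for b in ann]),
            "sdrr": rr.std(),
            "emd": np.mean([(b["MC"] - b["Q"]) / fs for b in ann]),
            "pep": np.mean([(b["AO"] - b["Q"]) / fs for b in ann]),
            "lvet": np.mean([(b["AC"] - b["AO"]) / fs for b in ann]),
        }
        assert abs(m.hr - truth["hr"]) < 1.0  # bpm
        for key in ("qt", "sdrr", "emd", "pep", "lvet"):
            assert abs(getattr(m, key) - truth[key]) < 0.005, key

    def test_scale_invariance(self, noiseless_rest):
        rec = noiseless_rest
        fid1 = detect_trimodal_fiducials(rec)
        from pentacardio.recording import TrimodalRecording

        rec2 = TrimodalRecording(7.3 * rec.data, 200.0, rec.layout)
        fid2 = detect_trimodal_fiducials(rec2)
        assert fid1.beats == fid2.beats
        m1, m2 = compute_metrics(fid1), compute_metrics(fid2)
        assert m1.as_dict() == m2.as_dict()

    def test_intensity_sweep_trends(self):
        """HR rises while QT, SDRR, EMD, PEP, PEP/LVET all fall."""
        rows = []
        for state in pc.MOTION_STATES:
            rec = pc.generate_recording(
                template=pc.template_for_state(state),
                motion_schedule=[("sitting", 60.0)],
                seed=61,
                config=pc.NOISELESS,
            )
            rows.append(compute_metrics(detect_trimodal_fiducials(rec)))
        hr = [m.hr for m in rows]
        assert all(a < b for a, b in zip(hr, hr[1:]))
        for key in ("qt", "sdrr", "emd", "pep", "pep_over_lvet"):
            vals = [getattr(m, key) for m in rows]
            assert all(a > b for a, b in zip(vals, vals[1:])), key

    def test_segment_metrics_one_row_per_window(self, noiseless_rest):
        df = segment_metrics(noiseless_rest, window_s=10.0)
        assert len(df) == 6
        assert df["n_beats"].sum() <= len(noiseless_rest.annotations.beats) + 2
        assert (df["hr"] > 0).all()
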