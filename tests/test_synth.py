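"""Synthetic generator: templates, phenotypes, artifacts, recordings."""

from dataclasses import replace

import numpy as np
import pytest

import pentacardio as pc
from pentacardio.sigutils import band_power, total_power
from pentacardio.synth import (
    MOTION_STATES,
    PHENOTYPES,
    CardiacTemplateParams,
    default_motion_profiles,
    generate_cardiac_cycle,
    generate_motion_artifact,
    generate_recording,
)


class TestCardiacCycle:
    def test_r_fiducial_index_and_waveform_peak(self):
        cyc = generate_cardiac_cycle(CardiacTemplateParams(), fs=200.0, r_offset=0.2)
        assert cyc["fiducials"]["R"] == 40
        peak = int(np.argmax(cyc["ecg"]))
        assert abs(peak - 40) <= 1

    def test_all_fiducial_peaks_near_indices(self):
        params = CardiacTemplateParams()
        cyc = generate_cardiac_cycle(params, fs=200.0)
        for key, sig in [("AO", cyc["scg"]), ("gJ", cyc["gcg"])]:
            idx = cyc["fiducials"][key]
            lo, hi = idx - 3, idx + 4
            assert abs(lo + np.argmax(sig[lo:hi]) - idx) <= 1

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            CardiacTemplateParams(pep0=0.02, emd0=0.08)  # AO before MC

    def test_hf_phenotype_scales_mechanical_amplitude_to_40_percent(self):
        base = CardiacTemplateParams()
        hf = PHENOTYPES["hf"].apply(base)
        cyc_n = generate_cardiac_cycle(base)
        cyc_h = generate_cardiac_cycle(hf)
        ao_n = cyc_n["scg"][cyc_n["fiducials"]["AO"]]
        ao_h = cyc_h["scg"][cyc_h["fiducials"]["AO"]]
        assert ao_h == pytest.approx(0.4 * ao_n, rel=0.05)

    def test_afib_phenotype_removes_p_and_sets_rr_cv(self):
        afib = PHENOTYPES["afib"].apply(CardiacTemplateParams())
        assert afib.ecg_amps["P"] == 0.0
        rng = np.random.default_rng(0)
        from pentacardio.synth import _draw_rr_series

        rr = _draw_rr_series(afib, 500 * afib.mean_rr, rng)[:500]
        cv = rr.std() / rr.mean()
        assert cv == pytest.approx(0.15, rel=0.10)

    def test_mi_phenotype_alters_q_and_t(self):
        mi = PHENOTYPES["mi"].apply(CardiacTemplateParams())
        base = CardiacTemplateParams()
        assert mi.ecg_amps["Q"] == pytest.approx(1.5 * base.ecg_amps["Q"])
        assert mi.ecg_amps["T"] == pytest.approx(0.5 * base.ecg_amps["T"])


class TestMotionArtifact:
    def test_sitting_with_zero_noise_floor_is_all_zero(self):
        p = replace(default_motion_profiles()["sitting"], broadband_noise_level=0.0)
        art = generate_motion_artifact(p, 200.0, 5.0, 0)
        assert np.all(art == 0.0)

    def test_running_spectral_peak_at_step_frequency(self):
        p = replace(default_motion_profiles()["running"], step_frequency=2.8)
        art = generate_motion_artifact(p, 200.0, 60.0, 3)
        z = art[0, 2]  # pad 1, Acc.Z
        freqs = np.fft.rfftfreq(len(z), 1 / 200.0)
        spec = np.abs(np.fft.rfft(z)) ** 2
        df = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(spec[1:]) + 1] - 2.8) <= df

    def test_same_seed_is_bit_identical(self):
        p = default_motion_profiles()["walking"]
        a = generate_motion_artifact(p, 200.0, 10.0, 11)
        b = generate_motion_artifact(p, 200.0, 10.0, 11)
        np.testing.assert_array_equal(a, b)

    def test_unknown_state_rejected(self):
        from pentacardio.synth import MotionProfile

        with pytest.raises(ValueError):
            MotionProfile("swimming", 1.0, 1.0, 0.1)

    def test_energy_monotone_in_intensity(self):
        profiles = default_motion_profiles()
        energies = []
        for state in MOTION_STATES:
            art = generate_motion_artifact(profiles[state], 200.0, 30.0, 5)
            energies.append(float(np.mean(art**2)))
        assert all(a < b for a, b in zip(energies, energies[1:]))

    def test_high_frequency_content_grows_with_intensity(self):
        """15-25 Hz band power: running >= 5x sitting."""
        profiles = default_motion_profiles()
        sit = generate_motion_artifact(profiles["sitting"], 200.0, 30.0, 6)[0, 2]
        run = generate_motion_artifact(profiles["running"], 200.0, 30.0, 6)[0, 2]
        assert band_power(run, 200.0, 15, 25) >= 5 * band_power(sit, 200.0, 15, 25)

    def test_running_z_energy_tenfold_over_sitting(self):
        profiles = default_motion_profiles()
        sit = generate_motion_artifact(profiles["sitting"], 200.0, 30.0, 8)[0, 2]
        run = generate_motion_artifact(profiles["running"], 200.0, 30.0, 8)[0, 2]
        assert total_power(run) > 10 * total_power(sit)


class TestGenerateRecording:
    def test_default_layout_channel_counts(self, rest_recording):
        assert len(rest_recording.layout.mech_channels) == 30
        assert len(rest_recording.layout.ecg_channels) == 1
        assert rest_recording.data.shape[0] == 31

    def test_duration_in_samples(self):
        rec = generate_recording(motion_schedule=[("sitting", 10.0)], seed=0)
        assert rec.n_samples == 2000

    def test_rest_pad5_band_power_5_to_15x_compensation_pads(self, rest_recording):
        rec = rest_recording
        for axis in ("Acc.Z", "Rot.Y"):
            p5 = band_power(rec.channel(f"Pad5.{axis}"), 200.0, 1.0, 40.0)
            pm = np.mean(
                [band_power(rec.channel(f"Pad{p}.{axis}"), 200.0, 1.0, 40.0) for p in (1, 2, 3, 4)]
            )
            assert 5.0 <= p5 / pm <= 15.0

    def test_annotations_self_consistent(self, running_recording):
        rec = running_recording
        ann = rec.annotations
        n = rec.n_samples
        for beat in ann.beats:
            for idx in beat.values():
                assert 0 <= idx < n
        # state intervals tile the duration exactly
        assert ann.state_intervals[0][1] == 0.0
        assert ann.state_intervals[-1][2] == pytest.approx(rec.duration_s)
        for (_, _, e0), (_, s1, _) in zip(ann.state_intervals, ann.state_intervals[1:]):
            assert e0 == pytest.approx(s1)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            generate_recording(motion_schedule=[], seed=0)

    def test_pad5_equals_cardiac_plus_mixed_artifact(self):
        rec = generate_recording(
            motion_schedule=[("running", 20.0)], seed=9, config=pc.NOISELESS
        )
        comp = rec.annotations.extras["components"]
        pad5 = rec.channels(rec.layout.pad_channels(5))
        np.testing.assert_allclose(
            pad5, comp["pad5_cardiac"] + comp["pad5_artifact"], atol=1e-12
        )
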