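"""Vector-synthesis artifact compensation."""

from dataclasses import replace

import numpy as np
import pytest

import pentacardio as pc
from pentacardio.compensation import (
    CompensationConfig,
    attenuation_db,
    fit_compensation,
    predict_artifact,
    subtract_artifact,
)
from pentacardio.layout import ChannelLayout
from pentacardio.recording import TrimodalRecording

TRUE_W = (0.4, 0.3, 0.2, 0.1)


def _truth_matrix(model):
    W = np.zeros_like(model.weights)
    for a in range(6):
        for p in range(4):
            W[a, p * 6 + a] = TRUE_W[p]
    return W


class TestFit:
    def test_exact_copy_recovers_unit_weight(self):
        """Pad-5 artifact equals pad-1 exactly: weight 1 there, ~0 elsewhere."""
        from dataclasses import replace as drep

        t = pc.CardiacTemplateParams()
        t = drep(
            t,
            ecg_amps={k: 0.0 for k in t.ecg_amps},
            scg_amps={k: 0.0 for k in t.scg_amps},
            gcg_amps={k: 0.0 for k in t.gcg_amps},
        )
        cfg = replace(pc.NOISELESS, mixing_weights=(1.0, 0.0, 0.0, 0.0))
        rec = pc.generate_recording(
            template=t, motion_schedule=[("running", 60.0)], seed=21, config=cfg
        )
        model = fit_compensation(
            rec, (0, 30), CompensationConfig(ridge=0.0, fit_intercept=False)
        )
        for a in range(6):
            expected = np.zeros(24)
            expected[a] = 1.0
            np.testing.assert_allclose(model.weights[a], expected, atol=1e-9)

    def test_ground_truth_weights_recovered_within_1e6(self, cardiac_free_running):
        model = fit_compensation(
            cardiac_free_running, (0, 30), CompensationConfig(ridge=0.0, fit_intercept=False)
        )
        assert np.abs(model.weights - _truth_matrix(model)).max() < 1e-6

    def test_running_attenuation_at_least_10_db(self, running_recording):
        rec = running_recording
        comp, model = pc.compensate(rec, (0.0, 30.0))
        c = rec.annotations.extras["components"]
        residual = comp.channels(rec.layout.pad_channels(5)) - c["pad5_cardiac"]
        # sensor noise was present before compensation too; compare the
        # artifact component against what remains of it
        noise = rec.channels(rec.layout.pad_channels(5)) - c["pad5_cardiac"] - c["pad5_artifact"]
        assert attenuation_db(c["pad5_artifact"], residual - noise) >= 10.0

    def test_too_short_calibration_rejected(self, running_recording):
        with pytest.raises(ValueError, match="calibration"):
            fit_compensation(running_recording, (0.0, 0.5))

    def test_rank_deficiency_without_ridge_raises(self):
        layout = ChannelLayout()
        rng = np.random.default_rng(0)
        n = 4000
        data = np.zeros((layout.n_channels, n))
        x = rng.standard_normal(n)
        for ch in layout.channels[:30]:
            data[layout.channel_index(ch)] = x  # all regressors identical
        rec = TrimodalRecording(data, 200.0, layout)
        with pytest.raises(np.linalg.LinAlgError):
            fit_compensation(rec, None, CompensationConfig(ridge=0.0))


class TestPredictSubtract:
    def test_zero_channels_give_zero_estimate(self, cardiac_free_running):
        model = fit_compensation(
            cardiac_free_running, (0, 30), CompensationConfig(fit_intercept=False)
        )
        blank = TrimodalRecording(
            np.zeros((31, 2000)), 200.0, cardiac_free_running.layout
        )
        est = predict_artifact(model, blank)
        np.testing.assert_allclose(est, 0.0, atol=1e-12)

    def test_linearity_in_inputs(self, cardiac_free_running):
        rec = cardiac_free_running
        model = fit_compensation(rec, (0, 30), CompensationConfig(fit_intercept=False))
        est1 = predict_artifact(model, rec)
        doubled = TrimodalRecording(2.0 * rec.data, 200.0, rec.layout)
        est2 = predict_artifact(model, doubled)
        np.testing.assert_allclose(est2, 2.0 * est1, rtol=1e-9, atol=1e-12)

    def test_estimate_matches_truth_on_noiseless_mixture(self, cardiac_free_running):
        rec = cardiac_free_running
        model = fit_compensation(rec, (0, 30), CompensationConfig(ridge=0.0, fit_intercept=False))
        est = predict_artifact(model, rec)
        art = rec.annotations.extras["components"]["pad5_artifact"]
        assert np.corrcoef(est.ravel(), art.ravel())[0, 1] >= 0.99

    def test_exact_system_residual_is_cardiac(self, cardiac_free_running):
        """Fit on pure artifact, add a known cardiac trace, subtract."""
        rec = cardiac_free_running
        model = fit_compensation(rec, None, CompensationConfig(ridge=0.0, fit_intercept=False))
        cyc = pc.generate_cardiac_cycle(pc.CardiacTemplateParams())
        cardiac = np.tile(cyc["scg"], int(np.ceil(rec.n_samples / len(cyc["scg"]))))[
            : rec.n_samples
        ]
        data = rec.data.copy()
        idx = rec.layout.channel_index("Pad5.Acc.Z")
        data[idx] += cardiac
        rec2 = TrimodalRecording(data, 200.0, rec.layout)
        comp = subtract_artifact(rec2, predict_artifact(model, rec2))
        residual = comp.channel("Pad5.Acc.Z")
        assert np.abs(residual - cardiac).max() < 1e-9

    def test_zero_estimate_is_identity(self, running_recording):
        rec = running_recording
        out = subtract_artifact(rec, np.zeros((6, rec.n_samples)))
        np.testing.assert_array_equal(out.data, rec.data)

    def test_length_mismatch_rejected(self, running_recording):
        with pytest.raises(ValueError):
            subtract_artifact(running_recording, np.zeros((6, 10)))

    def test_other_channels_untouched(self, running_recording):
        rec = running_recording
        comp, _ = pc.compensate(rec, (0.0, 30.0))
        np.testing.assert_array_equal(comp.channel("ECG"), rec.channel("ECG"))
        np.testing.assert_array_equal(comp.channel("Pad1.Acc.X"), rec.channel("Pad1.Acc.X"))


class TestProperties:
    def test_compensation_never_increases_artifact_power_on_calibration(
        self, running_recording
    ):
        rec = running_recording
        comp, model = pc.compensate(rec, (0.0, 30.0))
        sl = slice(0, 30 * 200)
        before = rec.channels(rec.layout.pad_channels(5))[:, sl]
        after = comp.channels(rec.layout.pad_channels(5))[:, sl]
        # least-squares optimality: residual power <= input power per axis
        assert np.all(np.mean(after**2, axis=1) <= np.mean(before**2, axis=1) + 1e-12)

    def test_attenuation_monotone_in_regressor_noise(self):
        """More sensor noise on the reference pads => weaker attenuation."""
        attens = []
        for noise in (0.0, 0.1, 0.5):
            cfg = replace(pc.NOISELESS, sensor_noise_mech=noise)
            rec = pc.generate_recording(
                motion_schedule=[("running", 40.0)], seed=31, config=cfg
            )
            comp, _ = pc.compensate(rec, (0.0, 20.0))
            c = rec.annotations.extras["components"]
            resid = comp.channels(rec.layout.pad_channels(5)) - c["pad5_cardiac"]
            attens.append(attenuation_db(c["pad5_artifact"], resid))
        assert attens[0] > attens[1] > attens[2]

    def test_cardiac_distortion_shrinks_with_calibration_length(self):
        """Longer calibration decorrelates cardiac from the regressors."""
        distortions = []
        for calib_s in (10.0, 100.0):
            rec = pc.generate_recording(
                motion_schedule=[("running", max(calib_s, 100.0))],
                seed=33,
                config=pc.NOISELESS,
            )
            comp, _ = pc.compensate(rec, (0.0, calib_s))
            c = rec.annotations.extras["components"]
            resid = comp.channels(rec.layout.pad_channels(5)) - c["pad5_cardiac"]
            # residual beyond the true artifact = distortion of the cardiac part
            distortions.append(float(np.mean(resid**2)))
        assert distortions[1] < distortions[0]
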