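"""End-to-end evaluations of the pipeline against synthetic ground truth.

Each function builds its own inputs from the generator, runs one stage of
the pipeline, and measures recovery quality: artifact attenuation and
mixing-weight recovery for compensation, fiducial peak preservation and
spectral concentration for adaptive filtering, timing-metric recovery and
exercise-intensity trends for the metrics stage, and held-out
classification quality for the two learned stages.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .compensation import CompensationConfig, attenuation_db, compensate, fit_compensation
from .datasets import make_diagnosis_dataset, make_motion_dataset
from .diagnosis import ablation_study, train_diagnosis_model
from .fiducials import compute_metrics, detect_trimodal_fiducials
from .filters import build_filter_bank, filter_recording_channels
from .motion import MotionStateProbs, train_motion_classifier
from .recording import segment_recording
from .seqmodel import SequenceModelConfig, evaluate_classifier, preset
from .sigutils import band_power, total_power
from .synth import (
    MOTION_STATES,
    NOISELESS,
    CardiacTemplateParams,
    generate_recording,
    template_for_state,
)


def _cardiac_free_template() -> CardiacTemplateParams:
    t = CardiacTemplateParams()
    return replace(
        t,
        ecg_amps={k: 0.0 for k in t.ecg_amps},
        scg_amps={k: 0.0 for k in t.scg_amps},
        gcg_amps={k: 0.0 for k in t.gcg_amps},
    )


def measure_compensation(seed: int = 0) -> dict:
    """Weight recovery (noiseless, cardiac-free) and running attenuation."""
    free = generate_recording(
        template=_cardiac_free_template(),
        motion_schedule=[("running", 60.0)],
        seed=seed,
        config=NOISELESS,
    )
    model = fit_compensation(free, (0, 30), CompensationConfig(ridge=0.0, fit_intercept=False))
    truth = np.zeros_like(model.weights)
    w = free.annotations.mixing_weights["Acc.X"]
    for a in range(6):
        for p in range(4):
            truth[a, p * 6 + a] = w[p]
    weight_err = float(np.abs(model.weights - truth).max())

    rec = generate_recording(motion_schedule=[("running", 60.0)], seed=seed + 1)
    comp, _ = compensate(rec, (0.0, 30.0))
    c = rec.annotations.extras["components"]
    pads = rec.layout.pad_channels(rec.layout.acquisition_pad)
    noise = rec.channels(pads) - c["pad5_cardiac"] - c["pad5_artifact"]
    resid = comp.channels(pads) - c["pad5_cardiac"] - noise
    return {
        "weight_recovery_max_error": weight_err,
        "attenuation_db": attenuation_db(c["pad5_artifact"], resid),
    }


def measure_filtering(seed: int = 0) -> dict:
    """Peak preservation and cardiac-band concentration on running data."""
    bank = build_filter_bank(fs=200.0)
    clean = generate_recording(
        motion_schedule=[("running", 60.0)], seed=seed, config=NOISELESS
    )
    card = clean.annotations.extras["components"]["pad5_cardiac"][2]  # Acc.Z
    out = filter_recording_channels(card, MotionStateProbs.one_hot("running"), bank)
    shifts = []
    for beat in clean.annotations.beats:
        for key in ("AO", "AC"):
            idx = beat[key]
            if 10 <= idx < len(card) - 10:
                shifts.append(abs(int(np.argmax(out[idx - 3 : idx + 4])) - 3))
    max_shift = max(shifts)

    rec = generate_recording(motion_schedule=[("running", 60.0)], seed=seed + 1)
    comp, _ = compensate(rec, (0.0, 30.0))
    fins, fouts = [], []
    for seg in segment_recording(comp)[1:5]:
        x = seg.channel("Pad5.Acc.Z")
        y = filter_recording_channels(x, MotionStateProbs.one_hot("running"), bank)
        fins.append(band_power(x, 200.0, 10, 45) / total_power(x))
        fouts.append(band_power(y, 200.0, 10, 45) / total_power(y))
    return {
        "max_peak_shift_samples": float(max_shift),
        "cardiac_band_fraction_in": float(np.mean(fins)),
        "cardiac_band_fraction_out": float(np.mean(fouts)),
    }


def measure_metric_recovery(seed: int = 0) -> dict:
    """Noiseless timing recovery plus sitting->running metric trends."""
    rec = generate_recording(
        motion_schedule=[("sitting", 60.0)], seed=seed, config=NOISELESS
    )
    m = compute_metrics(detect_trimodal_fiducials(rec))
    ann = rec.annotations.beats
    fs = rec.sampling_rate
    rr = np.diff([b["R"] for b in ann]) / fs
    truth = {
        "qt": np.mean([(b["T"] - b["Q"]) / fs for b in ann]),
        "sdrr": rr.std(),
        "emd": np.mean([(b["MC"] - b["Q"]) / fs for b in ann]),
        "pep": np.mean([(b["AO"] - b["Q"]) / fs for b in ann]),
        "lvet": np.mean([(b["AC"] - b["AO"]) / fs for b in ann]),
    }
    errors_ms = {k: abs(getattr(m, k) - v) * 1000 for k, v in truth.items()}
    errors_ms["hr_bpm"] = abs(m.hr - 60.0 / rr.mean())

    sweep = []
    for state in MOTION_STATES:
        r = generate_recording(
            template=template_for_state(state),
            motion_schedule=[("sitting", 60.0)],
            seed=seed + 2,
            config=NOISELESS,
        )
        sweep.append(compute_metrics(detect_trimodal_fiducials(r)))
    hr = [x.hr for x in sweep]
    up = all(a < b for a, b in zip(hr, hr[1:]))
    down = all(
        all(
            getattr(a, k) > getattr(b, k)
            for a, b in zip(sweep, sweep[1:])
        )
        for k in ("qt", "sdrr", "emd", "pep", "pep_over_lvet")
    )
    return {
        "max_timing_error_ms": float(max(v for k, v in errors_ms.items() if k != "hr_bpm")),
        "hr_error_bpm": float(errors_ms["hr_bpm"]),
        "sweep_trends_monotone": float(up and down),
        "hr_range_bpm": (float(hr[0]), float(hr[-1])),
    }


def run_motion_benchmark(
    seed: int = 7,
    n_per_state: int = 200,
    config: SequenceModelConfig | None = None,
    dataset=None,
) -> dict:
    """Held-out macro-F1 of the desk-scale transformer and a forest baseline."""
    ds = dataset or make_motion_dataset(n_per_state=n_per_state, seed=seed)
    cfg = config or preset("desk")
    model = train_motion_classifier(ds.train_segments, ds.train_labels, "transformer", cfg, seed)
    res = evaluate_classifier(model, ds.test_segments, ds.test_labels)
    rf = train_motion_classifier(ds.train_segments, ds.train_labels, "random_forest", seed=seed)
    rf_res = evaluate_classifier(rf, ds.test_segments, ds.test_labels)
    return {
        "transformer_macro_f1": res["macro_f1"],
        "random_forest_macro_f1": rf_res["macro_f1"],
        "per_class_accuracy": res["per_class_accuracy"],
    }


def run_diagnosis_benchmark(
    seed: int = 11,
    n_per_class: int = 200,
    config: SequenceModelConfig | None = None,
    ablation_config: SequenceModelConfig | None = None,
    dataset=None,
) -> dict:
    """Held-out per-class accuracy plus the paired modality ablation."""
    ds = dataset or make_diagnosis_dataset(n_per_class=n_per_class, seed=seed)
    cfg = config or preset("desk")
    model = train_diagnosis_model(ds.train_segments, ds.train_labels, "transformer", cfg, seed)
    res = evaluate_classifier(model, ds.test_segments, ds.test_labels)
    ab_cfg = ablation_config or preset("desk", iterations=600)
    ab = ablation_study(
        ds.train_segments, ds.train_labels, ds.test_segments, ds.test_labels,
        config=ab_cfg, seed=seed,
    )
    unimodal = {k: v["macro_f1"] for k, v in ab.items() if v["n_channels"] < 7}
    return {
        "per_class_accuracy": res["per_class_accuracy"],
        "macro_f1": res["macro_f1"],
        "trimodal_macro_f1": ab["ecg+scg+gcg"]["macro_f1"],
        "unimodal_macro_f1": unimodal,
    }
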