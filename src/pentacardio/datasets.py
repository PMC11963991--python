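"""Synthetic benchmark datasets for motion recognition and diagnosis.

Each benchmark generates multiple recordings per class ("subjects" with
jittered templates, cadences and amplitudes), segments them into 10-s
windows, and splits train/test by recording so that no recording
contributes to both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .recording import Segment, segment_recording
from .synth import (
    MOTION_STATES,
    PHENOTYPES,
    STEP_FREQUENCY_RANGES,
    CardiacTemplateParams,
    DiseasePhenotype,
    GeneratorConfig,
    default_motion_profiles,
    generate_recording,
    template_for_state,
)


@dataclass
class BenchmarkDataset:
    train_segments: list[Segment]
    train_labels: list[str]
    test_segments: list[Segment]
    test_labels: list[str]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.train_labels))


def _jittered_template(base: CardiacTemplateParams, rng) -> CardiacTemplateParams:
    """Per-recording ("subject") variation around a base template."""
    return replace(
        base,
        mean_rr=base.mean_rr * rng.uniform(0.9, 1.1),
        ecg_amps={k: v * rng.uniform(0.9, 1.1) for k, v in base.ecg_amps.items()},
        scg_amps={k: v * rng.uniform(0.9, 1.1) for k, v in base.scg_amps.items()},
        gcg_amps={k: v * rng.uniform(0.9, 1.1) for k, v in base.gcg_amps.items()},
        pep0=base.pep0 + rng.uniform(-0.005, 0.005),
        lvet0=base.lvet0 + rng.uniform(-0.01, 0.01),
        qt0=base.qt0 + rng.uniform(-0.01, 0.01),
    )


def make_motion_dataset(
    n_per_state: int = 200,
    seed: int = 0,
    segments_per_recording: int = 5,
    test_fraction: float = 0.25,
    fs: float = 200.0,
) -> BenchmarkDataset:
    """Four-state motion benchmark (default 200 segments per state).

    Each recording uses the state's heart-rate preset, a cadence drawn
    from the state's plausible range, and +/-20% amplitude jitter.
    """
    rng = np.random.default_rng(seed)
    window_s = 10.0
    train_s, train_l, test_s, test_l = [], [], [], []
    for state in MOTION_STATES:
        n_rec = int(np.ceil(n_per_state / segments_per_recording))
        n_test_rec = max(int(round(n_rec * test_fraction)), 1)
        collected = 0
        for r in range(n_rec):
            profiles = default_motion_profiles()
            p = profiles[state]
            if state in STEP_FREQUENCY_RANGES:
                lo, hi = STEP_FREQUENCY_RANGES[state]
                p = replace(
                    p,
                    step_frequency=rng.uniform(lo, hi),
                    base_amplitude=p.base_amplitude * rng.uniform(0.8, 1.2),
                    broadband_noise_level=p.broadband_noise_level * rng.uniform(0.8, 1.2),
                )
            else:
                p = replace(
                    p, broadband_noise_level=p.broadband_noise_level * rng.uniform(0.8, 1.2)
                )
            profiles[state] = p
            n_seg = min(segments_per_recording, n_per_state - collected)
            if n_seg <= 0:
                break
            rec = generate_recording(
                template=_jittered_template(template_for_state(state), rng),
                motion_schedule=[(state, n_seg * window_s)],
                fs=fs,
                seed=rng,
                profiles=profiles,
                subject_id=f"{state}-{r}",
            )
            segs = segment_recording(rec, window_s)
            collected += len(segs)
            if r < n_rec - n_test_rec:
                train_s += segs
                train_l += [state] * len(segs)
            else:
                test_s += segs
                test_l += [state] * len(segs)
    return BenchmarkDataset(train_s, train_l, test_s, test_l)


def make_diagnosis_dataset(
    n_per_class: int = 200,
    seed: int = 0,
    segments_per_recording: int = 5,
    test_fraction: float = 0.25,
    fs: float = 200.0,
    hf_amp_scale: float = 0.4,
    hf_ao_shift: float = 0.020,
    config: GeneratorConfig | None = None,
) -> BenchmarkDataset:
    """Four-class heart-condition benchmark of resting recordings.

    Patients are modeled at rest (sitting schedule); each recording is an
    independent "subject" with a jittered normal template before the
    phenotype deltas are applied.  The heart-failure severity (amplitude
    scale, aortic-opening delay) is exposed for sensitivity sweeps.
    """
    rng = np.random.default_rng(seed)
    window_s = 10.0
    phenotypes = dict(PHENOTYPES)
    phenotypes["hf"] = DiseasePhenotype(
        "hf", mech_amp_scale=hf_amp_scale, ao_shift=hf_ao_shift
    )
    train_s, train_l, test_s, test_l = [], [], [], []
    for label in ("normal", "afib", "mi", "hf"):
        n_rec = int(np.ceil(n_per_class / segments_per_recording))
        n_test_rec = max(int(round(n_rec * test_fraction)), 1)
        collected = 0
        for r in range(n_rec):
            n_seg = min(segments_per_recording, n_per_class - collected)
            if n_seg <= 0:
                break
            rec = generate_recording(
                template=_jittered_template(CardiacTemplateParams(), rng),
                phenotype=phenotypes[label],
                motion_schedule=[("sitting", n_seg * window_s)],
                fs=fs,
                seed=rng,
                config=config,
                subject_id=f"{label}-{r}",
            )
            segs = segment_recording(rec, window_s)
            collected += len(segs)
            if r < n_rec - n_test_rec:
                train_s += segs
                train_l += [label] * len(segs)
            else:
                test_s += segs
                test_l += [label] * len(segs)
    return BenchmarkDataset(train_s, train_l, test_s, test_l)
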