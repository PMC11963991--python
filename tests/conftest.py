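import numpy as np
import pytest

import pentacardio as pc


@pytest.fixture(scope="session")
def rest_recording():
    """Default 120-s resting recording with ground truth."""
    return pc.generate_recording(motion_schedule=[("sitting", 120.0)], seed=101)


@pytest.fixture(scope="session")
def running_recording():
    """60-s running recording (default noise) with ground truth."""
    return pc.generate_recording(motion_schedule=[("running", 60.0)], seed=102)


@pytest.fixture(scope="session")
def noiseless_rest():
    """Noiseless, leak-free resting recording for exact recovery checks."""
    return pc.generate_recording(
        motion_schedule=[("sitting", 60.0)], seed=103, config=pc.NOISELESS
    )


@pytest.fixture(scope="session")
def cardiac_free_running():
    """Running recording with all cardiac amplitudes zeroed (pure artifact)."""
    from dataclasses import replace

    t = pc.CardiacTemplateParams()
    t = replace(
        t,
        ecg_amps={k: 0.0 for k in t.ecg_amps},
        scg_amps={k: 0.0 for k in t.scg_amps},
        gcg_amps={k: 0.0 for k in t.gcg_amps},
    )
    return pc.generate_recording(
        template=t,
        motion_schedule=[("running", 60.0)],
        seed=104,
        config=pc.NOISELESS,
    )


@pytest.fixture(scope="session")
def tiny_motion_dataset():
    """Small four-state benchmark for fast training tests."""
    return pc.make_motion_dataset(n_per_state=20, seed=201)


@pytest.fixture(scope="session")
def tiny_diagnosis_dataset():
    """Small four-class benchmark for fast training tests."""
    return pc.make_diagnosis_dataset(n_per_class=40, seed=202)


@pytest.fixture(scope="session")
def motion_benchmark():
    """Full four-state benchmark (200 segments per state, seed 7)."""
    return pc.make_motion_dataset(n_per_state=200, seed=7)


@pytest.fixture(scope="session")
def diagnosis_benchmark():
    """Full four-class benchmark (200 segments per class, seed 11)."""
    return pc.make_diagnosis_dataset(n_per_class=200, seed=11)


@pytest.fixture(scope="session")
def tiny_config():
    """Minimal transformer config for fast smoke training."""
    return pc.preset(
        "desk",
        input_projection_dim=32,
        feedforward_dim=64,
        encoder_layers=1,
        iterations=120,
        batch_size=32,
    )
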