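"""Synthetic five-pad trimodal recordings with exact ground truth.

No public five-pad SCG/GCG corpus exists, so this module emulates the
statistical structure the processing pipeline assumes:

* cardiac templates — ECG (P, Q, R, S, T), SCG (MC, AO, AC, MO) and GCG
  (g_I..g_L) fiducials rendered as Gaussian bumps at configured offsets,
  with rate-adaptive intervals (QT, EMD, PEP, LVET shorten as HR rises);
* motion-state artifact processes — stride-locked harmonic series plus
  band-limited broadband noise, with energy rising sharply from sitting
  through running (running Z-acceleration energy >> sitting);
* pad mixing — the acquisition pad (pad 5) sees cardiac signal plus a
  weighted sum of the four compensation pads' artifacts, so artifact
  compensation has a recoverable ground truth;
* disease phenotypes — normal, atrial fibrillation (irregular RR, absent
  P), myocardial infarction (deeper Q, flattened T), heart failure
  (mechanical contraction amplitudes reduced to ~0.4x, delayed aortic
  opening).

Every stochastic draw flows from one seed; annotations carry per-beat
fiducial sample indices, motion-state intervals, mixing weights and the
disease label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .layout import AXES, ChannelLayout
from .recording import Annotations, TrimodalRecording

MOTION_STATES = ("sitting", "walking", "jogging", "running")

#: Heart-rate presets (bpm) for the exercise-intensity sweep.
MOTION_STATE_HR = {"sitting": 60, "walking": 90, "jogging": 120, "running": 150}

ECG_FIDUCIALS = ("P", "Q", "R", "S", "T")
SCG_FIDUCIALS = ("MC", "AO", "AC", "MO")
GCG_FIDUCIALS = ("gI", "gJ", "gK", "gL")


# ------------------------------------------------------------------ templates

@dataclass
class CardiacTemplateParams:
    """Fiducial offsets/amplitudes/kernel widths of one cardiac cycle.

    Offsets are stated at the reference cycle length ``ref_rr``; intervals
    measured from the Q wave contract as the cycle shortens, each with its
    own exponent (a Bazett-like square-root law for QT and the ejection
    time, closer to linear for the pre-ejection intervals), so that HR up
    implies QT, EMD, PEP, LVET and PEP/LVET all down.
    """

    mean_rr: float = 0.8  # s
    rr_cv: float = 0.05  # coefficient of variation of RR
    ref_rr: float = 0.8  # cycle length at which offsets below are stated

    # ECG, relative to the R peak (s); amplitudes in mV; widths in s
    p_offset: float = -0.14
    q_offset: float = -0.04
    s_offset: float = 0.035
    qt0: float = 0.29  # Q->T interval at ref_rr
    ecg_amps: dict = field(
        default_factory=lambda: {"P": 0.15, "Q": -0.12, "R": 1.1, "S": -0.25, "T": 0.35}
    )
    ecg_widths: dict = field(
        default_factory=lambda: {"P": 0.025, "Q": 0.012, "R": 0.012, "S": 0.012, "T": 0.045}
    )

    # electromechanical intervals at ref_rr (s), all measured from Q
    emd0: float = 0.08  # Q -> MC
    pep0: float = 0.12  # Q -> AO
    lvet0: float = 0.30  # AO -> AC
    mo_delay0: float = 0.05  # AC -> MO
    gi0: float = 0.075  # Q -> g_I
    gj0: float = 0.115  # Q -> g_J
    gk_interval0: float = 0.29  # g_J -> g_K
    gl_delay0: float = 0.05  # g_K -> g_L

    # rate-adaptation exponents on (rr / ref_rr)
    exp_qt: float = 0.5
    exp_pre: float = 0.7  # EMD, PEP, g_I, g_J
    exp_eject: float = 0.5  # LVET, MO delay, g_K, g_L

    scg_amps: dict = field(
        default_factory=lambda: {"MC": 0.5, "AO": 1.0, "AC": 0.6, "MO": 0.4}
    )  # m/s^2 on the principal (Z) axis
    scg_widths: dict = field(
        default_factory=lambda: {"MC": 0.012, "AO": 0.012, "AC": 0.014, "MO": 0.014}
    )
    gcg_amps: dict = field(
        default_factory=lambda: {"gI": 1.5, "gJ": 3.0, "gK": 2.0, "gL": 1.2}
    )  # dps on the principal (Y) axis
    gcg_widths: dict = field(
        default_factory=lambda: {"gI": 0.015, "gJ": 0.015, "gK": 0.016, "gL": 0.016}
    )

    # projection of the canonical SCG/GCG waveform onto the pad-5 axes
    scg_axis_gains: dict = field(default_factory=lambda: {"X": 0.3, "Y": 0.4, "Z": 1.0})
    gcg_axis_gains: dict = field(default_factory=lambda: {"X": 0.4, "Y": 1.0, "Z": 0.3})

    ao_shift: float = 0.0  # extra pre-ejection delay (s), used by the HF phenotype

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        offs = self.fiducial_offsets(self.mean_rr)
        if not (offs["Q"] < offs["R"] < offs["T"] < self.mean_rr + offs["Q"] + 1e-9):
            raise ValueError("ECG fiducial ordering Q < R < T < RR violated")
        if not (offs["MC"] <= offs["AO"] < offs["AC"] <= offs["MO"]):
            raise ValueError("SCG fiducial ordering MC <= AO < AC <= MO violated")
        if not (offs["gI"] <= offs["gJ"] < offs["gK"] <= offs["gL"]):
            raise ValueError("GCG fiducial ordering gI <= gJ < gK <= gL violated")
        for d in (self.ecg_amps, self.scg_amps, self.gcg_amps):
            if not all(np.isfinite(list(d.values()))):
                raise ValueError("amplitudes must be finite")

    def fiducial_offsets(self, rr: float) -> dict[str, float]:
        """Per-fiducial time offsets relative to the R peak for a cycle of ``rr`` s."""
        s = rr / self.ref_rr
        q = self.q_offset
        out = {
            "P": self.p_offset,
            "Q": q,
            "R": 0.0,
            "S": self.s_offset,
            "T": q + self.qt0 * s**self.exp_qt,
        }
        out["MC"] = q + self.emd0 * s**self.exp_pre
        out["AO"] = q + self.pep0 * s**self.exp_pre + self.ao_shift
        out["AC"] = out["AO"] + self.lvet0 * s**self.exp_eject
        out["MO"] = out["AC"] + self.mo_delay0 * s**self.exp_eject
        out["gI"] = q + self.gi0 * s**self.exp_pre
        out["gJ"] = q + self.gj0 * s**self.exp_pre + self.ao_shift
        out["gK"] = out["gJ"] + self.gk_interval0 * s**self.exp_eject
        out["gL"] = out["gK"] + self.gl_delay0 * s**self.exp_eject
        return out


@dataclass
class DiseasePhenotype:
    """Parameter deltas applied to a normal cardiac template."""

    label: str = "normal"
    ecg_amp_scale: dict = field(default_factory=dict)  # per ECG fiducial
    mech_amp_scale: float = 1.0  # SCG and GCG amplitudes
    rr_cv: float | None = None
    ao_shift: float = 0.0  # s, added pre-ejection delay

    def apply(self, t: CardiacTemplateParams) -> CardiacTemplateParams:
        ecg_amps = {k: v * self.ecg_amp_scale.get(k, 1.0) for k, v in t.ecg_amps.items()}
        return replace(
            t,
            ecg_amps=ecg_amps,
            scg_amps={k: v * self.mech_amp_scale for k, v in t.scg_amps.items()},
            gcg_amps={k: v * self.mech_amp_scale for k, v in t.gcg_amps.items()},
            rr_cv=self.rr_cv if self.rr_cv is not None else t.rr_cv,
            ao_shift=t.ao_shift + self.ao_shift,
        )


#: Default phenotype library.  HF reduces mechanical contraction amplitude
#: to 0.4x normal (a ~60% reduction) and delays aortic opening by 20 ms;
#: A-Fib removes the P wave and makes RR highly irregular; MI deepens the
#: Q wave and flattens the T wave.
PHENOTYPES: dict[str, DiseasePhenotype] = {
    "normal": DiseasePhenotype("normal"),
    "afib": DiseasePhenotype("afib", ecg_amp_scale={"P": 0.0}, rr_cv=0.15),
    "mi": DiseasePhenotype("mi", ecg_amp_scale={"Q": 1.5, "T": 0.5}),
    "hf": DiseasePhenotype("hf", mech_amp_scale=0.4, ao_shift=0.020),
}

DISEASE_LABELS = ("normal", "afib", "mi", "hf")


# ------------------------------------------------------------------ motion

@dataclass
class MotionProfile:
    """Stride-locked artifact process for one motion state.

    The artifact on each pad axis is a harmonic series at the step
    frequency (amplitudes decaying geometrically across harmonics) plus
    band-limited broadband noise; per-pad gains and phases decorrelate the
    four compensation pads so the mixture on pad 5 is identifiable.
    """

    state: str
    step_frequency: float  # Hz; 0 when sitting
    base_amplitude: float  # m/s^2 scale of the fundamental on Acc.Z
    broadband_noise_level: float  # RMS, m/s^2 scale
    n_harmonics: int = 4
    harmonic_decay: float = 0.5
    acc_axis_gains: dict = field(default_factory=lambda: {"X": 0.5, "Y": 0.5, "Z": 1.0})
    rot_axis_gains: dict = field(default_factory=lambda: {"X": 1.2, "Y": 0.8, "Z": 0.6})
    per_pad_gain: tuple = (1.0, 0.9, 1.1, 0.95)
    noise_band: tuple = (0.5, 25.0)  # Hz; broadband content reaches ~25 Hz

    def __post_init__(self):
        if self.state not in MOTION_STATES:
            raise ValueError(f"unknown motion state {self.state!r}")
        if self.state == "sitting" and self.step_frequency != 0:
            raise ValueError("sitting profile must have step_frequency 0")


#: Default per-state profiles.  Amplitudes rise with cadence so that total
#: artifact energy is strictly monotone sitting < walking < jogging <
#: running, running Z-acceleration energy exceeds sitting >10-fold, and
#: high-frequency (15-25 Hz) content grows with intensity.
def default_motion_profiles() -> dict[str, MotionProfile]:
    return {
        "sitting": MotionProfile("sitting", 0.0, 0.0, 0.02),
        "walking": MotionProfile("walking", 1.8, 1.0, 0.10),
        "jogging": MotionProfile("jogging", 2.4, 2.5, 0.25),
        "running": MotionProfile("running", 2.8, 5.0, 0.50),
    }


#: Plausible per-state cadence ranges (Hz) used when sampling recordings.
STEP_FREQUENCY_RANGES = {
    "walking": (1.6, 2.0),
    "jogging": (2.2, 2.6),
    "running": (2.6, 3.0),
}


@dataclass
class GeneratorConfig:
    """Noise/mixing configuration shared by all generated recordings."""

    sensor_noise_mech: float = 0.01  # RMS, m/s^2 and dps
    sensor_noise_ecg: float = 0.01  # RMS, mV
    # cardiac leakage amplitude fraction reaching each compensation pad;
    # ~0.3 amplitude => ~1/0.09 ~= 11x band-power ratio pad5 : mean(pads 1-4)
    leak_fractions: tuple = (0.30, 0.28, 0.32, 0.30)
    # per-axis mixing weights of compensation-pad artifacts onto pad 5
    mixing_weights: tuple = (0.4, 0.3, 0.2, 0.1)
    drift_amplitude: float = 0.0  # optional slow baseline wander, mV
    drift_frequency: float = 0.2  # Hz

    def weights_for_axes(self) -> dict[str, list[float]]:
        return {
            f"{mod}.{ax}": list(self.mixing_weights)
            for mod in ("Acc", "Rot")
            for ax in AXES
        }


NOISELESS = GeneratorConfig(
    sensor_noise_mech=0.0, sensor_noise_ecg=0.0, leak_fractions=(0.0, 0.0, 0.0, 0.0)
)


# ------------------------------------------------------------------ kernels

def _add_gaussians(out, centers_s, amps, widths_s, fs):
    """Accumulate Gaussian bumps at continuous times, evaluated locally."""
    n = out.shape[-1]
    for c, a, w in zip(centers_s, amps, widths_s):
        if a == 0.0:
            continue
        half = max(int(np.ceil(5 * w * fs)), 2)
        ci = int(round(c * fs))
        i0, i1 = max(ci - half, 0), min(ci + half + 1, n)
        if i0 >= i1:
            continue
        t = np.arange(i0, i1) / fs
        out[i0:i1] += a * np.exp(-0.5 * ((t - c) / w) ** 2)


def generate_cardiac_cycle(
    params: CardiacTemplateParams, fs: float = 200.0, r_offset: float = 0.2
) -> dict:
    """Render a single cardiac cycle and its fiducial ground truth.

    Returns ``{"ecg", "scg", "gcg", "fiducials", "fs"}`` where the
    waveforms are 1-D canonical traces of one ``mean_rr``-long cycle with
    the R peak at ``r_offset`` seconds, and ``fiducials`` maps each
    fiducial name to its sample index (configured offset rounded to the
    nearest sample; each waveform peaks within +/-1 sample of it).
    """
    widths = {**params.ecg_widths, **params.scg_widths, **params.gcg_widths}
    if fs <= 2.0 / (2 * np.pi * min(widths.values())):
        raise ValueError("sampling rate too low for the narrowest kernel")
    n = int(round(params.mean_rr * fs))
    offs = params.fiducial_offsets(params.mean_rr)
    fid_times = {k: r_offset + v for k, v in offs.items()}
    ecg = np.zeros(n)
    scg = np.zeros(n)
    gcg = np.zeros(n)
    _add_gaussians(
        ecg,
        [fid_times[k] for k in ECG_FIDUCIALS],
        [params.ecg_amps[k] for k in ECG_FIDUCIALS],
        [params.ecg_widths[k] for k in ECG_FIDUCIALS],
        fs,
    )
    _add_gaussians(
        scg,
        [fid_times[k] for k in SCG_FIDUCIALS],
        [params.scg_amps[k] for k in SCG_FIDUCIALS],
        [params.scg_widths[k] for k in SCG_FIDUCIALS],
        fs,
    )
    _add_gaussians(
        gcg,
        [fid_times[k] for k in GCG_FIDUCIALS],
        [params.gcg_amps[k] for k in GCG_FIDUCIALS],
        [params.gcg_widths[k] for k in GCG_FIDUCIALS],
        fs,
    )
    fiducials = {k: int(round(v * fs)) for k, v in fid_times.items()}
    return {"ecg": ecg, "scg": scg, "gcg": gcg, "fiducials": fiducials, "fs": fs}


def _draw_rr_series(params: CardiacTemplateParams, duration_s: float, rng) -> np.ndarray:
    n_max = int(np.ceil(duration_s / max(params.mean_rr * (1 - 3 * params.rr_cv), 0.3))) + 4
    rr = rng.normal(params.mean_rr, params.rr_cv * params.mean_rr, size=n_max)
    return np.clip(rr, max(0.3, 0.5 * params.mean_rr), 2.0)


def _render_cardiac(params: CardiacTemplateParams, fs, n, rng):
    """Full-length canonical ECG/SCG/GCG traces plus per-beat fiducials."""
    duration = n / fs
    rr = _draw_rr_series(params, duration, rng)
    r_times = 0.4 + np.concatenate([[0.0], np.cumsum(rr)])
    ecg = np.zeros(n)
    scg = np.zeros(n)
    gcg = np.zeros(n)
    beats = []
    margin = 0.55  # keep the whole cycle inside the recording
    for i, r in enumerate(r_times):
        if r > duration - margin:
            break
        rr_i = rr[i] if i < len(rr) else params.mean_rr
        offs = params.fiducial_offsets(rr_i)
        fid_times = {k: r + v for k, v in offs.items()}
        _add_gaussians(
            ecg,
            [fid_times[k] for k in ECG_FIDUCIALS],
            [params.ecg_amps[k] for k in ECG_FIDUCIALS],
            [params.ecg_widths[k] for k in ECG_FIDUCIALS],
            fs,
        )
        _add_gaussians(
            scg,
            [fid_times[k] for k in SCG_FIDUCIALS],
            [params.scg_amps[k] for k in SCG_FIDUCIALS],
            [params.scg_widths[k] for k in SCG_FIDUCIALS],
            fs,
        )
        _add_gaussians(
            gcg,
            [fid_times[k] for k in GCG_FIDUCIALS],
            [params.gcg_amps[k] for k in GCG_FIDUCIALS],
            [params.gcg_widths[k] for k in GCG_FIDUCIALS],
            fs,
        )
        beats.append({k: int(round(v * fs)) for k, v in fid_times.items()})
    return ecg, scg, gcg, beats


# ------------------------------------------------------------------ artifacts

def _band_limited_noise(n, fs, band, rms, rng):
    if rms == 0.0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y * (rms / max(np.std(y), 1e-12))


def generate_motion_artifact(
    profile: MotionProfile, fs: float, duration_s: float, seed_or_rng
) -> np.ndarray:
    """Clean per-pad artifact series, shape (4 pads, 6 axes, n samples).

    Axis order follows the layout convention Acc.X, Acc.Y, Acc.Z, Rot.X,
    Rot.Y, Rot.Z.  Deterministic for a fixed seed; the spectral peak of a
    locomotion artifact sits at the profile's step frequency.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    gains = [profile.acc_axis_gains[a] for a in AXES] + [
        profile.rot_axis_gains[a] for a in AXES
    ]
    out = np.zeros((4, 6, n))
    for p in range(4):
        pg = profile.per_pad_gain[p]
        for ax in range(6):
            g = gains[ax] * pg
            x = np.zeros(n)
            if profile.step_frequency > 0 and profile.base_amplitude > 0:
                for h in range(1, profile.n_harmonics + 1):
                    amp = profile.base_amplitude * profile.harmonic_decay ** (h - 1)
                    phase = rng.uniform(0, 2 * np.pi)
                    x += amp * g * np.sin(2 * np.pi * h * profile.step_frequency * t + phase)
            x += g * _band_limited_noise(n, fs, profile.noise_band, profile.broadband_noise_level, rng)
            out[p, ax] = x
    return out


# ------------------------------------------------------------------ recordings

def generate_recording(
    template: CardiacTemplateParams | None = None,
    phenotype: DiseasePhenotype | str = "normal",
    motion_schedule: list[tuple[str, float]] | None = None,
    layout: ChannelLayout | None = None,
    fs: float = 200.0,
    seed: int | np.random.Generator = 0,
    config: GeneratorConfig | None = None,
    profiles: dict[str, MotionProfile] | None = None,
    subject_id: str = "synthetic",
) -> TrimodalRecording:
    """Synthesize a full five-pad trimodal recording with ground truth.

    Pad-5 mechanical channels carry the cardiac SCG/GCG waveforms plus a
    weighted mixture of the compensation pads' artifacts; pads 1-4 carry
    artifact, a configurable cardiac leakage fraction, and sensor noise.
    Annotations hold per-beat fiducial indices, motion-state intervals
    that tile the duration, the mixing weights, and the disease label;
    ``annotations.extras["components"]`` additionally keeps the clean
    cardiac and artifact components of pad 5 for end-to-end evaluation.
    """
    if template is None:
        template = CardiacTemplateParams()
    if isinstance(phenotype, str):
        phenotype = PHENOTYPES[phenotype]
    params = phenotype.apply(template)
    if motion_schedule is None:
        motion_schedule = [("sitting", 120.0)]
    if not motion_schedule:
        raise ValueError("motion_schedule must contain at least one state")
    if any(d <= 0 for _, d in motion_schedule):
        raise ValueError("schedule durations must be positive")
    if layout is None:
        layout = ChannelLayout()
    if config is None:
        config = GeneratorConfig()
    if profiles is None:
        profiles = default_motion_profiles()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    duration = float(sum(d for _, d in motion_schedule))
    n = int(round(duration * fs))

    ecg, scg, gcg, beats = _render_cardiac(params, fs, n, rng)

    # artifact per state span, concatenated along time
    art = np.zeros((4, 6, n))
    intervals = []
    t0 = 0.0
    for state, dur in motion_schedule:
        if state not in profiles:
            raise ValueError(f"unknown motion state {state!r}")
        i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
        if i1 > i0:
            art[:, :, i0:i1] = generate_motion_artifact(
                profiles[state], fs, (i1 - i0) / fs, rng
            )
        intervals.append((state, t0, t0 + dur))
        t0 += dur

    w = np.asarray(config.mixing_weights, dtype=float)
    pad5_art = np.einsum("p,pan->an", w, art)

    scg_gains = np.array([params.scg_axis_gains[a] for a in AXES])
    gcg_gains = np.array([params.gcg_axis_gains[a] for a in AXES])
    pad5_cardiac = np.concatenate(
        [scg_gains[:, None] * scg[None, :], gcg_gains[:, None] * gcg[None, :]], axis=0
    )

    data = np.zeros((layout.n_channels, n))
    noise = config.sensor_noise_mech
    comp_pads = layout.compensation_pads
    for j, pad in enumerate(comp_pads):
        idx = [layout.channel_index(c) for c in layout.pad_channels(pad)]
        leak = config.leak_fractions[j % len(config.leak_fractions)]
        data[idx] = art[j] + leak * pad5_cardiac
        if noise > 0:
            data[idx] += noise * rng.standard_normal((6, n))
    acq_idx = [layout.channel_index(c) for c in layout.pad_channels(layout.acquisition_pad)]
    data[acq_idx] = pad5_cardiac + pad5_art
    if noise > 0:
        data[acq_idx] += noise * rng.standard_normal((6, n))
    for ch in layout.ecg_channels:
        e = ecg.copy()
        if config.sensor_noise_ecg > 0:
            e = e + config.sensor_noise_ecg * rng.standard_normal(n)
        if config.drift_amplitude > 0:
            e = e + config.drift_amplitude * np.sin(
                2 * np.pi * config.drift_frequency * np.arange(n) / fs
                + rng.uniform(0, 2 * np.pi)
            )
        data[layout.channel_index(ch)] = e

    ann = Annotations(
        beats=beats,
        state_intervals=intervals,
        mixing_weights=config.weights_for_axes(),
        disease_label=phenotype.label,
        extras={
            "components": {
                "pad5_cardiac": pad5_cardiac,
                "pad5_artifact": pad5_art,
                "ecg_clean": ecg,
            }
        },
    )
    return TrimodalRecording(
        data=data, sampling_rate=fs, layout=layout, annotations=ann, subject_id=subject_id
    )


def template_for_state(state: str, base: CardiacTemplateParams | None = None) -> CardiacTemplateParams:
    """Template with the heart-rate preset of a motion state (60-150 bpm)."""
    if base is None:
        base = CardiacTemplateParams()
    hr = MOTION_STATE_HR[state]
    cv = {"sitting": 0.05, "walking": 0.04, "jogging": 0.03, "running": 0.02}[state]
    return replace(base, mean_rr=60.0 / hr, rr_cv=cv)
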