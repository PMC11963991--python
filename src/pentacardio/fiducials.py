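"""Beat detection, trimodal fiducial extraction, and cardiac timing metrics.

ECG R peaks are found with a Pan-Tompkins-style detector (band-pass,
squared derivative, moving-window integration, adaptive threshold, 200-ms
refractory); Q/S/T/P are located in windows relative to R.  The SCG and
GCG fiducials are ECG-gated: each mechanical fiducial is searched in a
configured window after the R peak, and a beat is flagged invalid for a
fiducial whose window holds no qualifying extremum.  All thresholds are
relative, so fiducial positions are invariant to amplitude scaling.

Conventions (configurable): EMD = Q -> MC, PEP = Q -> AO, LVET = AO -> AC;
SDS1 and SDgJ are the standard deviations of the beat-to-beat MC and g_J
intervals, the mechanical analogs of SDRR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import TrimodalRecording

ECG_KEYS = ("P", "Q", "R", "S", "T")
SCG_KEYS = ("MC", "AO", "AC", "MO")
GCG_KEYS = ("gI", "gJ", "gK", "gL")

DEFAULT_SCG_AXIS = "Acc.Z"
DEFAULT_GCG_AXIS = "Rot.Y"


@dataclass
class SearchWindows:
    """Post-R search windows (s) for the mechanical fiducials."""

    early_end: float = 0.060  # MC / g_I upper bound after R
    mid_end: float = 0.150  # AO / g_J upper bound after R
    late_start: float = 0.200  # AC / g_K lower bound after R
    late_end: float = 0.500  # AC / g_K upper bound after R
    tail_len: float = 0.150  # MO / g_L window after AC
    min_gap: float = 0.020  # enforced spacing between paired fiducials
    amp_fraction: float = 0.15  # validity threshold vs the median beat amplitude


@dataclass
class BeatFiducials:
    """Per-beat fiducial sample indices with validity flags."""

    fs: float
    beats: list[dict[str, int]] = field(default_factory=list)
    valid: list[dict[str, bool]] = field(default_factory=list)

    def __post_init__(self):
        r = [b["R"] for b in self.beats if "R" in b]
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("R indices must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    def times(self, key: str) -> np.ndarray:
        """Times (s) of one fiducial across beats where it is valid."""
        return np.array(
            [b[key] / self.fs for b, v in zip(self.beats, self.valid) if v.get(key)]
        )

    def interval(self, a: str, b: str) -> np.ndarray:
        """Per-beat interval b - a (s) over beats where both are valid."""
        out = []
        for beat, v in zip(self.beats, self.valid):
            if v.get(a) and v.get(b):
                out.append((beat[b] - beat[a]) / self.fs)
        return np.array(out)

    def merge(self, other: "BeatFiducials") -> "BeatFiducials":
        """Join fiducial sets detected on different channels, beat by beat."""
        if other.n_beats != self.n_beats:
            raise ValueError("beat counts differ; detect on the same R times")
        beats = [dict(a, **b) for a, b in zip(self.beats, other.beats)]
        valid = [dict(a, **b) for a, b in zip(self.valid, other.valid)]
        return BeatFiducials(self.fs, beats, valid)


# ------------------------------------------------------------------ ECG

def detect_r_peaks(ecg: np.ndarray, fs: float, refractory_s: float = 0.2) -> np.ndarray:
    """R-peak sample indices (Pan-Tompkins-style energy detector)."""
    ecg = np.asarray(ecg, float)
    if len(ecg) < 3 * fs:
        raise ValueError("need at least 3 s of ECG")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    sos = sps.butter(2, [5.0, min(25.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, ecg)
    e = np.gradient(y) ** 2
    w = max(int(round(0.15 * fs)), 1)
    integ = np.convolve(e, np.ones(w) / w, mode="same")
    peak = float(integ.max())
    if peak <= 0.0 or not np.isfinite(peak):
        return np.array([], dtype=int)
    thr = 0.25 * np.percentile(integ, 99.5)
    locs, _ = sps.find_peaks(integ, height=thr, distance=max(int(refractory_s * fs), 1))
    # refine to the extremum of the raw ECG near each energy peak
    half = int(round(0.06 * fs))
    out = []
    sign = 1.0 if abs(y.max()) >= abs(y.min()) else -1.0
    for loc in locs:
        i0, i1 = max(loc - half, 0), min(loc + half + 1, len(ecg))
        out.append(i0 + int(np.argmax(sign * ecg[i0:i1])))
    out = np.unique(out)
    keep = np.concatenate([[True], np.diff(out) >= refractory_s * fs])
    return out[keep].astype(int)


def detect_ecg_fiducials(ecg: np.ndarray, fs: float) -> BeatFiducials:
    """P/Q/R/S/T indices per beat; flat or empty signals give zero beats."""
    ecg = np.asarray(ecg, float)
    r = detect_r_peaks(ecg, fs)
    beats: list[dict[str, int]] = []
    valid: list[dict[str, bool]] = []
    if len(r) == 0:
        return BeatFiducials(fs, beats, valid)
    med_rr = np.median(np.diff(r)) / fs if len(r) > 1 else 0.8

    def win(i0, i1):
        return max(i0, 0), min(i1, len(ecg))

    for k, ri in enumerate(r):
        b = {"R": int(ri)}
        v = {"R": True}
        i0, i1 = win(ri - int(0.060 * fs), ri - int(0.005 * fs))
        if i1 > i0:
            b["Q"] = i0 + int(np.argmin(ecg[i0:i1]))
            v["Q"] = True
        i0, i1 = win(ri + int(0.005 * fs), ri + int(0.060 * fs))
        if i1 > i0:
            b["S"] = i0 + int(np.argmin(ecg[i0:i1]))
            v["S"] = True
        t_hi = min(0.6 * med_rr, 0.45)
        i0, i1 = win(ri + int(0.100 * fs), ri + int(t_hi * fs))
        next_r = r[k + 1] if k + 1 < len(r) else len(ecg)
        i1 = min(i1, next_r - int(0.05 * fs))
        if i1 > i0:
            b["T"] = i0 + int(np.argmax(ecg[i0:i1]))
            v["T"] = True
        i0, i1 = win(ri - int(0.220 * fs), ri - int(0.070 * fs))
        if i1 > i0:
            b["P"] = i0 + int(np.argmax(ecg[i0:i1]))
            v["P"] = True
        beats.append(b)
        valid.append(v)
    return BeatFiducials(fs, beats, valid)


# ------------------------------------------------------------------ SCG / GCG

def _gated_mech_fiducials(
    x: np.ndarray,
    fs: float,
    r_indices: np.ndarray,
    keys: tuple[str, str, str, str],
    windows: SearchWindows,
) -> BeatFiducials:
    x = np.asarray(x, float)
    r_indices = np.asarray(r_indices, int)
    if r_indices.size == 0:
        raise ValueError("mechanical fiducial detection needs R times (ECG-gated)")
    k_first, k_open, k_close, k_last = keys
    n = len(x)
    # robust per-recording amplitude scale from the post-R regions
    ref_amps = []
    for ri in r_indices:
        i0, i1 = ri, min(ri + int(windows.mid_end * fs) + 1, n)
        if i1 > i0:
            ref_amps.append(np.max(np.abs(x[i0:i1])))
    scale = np.median(ref_amps) if ref_amps else 0.0
    thr = windows.amp_fraction * scale

    beats, valid = [], []
    gap = max(int(windows.min_gap * fs), 1)
    for k, ri in enumerate(r_indices):
        next_r = r_indices[k + 1] if k + 1 < len(r_indices) else n
        b: dict[str, int] = {"R": int(ri)}
        v: dict[str, bool] = {"R": True}

        def search_max(i0, i1, key):
            i0, i1 = max(i0, 0), min(i1, n)
            if i1 <= i0:
                v[key] = False
                return None
            j = i0 + int(np.argmax(x[i0:i1]))
            if x[j] < thr:
                v[key] = False
                return None
            b[key] = j
            v[key] = True
            return j

        # the opening peak (AO / g_J) is the dominant deflection: find it first
        j_open = search_max(ri + gap, ri + int(windows.mid_end * fs) + 1, k_open)
        # the first peak (MC / g_I) precedes it
        hi = (j_open - gap + 1) if j_open is not None else ri + int(windows.early_end * fs) + 1
        search_max(ri, min(hi, ri + int(windows.early_end * fs) + 1), k_first)
        # closure peak (AC / g_K), clamped away from the next beat
        j_close = search_max(
            ri + int(windows.late_start * fs),
            min(ri + int(windows.late_end * fs) + 1, next_r - int(0.02 * fs)),
            k_close,
        )
        if j_close is not None:
            search_max(
                j_close + gap,
                min(j_close + int(windows.tail_len * fs) + 1, next_r),
                k_last,
            )
        else:
            v[k_last] = False
        beats.append(b)
        valid.append(v)
    return BeatFiducials(fs, beats, valid)


def detect_scg_fiducials(
    scg: np.ndarray,
    fs: float,
    r_indices: np.ndarray,
    windows: SearchWindows | None = None,
) -> BeatFiducials:
    """MC/AO/AC/MO per beat on the SCG trace, gated by the ECG R peaks."""
    return _gated_mech_fiducials(scg, fs, r_indices, SCG_KEYS, windows or SearchWindows())


def detect_gcg_fiducials(
    gcg: np.ndarray,
    fs: float,
    r_indices: np.ndarray,
    windows: SearchWindows | None = None,
) -> BeatFiducials:
    """g_I/g_J/g_K/g_L per beat on the GCG trace, gated by the ECG R peaks."""
    return _gated_mech_fiducials(gcg, fs, r_indices, GCG_KEYS, windows or SearchWindows())


def detect_trimodal_fiducials(
    rec: TrimodalRecording,
    scg_axis: str = DEFAULT_SCG_AXIS,
    gcg_axis: str = DEFAULT_GCG_AXIS,
    windows: SearchWindows | None = None,
) -> BeatFiducials:
    """ECG + SCG + GCG fiducials of a recording, merged per beat."""
    layout = rec.layout
    ecg = rec.channel(layout.ecg_channels[0])
    ef = detect_ecg_fiducials(ecg, rec.sampling_rate)
    if ef.n_beats == 0:
        return ef
    r = np.array([b["R"] for b in ef.beats])
    pad = layout.acquisition_pad
    sf = detect_scg_fiducials(
        rec.channel(f"Pad{pad}.{scg_axis}"), rec.sampling_rate, r, windows
    )
    gf = detect_gcg_fiducials(
        rec.channel(f"Pad{pad}.{gcg_axis}"), rec.sampling_rate, r, windows
    )
    return ef.merge(sf).merge(gf)


# ------------------------------------------------------------------ metrics

@dataclass
class CardiacMetrics:
    """Beat-averaged cardiac timing metrics (intervals in seconds)."""

    hr: float = np.nan  # bpm
    qt: float = np.nan
    sdrr: float = np.nan
    mc_mo: float = np.nan
    sds1: float = np.nan
    gi_gl: float = np.nan
    sdgj: float = np.nan
    emd: float = np.nan
    pep: float = np.nan
    lvet: float = np.nan
    pep_over_lvet: float = np.nan
    n_beats: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            k: float(getattr(self, k))
            for k in (
                "hr", "qt", "sdrr", "mc_mo", "sds1", "gi_gl", "sdgj",
                "emd", "pep", "lvet", "pep_over_lvet",
            )
        }


def _mean(x: np.ndarray) -> float:
    return float(np.mean(x)) if x.size else np.nan


def compute_metrics(fid: BeatFiducials, fs: float | None = None) -> CardiacMetrics:
    """HR/QT/SDRR plus mechanical and electromechanical timing metrics.

    HR = 60/mean(RR); SDRR = SD of RR; QT = mean(T-Q); MC_MO = mean(MO-MC);
    gI_gL = mean(gL-gI); EMD = mean(MC-Q); PEP = mean(AO-Q);
    LVET = mean(AC-AO); SDS1/SDgJ = SD of the beat-to-beat MC/g_J
    intervals.  Metrics with fewer than the required valid beats come back
    as NaN with a warning.
    """
    fs = fs or fid.fs
    m = CardiacMetrics(n_beats=fid.n_beats)
    r = fid.times("R")
    if len(r) < 2:
        warnings.warn("fewer than 2 beats: rhythm metrics unavailable", RuntimeWarning)
        return m
    rr = np.diff(r)
    m.hr = 60.0 / float(np.mean(rr))
    m.sdrr = float(np.std(rr, ddof=0))
    m.qt = _mean(fid.interval("Q", "T"))
    m.mc_mo = _mean(fid.interval("MC", "MO"))
    m.gi_gl = _mean(fid.interval("gI", "gL"))
    m.emd = _mean(fid.interval("Q", "MC"))
    m.pep = _mean(fid.interval("Q", "AO"))
    m.lvet = _mean(fid.interval("AO", "AC"))
    if np.isfinite(m.lvet) and m.lvet > 0 and np.isfinite(m.pep):
        m.pep_over_lvet = m.pep / m.lvet
    mc = fid.times("MC")
    if len(mc) >= 3:
        m.sds1 = float(np.std(np.diff(mc), ddof=0))
    gj = fid.times("gJ")
    if len(gj) >= 3:
        m.sdgj = float(np.std(np.diff(gj), ddof=0))
    return m


def beat_table(fid: BeatFiducials) -> pd.DataFrame:
    """Per-beat fiducial indices (NaN where invalid) as a DataFrame."""
    keys = ECG_KEYS + SCG_KEYS + GCG_KEYS
    rows = []
    for b, v in zip(fid.beats, fid.valid):
        rows.append({k: (b[k] if v.get(k) else np.nan) for k in keys if k in b or k in v})
    return pd.DataFrame(rows)


def segment_metrics(
    rec: TrimodalRecording,
    window_s: float = 10.0,
    scg_axis: str = DEFAULT_SCG_AXIS,
    gcg_axis: str = DEFAULT_GCG_AXIS,
) -> pd.DataFrame:
    """Metrics aggregated per window; beats are assigned by their R time."""
    fid = detect_trimodal_fiducials(rec, scg_axis, gcg_axis)
    fs = rec.sampling_rate
    rows = []
    n_win = int(rec.duration_s // window_s)
    for w in range(n_win):
        t0, t1 = w * window_s, (w + 1) * window_s
        sel = [
            (b, v)
            for b, v in zip(fid.beats, fid.valid)
            if t0 <= b["R"] / fs < t1
        ]
        sub = BeatFiducials(fs, [b for b, _ in sel], [v for _, v in sel])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(sub)
        rows.append({"start_s": t0, "n_beats": sub.n_beats, **m.as_dict()})
    return pd.DataFrame(rows)
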