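"""Recording and segment containers plus sliding-window segmentation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .layout import ChannelLayout

DEFAULT_FS = 200.0
DEFAULT_WINDOW_S = 10.0


@dataclass
class Annotations:
    """Ground truth attached to a synthetic recording.

    ``beats`` is a list of per-beat dicts mapping fiducial name (R, Q, T,
    MC, AO, ... gL) to a sample index; ``state_intervals`` is a list of
    ``(state, start_s, end_s)`` tiles covering the full duration;
    ``mixing_weights`` are the per-axis pad-mixing weights used to build
    the acquisition-pad artifact; ``disease_label`` is one of
    normal/afib/mi/hf.
    """

    beats: list[dict[str, int]] = field(default_factory=list)
    state_intervals: list[tuple[str, float, float]] = field(default_factory=list)
    mixing_weights: dict[str, list[float]] | None = None
    disease_label: str | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        # only JSON-safe extras survive serialization (ground-truth signal
        # components are kept in memory but not written out)
        def _safe(v):
            if isinstance(v, (str, int, float, bool, type(None))):
                return True
            if isinstance(v, (list, tuple)):
                return all(_safe(x) for x in v)
            if isinstance(v, dict):
                return all(isinstance(k, str) and _safe(x) for k, x in v.items())
            return False

        extras = {k: v for k, v in self.extras.items() if _safe(v)}
        return {
            "beats": [{k: int(v) for k, v in b.items()} for b in self.beats],
            "state_intervals": [
                [s, float(a), float(b)] for s, a, b in self.state_intervals
            ],
            "mixing_weights": self.mixing_weights,
            "disease_label": self.disease_label,
            "extras": extras,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Annotations":
        return cls(
            beats=[{k: int(v) for k, v in b.items()} for b in d.get("beats", [])],
            state_intervals=[
                (s, float(a), float(b)) for s, a, b in d.get("state_intervals", [])
            ],
            mixing_weights=d.get("mixing_weights"),
            disease_label=d.get("disease_label"),
            extras=d.get("extras", {}),
        )


@dataclass
class TrimodalRecording:
    """A multichannel recording: channels x time, one shared sampling rate."""

    data: np.ndarray
    sampling_rate: float = DEFAULT_FS
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    annotations: Annotations | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x time")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels, layout expects "
                f"{self.layout.n_channels}"
            )
        if self.annotations is not None:
            dur = self.duration_s
            for state, a, b in self.annotations.state_intervals:
                if not (0 <= a <= b <= dur + 1e-9):
                    raise ValueError(f"state interval {state} outside recording")
            n = self.n_samples
            for beat in self.annotations.beats:
                for name, idx in beat.items():
                    if not 0 <= idx < n:
                        raise ValueError(f"fiducial {name}@{idx} outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.layout.channel_index(name)]

    def channels(self, names) -> np.ndarray:
        idx = [self.layout.channel_index(n) for n in names]
        return self.data[idx]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class Segment:
    """One fixed-length window of all channels (default 10 s = 2000 samples)."""

    data: np.ndarray
    start_time: float
    sampling_rate: float
    layout: ChannelLayout
    window_s: float = DEFAULT_WINDOW_S
    motion_state: str | None = None
    disease_label: str | None = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.layout.channel_index(name)]

    def channels(self, names) -> np.ndarray:
        idx = [self.layout.channel_index(n) for n in names]
        return self.data[idx]


def window_samples(window_s: float, fs: float) -> int:
    """Window length in samples; non-integral products round to nearest."""
    w = window_s * fs
    n = int(round(w))
    if n <= 0:
        raise ValueError("window shorter than one sample")
    return n


def _majority_state(
    intervals: list[tuple[str, float, float]], t0: float, t1: float
) -> str | None:
    """Label with the largest overlap; ties go to the earlier-starting interval."""
    best, best_ov, best_start = None, 0.0, np.inf
    for state, a, b in intervals:
        ov = min(b, t1) - max(a, t0)
        if ov > best_ov + 1e-12 or (abs(ov - best_ov) <= 1e-12 and a < best_start and ov > 0):
            best, best_ov, best_start = state, ov, a
    return best


def segment_recording(
    rec: TrimodalRecording,
    window_s: float = DEFAULT_WINDOW_S,
    stride_s: float | None = None,
) -> list[Segment]:
    """Slice a recording into fixed-length windows.

    The default stride equals the window (non-overlapping 10-s segments).
    A recording of N samples yields ``floor((N - W) / S) + 1`` segments
    (0 when N < W).  Motion-state and disease labels are carried over from
    the annotations; the motion state of a segment is the annotated state
    with majority overlap.
    """
    if window_s <= 0 or (stride_s is not None and stride_s <= 0):
        raise ValueError("window_s and stride_s must be positive")
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if stride_s is None:
        stride_s = window_s
    fs = rec.sampling_rate
    W = window_samples(window_s, fs)
    S = window_samples(stride_s, fs)
    N = rec.n_samples
    if N < W:
        return []
    ann = rec.annotations
    segments = []
    for k in range((N - W) // S + 1):
        i0 = k * S
        t0 = i0 / fs
        state = None
        if ann is not None and ann.state_intervals:
            state = _majority_state(ann.state_intervals, t0, t0 + W / fs)
        segments.append(
            Segment(
                data=rec.data[:, i0 : i0 + W].copy(),
                start_time=t0,
                sampling_rate=fs,
                layout=rec.layout,
                window_s=window_s,
                motion_state=state,
                disease_label=ann.disease_label if ann is not None else None,
            )
        )
    return segments
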