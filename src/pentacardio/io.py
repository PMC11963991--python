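"""Recording I/O: CSV and EDF round trips, JSON ground truth, YAML config.

CSV stores one ``time`` column in seconds plus one column per channel and
is lossless.  EDF is the standard 16-bit biosignal container; no installed
library writes EDF, so a minimal writer/reader for the classic EDF layout
(one fixed-rate int16 stream per channel) lives here.  Round trips through
EDF are exact up to the 16-bit quantization step implied by the declared
physical range.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .layout import ChannelLayout
from .recording import Annotations, TrimodalRecording

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767


# ---------------------------------------------------------------- CSV

def write_csv(rec: TrimodalRecording, path) -> None:
    df = pd.DataFrame(rec.data.T, columns=list(rec.layout.channels))
    df.insert(0, "time", rec.times)
    df.to_csv(path, index=False, float_format="%.9g")


def read_csv(path, layout: ChannelLayout | None = None) -> TrimodalRecording:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("CSV recording needs a 'time' column in seconds")
    t = df["time"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("recording too short")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("unsupported input: non-uniform sampling")
    fs = 1.0 / dt[0]
    names = [c for c in df.columns if c != "time"]
    if layout is None:
        layout = ChannelLayout()
    layout.validate_names(names)
    return TrimodalRecording(
        data=df[names].to_numpy(float).T, sampling_rate=round(fs, 6), layout=layout
    )


# ---------------------------------------------------------------- EDF

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:n]
    return b + b" " * (n - len(b))


def _num(x, n: int) -> bytes:
    s = f"{x:.10g}"[:n] if isinstance(x, float) else str(x)[:n]
    return _pad(s, n)


def write_edf(rec: TrimodalRecording, path) -> None:
    """Write classic EDF: 1-s data records of int16 samples per channel.

    The physical range of each channel is taken from the data (slightly
    widened), which fixes the quantization step at range/65535.  The
    sampling rate must be a positive integer; recordings whose length is
    not a whole number of seconds are edge-padded to fill the last record.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    data = rec.data
    n = data.shape[1]
    n_rec = int(np.ceil(n / spr))
    if n_rec * spr != n:
        pad = np.repeat(data[:, -1:], n_rec * spr - n, axis=1)
        data = np.hstack([data, pad])
    ns = data.shape[0]
    names = rec.layout.channels

    pmins, pmaxs, scaled = [], [], []
    for ch in range(ns):
        lo, hi = float(data[ch].min()), float(data[ch].max())
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        span = hi - lo
        lo, hi = lo - 0.001 * span, hi + 0.001 * span
        pmins.append(lo)
        pmaxs.append(hi)
        dig = np.round(
            (data[ch] - lo) / (hi - lo) * (_EDF_DIG_MAX - _EDF_DIG_MIN) + _EDF_DIG_MIN
        ).astype("<i2")
        scaled.append(dig)

    header_bytes = 256 + ns * 256
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad(f"subject {rec.subject_id}" if rec.subject_id else "X", 80))
        f.write(_pad("pentacardio recording", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_num(header_bytes, 8))
        f.write(_pad("", 44))
        f.write(_num(n_rec, 8))
        f.write(_num(1, 8))
        f.write(_num(ns, 4))
        for field, width in [
            ([_pad(nm, 16) for nm in names], 16),
            ([_pad("", 80)] * ns, 80),
            ([_pad(rec.layout.unit(nm), 8) for nm in names], 8),
            ([_num(float(p), 8) for p in pmins], 8),
            ([_num(float(p), 8) for p in pmaxs], 8),
            ([_num(_EDF_DIG_MIN, 8)] * ns, 8),
            ([_num(_EDF_DIG_MAX, 8)] * ns, 8),
            ([_pad("", 80)] * ns, 80),
            ([_num(spr, 8)] * ns, 8),
            ([_pad("", 32)] * ns, 32),
        ]:
            for b in field:
                f.write(b)
        for r in range(n_rec):
            for ch in range(ns):
                f.write(scaled[ch][r * spr : (r + 1) * spr].tobytes())


def read_edf(path, layout: ChannelLayout | None = None) -> TrimodalRecording:
    with open(path, "rb") as f:
        raw = f.read()
    n_rec = int(raw[236:244].decode().strip())
    dur = float(raw[244:252].decode().strip())
    ns = int(raw[252:256].decode().strip())
    off = 256

    def fields(width):
        nonlocal off
        out = [raw[off + i * width : off + (i + 1) * width].decode().strip() for i in range(ns)]
        off += ns * width
        return out

    labels = fields(16)
    fields(80)  # transducer
    fields(8)  # physical dimension
    pmins = [float(x) for x in fields(8)]
    pmaxs = [float(x) for x in fields(8)]
    dmins = [float(x) for x in fields(8)]
    dmaxs = [float(x) for x in fields(8)]
    fields(80)  # prefiltering
    sprs = [int(x) for x in fields(8)]
    fields(32)
    if len(set(sprs)) != 1:
        raise ValueError("unsupported input: channels have mixed sampling rates")
    spr = sprs[0]
    fs = spr / dur
    if layout is None:
        layout = ChannelLayout()
    layout.validate_names(labels)

    body = np.frombuffer(raw[off:], dtype="<i2")
    body = body[: n_rec * ns * spr].reshape(n_rec, ns, spr)
    data = np.empty((ns, n_rec * spr))
    for ch in range(ns):
        gain = (pmaxs[ch] - pmins[ch]) / (dmaxs[ch] - dmins[ch])
        data[ch] = (body[:, ch, :].reshape(-1) - dmins[ch]) * gain + pmins[ch]
    return TrimodalRecording(data=data, sampling_rate=fs, layout=layout)


def edf_quantization_step(phys_min: float, phys_max: float) -> float:
    """Physical value of one 16-bit digital step for a declared range."""
    return (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)


# ---------------------------------------------------------------- front door

def write_recording(rec: TrimodalRecording, path, format: str | None = None) -> None:
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "csv":
        write_csv(rec, path)
    elif fmt == "edf":
        write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (csv or edf)")


def read_recording(
    path, format: str | None = None, layout: ChannelLayout | None = None
) -> TrimodalRecording:
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "csv":
        return read_csv(path, layout)
    if fmt == "edf":
        return read_edf(path, layout)
    raise ValueError(f"unknown format {fmt!r} (csv or edf)")


# ---------------------------------------------------------------- JSON / YAML

def write_annotations(ann: Annotations, path) -> None:
    with open(path, "w") as f:
        json.dump(ann.to_dict(), f, indent=1)


def read_annotations(path) -> Annotations:
    with open(path) as f:
        return Annotations.from_dict(json.load(f))


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}
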