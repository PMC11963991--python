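"""Signal power, SNR, and transmission-rate utilities."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps


def compute_snr(signal_power: float | np.ndarray, noise_power: float | np.ndarray) -> float:
    """Signal-to-noise ratio in dB, ``10 * log10(P_signal / P_noise)``.

    Accepts scalar powers or power series (averaged before the ratio).
    Zero noise power returns ``inf`` with a warning rather than raising.
    """
    ps = float(np.mean(signal_power))
    pn = float(np.mean(noise_power))
    if pn < 0 or ps < 0:
        raise ValueError("powers must be nonnegative")
    if pn == 0.0:
        warnings.warn("zero noise power: SNR is infinite", RuntimeWarning)
        return np.inf
    return 10.0 * np.log10(ps / pn)


def band_power(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> float:
    """Average signal power inside ``[f_lo, f_hi]`` Hz via the periodogram.

    Uses a boxcar periodogram so that band powers over a disjoint partition
    of [0, fs/2] sum to the total power (Parseval).
    """
    if not (0 <= f_lo < f_hi <= fs / 2 + 1e-12):
        raise ValueError(f"invalid band [{f_lo}, {f_hi}] for fs={fs}")
    x = np.asarray(x, dtype=float)
    f, pxx = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    df = f[1] - f[0]
    # half-open bins [f_lo, f_hi) except the last band which closes at fs/2
    mask = (f >= f_lo - 1e-12) & (f < f_hi - 1e-12)
    if f_hi >= fs / 2 - 1e-12:
        mask |= np.isclose(f, fs / 2)
    return float(np.sum(pxx[mask]) * df)


def total_power(x: np.ndarray) -> float:
    """Mean squared value (includes DC)."""
    x = np.asarray(x, dtype=float)
    return float(np.mean(x**2))


def transmissions_per_second(fs: float = 200.0, buffer_samples: int = 20) -> float:
    """Wireless transmission rate under buffered acquisition.

    Samples are accumulated into packets of ``buffer_samples`` before each
    transmission, so the radio fires ``fs / buffer_samples`` times per
    second (10 Hz for the default 200 Hz / 20-sample buffer).
    """
    if fs <= 0 or buffer_samples <= 0:
        raise ValueError("fs and buffer_samples must be positive")
    return fs / buffer_samples
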