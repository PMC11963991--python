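"""Motion-artifact compensation by vector synthesis.

During movement the acquisition pad records cardiac mechanics superposed
with body-motion artifacts, while the four peripheral pads record (almost)
pure motion.  Under rigid-body superposition the artifact reaching the
acquisition pad is a linear combination of the reference-pad channels, so
it can be estimated per target axis by ridge-regularized least squares on
the 24 compensation-pad mechanical channels (optionally with a small
integer lag per regressor) and subtracted, leaving the raw SCG/GCG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .layout import ChannelLayout
from .recording import TrimodalRecording


@dataclass
class CompensationConfig:
    ridge: float = 1e-3  # ridge strength, scaled by mean regressor power
    fit_intercept: bool = True
    max_lag: int = 0  # symmetric lag search range in samples (<= 5 typical)


@dataclass
class CompensationModel:
    """Per-target-axis linear maps from compensation-pad channels."""

    regressor_channels: list[str]
    target_channels: list[str]
    weights: np.ndarray  # (n_targets, n_regressors)
    intercepts: np.ndarray  # (n_targets,)
    lags: np.ndarray  # (n_regressors,) integer samples, shared across targets
    config: CompensationConfig = field(default_factory=CompensationConfig)

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(np.abs(self.lags) > max(self.config.max_lag, 0)):
            raise ValueError("lag magnitude exceeds configured maximum")

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "regressor_channels": self.regressor_channels,
                    "target_channels": self.target_channels,
                    "weights": self.weights.tolist(),
                    "intercepts": self.intercepts.tolist(),
                    "lags": self.lags.tolist(),
                    "config": vars(self.config),
                },
                f,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "CompensationModel":
        with open(path) as f:
            d = json.load(f)
        return cls(
            regressor_channels=d["regressor_channels"],
            target_channels=d["target_channels"],
            weights=np.asarray(d["weights"], float),
            intercepts=np.asarray(d["intercepts"], float),
            lags=np.asarray(d["lags"], int),
            config=CompensationConfig(**d["config"]),
        )


def _interval_to_slice(interval, fs, n) -> slice:
    if interval is None:
        return slice(0, n)
    a, b = interval
    i0, i1 = int(round(a * fs)), int(round(b * fs))
    if not 0 <= i0 < i1 <= n:
        raise ValueError(f"interval {interval} outside recording")
    return slice(i0, i1)


def _shifted(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift a series by an integer lag, zero-padding the edges."""
    if lag == 0:
        return x
    y = np.zeros_like(x)
    if lag > 0:
        y[lag:] = x[:-lag]
    else:
        y[:lag] = x[-lag:]
    return y


def _design_matrix(rec, channels, sl, lags):
    X = rec.channels(channels)[:, sl].T.copy()
    for j, lag in enumerate(lags):
        if lag:
            X[:, j] = _shifted(X[:, j], int(lag))
    return X


def _solve_ridge(X, Y, ridge, fit_intercept):
    n, k = X.shape
    if fit_intercept:
        xm = X.mean(axis=0)
        ym = Y.mean(axis=0)
        Xc, Yc = X - xm, Y - ym
    else:
        xm = np.zeros(k)
        ym = np.zeros(Y.shape[1])
        Xc, Yc = X, Y
    G = Xc.T @ Xc / n
    lam = ridge * np.trace(G) / k
    A = G + lam * np.eye(k)
    if lam == 0.0:
        # unregularized: fail loudly on rank deficiency
        if np.linalg.matrix_rank(G, tol=1e-10 * max(np.trace(G), 1e-300)) < k:
            raise np.linalg.LinAlgError(
                "rank-deficient regressor matrix; use a nonzero ridge term"
            )
    W = np.linalg.solve(A, Xc.T @ Yc / n)  # (k, n_targets)
    b = ym - xm @ W
    return W.T, b


def fit_compensation(
    rec: TrimodalRecording,
    calibration_interval: tuple[float, float] | None = None,
    config: CompensationConfig | None = None,
) -> CompensationModel:
    """Fit the artifact model on a calibration interval (seconds).

    Closed-form normal equations: for each acquisition-pad mechanical
    channel, the weights minimize the ridge-regularized squared error
    against the compensation-pad channels over the interval.  When
    ``config.max_lag`` > 0, a shared integer lag per regressor is chosen
    by maximizing cross-correlation with the principal target channel.
    """
    if config is None:
        config = CompensationConfig()
    layout = rec.layout
    reg_channels = [
        c for pad in layout.compensation_pads for c in layout.pad_channels(pad)
    ]
    tgt_channels = layout.pad_channels(layout.acquisition_pad)
    sl = _interval_to_slice(calibration_interval, rec.sampling_rate, rec.n_samples)
    n = sl.stop - sl.start
    if n < 10 * len(reg_channels):
        raise ValueError(
            f"calibration interval too short: {n} samples for {len(reg_channels)} "
            "regressors (need >= 10x)"
        )

    lags = np.zeros(len(reg_channels), dtype=int)
    if config.max_lag > 0:
        Y0 = rec.channels(tgt_channels)[:, sl]
        ref = Y0[np.argmax(np.var(Y0, axis=1))]
        ref = ref - ref.mean()
        for j, ch in enumerate(reg_channels):
            x = rec.channel(ch)[sl]
            x = x - x.mean()
            scores = [
                np.abs(np.dot(_shifted(x, lag), ref))
                for lag in range(-config.max_lag, config.max_lag + 1)
            ]
            lags[j] = int(np.argmax(scores)) - config.max_lag

    X = _design_matrix(rec, reg_channels, sl, lags)
    Y = rec.channels(tgt_channels)[:, sl].T
    W, b = _solve_ridge(X, Y, config.ridge, config.fit_intercept)
    return CompensationModel(
        regressor_channels=reg_channels,
        target_channels=tgt_channels,
        weights=W,
        intercepts=b,
        lags=lags,
        config=config,
    )


def predict_artifact(
    model: CompensationModel,
    rec: TrimodalRecording,
    interval: tuple[float, float] | None = None,
) -> np.ndarray:
    """Estimated artifact on the acquisition pad, shape (6 axes, n)."""
    missing = [c for c in model.regressor_channels if c not in rec.layout.channels]
    if missing:
        raise ValueError(f"recording lacks model channels {missing[:3]}...")
    sl = _interval_to_slice(interval, rec.sampling_rate, rec.n_samples)
    X = _design_matrix(rec, model.regressor_channels, sl, model.lags)
    return (X @ model.weights.T + model.intercepts).T


def subtract_artifact(
    rec: TrimodalRecording, artifact_estimate: np.ndarray
) -> TrimodalRecording:
    """Subtract the artifact estimate from the acquisition-pad channels.

    Returns a new recording whose acquisition-pad mechanical channels are
    the compensated raw SCG/GCG; all other channels are untouched.
    """
    tgt = rec.layout.pad_channels(rec.layout.acquisition_pad)
    est = np.asarray(artifact_estimate, float)
    if est.shape != (len(tgt), rec.n_samples):
        raise ValueError(
            f"artifact estimate shape {est.shape} != ({len(tgt)}, {rec.n_samples})"
        )
    data = rec.data.copy()
    for j, ch in enumerate(tgt):
        data[rec.layout.channel_index(ch)] -= est[j]
    return TrimodalRecording(
        data=data,
        sampling_rate=rec.sampling_rate,
        layout=rec.layout,
        annotations=rec.annotations,
        subject_id=rec.subject_id,
    )


def compensate(
    rec: TrimodalRecording,
    calibration_interval: tuple[float, float] | None = None,
    config: CompensationConfig | None = None,
) -> tuple[TrimodalRecording, CompensationModel]:
    """Fit on the calibration interval and subtract over the whole recording."""
    model = fit_compensation(rec, calibration_interval, config)
    est = predict_artifact(model, rec)
    return subtract_artifact(rec, est), model


def attenuation_db(artifact_true: np.ndarray, residual: np.ndarray) -> float:
    """Artifact attenuation 10*log10(P_before / P_after) in dB."""
    p0 = float(np.mean(np.asarray(artifact_true) ** 2))
    p1 = float(np.mean(np.asarray(residual) ** 2))
    return 10.0 * np.log10(p0 / max(p1, 1e-300))
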